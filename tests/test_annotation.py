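"""Prediction unions, ortholog mapping, UTR extension, seed-site scanning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mircor.annotation import (
    CoverageTrack,
    extend_utr,
    map_orthologs,
    scan_seed_sites,
    union_predictions,
)

MIRNA = "UUCCCUUUGUCAUCCUAUGCCU"  # any mature sequence >= 8 nt works
# target-side matches, 5'->3': [m8][nt7..2][A1]
CORE6 = "AAGGGA"  # revcomp of nt 2-7 (UCCCUU)
M8 = "A"  # complement of nt 8 (U)
SITE_8MER = M8 + CORE6 + "A"


class TestUnionPredictions:
    def test_union_drops_duplicates_keeps_provenance(self):
        ps = union_predictions({"x": ["A", "B"], "y": ["B", "C"], "z": []})
        assert ps.ids == {"A", "B", "C"}
        assert ps.sources["y"] == {"B", "C"}

    def test_all_empty(self):
        assert union_predictions([[], []]).ids == frozenset()

    @given(st.lists(st.lists(st.sampled_from("ABCDEFGH"), max_size=8),
                    min_size=1, max_size=4))
    @settings(max_examples=100, derandomize=True)
    def test_matches_set_union_and_is_order_invariant(self, lists):
        ps = union_predictions(lists)
        brute = set()
        for lst in lists:
            brute |= set(lst)
        assert ps.ids == brute
        assert union_predictions(lists[::-1]).ids == ps.ids
        # idempotent: union of the union is itself
        assert union_predictions([sorted(ps.ids)]).ids == ps.ids


class TestMapOrthologs:
    MAP = pd.DataFrame(
        {
            "transcript_id": ["t1", "t2", "t3", "t4"],
            "gene_id": ["g1", "g1", "g2", "g3"],
            "ortholog_gene_id": ["H1", "H1", "H2", "H2"],
        }
    )

    def test_many_to_one_collapses(self):
        mapped, unmapped = map_orthologs(["t1", "t2"], self.MAP)
        assert mapped == ["H1"]
        assert unmapped == 0

    def test_unmapped_ids_dropped_and_counted(self):
        mapped, unmapped = map_orthologs(["t1", "missing"], self.MAP)
        assert mapped == ["H1"]
        assert unmapped == 1

    def test_matches_brute_force_graph_traversal(self):
        rng = np.random.default_rng(0)
        rows = [(f"t{i}", f"g{i % 7}", f"H{i % 5}") for i in range(30)]
        table = pd.DataFrame(rows, columns=["transcript_id", "gene_id",
                                            "ortholog_gene_id"])
        query = [f"t{i}" for i in rng.choice(40, size=15, replace=False)]
        mapped, unmapped = map_orthologs(query, table)
        expected = set()
        missing = 0
        for q in query:
            hits = [r[2] for r in rows if r[0] == q]
            if hits:
                expected.update(hits)
            else:
                missing += 1
        assert mapped == sorted(expected)
        assert unmapped == missing


def _track(depth, start=1):
    return CoverageTrack(contig="c", start=start, depth=np.asarray(depth, dtype=int))


class TestExtendUTR:
    def test_extends_through_small_gaps_stops_at_long_gap(self):
        # 300 covered bases, then a 60-base gap, then more coverage
        depth = [5] * 100 + [5] * 300 + [0] * 60 + [5] * 50
        model = extend_utr(_track(depth), "tx", annotated_end=100,
                           min_cov=2, max_gap=50)
        assert model.extension_length == 300
        assert model.extended_end == 400

    def test_gap_within_tolerance_is_bridged(self):
        depth = [5] * 100 + [5] * 30 + [0] * 50 + [5] * 20
        model = extend_utr(_track(depth), "tx", annotated_end=100,
                           min_cov=2, max_gap=50)
        assert model.extended_end == 200

    def test_zero_downstream_coverage_means_no_extension(self):
        depth = [5] * 100 + [0] * 200
        model = extend_utr(_track(depth), "tx", annotated_end=100)
        assert model.extension_length == 0

    def test_boundary_clamps_continuous_coverage(self):
        depth = [5] * 500
        model = extend_utr(_track(depth), "tx", annotated_end=100, boundary=250)
        assert model.extended_end == 250

    def test_max_extension_caps_the_walk(self):
        depth = [5] * 1000
        model = extend_utr(_track(depth), "tx", annotated_end=100, max_extension=120)
        assert model.extension_length == 120

    def test_minus_strand_walks_leftward(self):
        depth = [0] * 50 + [5] * 250
        model = extend_utr(_track(depth), "tx", annotated_end=200, strand="-")
        assert model.extended_end == 51
        assert model.extension_length == 149

    def test_annotated_end_outside_domain_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            extend_utr(_track([1] * 10), "tx", annotated_end=99)

    def test_matches_linear_scan_oracle_on_random_tracks(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            depth = (rng.random(400) < 0.7) * rng.integers(1, 9, size=400)
            min_cov, max_gap = 2, int(rng.integers(0, 8))
            model = extend_utr(_track(depth), "tx", annotated_end=50,
                               min_cov=min_cov, max_gap=max_gap, max_extension=300)
            # independent scan
            end, gap = 50, 0
            for pos in range(51, 351):
                if depth[pos - 1] >= min_cov:
                    end, gap = pos, 0
                else:
                    gap += 1
                    if gap > max_gap:
                        break
            assert model.extended_end == end

    def test_invariant_to_coverage_values_above_threshold(self):
        rng = np.random.default_rng(2)
        base = (rng.random(300) < 0.8) * 3
        a = extend_utr(_track(base), "tx", 40, min_cov=2, max_gap=5)
        boosted = np.where(base >= 2, base * 50, base)
        b = extend_utr(_track(boosted), "tx", 40, min_cov=2, max_gap=5)
        assert a.extended_end == b.extended_end


class TestScanSeedSites:
    def test_planted_site_classes(self):
        cases = {
            SITE_8MER: "8mer",
            M8 + CORE6 + "G": "7mer-m8",
            "G" + CORE6 + "A": "7mer-A1",
            "G" + CORE6 + "G": "6mer",
        }
        for flank_site, expected in cases.items():
            seq = "GGGG" + flank_site + "GGGG"
            sites = scan_seed_sites(seq, MIRNA)
            assert [s.site_class for s in sites] == [expected], flank_site

    def test_site_at_sequence_start_without_m8_context(self):
        sites = scan_seed_sites(CORE6 + "A" + "CCC", MIRNA)
        assert sites[0].site_class == "7mer-A1"
        assert sites[0].position == 1

    def test_rna_and_dna_alphabets_equivalent(self):
        seq = "GG" + SITE_8MER + "GG"
        a = scan_seed_sites(seq, MIRNA)
        b = scan_seed_sites(seq.replace("T", "U"), MIRNA.replace("U", "T"))
        assert [(s.position, s.site_class) for s in a] == \
               [(s.position, s.site_class) for s in b]

    def test_absent_motif_gives_empty_list(self):
        assert scan_seed_sites("CCCCCCCCCCCCCCCC", MIRNA) == []

    def test_three_point_mutations_abolish_the_site(self):
        # the classic seed-mutation control: mutate 3 bases of the match
        mutated = SITE_8MER[:2] + "CTC" + SITE_8MER[5:]
        assert scan_seed_sites("GGGG" + mutated + "GGGG", MIRNA) == []

    def test_duplicate_sequence_doubles_site_count(self):
        one = scan_seed_sites("GG" + SITE_8MER + "GG", MIRNA)
        two = scan_seed_sites(("GG" + SITE_8MER + "GG") * 2, MIRNA)
        assert len(two) == 2 * len(one)
        assert {s.site_class for s in two} == {s.site_class for s in one}

    def test_junction_spanning_site_flagged(self):
        seq = "GGGG" + SITE_8MER + "GGGG"
        sites = scan_seed_sites(seq, MIRNA, junction=8)  # junction inside the site
        assert sites[0].spans_junction
        sites = scan_seed_sites(seq, MIRNA, junction=len(seq))
        assert not sites[0].spans_junction

    def test_alphabet_violations_rejected(self):
        with pytest.raises(ValueError):
            scan_seed_sites("ACGTN", MIRNA)
        with pytest.raises(ValueError):
            scan_seed_sites("ACGT", "UUCCXUUUG")
        with pytest.raises(ValueError, match="8 nt"):
            scan_seed_sites("ACGTACGT", "UUCCCUU")
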