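"""Predicted-target lists, ortholog mapping, 3'UTR extension, seed scanning.

Sequence-based miRNA target predictors are human-centric, so the study
organism's transcripts must be translated through a transcript -> gene ->
human-ortholog table before prediction lists and gene-set collections can
be used. Separately, transcript annotations are frequently stale at the 3'
end: RNA-Seq coverage often continues past the annotated transcript end,
and seed-match sites in that unannotated tail are invisible to annotation-
bound scanners. This module reconstructs the 3'UTR from per-base coverage
and scans (extended) UTR sequences for canonical seed-site classes.

Seed-site nomenclature follows the field convention: the seed is miRNA
nucleotides 2-8 from the 5' end; a site in the target (read 5'->3') is

    [m8 match][matches to nt 7..2][position 1]

where an adenine opposite position 1 ('A1') and a Watson-Crick match to
nt 8 ('m8') upgrade a 6mer core (nt 2-7) to 7mer-A1, 7mer-m8 or 8mer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PredictionSet:
    """Union of one or more in-silico prediction lists, with provenance."""

    ids: frozenset[str]
    sources: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, item: str) -> bool:
        return item in self.ids

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class CoverageTrack:
    """Per-base read depth on one contig; ``start`` is the 1-based first position."""

    contig: str
    start: int
    depth: np.ndarray

    @property
    def end(self) -> int:
        """1-based inclusive last position with a defined depth."""
        return self.start + len(self.depth) - 1

    def depth_at(self, pos: int) -> int:
        """Depth at a 1-based position; zero outside the track."""
        if self.start <= pos <= self.end:
            return int(self.depth[pos - self.start])
        return 0

    @classmethod
    def from_bedgraph(cls, intervals: pd.DataFrame, contig: str) -> "CoverageTrack":
        """Expand bedGraph intervals (0-based half-open) to per-base depth."""
        sub = intervals[intervals["contig"] == contig]
        if sub.empty:
            raise ValueError(f"no coverage for contig {contig!r}")
        lo = int(sub["start"].min())  # 0-based
        hi = int(sub["end"].max())
        depth = np.zeros(hi - lo, dtype=int)
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            depth[int(s) - lo: int(e) - lo] = int(v)
        return cls(contig=contig, start=lo + 1, depth=depth)

    def to_bedgraph(self) -> pd.DataFrame:
        """Run-length-encode the depth back to bedGraph intervals."""
        rows = []
        i = 0
        d = self.depth
        while i < len(d):
            j = i
            while j < len(d) and d[j] == d[i]:
                j += 1
            if d[i] > 0:
                rows.append((self.contig, self.start - 1 + i, self.start - 1 + j, int(d[i])))
            i = j
        return pd.DataFrame(rows, columns=["contig", "start", "end", "value"])


@dataclass
class UTRModel:
    """Annotated vs coverage-supported 3' end of one transcript."""

    transcript_id: str
    annotated_end: int  # 1-based inclusive
    extended_end: int
    strand: str

    @property
    def extension_length(self) -> int:
        return abs(self.extended_end - self.annotated_end)


@dataclass
class SeedSite:
    """One seed-match occurrence within a UTR sequence."""

    position: int  # 1-based start of the matched subsequence in the UTR
    site_class: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    matched: str
    spans_junction: bool = False


def union_predictions(lists: dict[str, list[str]] | list[list[str]]) -> PredictionSet:
    """Union of prediction lists, duplicates removed, per-ID provenance retained.

    ``lists`` maps a source label to its ID list (or is a plain list of
    lists, labelled positionally).
    """
    if not isinstance(lists, dict):
        lists = {f"list_{i}": ids for i, ids in enumerate(lists)}
    sources = {label: frozenset(ids) for label, ids in lists.items()}
    union: frozenset[str] = frozenset().union(*sources.values()) if sources else frozenset()
    return PredictionSet(ids=union, sources=sources)


def map_orthologs(
    ids,
    ortholog_map: pd.DataFrame,
    from_col: str = "transcript_id",
    to_col: str = "ortholog_gene_id",
) -> tuple[list[str], int]:
    """Map IDs through the ortholog table; collapse many-to-one; drop unmapped.

    Returns ``(sorted unique mapped IDs, number of unmapped inputs)``; the
    unmapped count is also logged rather than raised, since incomplete
    ortholog tables are the normal case.
    """
    for col in (from_col, to_col):
        if col not in ortholog_map.columns:
            raise ValueError(f"ortholog map lacks column {col!r}")
    lookup: dict[str, set[str]] = {}
    for src, dst in zip(ortholog_map[from_col], ortholog_map[to_col]):
        lookup.setdefault(str(src), set()).add(str(dst))
    mapped: set[str] = set()
    unmapped = 0
    for i in ids:
        hits = lookup.get(str(i))
        if hits:
            mapped.update(hits)
        else:
            unmapped += 1
    if unmapped:
        logger.info("ortholog mapping: %d of %d IDs unmapped", unmapped, len(list(ids)) or unmapped)
    return sorted(mapped), unmapped


def extend_utr(
    coverage: CoverageTrack,
    transcript_id: str,
    annotated_end: int,
    strand: str = "+",
    min_cov: int = 2,
    max_gap: int = 50,
    max_extension: int = 5000,
    boundary: int | None = None,
) -> UTRModel:
    """Extend a transcript's 3' end along contiguous read coverage.

    Walks 3'-ward from ``annotated_end`` (increasing coordinates on '+',
    decreasing on '-') and accepts bases with depth >= ``min_cov``,
    tolerating sub-threshold runs up to ``max_gap`` bases. Stops at the
    first longer gap, after ``max_extension`` bases, or upon reaching
    ``boundary`` (e.g. the next annotated feature); the extended end is the
    last accepted covered base, clamped to the boundary.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    if min_cov < 0 or max_gap < 0 or max_extension < 0:
        raise ValueError("min_cov, max_gap and max_extension must be nonnegative")
    if not coverage.start <= annotated_end <= coverage.end:
        raise ValueError(
            f"annotated_end {annotated_end} outside coverage domain "
            f"[{coverage.start}, {coverage.end}] on {coverage.contig}"
        )
    step = 1 if strand == "+" else -1
    extended_end = annotated_end
    gap_run = 0
    pos = annotated_end + step
    while abs(pos - annotated_end) <= max_extension:
        if boundary is not None and (pos - boundary) * step > 0:
            break
        if coverage.depth_at(pos) >= min_cov:
            extended_end = pos
            gap_run = 0
        else:
            gap_run += 1
            if gap_run > max_gap:
                break
        pos += step
    return UTRModel(
        transcript_id=transcript_id,
        annotated_end=annotated_end,
        extended_end=extended_end,
        strand=strand,
    )


def _normalize_rna(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _seed_site_8mer(mirna_sequence: str) -> str:
    """The canonical 8mer site (target 5'->3') for a miRNA: revcomp(nt 2-8) + A."""
    m = _normalize_rna(mirna_sequence, "miRNA")
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    return _revcomp(m[1:8]) + "A"


def scan_seed_sites(
    utr_sequence: str,
    mirna_sequence: str,
    junction: int | None = None,
) -> list[SeedSite]:
    """Find canonical seed-match sites in a UTR sequence.

    Locates every occurrence of the 6mer core (reverse complement of miRNA
    nt 2-7) and classifies it by its flanks: a Watson-Crick match to nt 8
    immediately 5' (in the target) and/or an A opposite position 1
    immediately 3' upgrade the class. Positions are 1-based within the UTR
    and refer to the first base of the matched subsequence (including the
    m8 base when present). If ``junction`` is given (1-based index of the
    last base of the annotated UTR), sites straddling it are flagged —
    these are exactly the sites an annotation-bound scan would miss.
    """
    utr = _normalize_rna(utr_sequence, "UTR")
    m = _normalize_rna(mirna_sequence, "miRNA")
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    core6 = _revcomp(m[1:7])  # matches miRNA nt 2-7
    m8c = _revcomp(m[7])  # complement of nt 8, sits 5' of the core in the target

    sites: list[SeedSite] = []
    i = utr.find(core6)
    while i != -1:
        has_m8 = i > 0 and utr[i - 1] == m8c
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            cls, lo, hi = "8mer", i - 1, i + 7
        elif has_m8:
            cls, lo, hi = "7mer-m8", i - 1, i + 6
        elif has_a1:
            cls, lo, hi = "7mer-A1", i, i + 7
        else:
            cls, lo, hi = "6mer", i, i + 6
        spans = junction is not None and lo + 1 <= junction < hi
        sites.append(SeedSite(position=lo + 1, site_class=cls,
                              matched=utr[lo:hi], spans_junction=spans))
        i = utr.find(core6, i + 1)
    return sites


def utr_models_to_bed(models: list[UTRModel]) -> pd.DataFrame:
    """Extended-UTR intervals as BED (0-based half-open) rows."""
    rows = []
    for m in models:
        lo = min(m.annotated_end, m.extended_end)
        hi = max(m.annotated_end, m.extended_end)
        rows.append((m.transcript_id, lo - 1, hi, m.strand, m.extension_length))
    return pd.DataFrame(rows, columns=["name", "start", "end", "strand", "extension_length"])
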