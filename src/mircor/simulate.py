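"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a bulk RNA-Seq perturbation study of a single miRNA:
nine libraries in three conditions (wild type, miRNA knockdown, miRNA
over-expression, three replicates each), negative-binomial counts with a
common dispersion, and a planted set of co-regulated target transcripts
that are repressed under over-expression and derepressed under knockdown
with deliberately small fold changes — direct miRNA targets typically move
by factors of only about 1.1-1.3, which is what makes them hard for
significance-based selection and motivates the correlation approach.

Co-expression among the true targets is induced by one shared Gaussian
latent factor added on the log2 scale: each sample draws one factor value
and every target's log-mean shifts by it. This is the simplest structure
under which "targets of the same miRNA are co-expressed" holds in
simulation.

Every generator is deterministic under a fixed seed, and each returns the
ground truth needed to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import PredictionSet
from .counts import CountMatrix

_COND_ORDER = ("WT", "KD", "OE")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic perturbation study.

    Defaults describe the reference simulation used throughout the test
    suite: 5000 transcripts, 150 planted direct targets with |log2 fold
    change| between 0.15 and 0.4 (fold changes of ~1.1-1.3), a prediction
    list of 200 transcripts half of which are true targets, a shared
    latent factor (sd 0.15 on the log2 scale) that makes targets
    co-expressed, and 2000 indirect condition-responsive transcripts with
    random-signed shifts — the transcriptome-wide downstream response that
    dominates sample-level structure in a real perturbation experiment.
    Library depth (~10M counts) and dispersion (0.005) describe deep
    sequencing of pooled-embryo replicate libraries, where biological
    variability between replicates is small.
    """

    n_transcripts: int = 5000
    n_true_targets: int = 150
    n_predicted: int = 200
    overlap_fraction: float = 0.5
    baseline_log_mean: tuple[float, float] = (4.0, 1.5)  # natural-log mean, sd
    nb_dispersion: float = 0.005
    effect_log2fc_range: tuple[float, float] = (0.15, 0.4)
    latent_factor_sd: float = 0.15
    libsize_range: tuple[int, int] = (8_000_000, 12_000_000)
    n_indirect: int = 2000
    indirect_log2fc_range: tuple[float, float] = (0.1, 0.6)
    n_replicates_per_condition: int = 3
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts <= 0 or self.n_replicates_per_condition <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 < self.n_true_targets <= self.n_transcripts:
            raise ValueError("need 0 < n_true_targets <= n_transcripts")
        if self.n_predicted <= 0:
            raise ValueError("n_predicted must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.effect_log2fc_range
        if lo < 0 or hi < lo:
            raise ValueError("effect_log2fc_range must be nonnegative and ordered")
        if self.latent_factor_sd < 0:
            raise ValueError("latent_factor_sd must be nonnegative")
        if self.n_indirect < 0 or self.n_indirect + self.n_true_targets > self.n_transcripts:
            raise ValueError("n_indirect must be nonnegative and leave room for targets")
        ilo, ihi = self.indirect_log2fc_range
        if ilo < 0 or ihi < ilo:
            raise ValueError("indirect_log2fc_range must be nonnegative and ordered")
        llo, lhi = self.libsize_range
        if llo <= 0 or lhi < llo:
            raise ValueError("libsize_range must be positive and ordered")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, for recovery scoring."""

    target_ids: frozenset[str]
    effect_log2fc: pd.DataFrame  # targets x {KD, OE}; signed log2 shifts
    library_sizes: pd.Series
    expected_mean: pd.DataFrame = field(repr=False)  # NB mean per transcript/sample
    indirect_ids: frozenset[str] = frozenset()
    enriched_set_ids: frozenset[str] = frozenset()


def _transcript_ids(n: int) -> list[str]:
    return [f"TX{i:06d}" for i in range(n)]


def _sample_ids(reps: int) -> tuple[list[str], pd.Series]:
    ids, conds = [], []
    for cond in _COND_ORDER:
        for r in range(1, reps + 1):
            ids.append(f"{cond}_{r}")
            conds.append(cond)
    return ids, pd.Series(conds, index=ids, name="condition")


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SimulationTruth]:
    """Draw one negative-binomial count matrix with planted targets.

    The mean of transcript g in sample s is

        mu_gs = L_s * p_g * 2**(delta_gs + f_s * 1[g is target])

    where L_s is the library size (uniform in ``libsize_range``), p_g the
    baseline relative abundance (log-normal, renormalized to sum to one),
    delta_gs the planted signed log2 effect (-e_OE under OE, +e_KD under
    KD for direct targets; independent random-signed shifts per condition
    for the indirect responders; zero otherwise) and f_s ~ N(0,
    latent_factor_sd) the shared latent factor carried by direct targets
    only. Counts are NB with common dispersion phi (variance mu + phi
    mu^2).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    G, reps = config.n_transcripts, config.n_replicates_per_condition
    tx = _transcript_ids(G)
    samples, design = _sample_ids(reps)
    n_samples = len(samples)

    mu0, sd0 = config.baseline_log_mean
    base = np.exp(rng.normal(mu0, sd0, size=G))
    p = base / base.sum()

    libsizes = rng.integers(config.libsize_range[0], config.libsize_range[1] + 1,
                            size=n_samples)

    target_idx = rng.choice(G, size=config.n_true_targets, replace=False)
    lo, hi = config.effect_log2fc_range
    e_kd = rng.uniform(lo, hi, size=config.n_true_targets)
    e_oe = rng.uniform(lo, hi, size=config.n_true_targets)

    conds = design.values
    kd_cols = np.where(conds == "KD")[0]
    oe_cols = np.where(conds == "OE")[0]
    delta = np.zeros((G, n_samples))
    delta[np.ix_(target_idx, kd_cols)] = e_kd[:, None]
    delta[np.ix_(target_idx, oe_cols)] = -e_oe[:, None]

    # indirect condition response: downstream of the perturbation but not
    # direct targets; signed log2 shifts drawn independently per condition
    non_target = np.setdiff1d(np.arange(G), target_idx)
    indirect_idx = rng.choice(non_target, size=config.n_indirect, replace=False)
    if config.n_indirect:
        ilo, ihi = config.indirect_log2fc_range
        i_kd = rng.uniform(ilo, ihi, config.n_indirect) * rng.choice([-1, 1], config.n_indirect)
        i_oe = rng.uniform(ilo, ihi, config.n_indirect) * rng.choice([-1, 1], config.n_indirect)
        delta[np.ix_(indirect_idx, kd_cols)] = i_kd[:, None]
        delta[np.ix_(indirect_idx, oe_cols)] = i_oe[:, None]

    factor = rng.normal(0.0, config.latent_factor_sd, size=n_samples)
    shift = delta.copy()
    shift[target_idx, :] += factor[None, :]

    mu = libsizes[None, :] * p[:, None] * np.exp2(shift)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=pd.Index(tx, name="transcript_id"),
                             columns=samples)
    target_ids = [tx[i] for i in target_idx]
    truth = SimulationTruth(
        target_ids=frozenset(target_ids),
        effect_log2fc=pd.DataFrame({"KD": e_kd, "OE": -e_oe}, index=target_ids),
        library_sizes=pd.Series(libsizes, index=samples, name="library_size"),
        expected_mean=pd.DataFrame(mu, index=tx, columns=samples),
        indirect_ids=frozenset(tx[i] for i in indirect_idx),
    )
    return CountMatrix(counts_df, design), truth


def simulate_predictions(truth: SimulationTruth, config: SimulationConfig) -> PredictionSet:
    """An in-silico prediction list with controlled overlap with the truth.

    Exactly ``round(overlap_fraction * n_predicted)`` entries are true
    targets; the rest are sampled from the non-targets. Emulates the union
    of several sequence-based prediction tools, which is never a perfect
    superset of the real targets.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 1)
    n_true = round(config.overlap_fraction * config.n_predicted)
    if n_true > len(truth.target_ids):
        raise ValueError(
            f"overlap demands {n_true} true targets but only "
            f"{len(truth.target_ids)} were planted"
        )
    all_ids = _transcript_ids(config.n_transcripts)
    non_targets = [t for t in all_ids if t not in truth.target_ids]
    n_false = config.n_predicted - n_true
    if n_false > len(non_targets):
        raise ValueError("n_predicted exceeds available non-target transcripts")
    chosen_true = rng.choice(sorted(truth.target_ids), size=n_true, replace=False)
    chosen_false = rng.choice(non_targets, size=n_false, replace=False)
    ids = frozenset(chosen_true) | frozenset(chosen_false)
    return PredictionSet(ids=ids, sources={"simulated": ids})


def simulate_genesets(
    truth: SimulationTruth,
    config: SimulationConfig,
    set_size: int = 50,
    n_target_members: int = 40,
    n_background_sets: int = 20,
) -> dict[str, tuple[str, frozenset[str]]]:
    """A GMT-style collection with one planted target-enriched set.

    The planted set draws ``n_target_members`` of its members from the true
    targets; background sets are uniform draws from all transcripts. If the
    truth has no targets the planted set degrades to a random set.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 2)
    all_ids = np.array(_transcript_ids(config.n_transcripts))
    targets = np.array(sorted(truth.target_ids))
    non_targets = np.array([t for t in all_ids if t not in truth.target_ids])

    n_t = min(n_target_members, len(targets))
    planted = set(rng.choice(targets, size=n_t, replace=False)) if n_t else set()
    planted |= set(rng.choice(non_targets, size=set_size - n_t, replace=False))

    sets: dict[str, tuple[str, frozenset[str]]] = {
        "planted_target_set": ("target-enriched set", frozenset(planted))
    }
    for i in range(n_background_sets):
        members = rng.choice(all_ids, size=set_size, replace=False)
        sets[f"background_{i:03d}"] = ("random background set", frozenset(members))
    return sets


def simulate_ortholog_map(
    config: SimulationConfig,
    many_to_one_fraction: float = 0.1,
) -> pd.DataFrame:
    """Transcript -> gene -> ortholog mapping table, mostly one-to-one.

    A fraction of transcripts share a gene with the next transcript
    (many-to-one), exercising the collapse rules of the ortholog mapping
    step. Returns a three-column DataFrame.
    """
    if not 0.0 <= many_to_one_fraction < 1.0:
        raise ValueError("many_to_one_fraction must lie in [0, 1)")
    rng = np.random.default_rng(config.rng_seed + 3)
    tx = _transcript_ids(config.n_transcripts)
    gene_of = {}
    gene_counter = 0
    i = 0
    while i < len(tx):
        gene = f"GENE{gene_counter:06d}"
        gene_of[tx[i]] = gene
        if rng.random() < many_to_one_fraction and i + 1 < len(tx):
            gene_of[tx[i + 1]] = gene
            i += 2
        else:
            i += 1
        gene_counter += 1
    rows = [
        (t, g, g.replace("GENE", "HUM")) for t, g in gene_of.items()
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "ortholog_gene_id"])


def simulate_utr_fixture(
    config: SimulationConfig,
    mirna_sequence: str = "UUCCCUUUGUCAUCCUAUGCCU",
    annotated_utr_length: int = 300,
    extension_length: int = 250,
    coverage_depth: int = 20,
    contig: str = "chr_sim",
):
    """Coverage track, annotation and sequence for 3'UTR-extension tests.

    Plants read coverage extending ``extension_length`` bases beyond the
    annotated transcript end, and a single seed-match site (the reverse
    complement of miRNA positions 2-8, followed by an A) inside the
    extended region only — the scenario in which a stale annotation hides a
    real target site. Returns ``(coverage, annotated_end, true_end,
    sequence, site_offset)`` where coordinates are 1-based on the contig,
    the sequence covers the full extended UTR starting at base 1, and
    ``site_offset`` is the 1-based position of the planted site within the
    sequence.
    """
    from .annotation import CoverageTrack, _seed_site_8mer

    config.validate()
    rng = np.random.default_rng(config.rng_seed + 4)
    site = _seed_site_8mer(mirna_sequence)
    total = annotated_utr_length + extension_length + 100

    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=total)
    # rejection-sample the background so the core match occurs nowhere else
    core = site[:-1]
    for _ in range(200):
        s = "".join(seq)
        pos = s.find(core)
        if pos == -1:
            break
        seq[pos] = bases[(np.where(bases == seq[pos])[0][0] + 1) % 4]
    site_offset = annotated_utr_length + (extension_length - len(site)) // 2
    seq[site_offset: site_offset + len(site)] = list(site)
    sequence = "".join(seq[: annotated_utr_length + extension_length])

    depth = np.zeros(total, dtype=int)
    depth[: annotated_utr_length + extension_length] = coverage_depth
    coverage = CoverageTrack(contig=contig, start=1, depth=depth)
    annotated_end = annotated_utr_length
    true_end = annotated_utr_length + extension_length
    return coverage, annotated_end, true_end, sequence, site_offset + 1
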