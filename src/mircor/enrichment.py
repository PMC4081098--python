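"""Over-representation analysis and comparison of the two target lists.

Enrichment of a gene list against a background uses the hypergeometric
upper tail per gene set, with Benjamini-Hochberg adjustment across the
tested sets. An EASE-style variant (overlap decremented by one before the
tail sum, the more conservative score popularized by the DAVID service) is
available behind a flag.

The module also implements the machinery for arguing that one selection
strategy beats another: the sets significant under each list, a paired
one-sided Wilcoxon signed-rank test on -log10 adjusted p over the commonly
significant sets, gene-level Venn counts, pathways-per-gene normalization
and the distribution of fold enrichments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

DEFAULT_ALPHA = 0.05


class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    def __init__(self, sets: dict[str, tuple[str, frozenset[str]]]):
        for name, (_desc, members) in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self._sets = dict(sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name][1]

    def description(self, name: str) -> str:
        return self._sets[name][0]

    def items(self):
        for name, (_desc, members) in self._sets.items():
            yield name, members

    def as_dict(self) -> dict[str, tuple[str, frozenset[str]]]:
        return dict(self._sets)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        from .io import read_gmt

        return cls(read_gmt(path))

    def to_gmt(self, path) -> None:
        from .io import write_gmt

        write_gmt(self._sets, path)


@dataclass
class EnrichmentResult:
    """Per-set overlap statistics for one gene list."""

    table: pd.DataFrame  # k, n, m, N, p, adj_p, fold_enrichment, significant
    list_size: int
    alpha: float

    def significant_sets(self) -> frozenset[str]:
        t = self.table
        return frozenset(t.index[t["significant"]])


@dataclass
class ListComparison:
    """How two enrichment profiles over the same collection differ."""

    common: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    common_pvalues: pd.DataFrame  # adj_p_a, adj_p_b per common set
    wilcoxon_stat: float | None
    wilcoxon_p: float | None
    venn_genes: dict[str, int] = field(default_factory=dict)


def enrich(
    gene_list,
    background,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    ease: bool = False,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Every set is intersected with the background before testing; genes in
    the list but not in the background are an error (the background defines
    the universe). With ``ease=True`` the overlap is decremented by one
    before the tail sum, the conservative EASE score variant.
    """
    genes = frozenset(gene_list)
    bg = frozenset(background)
    strays = sorted(genes - bg)
    if strays:
        raise ValueError(f"gene list not contained in background: {strays[:10]}")
    N = len(bg)
    n = len(genes)
    rows = []
    for name, members in sets.items():
        members_bg = members & bg
        m = len(members_bg)
        k = len(genes & members_bg)
        if ease:
            p = float(stats.hypergeom.sf(max(k - 1, 0) - 1, N, m, n)) if k > 0 else 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, m, n))
        fe = (k / n) / (m / N) if n > 0 and m > 0 else 0.0
        rows.append((name, k, n, m, N, min(p, 1.0), fe))
    table = pd.DataFrame(
        rows, columns=["set", "k", "n", "m", "N", "p", "fold_enrichment"]
    ).set_index("set")
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["adj_p"] < alpha
    return EnrichmentResult(table=table, list_size=n, alpha=alpha)


def compare_lists(
    res_a: EnrichmentResult,
    res_b: EnrichmentResult,
    genes_a=None,
    genes_b=None,
    paired: bool = True,
    alternative: str = "greater",
) -> ListComparison:
    """Compare two enrichment profiles over the same gene-set collection.

    Significance strength is compared on the commonly significant sets by a
    Wilcoxon test on -log10 adjusted p; the default is the paired
    signed-rank test, one-sided in the direction "B stronger" (B's
    adjusted p smaller). With no commonly significant sets the comparison
    is undefined and the test fields are None. Gene-level Venn counts are
    included when the two gene lists are supplied.
    """
    if set(res_a.table.index) != set(res_b.table.index):
        raise ValueError("enrichment results cover different gene-set collections")
    sig_a = res_a.significant_sets()
    sig_b = res_b.significant_sets()
    common = sig_a & sig_b
    pv = pd.DataFrame(
        {
            "adj_p_a": res_a.table.loc[sorted(common), "adj_p"],
            "adj_p_b": res_b.table.loc[sorted(common), "adj_p"],
        }
    )
    stat = pval = None
    if common:
        la = -np.log10(np.maximum(pv["adj_p_a"].to_numpy(), 1e-300))
        lb = -np.log10(np.maximum(pv["adj_p_b"].to_numpy(), 1e-300))
        if paired:
            diffs = lb - la
            if np.allclose(diffs, 0.0):
                stat, pval = 0.0, 1.0
            else:
                r = stats.wilcoxon(diffs, alternative=alternative)
                stat, pval = float(r.statistic), float(r.pvalue)
        else:
            r = stats.mannwhitneyu(lb, la, alternative=alternative)
            stat, pval = float(r.statistic), float(r.pvalue)
    venn: dict[str, int] = {}
    if genes_a is not None and genes_b is not None:
        ga, gb = frozenset(genes_a), frozenset(genes_b)
        venn = {
            "a_only": len(ga - gb),
            "b_only": len(gb - ga),
            "both": len(ga & gb),
        }
    return ListComparison(
        common=frozenset(common),
        only_a=frozenset(sig_a - sig_b),
        only_b=frozenset(sig_b - sig_a),
        common_pvalues=pv,
        wilcoxon_stat=stat,
        wilcoxon_p=pval,
        venn_genes=venn,
    )


def pathways_per_gene(results: list[EnrichmentResult]) -> list[float]:
    """Significant-set counts normalized by the size of the generating list.

    Bigger gene lists find more enriched categories for free; dividing by
    the list size makes per-strategy counts comparable.
    """
    out = []
    for res in results:
        if res.list_size <= 0:
            raise ValueError("cannot normalize by a zero-size gene list")
        out.append(len(res.significant_sets()) / res.list_size)
    return out


def fold_enrichment_distribution(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Summary of fold enrichments over each result's significant sets."""
    rows = []
    for i, res in enumerate(results):
        t = res.table
        fe = t.loc[t["significant"], "fold_enrichment"].to_numpy()
        if fe.size == 0:
            rows.append((i, 0, np.nan, np.nan, np.nan, np.nan))
        else:
            rows.append((
                i,
                fe.size,
                float(fe.mean()),
                float(np.quantile(fe, 0.25)),
                float(np.quantile(fe, 0.5)),
                float(np.quantile(fe, 0.75)),
            ))
    return pd.DataFrame(
        rows, columns=["list_index", "n_significant", "mean", "q25", "median", "q75"]
    ).set_index("list_index")
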