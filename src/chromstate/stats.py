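"""Association statistics used throughout the analyses.

Thin, well-specified wrappers over scipy/statsmodels: one-sided
Fisher-exact gene-list association grids with odds ratios, Mann-Whitney U
with midrank tie handling (exact enumeration at small n), upper-tail
hypergeometric category enrichment, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _ss
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "AssociationGrid",
    "fisher_exact",
    "odds_ratio",
    "association_grid",
    "mann_whitney_u",
    "hypergeometric_enrichment",
    "bh_adjust",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = overlap, b = row-only, c = column-only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact(table: ContingencyTable2x2, alternative: str = "greater") -> float:
    """Fisher's exact test p-value (default one-sided, 'greater')."""
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    _, p = _ss.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alternative
    )
    return float(p)


def odds_ratio(table: ContingencyTable2x2, haldane: bool = True) -> tuple[float, float]:
    """Sample odds ratio (a·d)/(b·c) and its log2.

    With any zero cell and ``haldane`` on, 0.5 is added to every cell
    (Haldane-Anscombe); with it off, a zero denominator yields inf.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        orr = float("inf") if a * d > 0 else float("nan")
    else:
        orr = (a * d) / (b * c)
    with np.errstate(divide="ignore"):
        return orr, float(np.log2(orr)) if orr > 0 else float("-inf")


@dataclass
class AssociationGrid:
    odds: pd.DataFrame
    log2_odds: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame


def association_grid(
    hit_sets: dict[str, set],
    gene_lists: dict[str, set],
    universe: set,
    alternative: str = "greater",
) -> AssociationGrid:
    """Fisher association of each hit set with each gene list.

    Per cell the 2x2 table cross-classifies universe genes by hit-set
    membership and list membership; BH adjustment runs across the whole
    grid.
    """
    if not universe:
        raise ValueError("empty universe")
    for name, lst in gene_lists.items():
        if not lst <= universe:
            raise ValueError(f"gene list {name!r} not contained in universe")
    rows, cols = list(hit_sets), list(gene_lists)
    odds = pd.DataFrame(index=rows, columns=cols, dtype=float)
    l2 = odds.copy()
    praw = odds.copy()
    for r in rows:
        hits = hit_sets[r] & universe
        for cname in cols:
            lst = gene_lists[cname]
            a = len(hits & lst)
            b = len(hits - lst)
            c = len(lst - hits)
            d = len(universe) - a - b - c
            t = ContingencyTable2x2(a, b, c, d)
            praw.loc[r, cname] = fisher_exact(t, alternative)
            o, lo = odds_ratio(t)
            odds.loc[r, cname] = o
            l2.loc[r, cname] = lo
    flat = praw.to_numpy().ravel()
    padj = pd.DataFrame(
        bh_adjust(flat).reshape(praw.shape), index=rows, columns=cols
    )
    return AssociationGrid(odds, l2, praw, padj)


def mann_whitney_u(
    x, y, alternative: str = "two-sided", exact_max_n: int = 8
) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties; exact when both samples are small.

    Uses full enumeration (scipy's exact method) when both n <= exact_max_n
    and there are no ties, otherwise the tie-corrected,
    continuity-corrected normal approximation. Fully tied inputs are
    degenerate: p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= exact_max_n and y.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = _ss.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def hypergeometric_enrichment(
    selected: set,
    categories: dict[str, set],
    universe: set,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each category in the
    selection, BH-adjusted across categories; significant at adjusted
    p < ``alpha``."""
    if not selected <= universe:
        raise ValueError("selected set must be contained in the universe")
    N, n = len(universe), len(selected)
    names, praw, ks, Ks = [], [], [], []
    for name, cat in categories.items():
        if not cat <= universe:
            raise ValueError(f"category {name!r} not contained in universe")
        K = len(cat)
        k = len(cat & selected)
        # P(X >= k) including the observed count
        p = float(_ss.hypergeom.sf(k - 1, N, K, n))
        names.append(name)
        praw.append(p)
        ks.append(k)
        Ks.append(K)
    padj = bh_adjust(np.array(praw)) if praw else np.array([])
    return pd.DataFrame(
        {
            "overlap": ks,
            "category_size": Ks,
            "p_raw": praw,
            "p_adj": padj,
            "significant": padj < alpha,
        },
        index=names,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
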