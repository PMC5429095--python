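"""Developmental expression normalisation and gene classification.

A genes x samples count matrix (CEL-seq-like 3'-end counts) is CPM
normalised, replicate columns are averaged into developmental stages
(17 by default), and genes are classified four ways:

* expressed / repressed by a normalized-count threshold (0.5);
* expression tertiles (high / mid / low) among expressed genes;
* high- vs low-variance by median absolute deviation (MAD) across stages,
  after a raw-count floor and positional eligibility filters;
* stable vs regulated by the coefficient of variation (CV) across stages,
  after a minimum-expression filter (>= 4 normalized counts in >= 2 stages).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotationInfo",
    "VarianceClassConfig",
    "StableRegulatedConfig",
    "normalize_cpm",
    "compress_stages",
    "classify_expressed",
    "tertile_bins",
    "positional_eligibility",
    "select_high_low_variance",
    "select_stable_regulated",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples counts plus the sample -> stage mapping."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    stage_map: dict[str, str]  # sample -> stage
    normalization: str = "raw"  # raw | cpm | log_cpm

    def __post_init__(self) -> None:
        missing = [c for c in self.counts.columns if c not in self.stage_map]
        if missing:
            raise ValueError(f"samples without stage mapping: {missing}")
        if not np.isfinite(self.counts.to_numpy(dtype=float)).all():
            raise ValueError("counts must be finite")
        if (self.counts.to_numpy(dtype=float) < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for c in self.counts.columns:
            st = self.stage_map[c]
            if st not in seen:
                seen.append(st)
        return seen


def normalize_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: divide by the sample total, multiply by 1e6."""
    totals = m.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    cpm = m.counts / totals * 1e6
    return ExpressionMatrix(cpm, dict(m.stage_map), "cpm")


def compress_stages(m: ExpressionMatrix) -> pd.DataFrame:
    """Average replicate columns per developmental stage.

    Returns a genes x stages frame in first-appearance stage order;
    single-replicate stages pass through unchanged.
    """
    groups: dict[str, list[str]] = {}
    for c in m.counts.columns:
        groups.setdefault(m.stage_map[c], []).append(c)
    empty = [st for st, cols in groups.items() if not cols]
    if empty:
        raise ValueError(f"stage(s) with zero samples: {empty}")
    out = {st: m.counts[cols].mean(axis=1) for st, cols in groups.items()}
    return pd.DataFrame(out)[m.stages]


def classify_expressed(values: pd.Series, threshold: float = 0.5) -> pd.Series:
    """'expressed' where normalized value > threshold, else 'repressed'.

    Both inequalities are strict, so the boundary value itself falls to
    repressed by convention."""
    return pd.Series(
        np.where(values > threshold, "expressed", "repressed"), index=values.index
    )


def tertile_bins(values: pd.Series) -> pd.Series:
    """Split genes into high/mid/low thirds by descending expression.

    Ties are broken by gene identifier so the split is deterministic; when
    the count is not divisible by 3 the extra genes go to the
    higher-expression bins.
    """
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 genes for tertiles")
    order = sorted(values.index, key=lambda g: (-values[g], str(g)))
    base, extra = divmod(n, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    labels = {}
    pos = 0
    for size, lab in zip(sizes, ("high", "mid", "low")):
        for g in order[pos : pos + size]:
            labels[g] = lab
        pos += size
    return pd.Series(labels).reindex(values.index)


@dataclass
class GeneAnnotationInfo:
    """Minimal positional facts per gene needed by the eligibility filters."""

    gene_scaffold: dict[str, str]
    gene_span: dict[str, tuple[int, int]]
    scaffold_length: dict[str, int]


def positional_eligibility(
    genes: list[str],
    ann: GeneAnnotationInfo,
    min_scaffold: int = 10_000,
    min_intergenic: int = 1_000,
) -> tuple[set[str], Counter]:
    """Positional eligibility filters: keep non-overlapping genes with
    intergenic distance above ``min_intergenic`` on both sides, on
    scaffolds longer than ``min_scaffold``."""
    reasons: Counter = Counter()
    by_scaf: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        s = ann.gene_scaffold[g]
        a, b = ann.gene_span[g]
        by_scaf.setdefault(s, []).append((a, b, g))
    eligible: set[str] = set()
    for s, items in by_scaf.items():
        items.sort()
        for i, (a, b, g) in enumerate(items):
            if ann.scaffold_length[s] <= min_scaffold:
                reasons["small_scaffold"] += 1
                continue
            prev_end = items[i - 1][1] if i > 0 else None
            next_start = items[i + 1][0] if i + 1 < len(items) else None
            if (prev_end is not None and prev_end > a) or (
                next_start is not None and next_start < b
            ):
                reasons["overlapping_gene"] += 1
                continue
            left = a - prev_end if prev_end is not None else None
            right = next_start - b if next_start is not None else None
            if (left is not None and left <= min_intergenic) or (
                right is not None and right <= min_intergenic
            ):
                reasons["short_intergenic"] += 1
                continue
            eligible.add(g)
    return eligible, reasons


@dataclass
class VarianceClassConfig:
    min_raw_total: float = 100.0
    n_mad: int = 15_000
    min_scaffold: int = 10_000
    min_intergenic: int = 1_000
    adult_stage: str | None = None  # defaults to the last stage
    # pseudocount for the log transform, in raw-count units (converted to
    # CPM scale via the mean library size); a moderated log2 stands in for
    # a variance-stabilising transform and this keeps shot noise of
    # one-count genes from dominating the MAD ranking
    log_pseudocount_counts: float = 2.0


def select_high_low_variance(
    raw: ExpressionMatrix,
    ann: GeneAnnotationInfo,
    config: VarianceClassConfig | None = None,
) -> tuple[pd.Series, Counter]:
    """High-/low-variance gene classes by MAD of log2(CPM + 1) across stages.

    Pipeline: (1) drop genes with fewer than ``min_raw_total`` raw counts
    over the whole time course; (2) moderated log2-CPM transform; (3) rank by
    MAD across stages and keep the top ``n_mad``; (4) positional filters
    plus detectable adult expression. Survivors are ``high_variance``; the
    remaining adult-expressed genes passing the positional filters are
    ``low_variance``; everything else is ``excluded``. Removal reasons are
    tallied in the returned Counter.
    """
    cfg = config or VarianceClassConfig()
    reasons: Counter = Counter()
    totals = raw.counts.sum(axis=1)
    kept = totals[totals >= cfg.min_raw_total].index
    reasons["low_total"] = int(len(raw.counts) - len(kept))

    cpm = normalize_cpm(raw)
    c = cfg.log_pseudocount_counts * 1e6 / raw.counts.sum(axis=0).mean()
    log_stage = np.log2(compress_stages(cpm) + c)
    adult = cfg.adult_stage or log_stage.columns[-1]
    mad = (log_stage.loc[kept] - log_stage.loc[kept].median(axis=1).values[:, None]) \
        .abs().median(axis=1)
    n_mad = min(cfg.n_mad, len(mad))
    top = set(mad.sort_values(ascending=False, kind="stable").index[:n_mad])
    reasons["below_mad_rank"] = len(kept) - len(top)

    eligible, pos_reasons = positional_eligibility(
        list(kept), ann, cfg.min_scaffold, cfg.min_intergenic
    )
    reasons.update(pos_reasons)

    cpm_stage = compress_stages(cpm)
    adult_expressed = set(cpm_stage.index[cpm_stage[adult] > 0])

    labels = {}
    for g in raw.counts.index:
        if g not in set(kept):
            labels[g] = "excluded"
        elif g not in eligible or g not in adult_expressed:
            labels[g] = "excluded"
        elif g in top:
            labels[g] = "high_variance"
        else:
            labels[g] = "low_variance"
    return pd.Series(labels).reindex(raw.counts.index), reasons


@dataclass
class StableRegulatedConfig:
    min_norm_count: float = 4.0
    min_stages: int = 2
    n_sel: int = 1_000
    focal_stage: str | None = None  # None: no stage-expression filter
    apply_positional: bool = True
    min_scaffold: int = 10_000
    min_intergenic: int = 1_000


def select_stable_regulated(
    stage_cpm: pd.DataFrame,
    ann: GeneAnnotationInfo | None = None,
    config: StableRegulatedConfig | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Stable vs developmentally regulated genes by expression CV.

    Eligibility requires >= ``min_norm_count`` normalized counts in at
    least ``min_stages`` stages (plus optional focal-stage expression and
    positional filters). Among eligible genes, the ``n_sel`` lowest-CV
    genes are 'stable' and the ``n_sel`` highest-CV are 'regulated';
    ``n_sel`` is capped at half the eligible cohort so the two sets cannot
    meet. Returns (labels, CV values over eligible genes).
    """
    cfg = config or StableRegulatedConfig()
    ok = (stage_cpm >= cfg.min_norm_count).sum(axis=1) >= cfg.min_stages
    eligible = set(stage_cpm.index[ok])
    if cfg.focal_stage is not None:
        eligible &= set(stage_cpm.index[stage_cpm[cfg.focal_stage] > 0])
    if cfg.apply_positional and ann is not None:
        pos, _ = positional_eligibility(
            list(eligible), ann, cfg.min_scaffold, cfg.min_intergenic
        )
        eligible &= pos
    eligible_idx = [g for g in stage_cpm.index if g in eligible]
    sub = stage_cpm.loc[eligible_idx]
    mean = sub.mean(axis=1)
    cv = sub.std(axis=1, ddof=1) / mean  # mean > 0 guaranteed by the filter
    n_sel = min(cfg.n_sel, len(eligible_idx) // 2)
    order = sorted(eligible_idx, key=lambda g: (cv[g], str(g)))
    stable = set(order[:n_sel])
    regulated = set(order[len(order) - n_sel :])
    if stable & regulated:
        raise ValueError("cohort too small: stable and regulated sets overlap")
    labels = {}
    for g in stage_cpm.index:
        if g in stable:
            labels[g] = "stable"
        elif g in regulated:
            labels[g] = "regulated"
        elif g in eligible:
            labels[g] = "neither"
        else:
            labels[g] = "ineligible"
    return pd.Series(labels).reindex(stage_cpm.index), cv
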