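"""Poisson enrichment scoring, region calling, and ChIP QC statistics.

Per-bin ChIP counts are scored against a depth-scaled input expectation with
an upper-tail Poisson p-value, the discretisation behind both the binary
observation matrices fed to the chromatin HMM (threshold 1e-4) and a
simplified broad/gapped region caller (broad p 0.1 containing at least one
narrow bin at p 0.01). QC follows ENCODE-style practice: FRiP >= 1%,
replicate fold-enrichment Pearson >= 0.5, and a pooled/pseudoreplicate
self-consistency ratio M/T >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, merge
from .tracks import BinnedTrack

__all__ = [
    "EnrichedRegion",
    "EnrichedRegionSet",
    "ReproducibilityReport",
    "poisson_bin_pvalues",
    "binarize",
    "call_regions",
    "filter_by_pvalue",
    "fold_enrichment_track",
    "frip",
    "replicate_correlation",
    "pseudoreplicate_split",
    "pseudoreplicate_reproducibility",
]


def _lambda_track(chip: BinnedTrack, input_: BinnedTrack) -> dict[str, np.ndarray]:
    """Per-bin Poisson expectation: depth-scaled input, floored at the
    depth-scaled genome-wide input mean so empty input bins cannot zero λ."""
    chip.require_same_binning(input_)
    input_total = input_.total_count
    if input_total <= 0:
        raise ValueError("input track has zero total count")
    scale = chip.total_count / input_total
    lam_floor = scale * input_total / input_.n_bins
    return {
        s: np.maximum(input_.data[s] * scale, lam_floor)
        for s in input_.data
    }


def poisson_bin_pvalues(chip: BinnedTrack, input_: BinnedTrack) -> BinnedTrack:
    """Upper-tail Poisson p-value P(X >= k | λ_bin) per bin.

    λ_bin is the bin's input count scaled to matching depth, floored at the
    depth-scaled genome-wide input mean. k = 0 gives p = 1.
    """
    lam = _lambda_track(chip, input_)
    out = {}
    for s in chip.data:
        k = chip.data[s]
        # sf(k-1) = P(X >= k)
        out[s] = stats.poisson.sf(k - 1, lam[s])
    return BinnedTrack(out, bin_width=chip.bin_width)


def binarize(
    chip: BinnedTrack, input_: BinnedTrack, threshold: float = 1e-4
) -> dict[str, np.ndarray]:
    """Discretise each bin to 1 (enriched: p < threshold) or 0."""
    p = poisson_bin_pvalues(chip, input_)
    return {s: (v < threshold).astype(np.uint8) for s, v in p.data.items()}


@dataclass(frozen=True)
class EnrichedRegion:
    interval: GenomicInterval
    min_narrow_p: float
    min_broad_p: float
    kind: str  # "gapped" or "broad"


@dataclass
class EnrichedRegionSet:
    regions: list[EnrichedRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(
            self.regions,
            key=lambda r: (r.interval.scaffold, r.interval.start, r.interval.end),
        )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def intervals(self) -> IntervalSet:
        return IntervalSet([r.interval for r in self.regions])

    def coordinates(self) -> set[tuple[str, int, int]]:
        return {
            (r.interval.scaffold, r.interval.start, r.interval.end)
            for r in self.regions
        }


def call_regions(
    chip: BinnedTrack,
    input_: BinnedTrack,
    narrow_p: float = 0.01,
    broad_p: float = 0.1,
    max_gap_bins: int = 1,
) -> EnrichedRegionSet:
    """Simplified gapped-region caller.

    Bins passing the broad threshold are merged, allowing gaps of at most
    ``max_gap_bins`` non-passing bins; merged regions lacking any bin at the
    narrow threshold are discarded. Output coordinates are bin-aligned.
    """
    if narrow_p > broad_p:
        raise ValueError("narrow_p must be <= broad_p")
    p = poisson_bin_pvalues(chip, input_)
    bw = chip.bin_width
    regions: list[EnrichedRegion] = []
    for s in sorted(p.data):
        pv = p.data[s]
        hits = np.flatnonzero(pv < broad_p)
        if hits.size == 0:
            continue
        # group hit bins allowing gaps
        breaks = np.flatnonzero(np.diff(hits) > max_gap_bins + 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [hits.size - 1]])
        for a, b in zip(starts, ends):
            lo, hi = hits[a], hits[b]
            seg = pv[lo : hi + 1]
            min_p = float(seg.min())
            if min_p >= narrow_p:
                continue
            regions.append(
                EnrichedRegion(
                    GenomicInterval(s, int(lo) * bw, (int(hi) + 1) * bw),
                    min_narrow_p=min_p,
                    min_broad_p=min_p,
                    kind="gapped",
                )
            )
    return EnrichedRegionSet(regions)


def filter_by_pvalue(
    regions: EnrichedRegionSet, max_p: float = 0.001
) -> EnrichedRegionSet:
    """Single-replicate mode: retain regions with narrow p below ``max_p``
    (used where no biological replicate exists, e.g. an H3K27ac-style
    library), ranked implicitly by p."""
    return EnrichedRegionSet([r for r in regions if r.min_narrow_p < max_p])


def fold_enrichment_track(
    chip: BinnedTrack, input_: BinnedTrack, pseudocount: float = 1.0
) -> BinnedTrack:
    """Per-bin fold enrichment (k + c) / (λ_bin + c) over expected background."""
    lam = _lambda_track(chip, input_)
    out = {
        s: (chip.data[s] + pseudocount) / (lam[s] + pseudocount)
        for s in chip.data
    }
    return BinnedTrack(out, bin_width=chip.bin_width)


def frip(
    chip: BinnedTrack,
    regions: EnrichedRegionSet | IntervalSet,
    min_fraction: float = 0.01,
) -> tuple[float, bool]:
    """Fraction of read (count) mass inside regions; pass at >= 1%.

    Regions need not be bin-aligned: a partially covered bin contributes its
    count prorated by the covered fraction of the bin.
    """
    total = chip.total_count
    if total == 0:
        raise ValueError("chip track has zero total count (FRiP undefined)")
    ivs = regions.intervals() if isinstance(regions, EnrichedRegionSet) else regions
    bw = chip.bin_width
    in_mass = 0.0
    for iv in merge(ivs, 0):
        v = chip.data.get(iv.scaffold)
        if v is None:
            continue
        end = min(iv.end, v.size * bw)
        if iv.start >= end:
            continue
        first, last = iv.start // bw, (end - 1) // bw
        for b in range(first, last + 1):
            ov = min(end, (b + 1) * bw) - max(iv.start, b * bw)
            in_mass += v[b] * ov / bw
    frac = in_mass / total
    return frac, frac >= min_fraction


def replicate_correlation(
    fe1: BinnedTrack, fe2: BinnedTrack, min_r: float = 0.5
) -> tuple[float, bool]:
    """Pearson correlation of two (fold-enrichment) tracks over all bins."""
    fe1.require_same_binning(fe2)
    x, y = fe1.concatenated(), fe2.concatenated()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a track has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r >= min_r


def pseudoreplicate_split(
    pool: BinnedTrack, rng: np.random.Generator
) -> tuple[BinnedTrack, BinnedTrack]:
    """Split pooled per-bin counts into two halves without replacement.

    Equivalent to labelling each pooled read, drawing half of them for
    pseudoreplicate 1 and leaving the rest for pseudoreplicate 2: a
    sequential (multivariate) hypergeometric draw across bins.
    """
    order = pool.scaffolds()
    counts = np.concatenate([pool.data[s] for s in order]).astype(np.int64)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("pooled track is empty")
    half = total // 2
    draws = np.zeros_like(counts)
    remaining_total, remaining_draw = total, half
    for i, n_i in enumerate(counts):
        if remaining_draw == 0:
            break
        n_i = int(n_i)
        other = remaining_total - n_i
        x = rng.hypergeometric(n_i, other, remaining_draw) if n_i > 0 else 0
        draws[i] = x
        remaining_total -= n_i
        remaining_draw -= x
    pr1_data, pr2_data = {}, {}
    off = 0
    for s in order:
        n = pool.data[s].size
        pr1_data[s] = draws[off : off + n].copy()
        pr2_data[s] = pool.data[s] - pr1_data[s]
        off += n
    return (
        BinnedTrack(pr1_data, bin_width=pool.bin_width),
        BinnedTrack(pr2_data, bin_width=pool.bin_width),
    )


@dataclass(frozen=True)
class ReproducibilityReport:
    n_r: int
    n_pr: int
    n_m: int
    n_t: int
    ratio: float
    passed: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        assert self.n_m <= self.n_t or self.degenerate


def _overlapping_both(
    pooled: EnrichedRegionSet, s1: EnrichedRegionSet, s2: EnrichedRegionSet
) -> list[EnrichedRegion]:
    from .intervals import intersect

    iv1, iv2 = s1.intervals(), s2.intervals()
    keep1 = {
        (iv.scaffold, iv.start, iv.end)
        for iv in intersect(pooled.intervals(), iv1, 0.0)
    }
    keep2 = {
        (iv.scaffold, iv.start, iv.end)
        for iv in intersect(pooled.intervals(), iv2, 0.0)
    }
    both = keep1 & keep2
    return [
        r
        for r in pooled
        if (r.interval.scaffold, r.interval.start, r.interval.end) in both
    ]


def pseudoreplicate_reproducibility(
    rep1: BinnedTrack,
    rep2: BinnedTrack,
    input_: BinnedTrack,
    narrow_p: float = 0.01,
    broad_p: float = 0.1,
    max_gap_bins: int = 1,
    min_ratio: float = 0.5,
    seed: int = 0,
) -> ReproducibilityReport:
    """Self-consistency of peak calls between true replicates and random
    half-splits of the pooled counts.

    R = pooled-data regions supported (>= 1 bp overlap) by both replicate
    call sets; PR = pooled regions supported by both pseudoreplicates;
    M = regions with identical coordinates in R and PR; T = M plus regions
    unique to either. Pass requires |M|/|T| >= 0.5. When no regions are
    called anywhere the ratio is 1 by convention (degenerate flag set).
    """
    rep1.require_same_binning(rep2)
    pool = rep1 + rep2
    if pool.total_count == 0:
        raise ValueError("pooled track is empty")
    rng = np.random.default_rng(seed)
    pr1, pr2 = pseudoreplicate_split(pool, rng)

    def call(t: BinnedTrack) -> EnrichedRegionSet:
        return call_regions(t, input_, narrow_p, broad_p, max_gap_bins)

    c_pool = call(pool)
    c_r1, c_r2 = call(rep1), call(rep2)
    c_pr1, c_pr2 = call(pr1), call(pr2)

    r_set = EnrichedRegionSet(_overlapping_both(c_pool, c_r1, c_r2))
    pr_set = EnrichedRegionSet(_overlapping_both(c_pool, c_pr1, c_pr2))
    r_coords, pr_coords = r_set.coordinates(), pr_set.coordinates()
    m = r_coords & pr_coords
    t = r_coords | pr_coords
    if not t:
        return ReproducibilityReport(0, 0, 0, 0, 1.0, True, degenerate=True)
    ratio = len(m) / len(t)
    return ReproducibilityReport(
        len(r_coords), len(pr_coords), len(m), len(t), ratio, ratio >= min_ratio
    )
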