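"""Synthetic miniature genome, chromatin, expression and qPCR generator.

Everything downstream of read alignment in the analysis pipeline can be
exercised on this module's output with known ground truth: a compact
multi-scaffold genome with short introns and short intergenic spacers, a
hidden chromatin-state chain over 200-bp bins emitting Poisson read counts
per histone mark, planted intronic/intergenic enhancers (optionally
enriched inside microsyntenic unit spans), a 17-stage developmental
expression matrix with stable / regulated / high-variance gene
populations, replicate ChIP tracks, and qPCR Cq tables with known fold
changes.

Counts per bin, not individual reads, are simulated; downstream read
subsampling is modelled as hypergeometric splits of bin counts, which
preserves the statistics the analysis procedures consume at desk scale.
All randomness flows from ``spec.seed`` through per-stage child seeds, so
identical specs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import Annotation, GeneModel
from .expression import ExpressionMatrix
from .intervals import Anchor, GenomicInterval, IntervalSet, merge
from .tracks import BinnedTrack

__all__ = [
    "SyntheticSpec",
    "PlantedEnhancer",
    "GroundTruth",
    "default_emission",
    "default_transition",
    "DEFAULT_STATE_NAMES",
    "DEFAULT_MARKS",
    "generate_genome",
    "plant_enhancers",
    "simulate_chromatin",
    "simulate_expression",
    "simulate_qpcr",
    "stationary_distribution",
]

DEFAULT_MARKS = ("H3K4me3", "H3K27ac", "H3K4me1", "H3K36me3", "H3K27me3", "RNAPII")
DEFAULT_STATE_NAMES = (
    "TssA",
    "TxFlnk",
    "TxEnhA",
    "EnhWk",
    "Tx",
    "BivTx",
    "EnhP",
    "ReprPC",
    "Quies",
)
# states whose presence defines an enhancer signature; TxEnhA also carries
# H3K27ac and so marks *activated* elements
ENHANCER_STATES = ("TxEnhA", "EnhWk", "EnhP")
ACTIVATED_STATE = "TxEnhA"
SILENT_ENHANCER_STATE = "EnhP"


def default_emission() -> np.ndarray:
    """Per-state Bernoulli mark-presence probabilities (states x marks).

    Mark order follows DEFAULT_MARKS; rows follow DEFAULT_STATE_NAMES and
    mimic the canonical mark combinations: H3K4me3 at active promoters,
    H3K4me1 (+H3K27ac) at enhancers, H3K36me3 over transcribed bodies,
    H3K27me3 over Polycomb-repressed chromatin.
    """
    return np.array(
        [
            # K4me3  K27ac  K4me1 K36me3 K27me3 RNAPII
            [0.95, 0.80, 0.05, 0.05, 0.02, 0.90],  # TssA
            [0.60, 0.40, 0.15, 0.70, 0.02, 0.50],  # TxFlnk
            [0.05, 0.85, 0.90, 0.60, 0.02, 0.40],  # TxEnhA
            [0.05, 0.15, 0.90, 0.10, 0.05, 0.10],  # EnhWk
            [0.05, 0.10, 0.05, 0.90, 0.02, 0.30],  # Tx
            [0.50, 0.05, 0.10, 0.10, 0.50, 0.10],  # BivTx
            [0.05, 0.05, 0.85, 0.05, 0.60, 0.05],  # EnhP
            [0.02, 0.02, 0.05, 0.02, 0.90, 0.02],  # ReprPC
            [0.02, 0.02, 0.02, 0.02, 0.05, 0.02],  # Quies
        ]
    )


def default_transition(n_states: int = 9, self_prob: float = 0.80) -> np.ndarray:
    """Sticky chain with a quiescent-dominated stationary distribution.

    Every state keeps ``self_prob`` on the diagonal; transitions out of a
    non-quiescent state preferentially fall back to the quiescent state
    (the last state), mirroring the large silent fraction of a real
    genome. For state counts other than the 9-state default the chain is
    plain sticky-uniform.
    """
    if n_states == 1:
        return np.array([[1.0]])
    t = np.full((n_states, n_states), (1.0 - self_prob) / (n_states - 1))
    np.fill_diagonal(t, self_prob)
    if n_states == 9:
        q = n_states - 1
        for i in range(q):
            t[i] = 0.0
            t[i, i] = self_prob
            t[i, q] = 0.12
            rest = 1.0 - self_prob - 0.12
            others = [j for j in range(n_states) if j not in (i, q)]
            t[i, others] = rest / len(others)
        t[q] = 0.1 / (n_states - 1)
        t[q, q] = 0.9
    return t


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    return v / v.sum()


@dataclass
class SyntheticSpec:
    n_scaffolds: int = 4
    scaffold_length: int = 200_000
    n_genes: int = 240
    mean_intergenic_gap: int = 300
    # every gap keeps at least this much room so any adjacent gene pair can
    # host a regulatory element; keeps syntenic units and control pairs
    # statistically exchangeable under uniform enhancer placement
    min_intergenic_gap: int = 800
    # log-normal intron law targeting the short introns of a compact
    # genome (analytic median = exp(meanlog) = 71 bp)
    intron_meanlog: float = math.log(71.0)
    intron_sdlog: float = 0.6
    n_lincrnas: int = 36
    n_syntenic_pairs: int = 60
    marks: tuple[str, ...] = DEFAULT_MARKS
    n_states: int = 9
    state_names: tuple[str, ...] = DEFAULT_STATE_NAMES
    transition_matrix: np.ndarray | None = None
    emission_probs: np.ndarray | None = None
    lambda_background: float = 1.0
    lambda_signal: float = 15.0
    # input library sequenced deeper than one ChIP replicate, as in a
    # typical design; per-bin input mean = lambda_background * input_depth
    input_depth: float = 5.0
    n_stages: int = 17
    replicates_per_stage: int = 2
    nb_dispersion: float = 0.3
    stable_dispersion: float = 0.05
    n_enhancers: int = 60
    activated_fraction: float = 0.6
    # fraction of multi-exon genes given one enlarged intron able to host a
    # regulatory element (the long tail of the intron-size law)
    long_intron_fraction: float = 0.25
    long_intron_meanlog: float = math.log(1200.0)
    long_intron_sdlog: float = 0.3
    synteny_enhancer_boost: float = 1.0
    n_qpcr_loci: int = 8
    qpcr_sigma: float = 0.1
    qpcr_input_fraction: float = 0.1
    bin_width: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = default_transition(self.n_states)
        if self.emission_probs is None:
            if (self.n_states, len(self.marks)) == (9, 6):
                self.emission_probs = default_emission()
            else:
                raise ValueError(
                    "emission_probs must be given for non-default state/mark counts"
                )
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.emission_probs = np.asarray(self.emission_probs, dtype=float)
        self.validate()

    def validate(self) -> None:
        t, e = self.transition_matrix, self.emission_probs
        if t.shape != (self.n_states, self.n_states):
            raise ValueError("transition_matrix must be K x K")
        if np.abs(t.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if e.shape != (self.n_states, len(self.marks)):
            raise ValueError("emission_probs must be K x M")
        if ((e < 0) | (e > 1)).any():
            raise ValueError("emission_probs must lie in [0, 1]")
        if not (self.lambda_signal > self.lambda_background > 0):
            raise ValueError("require lambda_signal > lambda_background > 0")
        for name in (
            "n_scaffolds",
            "n_genes",
            "n_lincrnas",
            "n_syntenic_pairs",
            "n_enhancers",
            "n_qpcr_loci",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.marks) == 0:
            raise ValueError("marks list must not be empty")
        if len(self.state_names) != self.n_states:
            raise ValueError("state_names must name every state")
        if self.scaffold_length % self.bin_width != 0:
            raise ValueError("scaffold_length must be a multiple of bin_width")

    def rng(self, stage: int) -> np.random.Generator:
        """Per-stage child generator derived stably from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )

    def enhancer_state_indices(self) -> dict[str, int]:
        idx = {name: i for i, name in enumerate(self.state_names)}
        return {name: idx[name] for name in ENHANCER_STATES if name in idx}


@dataclass(frozen=True)
class PlantedEnhancer:
    interval: GenomicInterval
    activated: bool
    planted: bool  # deliberately placed (vs emitted by the state chain)
    resolvable: bool  # spans >= 2 bins: reliably detectable at default depth
    distal: bool  # clear of every TSS window (with one bin of margin)
    target_gene: str | None = None  # host gene when forced into an intron


@dataclass
class GroundTruth:
    state_path: dict[str, np.ndarray] = field(default_factory=dict)
    enhancers: list[PlantedEnhancer] = field(default_factory=list)
    gene_class: dict[str, str] = field(default_factory=dict)
    lincrna_class: dict[str, str] = field(default_factory=dict)
    syntenic_pairs: list[tuple[str, str]] = field(default_factory=list)
    syntenic_has_enhancer: list[bool] = field(default_factory=list)
    qpcr_fold: dict[str, float] = field(default_factory=dict)

    def enhancer_set(self, activated_only: bool = False, distal_only: bool = False,
                     resolvable_only: bool = False) -> IntervalSet:
        return IntervalSet(
            [
                e.interval
                for e in self.enhancers
                if (not activated_only or e.activated)
                and (not distal_only or e.distal)
                and (not resolvable_only or e.resolvable)
            ]
        )


# ---------------------------------------------------------------------------
# genome generation


def _draw_intron(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    return max(20, int(round(rng.lognormal(spec.intron_meanlog, spec.intron_sdlog))))


def _draw_exon(rng: np.random.Generator) -> int:
    return max(60, int(round(rng.lognormal(math.log(150.0), 0.5))))


_CLASS_CYCLE = (
    ("stable", 0.15),
    ("regulated", 0.15),
    ("high_variance", 0.20),
    ("low_variance", 0.20),
    ("background", 0.30),
)

# expression-class genes get padded flanks so the positional eligibility
# filters (intergenic distance > 1 kb) cannot empty the planted classes
_CLASS_PAD = 1200


def generate_genome(spec: SyntheticSpec) -> tuple[Annotation, GroundTruth]:
    """Lay out genes, lincRNAs and syntenic pairs on the scaffolds.

    Genes are placed left to right with intergenic gaps drawn from an
    exponential law (mean ``mean_intergenic_gap``); intron lengths follow
    the log-normal law. Expression classes are assigned at placement time
    and their carriers receive >1-kb flanks. lincRNAs are interleaved into
    intergenic space with an elinc / plinc / neither class cycle.
    """
    spec.validate()
    rng = spec.rng(0)
    ann = Annotation(
        {f"scaffold_{i + 1}": spec.scaffold_length for i in range(spec.n_scaffolds)}
    )
    truth = GroundTruth()

    class_names = [c for c, _ in _CLASS_CYCLE]
    class_p = np.array([p for _, p in _CLASS_CYCLE])
    genes_per_scaf = [
        spec.n_genes // spec.n_scaffolds
        + (1 if i < spec.n_genes % spec.n_scaffolds else 0)
        for i in range(spec.n_scaffolds)
    ]
    linc_every = max(1, spec.n_genes // max(1, spec.n_lincrnas))
    n_linc_placed = 0
    gene_counter = 0

    for si, scaf in enumerate(sorted(ann.scaffold_lengths)):
        cursor = 200
        prev_padded = False
        for _ in range(genes_per_scaf[si]):
            gene_counter += 1
            gid = f"gene_{gene_counter:05d}"
            gclass = class_names[int(rng.choice(len(class_names), p=class_p))]
            gap = max(
                int(rng.exponential(spec.mean_intergenic_gap)) + 50,
                spec.min_intergenic_gap,
            )
            if gclass != "background" or prev_padded:
                gap = max(gap, _CLASS_PAD)
            cursor += gap

            # interleave a lincRNA before this gene now and then
            if (
                n_linc_placed < spec.n_lincrnas
                and gene_counter % linc_every == 0
            ):
                linc_len = int(rng.integers(1000, 1600))
                lstart = cursor
                lend = lstart + linc_len
                cursor = lend + max(
                    500, int(rng.exponential(spec.mean_intergenic_gap))
                )
                n_linc_placed += 1
                lid = f"linc_{n_linc_placed:04d}"
                lclass = ("elinc", "plinc", "neither")[n_linc_placed % 3]
                strand = "+" if rng.random() < 0.5 else "-"
                if lend > spec.scaffold_length - 200:
                    raise ValueError(
                        f"scaffold {scaf} too short to host requested features"
                    )
                ann.lincrnas[lid] = GeneModel(
                    lid, scaf, lstart, lend, strand, ((lstart, lend),), "lincRNA"
                )
                truth.lincrna_class[lid] = lclass

            n_exons = int(rng.integers(1, 7))
            long_intron_at = -1
            if n_exons > 1 and rng.random() < spec.long_intron_fraction:
                long_intron_at = int(rng.integers(0, n_exons - 1))
            exons = []
            pos = cursor
            for e in range(n_exons):
                elen = _draw_exon(rng)
                exons.append((pos, pos + elen))
                pos += elen
                if e < n_exons - 1:
                    if e == long_intron_at:
                        pos += int(
                            round(
                                rng.lognormal(
                                    spec.long_intron_meanlog, spec.long_intron_sdlog
                                )
                            )
                        )
                    else:
                        pos += _draw_intron(rng, spec)
            gstart, gend = cursor, pos
            if gend > spec.scaffold_length - 200:
                raise ValueError(
                    f"scaffold {scaf} too short to host requested genes "
                    f"(gene {gid} would end at {gend})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            ann.genes[gid] = GeneModel(gid, scaf, gstart, gend, strand, tuple(exons))
            truth.gene_class[gid] = gclass
            cursor = gend
            prev_padded = gclass != "background"

    # microsyntenic pairs: adjacent gene pairs with no intervening gene
    adjacent = ann.neighboring_pairs()
    if spec.n_syntenic_pairs > 0:
        used: set[str] = set()
        order = rng.permutation(len(adjacent))
        for i in order:
            a, b = adjacent[i]
            if a in used or b in used:
                continue
            truth.syntenic_pairs.append((a, b))
            used.update((a, b))
            if len(truth.syntenic_pairs) == spec.n_syntenic_pairs:
                break
        if len(truth.syntenic_pairs) < spec.n_syntenic_pairs:
            raise ValueError(
                "not enough disjoint adjacent gene pairs for requested synteny set"
            )

    # qPCR loci with planted fold changes (plus two intergenic controls)
    folds = [1.0, 2.0, 4.0, 8.0, 16.0]
    for i in range(spec.n_qpcr_loci):
        truth.qpcr_fold[f"locus_{i + 1:02d}"] = float(folds[i % len(folds)])

    return ann, truth


# ---------------------------------------------------------------------------
# enhancer planting


def _tss_forbidden_windows(
    ann: Annotation, flank: int, linc_flank: int | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Merged exclusion windows around every TSS (coding and lincRNA).

    lincRNA windows can be wider because the generator paints a broad
    chromatin domain around classed lincRNA TSSs.
    """
    lf = flank if linc_flank is None else linc_flank
    ivs = IntervalSet(
        [
            GenomicInterval(a.scaffold, max(0, a.pos - flank), a.pos + flank + 1)
            for a in ann.coding_tss()
        ]
        + [
            GenomicInterval(a.scaffold, max(0, a.pos - lf), a.pos + lf + 1)
            for a in ann.lincrna_tss()
        ]
    )
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in merge(ivs, 0):
        out.setdefault(iv.scaffold, []).append((iv.start, iv.end))
    return out


def plant_enhancers(
    ann: Annotation,
    truth: GroundTruth,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> None:
    """Choose genomic runs for deliberately planted enhancers.

    Candidate slots are bin-aligned runs of 2-3 bins lying wholly inside a
    coding-gene intron or an intergenic span, clear of every TSS +/- 400 bp
    window. Slots inside a microsyntenic unit span get their sampling
    weight multiplied by ``synteny_enhancer_boost``; boost 1 is uniform.
    Chosen runs are appended to ``truth.enhancers`` (activated with
    probability ``activated_fraction``) and the per-unit enhancer flags are
    recorded.
    """
    if rng is None:
        rng = spec.rng(1)
    bw = spec.bin_width
    forbidden = _tss_forbidden_windows(ann, flank=600, linc_flank=2400)

    unit_spans: dict[str, list[tuple[int, int]]] = {}
    for a, b in truth.syntenic_pairs:
        ga, gb = ann.genes[a], ann.genes[b]
        unit_spans.setdefault(ga.scaffold, []).append(
            (min(ga.start, gb.start), max(ga.end, gb.end))
        )

    host_regions: list[tuple[GenomicInterval, str | None]] = []
    for g in ann.genes.values():
        for iv in g.introns():
            host_regions.append((iv, g.gene_id))
    for iv in ann.intergenic():
        # scaffold-edge gaps are assembly margins, not regulatory space
        if iv.start == 0 or iv.end == ann.scaffold_lengths[iv.scaffold]:
            continue
        host_regions.append((iv, None))

    slots: list[tuple[str, int, int, str | None]] = []  # scaffold, b0, nbins, host
    weights: list[float] = []
    for iv, host in host_regions:
        first_bin = -(-iv.start // bw)  # ceil
        last_bin = iv.end // bw  # exclusive
        for nbins in (2, 3):
            for b0 in range(first_bin, last_bin - nbins + 1):
                lo, hi = b0 * bw, (b0 + nbins) * bw
                bad = any(
                    lo < e and s < hi for s, e in forbidden.get(iv.scaffold, ())
                )
                if bad:
                    continue
                in_unit = any(
                    lo >= s and hi <= e for s, e in unit_spans.get(iv.scaffold, ())
                )
                slots.append((iv.scaffold, b0, nbins, host))
                weights.append(spec.synteny_enhancer_boost if in_unit else 1.0)
    if spec.n_enhancers == 0:
        return
    if not slots:
        raise ValueError("no candidate slots for enhancer planting")

    w = np.asarray(weights)
    order = rng.choice(len(slots), size=len(slots), replace=False, p=w / w.sum())
    taken: dict[str, list[tuple[int, int]]] = {}
    placed = 0
    for i in order:
        scaf, b0, nbins, host = slots[i]
        lo, hi = b0 - 1, b0 + nbins + 1  # one bin of clearance between plants
        if any(lo < e and s < hi for s, e in taken.get(scaf, [])):
            continue
        taken.setdefault(scaf, []).append((b0, b0 + nbins))
        activated = bool(rng.random() < spec.activated_fraction)
        truth.enhancers.append(
            PlantedEnhancer(
                GenomicInterval(scaf, b0 * bw, (b0 + nbins) * bw),
                activated=activated,
                planted=True,
                resolvable=True,
                distal=True,
                target_gene=host,
            )
        )
        placed += 1
        if placed == spec.n_enhancers:
            break
    if placed < spec.n_enhancers:
        raise ValueError(
            f"could only place {placed} of {spec.n_enhancers} enhancers"
        )

    enh_set = truth.enhancer_set()
    from .intervals import _merged_by_scaffold, _overlap_bases

    spans = _merged_by_scaffold(enh_set)
    truth.syntenic_has_enhancer = []
    for a, b in truth.syntenic_pairs:
        ga, gb = ann.genes[a], ann.genes[b]
        span = GenomicInterval(
            ga.scaffold, min(ga.start, gb.start), max(ga.end, gb.end)
        )
        truth.syntenic_has_enhancer.append(
            _overlap_bases(span, spans.get(span.scaffold, ())) > 0
        )


# ---------------------------------------------------------------------------
# chromatin simulation


def _sample_chain(
    rng: np.random.Generator, transition: np.ndarray, n: int
) -> np.ndarray:
    pi = stationary_distribution(transition)
    K = transition.shape[0]
    cum = transition.cumsum(axis=1)
    path = np.empty(n, dtype=np.int64)
    path[0] = rng.choice(K, p=pi)
    u = rng.random(n)
    for t in range(1, n):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    return path


def _force_runs(
    truth: GroundTruth, ann: Annotation, spec: SyntheticSpec
) -> tuple[
    dict[str, list[tuple[int, int, int]]], dict[str, list[tuple[int, int]]]
]:
    """Bin runs to overwrite in the sampled chain, plus quiet zones.

    Returns ``(forced, quiet)``: forced runs as (start_bin, end_bin,
    state); quiet zones are spans (around classed lincRNA TSSs) where
    chain-emitted promoter/enhancer states yield to the quiescent state so
    the planted ratio signature is not confounded by chance neighbours.
    """
    bw = spec.bin_width
    name_to_idx = {n: i for i, n in enumerate(spec.state_names)}
    forced: dict[str, list[tuple[int, int, int]]] = {}
    quiet: dict[str, list[tuple[int, int]]] = {}

    for e in truth.enhancers:
        if not e.planted:
            continue
        st = name_to_idx[ACTIVATED_STATE if e.activated else SILENT_ENHANCER_STATE]
        b0, b1 = e.interval.start // bw, e.interval.end // bw
        forced.setdefault(e.interval.scaffold, []).append((b0, b1, st))

    # lincRNA promoter chromatin: elinc TSSs are H3K4me1-dominant with a
    # one-bin H3K4me3-state satellite (so the locus still overlaps H3K4me3
    # and RNAPII peaks and stays eligible); plinc TSSs are the reverse
    if "TssA" in name_to_idx and "EnhWk" in name_to_idx:
        tssa, enhwk = name_to_idx["TssA"], name_to_idx["EnhWk"]
        for lid, lclass in truth.lincrna_class.items():
            if lclass == "neither":
                continue
            g = ann.lincrnas[lid]
            tb = g.tss.pos // bw
            n_bins = ann.scaffold_lengths[g.scaffold] // bw
            main = enhwk if lclass == "elinc" else tssa
            sat = tssa if lclass == "elinc" else enhwk
            b0, b1 = max(0, tb - 5), min(n_bins, tb + 6)
            forced.setdefault(g.scaffold, []).append((b0, b1, main))
            # satellite of the opposite mark at the far (TES) end of the
            # locus: keeps the locus overlapping all three eligibility
            # peak sets without flipping the TSS-window ratio
            sb = g.tes.pos // bw
            if sb != tb:
                forced.setdefault(g.scaffold, []).append((sb, sb + 1, sat))
            quiet.setdefault(g.scaffold, []).append(
                (max(0, tb - 10), min(n_bins, tb + 11))
            )
    return forced, quiet


def simulate_chromatin(
    ann: Annotation,
    truth: GroundTruth,
    spec: SyntheticSpec,
    n_replicates: int = 2,
    replicate_concordance: float = 1.0,
) -> tuple[dict[str, list[BinnedTrack]], BinnedTrack]:
    """Sample the hidden state chain and emit per-mark count tracks.

    Per scaffold the chain is drawn from ``transition_matrix`` (stationary
    start), planted enhancer and lincRNA runs are overwritten, and every
    maximal run of an enhancer-designated state is recorded in the truth.
    Per bin and mark, mark presence is Bernoulli(emission[state, mark]);
    each replicate's count is Poisson(lambda_signal) where the mark is
    present and Poisson(lambda_background) otherwise; the input track is
    Poisson(lambda_background) everywhere. ``replicate_concordance`` < 1
    makes each replicate drop (ignore) each present mark run independently
    with that probability of keeping it, giving discordant replicates.

    Returns ({mark: [replicate tracks]}, input track) and fills
    ``truth.state_path``.
    """
    if len(spec.marks) == 0:
        raise ValueError("marks list must not be empty")
    rng = spec.rng(2)
    bw = spec.bin_width
    forced, quiet = _force_runs(truth, ann, spec)
    enh_idx = set(spec.enhancer_state_indices().values())
    name_to_idx = {n: i for i, n in enumerate(spec.state_names)}
    activated_idx = name_to_idx.get(ACTIVATED_STATE, -1)

    tss_margin = _tss_forbidden_windows(ann, flank=400)
    planted_keys = {
        (e.interval.scaffold, e.interval.start, e.interval.end)
        for e in truth.enhancers
    }

    tracks: dict[str, list[dict[str, np.ndarray]]] = {
        m: [dict() for _ in range(n_replicates)] for m in spec.marks
    }
    input_data: dict[str, np.ndarray] = {}

    for scaf in sorted(ann.scaffold_lengths):
        n_bins = ann.scaffold_lengths[scaf] // bw
        path = _sample_chain(rng, spec.transition_matrix, n_bins)
        planted_mask = np.zeros(n_bins, dtype=bool)
        for b0, b1, st in forced.get(scaf, []):
            planted_mask[b0:b1] = True
        if "Quies" in spec.state_names and planted_mask.any():
            quies = list(spec.state_names).index("Quies")
            # keep planted elements separable: chain-emitted enhancer
            # states within 2 bins of a planted run would fuse with it at
            # the region caller's gap tolerance
            near = np.convolve(planted_mask, np.ones(5), mode="same") > 0
            clash = near & ~planted_mask & np.isin(path, list(enh_idx))
            path[clash] = quies
            # quiet zones around classed lincRNA TSSs: chance chromatin
            # rich in either H3K4 mark would confound the planted ratio
            loud = list(enh_idx) + [
                name_to_idx[n]
                for n in ("TssA", "TxFlnk", "BivTx")
                if n in name_to_idx
            ]
            for z0, z1 in quiet.get(scaf, []):
                zone = np.zeros(n_bins, dtype=bool)
                zone[z0:z1] = True
                clash = zone & ~planted_mask & np.isin(path, loud)
                path[clash] = quies
        for b0, b1, st in forced.get(scaf, []):
            path[b0:b1] = st
        truth.state_path[scaf] = path

        # record chain-emitted enhancer runs not already planted
        is_enh = np.isin(path, list(enh_idx))
        d = np.diff(is_enh.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if is_enh.size and is_enh[0]:
            starts.insert(0, 0)
        if is_enh.size and is_enh[-1]:
            ends.append(n_bins)
        for a, b in zip(starts, ends):
            iv = GenomicInterval(scaf, a * bw, b * bw)
            if (scaf, iv.start, iv.end) in planted_keys:
                continue
            distal = not any(
                iv.start < e and s < iv.end for s, e in tss_margin.get(scaf, ())
            )
            truth.enhancers.append(
                PlantedEnhancer(
                    iv,
                    activated=bool((path[a:b] == activated_idx).any()),
                    planted=False,
                    resolvable=(b - a) >= 2,
                    distal=distal,
                )
            )

        present = rng.random((n_bins, len(spec.marks))) < spec.emission_probs[path]
        for mi, m in enumerate(spec.marks):
            for r in range(n_replicates):
                pres = present[:, mi].copy()
                if replicate_concordance < 1.0:
                    keep = rng.random(n_bins) < replicate_concordance
                    pres &= keep
                lam = np.where(pres, spec.lambda_signal, spec.lambda_background)
                tracks[m][r][scaf] = rng.poisson(lam)
        input_data[scaf] = rng.poisson(
            spec.lambda_background * spec.input_depth, size=n_bins
        )

    out = {
        m: [BinnedTrack(rep, bin_width=bw) for rep in reps]
        for m, reps in tracks.items()
    }
    return out, BinnedTrack(input_data, bin_width=bw)


# ---------------------------------------------------------------------------
# expression simulation


def _stage_means(
    gclass: str, n_stages: int, rng: np.random.Generator
) -> np.ndarray:
    if gclass == "stable":
        return np.full(n_stages, rng.lognormal(math.log(50.0), 0.5))
    if gclass == "low_variance":
        return np.full(n_stages, rng.lognormal(math.log(8.0), 0.3))
    if gclass == "regulated":
        # restricted expression: two adjacent stages on, near-zero elsewhere
        mu = np.full(n_stages, 0.2)
        s = int(rng.integers(0, n_stages - 1))
        mu[s : s + 2] = rng.lognormal(math.log(200.0), 0.4)
        return mu
    if gclass == "high_variance":
        # dynamic developmental trajectory: a permuted log2 ladder with a
        # guaranteed amplitude, so the median absolute deviation across
        # stages is large for every member of the class
        base = rng.lognormal(math.log(30.0), 0.5)
        amplitude = rng.uniform(1.5, 2.5)
        ladder = np.linspace(-1.5, 1.5, n_stages)
        mu = base * 2.0 ** (amplitude * rng.permutation(ladder))
        mu[-1] = max(mu[-1], 10.0)  # detectable in the adult stage
        return mu
    return np.full(n_stages, 0.05)  # background: below the raw-count floor


def simulate_expression(
    ann: Annotation, truth: GroundTruth, spec: SyntheticSpec
) -> ExpressionMatrix:
    """Negative-binomial counts for every coding gene over the stage series.

    Replicates of a stage share the gene's stage mean. Stable genes get a
    housekeeping-like low dispersion (``stable_dispersion``); all other
    classes use ``nb_dispersion``. Dispersion exactly 0 is the noiseless
    limit: counts equal the rounded means.
    """
    if spec.n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    if set(truth.gene_class) != set(ann.genes):
        raise ValueError("gene_class must label every coding gene")
    rng = spec.rng(3)
    stages = [f"stage_{i + 1:02d}" for i in range(spec.n_stages)]
    samples, stage_map = [], {}
    for st in stages:
        for r in range(spec.replicates_per_stage):
            name = f"{st}_rep{r + 1}"
            samples.append(name)
            stage_map[name] = st

    rows = {}
    for gid in sorted(ann.genes):
        gclass = truth.gene_class[gid]
        mu = _stage_means(gclass, spec.n_stages, rng)
        phi = spec.stable_dispersion if gclass == "stable" else spec.nb_dispersion
        counts = np.empty(len(samples), dtype=np.int64)
        for si, st in enumerate(stages):
            for r in range(spec.replicates_per_stage):
                j = si * spec.replicates_per_stage + r
                if phi == 0:
                    counts[j] = int(round(mu[si]))
                else:
                    lam = rng.gamma(1.0 / phi, mu[si] * phi)
                    counts[j] = rng.poisson(lam)
        rows[gid] = counts
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return ExpressionMatrix(frame, stage_map, "raw")


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_qpcr(
    truth: GroundTruth,
    spec: SyntheticSpec,
    control_loci: tuple[str, str] = ("intergenic_1", "intergenic_2"),
) -> pd.DataFrame:
    """Long-format Cq table inverting the ddCq equations.

    IP Cq = baseline - log2(efficiency x fold) + N(0, sigma); the input
    aliquot represents ``qpcr_input_fraction`` of the chromatin, adding
    -log2(fraction) cycles to input Cq. Control loci have fold 1, so at
    sigma = 0 the ddCq pipeline returns the planted fold exactly.
    """
    if any(f <= 0 for f in truth.qpcr_fold.values()):
        raise ValueError("planted fold changes must be positive")
    rng = spec.rng(4)
    b_ip, b_input, eff = 27.0, 24.0, 0.05
    rows = []
    loci = {**truth.qpcr_fold, **{c: 1.0 for c in control_loci}}
    for locus in sorted(loci):
        fold = loci[locus]
        rows.append(
            {
                "locus": locus,
                "assay": "ip",
                "cq": b_ip
                - math.log2(eff * fold)
                + rng.normal(0.0, spec.qpcr_sigma),
            }
        )
        rows.append(
            {
                "locus": locus,
                "assay": "input",
                "cq": b_input
                - math.log2(spec.qpcr_input_fraction)
                + rng.normal(0.0, spec.qpcr_sigma),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery helpers


def enhancer_recovery(
    predicted: IntervalSet, truth: GroundTruth
) -> dict[str, float]:
    """Element-level recall and precision of predictions vs true enhancers.

    Recall is measured over the deliberately planted elements (placed
    distal and at resolvable size); chain-emitted runs can sit closer to a
    promoter than the region caller can separate, so they bound precision
    but are not demanded for recall. Precision counts a prediction as
    correct when it overlaps any true enhancer run.
    """
    from .intervals import _merged_by_scaffold, _overlap_bases

    target = IntervalSet(
        [e.interval for e in truth.enhancers if e.planted]
    ) or truth.enhancer_set(distal_only=True, resolvable_only=True)
    pred_spans = _merged_by_scaffold(predicted)
    hit = sum(
        1
        for iv in target
        if _overlap_bases(iv, pred_spans.get(iv.scaffold, ())) > 0
    )
    recall = hit / len(target) if len(target) else float("nan")
    all_spans = _merged_by_scaffold(truth.enhancer_set())
    correct = sum(
        1
        for iv in predicted
        if _overlap_bases(iv, all_spans.get(iv.scaffold, ())) > 0
    )
    precision = correct / len(predicted) if len(predicted) else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_true": len(target),
        "n_predicted": len(predicted),
    }
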