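"""Multivariate Bernoulli-emission hidden Markov model for chromatin states.

Each 200-bp genomic bin carries a binary presence/absence vector over the
assayed histone marks. A K-state HMM with independent Bernoulli emissions
per mark — P(o | s) = Π_m p_{s,m}^{o_m} (1 - p_{s,m})^{1 - o_m} — is trained
by Baum-Welch over all scaffolds (treated as independent chains) and decoded
by posterior marginals or Viterbi. State/feature overlap and TSS/TES
neighbourhood enrichment tables reproduce the normalisations used to assign
biological mnemonics to states.

Numerics: scaled forward-backward with per-bin normalisation constants;
emission and transition probabilities clipped to [1e-6, 1 - 1e-6].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import Anchor, GenomicInterval, IntervalSet, intersect, merge
from .tracks import BinnedTrack

__all__ = [
    "BinaryObservationMatrix",
    "ChromatinHMM",
    "Segmentation",
    "StateEnrichmentTable",
    "train",
    "decode",
    "loglikelihood",
    "overlap_enrichment",
    "column_scale",
    "global_scale",
    "positional_enrichment",
    "best_state_relabeling",
]

_EPS = 1e-6


@dataclass
class BinaryObservationMatrix:
    """Per scaffold, a (bins x marks) 0/1 matrix with a fixed mark order."""

    data: dict[str, np.ndarray]
    marks: tuple[str, ...]
    bin_width: int = 200

    def __post_init__(self) -> None:
        self.marks = tuple(self.marks)
        self.data = {s: np.asarray(v, dtype=np.uint8) for s, v in self.data.items()}
        for s, v in self.data.items():
            if v.ndim != 2 or v.shape[1] != len(self.marks):
                raise ValueError(f"observation matrix for {s} must be bins x marks")
            if not np.isin(v, (0, 1)).all():
                raise ValueError("observations must be binary")

    @classmethod
    def from_binarized(
        cls, binarized: dict[str, dict[str, np.ndarray]], marks: list[str],
        bin_width: int = 200,
    ) -> "BinaryObservationMatrix":
        """Assemble from per-mark binarized tracks ``{mark: {scaffold: vec}}``."""
        scaffolds = sorted(binarized[marks[0]])
        data = {
            s: np.stack([binarized[m][s] for m in marks], axis=1)
            for s in scaffolds
        }
        return cls(data, tuple(marks), bin_width)

    def scaffolds(self) -> list[str]:
        return sorted(self.data)

    @property
    def n_bins(self) -> int:
        return int(sum(v.shape[0] for v in self.data.values()))


@dataclass
class ChromatinHMM:
    initial: np.ndarray  # (K,)
    transition: np.ndarray  # (K, K) row-stochastic
    emission: np.ndarray  # (K, M) Bernoulli success probabilities
    marks: tuple[str, ...]
    training_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        K = self.initial.size
        if self.transition.shape != (K, K):
            raise ValueError("transition must be K x K")
        if self.emission.shape[0] != K or self.emission.shape[1] != len(self.marks):
            raise ValueError("emission must be K x M")
        if abs(self.initial.sum() - 1) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.initial.size


@dataclass
class Segmentation:
    """Per-scaffold per-bin state assignment."""

    states: dict[str, np.ndarray]
    n_states: int
    bin_width: int = 200
    method: str = "posterior"
    state_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.states = {s: np.asarray(v, dtype=np.int64) for s, v in self.states.items()}
        for s, v in self.states.items():
            if v.size and (v.min() < 0 or v.max() >= self.n_states):
                raise ValueError(f"state index out of range on {s}")

    def scaffolds(self) -> list[str]:
        return sorted(self.states)

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.states.values()))

    def occupancy(self) -> np.ndarray:
        """Genome-wide fraction of bins per state."""
        counts = np.zeros(self.n_states)
        for v in self.states.values():
            counts += np.bincount(v, minlength=self.n_states)
        return counts / max(1, self.n_bins)

    def state_intervals(self, state: int) -> IntervalSet:
        """Maximal runs of one state as genomic intervals."""
        out = []
        bw = self.bin_width
        for s, v in self.states.items():
            if v.size == 0:
                continue
            is_state = v == state
            diff = np.diff(is_state.astype(np.int8))
            starts = list(np.flatnonzero(diff == 1) + 1)
            ends = list(np.flatnonzero(diff == -1) + 1)
            if is_state[0]:
                starts.insert(0, 0)
            if is_state[-1]:
                ends.append(v.size)
            for a, b in zip(starts, ends):
                out.append(GenomicInterval(s, a * bw, b * bw))
        return IntervalSet(out)

    def intervals_for_states(self, states: set[int]) -> IntervalSet:
        ivs = []
        for st in states:
            ivs.extend(self.state_intervals(st).intervals)
        return merge(IntervalSet(ivs), 0)


def _emission_loglik(obs: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """(T x K) log P(o_t | s) for binary obs (T x M)."""
    p = np.clip(emission, _EPS, 1 - _EPS)
    return obs.astype(float) @ np.log(p).T + (1 - obs).astype(float) @ np.log1p(-p).T

def _forward_backward(
    loglik_b: np.ndarray, initial: np.ndarray, transition: np.ndarray
):
    """Scaled forward-backward. Returns (alpha, beta, scales, loglik)."""
    T, K = loglik_b.shape
    b = np.exp(loglik_b - loglik_b.max(axis=1, keepdims=True))
    alpha = np.empty((T, K))
    scales = np.empty(T)
    alpha[0] = initial * b[0]
    scales[0] = alpha[0].sum()
    alpha[0] /= scales[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * b[t]
        scales[t] = a.sum()
        alpha[t] = a / scales[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transition @ (b[t + 1] * beta[t + 1])) / scales[t + 1]
    loglik = float(np.log(scales).sum() + loglik_b.max(axis=1).sum())
    return alpha, beta, scales, loglik


def loglikelihood(model: ChromatinHMM, obs: BinaryObservationMatrix) -> float:
    """Total log-likelihood of the observations, scaffolds independent."""
    total = 0.0
    for s in obs.scaffolds():
        ll_b = _emission_loglik(obs.data[s], model.emission)
        *_, ll = _forward_backward(ll_b, model.initial, model.transition)
        total += ll
    return total


def _em_iteration(model: ChromatinHMM, obs: BinaryObservationMatrix):
    K, M = model.emission.shape
    init_acc = np.zeros(K)
    trans_acc = np.zeros((K, K))
    gamma_sum = np.zeros(K)
    emit_acc = np.zeros((K, M))
    total_ll = 0.0
    for s in obs.scaffolds():
        o = obs.data[s]
        if o.shape[0] == 0:
            continue
        ll_b = _emission_loglik(o, model.emission)
        alpha, beta, scales, ll = _forward_backward(
            ll_b, model.initial, model.transition
        )
        total_ll += ll
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        init_acc += gamma[0]
        b = np.exp(ll_b - ll_b.max(axis=1, keepdims=True))
        # xi_t(i,j) ∝ alpha_t(i) A_ij b_{t+1}(j) beta_{t+1}(j); summed over t
        if o.shape[0] > 1:
            c = (b[1:] * beta[1:]) / scales[1:, None]
            trans_acc += model.transition * (alpha[:-1].T @ c)
        gamma_sum += gamma.sum(axis=0)
        emit_acc += gamma.T @ o
    initial = init_acc / init_acc.sum()
    rows = trans_acc.sum(axis=1, keepdims=True)
    transition = np.where(rows > 0, trans_acc / np.maximum(rows, 1e-300), model.transition)
    transition /= transition.sum(axis=1, keepdims=True)
    emission = np.clip(emit_acc / gamma_sum[:, None], _EPS, 1 - _EPS)
    return ChromatinHMM(initial, transition, emission, model.marks), total_ll


def train(
    obs: BinaryObservationMatrix,
    n_states: int,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> ChromatinHMM:
    """Baum-Welch training with multiple random restarts.

    Per restart, emissions start uniform in [0.1, 0.9] and the transition
    matrix near-uniform with a self-transition boost; the restart with the
    highest final log-likelihood wins. The per-iteration log-likelihood is
    recorded in ``training_log`` and is non-decreasing (up to 1e-8).
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if obs.n_bins == 0:
        raise ValueError("empty observation matrix")
    rng = np.random.default_rng(seed)
    M = len(obs.marks)
    best: ChromatinHMM | None = None
    best_ll = -np.inf
    for _ in range(max(1, n_restarts)):
        emission = rng.uniform(0.1, 0.9, size=(n_states, M))
        transition = np.full((n_states, n_states), 1.0) + 0.5 * n_states * np.eye(
            n_states
        )
        transition /= transition.sum(axis=1, keepdims=True)
        initial = np.full(n_states, 1.0 / n_states)
        model = ChromatinHMM(initial, transition, emission, obs.marks)
        log: list[float] = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            new_model, ll = _em_iteration(model, obs)
            if log and ll < log[-1] - 1e-8:
                raise AssertionError("EM log-likelihood decreased")
            log.append(ll)
            model = new_model
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
                break
            prev_ll = ll
        final_ll = loglikelihood(model, obs)
        model.training_log = log
        if final_ll > best_ll:
            best_ll, best = final_ll, model
    assert best is not None
    return best


def posterior_marginals(
    model: ChromatinHMM, obs: BinaryObservationMatrix
) -> dict[str, np.ndarray]:
    out = {}
    for s in obs.scaffolds():
        ll_b = _emission_loglik(obs.data[s], model.emission)
        alpha, beta, *_ = _forward_backward(ll_b, model.initial, model.transition)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        out[s] = gamma
    return out


def _viterbi(loglik_b: np.ndarray, initial: np.ndarray, transition: np.ndarray):
    T, K = loglik_b.shape
    log_a = np.log(np.clip(transition, 1e-300, None))
    delta = np.log(np.clip(initial, 1e-300, None)) + loglik_b[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + log_a
        back[t] = cand.argmax(axis=0)
        delta = cand[back[t], np.arange(K)] + loglik_b[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def decode(
    model: ChromatinHMM, obs: BinaryObservationMatrix, method: str = "posterior"
) -> Segmentation:
    """Assign a state to every bin by posterior argmax or Viterbi."""
    if tuple(model.marks) != tuple(obs.marks):
        raise ValueError(
            f"model marks {model.marks} do not match observations {obs.marks}"
        )
    if method not in ("posterior", "viterbi"):
        raise ValueError(f"unknown decode method {method!r}")
    states = {}
    for s in obs.scaffolds():
        ll_b = _emission_loglik(obs.data[s], model.emission)
        if method == "posterior":
            alpha, beta, *_ = _forward_backward(ll_b, model.initial, model.transition)
            gamma = alpha * beta
            states[s] = gamma.argmax(axis=1)
        else:
            states[s] = _viterbi(ll_b, model.initial, model.transition)
    return Segmentation(states, model.n_states, obs.bin_width, method)


@dataclass
class StateEnrichmentTable:
    values: np.ndarray  # states x features
    features: tuple[str, ...]
    normalization: str = "raw_fold"  # raw_fold | column_scaled | global_scaled


def overlap_enrichment(
    seg: Segmentation,
    features: dict[str, IntervalSet],
    genome_size: int,
    alt_normalization: bool = False,
) -> StateEnrichmentTable:
    """Fold enrichment of each chromatin state in each genomic feature.

    raw_fold(s, f) = (bases of s within f / bases of s) / (bases of f /
    genome size), so 1.0 means the state covers the feature no more than
    chance. ``alt_normalization`` switches the numerator's denominator to
    the feature size instead of the state size (an alternative reading of
    the same ratio); the default matches the segmentation tool's formula.
    """
    names = tuple(features)
    K = seg.n_states
    vals = np.full((K, len(names)), np.nan)
    state_sets = {st: seg.state_intervals(st) for st in range(K)}
    for j, fname in enumerate(names):
        fset = merge(features[fname], 0)
        f_bases = fset.total_bases()
        if f_bases == 0:
            continue  # zero-length feature set: column stays missing
        f_frac = f_bases / genome_size
        for st in range(K):
            s_bases = state_sets[st].total_bases()
            if s_bases == 0:
                continue
            inter = 0
            from .intervals import _merged_by_scaffold, _overlap_bases

            spans = _merged_by_scaffold(fset)
            for iv in state_sets[st]:
                inter += _overlap_bases(iv, spans.get(iv.scaffold, ()))
            denom = f_bases if alt_normalization else s_bases
            vals[st, j] = (inter / denom) / f_frac
    return StateEnrichmentTable(vals, names, "raw_fold")


def column_scale(table: StateEnrichmentTable) -> StateEnrichmentTable:
    """Scale each column to [0, 1]: subtract its minimum, divide by the
    resulting maximum. Constant columns map to all zeros."""
    v = table.values.astype(float).copy()
    for j in range(v.shape[1]):
        col = v[:, j]
        ok = np.isfinite(col)
        if not ok.any():
            continue
        col = col - col[ok].min()
        mx = col[ok].max()
        v[:, j] = col / mx if mx > 0 else 0.0
        v[~ok, j] = np.nan
    return StateEnrichmentTable(v, table.features, "column_scaled")


def global_scale(table: StateEnrichmentTable) -> StateEnrichmentTable:
    """Scale the whole matrix to [0, 1] by its global min and max."""
    v = table.values.astype(float).copy()
    ok = np.isfinite(v)
    if ok.any():
        v = v - v[ok].min()
        mx = v[ok].max()
        v = v / mx if mx > 0 else np.zeros_like(v)
    return StateEnrichmentTable(v, table.features, "global_scaled")


def positional_enrichment(
    seg: Segmentation,
    anchors: list[Anchor],
    flank: int = 1000,
    step: int = 100,
    scale: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """State enrichment in ``step``-bp positions around stranded anchors.

    Returns (offsets, table) where table is states x positions: the
    frequency of each state at each offset divided by its genome-wide
    occupancy. Minus-strand anchors contribute with mirrored offsets so
    positive offsets always point downstream. With ``scale`` the table is
    min-max scaled over the whole matrix.
    """
    offsets = np.arange(-flank, flank, step)
    K = seg.n_states
    counts = np.zeros((K, offsets.size))
    totals = np.zeros(offsets.size)
    bw = seg.bin_width
    for an in anchors:
        if an.strand not in ("+", "-"):
            raise ValueError(f"anchor {an} lacks strand (strand-aware mode)")
        v = seg.states.get(an.scaffold)
        if v is None:
            continue
        for i, off in enumerate(offsets):
            pos = an.pos + (off if an.strand == "+" else -off - step + 1)
            b = pos // bw
            if pos < 0 or b >= v.size:
                continue
            counts[v[b], i] += 1
            totals[i] += 1
    occ = seg.occupancy()
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / np.maximum(totals, 1)
        table = freq / np.where(occ > 0, occ, np.nan)[:, None]
    if scale:
        tab = StateEnrichmentTable(table, tuple(str(o) for o in offsets))
        table = global_scale(tab).values
    return offsets, table


def best_state_relabeling(
    true_emission: np.ndarray, est_emission: np.ndarray
) -> np.ndarray:
    """Permutation mapping estimated states onto true states minimising the
    total absolute emission difference (states are label-free)."""
    from scipy.optimize import linear_sum_assignment

    K = true_emission.shape[0]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(true_emission[i] - est_emission[j]).sum()
    _, col = linear_sum_assignment(cost)
    return col  # col[i] = estimated state matching true state i
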