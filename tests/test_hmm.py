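"""Bernoulli-emission HMM: exact small-chain oracles and recovery."""

import itertools

import numpy as np
import pytest

from chromstate import hmm
from chromstate.intervals import Anchor, GenomicInterval, IntervalSet


def brute_force_loglik(initial, transition, emission, obs):
    """Log-likelihood by exhaustive summation over all K^T state paths."""
    T = obs.shape[0]
    K = initial.size
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = initial[path[0]]
        for t in range(1, T):
            p *= transition[path[t - 1], path[t]]
        for t, s in enumerate(path):
            for m in range(obs.shape[1]):
                pm = emission[s, m]
                p *= pm if obs[t, m] else (1 - pm)
        total += p
    return np.log(total)


def _random_model(rng, K, M):
    initial = rng.dirichlet(np.ones(K))
    transition = rng.dirichlet(np.ones(K), size=K)
    emission = rng.uniform(0.05, 0.95, size=(K, M))
    return initial, transition, emission


@pytest.mark.parametrize("K,M,T", [(2, 1, 6), (3, 2, 6), (4, 2, 8), (2, 3, 8)])
def test_likelihood_matches_path_enumeration(K, M, T):
    rng = np.random.default_rng(K * 100 + T)
    initial, transition, emission = _random_model(rng, K, M)
    obs = (rng.random((T, M)) < 0.5).astype(np.uint8)
    model = hmm.ChromatinHMM(
        initial, transition, emission, tuple(f"m{i}" for i in range(M))
    )
    o = hmm.BinaryObservationMatrix({"s": obs}, model.marks)
    assert hmm.loglikelihood(model, o) == pytest.approx(
        brute_force_loglik(initial, transition, emission, obs), abs=1e-9
    )


def test_trained_model_likelihood_matches_enumeration_on_toy_chain():
    rng = np.random.default_rng(0)
    obs = (rng.random((6, 1)) < 0.5).astype(np.uint8)
    o = hmm.BinaryObservationMatrix({"s": obs}, ("m",))
    model = hmm.train(o, 2, n_restarts=2, max_iter=50, seed=1)
    assert hmm.loglikelihood(model, o) == pytest.approx(
        brute_force_loglik(model.initial, model.transition, model.emission, obs),
        abs=1e-9,
    )


def test_k1_closed_form():
    rng = np.random.default_rng(2)
    obs = (rng.random((50, 3)) < [0.2, 0.5, 0.8]).astype(np.uint8)
    o = hmm.BinaryObservationMatrix({"s": obs}, ("a", "b", "c"))
    model = hmm.train(o, 1, n_restarts=1, max_iter=20, seed=0)
    assert model.transition == pytest.approx(np.array([[1.0]]))
    assert model.emission[0] == pytest.approx(obs.mean(axis=0), abs=1e-9)
    seg = hmm.decode(model, o)
    assert (seg.states["s"] == 0).all()


def test_em_loglik_monotone_and_posteriors_normalized():
    rng = np.random.default_rng(3)
    obs = (rng.random((400, 2)) < 0.4).astype(np.uint8)
    o = hmm.BinaryObservationMatrix({"s": obs}, ("a", "b"))
    model = hmm.train(o, 3, n_restarts=3, max_iter=60, seed=5)
    log = np.array(model.training_log)
    assert (np.diff(log) >= -1e-8).all()
    gamma = hmm.posterior_marginals(model, o)["s"]
    assert np.abs(gamma.sum(axis=1) - 1).max() < 1e-9


def _planted_chain(rng, T):
    true_em = np.array(
        [[0.9, 0.1, 0.2, 0.8], [0.2, 0.85, 0.7, 0.1], [0.05, 0.05, 0.05, 0.05]]
    )
    trans = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.05, 0.05, 0.9]])
    path = np.zeros(T, dtype=int)
    cum = trans.cumsum(axis=1)
    u = rng.random(T)
    for t in range(1, T):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    obs = (rng.random((T, 4)) < true_em[path]).astype(np.uint8)
    return true_em, trans, path, obs


def test_parameter_recovery_small():
    # quick version of the recovery check (full size runs in acceptance)
    rng = np.random.default_rng(4)
    true_em, trans, path, obs = _planted_chain(rng, 10_000)
    o = hmm.BinaryObservationMatrix({"s": obs}, ("a", "b", "c", "d"))
    model = hmm.train(o, 3, n_restarts=3, max_iter=100, seed=0)
    perm = hmm.best_state_relabeling(true_em, model.emission)
    assert np.abs(true_em - model.emission[perm]).max() <= 0.05
    inv = np.empty(3, dtype=int)
    inv[perm] = np.arange(3)
    seg = hmm.decode(model, o, "posterior")
    assert (inv[seg.states["s"]] == path).mean() >= 0.9


def test_posterior_and_viterbi_agree_in_noiseless_limit():
    # deterministic emissions + sticky transitions: both decoders recover
    # the unambiguous path
    em = np.array([[1.0, 0.0], [0.0, 1.0]])
    trans = np.array([[0.95, 0.05], [0.05, 0.95]])
    model = hmm.ChromatinHMM(np.array([0.5, 0.5]), trans, em, ("a", "b"))
    obs = np.array([[1, 0]] * 5 + [[0, 1]] * 5 + [[1, 0]] * 5, dtype=np.uint8)
    o = hmm.BinaryObservationMatrix({"s": obs}, ("a", "b"))
    post = hmm.decode(model, o, "posterior").states["s"]
    vit = hmm.decode(model, o, "viterbi").states["s"]
    assert (post == vit).all()
    assert (post == np.array([0] * 5 + [1] * 5 + [0] * 5)).all()


def test_decode_rejects_mark_mismatch():
    model = hmm.ChromatinHMM(
        np.array([1.0]), np.array([[1.0]]), np.array([[0.5]]), ("x",)
    )
    o = hmm.BinaryObservationMatrix({"s": np.zeros((3, 1), dtype=np.uint8)}, ("y",))
    with pytest.raises(ValueError):
        hmm.decode(model, o)


def _segmentation(states, bw=200):
    return hmm.Segmentation({"s": np.asarray(states)}, int(np.max(states)) + 1, bw)


def test_overlap_enrichment_arithmetic():
    # state 1 occupies exactly a feature covering 10% of the genome
    states = np.zeros(100, dtype=int)
    states[:10] = 1
    seg = _segmentation(states)
    feat = IntervalSet([GenomicInterval("s", 0, 2000)])
    table = hmm.overlap_enrichment(seg, {"f": feat}, genome_size=20_000)
    assert table.values[1, 0] == pytest.approx(10.0)
    whole = IntervalSet([GenomicInterval("s", 0, 20_000)])
    t2 = hmm.overlap_enrichment(seg, {"g": whole}, genome_size=20_000)
    assert t2.values[0, 0] == pytest.approx(1.0)
    assert t2.values[1, 0] == pytest.approx(1.0)


def test_overlap_enrichment_null_near_one():
    rng = np.random.default_rng(8)
    states = rng.integers(0, 3, size=10_000)
    seg = _segmentation(states)
    feats = {
        "f1": IntervalSet([GenomicInterval("s", 0, 1_000_000)]),
        "f2": IntervalSet(
            [GenomicInterval("s", int(p), int(p) + 5000) for p in range(0, 2_000_000, 20_000)]
        ),
    }
    table = hmm.overlap_enrichment(seg, feats, genome_size=2_000_000)
    ok = np.isfinite(table.values)
    assert ((table.values[ok] > 0.8) & (table.values[ok] < 1.25)).all()


def test_column_scale_and_global_scale():
    t = hmm.StateEnrichmentTable(
        np.array([[2.0, 5.0], [4.0, 5.0], [6.0, 5.0]]), ("a", "b")
    )
    scaled = hmm.column_scale(t)
    assert scaled.values[:, 0] == pytest.approx([0.0, 0.5, 1.0])
    assert scaled.values[:, 1] == pytest.approx([0.0, 0.0, 0.0])  # constant -> zeros
    assert scaled.normalization == "column_scaled"
    g = hmm.global_scale(t)
    assert g.values.min() == 0.0 and g.values.max() == 1.0


def test_positional_enrichment_constant_segmentation_flat():
    seg = _segmentation(np.zeros(200, dtype=int))
    offs, table = hmm.positional_enrichment(
        seg, [Anchor("s", 20_000, "+")], flank=1000, step=100
    )
    assert table.shape == (1, offs.size)
    assert table[0] == pytest.approx(np.ones(offs.size))


def test_positional_enrichment_peak_at_anchor_and_mirroring():
    # state 1 planted in the bins right of two anchors (strand-aware)
    states = np.zeros(400, dtype=int)
    plus_tss, minus_tss = 20_000, 60_000
    states[plus_tss // 200 : plus_tss // 200 + 3] = 1  # downstream of + anchor
    states[minus_tss // 200 - 2 : minus_tss // 200 + 1] = 1  # downstream of -
    seg = _segmentation(states)
    anchors = [Anchor("s", plus_tss, "+"), Anchor("s", minus_tss, "-")]
    offs, table = hmm.positional_enrichment(seg, anchors, flank=1000, step=100)
    prof = table[1]
    downstream = prof[offs >= 0]
    upstream = prof[offs < -200]
    assert np.nanmax(downstream) > np.nanmax(upstream)
    with pytest.raises(ValueError):
        hmm.positional_enrichment(seg, [Anchor("s", 100, ".")])


def test_segmentation_state_intervals_roundtrip():
    states = np.array([0, 0, 1, 1, 1, 0, 2, 2])
    seg = _segmentation(states)
    ivs = seg.state_intervals(1)
    assert ivs.intervals == [GenomicInterval("s", 400, 1000)]
    assert seg.occupancy() == pytest.approx([3 / 8, 3 / 8, 2 / 8])
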