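"""Expression normalisation, stage compression and gene classes."""

import numpy as np
import pandas as pd
import pytest

from chromstate.expression import (
    ExpressionMatrix,
    StableRegulatedConfig,
    VarianceClassConfig,
    classify_expressed,
    compress_stages,
    normalize_cpm,
    positional_eligibility,
    select_high_low_variance,
    select_stable_regulated,
    tertile_bins,
)


def _matrix(counts, stages=None):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    stages = stages or {c: c for c in df.columns}
    return ExpressionMatrix(df, stages)


def test_cpm_single_gene_and_column_sums():
    m = _matrix([[5, 2]])
    cpm = normalize_cpm(m)
    assert (cpm.counts.to_numpy() == 1e6).all()
    m2 = _matrix([[10, 0], [30, 50], [60, 50]])
    cpm2 = normalize_cpm(m2)
    assert cpm2.counts.sum(axis=0).to_numpy() == pytest.approx([1e6, 1e6])
    assert cpm2.counts["s0"].to_numpy() == pytest.approx([1e5, 3e5, 6e5])


def test_cpm_rejects_zero_total_sample_by_name():
    m = _matrix([[1, 0], [2, 0]])
    with pytest.raises(ValueError, match="s1"):
        normalize_cpm(m)


def test_cpm_preserves_within_sample_rank_order():
    rng = np.random.default_rng(0)
    m = _matrix(rng.integers(0, 100, size=(30, 4)))
    cpm = normalize_cpm(m)
    for c in m.counts.columns:
        assert (
            m.counts[c].rank(method="average")
            == cpm.counts[c].rank(method="average")
        ).all()


def test_compress_stages_means_and_loop_oracle():
    m = _matrix([[2, 4], [1, 5]], stages={"s0": "A", "s1": "A"})
    st = compress_stages(m)
    assert st["A"].to_numpy() == pytest.approx([3.0, 3.0])
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 50, size=(20, 6))
    stages = {f"s{i}": f"stage{i % 3}" for i in range(6)}
    m2 = _matrix(counts, stages)
    st2 = compress_stages(m2)
    for g in range(20):
        for k in range(3):
            cols = [i for i in range(6) if i % 3 == k]
            assert st2.iloc[g][f"stage{k}"] == pytest.approx(
                np.mean([counts[g, i] for i in cols])
            )


def test_classify_expressed_strict_boundaries():
    vals = pd.Series({"a": 0.6, "b": 0.0, "c": 0.5})
    out = classify_expressed(vals)
    assert out["a"] == "expressed"
    assert out["b"] == "repressed"
    assert out["c"] == "repressed"  # boundary goes to repressed


def test_tertile_bins_sizes_and_tie_determinism():
    vals = pd.Series({chr(97 + i): v for i, v in enumerate([6, 5, 4, 3, 2, 1])})
    out = tertile_bins(vals)
    assert set(out[out == "high"].index) == {"a", "b"}
    assert set(out[out == "low"].index) == {"e", "f"}
    vals7 = pd.Series({f"g{i}": float(i) for i in range(7)})
    out7 = tertile_bins(vals7)
    assert out7.value_counts().to_dict() == {"high": 3, "mid": 2, "low": 2}
    ties = pd.Series({f"g{i}": 1.0 for i in range(6)})
    assert tertile_bins(ties).equals(tertile_bins(ties.sample(frac=1, random_state=0).sort_index()))
    with pytest.raises(ValueError):
        tertile_bins(pd.Series({"a": 1.0, "b": 2.0}))


def test_mad_and_cv_match_loop_oracles():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 100, size=(40, 17))
    df = pd.DataFrame(x, index=[f"g{i}" for i in range(40)])
    mad = (df - df.median(axis=1).values[:, None]).abs().median(axis=1)
    cv = df.std(axis=1, ddof=1) / df.mean(axis=1)
    for i in range(40):
        row = x[i]
        med = np.median(row)
        assert mad.iloc[i] == pytest.approx(np.median(np.abs(row - med)), abs=1e-12)
        assert cv.iloc[i] == pytest.approx(
            np.std(row, ddof=1) / np.mean(row), abs=1e-12
        )


def test_positional_eligibility_filters():
    from chromstate.expression import GeneAnnotationInfo

    info = GeneAnnotationInfo(
        gene_scaffold={"a": "s1", "b": "s1", "c": "s1", "d": "s2"},
        gene_span={"a": (0, 1000), "b": (1500, 2500), "c": (10_000, 11_000),
                   "d": (0, 500)},
        scaffold_length={"s1": 50_000, "s2": 5_000},
    )
    ok, reasons = positional_eligibility(list("abcd"), info)
    # a-b gap is 500 <= 1 kb: both fail; c is isolated; d sits on a small scaffold
    assert ok == {"c"}
    assert reasons["short_intergenic"] == 2
    assert reasons["small_scaffold"] == 1


def test_variance_class_low_total_filter_and_spike_mad():
    # constant gene has MAD 0; a stage spike (here over a two-stage course,
    # where the median absolute deviation picks it up) ranks strictly above
    stages = {f"s{i}": f"st{i}" for i in range(2)}
    # filler genes keep library sizes balanced so CPM of constant genes
    # stays constant despite the spike
    counts = np.array(
        [
            [50, 50],
            [10, 400],
            [1, 1],  # total < 100 -> excluded
        ]
        + [[1000, 1000]] * 10
    )
    m = _matrix(counts, stages)
    from chromstate.expression import GeneAnnotationInfo

    info = GeneAnnotationInfo(
        gene_scaffold={g: "s" for g in m.counts.index},
        gene_span={g: (i * 5000, i * 5000 + 1000) for i, g in enumerate(m.counts.index)},
        scaffold_length={"s": 100_000},
    )
    labels, reasons = select_high_low_variance(
        m, info, VarianceClassConfig(n_mad=1)
    )
    assert labels["g2"] == "excluded" and reasons["low_total"] == 1
    assert labels["g1"] == "high_variance"
    assert labels["g0"] == "low_variance"


def test_stable_regulated_eligibility_and_constant_gene():
    stage = pd.DataFrame(
        {
            "st0": [10.0, 0.0, 10.0, 5.0],
            "st1": [10.0, 5.0, 12.0, 6.0],
            "st2": [10.0, 0.0, 30.0, 5.5],
        },
        index=["const", "one_stage", "var", "mild"],
    )
    labels, cv = select_stable_regulated(
        stage, None, StableRegulatedConfig(n_sel=1, apply_positional=False)
    )
    assert labels["one_stage"] == "ineligible"  # >= 4 counts in only one stage
    assert labels["const"] == "stable"  # CV exactly 0
    assert labels["var"] == "regulated"
    assert cv["const"] == 0.0


def test_planted_class_recovery(expression_dataset):
    ann = expression_dataset["ann"]
    truth = expression_dataset["truth"]
    expr = expression_dataset["expr"]
    info = ann.to_info()
    planted = {
        c: [g for g, cl in truth.gene_class.items() if cl == c]
        for c in ("stable", "regulated", "high_variance", "low_variance")
    }
    labels_v, _ = select_high_low_variance(
        expr, info, VarianceClassConfig(n_mad=len(planted["high_variance"]))
    )
    stage = compress_stages(normalize_cpm(expr))
    labels_sr, _ = select_stable_regulated(stage, info, StableRegulatedConfig())

    def recovery(genes, labels, want):
        eligible = [g for g in genes if labels[g] not in ("excluded", "ineligible")]
        assert eligible, "eligibility filters removed every planted gene"
        return np.mean([labels[g] == want for g in eligible])

    assert recovery(planted["high_variance"], labels_v, "high_variance") >= 0.95
    assert recovery(planted["low_variance"], labels_v, "low_variance") >= 0.95
    assert recovery(planted["stable"], labels_sr, "stable") >= 0.95
    assert recovery(planted["regulated"], labels_sr, "regulated") >= 0.95


def test_classification_is_deterministic(expression_dataset):
    expr = expression_dataset["expr"]
    info = expression_dataset["ann"].to_info()
    a, _ = select_high_low_variance(expr, info, VarianceClassConfig(n_mad=40))
    b, _ = select_high_low_variance(expr, info, VarianceClassConfig(n_mad=40))
    assert a.equals(b)
    stage = compress_stages(normalize_cpm(expr))
    la, _ = select_stable_regulated(stage, info, StableRegulatedConfig())
    lb, _ = select_stable_regulated(stage, info, StableRegulatedConfig())
    assert la.equals(lb)
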