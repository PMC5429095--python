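"""Distal enhancer prediction cascade and its characterisations."""

import numpy as np
import pytest

from chromstate import enhancers as enh
from chromstate.annotation import Annotation, GeneModel
from chromstate.intervals import Anchor, GenomicInterval, IntervalSet
from chromstate.simulate import enhancer_recovery


def _iv(s, a, b, name=None):
    return GenomicInterval(s, a, b, name=name)


def test_predict_removes_tss_proximal_by_single_base():
    # window for TSS at 5000 is [4800, 5201); region touching 4800 goes
    me1 = IntervalSet([_iv("s", 4700, 4801), _iv("s", 2000, 2400)])
    segs = IntervalSet([_iv("s", 0, 10_000)])
    out = enh.predict_enhancers(me1, [Anchor("s", 5000, "+")], [], segs)
    assert [iv.start for iv in out.candidates] == [2000]
    assert len(out.removed["tss_proximal"]) == 1


def test_predict_requires_enhancer_state_overlap():
    me1 = IntervalSet([_iv("s", 2000, 2400), _iv("s", 8000, 8400)])
    segs = IntervalSet([_iv("s", 2399, 2500)])  # 1 bp with the first only
    out = enh.predict_enhancers(me1, [], [], segs)
    assert [iv.start for iv in out.candidates] == [2000]
    assert len(out.removed["no_enhancer_state"]) == 1


def test_predict_empty_input_and_provenance_conservation():
    segs = IntervalSet([_iv("s", 0, 1000)])
    out = enh.predict_enhancers(IntervalSet(), [], [], segs)
    assert len(out.candidates) == 0
    rng = np.random.default_rng(0)
    me1 = IntervalSet(
        [_iv("s", int(p), int(p) + 300) for p in rng.integers(0, 50_000, 40)]
    )
    tss = [Anchor("s", int(p), "+") for p in rng.integers(0, 50_000, 10)]
    out = enh.predict_enhancers(me1, tss, [], IntervalSet([_iv("s", 0, 20_000)]))
    assert out.n_input == len(me1)


def test_activation_fraction_boundary():
    cand = enh.EnhancerCandidateSet(IntervalSet([_iv("s", 1000, 1200)]))
    just_under = IntervalSet([_iv("s", 1000, 1099)])  # 99 of 200 bases
    enh.activate(cand, just_under)
    assert not cand.activated[("s", 1000, 1200)]
    exactly_half = IntervalSet([_iv("s", 1000, 1100)])
    enh.activate(cand, exactly_half)
    assert cand.activated[("s", 1000, 1200)]
    full = IntervalSet([_iv("s", 900, 1300)])
    enh.activate(cand, full)
    assert cand.activated[("s", 1000, 1200)]


@pytest.mark.parametrize("seed", range(5))
def test_activation_matches_per_base_coverage_oracle(seed):
    rng = np.random.default_rng(seed)
    cands = enh.EnhancerCandidateSet(
        IntervalSet([_iv("s", int(p), int(p) + int(l)) for p, l in
                     zip(rng.integers(0, 9000, 50), rng.integers(50, 500, 50))])
    )
    k27 = IntervalSet(
        [_iv("s", int(p), int(p) + int(l)) for p, l in
         zip(rng.integers(0, 9000, 50), rng.integers(50, 500, 50))]
    )
    enh.activate(cands, k27)
    mask = np.zeros(20_000, dtype=bool)
    for iv in k27:
        mask[iv.start : iv.end] = True
    for iv in cands.candidates:
        expect = mask[iv.start : iv.end].sum() >= 0.5 * len(iv)
        assert cands.activated[(iv.scaffold, iv.start, iv.end)] == expect


def test_assign_targets_nearest_and_single():
    elements = IntervalSet([_iv("s", 5000, 5400)])
    t = enh.assign_targets(elements, [Anchor("s", 9000, "+", "far")])
    assert t[0][1].name == "far"
    t2 = enh.assign_targets(
        elements,
        [Anchor("s", 4700, "+", "near"), Anchor("s", 6300, "+", "far")],
    )
    assert t2[0][1].name == "near" and t2[0][2] == 300
    with pytest.raises(ValueError):
        enh.assign_targets(elements, [])


def _toy_annotation():
    genes = {
        "g1": GeneModel(
            "g1", "s", 1000, 5000, "+",
            ((1000, 2000), (3000, 3500), (4500, 5000)),
        )
    }
    return Annotation({"s": 20_000}, genes)


def test_classify_location_majority_rule():
    ann = _toy_annotation()
    cands = IntervalSet(
        [
            _iv("s", 2200, 2800),  # wholly intronic
            _iv("s", 1800, 2300),  # 200 exon vs 300 intron -> intronic
            _iv("s", 1500, 2100),  # 500 exon vs 100 intron -> exonic
            _iv("s", 8000, 8400),  # intergenic
        ]
    )
    labels, fractions = enh.classify_location(cands, ann)
    assert labels[("s", 2200, 2800)] == "intronic"
    assert labels[("s", 1800, 2300)] == "intronic"
    assert labels[("s", 1500, 2100)] == "exonic"
    assert labels[("s", 8000, 8400)] == "intergenic"
    assert sum(fractions[k] for k in ("intronic", "exonic", "intergenic")) == (
        pytest.approx(1.0)
    )


def test_intron_size_comparison_planted_shift_and_empty():
    rng = np.random.default_rng(3)
    introns, cands = [], []
    pos = 0
    sizes = np.concatenate([rng.integers(60, 120, 150), rng.integers(800, 2000, 150)])
    rng.shuffle(sizes)
    for ln in sizes:
        introns.append(_iv("s", pos, pos + int(ln)))
        if ln >= 800:  # candidates only inside the long introns
            cands.append(_iv("s", pos + 10, pos + 210))
        pos += int(ln) + 50
    res = enh.intron_size_comparison(IntervalSet(cands), IntervalSet(introns))
    assert res["median_harboring"] > res["median_all"]
    assert res["p_value"] < 0.01
    empty = enh.intron_size_comparison(IntervalSet(), IntervalSet(introns))
    assert empty["p_value"] is None and empty["harboring_sizes"].size == 0
    with pytest.raises(ValueError):
        enh.intron_size_comparison(IntervalSet(cands), IntervalSet())


def test_intron_size_comparison_null_calibration():
    # harboured introns drawn uniformly per intron (size-blind): the
    # comparison is null and should not reject systematically
    rng = np.random.default_rng(4)
    ps = []
    for rep in range(20):
        introns, pos = [], 0
        sizes = rng.integers(60, 2000, 200)
        for ln in sizes:
            introns.append(_iv("s", pos, pos + int(ln)))
            pos += int(ln) + 10
        chosen = rng.choice(len(introns), 60, replace=False)
        cands = [
            _iv("s", introns[i].start, introns[i].start + 1) for i in chosen
        ]
        res = enh.intron_size_comparison(IntervalSet(cands), IntervalSet(introns))
        if res["p_value"] is not None:
            ps.append(res["p_value"])
    assert np.mean(np.array(ps) < 0.01) <= 0.2


def test_rnapii_cooccupancy_limits():
    cands = IntervalSet([_iv("s", 0, 100), _iv("s", 500, 600)])
    frac, flags = enh.rnapii_cooccupancy(cands, IntervalSet())
    assert frac == 0.0
    frac, flags = enh.rnapii_cooccupancy(cands, IntervalSet([_iv("s", 0, 1000)]))
    assert frac == 1.0 and all(flags.values())


def test_cascade_on_synthetic_genome(default_dataset):
    from chromstate import enrichment, hmm
    from chromstate.intervals import subtract_window_hits

    spec = default_dataset["spec"]
    ann, truth = default_dataset["ann"], default_dataset["truth"]
    pooled, inp = default_dataset["pooled"], default_dataset["input"]
    seg = hmm.Segmentation(truth.state_path, spec.n_states, spec.bin_width)
    segments = seg.intervals_for_states(set(spec.enhancer_state_indices().values()))
    me1 = enrichment.call_regions(pooled["H3K4me1"], inp).intervals()
    k27 = enrichment.call_regions(pooled["H3K27ac"], inp).intervals()
    cands = enh.predict_enhancers(
        me1, ann.coding_tss(), ann.lincrna_tss(), segments
    )
    enh.activate(cands, k27)
    rec = enhancer_recovery(cands.candidates, truth)
    assert rec["recall"] >= 0.9
    assert rec["precision"] >= 0.9
    # cascade monotonicity and exhaustive TSS-window check
    assert len(cands.activated_set()) <= len(cands.candidates) <= len(me1)
    survivors = subtract_window_hits(cands.candidates, ann.all_tss(), 200)
    assert survivors == cands.candidates
    # provenance conserves counts
    assert cands.n_input == len(me1)
    # target assignment agrees with a linear-scan nearest-TSS oracle
    anchors = ann.all_tss()
    targets = enh.assign_targets(cands.candidates, anchors)
    for q, a, d in targets:
        best = None
        for an in anchors:
            if an.scaffold != q.scaffold:
                continue
            if q.start <= an.pos < q.end:
                dd = 0
            elif an.pos < q.start:
                dd = q.start - an.pos
            else:
                dd = an.pos - q.end
            if best is None or dd < best:
                best = dd
        assert d == best


def test_assign_targets_intronic_enhancer_reaches_host():
    # an element inside a gene's intron has that gene's TSS nearest when
    # no other anchor comes closer — the planted-pair construction
    ann = _toy_annotation()
    element = IntervalSet([_iv("s", 2200, 2600)])  # inside g1's first intron
    anchors = [g.tss for g in ann.genes.values()] + [Anchor("s", 15_000, "+", "g2")]
    t = enh.assign_targets(element, anchors)
    assert t[0][1].name == "g1"
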