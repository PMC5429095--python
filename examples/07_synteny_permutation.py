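"""Test enhancer enrichment in microsyntenic units by permutation.

Counts conserved neighbouring gene pairs whose unit span (both genes plus
intervening sequence) contains an enhancer element, then compares against
random disjoint sets of adjacent gene pairs. Shown on a null genome
(uniform enhancer placement) and on one with a 5x placement boost inside
unit spans.
"""

from chromstate import simulate, synteny

for boost in (1.0, 5.0):
    spec = simulate.SyntheticSpec(seed=7, synteny_enhancer_boost=boost)
    ann, truth = simulate.generate_genome(spec)
    simulate.plant_enhancers(ann, truth, spec)
    pairs = synteny.build_unit_spans(truth.syntenic_pairs, ann)
    res = synteny.permutation_test(
        pairs, ann, truth.enhancer_set(), n_iter=999, seed=0
    )
    print(
        f"boost {boost:.0f}x: {res.observed}/{len(pairs)} units contain an "
        f"enhancer; null mean {res.null_counts.mean():.1f}; "
        f"empirical p = {res.p_value:.3g}"
    )
# Under uniform placement the observed count sits inside the null
# distribution (p large); with boosted placement the syntenic units carry
# far more enhancers than random neighbour pairs and p collapses to the
# add-one floor of 1/(n_iter + 1).
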