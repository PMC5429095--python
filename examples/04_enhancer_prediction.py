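"""Predict distal enhancer-like elements and characterise them.

H3K4me1 regions clear of every TSS +/- 200 bp window that overlap an
enhancer chromatin state become candidates; candidates at least half
covered by H3K27ac peaks are activated. Activated elements get a nearest
TSS, a genomic location class, an RNAPII co-occupancy flag, and the
introns harbouring them are size-compared with all introns.
"""

from chromstate import enhancers, enrichment, hmm, simulate

spec = simulate.SyntheticSpec(seed=4)
ann, truth = simulate.generate_genome(spec)
simulate.plant_enhancers(ann, truth, spec)
tracks, input_track = simulate.simulate_chromatin(ann, truth, spec)
pooled = {m: r1 + r2 for m, (r1, r2) in tracks.items()}

seg = hmm.Segmentation(truth.state_path, spec.n_states, spec.bin_width)
enh_segments = seg.intervals_for_states(
    set(spec.enhancer_state_indices().values())
)
me1 = enrichment.call_regions(pooled["H3K4me1"], input_track).intervals()
k27 = enrichment.call_regions(pooled["H3K27ac"], input_track).intervals()
rnapii = enrichment.call_regions(pooled["RNAPII"], input_track).intervals()

cands = enhancers.predict_enhancers(
    me1, ann.coding_tss(), ann.lincrna_tss(), enh_segments
)
enhancers.activate(cands, k27)
print(f"H3K4me1 regions: {cands.n_input}; removed: "
      f"{dict(cands.removal_counts())}; candidates: {len(cands.candidates)}")
activated = cands.activated_set()
print(f"activated (>= 50% H3K27ac coverage): {len(activated)}")

rec = simulate.enhancer_recovery(cands.candidates, truth)
print(f"recovery vs planted truth: recall {rec['recall']:.2f}, "
      f"precision {rec['precision']:.2f}")

_, fractions = enhancers.classify_location(cands.candidates, ann)
print(f"location: {fractions['intragenic']:.0%} intragenic, "
      f"{fractions['intergenic']:.0%} intergenic")

frac, _ = enhancers.rnapii_cooccupancy(activated, rnapii)
print(f"RNAPII co-occupancy of activated elements: {frac:.0%}")

sizes = enhancers.intron_size_comparison(cands.candidates, ann.all_introns())
print(f"harbouring introns: median {sizes['median_harboring']:.0f} bp vs "
      f"all introns {sizes['median_all']:.0f} bp "
      f"(Mann-Whitney p = {sizes['p_value']:.2e})")
# Elements concentrate in the long tail of the intron-size law, so
# harbouring introns are much longer than the genomic median.
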