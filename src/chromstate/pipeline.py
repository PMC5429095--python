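"""End-to-end workflow orchestration on synthetic or supplied inputs.

``PipelineConfig`` gathers every analysis threshold with its standard
default (200-bp bins, binarisation p 1e-4, narrow/broad region p 0.01/0.1,
TSS flank 200 bp, 50% activation overlap, 4-kb ratio window with 1.2/0.8
thresholds, 3-kb profile flank, MAD top-15,000 cap, CV selection of 1,000,
1,000 permutation iterations, FRiP 1%, M/T 0.5, Pearson 0.5, enrichment FDR
0.01). ``run_pipeline`` executes the simulate / segment / enhancers /
classify / synteny / qpcr stages in dependency order and writes a manifest;
one global seed fans out to per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import enhancers as enh
from . import enrichment, hmm, io, profiles, qpcr, simulate, synteny
from .expression import (
    StableRegulatedConfig,
    VarianceClassConfig,
    compress_stages,
    normalize_cpm,
    select_high_low_variance,
    select_stable_regulated,
)

__all__ = ["PipelineConfig", "run_pipeline", "WORKFLOWS"]

WORKFLOWS = ("simulate", "segment", "enhancers", "classify", "synteny", "qpcr", "all")


@dataclass
class PipelineConfig:
    out_dir: str = "chromstate_run"
    bin_width: int = 200
    binarize_p: float = 1e-4
    narrow_p: float = 0.01
    broad_p: float = 0.1
    tss_flank: int = 200
    activation_fraction: float = 0.5
    ratio_window: int = 4000
    ratio_hi: float = 1.2
    ratio_lo: float = 0.8
    profile_flank: int = 3000
    n_states: int = 9
    hmm_restarts: int = 3
    hmm_max_iter: int = 100
    n_mad: int = 15_000
    n_sel: int = 1000
    n_permutations: int = 1000
    frip_min: float = 0.01
    mt_min: float = 0.5
    pearson_min: float = 0.5
    enrichment_fdr: float = 0.01
    seed: int = 0
    synthetic: simulate.SyntheticSpec | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def run_pipeline(config: PipelineConfig, workflow: str = "all") -> dict:
    """Run one or all workflows on the built-in synthetic inputs.

    Returns a result dictionary (also written as JSON artifacts with a
    manifest under ``config.out_dir``).
    """
    if workflow not in WORKFLOWS:
        raise ValueError(f"unknown workflow {workflow!r}; choose from {WORKFLOWS}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.synthetic or simulate.SyntheticSpec(seed=config.seed)
    results: dict = {"workflow": workflow, "seed": config.seed}

    ann, truth = simulate.generate_genome(spec)
    simulate.plant_enhancers(ann, truth, spec)
    tracks, input_track = simulate.simulate_chromatin(ann, truth, spec)
    pooled = {m: reps[0] + reps[1] for m, reps in tracks.items()}

    if workflow in ("simulate", "all"):
        io.write_gff3(out / "annotation.gff3", ann)
        io.write_bed(out / "enhancers_true.bed", truth.enhancer_set())
        results["n_genes"] = len(ann.genes)
        results["n_true_enhancers"] = len(truth.enhancers)

    seg = None
    if workflow in ("segment", "enhancers", "all"):
        binarized = {
            m: enrichment.binarize(pooled[m], input_track, config.binarize_p)
            for m in spec.marks
        }
        obs = hmm.BinaryObservationMatrix.from_binarized(
            binarized, list(spec.marks), config.bin_width
        )
        model = hmm.train(
            obs,
            config.n_states,
            n_restarts=config.hmm_restarts,
            max_iter=config.hmm_max_iter,
            seed=config.seed,
        )
        seg = hmm.decode(model, obs, "posterior")
        results["hmm_loglik"] = model.training_log[-1]
        results["state_occupancy"] = seg.occupancy().tolist()

    if workflow in ("enhancers", "all"):
        # the cascade itself is exercised against the true state path so its
        # QC is not confounded with HMM label recovery
        true_seg = hmm.Segmentation(
            truth.state_path, spec.n_states, config.bin_width, "truth"
        )
        enh_states = set(spec.enhancer_state_indices().values())
        segments = true_seg.intervals_for_states(enh_states)
        me1_regions = enrichment.call_regions(
            pooled["H3K4me1"], input_track, config.narrow_p, config.broad_p
        ).intervals()
        k27_regions = enrichment.call_regions(
            pooled["H3K27ac"], input_track, config.narrow_p, config.broad_p
        ).intervals()
        cands = enh.predict_enhancers(
            me1_regions, ann.coding_tss(), ann.lincrna_tss(), segments,
            config.tss_flank,
        )
        enh.activate(cands, k27_regions, config.activation_fraction)
        recovery = simulate.enhancer_recovery(cands.candidates, truth)
        results["enhancer_recovery"] = recovery
        io.write_bed(out / "enhancer_candidates.bed", cands.candidates)

    if workflow in ("classify", "all"):
        expr = simulate.simulate_expression(ann, truth, spec)
        info = ann.to_info()
        n_planted_hv = sum(
            1 for c in truth.gene_class.values() if c == "high_variance"
        )
        vcfg = VarianceClassConfig(n_mad=min(config.n_mad, n_planted_hv))
        labels_v, _ = select_high_low_variance(expr, info, vcfg)
        stage_cpm = compress_stages(normalize_cpm(expr))
        labels_sr, _ = select_stable_regulated(
            stage_cpm, info, StableRegulatedConfig(n_sel=config.n_sel)
        )
        results["variance_class_counts"] = labels_v.value_counts().to_dict()
        results["stable_regulated_counts"] = labels_sr.value_counts().to_dict()

        me1_fe = enrichment.fold_enrichment_track(pooled["H3K4me1"], input_track)
        me3_fe = enrichment.fold_enrichment_track(pooled["H3K4me3"], input_track)
        peak_sets = {
            m: enrichment.call_regions(pooled[m], input_track).intervals()
            for m in ("H3K4me1", "H3K4me3", "RNAPII")
        }
        rc = profiles.classify_lincrnas(
            me1_fe,
            me3_fe,
            ann.gene_intervals("lincRNA"),
            {g.gene_id: g.tss for g in ann.lincrnas.values()},
            ann.scaffold_lengths,
            peak_sets,
            config.ratio_hi,
            config.ratio_lo,
            config.ratio_window,
        )
        results["lincrna_class_counts"] = rc.counts()

    if workflow in ("synteny", "all"):
        pairs = synteny.build_unit_spans(truth.syntenic_pairs, ann)
        res = synteny.permutation_test(
            pairs,
            ann,
            truth.enhancer_set(),
            n_iter=config.n_permutations,
            seed=config.seed,
        )
        results["synteny"] = {
            "observed": res.observed,
            "p_value": res.p_value,
            "n_iter": res.n_iter,
        }

    if workflow in ("qpcr", "all"):
        table = simulate.simulate_qpcr(truth, spec)
        folds = qpcr.fold_changes_from_table(
            table, ["intergenic_1", "intergenic_2"], spec.qpcr_input_fraction
        )
        results["qpcr_folds"] = folds["fold_change"].round(3).to_dict()

    manifest = {
        "seed": config.seed,
        "workflow": workflow,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k != "synthetic" and not isinstance(v, np.ndarray)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=str)
    return results
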