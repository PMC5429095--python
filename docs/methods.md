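# Methods

This note documents the models and procedures the package implements, the
synthetic data they are validated on, the numerical choices, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Enrichment scoring and region calling

ChIP and input reads are summarised as counts in non-overlapping 200-bp
bins. Each bin's evidence of enrichment is the upper-tail Poisson
probability P(X ≥ k | λ_bin), with

    λ_bin = max(input_bin × depth_scale, genome-wide scaled input mean),

where `depth_scale = chip_total / input_total`. The genome-wide floor
prevents zero-λ bins on a shallow input; it is a deliberately simple
stand-in for the multi-scale local-λ machinery of a full peak caller and
behaves conservatively where the ChIP library carries substantial signal
mass (the floor then exceeds the background rate). Binarisation for the
chromatin model thresholds at p < 1e-4; on pure-null tracks the
false-positive rate stays below 1.5× the threshold (checked by
Monte-Carlo at 10^5 bins).

Region calling mimics a gapped/broad caller: bins with p below a broad
threshold (0.1) are merged across gaps of at most one non-significant
bin, and a merged region is kept only if it contains at least one bin
below the narrow threshold (0.01). Coordinates are bin-aligned, which
makes exact-coordinate matching between calls meaningful. A
single-replicate mode keeps regions with narrow p < 0.001 for marks
lacking replication.

Fold-enrichment tracks use (k + c)/(λ_bin + c) with pseudocount c = 1;
the pseudocount matters only at low counts.

### Reproducibility QC

Pseudoreplicates model "label every pooled read, draw half without
replacement": a sequential hypergeometric split of the pooled per-bin
counts. Regions are called on pooled data (P), each replicate (R1, R2)
and each pseudoreplicate (PR1, PR2). R is the subset of P supported
(≥ 1-bp overlap) by both replicates, PR the subset supported by both
pseudoreplicates, M the exact-coordinate intersection of R and PR, and
T their union. The pass rule is M/T ≥ 0.5; when no regions are called at
all the ratio is 1 by convention with a degenerate flag. With a fixed
seed the whole procedure is deterministic and symmetric in the
replicates. Sub-bin-scale marginal regions sit at the detection boundary
of a half-depth pseudoreplicate, so even identical replicates give M/T
slightly below 1 (≈ 0.9 on the default simulation); the discordant
condition (disjoint signal sets) collapses the ratio well below 0.5.

## Chromatin-state model

The segmentation model is a K-state HMM whose emission in state s is a
vector of independent Bernoulli variables, one per mark:
P(o | s) = Π_m p_sm^o_m (1 − p_sm)^(1 − o_m). Scaffolds are independent
chains sharing parameters. Training is Baum–Welch with the scaled
forward–backward recursion (per-bin normalisation constants; no
log-space arithmetic is needed at these chain lengths); probabilities are
clipped to [1e-6, 1 − 1e-6]. Initialisation per restart draws emissions
uniformly in [0.1, 0.9] and starts transitions near-uniform with a
self-transition boost; the best of (default) five restarts by final
log-likelihood wins. Convergence is a relative log-likelihood change
below 1e-4 or 200 iterations. The training log asserts monotonicity to
1e-8. Exactness is verified against brute-force path enumeration on
chains of ≤ 8 bins, and parameter recovery on a planted 3-state, 4-mark
model at 5×10^4 bins (emissions within 0.05, posterior decoding accuracy
≥ 0.9 after optimal relabeling by linear assignment on emission
distance).

State labels are arbitrary; biological mnemonics are assigned by the
user from enrichment tables, not inferred. Overlap enrichment of state s
in feature f is (bases of s in f / bases of s) ÷ (bases of f / genome
size); the alternative reading that divides by the feature size instead
is available behind a flag but never the default. Column scaling maps
each feature column to [0, 1] by min subtraction and max division
(constant columns to zero); neighbourhood profiles use the analogous
whole-matrix scaling. Positional profiles assign each 100-bp offset
position to its containing 200-bp state bin and mirror minus-strand
anchors so positive offsets are always downstream.

## Enhancer cascade

Candidates are H3K4me1 regions of enrichment that (1) do not intersect
any TSS ± 200 bp window — coding genes and lincRNAs both count — and
(2) overlap (≥ 1 bp) a segment assigned to an enhancer-designated state.
Activation requires at least half the candidate's bases covered by
H3K27ac peaks; the boundary fraction counts as activated. Each removal is
logged with a reason, and the provenance identity
|input| = |kept| + Σ removals is asserted exhaustively, as is the absence
of any TSS-window violation in the output. Nearest-TSS assignment breaks
exact ties toward the lower coordinate (a repository convention; the
underlying tools do not document theirs).

## Expression classes

Counts are CPM-normalised per sample and replicate columns averaged into
stages (17 by default). Four classifications:

- expressed (> 0.5 normalized counts) vs repressed (< 0.5); a value of
  exactly 0.5 is repressed — both threshold inequalities are strict,
  leaving the boundary to a convention;
- tertiles among expressed genes, descending, ties broken by gene
  identifier, remainders assigned to the higher-expression bins;
- high- vs low-variance: drop genes under 100 raw counts total, rank by
  MAD of the log2 stage matrix, keep the top-N (15,000 at full scale;
  proportional on small cohorts), then apply positional filters
  (non-overlapping genes, intergenic distance > 1 kb, scaffolds > 10 kb)
  and detectable adult expression; survivors are high-variance, the
  remaining filtered expressed genes low-variance;
- stable vs regulated: require ≥ 4 normalized counts in ≥ 2 stages, rank
  by CV across stages, take the bottom/top n (1,000 at full scale, capped
  at half the eligible cohort); ties broken by identifier.

The log transform used before MAD ranking is a moderated log2 of CPM
with a pseudocount worth two raw counts (converted to CPM scale via the
mean library size). A variance-stabilising transform fills this role in
the original design; the moderated log2 is a pluggable stand-in whose
purpose here is identical — without it, one-count shot noise at near-zero
genes dominates the MAD ranking. The MAD ranking, not the transform,
carries the classification.

The stage-expression filter before the stable/regulated ranking
(`focal_stage`) is off by default and set explicitly by pipelines that
analyse a particular stage, since a gene regulated outside the focal
stage is not expressed there by construction.

## lincRNA ratio classes

Eligibility: locus on a scaffold > 10 kb with ≥ 1-bp overlap of H3K4me1,
H3K4me3 and RNAPII regions of enrichment. The ratio is
(mean H3K4me1 FE + c)/(mean H3K4me3 FE + c) over TSS ± 2 kb with c = 0.1
(the classification rule fixes the window and thresholds but not the
formula; mean input-normalised fold enrichment with a small pseudocount
is the natural reading). Strict thresholds: > 1.2 enhancer-like, < 0.8
promoter-like, the closed band in between unassigned, so the three class
counts always sum to the eligible count.

## Microsynteny permutation test

A unit span runs from the leftmost to the rightmost coordinate of the
two genes, intervening sequence included; pairs on different scaffolds
or with more than two intervening genes are rejected on load. A unit
"contains" an enhancer at ≥ 1-bp span overlap. The null draws, per
iteration, as many disjoint adjacent gene pairs (no shared genes,
mirroring how a curated unit set is disjoint) as there are units, builds
spans identically, and counts. The empirical p uses the add-one
convention (1 + #{null ≥ obs})/(1 + n_iter), so the smallest attainable
p is 1/(n_iter + 1) and p is never zero; a normal-approximation p on the
null counts is reported alongside, clearly labelled.

The null pool includes the syntenic pairs themselves. At genome scale
the distinction from a nonsyntenic-only pool is negligible (tens of
units against tens of thousands of neighbour pairs), but on the
miniature test genome excluding a quarter of the pool demonstrably
breaks exchangeability and inflates the low tail; `exclude_syntenic=True`
restores the literal nonsyntenic control for large inputs. Because the
count statistic is discrete, the reported add-one p is conservative
(its null mean exceeds 0.5); the calibration test therefore checks
uniformity of the randomized p — exactly uniform under exchangeability —
and sub-uniformity of the reported p at conventional levels.

## Association statistics

Fisher exact tests default to the one-sided "greater" alternative (the
overlap-association convention of gene-list tools); odds ratios are
(a·d)/(b·c) with the Haldane–Anscombe +0.5 correction when a cell is
zero. Mann–Whitney U uses midranks with tie-corrected, continuity-
corrected normal approximation, switching to exact enumeration when both
samples have ≤ 8 observations and no ties; fully tied inputs are
degenerate with p = 1. Hypergeometric category enrichment is upper-tail
including the observed count. BH adjustment is the step-up procedure
with monotonicity enforcement; note the step-up map is not idempotent in
general (a second pass can only raise values), only constant flattened
vectors are fixed points.

## ChIP-qPCR

The input aliquot represents a fraction of the chromatin (10% by
default), so log2(1/fraction) cycles — 3.3219…, printed as 3.32 — are
subtracted from the input Cq. Fold change is 2^(−ddCq) with
ddCq = (Cq_IP − Cq_IP,intergenic) − (Cq_input,adj − Cq_input,adj,intergenic);
two intergenic negative-control loci are averaged per assay before use
(single-control mode available). The exact constant is used internally;
3.32 appears only in display rounding. Noiseless synthetic tables invert
exactly; with noise, the control Cq is shared across loci of a run, so
per-locus errors within a run are correlated and unbiasedness holds
across runs.

## The synthetic data generator

The generator emulates the statistical structure the analyses assume,
with ground truth recorded for every planted feature.

**Genome.** Four 200-kb scaffolds; 240 coding genes laid left to right
with exponential intergenic gaps (mean 300 bp, floor 800 bp) and
log-normal intron lengths (median 71 bp, log-sd 0.6) — the compact-genome
regime of a demosponge assembly. A quarter of multi-exon genes carry one
enlarged intron (median 1.2 kb), the long tail that can host a
regulatory element. The gap floor keeps every adjacent gene pair able in
principle to host an element, which keeps syntenic units statistically
exchangeable with control pairs under uniform placement. Genes carrying
expression-class labels get > 1-kb flanks so the positional filters
cannot empty a planted class. 36 lincRNAs are interleaved into
intergenic space; 60 disjoint adjacent gene pairs form the microsyntenic
unit set, matching the scale of a curated metazoan unit collection.

**Chromatin.** A sticky 9-state chain (self-transition 0.8, transitions
preferentially falling back to a quiescent state that occupies ~55% of
the genome at stationarity) emits six marks (five histone PTMs plus
RNAPII) per 200-bp bin as independent Bernoulli draws from a
biologically patterned emission table: H3K4me3+H3K27ac+RNAPII at active
promoters, H3K4me1-dominant enhancer states (one also H3K27ac-rich, one
H3K27me3-poised), H3K36me3 over transcribed bodies, H3K27me3 over
repressed chromatin. Counts are Poisson: mean 15 per replicate where the
mark is present, 1 otherwise; the input track is Poisson with mean 5
(the deeper-input design of a typical experiment). Sixty enhancers of
2–3 bins are planted into bin-aligned slots inside introns and
intergenic gaps, clear of TSS windows, with slot weights multiplied by
`synteny_enhancer_boost` inside unit spans (boost 1 = uniform). All
enhancer-state runs, planted or chain-emitted, are recorded in the
truth; recall of the prediction cascade is measured over planted
elements (placed distal at resolvable ≥ 2-bin size), while precision
counts overlap with any true run — chain-emitted runs can sit closer to
a promoter than the gapped caller's merge tolerance can separate, which
is a resolution property of the method, not an error. To keep planted
signatures readable the chain's enhancer states are suppressed within
two bins of a planted run, and H3K4-rich chain states are quieted within
±2 kb of classed lincRNA TSSs (elincRNA TSSs are painted with an
H3K4me1-dominant domain plus a one-bin H3K4me3 satellite at the far end
of the locus, so the locus stays eligible; plincRNAs are the mirror
image).

**Expression.** Negative-binomial counts (gamma–Poisson, dispersion 0.3;
0.05 for stable genes, reflecting housekeeping-like tightness) over 17
stages × 2 replicates. Stable genes have constant means (~50); regulated
genes spike in two adjacent stages (~200) over a near-zero baseline —
two stages, not one, so the ≥-4-counts-in-≥-2-stages filter keeps them;
high-variance genes follow a permuted log2 ladder with amplitude 1.5–2.5
(guaranteed MAD, CV below the regulated spikes — the MAD and CV rankings
deliberately pick out different populations, the robust statistic
ignoring short spikes and the CV ignoring sustained dynamics);
low-variance genes are constant at low mean (~8); background genes sit
below the 100-raw-count floor. Dispersion exactly 0 is the deterministic
limit (counts equal rounded means).

**qPCR.** Cq = baseline − log2(template) + N(0, σ): the IP template
scales with pulldown efficiency × planted fold, the input template with
the aliquot fraction; control loci have fold 1. σ = 0 makes the ddCq
round trip exact by construction.

**Determinism.** Every stage derives its generator from
`SyntheticSpec.seed` through fixed spawn keys, so identical specs give
byte-identical outputs and stages can be re-run in isolation.

### What the generator does not emulate

No sequence content (FASTA), mappability or GC bias, fragment-length
effects, duplicate reads, copy-number variation, or cell-type mixture;
replicate disagreement is a simple per-bin signal-dropout model rather
than biological variability. Passing recovery tests therefore show that
the procedures are implemented correctly and behave as designed under
their own assumptions — not that those assumptions hold for any real
library. Problem sizes (10^4–10^5 bins, hundreds of genes, 200–999
permutation iterations) are chosen so the full suite validates every
stage in minutes on one core; the statistical conditions (signal-to-
background ~15:1, 60 units, 17 stages) mirror the study design the
package targets.

## Known limitations

- The Poisson caller is a single-scale simplification; it has no
  fragment model, no multi-scale local λ, and its regions are
  bin-quantised.
- The Bernoulli-emission HMM ignores mark covariance within a state and
  chooses K by the user's judgement; no model-selection machinery is
  included.
- The M/T procedure is self-consistency, not an error-rate-controlling
  reproducibility analysis (no copula/IDR model).
- Empirical permutation p-values are bounded below by 1/(n_iter + 1);
  claims far below that bound require either more iterations or the
  clearly-labelled normal approximation.
- The moderated log2 transform is a stand-in for a proper
  variance-stabilising transform and underperforms it on strongly
  mean-dependent dispersion.
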