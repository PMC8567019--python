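# Methods

This note documents the statistical models, the synthetic-data generative
model, the numerical choices, and the limits of what the test suite shows.

## Data model and conventions

The central object is a probes × samples matrix of β values (fraction
methylated, [0, 1]), accompanied by a probe manifest (chromosome, 1-based
position, Infinium chemistry type I/II, per-gene region labels among
TSS1500/TSS200/5′UTR/Body/3′UTR/ExonBnd, CpG-island context) and a sample
sheet (group HC/Pso/PsA, treatment timepoint, batch, sex, age, PASI).
Coordinates are 1-based inclusive throughout; only the BED exporter
converts to 0-based half-open, and a property test pins width
conservation across the conversion. Missing β values are rejected at
read time: the QC step is expected to remove unreliable probes before
any statistics, and supporting NA propagation through every stage would
complicate all downstream contracts for no analytical gain. Strand is
carried but ignored (methylation is strand-symmetric after bisulfite
conversion). The genome assembly is pass-through metadata; nothing in the
pipeline depends on it.

## Preprocessing

**Filter order.** detection-p → SNP → non-CpG → cross-reactive, fixed, so
the per-reason counts in the `FilterReport` reconcile exactly
(n_input − Σ removed = n_retained) even when a probe matches several
rules. "Non-CpG" is decided by probe-id prefix (ids not starting with
`cg`), the array-manifest convention.

**β↔M.** M = log₂(β/(1−β)) with β clipped to [ε, 1−ε], ε = 10⁻⁶, which
bounds |M| ≈ 19.9 — far outside the biological range, so clipping only
prevents infinities. The inverse is exact to 1e−10 on the clipped domain.

**Probe-type normalization.** The two Infinium chemistries yield
systematically different β distributions (type II compressed toward 0.5).
Within each sample the type II values are mapped through the type I
empirical quantile function, evaluated at the type II mid-ranks
(ties averaged, so equal inputs map to equal outputs). The map is
monotone; when the two distributions already coincide it is the identity.
This single quantile map plays the role of the usual two-step
quantile + β-mixture (BMIQ-style) correction: the goal — aligning the two
chemistry-specific distributions — is the same, the mechanism is simpler
and directly testable by distribution-distance reduction. Samples with
fewer than 10 probes of either type are rejected (the empirical quantile
function would be meaningless).

**Batch correction.** The parametric empirical-Bayes location/scale
model: per probe, fit batch means and group effects by least squares;
standardize with the batch-size-weighted grand mean and the pooled
residual variance; estimate per-batch location γ̂ and scale δ̂²; shrink
them toward a normal (γ̄, τ²) and inverse-gamma (moment-fitted a, b)
prior via the standard fixed-point iteration (relative tolerance 1e−4,
max 100 iterations); adjust and back-transform. The group covariate is
part of the design so biological contrasts are preserved; a batch
confounded with group (design rank-deficient) or containing a single
sample is rejected with a named error, and a single-batch input is
returned unchanged. The implementation agrees with the Bioconductor
reference (sva::ComBat, parametric priors) to ~1e−4 in the test suite.
Note that EB shrinkage deliberately leaves the fraction δ²/(nτ² + δ²) of
each probe's batch-mean noise uncorrected, so the correction is only
*approximately* idempotent — a second pass moves values at noise scale,
an intrinsic property of the model, not an implementation artifact.

## Differential methylation

**Moderated t.** Per-probe residual variances s² (pooled two-sample, or
one-sample on within-subject differences in paired mode) with d df are
shrunk toward a prior (d₀, s₀²) fitted by matching the mean and variance
of log s² to a scaled-F model: e = log s² − ψ(d/2) + log(d/2);
d₀ = 2·ψ′⁻¹(var(e) − ψ′(d/2)); s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)),
with ψ′⁻¹ computed by Newton iteration (accurate to 1e−8, property-tested).
Degenerate branches: numerically identical variances give d₀ = ∞ with
s₀² = the common variance; a merely sub-trigamma dispersion gives d₀ = ∞
with s₀² = exp(mean(e)) (the moment-matching limit). d₀ = 0 is accepted
as an explicit no-moderation limit and reproduces the classical t exactly
(oracle-tested against scipy); d₀ = ∞ gives a pooled-prior z statistic.
The full fit agrees with limma's `eBayes` to 1e−8 in the test suite.

**Calling rule.** Statistics (t, p, FDR) are computed on M values;
effect sizes Δβ = mean_β(b) − mean_β(a) on β values — the suite includes
a construction where the two scales rank effects differently. A probe is
a DMP when FDR < 0.05 (Benjamini–Hochberg, per contrast) and |Δβ| > 0.1;
direction is *hyper* when the second-listed group is more methylated.
Contrasts are plain two-group comparisons without covariate adjustment
(sex/age are recorded but not modeled); the before/after-treatment
contrast defaults to paired mode keyed on subject id, with the unpaired
alternative one flag away since small-cohort designs vary.

**DMRs.** Probe t² is smoothed along each chromosome with a Gaussian
kernel (bandwidth λ = 1000 bp, sd = λ/C, C = 2 — the conventional
defaults of kernel-based region callers; both exposed). Candidates are
probes with FDR below threshold whose smoothed t² is at or above the
chromosome-wide median of the smoothed field — the smoother confirms and
ranks candidates, while significance gating stays at the probe level,
which keeps the caller checkable against exact oracles. Consecutive
candidates with gaps ≤ λ merge; regions need n_cpgs ≥ min (5/10/20) and
|mean Δβ| ≥ 0.1. By construction the region sets nest as min CpGs grows.
Each region reports Stouffer (Φ applied to the mean probit), Fisher
(χ²_{2k}), and the harmonic mean of member FDRs; p = 0 inputs are clipped
to 1e−300 with a warning. A region's genes are the union of its member
probes' manifest gene labels (positional interval overlap against a gene
model is deliberately out of scope — the manifest is the annotation
source everywhere else too). The smoothed-variance Satterthwaite p-value
of the original region caller is not reproduced.

## Annotation and enrichment

For the distribution table each probe counts once per axis, classified by
precedence promoter (TSS1500/TSS200/5′UTR) > 3′UTR > ExonBnd > Body > IGR
— single-count classification is what makes the percentages sum to 100.
For gene-*set* construction, by contrast, every annotated gene of a
multi-gene probe qualifies. Over-representation uses the hypergeometric
upper tail P(X ≥ k) with Bonferroni correction over the tested terms; the
gene universe is all genes annotated on the post-filter manifest (the
array-aware background), and gene sets come from GMT files — no live
database queries, for reproducibility. The p-values are oracle-tested
against exhaustive enumeration (all universes N ≤ 12) and the one-sided
exact test of the 2×2 table.

## Disease-activity score

Candidates are DMPs annotated to a supplied pathway gene set (in the
motivating study: TNF-α and IL-17 signaling). A candidate survives when
the Pearson correlation between its β values and PASI across patient
samples strictly exceeds |0.8|. Each survivor is standardized against the
healthy controls — SV = (β − mean_HC)/SD_HC, SD with the n−1 denominator
(unspecified in the source procedure; the unbiased choice) — and SVs sum
to a per-sample score, whose Pearson correlation with PASI is reported
with the two-sided t-transform p.

By default the selection correlation uses every patient sample with a
PASI value, including after-treatment samples; the published procedure
this mirrors then evaluates the score against the same samples, a
circularity the result object states outright
(`selection_overlaps_evaluation`) instead of hiding. The
`selection_timepoint="before"` variant selects on before-treatment
samples only, as a partial hold-out. Degenerate cases: zero-SD probes
are dropped with a warning; an empty post-selection set is an explicit
error; correlations need ≥ 3 pairs and nonzero variance.

## Synthetic cohorts

The generator emulates the structure, not the biology, of a small EPIC
cohort. Per probe g and sample i, on the M scale:

M_gi = logit₂(β_g) + group effect + batch offset + activity term + N(0, σ_M)

* **Baselines** β_g: trimodal mixture, Beta(2,18) / Beta(12,12) /
  Beta(18,2) with weights 0.35/0.25/0.40 — the low/intermediate/high
  methylation modes of real arrays.
* **Effects** are specified as β-scale differences and converted to
  M-shifts at each probe's baseline (targets clipped into [0.02, 0.98]
  with a warning), so β stays bounded without truncating the noise, and
  the statistics see realistically heteroscedastic β.
* **Cohort**: 9 HC, 10 Pso, 7 PsA; 5 treated subjects (4 Pso, 1 PsA)
  with before/after pairs — the structure of the motivating study.
* **DMPs**: 1% of probes at |Δβ| = 0.2 (sign random mid-range, forced
  inward at extreme baselines), split between the Pso and PsA groups.
* **DMRs**: three 6-CpG blocks on the first chromosome, direction-coherent
  with mid-range (0.35–0.6) baselines per block — real regions are
  coherent runs, and a mixed-sign block would have no mean effect to
  detect.
* **Batches**: samples alternate between 2 batches; offsets
  N(0, 0.3²) per (batch, probe) on M.
* **Activity**: 10 gene-annotated CpGs lose β in proportion to a latent
  per-subject activity (≈ U(8, 25) before treatment, ×0.15 after) with
  slope −0.015 β per activity unit, chosen so that strongly coupled CpGs
  genuinely exist for the |r| > 0.8 filter to find — the filter is the
  procedure under test, so the generator must plant signal on its scale.
  PASI is then an affine function of each sample's realized mean β over
  the activity CpGs with negative coefficient plus N(0, 1) noise:
  hypomethylation ↔ higher disease activity, and after-treatment scores
  recover toward the healthy level.
* **Noise** σ_M = 0.3, a typical between-replicate M-value dispersion for
  arrays.
* PASI is generated from the *mean* β over activity CpGs rather than
  per-CpG sums so that each individual CpG correlates with PASI and the
  per-probe |r| filter has a recoverable target.

Determinism: all draws flow from one `numpy` `default_rng` seeded from the
design; the pipeline fans a global seed out to per-stage seeds by stable
CRC hashing, and reruns are byte-identical (hash-compared in the tests).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-specific chemistry (detection failures,
SNP overlap and cross-reactivity are sampled labels, not modeled
physics), cell-composition effects, age/sex covariance with methylation,
spatial correlation beyond the planted blocks, and realistic gene/island
geometry. Recovery rates here are upper bounds relative to real cohorts.

## Problem sizes in the checked claims

The statistical guarantees in the test suite and acceptance script are
computed at desk scale, chosen to make each claim sharp while the whole
suite stays fast: null calibration over 200 cohorts of 5,000 probes
(9 vs 10 samples); prior recovery at 10⁴ probes; DMP recovery at 10⁴
probes with 1% planted effects (10 vs 10); DMR recovery over 100 planted
and 200 effect-free cohorts of 5,000 probes; the score chain over 100
full-pipeline replicates of the default 5,000-probe cohort. A real EPIC
array has ~850k probes; every algorithm here is vectorized per probe and
scales linearly in probe count.

## Known limitations

* Two-group contrasts only; no covariate adjustment, surrogate variables
  or cell-type deconvolution.
* The DMR caller's significance is probe-gated; smoothing only confirms
  and merges. Very wide regions of individually weak probes will be
  missed by design.
* The score construction is the published-style in-sample procedure; the
  held-out variant mitigates but does not remove selection bias, and no
  cross-validated or penalized construction is attempted.
* IDAT parsing, raw-intensity normalization (noob, functional
  normalization, dye bias) and sex prediction are out of scope; the
  pipeline starts from a β matrix.
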