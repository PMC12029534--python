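# Methods

This note records the statistical models, conventions and numerical choices
behind `gcmet`, and what the synthetic validation does and does not
demonstrate.

## Data model and normalization

A peak table is a samples × metabolites matrix of non-negative MS responses
(pandas DataFrame; missing = NaN), with sample records (patient pairing,
tissue type tumor/adjacent/QC, tissue weight in mg, TNM stage, categorical
clinical indices) and metabolite annotations (chemical class, assigned
internal standard, ionization mode).

Normalized response = raw ÷ (assigned internal-standard response in the same
sample) ÷ tissue weight; pooled-QC injections carry no tissue weight and are
divided by the internal standard only.  Dividing by both factors makes the
result invariant to joint rescaling of raw and internal-standard responses
within a sample, which is asserted exactly in the tests.  A zero or missing
internal-standard response flags the affected cells missing (with a warning)
rather than aborting; a zero tissue weight is a hard error because it would
silently corrupt a whole sample.  Spiked-standard columns are reagents, not
analytes, and are dropped from the normalized table.  A normalized table
records its state so double normalization is rejected.

Missing-value policy (applied after normalization): metabolites missing in
more than a configurable fraction of samples (default 0.5) are dropped;
remaining gaps are imputed with half the metabolite's observed minimum, the
usual below-detection-limit stand-in.  QC RSD uses the n−1 standard
deviation (configurable) and requires at least 3 QC injections; summary
fractions below 20 % and 30 % are reporting-only by default — the RSD filter
is available but not applied before statistics, since reproducibility
reporting and feature filtering are separate decisions.

## Univariate screen

Tumor-vs-adjacent differences use the Wilcoxon signed-rank test on
per-patient differences, dropping zero differences (Wilcoxon convention).
With ≤ 12 non-zero differences the two-sided p is computed by enumerating
all 2ⁿ sign assignments of the tie-averaged ranks — exact even under ties,
which classical exact tables do not cover — and otherwise by the
tie-corrected normal approximation (scipy).  The Mann–Whitney test used for
clinical associations switches the same way at a total n of 12, enumerating
the C(n, n₁) group relabelings.  The switchover at 12 keeps enumeration
below ~4096 (or 924) evaluations per test; it is configurable.

log₂ fold change is log₂ of the median per-pair tumor/adjacent ratio — the
paired analogue of a fold change, robust to outlying pairs.  FDR control is
Benjamini–Hochberg step-up (Benjamini–Yekutieli available).  Multi-level
clinical indices are scanned as all pairwise binary contrasts on
tumor-tissue values; per-index counts of significant metabolites support
ranking indices by how much of the metabolome tracks them.

Pathway over-representation is the upper-tail hypergeometric probability of
the observed overlap between the selected set and each pathway set
(intersected with the measured universe; minimum pathway size 1), with BH
correction across pathways.  Note the degenerate case: a pathway with zero
overlap has p = 1 (the upper tail at overlap ≥ 0), so misses are
uninformative rather than anti-enriched.  Topology-weighted pathway impact
is out of scope — it requires curated pathway graphs; enrichment here is
purely set-based against user-supplied GMT files.

## PLS-DA

NIPALS PLS1 on the ±1-encoded class response after auto-scaling
(mean-center, unit variance; constant columns dropped with a warning).  For
one response each component reduces to w = X'f/‖X'f‖, t = Xw, p = X't/t't,
q = f't/t't, with X-deflation; the accumulated regression vector
B = W(P'W)⁻¹q turns prediction into a single linear score, and class
prediction is its sign.  Scores of distinct components are orthogonal and
deflation conserves sums of squares; both are asserted to 1e−8.  The
implementation is cross-checked against sklearn's `PLSRegression`
predictions to 1e−8 in the tests (sklearn is never used in the pipeline
path).

Component count: stratified 5-fold cross-validation; Q² = 1 − PRESS/TSS,
chosen count = argmax Q².  Validation: B label permutations of the full
protocol at the chosen count; p = (#{permuted ≥ observed} + 1)/(B + 1), with
analytic floor 1/(B+1) (0.0005 at the protocol's B = 2000).  The permutation
statistic is Q² by default; CV accuracy is available, since permutation
conventions differ across tools.

A calibration fact worth recording: on pure-noise labels the probability
that *every* candidate component count has Q² ≤ 0 is about 0.87–0.88 (we
verified the same rate with an independent sklearn-based CV), so roughly one
noise dataset in eight shows a marginally positive Q² at some component
count.  Q² > 0 alone is therefore weak evidence; the permutation test is the
decision criterion.  Note also that "one planted component" must be read in
the bilinear sense: when X follows a rank-one model t·w' + noise,
cross-validation selects one component; when the class signal sits on a
single raw feature among noise features, extra components genuinely improve
prediction (they undo the one-component shrinkage toward the covariance
direction), and argmax-Q² legitimately exceeds 1.

## Differential correlation network

Spearman ρ is the Pearson correlation of tie-averaged ranks, computed
matrix-wise; p-values use the t approximation t = ρ√((n−2)/(1−ρ²)) for
n > 8 and the exact permutation null (all n! orderings, enumerated once per
pair) for n ≤ 8.  Constant columns give NaN with a warning.

Group contrast per pair: Fisher z with variance 1/(n−3) per group (the
Fieller correction 1.06/(n−3) for Spearman is behind a flag), two-sided
normal p, BH-FDR across all tested pairs, edges kept at FDR < 0.05.  Edge
direction records gain or loss of correlation from adjacent to tumor.
Connected components of the surviving graph are the modules; nodes are
degree-ranked with ties sharing the better rank, and the full table is
exported so "top-k" statements are reproducible.  The paired structure of
the cohort is ignored in this test (groups treated as independent), a known
approximation of the standard differential-correlation workflow.  Under a
common population the unadjusted p < 0.05 rate measures ≈ 0.04–0.06 — the
1/(n−3) variance is slightly anticonservative for Spearman, which is why
the FDR-filtered network, not raw p, is the reported object.

## Acylcarnitine ratio panel

Eight per-sample ratios, each sum(numerator)/sum(denominator) of normalized
responses: (C16+C18)/C0 (∝ CPT1 activity), C14:1/C16 (∝ 1/VLCAD), C4/C3
(∝ 1/SCAD), C2/C0, C8/C10 (∝ 1/MCAD), C10-OH/C10, C8-OH/C8, C4-OH/C4
(∝ 1/ECHS1).  Ratios are exactly invariant to per-sample multiplicative
factors, so normalization errors cancel; a sample missing any component is
flagged missing for that ratio (no partial sums), and a ratio referencing an
unmeasured metabolite is skipped with a warning.  An alias map absorbs the
mixed hydroxy-acylcarnitine spellings found in annotation exports.  Group
shifts are assessed with the same paired Wilcoxon as the univariate screen.
The panel is a descriptive proxy for β-oxidation enzyme activities, not a
kinetic model.

## Biomarker evaluation

Patients (never individual samples) are split 4:1 into discovery and
validation, so both members of a pair share a set; the validation count is
round(0.2·n).  Marker ranking is by discovery-set paired-test p (ties broken
by |log₂FC|, then id).  AUC is computed by the pair-counting / Mann–Whitney
identity, which handles ties exactly and agrees with trapezoidal ROC
integration to 1e−12 (asserted over 1000 random score vectors).  The
two-marker combination is an unpenalized logistic model on discovery-scaled
markers; its linear predictor is the score.  Perfect separation (detected by
a numerically zero log-likelihood, a non-converged fit, or exploding
coefficients) triggers a fall-back to a rank-based combined score with a
warning, since the logistic MLE does not exist there.  The operating
threshold maximizes Youden's J on discovery and is applied unchanged to
validation; validation data influence nothing upstream, which a dedicated
leakage test enforces.

## Stage-wise network topology

Per TNM stage t ∈ {I, II, III} a network G_t on the full metabolite set is
built from tumor samples: w_t(f_i, f_j) = Spearman ρ when the stage-t
correlation has p < 0.01, else exactly 0.  Stage IV is excluded by default
(too few patients in the emulated design for a rank correlation); any stage
below 5 samples is dropped with a warning.

The monotone subnetwork SG_t keeps the edges of G_t whose weight triple
(w_I, w_II, w_III) (i) moves by more than 0.05 in at least one adjacent
stage pair and (ii) is monotone under relaxed comparisons — each adjacent
step may violate the order by at most 0.02, the "almost equal" band; a
strict mode removes the band for sensitivity analysis.  Monotonicity is
evaluated on signed weights, and negating all weights swaps
increasing/decreasing verdicts (property-tested).  Because membership also
requires presence in G_t, the three subnetworks differ: an edge with
accepted triple (0.8, 0.5, 0) belongs to SG_I and SG_II but not SG_III.
Two structural consequences are worth stating plainly: an edge significant
in stage II only, (0, w, 0), is never monotone and is always rejected;
an edge significant in stage I only (or III only), (w, 0, 0), *is* monotone
and is always accepted whenever |w| > 0.05 — i.e. every single-stage edge
whose stage is terminal enters the subnetwork.  Since any correlation
passing p < 0.01 at realistic n has |ρ| well above 0.05, the per-stage
false-positive rate (1 % per stage pair under the null) passes through to
the reported edge set essentially unfiltered.  The planted-recovery
simulation quantifies this: sensitivity for planted monotone trajectories
0.8→0.5→0.1 at n = 40/stage is ≈ 0.95–1.0, but ≈ 80 % of reported edges are
background single-stage edges.  Consumers should treat SG membership as a
screen and read the per-edge weight triples (exported alongside) before
interpretation; requiring presence in at least two stage networks is an
effective post-filter, though it is not part of the method as defined.

Hubs: nodes ranked by degree within SG_t; the top 15 per stage are kept with
all ties at the cutoff included (deterministic and order-independent), and
the union across stages forms the hub set.  For each hub v the informative
triplet Tri(v) collects v's incident SG_t edges per stage with the
correlation sign annotated.  An adjacent-tissue reference network built with
the same rule is exported for display parity only; it plays no role in
extraction.  No significance is attached to hub identity — the method
defines none.

The implementation is validated by exhaustive equivalence against an
independent brute-force re-implementation (per-pair scipy Spearman, plain
loops, literal condition checks) on 100 random instances of ≤ 12 nodes and
≤ 20 samples per stage: subnetworks, hub sets and triplet stars are
identical on all instances.

## Synthetic cohorts

The generator emulates the study design the pipeline assumes: default 80
patients (TNM I/II/III/IV = 13/24/39/4), one tumor + one adjacent sample
each, 234 metabolites over realistic chemical-class proportions with a fixed
core (the acylcarnitine panel, key fatty acids and choline species, amino
acids) so panel and hub analyses always resolve; log-normal intensities
(baseline log-means uniform over ln 10⁴–ln 10⁶, log-scale sd 0.4);
per-sample internal-standard response factors (log-sd 0.1) and tissue
weights (10–50 mg) multiplying the raw responses; one pooled-QC injection
per 10 tissue samples whose log-noise is solved from the target RSD
(default 15 %) via sd = √ln(1 + RSD²).

Planted structure: tumor-vs-adjacent effects on 30 % of metabolites with
|log₂FC| uniform in [0.5, 2] and random sign (effect sizes are not stated by
any design source; these are editable placeholders); rank-correlation
targets per stage realized through a Gaussian copula with Pearson parameter
r = 2·sin(πρ_s/6) — the exact population inverse of the bivariate-normal
Spearman relation, so targets are stated on the Spearman scale the analysis
consumes, with no calibration loop.  Planted blocks are Cholesky-validated
and a non-positive-definite request is an error naming the block (a star of
k leaves, for instance, requires Σr² < 1).  Correlations are planted on
tumor samples stratified by stage; adjacent samples get their own (default
zero) targets.  Ground truth (effects with signs, planted edges and their
monotonicity, hub, pre-noise latent values) is returned and serialized.

What passing tests on this generator do *not* show about real data: no
chromatographic drift, batch effects, adducts/isotopes, censored
(left-truncated) intensities, or heavy-tailed noise; effect sizes and
correlation strengths are cleaner than biology; tumor and adjacent samples
of a patient are drawn independently, so the paired tests' variance
advantage is understated.  Recovery rates here are upper bounds on field
performance.

## Problem sizes and runtime

The validation suite uses deliberately scaled runs chosen for quick
iteration: 20-patient/60-metabolite cohorts for end-to-end checks,
120-patient/70-metabolite cohorts (40 per stage) × 20 seeds for stage-wise
recovery, 100 instances for the brute-force oracle, 2 × 1225 pairs for null
calibration, and B = 2000 permutations only where the floor itself is the
claim.  The full default-scale cohort (80 patients, 234 metabolites) runs
end to end in well under a minute on one CPU; `scripts/acceptance.py`
repeats the whole battery in about half a minute.

## Known limitations

- The differential-correlation and stage-network tests treat groups as
  independent samples; within-patient correlation is not modeled.
- Fisher-z variance 1/(n−3) is mildly anticonservative for Spearman; the
  Fieller flag trades that for conservatism.
- The stage-wise monotone screen has high background admission from
  single-terminal-stage edges (quantified above); its output is a candidate
  list, not an inference.
- Enrichment ignores pathway topology and metabolite identifiability
  (isomers share ids if the annotation does).
- The logistic combination is limited to the two-marker case the pipeline
  reports; no multi-marker regularization is provided.
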