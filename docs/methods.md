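# Methods

## Discovery model

For each gene the discovery cohort (21 patients × 2 samples) is fitted by
the fixed-effects parallel-lines ANCOVA

    y_ij = beta_0 + beta_i + alpha * SAV_ij + eps_ij,

where y_ij is the log-ratio expression of patient i's sample j, beta_i is
the patient intercept and alpha the common slope in expression units per
cm²/mL. Patient intercepts are sum-to-zero coded so beta_0 is the
grand-mean intercept; any full-rank coding gives identical alpha and
p-values (asserted in the tests against a treatment-coded oracle). The
model is deliberately fixed-effects: with two samples per patient and
interest centred on the common slope, a random-intercept likelihood adds
machinery without changing alpha's least-squares estimate, and no
per-patient slope (interaction) term is included.

Inference:

* **P_slope** — two-sided t-test of alpha = 0 on the residual df
  (n − n_patients − 1; 20 for the full design). Two-sided because
  associations in both directions are of interest. For a single covariate
  this t-test coincides with the partial F-test, so the choice is moot.
* **P_patient** — extra-sum-of-squares F-test of the full model against
  y = beta_0 + alpha·SAV + eps, on (n_patients − 1, residual df) df.

Fitting is least squares on the shared design matrix, vectorised over
genes (one cross-product inverse per cohort), so the full 23,757-gene scan
takes well under a second. Correctness is pinned to an independent oracle
(statsmodels formula OLS plus `anova_lm`) at 1e-8 relative tolerance on
random designs.

Degenerate inputs: a zero-variance gene, a design in which SA/V is
constant within every patient (rank deficiency), or a gene left with fewer
than n_patients + 2 complete samples is flagged degenerate and carries NaN
statistics; it is never silently dropped, and never selected. A gene
missing one sample of a patient keeps that patient's other sample — the
patient still contributes an intercept and the design remains valid.
Exact (zero-residual) fits report p_slope = 0 when the slope is nonzero,
and p_patient = 0 or 1 according to whether the patient block explains the
remaining variation.

## Batch adjustment

Expression was processed in two batches, modelled as a per-gene per-batch
offset. The adjustment used here is per-gene within-batch mean centering:
after it, every gene's mean over each batch's samples is zero to machine
precision and all within-batch contrasts are untouched. It is applied to
both cohorts by default and can be disabled in the pipeline config. Batch
labels are assigned per patient (both samples of a discovery patient share
a batch), modelling processing phases; a consequence is that patient
intercepts absorb batch offsets exactly in the ANCOVA, so the discovery
slope is insensitive to the batch effect even without centering, while the
replication regression benefits from the centering.

## Selection, FDR and replication

Marker selection applies three cutoffs with strict inequalities:
mean log-intensity > −1 (adequately expressed probes), P_slope < 0.05
(association with SA/V), and P_patient > 0.1 (little between-patient
variation, so that a patient-free model is defensible in a cohort with one
sample per patient). Boundary values fail. Relaxing any threshold can only
grow the selected set (tested).

Benjamini–Hochberg q-values are computed genome-wide over all
non-degenerate fits *before* the intensity filter: multiplicity adjustment
describes the whole scan, while the intensity cutoff is part of marker
selection. The implementation wraps `statsmodels.stats.multitest` and is
tested against the O(m²) step-up definition.

Replication fits ordinary least squares of expression on SA/V in the
22-sample cohort (two-sided slope t-test on n − 2 df; degenerate below 3
complete samples or with constant SA/V). A marker replicates when its
replication p-value is below 0.05 **and** the slope sign matches
discovery; requiring concordance prevents an opposite-direction effect
from counting as confirmation. The concordance summary reports the number
selected, sign-concordant, replicated, and the Pearson correlation of the
slope pairs.

## Synthetic cohorts

The generator emulates the study design: 23,757 genes; 21 discovery
patients with paired samples whose SA/V values differ by more than
49 cm²/mL (low value uniform on the feasible interval, high value uniform
above low + delta; boundary draws rejected); 22 replication patients with
SA/V uniform on [100, 300] cm²/mL; patients assigned round-robin to two
batches. Expression is

    y = beta_i + alpha_true * SAV + batch_offset + eps

with Gaussian patient intercepts (per gene per patient), Gaussian noise,
Gaussian per-gene per-batch offsets, and a zero overall intercept
(log-ratios against a pooled reference are centred by construction).
Exactly round(frac_affected × n_genes) genes carry a nonzero slope, signs
balanced ±1 up to rounding, magnitudes uniform on the slope_scale range
(default 2–7 × 10⁻⁴ per cm²/mL, the magnitude range of the published
replicated markers). A per-gene mean log-intensity channel ~
N(intensity_mean, intensity_sd²) (default N(0,1)), independent of the
expression effect, makes the intensity filter exercisable. The noise
family is Gaussian throughout, matching the least-squares inference
applied to it. All randomness flows from a single `numpy.random.Generator`
seeded once.

**Calibration of the noise defaults.** The published study does not report
variance components, so the defaults are the package's own choice, fixed
a priori by a power argument anchored to printed numbers: a replication
slope of 9.6 × 10⁻⁴ per cm²/mL reported at p = 0.003 with n = 22 and SA/V
spread ~58 cm²/mL implies a replication-stage residual SD near 0.08 log
units. Defaults patient_sd = 0.03 and noise_sd = 0.05 give a combined
replication-stage SD of ~0.058, which places a top-of-range slope
(7 × 10⁻⁴) at roughly 85% replication power while keeping the P_patient
filter discriminating (about half of null genes pass it); batch_sd = 0.1
makes the batch effect substantial, as described. frac_affected defaults
to 0.05.

What the simulator does **not** model: probe-level two-colour dye
chemistry, spatial artifacts, reference-pool composition, non-Gaussian or
heteroskedastic noise, correlation between genes, and any dependence of a
gene's patient-effect size between cohorts. Passing tests therefore show
that the estimators and the two-stage logic behave correctly under the
assumed data-generating model — not that the biological findings would
reproduce on new tissue.

## Numerical and design choices

* Sample-to-column alignment is always by id; permuting either file leaves
  every statistic unchanged (tested end to end).
* Results, truth and heatmap exports are plain TSV, "." decimals, "NA"
  missing, floats at %.10g — write→read round trips are lossless at that
  precision, and a fixed seed yields byte-identical output files.
* Heatmaps display per-gene z-scores over the shown samples (constant
  genes become all-zero rows), samples ordered by increasing SA/V, genes
  grouped negative-slope block first and ordered by ascending discovery
  P_slope within blocks; the display convention is recorded in the export
  header. PNG rendering is a thin optional layer; every checked quantity
  lives in the TSV export.
* Ties in p-values are handled by the BH step-up minimum itself; no
  jittering.

## Problem sizes and known limitations

The test suite exercises the full 23,757-gene scan where the design scale
matters (calibration, the two-stage property) and 150–5,000 genes
elsewhere; the vectorised fit makes the full scan cheap, so these sizes
are statistical choices, not shortcuts. Two stochastic properties deserve
a caveat: the conditional replication rate of affected genes depends
noticeably on the realised SA/V spread of the 22 replication draws (a
single draw shared by all genes), so across generator seeds it fluctuates
in roughly the 0.75–0.90 band around its ~0.85 mean at top-of-range
slopes; the packaged checks pin fixed seeds. And because the true
adjustment used on the original data is not public, the centering step
here is a declared stand-in: it reproduces the *kind* of correction (a
conservative removal of a two-level processing offset), not the exact
published procedure.
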