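# Methods

This note documents the models and procedures monopred implements, the
defaults it ships, and the places where its behaviour is a deliberate
design choice rather than a forced consequence of the underlying method.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Cohort model and study design (`design`, `synthdata.gen_cohort`)

The planned analysis is a univariable logistic regression on a z-scored
indicator X:

    logit Pr(Y=1 | X) = α₀ + σ·X,   σ = ln(OR),   α₀ = logit(P),

where Y=1 is pCR/MPR response, P is the anticipated response probability
at the covariate mean, and OR is the odds ratio per 1-SD increase.  The
required cohort size uses the information-based approximation
(Whittemore's development, in Hsieh's corrected and tabulated form) for a
single continuous covariate:

    N = (z₁₋α/₂ + z₁₋β)² / (P(1−P)·σ²),  ceiled,

and its inversion gives the analytic power of the two-sided Wald test,
Φ(√(N·P(1−P))·|σ| − z₁₋α/₂).  z-quantiles come from the standard normal
inverse CDF rather than printed tables, which removes table-rounding
ambiguity; with OR = 2.3, P = 0.65, α = 0.05 and power 0.80 the raw value
is 49.7, so the ceiled requirement is 50 patients.  A continuous-covariate
adjustment is available as an explicitly labeled option
(`correction="multiple-correlation"`, dividing N by 1−ρ² for a covariate
with squared multiple correlation ρ² with other model terms); it reduces
to the base formula at ρ² = 0, which is the default.

Two properties of this approximation matter in practice and are covered
by tests rather than assumed:

* N is **minimal** at P = 0.5 and grows as the outcome becomes
  imbalanced (N ∝ 1/(P(1−P))).
* The approximation evaluates the Fisher information at the covariate
  mean.  At moderate effects (OR ≈ 1.5) simulated Wald power matches the
  analytic value closely; at OR = 2.3 the response probability varies
  strongly across the covariate range, the realized information is
  smaller, and the simulated power at N = 50 sits near 0.71–0.75 rather
  than 0.80.  The formula is therefore mildly anti-conservative exactly
  at the design point it is most often quoted for; `simulate_power`
  exists so users can check this for their own inputs.

`gen_cohort` draws indicators as (optionally correlated) standard normal
variables and the outcome from the model above with α₀ = logit(P).
Because the expit is nonlinear, the *marginal* response rate equals P
exactly only at OR = 1; at OR = 2.3 it is attenuated to ≈ 0.63.  The
generator keeps the printed model (no intercept recalibration) and
records (α₀, σ_k) as ground truth.

`fit_logistic` is maximum likelihood via statsmodels' `Logit` on the
z-scored indicator; complete separation or non-convergence is reported as
such (`converged=False`) instead of returning a silent estimate.
`simulate_power` derives one substream per replicate from the user seed
(`default_rng([seed, rep])`), so runs are reproducible without state.

## 2. Composition and TCR statistics (`composition`)

Per-sample cell-type proportions are renormalized over non-excluded types
(neutrophils are the canonical exclusion, being inconsistently captured);
a sample left without cells is dropped with a warning, and samples
lacking a cell type contribute proportion 0 for it in comparisons.

Group comparisons use the two-sided Wilcoxon rank-sum test.  Cohorts at
this scale have 4–7 samples per arm, where the normal approximation is
unreliable and ties in proportions are common, so for pooled sizes up to
14 the p-value is computed by exact-conditional enumeration of all
assignments using mid-ranks; larger inputs fall back to the tie-corrected
asymptotic test (`scipy.stats.mannwhitneyu`).  Strata where either group
has fewer than 2 samples (configurable) are reported as unavailable, not
errors — the "not enough samples" convention for sparse compartment ×
timepoint cells.

TCR clonotypes are binned by expansion level — Single (1), Small (2–5),
Medium (6–20), Large (21–100), Hyperexpanded (>100) — and clonal
diversity is the Gini–Simpson index 1 − Σ pᵢ² over clonotype
frequencies.  Only this named index is implemented.

## 3. Case-deletion diagnostics (`cdd`)

Differential expression between responder and non-responder monocytes is
computed per gene as a two-sided rank-sum test across cells, a log2 fold
change of pseudocount-stabilized group means (pseudocount 1e−9 on mean
expression, which bounds all-zero genes instead of producing infinities),
the percentage-point difference in expressing-cell fractions, and
Bonferroni adjustment over the panel.  Expression values are used as
given; per-cell library-size normalization is available but off by
default, because totals restricted to a small panel would make fold
changes compositional.

The deletion screen then:

1. recomputes the fold-change profile with one sample removed at a time
   (responder side by default, either side optionally), plus the
   no-deletion Control;
2. centers the profiles, projects them onto the first two principal
   components, and flags profiles whose Euclidean distance from the
   medoid exceeds 3 median-absolute-deviations (robust z).  The number of
   components and the cutoff are configurable: the underlying procedure
   prescribes "PCA and outlier" but no numeric rule, so these defaults
   are this package's documented choice, scale-free and matched to
   visual outlier reading.  The Control profile is never flaggable;
3. for each flagged sample, compares the top-100 upregulated and top-100
   downregulated DEGs (ranked by signed log2FC among genes with adjusted
   p < 0.05) between Control and the deletion.  When fewer than 100 genes
   qualify, k shrinks to the available count and is recorded.  The sample
   is retained when the overlap fraction reaches 0.8 in both directions
   (configurable — again a documented choice, as the source procedure
   says only "similar") and removed otherwise.

The two-stage design is deliberately forgiving: a spurious PCA flag is
rescued by the overlap check, which is why planted-outlier recovery holds
with both sensitivity and specificity ≥ 0.9 across seeded synthetic
cohorts in the acceptance tests.

## 4. Threshold screening (`screen`)

For indicators A, B, C the candidate range of each threshold is
[L_k, U_k] with L_k the responder minimum and U_k the non-responder
maximum; a combination S predicts pCR/MPR iff x_ik ≥ τ_k (inclusive) for
all k ∈ S.  The default grid is the sorted unique observed values inside
the range (always including L_k) — exhaustive for step-function metrics —
with an optional fixed-step grid.  The allowed combinations are the three
singles and three pairs; the full triple is available behind
`include_triple`.  Perfectly separating indicators (L_k > U_k) collapse
to the single point L_k and are flagged degenerate.

Reported metrics follow two coverage definitions, both returned:
responder coverage (responders passing / all responders — the headline
definition) and prediction coverage (patients receiving a prediction /
all patients).  Accuracy is responders passing / all passing, and is
*unavailable* (not 0) when nobody passes.  Patients with a missing
required indicator are unassigned and excluded from both numerators and
denominators, but counted and reported.

The selection score is accuracy/√n_pass, exactly as specified for this
screening procedure.  Note a structural quirk: at fixed accuracy this
score *decreases* with coverage, so it is maximized by the smallest pure-
responder pass set (typically a single extreme patient), despite being
motivated as an accuracy/coverage balance.  The package implements the
printed score verbatim as the default and ships accuracy·√n_pass behind
an explicit flag (`score_variant="times-sqrt"`) for users who want the
balance the motivation describes; the tests demonstrate both behaviours.
Ranking ties break deterministically: fewer indicators, then higher
accuracy, higher coverage, lexicographic combination, ascending
thresholds.  `validate_external` applies a frozen rule to a held-out
table with no refitting.

## 5. Image gating (`gate`) and the image generator

Channel conventions: page order DAPI, CD14 (ch1), CD16 (ch2), APOBEC3A
(ch3); row/column pixel grid, 0-based; masks are per-pixel booleans.

Positivity masks: rolling-ball-style background correction is a
grayscale opening with a flat structuring element (width 2r+1, default
r = 30 px), implemented with separable min/max filters — identical to a
ball on flat backgrounds, an exact no-op on zero background, and O(n·r)
rather than O(n·r²).  The threshold is the 50th percentile (default,
configurable) of the corrected intensity distribution over the whole
image ("global"), strict comparison, followed by removal of objects
smaller than 9 px and optional closing.

A percentile-of-the-whole-image threshold is only well-posed when most
background pixels tie at one value: with continuous noise, any such
threshold marks roughly half the background.  `MaskParams` therefore
applies a robust noise floor before the percentile: pixels within
`noise_floor_mads` (default 4.0) scaled MADs of the median of the
corrected image are set to 0, re-quantizing the background.  On noiseless
images the MAD is 0 and the step is an exact no-op, so it does not touch
the noiseless ground-truth oracle; the default multiplier sits on the
4–5 plateau where gated counts stay within 5% of ground truth down to
signal-to-noise 5 (an artifact-level regression bound, not a claim about
the source data).

Nuclei are segmented on DAPI by the same mask construction (min object
size 30 px) plus connected components, with an optional
distance-transform watershed for touching nuclei — the rendered fixtures
keep nuclei separated, so the default path has no splitting.  Per nucleus
and channel:

* **O_c** — the ring is dilate(nucleus, 4 px) minus erode(nucleus, 1 px),
  excluding other nuclei; ring pixels fall into 36 half-open angular bins
  about the nucleus centroid; a bin is positive with ≥ 1 positive pixel;
  O_c = 1 iff ≥ 50% of bins are positive *and* the largest circular run
  of negative bins spans < 90°.  Every geometric parameter is exposed in
  `RingParams`; these defaults are this package's documented choices, as
  the procedure names the parameters without printing values.
* **N_c** — the positive fraction of nuclear pixels must be strictly
  greater than 0.5 ("greater than", hence exactly 50% fails).

The Boolean rules A1 = O₂∧¬(O₁∨N₁), A2 = O₂∨O₁∨N₁, A3 = (N₃∧O₃)∧A2,
A4 = N₃∧O₃ imply A1⇒A2 and A3 = A4∧A2 on every image.  Phenotype labels
in summaries follow the immunophenotype convention and are overridable:
monocyte = A2, APOBEC3A⁺ monocyte = A3, APOBEC3A⁺ cell = A4,
non-classical = A1, classical = (O₁∨N₁)∧¬O₂ (CD14⁺CD16⁻).  Reported
ratios: A3/A2 (APOBEC3A⁺ monocyte ratio), A4/total cells, A3/A4; zero
denominators yield "unavailable", never 0.

The generator renders ellipse nuclei (semi-major 7–10 px, eccentricity
≤ 0.6 so rings stay well-posed), membrane markers as 3-px annuli,
APOBEC3A as nucleus+ring, placed by rejection sampling with a 12-px
minimum edge separation so that rendered signal and gating rings of
neighbouring cells cannot touch; placement failure yields a partial image
with a warning and the reduced count recorded.  Default intensities are
3000 (positive) over 0 background with Gaussian noise (sd 20) and a
smooth background gradient (amplitude 10) — a clean but non-trivial
imaging regime; tests exercise sd 0 (exact recovery) through sd 600
(SNR 5).

## 6. What the synthetic data does and does not emulate

The generators reproduce the *structure* the pipeline consumes:
group-shifted cell-type proportions, negative-binomial panel counts with
planted monocyte fold changes, power-law clonotype sizes (truncated
discrete power law, default exponent 2, so all five expansion bins are
reachable), the logistic outcome model at stated OR and prevalence, and
renderable images with per-cell phenotype truth.  They do not emulate
read-level sequencing noise, doublets, batch effects, spatial tissue
architecture, or optical PSF/bleed-through.  Passing tests therefore
certify the computational machinery — estimator consistency, oracle
equivalence, planted-signal recovery — not the biology of any real
cohort.

## 7. Known limitations

* The verbatim selection score's preference for minimal pass sets (see
  §4) means its top-ranked rule should not be expected to generalize;
  external validation of any chosen rule is the point of
  `validate_external`.
* The information approximation's anti-conservatism at large OR (§1)
  means a cohort sized at N = 50 for OR = 2.3 has closer to ~75% realized
  Wald power under the model itself.
* Exact rank-sum enumeration is limited to pooled n ≤ 14 by default;
  beyond that the tie-corrected asymptotic p is used.
* The gating defaults are tuned for the generator's geometry (nucleus
  radius ≥ 6 px, rings ≥ 2 px); substantially different magnifications
  need `RingParams`/`MaskParams` adjusted.
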