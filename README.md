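# monopred

Monocyte-derived predictors of immunochemotherapy (IC) response in lung
squamous cell carcinoma (LUSC): a tested, reusable implementation of the
computational framework around that biomarker programme, exercised
end-to-end on synthetic data with known ground truth.

In neoadjuvant IC, patients reaching pathologic complete response or major
pathological response (pCR/MPR) can be anticipated from monocyte-derived
indicators: the routine-CBC blood monocyte ratio, the tumor
classical-monocyte ratio, and the tumor APOBEC3A+ monocyte ratio.  This
package implements the analysis machinery such a programme needs, for
bioinformaticians and biostatisticians who want to reuse or audit it:

* **`monopred.synthdata`** — generators for patient cohorts, per-cell
  tables with a negative-binomial expression panel, and multiplex IF
  images (DAPI/CD14/CD16/APOBEC3A), each with recorded ground truth.
* **`monopred.composition`** — per-sample cell-type proportions, exact
  two-sided Wilcoxon rank-sum group comparisons, TCR clonotype expansion
  bins (Single / Small / Medium / Large / Hyperexpanded) and the
  Gini–Simpson index 1 − Σ pᵢ².
* **`monopred.cdd`** — imitating case-deletion diagnostics: leave-one-out
  DEG fold-change profiles, PCA outlier flagging, and a top-100 up/down
  DEG-overlap retention rule for influential samples.
* **`monopred.screen`** — threshold-combination screening: a patient is
  predicted pCR/MPR iff x_ik ≥ τ_k for every indicator k in the chosen
  combination S; thresholds are searched over [L_k, U_k] (responder
  minimum to non-responder maximum) and configurations scored by
  accuracy/√n_pass.
* **`monopred.gate`** — multi-channel logical gating of IF images:
  per-nucleus ring predicates O_c (angular-bin coverage of a perinuclear
  annulus) and nuclear predicates N_c, combined by the Boolean rules
  A1 = O₂∧¬(O₁∨N₁), A2 = O₂∨O₁∨N₁, A3 = (N₃∧O₃)∧A2, A4 = N₃∧O₃.
* **`monopred.design`** — a priori sample size for univariable logistic
  regression with a standardized continuous predictor
  (N = (z₁₋α/₂ + z₁₋β)² / (P(1−P)·ln²OR), the Whittemore/Hsieh
  information approximation), its power inversion, maximum-likelihood
  validation fits, and Monte-Carlo power checks.

## Worked example

```python
from monopred import design, gate, synthdata

# 1. design: how many patients does the validation cohort need?
spec = design.DesignSpec(odds_ratio=2.3, event_prob=0.65, alpha=0.05, power=0.80)
print(design.hsieh_n(spec))                      # 50
print(round(design.hsieh_power(50, 2.3, 0.65), 4))  # 0.8021

# 2. simulate a cohort of that scale and refit each indicator
coh = synthdata.gen_cohort(synthdata.CohortSimSpec(
    n_patients=54, prevalence=0.65,
    or_per_sd={"A": 2.3, "B": 2.3, "C": 2.3}, seed=1))
for k in "ABC":
    f = design.fit_logistic(coh.data[k], coh.data["y"])
    print(k, f"OR {f.odds_ratio:.2f} (95% CI {f.conf_int[0]:.2f}-{f.conf_int[1]:.2f})"
          f" p={f.pvalue:.4f}")

# 3. gate a synthetic IF image
img = synthdata.gen_image(synthdata.ImageSimSpec(seed=1))
s = gate.gate_image(img.stack).summary
print({k: s[k] for k in ("n_cells", "A1", "A2", "A3", "A4")})
```

prints

```
50
0.8021
A OR 1.21 (95% CI 0.70-2.10) p=0.5017
B OR 2.80 (95% CI 1.37-5.72) p=0.0046
C OR 2.09 (95% CI 1.11-3.92) p=0.0216
{'n_cells': 25, 'A1': 5, 'A2': 12, 'A3': 4, 'A4': 7}
```

Reading: 50 patients suffice for 80% analytic power to detect OR 2.3 per
1-SD at a 65% response rate, and the assembled 54-patient cohort meets
that bar.  Refits on one simulated 54-patient cohort show what that power
means in practice — the true per-indicator OR is 2.3, two of three
indicators reach significance on this draw.  On the gated image, 12 of 25
cells carry a monocyte marker (A2), 5 are CD16⁺CD14⁻ non-classical
monocytes (A1), 7 are APOBEC3A⁺ cells (A4) and 4 of those are monocytes
(A3); on noiseless renders these counts reproduce the generator's ground
truth exactly.

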