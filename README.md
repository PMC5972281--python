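# cfasim

Monte Carlo evaluation of one-factor CFA scale validation: how well does
confirmatory factor analysis recover a known unifactorial structure at the
sample sizes, indicator counts and loading magnitudes typical of applied
scale construction — and do the usual goodness-of-fit indices tell you when
it fails?

`cfasim` is for psychometricians, methodologists and students of structural
equation modeling who want a fully scripted, reproducible version of the
classic simulation design: generate multivariate-normal data from a known
one-factor population, fit the model by discrepancy-function minimization,
screen out improper solutions, and score parameter recovery against fit
indices.

## The model

Population: the common factor model `x = Λξ + δ`, implying
`Σ = ΛΦΛ′ + Θ`, with one factor (Φ = 1 fixed), equal loadings
λ ∈ {0.2, 0.3, 0.4} on p ∈ {4, 5, 6, 7, 15} unit-variance indicators, and
N ∈ {200, 300, 400, 500} — 60 conditions × 1,000 replications.

Estimation: minimize either the normal-theory ML discrepancy
`F_ML = ln|Σ*| + tr(SΣ*⁻¹) − ln|S| − p` on the covariance matrix S, or the
ULS discrepancy `F_ULS = d′d` (sum of squared moment residuals) on the
correlation matrix R, with a 250-iteration cap. A converged fit with some
θ̂ᵢ < 0 is a **Heywood case**; Heywood and non-convergent fits are
**improper** and filtered before summarizing.

Scoring: Tucker's coefficient of congruence
`C_k = Σλ̂λ / √(Σλ̂² · Σλ²)` (0.85–0.95 "fair", > 0.95 "good") against the
fit side's `χ² = (n−1)F`, `RMSEA = √(max(χ²−df,0)/(df(n−1)))` and the CFI
noncentrality ratio versus the independence baseline
(`χ²_b = −(n−1)ln|R|`).

## Worked example

```python
from cfasim import (PopulationModel, OneFactorCFA, generate_sample,
                    compute_moments, congruence)

model = PopulationModel.equal_loading(0.4, 6)       # λ = 0.4, p = 6
sample = generate_sample(model, 500, rng=7)          # one N = 500 draw
res = OneFactorCFA(compute_moments(sample)).fit_ml()
print(res.summary())
ck = congruence(res.standardized_loadings, model.loadings)
print(f"congruence with population loadings: C_k = {ck.c_k:.3f} ({ck.interpretation})")
```

```
One-factor CFA results
==========================================================
Method:   ML    Input: S    n = 500    p = 6    df = 9
Status: proper (converged=True, iterations=14, |grad|=3.85e-08)
Minimized discrepancy F = 0.00809495
----------------------------------------------------------
 indicator   loading  std.load  uniq.var       SE        t
        X1    0.4534    0.4592    0.7691   0.0592     7.65
        X2    0.4101    0.4035    0.8649   0.0603     6.81
        X3    0.4098    0.4278    0.7498   0.0570     7.19
        X4    0.3472    0.3505    0.8607   0.0587     5.92
        X5    0.3716    0.3734    0.8520   0.0591     6.28
        X6    0.5015    0.4965    0.7688   0.0609     8.23
----------------------------------------------------------
chi2(9) = 4.0394   p = 0.9088   RMSEA = 0.0000   CFI = 1.0000
congruence with population loadings: C_k = 0.993 (good)
```

Reading it: all six loadings are estimated near the population value 0.4
with standard errors ≈ 0.06 (every |t| > 1.96), the solution is proper, the
model is not rejected (p = 0.91), and recovery is essentially perfect
(C_k = 0.993). At λ = 0.2 and N = 200 the same pipeline instead produces
improper solutions in roughly a third of replications — the phenomenon the
study quantifies.

## Running the study

```sh
cfasim study --seed 1 --reps 1000 --out study_out      # full 60-condition grid
cfasim summarize study_out/results_ml.csv              # pooled 3 × 6 table
cfasim simulate --lam 0.3 --p 4 --n 200 --reps 1000 --seed 1 --out raw
cfasim diagnose raw/N200L030.csv --case 90             # eigenvalues, outliers, refit
```

`study` writes per-replication results (CASE, loadings, SEs, status, χ²,
RMSEA, CFI, C_k), the pooled summary table, and the congruence-ranking vs
p-value table; everything is reproducible from the master seed, and any
CASE's raw data can be regenerated in isolation (`cfasim.locate_case`).

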