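# paleomort

Parametric hazards analysis of skeletal age-at-death data, built for
bioarchaeologists and paleodemographers asking whether a binary covariate —
typically estimated sex — shifted mortality risks in an archaeological
assemblage.

Cemetery samples are small, selectively buried, and carry estimated (not
registered) ages, so nonparametric life tables are noisy and fragile. A
fully parametric mortality model smooths random variation without imposing a
fixed age pattern. `paleomort` implements:

- **Gompertz and Gompertz–Makeham mortality models.** The Gompertz hazard
  h(t) = α·e^{βt} captures senescent mortality rising exponentially with
  age; the Gompertz–Makeham form h(t) = α₁ + α₂·e^{βt} adds a constant
  age-independent risk α₁. Age is measured from an entry age of 15 years
  (t = calendar age − 15), which makes the left truncation of adults-only
  samples exact.
- **A proportional-hazards covariate.** A 0/1 code x (0 = male, 1 = female)
  multiplies the baseline hazard: h_i(t) = h(t)·e^{x_i ρ}. Positive ρ means
  higher female mortality risk. ρ is estimated by maximum likelihood jointly
  with the baseline, with Wald and profile-likelihood confidence intervals,
  and tested with the likelihood-ratio statistic 2(ln L_full − ln L_reduced)
  against χ²₁ (significance assessed at α = 0.1 by default). Per-period
  stratified fits are compared by CI overlap, with overlapping intervals
  reported as *failing to indicate* a difference — never as "no difference".
- **Transition-analysis-style Bayesian age estimation.** Cumulative-link
  (logit/probit) stage-given-age models per ordinal skeletal trait, an
  informative mortality prior, and a discretised posterior over age with
  posterior-mean point estimates and HPD intervals. Models are fitted to any
  known-age reference sample.
- **Sectioning-point metric sex classification.** Sample-mean sectioning
  points for six humeral/femoral measurements, majority-vote combination,
  and reconciliation against an externally supplied morphological estimate
  (metric wins over cranium-only morphology; pelvis-backed morphology
  stands).
- **A seeded synthetic-assemblage generator** emulating a 10-site, two-period
  medieval assemblage of 335 adults, so every pipeline stage is testable
  end-to-end with no external data, plus a recovery harness measuring bias,
  CI coverage, and LRT rejection rates.

## Worked example

Simulate an assemblage of 335 adults with no true sex effect (ρ = 0) and run
the full analysis:

```bash
cat > example.yaml <<'EOF'
simulate:
  n: 335
  rho: 0.0
seed: 42
alpha: 0.1
n_starts: 10
EOF
paleomort report --config example.yaml
```

prints

```
All individuals (n = 335) | -0.11 (0.11) | -0.33, 0.10 | 1.01 (0.31)
Early period (n = 87) | -0.12 (0.22) | -0.54, 0.31 | —
Late period (n = 248) | -0.12 (0.13) | -0.37, 0.13 | —
The likelihood-ratio test failed to indicate an effect of the covariate on mortality risks (LRT p = 0.314 at alpha = 0.1); this is not evidence of no effect.
The 95% confidence intervals for the covariate effect overlap between strata, failing to indicate a significant difference between time periods (which is not evidence of no difference).
```

Each row gives the stratum and sample size, the estimated covariate effect
ρ̂ with its standard error, the 95% confidence interval, and (for the pooled
fit) the likelihood-ratio statistic with its χ²₁ p-value. Here the true
effect is zero: ρ̂ = −0.11 sits well inside its interval (−0.33, 0.10), the
LRT p of 0.31 exceeds α = 0.1, and the early/late intervals overlap —
exactly the "failed to indicate an effect" outcome the report language
describes.

The same analysis runs on real data from a CSV
(`paleomort fit excavation.csv`), with idiosyncratic headers resolved
through a mapping config and invalid rows (e.g. ages under the 15-year
inclusion floor) quarantined with reasons. See `paleomort --help` for the
other subcommands (`simulate`, `lrt`, `age-estimate`, `sex-estimate`,
`recover`, `report`).

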