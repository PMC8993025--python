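# grmkit

Calibration, scoring and predictive evaluation for the unidimensional
graded response model (GRM) on ordinal (Likert-style) response data.

Two calibration routes produce interchangeable item banks:

- **MML-EM** — Bock–Aitkin marginal maximum likelihood with a fixed
  standard-normal latent population (`grmkit.mml`);
- **Regularized Bayesian** — the hierarchical model with half-Cauchy priors
  on discriminations and population scales and ordered normal thresholds,
  sampled by a built-in HMC sampler with analytic gradients (a mean-field
  variational fallback is available), diagnosed with arviz
  (`grmkit.bayes`).  Draws are mapped to the unit-ability frame so the two
  routes share a scale convention.

Four scoring estimators return `(theta, se)` against a fixed bank
(`grmkit.scoring`): maximum likelihood, Jeffreys-weighted likelihood (WLE),
EAP under a compactly truncated normal prior, and a marginal-maximum-
likelihood fixed point.  `grmkit.evaluation` implements seeded K-fold
partitioning and an uncertainty-aware predictive deviance: each scored
person is treated as Gaussian `N(theta, se^2)` and their observed responses
enter through a probit-scaled logistic-normal approximation (`-2 log`
scale; a point-variance mode sets `se = 0`).  `grmkit.simulate` generates
seeded synthetic banks, populations and sparse response matrices so the
whole pipeline runs without external data.

## CLI

```bash
grmkit simulate --items 12 --categories 4 --persons 500 --control-persons 200 \
    --seed 7 --out-dir runs/demo
grmkit calibrate --responses runs/demo/responses.csv --method bayes \
    --out-bank runs/demo/bank.json --out-scores runs/demo/calibration_scores.csv
grmkit score --responses runs/demo/responses.csv --bank runs/demo/bank.json \
    --method eap --out runs/demo/eap.csv
grmkit evaluate --responses runs/demo/responses.csv --k 4 \
    --calibration mml --scoring eap --seed 1 --out runs/demo/deviance.json
grmkit evaluate --responses runs/demo/control_responses.csv \
    --bank runs/demo/bank.json --scoring eap --out runs/demo/holdout.json
grmkit compare --scores-a runs/demo/calibration_scores.csv \
    --scores-b runs/demo/eap.csv --out runs/demo/agreement.csv
```

Formats: response matrices are CSV (`person_id` column then item columns,
empty cell = missing, 1-based integer codes); item banks are JSON with full
double precision; scores are CSV (`person_id, theta, se, method, flagged`).
Every output carries a JSON sidecar (or embedded `meta`) recording the seed
and configuration that produced it.

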