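# Methods

This note documents the models implemented in `strongties`, the choices
made where the design was genuinely open, and what the synthetic data can
and cannot establish. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic respondent data

The generator (`strongties.synthetic_data`) emulates the *structure* of a
large household survey of adults aged 45+ — one row per respondent with
economic-transfer pairs to five relative categories, three
social-interaction indicators, a 0–6 contact-frequency scale, ten controls,
a supplementary-medical-insurance indicator `medical`, and the binary
care-model outcome `care_all` — under a fully known data-generating
process, so that every downstream stage can be tested by parameter
recovery.

Covariate marginals (defaults, first moments only):

| field | distribution | default target |
|---|---|---|
| age (years) | truncated normal on [45, 121]; parent N(63.61, 11.35²) | truncated mean 64.857, sd 10.207 |
| gender, edu, married, health, insurance, urban, province | independent Bernoulli | 0.473 / 0.127 / 0.851 / 0.250 / 0.970 / 0.289 / 0.309 |
| l_expen (log monthly expenditure) | N(7.1346, 1.0272²) | — |
| family (household size) | Poisson(3.07) clipped to [0, 20] | subgroup means ~3.05–3.08 |

The published descriptive table prints household-size mean 7.1346 — an
evident typesetting duplication of the expenditure mean (its own sd is
1.84, max 20, and the subgroup breakdown reports means 3.05/3.08); the
generator therefore targets ≈3.07. The same table's age row (mean 64.86,
max 121) contradicts the stated 45–60 sampling window; the generator
follows the table.

**Transfers.** Each of the ten give/receive amounts is zero-inflated
log-normal: inactive with probability `p_zero = 0.9241` (so the
any-transfer share is `1 − 0.9241¹⁰ ≈ 0.546`, matching the `clan` mean),
otherwise `exp(N(1.997, 2.0²))`, rounded to cents. The log-mean was solved
by bisection so `E[ln(1 + Σ amounts)] ≈ 1.496`. This reproduces the
kinship index's published mean, exact zeros, and heavy right tail; it does
not reproduce its extreme maximum (≈14, i.e. totals above 10⁶), which
would require a heavier tail than the mean constraint allows. Only first
moments are calibrated.

**Friendship indicators.** Spending, guest meals and activity counts share
a weak latent "sociability" factor (loading 0.25) plus idiosyncratic
noise: spending is zero-inflated log-normal (65% active, log-sd 1.3 —
the heavy tail behind the index's large positive maximum), the counts are
log-linear Poisson in the latent factor. The implied pairwise correlations
are ~0.03–0.05, giving a first eigenvalue near 1.04 and an overall KMO
near 0.51 — the same "barely adequate, only one component above 1"
regime as the reference analysis. Contact frequency (0–6) is an
over-dispersed latent-rate Poisson clipped at 6 (mean ≈0.70, sd ≈1.1).

**Outcomes.** `medical` is Bernoulli-logistic with linear predictor
`−1.9886 + ln(1.082)·hosnet_F` (take-up ≈0.12 — the survey does not print
this prevalence; 12% is a plausible supplementary-insurance rate and gives
the mediation channel workable power at n = 20,000). `care_all` is
Bernoulli-logistic in the **derived** kinship index (computed with the same
code the pipeline uses), the ten controls and `medical`; default
coefficients are the logs of the headline odds ratios (kinship 1.091, age
1.036, gender 1.048, edu 0.914, married 0.881, health 1.069, insurance
1.736, l_expen 1.032, family 1.010, urban 1.007, province 1.318, medical
1.823) with intercept −4.7575 solved for prevalence 0.1975. The friendship
index has **no direct** care_all coefficient by default: it acts only
through `medical`, which is exactly the mechanism structure the Table-10-
style battery probes, and makes `hosnet_F` a true null for size checks.
Interaction keys (`"a:b"`) allow subgroup-specific effects, e.g. a
rural-only kinship effect for heterogeneity power checks.

Missingness is independent Bernoulli per field (default 0) — a
missing-completely-at-random device to exercise listwise deletion, not a
model of survey nonresponse.

**What passing tests do not show.** The generator matches first moments
and one correlation regime; it has no survey weights, no panel structure,
no spatial clustering, and independent covariates. Recovery of the
generating coefficients demonstrates the *pipeline* is correct, not that
the substantive estimates would replicate on the real survey.

## 2. Tie indices

* Kinship: `ln(1 + Σ give + Σ receive)`. `ln(1+x)` rather than `ln(x)`
  because the published index minimum is 0 with zero-transfer respondents
  present; give and receive are summed (reciprocity framing), not netted.
* KMO: overall and per-item measures from the inverse correlation matrix
  (`p_ij = −c_ij/√(c_ii c_jj)`). A numerically orthogonal design makes the
  defining ratio 0/0; it is reported as 0 with a `RuntimeWarning`.
* Friendship index: columns standardized (sample sd, ddof = 1),
  eigendecomposition of the correlation matrix, components with eigenvalue
  ≥ 1 retained (inclusive at the boundary; floored at one component since
  scoring always uses the first PC). The eigenvector sign is arbitrary, so
  scores are oriented to load spending positively; scores are re-centered
  once to absorb ~1e-16 float drift. Rows with any missing indicator get
  no score (complete-case PCA; no imputation, no rotation).
* `clan` = 1 iff total transfers > 0; `friend` = validated 0–6 contact
  frequency.

## 3. Binary-choice estimation

Newton–Raphson ML for logit and probit with step-halving; convergence at
score max-norm ≤ 1e-10 (tight enough that the 2×2-design odds ratio equals
the cross-product ratio to 1e-10), max 100 iterations, non-convergence
returning a flagged partial result. Standard errors are
observed-information (no clustering or robust sandwich — the reference
analysis mentions none). Separation is flagged when a standardized
coefficient exceeds 20 with a non-vanishing score; rank deficiency raises
an error naming the collinear columns. Missing data: listwise deletion per
model (the varying per-model sample sizes in the reference tables imply
this). "Adjusted R-squared" for these models is interpreted as McFadden's
adjusted pseudo-R², `1 − (LL − k)/LL₀` with k the number of estimated
parameters, since no definition is printed. Significance stars follow
computed two-sided Wald p-values strictly (10/5/1%), even where the
reference table's starring is internally inconsistent (an OR starred at
10% with |z| = 1.61, nominally p ≈ 0.107).

Batteries: baseline (each index bare and with all ten controls),
robustness (clan/friend under logit reporting odds ratios; the original
indices under probit reporting raw coefficients), heterogeneity
(east/mid-west × urban/rural per index, the split dummy dropped from the
controls inside its own subgroups), and mechanism (index → medical;
care_all on medical + index + controls; the same restricted to healthy
respondents with the health dummy dropped). No instrumental variables,
survey weights, or formal mediation decomposition.

## 4. SIRS care-market model

States: uninformed non-choosers S, risk-aware non-choosers I, formal-care
choosers R, constant population N. Rates α (tie-strength contact), β
(adoption via learning/imitation), δ (reversion I→S), λ (abandonment
R→S), all strictly positive. Incidence is bilinear αSI exactly as the
model is written; with the default N = 1 this coincides with
frequency-dependent mixing, so α is "per contact per unit time" on the
population-share scale and the rates are illustrative, not calibrated —
the model is used analytically, and its link to the mechanism regressions
is qualitative (both sides are implemented; no formal identification is
claimed).

The interior equilibrium `S* = (β+δ)/α`, `I* = λ(N−S*)/(β+λ)`,
`R* = β(Nα−β−δ)/(α(λ+β))` exists iff `αN > β+δ`; otherwise the system
settles at `(N, 0, 0)`. `S*` is strictly decreasing in α and independent
of λ — the comparative static behind "stronger ties shrink the uninformed
pool".

Numerics: classical fixed-step RK4 (default dt = 0.01), which preserves
the linear invariant S+I+R = N to roundoff; accuracy is verified by step
halving (terminal-state change < 1e-8) and by convergence of endemic
trajectories to the closed form within 1e-5–1e-6 relative error. Stability
is checked by simulation from `S ≫ I > R` initial states, not by Jacobian
eigenvalues. Initial states must be nonnegative and sum to N within 1e-9.

## 5. Pipeline and reproducibility

A run is a YAML config (seed, generator block, battery list, SIRS block).
Each stage draws its RNG substream from `SeedSequence(seed,
spawn_key=(stage,))`, so toggling one stage never shifts another's
randomness. Every artifact is delimited text (CSV with one header row,
empty fields for missing values, nullable-integer dtype contract on read)
plus aligned text renderings of the regression tables; the manifest
records SHA-256 checksums, and rerunning an identical config reproduces
identical checksums. Config validation collects *all* violations (positive
n, strictly positive SIRS rates, increasing α grid, consistent initial
state) before failing; a missing seed defaults to 0 with a warning.

## 6. Problem sizes in the checked examples

The test suite runs its Monte-Carlo checks at the sizes the recovery
design calls for: 100 replicates of n = 20,000 for CI coverage of the four
headline odds ratios, 200 replicates of n = 20,000 for the size of the
Wald test on the true-null friendship coefficient (at much smaller n that
test is measurably conservative because the index is heavy-tailed), 50
random endemic SIRS parameter draws integrated to t = 800, and n = 50,000
for the equicorrelated KMO design, which is constructed with *exact*
sample correlation 0.5 (whiten-then-recolor) so the closed form 0.6923 is
met deterministically.

## 7. Known limitations

* The generator's covariates are mutually independent apart from the
  latent sociability factor; real survey covariates are not.
* The kinship index's published maximum (totals ~10⁶) is not reproduced
  under the mean-calibrated transfer tail.
* Heterogeneity in the defaults is homogeneous (one care_all coefficient
  vector); subgroup-specific regimes must be configured explicitly.
* Probit fits share the logit DGP, so probit coefficient recovery is only
  checked up to the standard ≈1.6 link rescaling.
* The SIRS rates have no empirical units; comparative statics are
  qualitative.
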