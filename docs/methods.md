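# Methods

## Model and assumptions

`foxdepletion` implements a generalized depletion model for an open,
intensively culled fox population observed through an effort-based detection
index. The core assumptions:

* **Observable population.** `N_t` counts adults plus cubs active away from
  the breeding earth after weaning — the subset a lamping operator can see.
  Pre-weaning cubs enter only through the recruitment schedule.
* **Two-week time-step.** Fine enough to separate removals from replacement
  (territory vacancies can refill within weeks), coarse enough to keep the
  latent-state dimension manageable. Calendar convention: week =
  ceil(day-of-year/7), step s covers weeks 2s−1..2s, 26 steps/year with
  days 365/366 folded into step 26. February = steps 3–4; the week-10–30
  nesting window = steps 5–15; April–July = steps 7–15.
* **Density dependence.** Immigration `v(1 − N/K)` and recruitment
  `w_t r N (1 − N/K)` both shut off at the carrying capacity `K`, which is
  assumed constant per estate. Non-culling mortality `M` is
  density-independent. There is no age or sex structure; a 50:50 sex ratio
  with all females breeding is folded into `r`.
* **Process error.** Lognormal with fixed σ_p = 0.2 and the −σ_p²/2
  correction so the multiplicative shock has mean one (the state equation
  tracks expected rather than median density). σ_p is fixed because it is
  only weakly identifiable jointly with density dependence; the sensitivity
  suite provides fixed alternatives (0.05, 0.1) and estimable variants
  (uniform(0.001, 1) or lognormal(ln 0.05, CV 0.2) priors).
* **Observation model.** `Y_t ~ Poisson(d E_t N_t)` — a Holling disc with
  zero handling time, defensible at the low densities of culled rural
  populations. Zero-effort steps contribute no likelihood but states still
  propagate, so series with recording gaps remain fittable.
* **Positivity.** The deterministic balance is floored at 0.001 fox·km⁻²
  *after* the full balance (recruitment debits included), and sampled states
  are constrained to the same floor. Conditioning on a recorded cull can
  otherwise drive predictions negative.

## Recruitment schedule

Conception dates are modelled as logistic(location, scale) in week-of-year
units; recruitment time is conception + gestation (7.4 wk) + weaning-to-
independence (8 wk). Weights are the CDF mass falling in each two-week step;
steps receiving <1% are zeroed and the rest renormalized (the logistic has
unbounded support, so a compact within-year support requires truncation).
Defaults location = week 6.0, scale = 1.2 wk put median conception in early
February and births mid-March–mid-April, giving support over steps 9–14
(May–mid-July) with mode at step 11. These defaults are calibrated to that
phenology, not to any external fit's exact parameters, and are exposed as
config (`schedule.location_week`, `schedule.scale_weeks`,
`schedule.gestation_weeks`, `schedule.weaning_weeks`). Mass crossing 31
December is an error rather than wrapped: spring recruitment cannot span the
year boundary. Annual cub-cull totals are redistributed as `w_t × total`
within each calendar year; when a series covers a recruitment window only
partially, weights are renormalized over the covered steps so totals are
conserved exactly.

## Priors

Lognormal priors are specified by median and coefficient of variation with
σ² = ln(1 + CV²) — the CV is the distribution's own CV. Annual rates (v, M)
are divided by 26 for the two-weekly model scale and reported weekly
(annual/52). The joint constraint N₀ ≤ K is implemented as
N₀ | K ~ uniform(0.001, K). Vague mode replaces v, r, M, d with wide
uniforms whose upper bounds (1.0 fox·km⁻²·2wk⁻¹, 6 cub·fox⁻¹·yr⁻¹,
0.1 2wk⁻¹, 10 km²·hr⁻¹) are generous multiples of the informative medians;
they are this package's re-specification, not a published set.

## Sampler

The model is fitted on the proportion scale P_t = N_t/K, which decorrelates
the states from K. The sampler is an adaptive random-walk
Metropolis-within-Gibbs, numba-compiled, with per sweep:

1. single-site log-scale updates of the six parameters (step sizes adapted
   to 44% acceptance during burn-in);
2. one joint adaptive-Metropolis block move using the running covariance of
   log-parameters (scale 2.38²/6);
3. a density-invariant K move (K → cK, all x_t = ln P_t shifted by −ln c,
   N₀ co-scaled) and a detection-invariant d move (d → cd, x shifted by
   −ln c): both are shears with unit Jacobian and symmetric proposals, so
   the plain Metropolis ratio applies; they traverse the stiff K- and
   d-versus-trajectory ridges that single-site updating crosses only
   diffusively;
4. leading-segment and random interior-window level shifts of the latent
   states (the level of data-poor stretches is the slow direction);
5. single-site latent updates, emulating one-site Gibbs updating.

All adaptation freezes at the end of burn-in, preserving the stationary
target. Chains initialize from the best of 50 joint-prior draws pushed
through a deterministic forward pass — a guard against starting inside the
degenerate floor region of the posterior, where a trajectory pinned at the
density floor pays no process-error cost and a greatly inflated `d` can fit
the detections. Convergence is monitored by split Gelman–Rubin statistics
(via `arviz`, classic split form) on all parameters and latent states with
threshold 1.01; non-convergence raises a `ConvergenceWarning`, never a
silent success.

Profiles (burn-in / thinning / recorded draws per chain, 2 chains):
`full` = 150 000 / 100 / 10 000 (mirrors the reference protocol; ~2 min per
fit on one CPU, reaches max split R-hat < 1.01 on standard synthetic
estates); `standard` = 30 000 / 30 / 1 500 (~8 s per fit, the
simulation-estimation default); `reduced` = 10 000 / 10 / 1 000 (quick
smoke fits; too short for reliable convergence and gated accordingly).

Realized process errors are extracted per draw as
ε_t = ln P_t − (ln B_{t−1} − σ_p²/2), where B is the floored deterministic
balance; empirical σ_p is the over-time standard deviation averaged over
draws. On the P or N scale the extraction is algebraically identical.

## Operating model (synthetic data)

The generator emulates the structure of gamekeeper diaries: seasonal
lamping effort (lowest in summer, lognormal step-level noise, optional
recording gaps), Poisson detections `d E_t N_t`, a lamping cull that is a
binomial thinning of the *realized* detections at kill probability 0.30
(culled never exceed detected in a step), other-method culls as Poisson
counts with a winter-biased seasonal weight scaled so lamping is ~66% of
the adult cull in expectation, and an annual cub cull drawn binomially
(default fraction 0.10) from the year's expected cub production, recorded
at the first recruitment step and redistributed exactly as the estimator
redistributes it. States propagate with the realized culls and σ_p = 0.2.

The data-requirement screen operationalizes the informativeness rules:
≥3 complete recruitment periods (steps with w_t > 0) in the span; ≥2
effort-positive steps within each covered recruitment period; ≥8 weeks
(4 effort-positive steps) of lamping per covered year; no gap between
effort-positive steps longer than nine months (19 steps); ≥1
effort-positive step in each of the first three 4-week windows.

### Calibration of the simulation–estimation study conditions

Truths for the recovery experiments are drawn as: r and M from the
informative priors; K ~ uniform(2, 8.5) fox·km⁻²; N₀ uniform on
(0.2K, K); v lognormal(median 0.25 per step, CV 0.84); d lognormal(median
0.35 km²·hr⁻¹, CV 0.50). The v and d centres sit at estate-level scale
rather than at the prior medians: populations generated with prior-median
search rates (2.01 km²·hr⁻¹) either collapse onto the density floor under
realistic lamping effort or, with effort scaled down to avoid collapse,
yield detection series far sparser than real diaries, because sustainable
detections are capped by the replacement rate. With the calibrated truths
and the default effort pattern (1.0/0.7/0.35/1.0 hr·wk⁻¹ by season,
4-year series), simulated estates reproduce the regime real estates show:
pre-breeding density averaging ~39% of K (10–90% range 0.17–0.66),
detection rates under one fox per lamping hour, tens of culls per year,
and no floor saturation. This calibration was fixed against those data
features before any recovery quantities were computed.

What the generator does **not** emulate: spatial structure and
neighbour-estate source–sink dynamics, operator behaviour responding to fox
sightings, weather/moonlight detectability variation (beyond lognormal
effort noise), age/sex structure, and between-year variation in K. Passing
recovery tests therefore demonstrate internal consistency of the
estimator under the model's own assumptions plus realistic observation
budgets — not robustness to these unmodelled features of real data.

### Known limitation: density-bias magnitudes

The recovery experiments reproduce the qualitative findings — density bias
is reduced by informative priors, vague priors inflate density and the
N₀/K/M parameters, and 80% credible intervals cover truth at roughly
nominal rates — but the *magnitude* of the mean percent relative bias of
posterior-median density is larger and noisier here (tens of percent, with
per-replicate spread of similar size) than the few percent a richer
detection budget would give. Two mechanisms dominate: the per-step percent
bias statistic is driven by low-density troughs, where a series holding
~40 detections per year carries almost no information and the posterior
median sits above a near-zero truth; and the informative d prior, centred
several-fold above estate-level search rates, pulls density downward when
the index is weak. Both effects shrink as the detection budget grows.

## Numerical choices

* Density floor 0.001 fox·km⁻², applied to the balance after the full
  debit and to sampled states (as 0.001/K on the P scale).
* Negative recruitment (cub cull exceeding a step's production) is
  permitted and flows into the next balance; redistribution guarantees
  cubs are not removed before production only in annual aggregate.
* Detection likelihood contributes 0 for zero-effort steps and −∞ (flagged,
  not raised) for a positive count against a zero expectation.
* Replicates whose worst parameter split R-hat exceeds 1.1 are refitted
  once with a fresh seed, then excluded with the count reported.
* One master seed; per-chain and per-replicate seeds derive from it via
  `numpy.random.SeedSequence`.
* Sensitivity "truncation" diagnostic: a uniform-prior parameter with >15%
  of posterior mass in the top 5% of its prior support is flagged as
  bound-truncated (a heuristic, documented here).

## Design choices where the design was open

* The recruitment-schedule defaults encode the quoted phenology (births
  mid-March–mid-April, weaning 6–8 weeks) rather than an external fit; the
  1% truncation threshold gives the schedule compact support.
* The CLI is a thin layer; the library API and `examples/` scripts are the
  primary interface.
* The Gelman–Rubin implementation routes through `arviz`; tests verify it
  against the closed-form between/within formula independently.
* No probabilistic-programming backend: the built-in sampler is the
  reference implementation, and posterior identity (not sampler identity)
  is the requirement.

## Limitations

Beyond the operating-model gaps above: the model assumes `d` constant over
time (no lamp-shyness or seasonal detectability), `K` constant within an
estate, and culls recorded without error. The floor introduces a mild
boundary bias in realized process errors for heavily over-culled steps.
Real-data application requires the supplementary culling-record dataset;
all results in this repository are computed on synthetic data or on printed
summary values.
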