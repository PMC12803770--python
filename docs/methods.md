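# Methods

## Model and procedure

The package assumes each donor $i$ has a stable haematological setpoint
$\mu_i$ and that an on-site Hb measurement at visit $t$ is

$$x_{it} = \mu_i - d_{it} + \varepsilon_{it}, \qquad
\varepsilon_{it} \sim \mathcal{N}(0, \sigma_s^2)\ \text{i.i.d.},$$

where $\sigma_s$ is the sex-specific measurement SD (capturing
pre-analytical, analytical and short-term biological variation together) and
$d_{it} \ge 0$ is an optional post-donation deficit. Eligibility decisions
treat $d_{it}=0$; the deficit exists in the generator to probe estimator
robustness.

Under this model the historical mean of $n$ prior measurements is
$\mathcal{N}(\mu_i, \sigma^2/n)$, which justifies the two decision rules:

* **Reason A.** Compare a bound on the historical mean with the legal
  threshold $T$. With `alpha_mean` $=\alpha_m \in (-1,1)$ the bound is
  $\bar{x} + \mathrm{sign}(\alpha_m) z_{(1+|\alpha_m|)/2} \sigma/\sqrt{n}$,
  i.e. the lower (negative $\alpha_m$) or upper (positive) limit of the
  two-sided $|\alpha_m|\cdot100\%$ confidence interval; at $\alpha_m=0$ the
  mean itself. Deferral iff bound $< T$.
* **Reason B.** Flag a single low reading:
  $x < \bar{x} - z_{\alpha_o}\sigma a$. With the prediction-interval
  adjustment ($a=\sqrt{1+1/n}$) the statistic $x-\bar{x}$ is exactly
  $\mathcal{N}(0, \sigma^2(1+1/n))$ for a stable donor, so the false-positive
  rate equals $1-\alpha_o$ at every $n$ — the setting under which the
  "1 in 1000" reading of $\alpha_o = 0.999$ is exact. Without it ($a=1$,
  the default) the rule uses measurement variability alone and is slightly
  more conservative at small $n$.

Decision order per visit: not assessed if fewer than
`min_prior_measurements` priors; else reason A; else reason B; else
eligible. The current policy defers iff $x < T$; equality donates, so the
threshold itself is eligible under both policies.

## Design choices where the procedure was open

These conventions are explicit options with documented defaults rather than
silent guesses:

* **Two-sided interval, one bound compared.** The confidence interval is
  two-sided at $|\alpha_m|\cdot100\%$; the sign of $\alpha_m$ selects the
  bound. This keeps the $\alpha_m \to 0^\pm$ limits continuous with the
  $\alpha_m=0$ mean-only rule.
* **The current measurement never enters its own reference mean.** A new
  observation is judged against the mean of *prior* data; one auditable
  convention, deliberately not configurable.
* **Reason B does not additionally require $x < T$** by default — an outlier
  w.r.t. the donor's own level is flagged even above the legal threshold; a
  strict mode (`outlier_requires_below_threshold`) adds the requirement.
* **Deferral visits stay in the history** (`history_scope: all_visits`):
  donations and deferrals form one measurement series;
  `donations_only` is provided for sensitivity analyses, as is an optional
  `max_history` cap on the number of most recent prior measurements.
* **$\sigma$ is population-level and sex-specific**, not per-donor: per-donor
  variance estimates are far too unstable at typical career lengths.
* **Assessment is static**: relabelled decisions never alter which
  measurements enter later histories, and deferral periods / minimum
  donation intervals are ignored in the retrospective relabelling (they
  exist only in the generator). Re-running the evaluation is idempotent.

## Variability estimation

$\hat\sigma$ = sample SD (n−1 denominator) of all within-donor consecutive
differences pooled across donors of one sex, divided by $\sqrt{2}$.
Differences cancel the setpoint, so between-donor spread cannot leak in
(shift-invariance is property-tested). Pairs spanning a deferral are
included; an optional `max_gap_days` drops long-separated pairs. Estimates
from fewer than 30 pairs are flagged unusable and downstream code refuses to
run without an explicit override. No recovery correction is applied: real
within-donor change makes $\hat\sigma$ an upper limit for the measurement
SD, and with the generator's recovery switched on the estimate indeed rises
(by ~0.003 g/dL at the default recovery profile — small relative to the
0.70 g/dL it estimates, which is why a correction is not worth its
complexity).

## Evaluation metrics

Counts are over assessed visits only (each donor's first
`min_prior_measurements` visits are excluded from every numerator **and**
denominator). The accounting identity
$d_{alt} - d_{cur} = \text{newly deferred} - \text{newly eligible}$ holds
exactly and is enforced (a violation raises). Denominators: deferral rates
and the newly-deferred share divide by assessed visits; the net change in
donations divides by current-policy donations, giving
$(\text{rate}_{cur}-\text{rate}_{alt})/(1-\text{rate}_{cur}/100)$ — the
convention that reproduces published country summaries from their printed
rate pairs. Ratios with zero denominators are reported as `None`, never 0.
Rounding (2 decimals for rates, 1 for the change in deferrals) happens only
at presentation.

## Synthetic donor careers

The generator emulates a registry extract under exactly the assumptions the
rules rely on: Gaussian setpoints (per-sex mean and between-donor SD),
i.i.d. Gaussian measurement noise, visit dates advancing by the sex-specific
minimum donation interval plus uniform jitter. Defaults (chosen once):

| parameter | default | why |
|---|---|---|
| per-sex mean Hb / measurement SD | 15.06 / 0.70 (M), 13.54 / 0.67 (F) g/dL | typical capillary-measurement donor population (Netherlands-like); other country presets available |
| between-donor SD | 1.0 g/dL | puts the total cross-sectional SD near the ~1.2 g/dL seen in donor populations |
| visits per donor | 10 | a mid-career repeat donor |
| min interval / jitter | 56 d (M), 122 d (F) / 28 d | statutory whole-blood intervals plus scheduling noise |
| recovery dip / time | 1.5 g/dL over 150 d, linear in log(time); **off** by default | ~10% red-cell-mass loss from a 500 mL donation; iron-limited replenishment slower than the minimum interval |

`inject_low_mean_donors` moves a chosen fraction of setpoints to
$T - \text{offset}$, shifting that donor's measurements rigidly (noise is
preserved), and returns the IDs for ground-truth scoring.

Each donor has an independent random stream keyed by (seed, donor index), so
populations are bit-reproducible and donor-parallel generation is safe.

**What the generator does not emulate — and what that means for the tests.**
Real registries are shaped by donor-pool self-selection: donors deferred
repeatedly lapse, so few active donors keep setpoints below threshold, and
observed deferral rates are 1–8%, not the ~15% a truncation-free Gaussian
population with a 1.0 g/dL spread produces against the female threshold.
Passing tests therefore validate the algorithm's calibration and accounting
on data satisfying its assumptions, not country-level magnitudes. The
detection experiment (1% injected donors 0.5 g/dL below threshold,
20-visit careers) accordingly uses a male-only cohort with between-donor SD
0.7 g/dL — total spread still ~1 g/dL, but naturally-consistently-low donors
rare — so that the injected 1% *is* the consistently-low subpopulation and
the newly-deferred share lands in the ~0.2–2% range reported across real
services. Also absent: seasonal/diurnal Hb variation, device drift,
menopause-related setpoint change, ferritin/iron-store dynamics, and
donor-return behaviour.

## Numerical choices

* Normal quantiles via `scipy.stats.norm.ppf`, validated against bisection
  on an erf-based CDF to 1e−8 in the tests.
* Sample (n−1) SD for $\hat\sigma$; the difference from the population SD is
  negligible at registry scale.
* Vectorised assessment uses per-donor cumulative sums; it matches the
  per-visit reference implementation to 1e−9 g/dL (property-tested). The
  `max_history` cap takes a per-donor slow path.
* Strict inequalities throughout (`bound < T`, `x < cutoff`, `x < T`), so
  boundary values are eligible/donating.
* Ties in same-day measurements collapse per `same_day_rule`
  (default `max`, mirroring best-of-repeated-sticks recording; `min`/`mean`
  for sensitivity); date ties are otherwise broken by input order.
* Hb is validated to [5, 25] g/dL after explicit unit conversion
  (`units: g_L` divides by 10); units are never auto-detected.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 2,000 donors × 100 visits
for the reason-B false-positive calibration (±3 binomial SE around 1/1000);
10,000 donors × 10 visits for σ recovery (Monte-Carlo tolerance ±0.02);
4,000 donors × 20 visits for the consistently-low-donor detection
experiment; and 100 random small datasets for the exact accounting identity.
The full suite runs in well under a minute on one CPU.

## Known limitations

The evaluation is a static relabelling: it cannot say how donor behaviour,
return rates, or Hb trajectories would change under the new policy, and it
offers no rule for a donor's first two visits. $\hat\sigma$ is an upper
limit, so reason-B deferrals are, if anything, slightly under-triggered.
Setpoint non-stationarity (e.g. around menopause) argues for the
`max_history` cap, whose choice is left to the user.
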