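# Methods

## Cohort model

The model follows a closed cohort of advanced-NSCLC patients who completed
first-line platinum-based chemotherapy without progression. Time advances in
21-day cycles (174 cycles ≈ 10 years); state occupancy is a deterministic
fraction vector over four states: progression-free (PFS), progressed on
2nd-line chemotherapy (PD_2L), progressed on supportive care (PD_SC), and
death. The whole cohort starts in PFS. Each cycle, the PFS exit probability
comes from the Weibull curve fitted to the control arm's progression-free
survival (scale 0.1559, shape 1.045 per cycle), `P_t = 1 − S(t)/S(t−1)`;
exits split 56.6% : 43.4% between PD_2L and PD_SC. There is no direct
PFS→death channel and no return from progression: every exit from PFS is a
progression, and all mortality is modelled post-progression. This mirrors a
structure in which separate overall-survival curves apply only after
progression; over horizons of two years and more it is immaterial because
essentially the entire cohort progresses first.

Post-progression mortality uses the overall-survival Weibulls of 2nd-line
chemotherapy (0.03897, 1.509) and supportive care (0.04006, 1.156),
evaluated on a subcohort clock that restarts at the progression cycle
(semi-Markov tunnel). Progressed occupancy is therefore stratified by entry
cycle; the implementation stores entry fractions and tunnel survival
vectors and reconstructs occupancy by discrete convolution, which is exact
and O(N²) at worst.

Occupancy at cycle *t* is measured after the cycle-*t* transitions, and all
accrual (costs, life-years, QALYs) runs over cycles 1..N; cycle 0 carries
only the one-time genotyping cost. No half-cycle correction is applied by
default (a flag enables a simple first-cycle half-weight variant); the
incremental results that matter are insensitive to this choice because both
strategies shift together.

### Strategies

*Control*: routine follow-up for everyone. *Gefitinib*: everyone is
genotyped; the EGFR-mutation-positive stratum (frequency 0.50) receives
daily gefitinib with the PFS hazard multiplied by HR 0.17 (Weibull
proportional hazards: scale × HR, shape unchanged), the negative stratum
follows the control PFS curve with HR 1.0 — it receives routine follow-up
only, and its published hazard ratio was not significantly different from
one. Strategy results are mixture-weighted over strata.

## Time-unit convention and calibration

The published Weibull parameters come without a stated time unit. On a
per-cycle (3-week) clock the PFS curve's median is 4.17 cycles ≈ 2.9 months,
matching the quoted 2.8-month trial median, so the per-cycle reading is the
default for all curves. The OS curves fit no unit cleanly: per cycle their
medians are 4.7 months (2nd-line) and 8.1 months (supportive care) against
quoted trial medians of 7.5 and 4.6 — note the printed supportive-care
parameters imply *longer* survival than 2nd-line, inverting the trials'
ordering, which suggests a transcription problem in the source. Parameters
are nevertheless stored exactly as printed. `rescale_to_median` can pin any
curve's median to a user-supplied value (shape preserved), and a
`time_unit="month"` flag rescales a per-month curve onto the cycle grid, for
users who prefer either calibration; neither changes the incremental
results materially, because the tunnel clock makes per-progressor
post-progression survival identical across strategies, so it largely
cancels from ΔCost, ΔQALY and ΔLY.

## Economics

All costs are 2012 USD. Discounting: (1.03)^(−years) on the cycle grid,
applied to costs and QALYs; life-years are reported undiscounted by default
(`discount_life_years` exposes the discounted variant, and discounted
values are always computed alongside).

| parameter | base | range | PSA family |
|---|---|---|---|
| EGFR genotyping (one-time) | 507.9 | 381–634.9 | log-normal |
| gefitinib per 250 mg/day | 77.8 | 38.9–77.8 | log-normal |
| follow-up visit | 55.6 | 41.7–69.4 | log-normal |
| 2nd-line chemo per cycle | 2352.7 | 1921.1–4383.3 | log-normal |
| supportive care per cycle | 337.5 | 158.7–793.7 | log-normal |
| SAE (platinum) per cycle | 507.4 | 189.7–825.0 | log-normal |
| end-of-life (one-time) | 3664.3 | 21.4–48750.2 | log-normal |
| utility PFS / progressed | 0.65 / 0.47 | 0.26–0.87 / 0.19–0.58 | beta |
| EGFR mutation frequency | 0.50 | 0.08–0.70 | beta |
| 2nd-line uptake | 0.566 | 0.26–0.72 | beta |
| SAE risk gefitinib / control / platinum | 0.07 / 0.03 / 0.80 | ±25% / ±25% / 0.6–1.0 | beta |
| PFS hazard ratio (EGFR+) | 0.17 | 0.07–0.42 (95% CI) | log-normal (CI) |

Conventions worth noting:

* **Gefitinib** costs 21 × 77.8 = $1,633.80 per fully adherent PFS cycle.
  (The source text quotes "nearly $1,663.10" for the first whole-cohort
  cycle; 21 days × the printed unit price gives $1,633.80, a 1.8%
  difference left unexplained there. The implementation uses 21 × unit
  price.) Under **GPAP** the price applies only to the first six months of
  treatment: 182.625/21 = 8.696 cycles, i.e. cycles 1–8 in full, cycle 9
  prorated at 0.696, donated thereafter. Since maintenance starts at model
  start, the treatment clock and the model clock coincide.
* **Follow-up** is amortised per occupied cycle (one visit per 4 months
  through year 2, one per year after) rather than charged as discrete
  visits — visit timing inside a 3-week grid is unspecified, and
  amortisation is grid-independent. It is charged to all alive states by
  default (`followup_all_states=False` restricts it to PFS).
* **SAE management** is charged per PFS cycle as
  `cost_SAE_platinum × p_arm / p_platinum` (0.07 for the gefitinib-treated
  stratum, 0.03 otherwise), the events being assumed equally likely in
  every cycle.
* **2nd-line chemotherapy** is charged for the first 4 cycles on the
  subcohort clock (the median number of cycles); PD_2L occupants beyond
  that incur supportive-care cost while keeping their 2nd-line survival
  curve. The per-cycle price is the published weighted mean of the drug mix
  (50/20/15/15 docetaxel/gefitinib/erlotinib/pemetrexed); the mix itself is
  retained in `SECONDLINE_DRUG_MIX` for sensitivity use.
* **End-of-life** cost is charged once per death at the death cycle,
  whatever the pathway; patients alive at the horizon are censored without
  it.

## Sensitivity analyses

*Tornado*: each of the 15 registry parameters in turn at its published low
and high (everything else at base), recording both ICERs; entries sorted by
spread. *Two-way*: ICER over an EGFR-frequency × genotyping-cost grid.
*PSA*: all 15 parameters drawn independently — costs log-normal and
utilities/probabilities/proportions beta, both moment-matched to mean =
base and SD = 25% of the mean (a beta request whose SD exceeds the
feasibility bound falls back to 95% of it); the hazard ratio log-normal
with median 0.17 and σ = (ln 0.42 − ln 0.07)/(2·1.96) from CI inversion.
Weibull scale/shape are held fixed: the source assigns distributions only
to costs, utilities and probabilities/proportions, and PFS uncertainty is
carried by the hazard ratio. The default CEAC grid is $0–$100,000/QALY in
$1,000 steps. A single seeded `numpy` generator drives all draws, so
results are bitwise reproducible from the seed.

## Synthetic data

`simulate_cohort` draws Weibull event times by inverse transform,
T = (−ln U/λ)^(1/γ), with administrative censoring at a fixed cutoff —
emulating trial-duration truncation, not dropout (no random censoring).
`km_estimate` wraps the product-limit estimator and returns the
right-continuous step values at event times, the same dialect
`fit_weibull` consumes. Passing recovery tests on these cohorts shows the
fitting stage is correct under clean Weibull data with administrative
censoring; real digitised curves add digitisation error, non-administrative
censoring and non-Weibull tails that the generator deliberately omits.

## Numerical choices

* Fitting uses OLS on ln(−ln S) = ln λ + γ ln t; points with t = 0 or
  S ∉ (0,1) are uninformative on that scale and are dropped; tied times
  keep the last (lowest) survival value. At trial-sized samples the scale
  and shape errors of this fit anticorrelate strongly, so recovery
  tolerances are stated on multi-seed means.
* Horizon length in cycles is `round(years × 365.25/21)` (17, 35, 87, 174
  for the 1/2/5/10-year scenarios). Any positive horizon is accepted.
* The ICER is reported as None (undefined) when ΔQALY = 0, with dominance
  flags when sign patterns make a ratio misleading.
* Brute-force oracle tests enumerate progression-cycle × death-cycle paths
  at 12-cycle horizons; the engine matches to 1e−9 per cell, and PFS
  occupancy matches exp(−λt^γ) to machine precision at all horizons.

## Known limitations

* The model reproduces incremental quantities (ΔCost, ΔQALY, ΔLY, ICERs,
  PSA probabilities) well; absolute per-strategy life-years and costs
  depend on post-progression survival levels that the printed OS
  parameters pin down only ambiguously (see the time-unit section), and
  short-horizon (1-year) scenario results inherit part of that ambiguity.
* PSA draws are independent across parameters (no correlation structure)
  and the utilities of different states are sampled independently, so
  draws with progressed utility above PFS utility can occur.
* No comparator arms beyond routine follow-up (no erlotinib/pemetrexed),
  no genotyping sensitivity/specificity, no indirect costs, no
  budget-impact stage, and no EVPI.
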