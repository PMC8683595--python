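# Methods

## Model overview

`densescreen` is an individual-level (micro)simulation of breast-cancer
screening in women with mammographically dense breasts, followed from
cohort entry at age 50 to death (age 100 at most). A woman's life course
is composed of independent building blocks — tumour incidence, growth,
self-detection, breast density, other-cause mortality — on top of which a
screening scenario acts. Outcomes are tallied per 10,000 women and fed
into a standard incremental cost-effectiveness analysis.

All randomness is drawn once per cohort (`synthetic_data.draw_variates`)
as uniform/standard-normal variates; the simulation engine is a
deterministic function of those variates and a parameter set. This gives
common random numbers across scenarios *and* across parameter
perturbations for free, which is what makes paired life-years-gained
(LYG) estimates and tornado bars tight. Published point estimates are per
10,000 women over ten repeats of 100,000 women; the shipped tests and
examples run smaller cohorts (1,000–100,000 women, 1–3 repeats), chosen
so the whole suite completes in seconds while Monte-Carlo error stays
well inside the asserted tolerances.

## Natural history

* **Incidence.** At most one spontaneous tumour per woman. Presence
  probability is f = L·(1−Φ(z₂₀))/(Φ(z₇₅)−Φ(z₂₀)), where L is the
  lifetime risk to age 75 of the baseline density category (0.155 for
  BI-RADS c, 0.202 for d) and onset age is Normal(67.9, 21.1²) truncated
  below at 20 years. The normalisation makes P(onset ≤ 75) equal L
  *exactly* under the truncated onset distribution (a plain L/Φ(z₇₅)
  would undershoot by the truncated mass). Women whose tumour would have
  surfaced clinically before 50 are re-drawn: the simulated population is
  women alive and undiagnosed at entry, which is who a program invites.
* **Growth.** Tumour volume doubles per TVDT; spherical equivalence gives
  one diameter doubling per 3 TVDT. TVDT is log-normal (moment-matched to
  the natural-scale mean/sd per age group: 80(28), 157(25), 188(52) days
  for <50, 50–70, >70). By default the onset age fixes the TVDT group for
  the tumour's lifetime (`tvdt_rule="onset"`); the `"piecewise"` rule
  instead switches the doubling rate at the group boundaries, mapping the
  same standard-normal draw through each group's distribution so growth
  is continuous and the tumour keeps its growth rank. The onset rule is
  the default because the piecewise rule makes a tumour's entire history
  depend on ages it reaches only with low probability, and the two differ
  materially only for tumours spanning a boundary.
* **Self-detection.** Log-normal clinical-surfacing diameter, log-mean
  2.9 ln(mm), log-sd 0.6 (median ≈ 18.2 mm). The surfacing *age* is the
  closed-form inversion of the growth law; thresholds at or above the
  128 mm cap never surface.
* **Other-cause mortality.** Annual life table q(a), sequential Bernoulli
  (vectorised as an inverse-CDF lookup); death is placed mid-way through
  the death year. A two-column CSV (age, q) can be supplied; the default
  is a Gompertz–Makeham fixture (μ(a) = 1.2e-4 + 3e-6·e^{0.120a}) chosen
  once to give a female-like curve (life expectancy 83.6 at birth, 84.3
  at 50). This is a synthetic stand-in, not a national table.

## Density

Only the cross-sectional BI-RADS distribution per age group is available
(e.g. 0/0/0.67/0.33 for a/b/c/d at 50–60, falling to 0.29/0.35/0.31/0.05
above 70). Individual trajectories are built by **quantile coupling**:
each woman keeps a lifetime density rank u ∈ (0,1) and her category at
age a is read off the age group's cumulative distribution ordered densest
first. Cross-sections then match the marginals exactly, and because the
densest-first cumulative thresholds shrink with age, no woman's density
ever increases — the deterministic, testable version of "density declines
with age". An `"independent"` per-age-group redraw mode exists for
comparison. Age groups are half-open: [50,60), [60,70), [70,∞).

Screening-strategy *assignment* (who gets AP-MRI) uses the category at
entry (age 50); the mammography *sensitivity* uses the current,
age-evolving category's mean area percent density m (0.06/0.16/0.40/0.83
for a/b/c/d). A `dynamic` assignment flag re-evaluates the stratum at
each round.

## Screening engine

Per scheduled round (per baseline stratum; concurrent blocks of different
modalities may overlap, which expresses the combined mammography+AP-MRI
strategies): a live, undiagnosed woman attends with probability 0.80
(independent per round; a per-woman always/never mode exists). An
undetected tumour ≥ 2 mm is found with the modality's sensitivity — 0.95
for AP-MRI regardless of density; for mammography
s = (1−ε)·logistic(β₀+β₁d+β₂m+β₃·m/d²), ε = 0.10, capping s at 0.90 (the
fraction of tumours undetectable on mammography regardless of size).
Rounds without a true detection yield a false positive with probability
1−specificity (0.89 mammography, 0.87 AP-MRI), at most one per round and
never alongside a true positive. Tumours crossing their self-detection
diameter before the next opportunity surface as **interval cancers**; the
label applies to every self-detected cancer including after the last
round, so screen-detected + interval = all detected cancers. Detection
ends screening for that woman.

Each attended mammogram adds 3 mGy and induces a tumour with probability
dose(Gy) × 0.51/Gy; an induced tumour starts growing after a latency
(calibrated, see below) and then follows the standard growth/detection
model, counted only if it surfaces before death. The engine tracks at
most one induced tumour per woman alongside the spontaneous one; when
both are present the larger drives detection.

## Survival and the lead-time question

At detection the tumour's size class (<20, 20–50, >50 mm) sets a
breast-cancer death probability and, if death occurs, an exponential
survival time. The survival clock starts at the tumour's
**clinical-surfacing age** — when it would have self-detected — not at
the detection age. Clocking from detection would credit lead time as
survival: a screen-detected woman would die *earlier* than her
self-detected counterfactual whenever the survival draw is short, and the
paired LYG estimate becomes noisy and biased. With the surfacing-age
anchor, screening benefit flows only through the size class at detection
(higher cure probability, longer mean survival) — the stage-shift
mechanism. Realised death is the earlier of breast-cancer and other-cause
death; a tie within the same year is recorded as a breast-cancer death.

## Economics

Point costs (2019 €) are discounted at the event age, life-years
continuously with mid-year discounting, both to age 50 at 3%/3% (Dutch
guideline 4%/1.5% available). Each attended screen costs its modality
price (AP-MRI 272 + 55 implementation surcharge), each false positive a
191 € biopsy, each detected cancer one size-class treatment cost
(6875/7612/8224 €). Biopsy costs attach to false positives only; workup
of true positives is assumed inside the treatment cost.

ACERs compare each strategy to the biennial-mammography reference;
ICERs are assigned along the efficient frontier over *all* strategies in
a run: strictly dominated points are removed, then extended-dominated
points (above the lower convex hull) iteratively, and each surviving
strategy's ICER is taken against its frontier predecessor. The
implementation is validated against a brute-force convex-hull oracle on
random instances. Effect ties keep the cheaper strategy.

## Sensitivity analyses

The univariate tornado varies one parameter at a time across its
published 95% CI (±50% for the AP-MRI unit cost), re-running the paired
simulation with common random numbers, and reports the pairwise ICER of
the strategy of interest versus the reference. The PSA draws every CI'd
parameter from a truncated Normal (sd = CI-width/3.92, truncation by
resampling to the valid support) — the "distribution" column of the
source table describes *population heterogeneity* (TVDT, self-detection
diameter), not parameter uncertainty, so only parameters with CIs are
varied. By default each PSA iteration also redraws the cohort
(`redraw_cohort=False` isolates parameter uncertainty). The CEAC reports
the fraction of iterations with positive net monetary benefit λ·ΔE − ΔC
over a willingness-to-pay grid including 20,000 €/LYG.

## Calibrated placeholder inputs

Three inputs of the published analysis are not available in print and are
shipped as **calibrated placeholders**, clearly exposed in the
configuration:

* the mammography logistic coefficients (β₀, β₁, β₂, β₃) =
  (−1.1, 0.38, −1.8, −8.0);
* survival by size class: death probabilities (0.63, 0.97, 1.0) with mean
  survival (11, 2, 1) years;
* the radiation-induction latency, 25 years (with the per-Gy reading of
  the 0.51 induction coefficient; a percent-per-Gy flag exists but
  produces ~2 rather than ~18 expressed induced tumours per 10,000).

They were tuned by hand against the reference arm's published per-10,000
outcomes (breast-cancer deaths ≈ 736, screen-detected ≈ 573, interval
≈ 671, induced ≈ 18). Under the defaults the model reproduces the
reference arm within a few percent and the biennial AP-MRI strategies
gain 170–490 discounted LYG (published: 132–562) with the published
ordering. The remaining gaps — interval cancers run ~10% high, the
LYG spread across strategies is compressed, and incremental costs (hence
ACERs) come out ~1.5× the published ones even though every unit cost
follows the published table — cannot be closed without the unpublished
inputs; the arithmetic of extra AP-MRI screens × (327−68) € per screen is
faithfully reflected in the package's ACERs.

## What the synthetic data does and does not show

The generator reproduces the *stated study conditions*: density-stratified
lifetime risks, onset distribution, TVDT and self-detection
distributions, age-dependent density marginals, 80% participation, and a
female-like life table. It does not emulate registry microdata: no DCIS,
no multiple synchronous primaries, no tumour regression, no recall
pathways or reader variability, no secular trends in mortality or costs.
Passing tests therefore demonstrate internal correctness of the model and
the published-value arithmetic, not external validity for a particular
country's program.

## Numerical choices

* Death-year sampling, onset truncation and category assignment use
  inverse-CDF transforms of pre-drawn uniforms (fully vectorised,
  reproducible from one integer seed; per-repeat seeds are spawned from
  the master seed and kept below 2³¹).
* Diameters are capped at 128 mm; self-detection thresholds at or above
  the cap never trigger.
* Boundary conventions: size classes <20 / [20,50] / >50 mm; TVDT groups
  <50 / [50,70] / >70; density age groups half-open from 50.
* Same-year ties between breast-cancer and other-cause death count as
  breast-cancer deaths (conservative toward measuring screening benefit).
* Exponential survival times use −mean·log1p(−u) with shared uniforms so
  outcomes stay paired across scenarios.

## Known limitations

* Survival-by-size and mammography-sensitivity coefficients are
  calibrated placeholders (above); absolute ACER/ICER levels from the
  simulation should be read accordingly. The frontier machinery itself is
  exact and independently validated.
* One spontaneous plus at most one induced tumour per woman.
* The per-woman attendance mixture and dynamic stratum assignment are
  implemented but not part of the default analysis.
* Costs are fixed 2019 € with no indexation; no QALY weighting (effects
  are life-years only).
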