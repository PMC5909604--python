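# Methods

## Model and assumptions

The package implements a deterministic, cell-based comparative-risk-assessment
model. Its atomic unit is a stratum — one (sex, age band, socioeconomic
quintile) cell out of 60 — and every quantity is computed per stratum and then
summed; nothing is ever derived from pre-aggregated rates. The model's core
assumptions are:

- base-year mortality rates, applied to final-year population counts, define
  the counterfactual "no change" death toll; the gap to observed deaths
  (deaths prevented or postponed, DPPs) is the quantity to be explained;
- treatment benefits are products of eligible patients, uptake change,
  compliance, trial relative risk reduction (RRR), and the one-year case
  fatality the RRR acts on; disease groups are mutually exclusive upstream
  (each patient counted once, in the highest-risk group), so no overlap logic
  exists downstream;
- within a disease group, multiple medications combine multiplicatively
  (Mant–Hicks): joint benefit `1 − Π(1 − RRR_i·u_i·c_i)`, preventing
  double-counting under polypharmacy;
- continuous risk factors act log-linearly on mortality (`β = ln(1 − r)` per
  unit), binary factors through the population attributable risk fraction;
  benefits of different factors within a stratum combine cumulatively
  (`1 − Π(1 − f_i)`), not additively;
- risk-factor DPPs for blood pressure and cholesterol are reported net of the
  corresponding primary-prevention treatment DPPs, since the observed level
  change already embeds the treatment effect.

DPPs are real-valued throughout; rounding to integers (half away from zero)
happens only in display output. Negative DPPs (deaths brought forward, e.g.
by rising BMI or diabetes) are reported with sign, never clamped.

## Apportionment of joint benefits

Both the Mant–Hicks group DPP and the cumulative joint risk-factor DPP must
be attributed back to individual components. The adjusted total is split
proportionally to the components' unadjusted (gross) DPPs — algebraically
`adj_i = gross_i · total/Σ gross_j` — which preserves each component's sign
and makes the parts sum to the adjusted total exactly. When the signed sum is
zero (offsetting components) the split falls back to absolute-value weights.

## Age standardisation

Two variants are provided: direct (weight-averaged stratum rates) and
indirect (standardised mortality ratio × reference crude rate). The reference
defaults to the pooled base-year population of the input data itself; an
external reference weight table can be supplied. Weights are renormalised
over occupied age bands, so both variants collapse to the crude rate for a
population concentrated in a single band. Published standardised rates are
not reproducible without the original (unpublished) reference population, so
they serve as descriptive output only; the DPP accounting never depends on
standardisation.

## Monte Carlo uncertainty

Fixed inputs are replaced by distributions respecting each parameter's
domain: beta for proportions (uptakes, compliance, case fatality,
prevalences), parameterised by method of moments from the central value and a
relative standard error (default 10%); mean-preserving lognormal noise for
relative risks and for 1−RRR (so sampled RRRs stay below 1); normal for
continuous risk-factor means (default relative SE 1%, since survey means are
estimated precisely). Patient counts and populations are fixed by default —
they are near-census registry quantities. Case fatality is drawn once per
disease group and stratum and broadcast to the group's treatments, because it
is a property of the disease, not the treatment.

Each parameter owns a private random substream keyed by (seed, run index,
CRC32 of the parameter path): adding a parameter never perturbs another's
draws, and identical seeds give bit-identical intervals. Intervals are the
2.5th/97.5th empirical centiles of the stored draws. The full-scale analysis
convention is 10,000 runs; the bundled driver defaults to a desk-scale 1,000
runs (the interval endpoints' order-statistic error at 1,000 runs is already
small relative to the interval widths), and tests use smaller runs still.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of a registry-based study: 60 fully
populated strata with equal quintile populations; a steep age gradient in CHD
mortality; a configurable deprivation gradient (default 2× rate ratio,
quintile 5 vs 1); an overall mortality decline around 75% tilted slightly
toward the affluent (78% vs 71%); nine disease groups with age-increasing
patient prevalence and case fatality; six risk factors with age-specific
effect sizes and deprivation tilts (default changes: cholesterol −1.2 mmol/l,
SBP −4 mmHg, BMI +0.8 kg/m², smoking −12 pp, inactivity −5 pp, diabetes
×1.9). Eligible-patient prevalence and case fatality fall steeply toward
young ages (CHD is rare and mild below 45), which keeps every stratum's
modelled fractional reduction below 1 and the default aggregate shares
loosely realistic (~28% treatment, ~43% risk factors, ~71% explained).

All treatment uptakes, RRRs, case fatalities and risk-factor magnitudes are
illustrative: only one worked value per method is published for the original
study, so the catalogue is invented at plausible magnitudes and must not be
read as Danish estimates. The generator does not emulate person-level
microdata, ICD coding, registry linkage, survey non-response, or correlation
between risk factors and treatment uptake within individuals. Passing tests
therefore demonstrate the correctness and internal consistency of the
accounting, not the validity of any substantive epidemiological estimate.

With `noise = 0` (the default) generation is purely structural; a positive
noise level jitters proportions on the logit scale and positive quantities on
the log scale, so generated values never leave their domains.

## Known-truth construction

`generate_known_truth` rewrites the observed final-year deaths of a generated
scenario so that the model's explained share of total DPPs is known exactly.
The modelled DPPs per stratum are computed with the same accounting the
pipeline uses; the unexplained remainder, `Σmodelled · u/(1−u)` for residual
`u`, is distributed across strata proportionally to headroom (expected −
modelled deaths). A per-stratum multiplicative residual was rejected because
real data contain strata where a single factor explains a large share of the
stratum's expected deaths (the published cholesterol example explains 75 of
176), making a uniform per-stratum residual infeasible; the aggregate
construction is exact (`explained = 1 − u`) and feasible whenever every
stratum's modelled fraction is below 1. Observed deaths in these scenarios
are real-valued (expectation-scale), keeping the closure exact.

## Numerical choices and degenerate inputs

- Validation is consolidated: a run reports every schema/domain violation at
  once, naming the offending stratum or field, before any computation.
- Zero base population with nonzero base deaths is an error; zero deaths with
  zero population contributes zero expected deaths.
- Zero total DPPs make contribution shares undefined; they are reported as
  missing, never as zero.
- A risk factor whose gross DPP reaches a stratum's expected deaths
  (fraction ≥ 1) is rejected as invalid input.
- Survey-year extrapolation uses an ordinary least-squares line through the
  measurement points; prevalences are clipped to [0, 1] afterwards with a
  warning on every clip.
- Beta sampling caps the variance at 95% of the Bernoulli bound `m(1−m)` so
  method-of-moments parameters stay valid near the domain edges; central
  values of exactly 0 or 1 pass through unperturbed.

## Known limitations

- The treatment/risk-factor input catalogue carries no real epidemiology; all
  substantive conclusions require real inputs in the documented CSV schemas.
- One published summary row (the female total DPPs) is internally
  inconsistent in the source tables (printed 4,135 vs computed
  5,575 − 1,462 = 4,113); the package reproduces the arithmetic and does not
  imitate the printed value.
- Printed uncertainty intervals are not bit-reproducible because the original
  distribution families were not published; the defaults here are the
  package's own, domain-respecting choices.
- Interaction and effect modification between risk factors, mediation (e.g.
  diet acting through cholesterol), and treatment overlap between disease
  groups are out of scope by design.
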