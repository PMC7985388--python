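# Methods

## The score and its assumptions

The cumulative transition-metal oxidative potential of an air sample is a
weighted sum over the five DTT-active metals,

    OP_tm* = Σᵢ rᵢ χᵢ Tᵢ fᵢ ,    i ∈ {Cu, Mn, Fe, V, Ni},

in nmol-DTT min⁻¹ m⁻³. The score deliberately omits organic DTT-active
compounds and metal–organic interaction terms: it is an idealized,
primary-aerosol-only OP, and its absolute level is dominated by the choice
of laboratory rᵢ values. The two built-in parameter sets (CA, F) differ
only in rᵢ; for equal molar concentrations of the five metals their summed
weights Σ rᵢχᵢ are 1.752483 and 17.4104, a factor ≈ 9.93, so analyses
should lean on relative (temporal, spatial, source-share) structure, which
the two sets largely agree on.

Assumptions inherited by every downstream operation:

* **Linearity.** The score is linear in the tagged concentrations, so any
  tag subset's contribution is the sum of its cells; additivity holds to
  floating-point round-off and is asserted at 1e-10 relative tolerance.
* **Constant solubility.** χᵢ is a fixed per-metal constant; no dependence
  on aerosol acidity or source is modelled.
* **Mixed Fe valence.** The single Fe weight already represents an equal
  Fe(II)/Fe(III) mix; no runtime valence split.
* **Units.** Inputs are mass concentrations (ng m⁻³) converted to molar
  (nmol m⁻³) with IUPAC standard atomic masses (Cu 63.546, Mn 54.938,
  Fe 55.845, V 50.942, Ni 58.693 g mol⁻¹); the conversion is exact
  division, and the laboratory r units (per μM) force this molar basis.

## Bias calibration

The per-metal correction is fᵢ = median(obsᵢ)/median(simᵢ) on pooled
paired daily concentrations — a ratio of medians, not a median of ratios;
the median of an even-length sample is the mean of the two central values.
fᵢ multiplies *simulated* concentrations only (`apply_f=True`); scoring
observations always uses f = 1, and the flag is explicit at every call so
the two conventions cannot be confused. Calibration is conventionally done
on the fine (SUB / PM2.5-class) concentrations and the same fᵢ is reused
for every size class; `derive_bias_factors` accepts whatever paired series
the caller supplies, so either convention is a one-line selection. Pooling
across stations is the default (per-site calibration is a trivial loop for
the caller); a zero simulated median is an error rather than an infinite
factor.

## Evaluation statistics

N, observation median, Sim:Obs median ratio, Pearson correlation on
untransformed values, Fa2/Fa5, RMSE, and NRMSE = RMSE / mean(obs). Fa2/Fa5
boundaries are inclusive (a ratio of exactly 2 is "within a factor of
two") and pairs with a zero observation are excluded from the Fa2/Fa5
denominators. Daily pairing averages duplicate same-day records first,
aligns on local calendar day (timestamps with explicit offsets are read as
local wall-clock time; the daily boundary is local midnight), and drops
days missing on either side. Undefined statistics (zero observation
median/mean, constant series, empty Fa denominators) are NaN, serialized
as JSON null.

A motivating property of the summed score is error cancellation: when the
per-metal simulation errors are independent, the NRMSE of the weighted sum
is below the worst per-metal NRMSE. This is not a theorem for arbitrary
error structure, so the test suite asserts it statistically (≥95 % of 200
synthetic station-years), not universally.

## Apportionment conventions

* **Domestic fraction** = domestic anthropogenic / total anthropogenic;
  mineral dust is excluded from both sides (an `include_dust` variant puts
  dust in the denominator). Attribution is by tag accounting on fields
  that carry origin tags, not by zero-out re-simulation.
* **Size classes.** SUB → PM2.5, COR → PMc, MD → dust; PM10 = the exact
  sum and stands in for TSP, since the model carries no super-10-μm mass.
  Fine dust mass that in reality belongs to PM2.5 is not reassigned.
* **Windowed fractions** are ratios of window-summed numerator and
  denominator over fixed, non-overlapping blocks anchored at the first
  timestamp (ratio of means). This estimator is also what the
  Monte-Carlo recovery tests use at the annual scale, because a mean of
  daily ratios carries a small Jensen bias under multiplicative noise
  while the ratio of sums does not (to first order).
* **Seasons** are MAM/JJA/SON, with winter = Jan + Feb + Dec of the same
  calendar year (single-year convention); the annual mean is over all
  timestamps. Regional statistics are unweighted means or maxima over the
  member locations; analysis regions are disjoint, with an optional
  overlapping total region.
* **Sector accounting** scores annual sector × metal emissions with the
  same molar weights as ambient concentrations: W_s = Σᵢ rᵢχᵢ E_{s,i}/Mᵢ,
  shares W_s/ΣW. The bias factor is off by default there (f corrects a
  transport simulation, not an inventory) and switchable. Sector–region
  pairs absent from an inventory (e.g. railway outside Kanto) are treated
  as zero, not missing.

## Synthetic study design

The generator emulates one or more station-years of chemistry-transport
output at the fidelity the pipeline consumes, not the meteorology behind
it. Defaults describe the study conditions; all are dataclass fields.

* **Anthropogenic metals**: lognormal day-to-day variability
  (`conc_sigma = 0.5` in log space) around per-metal medians chosen at
  ambient Japanese levels (Cu 15, Mn 15, Fe 400, V 4, Ni 3 ng m⁻³),
  modulated by a single-harmonic seasonal factor exp(a·cos) peaking in
  mid-January (`seasonal_amplitude = 0.4`, dimensionless log-amplitude).
* **Tag structure**: the anthropogenic total splits deterministically by
  fine fraction 0.7, domestic share 0.5 and nine sector shares (brake
  wear 0.30 and iron–steel 0.25 leading); an optional per-cell lognormal
  jitter (`tag_sigma = 0.2`) makes recovered fractions fluctuate around
  the configured values instead of matching exactly.
* **Mineral dust**: small lognormal baseline (Fe-dominated), multiplied on
  Bernoulli days within March–May (`dust_pulse_prob = 0.15`) by a
  lognormal pulse of median ×10 — episodic spring dust.
* **Observations**: obsᵢ(t) = tag-summed truth / bᵢ · exp(σz),
  σ = 0.4, with whole days lost at probability 0.03 jointly across metals
  (instrument outage). The default biases bᵢ are the inverses of the
  built-in fᵢ (Cu 3.30, Mn 1.20, Fe 1.10, V 2.60, Ni 3.70), so the
  calibration stage is expected to recover the built-in factors.
* **Reproducibility**: one root seed; each (site, stream) gets an
  independent child seed, so adding a site never perturbs existing draws.

What the generator does **not** emulate: spatial correlation, transport
dynamics, speciation or acidity-dependent solubility, autocorrelated or
heteroscedastic measurement error. Passing recovery tests therefore show
the estimators are correct and consistent under the assumed noise model,
not that a real chemistry-transport simulation is unbiased.

## Numerical choices

* Missing data are conservative: a missing constituent makes any total
  over it missing, which keeps additivity exact; fractions with a zero or
  missing denominator are missing.
* Metal shares are undefined (NaN) where the total score is zero.
* CSV numbers are written at 10 significant digits; JSON reports round
  floats the same way, so repeated runs are byte-identical.
* Dense NetCDF output stores an int8 presence mask beside the values so
  structurally absent tag combinations round-trip distinct from genuinely
  missing ones.

## Problem sizes in the test and acceptance runs

The Monte-Carlo experiments use one synthetic site: 100 replications of a
365-day year for the mean recovered f_Cu (reported against 1/3.30 ≈
0.303), a 60-replication consistency sweep over series lengths
{30, 365, 3650} days (run with a single-sector tag axis, since bias
recovery is independent of the sector split), 100 replications of 90- and
60-day years for fraction and sector-share recovery, and 200 replications
of 120-day years for the error-cancellation property. These sizes give
Monte-Carlo standard errors a factor ≳10 below the asserted tolerances.

## Known limitations

* Absolute score levels inherit the inter-laboratory spread of rᵢ; only
  relative structure is robust.
* Constant χᵢ ignores acidity-driven solubility changes during transport.
* The domestic/transboundary split requires origin-tagged input; the
  package does not infer origin.
* Evaluation reports carry no uncertainty intervals; the statistics are
  point estimates.
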