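# Methods

## Isotope bookkeeping

Delta values are carried in permil against the conventional standards (VPDB
for ¹³C/¹²C, VSMOW for ²H/¹H). Absolute standard ratios (0.0111802 and
0.00015576) are included only for absolute-ratio export; every fitted
quantity uses the standard-free ratio factor
R_t/R_0 = (δ_t + 1000)/(δ_0 + 1000), so the choice of standard constant can
never perturb a result. Deltas at or below −1000‰ are rejected (they imply a
non-positive isotope ratio).

Fractions remaining f = C_t/C_0 above 1 — evaporative or handling artifacts —
are reported as-is with a flag, never silently clipped or dropped; dropping
is the caller's decision. When a measurement carries no delta uncertainty,
the element's typical replicate reproducibility (0.3‰ for C, 2.5‰ for H,
interpreted as 1σ Gaussian) is assumed.

## Rayleigh regression

The linearized Rayleigh form ln(R_t/R_0) = (ε/1000)·ln f is exact for a
closed system, not an approximation, so on noiseless data the fit recovers ε
to machine precision regardless of the f grid — a property the test suite
asserts over random draws. The default regression has a free intercept, with
the intercept reported as a diagnostic (a non-zero intercept flags a
reference-point problem); forcing the line through the origin is an option,
since both conventions are used in CSIA practice. The 95% CI is the
two-sided t-interval on the slope standard error; no bootstrap. Duplicate
analyses at one time point would enter as separate regression points. With a
constant response (all δ_t = δ_0), R² is undefined by the centered formula;
a zero-residual fit reports R² = 1, otherwise 0.

The position correction ε_rp = (n_total/x_reactive)·ε_bulk and
AKIE = 1/(1 + z·ε_rp/1000) use z = n = x = 6 for benzene (a symmetric
molecule; the correction is then the identity). The AKIE confidence interval
is obtained by pushing ε_rp ± CI through the same transform and reporting
the larger half-width, since the transform is nonlinear and the interval
asymmetric. From ε_C = −2.4‰ this gives AKIE_C = 1.0146; from ε_H = −57‰ it
gives 1.5198 (a published value of 1.5184 for the same enrichment derives
from an unrounded ε_H ≈ −56.9‰; the difference is well inside the ±0.0283
interval).

## Dual-isotope slope

Λ is the free-intercept OLS slope of Δδ²H on Δδ¹³C over time points carrying
both deltas (no interpolation across time points — in practice both isotopes
are measured on the same flask samples). Orthogonal-distance regression is
available as an option because both axes carry measurement error; OLS is the
default because it is what the field's dual plots report, and the packaged
interval ranges were themselves derived from OLS slopes. The ratio estimate
ε_H/ε_C is computed and labelled separately; the two agree closely but are
different estimators.

Two systematic effects are worth knowing. First, the exact trajectories are
curved, so the regression slope over a wide f range sits slightly above the
ε ratio (about +2.5% over f = 1→0.19 at the default parameters). Second, the
small-fractionation limit of the slope is
(1000+δ₀H)/(1000+δ₀C) · ε_H/ε_C, i.e. it carries the baseline factor
(≈0.98 at δ₀ = −25.2/−43.5‰); the "slope ≈ ε_H/ε_C" shorthand is exact only
for equal baselines. With noisy data, OLS additionally attenuates the slope
slightly because the carbon axis carries error (≈ −1.5% at the default
design); 50-replicate means land within ±1 of the reference value, which is
the accuracy claimed.

## Redox classification and reference library

The classification rule is pure interval membership with inclusive
boundaries: Λ ∈ [22, 28] → low_redox, Λ ∈ [12, 16] → high_redox, anything
else (including the gap) → unclassified; no published rule covers the gap,
and snapping to the nearest interval would manufacture confidence. If a CI
is supplied and straddles a boundary, the result is flagged ambiguous.

The packaged database holds 15 (ε_C, ε_H) entries — pure aerobic strains,
one chlorate-reducing culture, and mixed nitrate-reducing, iron-reducing,
sulfate-reducing and methanogenic enrichments, including the
sulfate-reducing *Desulfotomaculum* enrichment at (−2.4, −57). Culture-type
labels ("mixed negative", "enriched positive") are stored verbatim from the
source compilation. Nearest-neighbour lookup uses Euclidean distance in
(ε_C, ε_H/20) space; the factor 20 balances the typical magnitude ratio of
the two axes. Ties break by table order. Users can extend the table in the
same TSV format.

## Kinetics rules

Residual percentage is 100·(C_t/IS_t)/(C_c/IS_c) with an internal standard,
else 100·C_t/C_c. Live and control flasks must share exact sampling times;
no interpolation, because silent alignment errors are worse than a hard
failure. The double normalization makes the curve exactly scale-invariant in
the live-flask signal and cancels shared physical losses (septa absorption,
sampling withdrawal) when those losses affect both flasks equally.

Lag is the first sampled time whose residual is below (100 − threshold)% and
stays below for a configurable number of consecutive samples (defaults: 5%,
2 points). There is no field-standard operational lag definition, so the
parameters are exposed. Halt (inhibition) is the earliest trailing window
(default 3 points) whose fitted slope magnitude is ≤ 0.05 %/day after
removal has begun, with the plateau residual required to exceed a floor
(default 5%) — without the floor, completed removal flat at ~0% would read
as a halt. Doubling time is log-linear between two counts,
dt·ln2/ln(n₂/n₁); it is a two-point summary, not a growth-model fit.

## Simulator

The generator emulates the statistical structure the analysis assumes:

- control flask: C(t) = c₀·e^(−k_abiotic·t), first-order non-fractionating
  septa absorption (default 5×10⁻⁴ /day in the BTEX scenario, 0 in the
  short benzene isotope scenario), applied equally to live and control so
  control normalization is exact;
- live flask: the control trajectory times a biological fraction
  f_bio(t) = e^(−k·(t−lag)₊), first-order after a deterministic lag (the
  rate law is a modelling choice; zero-order is not implemented);
- isotopes: exact Rayleigh trajectories on f_bio only,
  δ_t = (δ₀+1000)·f_bio^(ε/1000) − 1000 — abiotic loss does not fractionate;
- noise: i.i.d. Gaussian, 0.3‰ on δ¹³C, 2.5‰ on δ²H (replicate IRMS
  reproducibilities interpreted as 1σ, the standard reporting convention),
  2% relative on concentrations; a single mandatory seed makes output
  bit-identical;
- inhibition: an instantaneous rate → 0 switch at a configurable time,
  mimicking molybdate shutting down sulfate reduction.

The canonical scenarios: a six-compound BTEX microcosm at 100 ppm each with
sequential ethylbenzene → toluene → benzene onset (lags 50/90/120 days,
rates 0.046/0.035/0.038 /day sized so each compound clears within roughly
100–150 days of its onset — approximate calibrations to observed completion
times, not fitted constants), xylenes undegraded with o-xylene as the
internal standard; and a benzene-only isotope microcosm at 12 ppm sampled at
10 points spanning f = 1→0.19 with ε_C = −2.4‰, ε_H = −57‰,
δ₀ = −25.2/−43.5‰.

What the simulator does **not** emulate — and therefore what passing tests
cannot show about real data: flask-to-flask biological variability,
non-first-order kinetics, temporally correlated instrument drift,
fractionating abiotic losses, and co-contaminant inhibition chemistry. Tests
against it validate the estimators under the stated model, not the model
itself.

## Problem sizes and numerical choices

Statistical tests use deliberately modest sizes chosen to give stable
verdicts: 100 random draws for exact recovery, 200 noisy replicates for CI
coverage (expected in 90–99%), 50 replicates for the Λ mean, 1000 draws for
the noise-calibration check. Exact-recovery assertions use 1e−9‰ absolute
tolerance; oracle-equivalence 1e−10. Degenerate inputs fail loudly:
zero concentrations (log undefined), zero variance in ln f, missing t₀
deltas, non-finite Λ, unmatched control times.

## Known limitations

- Single-element, single-compound Rayleigh fits only; no multi-element joint
  fitting or Monte Carlo error propagation.
- Λ is C–H only, per the benzene application.
- The reference intervals and compilation are benzene-specific; classifying
  other compounds' Λ values against them would be wrong.
- CIs treat regression points as independent; pooled duplicate analyses are
  not modelled separately.
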