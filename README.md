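# btexcsia

Compound-specific isotope analysis (CSIA) tooling for monitoring anaerobic
biodegradation of monoaromatic hydrocarbons (BTEX) in microcosm experiments —
the kind of evidence used to demonstrate microbial natural attenuation of
benzene in anoxic aquifers, where no functional-gene probe exists and the
stable-isotope signature of the residual substrate is the main diagnostic.

It is aimed at biogeochemists and bioremediation practitioners who have
reduced GC-IRMS time series (concentrations plus δ¹³C / δ²H of the residual
compound) and want the standard derived quantities with honest uncertainties.

## What it computes

**Rayleigh enrichment factors.** In a closed system the residual substrate
follows the Rayleigh distillation law, linearized as

    ln(R_t/R_0) = (ε/1000) · ln(C_t/C_0),    R_t/R_0 = (δ_t + 1000)/(δ_0 + 1000)

The bulk enrichment factor ε (‰) is 1000 × the OLS slope of ln(R_t/R_0) on
ln f (f = C_t/C_0), with a 95% t-interval and R².

**AKIE.** The apparent kinetic isotope effect corrects ε for non-reacting
positions and intramolecular competition:

    AKIE = 1 / (1 + z · ε_reactive_position/1000)

with z = 6 for benzene (six equivalent positions, so the position correction
is the identity).

**Dual-isotope slope Λ.** The slope of Δδ²H versus Δδ¹³C (Δδ = δ_t − δ_0),
≈ ε_H/ε_C, discriminates redox regimes of anaerobic benzene degradation:
Λ = 22–28 for low-redox (fermenting / methanogenic / sulfate-reducing)
communities, Λ = 12–16 for nitrate-reducing ones.

**Reference library.** A packaged 15-entry compilation of published
(ε_C, ε_H) pairs for benzene biodegradation across redox conditions, with
interval classification, nearest-neighbour lookup and AKIE biplot export.

**Kinetics.** Control-normalized residual percentages (optionally
double-normalized to o-xylene as internal standard), lag and inhibition-halt
detection, removal extents, biomass doubling time.

**Simulator.** A seeded forward model of BTEX microcosms (first-order removal
after a lag, non-fractionating septa losses, exact Rayleigh isotope
trajectories, Gaussian IRMS noise) so the whole pipeline is testable without
laboratory data.

## Worked example

Simulate the benzene isotope microcosm (12 ppm benzene, ε_C = −2.4‰,
ε_H = −57‰, δ₀ = −25.2 / −43.5‰, realistic measurement noise) and run the
full pipeline:

```sh
btexcsia simulate --variant benzene_isotope --seed 1 --out benzene.tsv
btexcsia report benzene.tsv --out report.json
```

which prints

```
element  eps_bulk [permil]  +/-95% CI  R^2      n   AKIE
C              -2.55       0.20   0.991   10   1.0156
H             -57.85       4.78   0.990   10   1.5316
Lambda = 23.0 +/- 2.4 (R^2 = 0.98, n = 10)
redox category: low_redox
```

Read: the fitted carbon and hydrogen enrichment factors (−2.55‰ and −57.8‰)
recover the simulation's true values within their confidence intervals; the
carbon AKIE of ~1.016 indicates a primary carbon isotope effect at the
reacting bond; the dual-isotope slope of ~23 falls in the 22–28 window, so
the degradation signature classifies as low-redox — consistent with a
sulfate-reducing community. The JSON report carries every fitted quantity,
the input checksum and the parameters used.

The same pipeline runs on real data: any UTF-8 delimited table with columns
`time_days, compound, conc, conc_control, conc_internal_std,
delta13C_permil, delta2H_permil` (see `btexcsia.tables`). `btexcsia fit`,
`classify`, `kinetics` expose the individual stages; the library API
(`fit_rayleigh`, `fit_lambda`, `akie`, `classify_redox`, …) gives full
control.

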