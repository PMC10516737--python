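# Methods

## Assay processing

A clonogenic assay yields, per tube, seeded cells and counted colonies.
The control tubes of each arm define the plating efficiency
PE = mean(colonies/seeded); each irradiated replicate's survival fraction
is (colonies/seeded)/PE. Replicates at a dose are aggregated as the mean
of per-replicate SFs with the sample SD (n−1 denominator), matching how
such data are conventionally reported (mean ± SD over 2–3 tubes), rather
than by pooling counts; with 2–3 tubes the two differ negligibly but the
mean-of-replicates convention keeps the plotted points and the fitted
points identical. Each arm carries its own control.

Survival fractions above 1 (possible by counting noise at low dose) are
retained and flagged, not clipped: clipping would bias the log-scale fit.
A dose at which every replicate yields zero colonies has no defined point
on the log scale; by default this is an error, and with
`drop_unestimable` the dose level is omitted with a warning — the
practical handling when the highest dose outruns the number of seeded
cells, which on a steep mixed-beam curve can happen at 8 Gy.

## LQ fitting and the D10 endpoint

The LQ model SF = exp(−αD − βD²) is linear in (α, β) on the log scale
with a zero intercept (SF(0) = 1 by construction of the normalization),
so the fit minimizes Σ wᵢ(ln SFᵢ + αDᵢ + βDᵢ²)². Non-negativity of α and
β (negative coefficients are unphysical) makes this a non-negative
least-squares problem, which NNLS solves exactly — no starting values, no
local minima; boundary solutions (typically β = 0 for high-LET arms) are
reported as fits, not errors. Weights are 1 by default; inverse-variance
weighting on the log scale (≈ (sf/sd)²) is available but not the default,
since with n = 2–3 the replicate SDs are too noisy to be good weights.
The coefficient covariance is the linearized OLS covariance
σ̂²(XᵀWX)⁻¹ with σ̂² = RSS/(n−2).

D₁₀ solves βD² + αD = ln 10. The root is evaluated as
D₁₀ = 2 ln 10/(α + √(α² + 4β ln 10)), algebraically identical to the
quadratic formula but free of subtractive cancellation as β → 0; its
floating-point limit at β = 0 is exactly ln 10/α, so no branch is needed.
The endpoint level is configurable (`endpoint_survival`, default 0.1);
10% survival is used because at that level the gamma-equivalent dose is
comparable to a typical 1-h healthy-tissue neutron exposure (~2 Gy).

### D10 uncertainty

The ±SD on D₁₀ is a nonparametric bootstrap: replicate SFs are resampled
with replacement within each dose level, re-aggregated and refitted
(default 1000 resamples, default seed 20230822). Two refinements matter
at clonogenic replicate counts (n = 2–3):

* the control tubes are resampled too, and each resample's SFs rescaled
  by PE/PE* — plating-efficiency uncertainty is part of the experiment
  and contributes materially to the D₁₀ spread;
* resampling n of n values plugs in the biased population variance
  (n−1)/n·s², a 33% variance deficit at n = 3; resampled deviations from
  the dose mean are therefore inflated by √(n/(n−1)).

With both, the mean bootstrap SD is within ~10% of the Monte-Carlo SD of
D₁₀ over fresh simulated experiments at the default study conditions, and
normal intervals D₁₀ ± 1.96·SD achieve ≈ 90% empirical coverage at
nominal 95% (the residual shortfall is the usual small-sample noise in
the bootstrap SD itself). Resamples whose refit fails are dropped; a
failure rate above 10% is an error.

## Mixed-field decomposition and the two RBE estimators

The beam dose splits into a contamination-gamma fraction f and a
pure-neutron fraction 1 − f; f is constant across dose levels
(single-field geometry). It can be supplied directly or derived as the
gamma/(gamma+neutron) dose-rate ratio; an explicit value takes precedence
because in-sample dosimetry can differ from the free-in-air ratio (the
reference beam's applied 28.25% versus the 28.21% rate ratio).

**Dose partition** works entirely at the endpoint:
RBE_pure = (D₁₀,γ − f·B)/((1−f)·B) with B the beam D₁₀. **SF division**
works on the curve: each beam point SF(D) is divided by the fitted gamma
survival at the contamination dose f·D — the fitted reference curve, so
the quotient is exact under the independence model and the two estimators
coincide whenever both responses are log-linear — and the corrected
points, against pure-neutron dose (1−f)·D, are refitted; corrected SDs
are scaled by 1/SF_γ (quotient by a constant at fixed dose) for use by
weighted refits.

The estimators are **not** identical in general: equality requires
β = 0 on both arms (or f = 0). With a curved gamma response their
population values differ by a few percent — for the default scenario
2.2496 vs 2.3685 (5.0%) — which is the same order as the 1.55–3.85%
inter-method spread seen in real four-line data. Parameter-recovery
checks therefore compare each estimator with *its own* analytic
population value (computed from the generating curves by
`synthetic.analytic_truth`); comparing both to one number would conflate
the methods' intrinsic offset with estimator error. The exact-equivalence
property is verified in the log-linear configuration where the model
predicts it.

Cohort summaries use the unweighted mean over cell lines and report the
per-line inter-method percentage difference |r₂ − r₁|/max(r₁, r₂)·100 —
the denominator is the **larger** estimate; conventions differ, so this
is stated wherever the number appears. In paper-values mode (analysis
from pre-computed D₁₀ endpoints), displayed values and the inter-method
comparison are rounded to 2 decimals, the precision at which such
endpoints are reported; full precision is retained in JSON reports from
raw-count runs.

## Spectrum-weighted RBE

RBE_T = ∫Φ(E)RBE(E)dE / ∫Φ(E)dE is computed by the trapezoid rule on the
union of the spectrum grid and the curve nodes inside its support
(Simpson offers no advantage on non-uniform log-spaced grids and is less
robust). The RBE(E) curve is interpolated linearly in (ln E, RBE), since
such curves vary over decades of energy; queries outside the tabulated
range clamp to the end values with a warning. Energies are eV internally;
MeV inputs are converted on read. The result is scale-invariant in Φ and
bounded by the interpolated RBE range. Published beam-averaged values for
specific sources depend on spectrum tables that are not distributed here;
the module is validated by closed forms (Φ ∝ 1/E with a log-linear curve
has analytic mean a + b(ln E₁ + ln E₂)/2), identities (constant curve,
delta-like spectrum) and the qualitative ordering that a thermal-heavy
spectrum averages higher than an epithermal-peaked one under a thermally
elevated curve — the expected reactor-vs-accelerator ordering.

## Synthetic data: the study conditions

`SimulationParams` defaults emulate the characterization design: total
doses {2, 4, 6, 8} Gy on both arms, triplicate tubes, PE = 0.5, 1000
cells seeded per tube, f = 0.2825, Poisson colony counts (the standard
model for colony counts at low plating density; a binomial-thinning mode
would differ only at PE·SF near 1). The default LQ parameters are the
"sas-like" scenario, chosen from two constraints and two conventions:
gamma D₁₀ = 5.50 Gy with α/β = 10 Gy (a typical tumour value) gives
α_γ = 0.2701, β_γ = 0.02701; the pure-neutron response is log-linear
(β_n = 0, the usual shape for high-LET radiation) and placed so the
mixed-beam D₁₀ is 2.90 Gy, giving α_n = 0.9916. With 1000 cells seeded
the expected beam-arm colony count at 8 Gy is ≈ 0.8, which is the
low-count regime the generator warns about — deliberately kept, as real
steep curves hit it; recovery studies run with `drop_unestimable`.

`noise_mode="none"` emits exact (fractional) expected counts so
round-trip tests can work at 1e−10 precision; `"rounded"` gives the
integer version. Features of real assays *not* emulated: dose-dependent
seeding, plating-efficiency drift between arms, inter-experiment
(day-to-day) variability, counting/identification error beyond Poisson,
and cell-cycle or repair effects — so passing recovery tests demonstrate
statistical correctness of the estimators under the stated model, not
robustness to those systematics.

Simulated spectra (`epithermal_peak`, `thermal_heavy`, `flat`) are
log-normal bumps in ln E on a 0.01 eV–1 MeV log grid with 5% seeded
log-normal jitter; they are shape stand-ins for testing the weighting
machinery, not transport calculations.

## Problem sizes

The statistical acceptance checks run 200 simulated experiments with
400-resample bootstraps, and the fit oracle compares against a
two-stage exhaustive grid (10⁻³ step, refined 100× around the coarse
argmin — one grid alone cannot localize the diagonal α–β valley to one
step per axis). These sizes give Monte-Carlo error well inside the
asserted tolerances (e.g. coverage SE ≈ 2% at 200 experiments).

## Known limitations

* The independence assumption SF_{n+γ} = SF_n·SF_γ ignores any
  interaction between the radiation qualities; the SF-division estimator
  inherits it, and corrected SFs above 1 trigger a warning that the
  assumption is strained.
* RBE here is endpoint-specific (10% survival); the package does not
  model the dose dependence of RBE.
* The bootstrap D₁₀ interval is calibrated to ≈ 90% at nominal 95% under
  the default conditions; with n = 2 replicates it will be noisier.
* Boron dose components and compound factors are out of scope (no ¹⁰B in
  the modelled experiments), as are neutron transport, KERMA evaluation
  and the derivation of RBE(E) curves.
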