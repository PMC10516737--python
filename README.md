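# nrbe — neutron-beam RBE from clonogenic survival data

`nrbe` determines the relative biological effectiveness (RBE) of a mixed
neutron–gamma beam — such as an accelerator-based epithermal neutron source
for boron neutron capture therapy (BNCT) — from in vitro clonogenic
survival assays, for radiobiologists and medical physicists characterizing
such beams.

## The analysis

Colony counts are normalized by plating efficiency into survival fractions
and fitted, per radiation arm, with the linear-quadratic (LQ) model

```
SF(D) = exp(−αD − βD²),   α ≥ 0 [Gy⁻¹], β ≥ 0 [Gy⁻²]
```

by constrained least squares on ln SF. The effect endpoint is D₁₀, the
dose giving 10% survival:

```
D₁₀ = 2 ln 10 / (α + √(α² + 4β ln 10))
```

with a nonparametric-bootstrap SD. A mixed beam delivers a fraction *f* of
its dose as contamination gamma rays, so the pure-neutron RBE at the D₁₀
endpoint is estimated two ways:

* **dose partition** — from the gamma-equivalent dose balance
  `γ-D₁₀ = pure-neutron dose × RBE_pure + contamination γ-dose`:

  `RBE_pure = (D₁₀,γ − f·D₁₀,beam) / ((1 − f)·D₁₀,beam)`

* **SF division** — assuming independent action,
  `SF_{n+γ}(D) = SF_n((1−f)D) × SF_γ(fD)`, each beam survival point is
  divided by the fitted gamma survival at the contamination dose; the
  corrected pure-neutron curve is refitted and
  `RBE_pure = D₁₀,γ / D₁₀,pure-neutron`.

Cell lines are averaged into a cohort mean per method. Given a tabulated
fluence spectrum Φ(E) and an RBE(E) curve, the beam-averaged RBE

```
RBE_T = ∫Φ(E)·RBE_T(E) dE / ∫Φ(E) dE
```

is evaluated by trapezoidal integration. A seeded synthetic-data module
generates complete experiments (LQ curves, independence-combined mixed
beam, Poisson colony counts) so every stage is testable without external
data.

## Worked example

The built-in reference table carries the D₁₀ endpoints of a four-cell-line
characterization (SAS, SCCVII, U87-MG, NB1RG) of the CBENS epithermal
beam against Co-60 gammas, with contamination-gamma fraction f = 0.2825:

```
$ nrbe paper-values
{
  "gamma_fraction": 0.2825,
  "cell_lines": [
    {
      "cell_line": "SAS",
      "gamma_d10_gy": 5.5,
      "beam_d10_gy": 2.9,
      "contamination_gamma_dose_gy": 0.82,
      "pure_neutron_dose_gy": 2.08,
      "rbe_dose_partition": 2.25,
      "rbe_sf_division": 2.34,
      "percent_difference": 3.84615384615384
    },
    ...
  ],
  "mean_rbe_dose_partition": 2.56,
  "mean_rbe_sf_division": 2.62,
  "percent_difference_range": [1.5544041450777215, 3.84615384615384]
}
```

Reading the SAS row: of the 2.90 Gy beam D₁₀, 0.82 Gy is contamination
gamma and 2.08 Gy pure neutron dose; matching the 5.50 Gy gamma D₁₀ gives
a pure-neutron RBE of 2.25 (dose partition) versus 2.34 (SF division), a
3.85% inter-method difference. The cohort means are 2.56 and 2.62.

A full run from raw counts uses a YAML config:

```
$ nrbe synth-assay --seed 11 --out counts.csv     # or your own counts table
$ nrbe run --config run.yaml                      # → report.json, report.csv, survival.csv
```

with `run.yaml` pointing at the counts table and declaring the beam
composition (dose rates or an explicit gamma fraction). Spectrum-weighted
RBE is available as `nrbe spectrum-rbe --spectrum s.tsv --rbe-curve c.tsv`.

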