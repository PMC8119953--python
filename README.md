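# cdomkit

Optical chemometrics for dissolved organic matter (DOM) degradation
studies: CDOM absorption spectra, excitation–emission matrix (EEM)
fluorescence, non-negative PARAFAC decomposition, and photobleaching
decay kinetics — with a ground-truth-known synthetic campaign generator
so the whole chain is testable without instrument data.

## Who this is for

Aquatic biogeochemists running photochemical and microbial incubation
experiments on river, plume and coastal-ocean water: you measure decadal
absorbance spectra and EEMs at a series of incubation timepoints, and you
want reproducible, scriptable versions of the standard analysis chain
usually done with drEEM/staRdom-style tooling:

1. **Absorbance → absorption.** Napierian absorption coefficients
   `a_CDOM(λ) = 2.303·A(λ)/l` (pathlength `l` in meters), replicate-scan
   quality control, SUVA254.
2. **Spectral slopes.** Nonlinear least-squares fits of
   `a_CDOM(λ) = a_CDOM(λ₀)·exp(−S(λ−λ₀))` over the 275–295 and 350–400 nm
   windows (λ₀ = 285 or 375 nm), giving S275:295 and S350:400 in nm⁻¹.
3. **EEM correction.** Blank subtraction, absorbance-based inner-filter
   correction (`F_corr = F_obs·10^{(A_ex+A_em)/2}`, per-cm absorbance),
   Raman-unit normalization against the integrated water Raman peak of a
   same-day blank, and Rayleigh/Raman scatter masking.
4. **PARAFAC.** The trilinear model
   `X_ijk = Σ_f a_if·b_jf·c_kf` (sample scores × emission loadings ×
   excitation loadings), fitted by masked non-negative alternating least
   squares with multiple starts, validated by split-half analysis with
   Tucker-congruence component matching, plus leverage-based outlier
   screening, core consistency, and OpenFluor-style spectral matching.
5. **Component metrics.** Fmax per sample and component, percent
   contribution to total fluorescence (rows sum to 100%), percent change
   vs day 0, iterative Grubbs outlier screening of change populations.
6. **Decay kinetics.** Single- vs double-exponential photobleaching fits
   `y(t) = a·(f₁e^{−k₁t} + (1−f₁)e^{−k₂t})` with AIC-based model
   selection and a physical degeneracy guard, and the wavelength of peak
   absolute absorption loss.
7. **Campaign tables.** River/plume/ocean grouping by salinity and
   mean ± sd summaries of day-24 changes per parameter × group ×
   treatment.

The synthetic generator (`cdomkit.synthetic`) emulates the incubation
design end to end — stations along a salinity gradient, a UV
photobleaching treatment, dark size-fractionated microbial treatments,
six canonical fluorophores (visible/long-wavelength/UV/degraded humics,
terrestrial derivatives, protein-like) with realistic kinetics, exact
exponential absorbance spectra, and configurable noise — and returns the
generating truth for parameter-recovery testing.

## Worked example

```python
import numpy as np
from cdomkit import (CampaignConfig, simulate_campaign, fit_parafac,
                     split_half_validate, fmax, percent_contribution,
                     absorbance_to_absorption, fit_spectral_slope, S275_295)

config = CampaignConfig(
    n_stations=8,
    treatments=("PB",),                       # UV photobleaching
    timepoints_days={"PB": (0, 1, 3, 7, 14, 24)},
    replicates={"PB": 1},
    ex_grid=np.arange(240.0, 651.0, 10.0),
    em_grid=np.arange(300.0, 601.0, 5.0),
    seed=42,
)
campaign = simulate_campaign(config)
ds = campaign.dataset

model = fit_parafac(ds, F=6, n_starts=5, tol=1e-8, seed=0)
report = split_half_validate(ds, F=6, threshold=0.95, seed=0)

table = fmax(model, ds.manifest)
day0 = table[table["timepoint_days"] == 0].iloc[0]
contrib = percent_contribution(day0[[f"C{i}" for i in range(1, 7)]].to_numpy())

sid = ds.sample_ids[0]
a = absorbance_to_absorption(campaign.absorbance[sid])
slope = fit_spectral_slope(a, S275_295)
```

Output:

```
48 samples, tensor (48, 61, 42)
explained variance: 99.9976%
split-half validated: True (min congruence 1.000)
day-0 contributions (%): [ 6.6 24.1 21.   5.1 15.4 27.8]
S275:295 of S00_PB_T00_R1: 0.0148 nm^-1 (truth 0.0148)
```

Reading this: the six-component non-negative PARAFAC model explains
99.998% of the observed (unmasked) variation — the residual is the 0.5%
multiplicative measurement noise the generator injected.  Split-half
validation refits the model on three pairs of disjoint dataset halves
and finds every component reproduced with Tucker congruence ≥ 0.95 in
both spectral modes, so six components are supported.  The day-0 percent
contributions sum to 100% across components, and the fitted spectral
slope reproduces the generating slope of that station's exact-exponential
absorbance spectrum to the printed precision.

## Command line

A thin CLI wraps the pipeline (`simulate`, `fit`, `run`, …):

```bash
cdomkit run --config config.yaml --seed 1 --out results/run1
```

`run` executes simulate → preprocess → PARAFAC → metrics → kinetics →
summary table, writes `table1.csv`, `kinetics.csv`, `fmax.csv`,
`changes.csv`, model loadings (OpenFluor-style layout) and a
`run_manifest.json` with per-file checksums; identical config + seed
reproduces identical checksums.

## Layout

```
src/cdomkit/
  synthetic.py    # campaign generator with ground truth
  optics.py       # absorbance QC, absorption, slopes, SUVA254
  preprocess.py   # EEM correction chain and dataset assembly
  parafac.py      # masked non-negative ALS, validation, diagnostics
  metrics.py      # Fmax, contributions, percent change, Grubbs screen
  kinetics.py     # decay fits, model selection, peak-loss wavelength
  tables.py       # salinity classes and campaign summaries
  io.py           # CSV dialects and model export
  pipeline.py     # stage orchestration, config, run manifest
  cli.py          # command-line entry points
docs/methods.md   # model assumptions, parameter choices, limitations
```
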