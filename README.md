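# amorphdyn

Analyses for the molecular dynamics of **amorphous chiral drugs** —
pure enantiomers versus their racemate — combining broadband dielectric
spectroscopy (BDS) observables with structural statistics of molecular
configurations. The package is aimed at researchers studying glass-forming
pharmaceuticals who need a tested, scriptable version of the standard
analysis chain:

**Dielectric branch**

1. Deconvolute loss spectra ε″(f) into a dc-conductivity wing plus
   Havriliak–Negami (HN) processes,
   ε″(ω) = σ_dc/(ε₀ω) + Σ Im[−Δε/(1+(iωτ)^α)^β],
   and convert HN times to loss-peak times τ_α via the Kremer–Schönhals
   closed form.
2. Fit τ_α(T) with the VFT law τ = τ∞·exp[B/(T−T₀)] and the full
   τ_α(T, p) surface with the modified Avramov equation
   τ(T,p) = τ∞·exp{ln(τ_g/τ∞)·[(T_r/T)(1+p/Π)^{β/α₀}]^{α₀}},
   τ_g fixed at 100 s (the dielectric T_g definition).
3. Derive T_g(p) = T_r(1+p/Π)^{β/α₀}, its pressure coefficient dT_g/dp,
   the steepness (fragility) index m, and the activation volume
   ΔV_α = ln(10)·R·T·(∂log₁₀τ_α/∂p)_T, which at T_g obey the isochrone
   identity ΔV_α = ln(10)·R·m·(dT_g/dp).

**Structural branch**

4. Detect hydrogen bonds in periodic configurations (minimum-image
   O···O ≤ 3.5 Å, O–H···O ≥ 150°), partition molecules into clusters,
   compute size histograms, the low-molecular (2–4) cluster fraction and
   cyclic/linear dimer–trimer topology shares.
5. Build RDF × ADF 2D maps of the F···C_ring distance versus the angle
   between F→C_ring vectors, and census parallel (~4 Å, 180°) and
   antiparallel (~6 Å, 0°) F–Π stacking pairs by chirality pair.

A first-class synthetic-data module generates spectra, relaxation maps and
periodic configurations with planted, manifest-recorded ground truth, so
every stage is testable by exact or tolerance-bounded recovery.

## Worked example

Run the built-in two-sample demo study (an enantiomer-like and a
racemate-like system, both fully synthetic):

```bash
amorphdyn run --demo --seed 1 --out results/demo
cat results/demo/report.md
```

which prints:

```
# Study report

## Sample RS
- Tg (tau_alpha = 100 s, 0.1 MPa): 261.93 K
- dTg/dp at ambient pressure: 247.7 K/GPa
- steepness (fragility) m: 71.1
- activation volume at Tg: 337.2 cm^3/mol
- H-bond clusters: 59 (low-molecular 2-4 fraction: 0.441)
- stacking census: 5 parallel, 4 antiparallel

## Sample S
- Tg (tau_alpha = 100 s, 0.1 MPa): 263.42 K
- dTg/dp at ambient pressure: 247.0 K/GPa
- steepness (fragility) m: 81.5
- activation volume at Tg: 385.3 cm^3/mol
- H-bond clusters: 44 (low-molecular 2-4 fraction: 0.568)
- stacking census: 6 parallel, 0 antiparallel
```

Reading the numbers: the two systems vitrify at nearly the same
temperature and show almost identical pressure coefficients of T_g, yet
the racemate-like sample has a clearly smaller activation volume — the
signature that the local molecular arrangement of the two liquids
differs. The structural branch shows the matching contrast: the
enantiomer-like box is dominated by small H-bond clusters (56.8 % of
clusters have 2–4 molecules) and only parallel ring stacking, while the
racemate-like box has more extended chains (44.1 % small clusters) and
both stacking arrangements. Every number above is recomputed from
synthetic data by the full pipeline (fit → surface → derivatives), and
`report.json` holds the machine-readable version with per-stage
artifacts next to it.

Library use mirrors the CLI:

```python
from amorphdyn import (preset_spectra_scenario, gen_spectra, fit_spectrum,
                       hn_peak_time)

scenario = preset_spectra_scenario("enantiomer-like", seed=1)
spectra, truth = gen_spectra(scenario)
fit = fit_spectrum(spectra[0], n_processes=2)
structural = max(fit.model.processes, key=hn_peak_time)
print(hn_peak_time(structural))   # loss-peak relaxation time, s
```

Other subcommands: `fit-spectra`, `fit-surface`, `derive`, `clusters`,
`stacking`, `simulate-spectra`, `simulate-config` (see `amorphdyn --help`).

## Layout

```
src/amorphdyn/
  spectra.py     HN loss model, peak-time conversion, spectrum fitting
  surface.py     VFT + modified Avramov fits, Tg(p), dTg/dp, m, dV
  structures.py  periodic configurations, roles, extended-XYZ I/O
  hbonds.py      H-bond detection, clusters, topology statistics
  stacking.py    RDF x ADF maps, parallel/antiparallel census
  synth.py       synthetic generators with ground-truth manifests
  pipeline.py    end-to-end study flow and reporting
  cli.py         `amorphdyn` command-line interface
docs/methods.md  model assumptions, parameter choices, limitations
```
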