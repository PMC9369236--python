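# piezodyn

Analysis pipeline for elastic and quasi-elastic incoherent neutron-scattering
(EINS/QENS) studies of protein dynamics under combined temperature and
hydrostatic-pressure scans — the kind of experiment used to compare how
orthologous enzymes from piezophilic (pressure-adapted) and piezosensitive
organisms respond to pressures of 1–600 bar between 283 and 363 K.

It is written for neutron-scattering practitioners and structural biologists
who want a tested, scriptable alternative to instrument-side reduction and
ad-hoc fitting notebooks, and it ships a forward generator of raw-like
synthetic data with known ground truth so that every stage of the pipeline can
be validated without access to beamtime data.

## What it computes

**Reduction.** Raw sample / empty-cell / buffer (D₂O) / vanadium measurements
with transmissions are turned into fit-ready datasets:
transmission-scaled background subtraction, vanadium (detector-efficiency)
normalization, detailed-balance symmetrization
S → S·exp(−ħω/2k_BT), 10 K temperature binning, hysteresis-checked merging of
up/down scans, and flux-conserving energy rebinning.

**Two-state elastic model.** Elastic scans I(q; T) at one pressure are fitted
globally with hydrogen motions modelled as two harmonic wells a distance *d*
apart with free-energy difference ΔG = ΔH − TΔS:

    S(q, 0) = exp(−⟨Δx₀²⟩q²) · [1 − 2p₁p₂(1 − sinc(qd))],   p₁/p₂ = e^(−ΔH/RT + ΔS/R)

with (d, ΔH, ΔS) shared across temperatures and the single-well MSD ⟨Δx₀²⟩(T)
free per temperature.  Derived quantities: the total MSD
⟨Δx_tot²⟩ = ⟨Δx₀²⟩ + p₁p₂d²/3, its slope (resilience / pseudo force constant)
and a two-segment breakpoint test for dynamical transitions.

**Hall–Ross QENS model.** S(q, ω) maps are fitted globally with an elastic
incoherent structure factor A₀(q) fixed from direct integration of the
spectra, a jump-diffusion Lorentzian of HWHM
Γ_j(q) = (ħ/τ)[1 − exp(−q²⟨l⟩²/2)] and a q-independent localized-motion
width Γ_loc, convolved with the measured vanadium resolution:

    S(q, ω) = A₀(q)·L(ω; Γ_j) + (1 − A₀(q))·L(ω; Γ_j + Γ_loc)

leaving three physical free parameters (τ, ⟨l⟩, Γ_loc).  A model-free
Lorentzian survey (AICc-selected component count, flat-vs-saturating width
trends) supports the model choice.

**EISF geometry.** A₀(q) is decomposed into an immobile fraction *p*, a
fraction *s* confined in a sphere of radius *R* and methyl three-site jumps
(a_M = 1.715 Å): A₀ = p + (1−p)[s·j₀²(qR/2) + (1−s)(1 + 2j₀(q·a_M))/3].
Confinement radii can be compared with cavity equivalent radii (3V/4π)^⅓.

**Thermal laws.** Fitted Γ_loc(T) and τ(T) are analysed with Arrhenius
(Γ = Γ₀e^(−E_A/RT), τ = τ₀e^(+E_A/RT)) and Vogel–Fulcher–Tammann
(τ = τ₀·exp(DT₀/(T−T₀)), fragility 1/D) laws, compared by small-sample
corrected AIC; D_pseudo = ⟨l⟩²/2τ is reported for comparison across studies.

**Sequence comparison.** Ortholog pairs are globally aligned (BLOSUM62) and
their substitutions enumerated and classified by residue polarity
(acidic/basic/polar/hydrophobic), with labels such as `I35V` numbered on the
first sequence.

## Worked example

```python
import numpy as np
from piezodyn import synthetic_data as sd
from piezodyn import (reduce_elastic, reduce_qens, fit_two_state_global,
                      total_msd, resilience, extract_eisf, fit_qens_global,
                      fit_eisf, select_thermal_law, pseudo_diffusion)

truth = sd.preset_profiles("piezophile_like", seed=42)

elastic = sd.generate_elastic_dataset(truth, seed=42)
scans = reduce_elastic(elastic["sample"], elastic["empty_cell"],
                       elastic["buffer"], elastic["vanadium"])
fit = fit_two_state_global(scans.select_pressure(1.0))
msd = total_msd(fit)

qens = sd.generate_qens_dataset(truth, seed=43)
spectra = reduce_qens(qens["sample"], qens["empty_cell"],
                      qens["buffer"], qens["vanadium"])
spec = spectra.select_condition(303.0, 1.0)
eisf = extract_eisf(spec)
hr = fit_qens_global(spec, eisf)
geom = fit_eisf(eisf)
```

This generates a full synthetic study (Arrhenius-type preset, true
d = 1.4 Å, ΔH = 12 kJ/mol, ΔS = 25 J/(mol·K); τ ≈ 2.6 ps at 303 K), reduces
the raw data and prints, with the snippet in the repository:

```
d  = 1.405 +- 0.025 A
dH = 11.64 +- 1.23 kJ/mol
dS = 23.11 +- 4.44 J/(mol K)
MSD slope = 0.0034 A^2/K -> pseudo force constant 0.819 N/m
tau = 2.65 ps, <l> = 1.20 A, Gloc = 0.358 meV
D_pseudo = 0.272 A^2/ps
EISF geometry: p = 0.34, s = 1.00, R = 2.68 A
tau(T) law: arrhenius (dAICc = -4.8), EA = 2.40 kcal/mol
```

The two-state parameters come back within their 1σ uncertainties of the
generating values; the τ(T) series across all nine temperatures is correctly
classified as Arrhenius, with an activation energy in the 1.5–3.8 kcal/mol
range characteristic of methyl-group rotation.

A command-line interface mirrors this flow:

```bash
piezodyn simulate --preset piezophile_like --seed 42 --out sim/
piezodyn reduce --manifest sim/elastic_manifest.json --out reduced.tsv
piezodyn fit-eins reduced.tsv --pressure 1 --out params.json --msd msd.tsv
piezodyn fit-qens qens_reduced.h5 --temperature 303 --pressure 1 --out fit.json
piezodyn compare-seq a.fasta b.fasta --out subs.tsv
```

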