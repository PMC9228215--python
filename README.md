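# cyclosense

Tools for characterising anion binding by cyclopeptide receptors in organic
solvents. A cyclic pentapeptide presents its five backbone amide N–H groups
as a convergent binding site for halides, thiocyanate and oxoanions; the
package implements the complete inference chain used to quantify and
rationalise that binding:

* **equilibrium speciation** over a receptor L and an anion A, including
  competing anion self-association (the dihydrogen phosphate dimer A₂ and
  the dimer complex LA₂), solved from the mass balances by damped Newton
  iteration in log-concentration space;
* **global multivariate fitting** of full-spectrum fluorimetric/UV
  titrations and of fast-exchange ¹H NMR shift titrations. The bilinear
  model `Yᵀ = C(log β)·S + E` is fitted by variable projection: the molar
  responses `S` (per-species spectra or limiting shifts) are solved exactly
  by linear least squares at each trial of the stability constants
  `log β`, and the outer nonlinear search is Levenberg–Marquardt with
  optional multistart;
* **one-site ITC analysis**: a displaced-volume forward model for
  per-injection heats, nonlinear least-squares recovery of K and Δ<sub>r</sub>H°,
  blank (dilution-heat) correction, and the entropy from
  Δ<sub>r</sub>G° = −RT ln K = Δ<sub>r</sub>H° − TΔ<sub>r</sub>S°;
* **solvent-transfer thermodynamic cycles** connecting complexation in two
  solvents through transfer Gibbs energies of every participant,
  Δ<sub>t</sub>G°(LA⁻) = Δ<sub>t</sub>G°(A⁻) + Δ<sub>t</sub>G°(L) +
  Δ<sub>r</sub>G°(target) − Δ<sub>r</sub>G°(source), with the ligand leg
  from saturation solubilities (Δ<sub>t</sub>G° = −RT ln(s₂/s₁));
* **ensemble structural statistics** over MD-style coordinate trajectories:
  coordination matrices of amide–anion distances and angles, intramolecular
  hydrogen-bond censuses, per-amide coordination occupancies, PCA +
  clustering selection of representative structures, phenyl-ring–to–backbone
  distance distributions, and strided averaging of per-frame spectra;
* **synthetic data generators** for every input, with known ground truth,
  so each stage is testable end to end.

Fitting follows a Model/Results convention: build a model object from the
data, call `fit()`, inspect the results object (`summary()`, estimates,
standard errors, residuals).

## Worked example

Simulate a chloride-like calorimetric titration (1.4 mL cell, 25 × 10 µL
injections, 1 % heat noise) from a known enthalpy/entropy pair, correct it
with its blank, and fit the one-site model:

```python
from cyclosense import synthetic_data as syn
from cyclosense.itc import ITCModel, subtract_blank

cfg = syn.ITCConfig(dH=-15e3, dS=65.0, noise_frac=0.01)
thermogram, blank, truth = syn.gen_thermogram(cfg, seed=2025)
result = ITCModel(subtract_blank(thermogram, blank), fit_blank=False).fit()
print(result.summary())
```

```
One-site ITC fit
============================================
log K              6.0235 +/- 0.0256
dG / kJ mol-1      -34.38
dH / kJ mol-1      -15.10 +/- 0.07
dS / J mol-1K-1      64.7 +/- 0.5
T / K              298.15
blank / J       0.000e+00
c parameter         105.6
ssr / J^2       9.858e-11   converged: True
```

The simulation truth was log K = 6.023 (from ΔG = ΔH − TΔS), ΔH = −15
kJ mol⁻¹ and ΔS = 65 J mol⁻¹ K⁻¹; the fit recovers all three within a few
standard errors, and the Wiseman c parameter (K·c_cell ≈ 106) confirms the
titration sits in the well-conditioned regime.

A spectral titration runs the same way with
`cyclosense.global_fit.SpectralTitrationModel`, and the command line mirrors
the library:

```sh
cyclosense simulate --what itc --seed 3 --out-dir sim
cyclosense fit-itc --input sim/itc.csv --blank sim/itc_blank.csv
cyclosense pipeline --stages simulate-itc,fit-itc,cycle --seed 7 --out-dir run
```

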