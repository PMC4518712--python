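# assocfit

Quantitative analysis of protein self-association, built around the
biophysics of the p85α regulatory subunit of PI3K, whose monomer–homodimer
equilibrium (mediated by trans SH3:PR1 and BH:BH contacts) tunes PTEN
stability and PI3K signalling.  The package is for structural biologists and
biophysicists who need to:

* fit **sedimentation-equilibrium (SE)** data globally across rotor speeds
  and loading concentrations with hard mass conservation, for
  monomer–dimer or monomer–dimer–tetramer schemes, with Monte Carlo
  confidence intervals;
* fit **microscale thermophoresis (MST)** dose–response series, including a
  trace-label *self-association* isotherm, and **isothermal titration
  calorimetry (ITC)** one-site injection heats with full thermodynamic
  output (K_d, ΔG, ΔH, TΔS, N);
* **audit structural models**: buried interface areas, core/rim residue
  classes, residue contacts, cis/trans linker-reach feasibility and
  declarative constraint sets;
* **simulate** all of the above with seeded generators so every stage is
  testable without raw instrument data.

## Models

**Sedimentation equilibrium.** At equilibrium each oligomer of size *n*
follows an exponential in r²,

    c_n(r) = c_n(r0) · exp[ n σ (r² − r0²) / 2 ],      σ = M(1 − v̄ρ)ω² / RT,

where σ is the reduced buoyant molar mass of the monomer.  Species are
coupled by mass action, K_n = [M]ⁿ/[M_n] (for the dimer, the familiar
K_d = [M]²/[D]), and every channel obeys sector-shaped mass conservation,

    loading = 2 ∫ c(r) r dr / (b² − m²),

imposed as a hard constraint that eliminates the per-channel reference
concentration.  The only global parameters are the log₁₀ K's; per-channel
baselines are solved in closed form.

**MST.** The labeled species' bound fraction: exact 1:1 quadratic, or — for
a protein titrated with itself — the trace-label self-association isotherm
f_b = u/(K_d/2 + u), where u is the unlabeled free monomer from the
dimerization quadratic and K_d/2 is the statistical heterodimer constant.

**ITC.** Standard one-site injection-heat model with perfusion dilution
(1 − v/V) per injection; ΔG = RT ln K_d and TΔS = ΔH − ΔG close the
thermodynamic cycle.

**Structure.** Shrake–Rupley SASA (probe 1.4 Å); buried area per monomer
(SASA_A + SASA_B − SASA_AB)/2; interface residues classified core/rim by
relative accessibility (7 % rule); linker feasibility |a₁ − a₂| ≤ n·d_max
with d_max = 3.8 Å per residue; declarative constraint auditing
(contact / interface_contains / buried / accessible / disjoint_interfaces /
symmetric).

## Worked example

```python
from assocfit import SEGlobalFitter, MSTFitter
from assocfit import synthetic as synth

# 3 speeds (11.8/12.8/13.8 krpm) x 3 loadings (1.0/0.5/0.25 mg/ml),
# 84 kDa monomer, 0.005 AU noise, generated at a 7 uM dimerization Kd
exp = synth.gen_se(7e-6, monomer_mass=84_000.0, seed=1)
fitter = SEGlobalFitter().fit(exp)
res = fitter.monte_carlo_ci(n_iter=100, level=0.95, seed=1)
lo, hi = res.kd_ci[0]
print(f"SE global fit: Kd = {fitter.kd_[0]*1e6:.2f} uM "
      f"(95% CI {lo*1e6:.2f}-{hi*1e6:.2f}), reduced chi2 = {fitter.reduced_chi2_:.3f}")

series = synth.gen_mst(3.9e-6, seed=1)   # 20 nM label, 1:1 dilution from 50 uM
print(f"MST self-association fit: Kd = {MSTFitter().fit(series).kd_*1e6:.2f} uM")
```

prints

```
SE global fit: Kd = 7.01 uM (95% CI 6.99-7.03), reduced chi2 = 1.000
MST self-association fit: Kd = 3.91 uM
```

The fitted constant recovers the generating 7 µM truth; the reduced χ² of
1.000 says the residual scatter matches the 0.005 AU generating noise; the
Monte Carlo interval is the parametric-bootstrap 95 % band.

The same analyses run from the shell:

```bash
assocfit simulate se --kd 7 --mass 84 --seed 1 --out sedata/
assocfit fit se --manifest sedata/manifest.yaml --scheme 1,2 --mc 100 --out report
assocfit struct linker --n 5 --anchor1 0,0,0 --anchor2 40,0,0
assocfit struct audit --pdb model.pdb            # shipped constraint set
```

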