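# Methods

This note documents the models implemented in `assocfit`, the defaults and
their rationale, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer would want to know.

## Self-association equilibria

An association pathway is a list of oligomer sizes starting at the monomer
(`(1,2)` or `(1,2,4)`) with one **overall** dissociation constant per
oligomer, K_n = [M]ⁿ/[M_n], in units of M^(n−1).  For the dimer this is the
molar K_d = [M]²/[D].  For the tetramer the constant is the overall
[M]⁴/[Tet] (units M³); a dimer-of-dimers constant K_dd = [D]²/[Tet] converts
as K_4 = K_dd·K_2².  We expose the overall constant because it maps directly
onto the SE exponential model; the convention is stated here because
instrument software differs and rarely says which it uses.

Given a total concentration in monomer units, the free monomer is the
unique non-negative root of total = m + Σ n·mⁿ/K_n, found by bracketed
bisection on [0, total] to 1e−12 relative tolerance (≈ 40–60 iterations,
capped at 300).  Bisection rather than the closed-form quadratic keeps one
code path for all schemes; the quadratic survives as a test oracle.
`K = inf` is accepted as the explicit no-association limit.

Thermodynamics: ΔG = RT ln(K_d/1 M) with R = 8.314 J/(mol K); TΔS = ΔH − ΔG.
Internal units are molar, kelvin and kJ/mol; µM and °C converters are
provided at the interfaces.

## Sedimentation equilibrium

Reduced buoyant molar mass σ = M(1 − v̄ρ)ω²/(RT) in cm⁻², computed in cgs
units (R = 8.314e7 erg/(mol K)).  The radial signal is

    s(r) = baseline + ε·l · Σ n c_n(r0) exp[n σ (r² − r0²)/2],

with ε·l converting molar monomer units to absorbance.  Exponents above 700
raise a model-range error rather than overflowing.

**Mass conservation is a hard constraint, not a penalty.**  For a
sector-shaped channel the implied loading is 2∫c(r)r dr/(b²−m²); because
every species is exponential in r², the integral has a closed form, and the
reference (meniscus) free monomer of each channel is solved from the known
loading by Brent's method at machine-precision tolerance.  The public
`conserve_mass` computes the same integral by adaptive quadrature (1e−10
relative) and is cross-checked against the closed form and against symbolic
integration in the tests.  Residual mismatch between implied and known
loading is below 1e−8 relative for every reported fit.

**Global fit.**  The only global parameters are the log₁₀ constants, with
bounds [−9, −1] on the molar (dimer) scale; for an oligomer of size n the
bounds stretch by (n−1) because the overall constant scales as the
(n−1)-th power of a molar constant.  Per-channel baselines (bound ±0.1 AU)
enter linearly and are solved as the clipped weighted-mean residual.
Optimization is Nelder–Mead with five starts log-spaced over ±2 decades
around a slope-based guess (apparent weight-average mass from ln s vs r²);
channels are weighted 1/σ² when a noise sigma is known.  Reduced χ² =
weighted SSR/(N − n_constants − n_baselines).  A constant within 1e−3 of a
bound sets a boundary flag and a warning — this is how an undetectably weak
association presents (the fitted constant runs to the upper bound, far
above the loading concentrations).

**Monte Carlo confidence intervals** are a parametric bootstrap: fresh
Gaussian noise at the fitted per-channel residual RMS is added to the
best-fit model and the fit repeated, starting each refit at the previous
optimum (standard bootstrap practice; the surface is unimodal near the
optimum).  The CI is the percentile interval.  A residual-resampling
variant is selectable.  More than 20 % failed refits aborts with a
CI-unreliable error.

**s20,w correction**: s·(η_buffer/η_20,w)·(1−v̄ρ)_20,w/(1−v̄ρ)_buffer with
η_20,w = 1.002 cP and ρ_20,w = 0.99823 g/ml fixed.

Defaults not printed in any protocol and therefore fixed here as documented
configuration: meniscus 6.95 cm, bottom 7.25 cm (a 3 mm column), radial
spacing 0.001 cm, pathlength 1.2 cm, v̄ = 0.73 ml/g, ρ = 1.005 g/ml,
temperature 293.15 K, and a 280 nm signal coefficient of 0.75 AU·ml/(mg·cm)
(so 1 mg/ml ≈ 0.9 AU in the 12-mm cell).  Generator and fitter share these
values; none is fitted.  Whether the original analysis fitted baselines per
channel or shared them is unknown; per-channel is standard practice and is
what we do.

## MST

Dose–response series are per-mil Fnorm versus a 1:1 serial dilution
(default 16 points from 50,000 nM) at 20 nM labeled protein.  Two isotherms:

* `one_to_one` — exact quadratic bound fraction;
* `self_association` — the unlabeled free monomer u follows the
  dimerization quadratic (the trace label does not perturb it) and the
  label binds with k_het = K_dim/2.  The factor 2 is combinatoric: a
  label·unlabeled pair forms in two ways where an unlabeled homodimer forms
  in one.  It is on by default and toggleable, because instrument 1:1 fits
  lack it — fitting a self-association series with a plain 1:1 model shifts
  the apparent constant about two-fold, which plausibly explains AUC/MST
  discrepancies of that size.

Fitting: log₁₀ K by five-start Nelder–Mead (single-start refits use bounded
scalar minimization); the two plateaus are profiled out by linear least
squares at each K, so the search is one-dimensional.  A fit whose realized
signal span (plateau difference × observed bound-fraction range) is below
3× the residual RMS raises an unidentifiable-amplitude error.  The
parametric bootstrap re-adds noise at the dof-corrected residual level
σ̂ = RMS·√(N/(N−3)); without the correction the 95 % intervals measurably
undercover (≈ 86 % instead of ≥ 93 % in the test-suite replication).

## ITC

One-site injection heats with perfusion dilution: per injection the cell
concentrations scale by (1 − v/V), the titrant gains X_s·v/V, the bound
complex follows the quadratic with stoichiometry N, and

    q_i = ΔH · V · (B_i − B_{i−1}(1 − v/V)) + q_dil,

reported in µcal (1 cal = 4.184 J).  Fit parameters: log₁₀ K_d, ΔH, N,
q_dil by five-start trust-region least squares; ΔG and TΔS derive at the
experiment temperature.  A Wiseman c-value N[cell]/K_d outside [0.05, 5000]
attaches a reliability warning instead of failing.  The first injection is
retained by default (the generator simulates no first-injection artifact);
`discard_first` mirrors common practice for real data.

Default design: 19 × 2 µl injections of 10× ligand into a 200 µl cell at
100 µM and 25 °C, reaching a final molar ratio ≈ 2.  At this design with
0.1 µcal noise the K_d is recovered with a broad but median-unbiased
distribution; the weaker protein-into-protein design (40 µM cell, 400 µM
syringe, c ≈ 2) is noticeably less identifiable — its K_d scatters several-
fold seed to seed — which is an honest property of shallow isotherms, not
of the optimizer.

## Structure analysis

PDB files are read first-model-only; alternate locations resolve to the
highest occupancy with ties taken alphabetically (altloc 'A'); waters are
always dropped and other heteroatoms by default.  SASA is Shrake–Rupley
sphere sampling (biotite's deterministic Fibonacci point set), probe 1.4 Å,
960 points by default, with van der Waals radii from a named table —
"chothia" (NACCESS-style: C 1.87, N 1.65, O 1.40, S 1.85) by default,
"bondi" or a custom element→Å mapping otherwise; every result records its
radii-set tag.  Unknown elements get 1.8 Å with a warning (or an error on
request).  Because published buried-area figures rarely name their
algorithm or radii, comparisons across radii sets should allow ±10 %.
Sphere sampling is orientation-dependent at the ~0.1 % level at 960 points;
use more points (the rotation-invariance tests use 5000) when that matters.
Coordinates are float32 internally, so geometric fixtures should stay above
~1e−3 Å feature sizes.

Buried area per monomer is (SASA_A + SASA_B − SASA_AB)/2.  Interface
residues (ΔSASA > 0) are *core* when relative SASA (against per-residue
theoretical maxima; non-standard residues fall back to their isolated-
residue area) drops below 7 % in the complex while being ≥ 7 % free, else
*rim*.  Contacts use heavy-atom distances with an inclusive cutoff
(default 4.5 Å).

Linker feasibility is the geometric bound |a₁ − a₂| ≤ n·d_max with
d_max = 3.8 Å (Cα–Cα virtual bond; 3.63 Å trans-peptide contour is the
conservative alternative).  It is an upper bound on reach — a *feasible*
verdict is necessary, not sufficient; an *infeasible* verdict is decisive,
which is the logic that forces SH3:PR1 contacts into trans in the
homodimer.

The constraint auditor evaluates declarative records (contact,
interface_contains, buried, accessible, disjoint_interfaces, symmetric)
against a structure, reporting pass/fail with numeric margins; a constraint
referencing an absent residue is *unevaluable*, never a failure.  Symmetry
is the Kabsch-superposition RMSD between the two protomers over matched
atoms.  The shipped default file encodes the main published constraints on
the homodimer:PTEN working model (PTEN-interface membership of BH residues
127/133/137, burial of PTEN K13, W298 proximity, GTPase/PTEN site
disjointness, two-fold symmetry) under a documented chain convention
(A/B = protomers, C = PTEN); the full 16-constraint set used in the
original modelling was never published in full, so the file is deliberately
user-extensible.  Crystal-symmetry mate generation is out of scope: dimer
analyses need a two-chain assembly file.

## Synthetic data: what it does and does not emulate

The generators reproduce the acquisition designs: SE at 11.8/12.8/13.8 krpm
× 1.0/0.5/0.25 mg/ml, 280 nm, 20 °C, 0.001 cm spacing; MST at 20 nM label
with a 16-point 1:1 dilution from 50,000 nM; ITC as above.  Noise is
i.i.d. Gaussian — SE 0.005 AU, MST 1 % of the thermophoresis amplitude,
ITC 0.1 µcal — magnitudes typical of the respective instruments.  Monomer
masses for the constructs are generator defaults: 84 kDa full-length,
37 kDa SH3-PR1-BH-PR2, 25 kDa PR1-BH.  MST plateaus default to 800/860
per mil.

Not emulated: radial- or time-invariant systematic noise, meniscus
artifacts and optical aberrations in SE; first-injection artifacts and
baseline-integration error in ITC; thermophoresis physics (the plateaus
are phenomenological) and concentration-dependent aggregation in MST.
Passing recovery tests therefore demonstrates correctness and statistical
calibration of the estimators under the stated designs, not robustness to
instrument systematics.

The toy structural fixtures are sphere pairs with closed-form buried caps
and exactly C2-symmetric clusters; they validate the surface pipeline
analytically, while published-structure numbers require the user to supply
the deposited coordinate files.

## Problem sizes and reproducibility

Recovery campaigns use 25 seeded datasets for SE and 50 for MST/ITC —
enough for a stable median at the designs' seed-to-seed spread; Monte Carlo
CIs use 100 iterations in the examples and tests (500–1000 is customary
for publication figures).  The bootstrap-coverage check runs 100
replications × 100 iterations on the MST fitter.  All randomness flows
through numpy Generators seeded explicitly; every generator is
byte-deterministic under a fixed seed, and reports echo the seed.

## Known limitations

* SE fitting assumes a single sample species set shared across channels —
  no incompetent-fraction or contaminant species.
* The SE reference-monomer elimination assumes the signal coefficient and
  loading are known exactly; loading is not refined.
* The MST self-association isotherm neglects titrant consumed by the trace
  label (exact coupled solution differs by ~0.2 % at 20 nM label).
* Percentile bootstrap CIs are first-order; profile-likelihood intervals
  are not implemented.
* The constraint language covers distance/burial/symmetry predicates only;
  no energetic scoring.
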