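"""Seeded generators emulating the study's experimental designs.

Defaults reproduce the published designs: sedimentation equilibrium at
11.8/12.8/13.8 krpm × 1.0/0.5/0.25 mg/ml loadings read at 280 nm and 20 °C
(0.001 cm radial spacing, 12-mm cells); MST with 20 nM labeled protein and a
16-point 1:1 serial dilution of the unlabeled titrant from 50,000 nM; ITC
with 2 µl injections of 10× ligand into a 100 µM cell at 25 °C.  Gaussian
measurement noise defaults: 0.005 AU (SE), 1 % of the thermophoresis
amplitude (MST), 0.1 µcal (ITC).  Monomer masses for the study's constructs
(generator defaults): full-length 84 kDa, SH3-PR1-BH-PR2 fragment 37 kDa,
PR1-BH fragment 25 kDa.

Every generator is deterministic under a fixed seed.  ``gen_toy_dimer``
produces two-chain pseudo-atomic assemblies with analytically known buried
areas (sphere-pair construction) and an exactly two-fold-symmetric variant
for exercising the structural module without any downloaded structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .equilibria import AssociationScheme
from .isotherms import (
    ITCExperiment,
    MSTSeries,
    dilution_series,
    fraction_bound_1to1,
    fraction_bound_self,
    itc_heats,
)
from .se import (
    SEChannel,
    SEExperiment,
    SolutionProperties,
    _ref_monomer_for_loading,
    reduced_buoyant_sigma,
    se_profile,
)
from .structure import StructureModel

__all__ = [
    "SEDesign",
    "MSTDesign",
    "ITCDesign",
    "MONOMER_MASSES",
    "gen_se",
    "gen_mst",
    "gen_itc",
    "gen_toy_dimer",
    "toy_sphere_separation",
    "toy_cap_area",
]

#: Construct monomer masses, g/mol (generator defaults).
MONOMER_MASSES = {
    "full_length": 84_000.0,
    "sh3_pr1_bh_pr2": 37_000.0,
    "pr1_bh": 25_000.0,
}


@dataclass(frozen=True)
class SEDesign:
    """Sedimentation-equilibrium acquisition design."""

    rotor_speeds: tuple[float, ...] = (11_800.0, 12_800.0, 13_800.0)  # rpm
    loadings_mg_ml: tuple[float, ...] = (1.0, 0.5, 0.25)
    radial_spacing: float = 0.001  # cm
    noise_sigma: float = 0.005  # AU
    meniscus: float = 6.95  # cm
    bottom: float = 7.25  # cm
    edge_margin: float = 0.005  # cm kept clear of meniscus/bottom

    def __post_init__(self):
        if self.radial_spacing <= 0 or self.noise_sigma < 0:
            raise ValueError("design values must be positive")
        if self.meniscus >= self.bottom:
            raise ValueError("meniscus must lie below the bottom radius")

    def radii(self) -> np.ndarray:
        return np.arange(
            self.meniscus + self.edge_margin,
            self.bottom - self.edge_margin + 0.5 * self.radial_spacing,
            self.radial_spacing,
        )


@dataclass(frozen=True)
class MSTDesign:
    """MST titration design."""

    top_nM: float = 50_000.0
    ratio: float = 0.5
    n_points: int = 16
    labeled_nM: float = 20.0
    f_free: float = 800.0  # per mil
    f_bound: float = 860.0  # per mil
    noise_fraction: float = 0.01  # of |f_bound - f_free|


@dataclass(frozen=True)
class ITCDesign:
    """ITC titration design (MicroCal-style perfusion cell)."""

    cell_volume_ul: float = 200.0
    cell_conc_uM: float = 100.0
    syringe_conc_uM: float = 1000.0
    n_injections: int = 19
    injection_ul: float = 2.0
    noise_ucal: float = 0.1
    temperature: float = 298.15  # K
    q_dilution_ucal: float = 0.0


def gen_se(
    kd: float | tuple[float, ...],
    monomer_mass: float = MONOMER_MASSES["full_length"],
    seed: int | None = None,
    scheme_stoich: tuple[int, ...] = (1, 2),
    design: SEDesign = SEDesign(),
    properties: SolutionProperties | None = None,
) -> SEExperiment:
    """Generate a noisy multi-channel SE experiment at a known truth.

    ``kd`` is the generating dissociation constant (molar; a tuple for
    multi-step schemes).  The forward model is the same mass-conserving
    species profile used by the fitter.
    """
    kds = (kd,) if np.isscalar(kd) else tuple(kd)
    scheme = AssociationScheme(scheme_stoich, kds)
    if properties is None:
        properties = SolutionProperties(monomer_mass=monomer_mass)
    rng = np.random.default_rng(seed)
    radii = design.radii()
    channels = []
    for speed in design.rotor_speeds:
        sigma1 = reduced_buoyant_sigma(properties, speed)
        for mg_ml in design.loadings_mg_ml:
            loading_molar = mg_ml / properties.monomer_mass  # g/l over g/mol
            loading_signal = loading_molar * properties.signal_per_molar
            m0 = _ref_monomer_for_loading(
                scheme, sigma1, loading_molar, design.meniscus, design.bottom
            )
            clean = se_profile(
                scheme, sigma1, design.meniscus, m0, radii, 0.0, properties
            )
            noisy = clean + rng.normal(0.0, design.noise_sigma, radii.size)
            channels.append(
                SEChannel(
                    radii=radii,
                    signal=noisy,
                    rotor_speed=speed,
                    loading_signal=loading_signal,
                    meniscus=design.meniscus,
                    bottom=design.bottom,
                    noise_sigma=design.noise_sigma or None,
                )
            )
    return SEExperiment(tuple(channels), properties, scheme)


def gen_mst(
    kd: float,
    seed: int | None = None,
    model: str = "self_association",
    statistical_factor: bool = True,
    design: MSTDesign = MSTDesign(),
) -> MSTSeries:
    """Generate a noisy MST dose–response series at a known truth (kd molar)."""
    rng = np.random.default_rng(seed)
    titrant_nM = dilution_series(design.top_nM, design.ratio, design.n_points)
    l_molar = design.labeled_nM * 1e-9
    if model == "self_association":
        fb = np.array(
            [
                fraction_bound_self(l_molar, t * 1e-9, kd, statistical_factor)
                for t in titrant_nM
            ]
        )
    elif model == "one_to_one":
        fb = np.array(
            [fraction_bound_1to1(l_molar, t * 1e-9, kd) for t in titrant_nM]
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    clean = design.f_free + (design.f_bound - design.f_free) * fb
    sigma = design.noise_fraction * abs(design.f_bound - design.f_free)
    noisy = clean + rng.normal(0.0, sigma, clean.size)
    return MSTSeries(
        titrant_total=titrant_nM, labeled_total=design.labeled_nM, fnorm=noisy
    )


def gen_itc(
    kd: float,
    dH: float,
    n_stoich: float = 1.0,
    seed: int | None = None,
    design: ITCDesign = ITCDesign(),
) -> ITCExperiment:
    """Generate a noisy one-site ITC titration (kd molar, dH kJ/mol)."""
    rng = np.random.default_rng(seed)
    volumes = np.full(design.n_injections, design.injection_ul)
    exp = ITCExperiment(
        cell_volume=design.cell_volume_ul,
        cell_conc=design.cell_conc_uM,
        syringe_conc=design.syringe_conc_uM,
        injection_volumes=volumes,
        heats=np.zeros(design.n_injections),
        temperature=design.temperature,
    )
    clean = itc_heats(exp, kd, dH, n_stoich, design.q_dilution_ucal)
    noisy = clean + rng.normal(0.0, design.noise_ucal, clean.size)
    return ITCExperiment(
        cell_volume=exp.cell_volume,
        cell_conc=exp.cell_conc,
        syringe_conc=exp.syringe_conc,
        injection_volumes=volumes,
        heats=noisy,
        temperature=exp.temperature,
    )


# ---------------------------------------------------------------------------
# Toy structural fixtures


def toy_cap_area(radius: float, separation: float, probe: float = 1.4) -> float:
    """Analytic per-sphere buried area for two equal overlapping spheres.

    Solvent-accessible spheres of radius ``radius + probe`` whose centers
    are ``separation`` apart bury a spherical cap of area 2π·R·h on each,
    with h = R − separation/2 (zero when they do not overlap).
    """
    r_eff = radius + probe
    h = max(r_eff - separation / 2.0, 0.0)
    return 2.0 * math.pi * r_eff * h


def toy_sphere_separation(
    cap_area: float, radius: float, probe: float = 1.4
) -> float:
    """Separation producing a requested per-sphere buried cap area."""
    r_eff = radius + probe
    h = cap_area / (2.0 * math.pi * r_eff)
    if h >= r_eff:
        raise ValueError("requested cap area exceeds a hemisphere")
    return 2.0 * (r_eff - h)


def _make_atoms(records) -> struc.AtomArray:
    atoms = struc.AtomArray(len(records))
    for i, (chain, res_id, res_name, atom_name, element, xyz) in enumerate(records):
        atoms.coord[i] = xyz
        atoms.chain_id[i] = chain
        atoms.res_id[i] = res_id
        atoms.res_name[i] = res_name
        atoms.atom_name[i] = atom_name
        atoms.element[i] = element
        atoms.hetero[i] = False
        atoms.ins_code[i] = ""
    return atoms


def gen_toy_dimer(
    mode: str = "spheres",
    separation: float = 10.0,
    seed: int | None = None,
    n_atoms_per_chain: int = 6,
    spread: float = 2.5,
) -> StructureModel:
    """Construct a two-chain pseudo-atomic assembly for structural tests.

    ``mode='spheres'``: each chain is a single carbon pseudo-atom; with a
    radii set mapping C to a chosen radius, the buried interface area has
    the closed spherical-cap form of :func:`toy_cap_area`.

    ``mode='c2'``: chain A is a seeded random atom cluster and chain B its
    exact 180° rotation about the z axis — a perfect two-fold-symmetric
    homodimer (superposition RMSD 0).
    """
    if mode == "spheres":
        records = [
            ("A", 1, "SPA", "C1", "C", (0.0, 0.0, 0.0)),
            ("B", 1, "SPB", "C1", "C", (separation, 0.0, 0.0)),
        ]
        return StructureModel(_make_atoms(records))
    if mode == "c2":
        rng = np.random.default_rng(seed)
        local = rng.normal(0.0, spread, size=(n_atoms_per_chain, 3))
        offset = np.array([separation / 2.0, 0.0, 0.0])
        coords_a = local + offset
        rot180 = np.diag([-1.0, -1.0, 1.0])  # 180° about z
        coords_b = coords_a @ rot180.T
        records = []
        for i, xyz in enumerate(coords_a):
            records.append(("A", i + 1, "TOY", "C1", "C", tuple(xyz)))
        for i, xyz in enumerate(coords_b):
            records.append(("B", i + 1, "TOY", "C1", "C", tuple(xyz)))
        return StructureModel(_make_atoms(records))
    raise ValueError(f"unknown toy-dimer mode {mode!r}")
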