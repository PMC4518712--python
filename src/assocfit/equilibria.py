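"""Mass-action species distributions and binding thermodynamics.

A self-association pathway (monomer–dimer, monomer–dimer–tetramer, ...) is
described by an :class:`AssociationScheme`: the oligomer sizes present and one
overall dissociation constant per oligomeric species,

    K_n = [M]^n / [M_n]        (units M^(n-1)),

so that for the dimer ``K_2 = [M]^2/[D]`` is the familiar molar dimerization
Kd.  Given a total concentration in monomer units, :func:`solve_species`
returns the unique mass-balanced species distribution.  The thermodynamic
helpers convert a dissociation constant into a standard free energy and close
the ΔG = ΔH − TΔS cycle.

All concentrations are molar, temperatures kelvin and energies kJ/mol
internally; convenience converters for µM and °C are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_GAS",
    "AssociationScheme",
    "SpeciesState",
    "ThermoResult",
    "solve_species",
    "gibbs_from_kd",
    "entropy_term",
    "micromolar",
    "celsius_to_kelvin",
]

#: Gas constant, J/(mol K)
R_GAS = 8.314


def micromolar(value_uM: float) -> float:
    """Convert a concentration in µM to molar."""
    return float(value_uM) * 1e-6


def celsius_to_kelvin(value_C: float) -> float:
    """Convert °C to kelvin."""
    return float(value_C) + 273.15


class EquilibriaError(ValueError):
    """Domain error in an equilibrium computation."""


class ConvergenceError(RuntimeError):
    """A root solve failed to converge; carries diagnostics in ``args``."""


@dataclass(frozen=True)
class AssociationScheme:
    """Stoichiometries and dissociation constants of a self-association path.

    Parameters
    ----------
    stoichiometries:
        Strictly increasing oligomer sizes, always starting with the
        monomer, e.g. ``(1, 2)`` or ``(1, 2, 4)``.
    kd_steps:
        One overall dissociation constant per non-monomer species,
        ``K_n = [M]^n/[M_n]`` in units of M^(n-1) (molar for the dimer).
        ``math.inf`` is accepted as the explicit no-association limit.
    """

    stoichiometries: tuple[int, ...]
    kd_steps: tuple[float, ...]

    def __post_init__(self):
        stoich = tuple(int(n) for n in self.stoichiometries)
        kds = tuple(float(k) for k in self.kd_steps)
        object.__setattr__(self, "stoichiometries", stoich)
        object.__setattr__(self, "kd_steps", kds)
        if not stoich or stoich[0] != 1:
            raise EquilibriaError("stoichiometries must start with the monomer (1)")
        if any(b <= a for a, b in zip(stoich, stoich[1:])):
            raise EquilibriaError("stoichiometries must be strictly increasing")
        if len(kds) != len(stoich) - 1:
            raise EquilibriaError(
                "need exactly one dissociation constant per non-monomer species"
            )
        if any((k <= 0 or math.isnan(k)) for k in kds):
            raise EquilibriaError("all dissociation constants must be > 0")

    @property
    def n_species(self) -> int:
        return len(self.stoichiometries)

    def species_conc(self, free_monomer: float) -> np.ndarray:
        """Concentration of every species at a given free-monomer level.

        The monomer entry is ``free_monomer`` itself; an infinite constant
        yields a zero concentration for that species.
        """
        m = float(free_monomer)
        out = [m]
        for n, kd in zip(self.stoichiometries[1:], self.kd_steps):
            out.append(0.0 if math.isinf(kd) else m**n / kd)
        return np.asarray(out)

    def total_monomer_units(self, free_monomer: float) -> float:
        """Total monomer-unit concentration at a given free-monomer level."""
        c = self.species_conc(free_monomer)
        return float(np.dot(np.asarray(self.stoichiometries, dtype=float), c))


@dataclass(frozen=True)
class SpeciesState:
    """A mass-balanced species distribution (all concentrations molar)."""

    free_monomer: float
    species_conc: np.ndarray
    total_monomer_units: float
    scheme: AssociationScheme = field(repr=False)

    def __post_init__(self):
        if np.any(np.asarray(self.species_conc) < 0):
            raise EquilibriaError("species concentrations must be non-negative")

    @property
    def fraction_in_species(self) -> np.ndarray:
        """Fraction of all monomer units residing in each species."""
        if self.total_monomer_units == 0:
            return np.zeros_like(np.asarray(self.species_conc))
        n = np.asarray(self.scheme.stoichiometries, dtype=float)
        return n * np.asarray(self.species_conc) / self.total_monomer_units


def solve_species(
    scheme: AssociationScheme,
    total: float,
    rtol: float = 1e-12,
    max_iter: int = 300,
) -> SpeciesState:
    """Solve the free-monomer concentration for a given total loading.

    The free monomer is the unique non-negative root of

        total = m + Σ_i n_i · m^{n_i} / K_i

    found by bracketed bisection on ``[0, total]`` to relative tolerance
    ``rtol``.  The total is in monomer units (molar).
    """
    total = float(total)
    if total < 0:
        raise EquilibriaError("total concentration must be >= 0")
    if total == 0:
        return SpeciesState(0.0, np.zeros(scheme.n_species), 0.0, scheme)

    def f(m: float) -> float:
        return scheme.total_monomer_units(m) - total

    lo, hi = 0.0, total
    # f(0) = -total < 0 and f(total) >= 0 since the monomer term alone is total
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if (hi - lo) <= rtol * max(hi, 1e-300):
            break
    else:
        raise ConvergenceError(
            "bisection did not converge", {"total": total, "bracket": (lo, hi)}
        )
    m = 0.5 * (lo + hi)
    conc = scheme.species_conc(m)
    return SpeciesState(m, conc, total, scheme)


def gibbs_from_kd(kd: float, temperature: float) -> float:
    """Standard free energy ΔG = R·T·ln(kd / 1 M) in kJ/mol.

    ``kd`` is molar, ``temperature`` kelvin.  A sub-molar Kd gives a negative
    (favourable) ΔG.
    """
    if kd <= 0:
        raise EquilibriaError("kd must be > 0")
    if temperature <= 0:
        raise EquilibriaError("temperature must be > 0 K")
    return R_GAS * temperature * math.log(kd) / 1000.0


def entropy_term(dH: float, dG: float) -> float:
    """TΔS = ΔH − ΔG (all kJ/mol)."""
    return dH - dG


@dataclass(frozen=True)
class ThermoResult:
    """Binding thermodynamics at a stated temperature.

    Satisfies ΔG = ΔH − TΔS and ΔG = R·T·ln(kd) by construction when built
    through :meth:`from_kd_dh`.
    """

    kd: float  # molar
    dG: float  # kJ/mol
    dH: float  # kJ/mol
    TdS: float  # kJ/mol
    n_stoich: float
    temperature: float  # kelvin

    def __post_init__(self):
        if self.kd <= 0:
            raise EquilibriaError("kd must be > 0")
        if abs(self.dG - (self.dH - self.TdS)) > 1e-9:
            raise EquilibriaError("ΔG must equal ΔH − TΔS")
        if abs(self.dG - gibbs_from_kd(self.kd, self.temperature)) > 1e-9:
            raise EquilibriaError("ΔG must equal R·T·ln(kd)")

    @classmethod
    def from_kd_dh(
        cls, kd: float, dH: float, temperature: float, n_stoich: float = 1.0
    ) -> "ThermoResult":
        dG = gibbs_from_kd(kd, temperature)
        return cls(
            kd=kd,
            dG=dG,
            dH=dH,
            TdS=entropy_term(dH, dG),
            n_stoich=n_stoich,
            temperature=temperature,
        )
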