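"""Structure parsing, surface areas, interface classification and auditing.

Buried interface area follows the usual convention

    buried_per_monomer = (SASA_A + SASA_B − SASA_AB) / 2,

with solvent-accessible surface areas from Shrake–Rupley numeric sphere
sampling (probe 1.4 Å, 960 points by default; biotite provides the sampler,
with van der Waals radii taken from a named table so every result records
its radii set).  Interface residues are classified core/rim by relative
accessibility: a residue touched by the interface (ΔSASA > 0) is *core* when
its relative SASA drops below 7 % in the complex while being at least 7 % in
the free monomer, and *rim* otherwise.

The module also provides a linker-reach feasibility check (can ``n`` linker
residues at ``d_max`` Å per residue span a given anchor distance — the test
that distinguishes cis from trans domain interactions) and a declarative
constraint-audit engine for candidate assembly models (contacts, interface
membership, burial, symmetry, ...), with a shipped default constraint file
for the p85α homodimer:PTEN working model.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

__all__ = [
    "StructureModel",
    "SASAResult",
    "InterfaceReport",
    "LinkerCheck",
    "Constraint",
    "ConstraintResult",
    "ConstraintReport",
    "read_pdb",
    "write_pdb",
    "sasa",
    "interface_area",
    "classify_interface_residues",
    "contact_residues",
    "linker_feasible",
    "audit_constraints",
    "parse_constraints",
    "load_default_constraints",
    "PDBParseError",
    "VDW_RADII_SETS",
    "MAX_ASA",
]


class PDBParseError(ValueError):
    """The file could not be interpreted as PDB coordinates."""


#: Named van der Waals radius tables (Å, by element).  "chothia" follows the
#: NACCESS/Chothia protein values; "bondi" the element-based Bondi radii.
VDW_RADII_SETS: dict[str, dict[str, float]] = {
    "chothia": {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90,
                "H": 1.00, "SE": 1.90},
    "bondi": {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
              "H": 1.20, "SE": 1.90},
}

#: Reference (theoretical maximum) accessible areas per residue type, Å²,
#: for relative-SASA normalisation (Tien et al. theoretical values).
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class StructureModel:
    """Parsed coordinates (first model), wrapping a biotite ``AtomArray``."""

    atoms: struc.AtomArray
    model_number: int = 1

    def __post_init__(self):
        if self.atoms.array_length() == 0:
            raise PDBParseError("structure contains no atoms")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise PDBParseError("non-finite coordinates")

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.atoms.chain_id))

    def chain(self, chain_id: str) -> struc.AtomArray:
        sel = self.atoms[self.atoms.chain_id == chain_id]
        if sel.array_length() == 0:
            raise ValueError(f"chain {chain_id!r} not present")
        return sel

    def residue_atoms(self, chain_id: str, res_id: int) -> struc.AtomArray:
        sel = self.atoms[
            (self.atoms.chain_id == chain_id) & (self.atoms.res_id == res_id)
        ]
        if sel.array_length() == 0:
            raise ValueError(f"residue {chain_id}:{res_id} not present")
        return sel

    def has_residue(self, chain_id: str, res_id: int) -> bool:
        return bool(
            np.any((self.atoms.chain_id == chain_id) & (self.atoms.res_id == res_id))
        )

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(self.atoms[mask], self.model_number)


@dataclass(frozen=True)
class SASAResult:
    """Per-atom/per-residue solvent-accessible areas with their provenance."""

    per_atom: np.ndarray  # Å²
    per_residue: dict[tuple[str, int], float]  # (chain, res_id) -> Å²
    total: float  # Å²
    probe_radius: float
    n_sphere_points: int
    radii_set_tag: str

    def __post_init__(self):
        if np.any(self.per_atom < -1e-9):
            raise ValueError("negative atomic area")
        if abs(self.total - float(np.sum(self.per_atom))) > 1e-6 * max(self.total, 1.0):
            raise ValueError("total must equal the per-atom sum")


@dataclass(frozen=True)
class InterfaceReport:
    """Dimer-interface summary for a chain pair."""

    chain_a: str
    chain_b: str
    buried_per_monomer: float  # Å²
    sasa_a: float  # free-monomer totals, Å²
    sasa_b: float
    sasa_complex: float
    residue_classes: dict[tuple[str, int], str] = field(default_factory=dict)
    contact_pairs: tuple[tuple[tuple[str, int], tuple[str, int]], ...] = ()

    def __post_init__(self):
        if self.buried_per_monomer < -1e-6:
            raise ValueError("buried area must be >= 0")


@dataclass(frozen=True)
class LinkerCheck:
    """Can ``n`` linker residues span the anchor distance?"""

    n_linker_residues: int
    anchor_distance: float  # Å
    max_extension_per_residue: float  # Å
    feasible: bool
    margin: float  # Å, n·d_max − distance

    def __post_init__(self):
        want = self.anchor_distance <= self.n_linker_residues * self.max_extension_per_residue
        if self.feasible != want:
            raise ValueError("feasibility flag inconsistent with geometry")


# ---------------------------------------------------------------------------
# PDB I/O


def _resolve_altlocs(atoms: struc.AtomArray) -> struc.AtomArray:
    """Keep one altloc per atom site: highest occupancy, ties -> 'A'."""
    altloc = atoms.get_annotation("altloc_id") if "altloc_id" in atoms.get_annotation_categories() else None
    if altloc is None or np.all((altloc == "") | (altloc == " ") | (altloc == ".")):
        return atoms
    occupancy = (
        atoms.get_annotation("occupancy")
        if "occupancy" in atoms.get_annotation_categories()
        else np.ones(atoms.array_length())
    )
    keys = {}
    for i in range(atoms.array_length()):
        key = (
            atoms.chain_id[i],
            int(atoms.res_id[i]),
            atoms.ins_code[i],
            atoms.atom_name[i],
        )
        alt = altloc[i].strip()
        if key not in keys:
            keys[key] = i
            continue
        j = keys[key]
        alt_j = altloc[j].strip()
        if occupancy[i] > occupancy[j] or (
            occupancy[i] == occupancy[j] and alt < alt_j
        ):
            keys[key] = i
    mask = np.zeros(atoms.array_length(), dtype=bool)
    mask[list(keys.values())] = True
    return atoms[mask]


def _diagnose_bad_line(path) -> str:
    coord_fields = [(30, 38), (38, 46), (46, 54)]
    try:
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    for a, b in coord_fields:
                        try:
                            float(line[a:b])
                        except ValueError:
                            return f" (malformed coordinate field at line {ln})"
    except OSError:
        pass
    return ""


def read_pdb(path, include_hetero: bool = False) -> StructureModel:
    """Read the first model of a PDB file.

    Alternate locations are resolved to the highest occupancy (ties take
    altloc 'A'); waters are always skipped; non-water heteroatoms are kept
    only with ``include_hetero=True``.
    """
    path = Path(path)
    try:
        pdb_file = PDBFile.read(path)
        atoms = pdb_file.get_structure(
            model=1, altloc="all", extra_fields=["occupancy"]
        )
    except Exception as exc:
        raise PDBParseError(
            f"cannot parse {path}: {exc}{_diagnose_bad_line(path)}"
        ) from exc
    if atoms.array_length() == 0:
        raise PDBParseError(f"{path} contains no ATOM records")
    atoms = _resolve_altlocs(atoms)
    keep = ~np.isin(atoms.res_name, list(_WATER_NAMES))
    if not include_hetero:
        keep &= ~atoms.hetero
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise PDBParseError(f"{path} contains no usable ATOM records")
    return StructureModel(atoms)


def write_pdb(structure: StructureModel, path) -> None:
    """Write a StructureModel to a PDB file."""
    pdb_file = PDBFile()
    pdb_file.set_structure(structure.atoms)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# SASA


def _atom_radii(
    atoms: struc.AtomArray,
    radii_set: str | dict[str, float],
    on_unknown: str = "default",
    default_radius: float = 1.8,
) -> tuple[np.ndarray, str]:
    if isinstance(radii_set, str):
        try:
            table = VDW_RADII_SETS[radii_set]
        except KeyError:
            raise ValueError(f"unknown radii set {radii_set!r}") from None
        tag = radii_set
    else:
        table, tag = dict(radii_set), "custom"
    radii = np.empty(atoms.array_length())
    for i, el in enumerate(atoms.element):
        el = el.upper()
        if el in table:
            radii[i] = table[el]
        elif on_unknown == "default":
            warnings.warn(
                f"no vdW radius for element {el!r}; using {default_radius} Å",
                RuntimeWarning,
            )
            radii[i] = default_radius
        else:
            raise ValueError(f"no vdW radius for element {el!r}")
    return radii, tag


def sasa(
    structure: StructureModel | struc.AtomArray,
    probe: float = 1.4,
    n_points: int = 960,
    radii_set: str | dict[str, float] = "chothia",
    on_unknown: str = "default",
) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area.

    Deterministic for a given (probe, n_points, radii_set).  ``radii_set``
    is a named table or an explicit element→Å mapping; unknown elements get
    a 1.8 Å default with a warning (or an error with ``on_unknown='error'``).
    """
    atoms = structure.atoms if isinstance(structure, StructureModel) else structure
    if atoms.array_length() == 0:
        raise ValueError("need at least one atom")
    radii, tag = _atom_radii(atoms, radii_set, on_unknown)
    per_atom = struc.sasa(
        atoms,
        probe_radius=probe,
        point_number=n_points,
        vdw_radii=radii,
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(per_atom, nan=0.0)
    per_res: dict[tuple[str, int], float] = {}
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
        per_res[key] = per_res.get(key, 0.0) + float(per_atom[i])
    return SASAResult(
        per_atom=per_atom,
        per_residue=per_res,
        total=float(np.sum(per_atom)),
        probe_radius=probe,
        n_sphere_points=n_points,
        radii_set_tag=tag,
    )


def interface_area(
    structure: StructureModel,
    chain_a: str,
    chain_b: str,
    probe: float = 1.4,
    n_points: int = 960,
    radii_set: str | dict[str, float] = "chothia",
    classify: bool = False,
    contact_cutoff: float = 4.5,
) -> InterfaceReport:
    """Buried area per monomer for a two-chain interface.

    buried_per_monomer = (SASA_A + SASA_B − SASA_AB)/2 using SASAs of each
    chain in isolation and of the two-chain complex.
    """
    a = structure.chain(chain_a)
    b = structure.chain(chain_b)
    ab = a + b
    s_a = sasa(a, probe, n_points, radii_set)
    s_b = sasa(b, probe, n_points, radii_set)
    s_ab = sasa(ab, probe, n_points, radii_set)
    buried = max((s_a.total + s_b.total - s_ab.total) / 2.0, 0.0)
    classes: dict[tuple[str, int], str] = {}
    contacts: list = []
    if classify:
        classes = classify_interface_residues(
            structure, chain_a, chain_b, probe, n_points, radii_set
        )
        contacts = _contact_pairs(a, b, contact_cutoff)
    return InterfaceReport(
        chain_a=chain_a,
        chain_b=chain_b,
        buried_per_monomer=buried,
        sasa_a=s_a.total,
        sasa_b=s_b.total,
        sasa_complex=s_ab.total,
        residue_classes=classes,
        contact_pairs=tuple(contacts),
    )


def _reference_area(
    atoms: struc.AtomArray,
    chain: str,
    res_id: int,
    res_name: str,
    probe: float,
    n_points: int,
    radii_set,
) -> float:
    """Max-ASA reference for relative SASA; falls back to the isolated
    residue's own area for non-standard residue types."""
    if res_name in MAX_ASA:
        return MAX_ASA[res_name]
    sel = atoms[(atoms.chain_id == chain) & (atoms.res_id == res_id)]
    return sasa(sel, probe, n_points, radii_set).total


def classify_interface_residues(
    structure: StructureModel,
    chain_a: str,
    chain_b: str,
    probe: float = 1.4,
    n_points: int = 960,
    radii_set: str | dict[str, float] = "chothia",
    core_threshold: float = 0.07,
) -> dict[tuple[str, int], str]:
    """Core/rim classes for residues touched by the A:B interface.

    A residue with ΔSASA > 0 is *core* when its relative SASA in the complex
    falls below the threshold (default 7 %) while its free-monomer relative
    SASA is at least the threshold; otherwise it is *rim*.  Residues with no
    area change are *none*.
    """
    a = structure.chain(chain_a)
    b = structure.chain(chain_b)
    ab = a + b
    free = {}
    free.update(sasa(a, probe, n_points, radii_set).per_residue)
    free.update(sasa(b, probe, n_points, radii_set).per_residue)
    complexed = sasa(ab, probe, n_points, radii_set).per_residue

    names = {}
    for atoms in (a, b):
        for i in range(atoms.array_length()):
            names[(str(atoms.chain_id[i]), int(atoms.res_id[i]))] = str(
                atoms.res_name[i]
            )

    classes: dict[tuple[str, int], str] = {}
    for key, area_free in free.items():
        d_sasa = area_free - complexed.get(key, 0.0)
        if d_sasa <= 1e-9:
            classes[key] = "none"
            continue
        ref = _reference_area(
            ab, key[0], key[1], names[key], probe, n_points, radii_set
        )
        rel_complex = complexed.get(key, 0.0) / ref
        rel_free = area_free / ref
        if rel_complex < core_threshold <= rel_free:
            classes[key] = "core"
        else:
            classes[key] = "rim"
    return classes


def _heavy(atoms: struc.AtomArray) -> struc.AtomArray:
    return atoms[np.char.upper(atoms.element.astype("U3")) != "H"]


def _contact_pairs(a: struc.AtomArray, b: struc.AtomArray, cutoff: float):
    a, b = _heavy(a), _heavy(b)
    d = cdist(a.coord, b.coord)
    ii, jj = np.nonzero(d <= cutoff)
    pairs = set()
    for i, j in zip(ii, jj):
        pairs.add(
            (
                (str(a.chain_id[i]), int(a.res_id[i])),
                (str(b.chain_id[j]), int(b.res_id[j])),
            )
        )
    return sorted(pairs)


def contact_residues(
    structure: StructureModel,
    chain: str,
    res_id: int,
    cutoff: float = 4.5,
    partner_chain: str | None = None,
) -> set[tuple[str, int]]:
    """Residues of other chains with any heavy-atom pair within ``cutoff`` Å
    (inclusive) of the named residue."""
    res = _heavy(structure.residue_atoms(chain, res_id))
    if partner_chain is not None:
        others = _heavy(structure.chain(partner_chain))
    else:
        others = _heavy(structure.atoms[structure.atoms.chain_id != chain])
    if others.array_length() == 0 or res.array_length() == 0:
        return set()
    d = cdist(res.coord, others.coord)
    hit = np.any(d <= cutoff, axis=0)
    return {
        (str(others.chain_id[j]), int(others.res_id[j]))
        for j in np.nonzero(hit)[0]
    }


def linker_feasible(
    anchor1,
    anchor2,
    n_linker_residues: int,
    d_max: float = 3.8,
) -> LinkerCheck:
    """Can a linker of ``n`` residues span the anchor distance?

    ``d_max`` is the maximum extension per residue (3.8 Å Cα–Cα virtual
    bond by default; 3.63 Å for a strict trans-peptide contour length).
    """
    if n_linker_residues < 0:
        raise ValueError("n_linker_residues must be >= 0")
    dist = float(np.linalg.norm(np.asarray(anchor1, float) - np.asarray(anchor2, float)))
    reach = n_linker_residues * d_max
    return LinkerCheck(
        n_linker_residues=int(n_linker_residues),
        anchor_distance=dist,
        max_extension_per_residue=d_max,
        feasible=dist <= reach,
        margin=reach - dist,
    )


# ---------------------------------------------------------------------------
# Declarative constraint audit


@dataclass(frozen=True)
class Constraint:
    """One declarative structural constraint.

    kinds and params:
      contact:              res_a, res_b, max_dist
      interface_contains:   chain_pair (a, b), residues (list)
      buried:               residue, max_rel_sasa
      accessible:           residue, min_rel_sasa
      disjoint_interfaces:  set1, set2 (residue lists)
      symmetric:            chain_pair (a, b), max_rmsd
    """

    kind: str
    params: dict
    label: str = ""


@dataclass(frozen=True)
class ConstraintResult:
    constraint: Constraint
    status: str  # pass | fail | unevaluable
    margin: float | None
    detail: str


@dataclass(frozen=True)
class ConstraintReport:
    results: tuple[ConstraintResult, ...]

    @property
    def overall_pass(self) -> bool:
        return all(r.status != "fail" for r in self.results)

    @property
    def n_failed(self) -> int:
        return sum(r.status == "fail" for r in self.results)


_RES_RE = re.compile(r"^([A-Za-z0-9]):(-?\d+)$")


def _parse_res(token: str) -> tuple[str, int]:
    m = _RES_RE.match(token)
    if not m:
        raise ValueError(f"bad residue token {token!r}; expected CHAIN:RESNUM")
    return m.group(1), int(m.group(2))


def _parse_res_list(token: str) -> list[tuple[str, int]]:
    return [_parse_res(t) for t in token.split(",") if t]


def parse_constraints(text: str) -> list[Constraint]:
    """Parse a constraint file: one whitespace-separated record per line.

    Grammar (``#`` starts a comment)::

        contact              A:176 B:164 4.5
        interface_contains   A:B   A:127,A:133,A:137
        buried               C:13  0.07
        accessible           A:21  0.25
        disjoint_interfaces  A:144,A:151 A:127,A:133,A:137
        symmetric            A:B   0.5
    """
    out = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        kind = tok[0]
        try:
            if kind == "contact":
                c = Constraint(kind, {
                    "res_a": _parse_res(tok[1]),
                    "res_b": _parse_res(tok[2]),
                    "max_dist": float(tok[3]),
                })
            elif kind == "interface_contains":
                a, b = tok[1].split(":")
                c = Constraint(kind, {
                    "chain_pair": (a, b),
                    "residues": _parse_res_list(tok[2]),
                })
            elif kind == "buried":
                c = Constraint(kind, {
                    "residue": _parse_res(tok[1]),
                    "max_rel_sasa": float(tok[2]),
                })
            elif kind == "accessible":
                c = Constraint(kind, {
                    "residue": _parse_res(tok[1]),
                    "min_rel_sasa": float(tok[2]),
                })
            elif kind == "disjoint_interfaces":
                c = Constraint(kind, {
                    "set1": _parse_res_list(tok[1]),
                    "set2": _parse_res_list(tok[2]),
                })
            elif kind == "symmetric":
                a, b = tok[1].split(":")
                c = Constraint(kind, {
                    "chain_pair": (a, b),
                    "max_rmsd": float(tok[2]),
                })
            else:
                raise ValueError(f"unknown constraint kind {kind!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"cannot parse constraint line {raw!r}: {exc}") from exc
        out.append(Constraint(c.kind, c.params, label=line))
    return out


def load_default_constraints() -> list[Constraint]:
    """Constraints shipped for the p85α homodimer:PTEN working model."""
    text = (
        resources.files("assocfit") / "data" / "p85_pten_constraints.txt"
    ).read_text()
    return parse_constraints(text)


def _rel_sasa(structure: StructureModel, residue, probe, n_points, radii_set) -> float:
    chain, res_id = residue
    res_atoms = structure.residue_atoms(chain, res_id)
    res_name = str(res_atoms.res_name[0])
    full = sasa(structure, probe, n_points, radii_set)
    area = full.per_residue.get((chain, res_id), 0.0)
    ref = _reference_area(structure.atoms, chain, res_id, res_name, probe, n_points, radii_set)
    return area / ref


def _symmetry_rmsd(structure: StructureModel, chain_a: str, chain_b: str) -> float:
    """RMSD of chain A superposed onto chain B (matched atom names/ids)."""
    a = structure.chain(chain_a)
    b = structure.chain(chain_b)
    key_a = {(int(a.res_id[i]), str(a.atom_name[i])): i for i in range(a.array_length())}
    key_b = {(int(b.res_id[i]), str(b.atom_name[i])): i for i in range(b.array_length())}
    common = sorted(set(key_a) & set(key_b))
    if len(common) < 3:
        raise ValueError("fewer than 3 matched atoms between chains")
    ca = a.coord[[key_a[k] for k in common]]
    cb = b.coord[[key_b[k] for k in common]]
    # Kabsch superposition
    ca_c = ca - ca.mean(axis=0)
    cb_c = cb - cb.mean(axis=0)
    u, s, vt = np.linalg.svd(ca_c.T @ cb_c)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = ca_c @ rot.T
    return float(np.sqrt(np.mean(np.sum((fitted - cb_c) ** 2, axis=1))))


def _eval_constraint(
    structure: StructureModel,
    c: Constraint,
    probe: float,
    n_points: int,
    radii_set,
) -> ConstraintResult:
    try:
        if c.kind == "contact":
            (ch_a, r_a), (ch_b, r_b) = c.params["res_a"], c.params["res_b"]
            a = _heavy(structure.residue_atoms(ch_a, r_a))
            b = _heavy(structure.residue_atoms(ch_b, r_b))
            dmin = float(cdist(a.coord, b.coord).min())
            margin = c.params["max_dist"] - dmin
            return ConstraintResult(
                c, "pass" if margin >= 0 else "fail", margin,
                f"min heavy-atom distance {dmin:.2f} Å (max {c.params['max_dist']:.2f})",
            )
        if c.kind == "interface_contains":
            ch_a, ch_b = c.params["chain_pair"]
            classes = classify_interface_residues(
                structure, ch_a, ch_b, probe, n_points, radii_set
            )
            missing = [
                r for r in c.params["residues"]
                if not structure.has_residue(*r)
            ]
            if missing:
                raise ValueError(f"residues absent: {missing}")
            outside = [
                r for r in c.params["residues"]
                if classes.get(r, "none") == "none"
            ]
            margin = float(len(c.params["residues"]) - len(outside))
            return ConstraintResult(
                c, "pass" if not outside else "fail", margin,
                f"{len(c.params['residues']) - len(outside)}/"
                f"{len(c.params['residues'])} residues in the interface",
            )
        if c.kind == "buried":
            rel = _rel_sasa(structure, c.params["residue"], probe, n_points, radii_set)
            margin = c.params["max_rel_sasa"] - rel
            return ConstraintResult(
                c, "pass" if margin >= 0 else "fail", margin,
                f"relative SASA {rel:.3f} (max {c.params['max_rel_sasa']:.3f})",
            )
        if c.kind == "accessible":
            rel = _rel_sasa(structure, c.params["residue"], probe, n_points, radii_set)
            margin = rel - c.params["min_rel_sasa"]
            return ConstraintResult(
                c, "pass" if margin >= 0 else "fail", margin,
                f"relative SASA {rel:.3f} (min {c.params['min_rel_sasa']:.3f})",
            )
        if c.kind == "disjoint_interfaces":
            for r in c.params["set1"] + c.params["set2"]:
                if not structure.has_residue(*r):
                    raise ValueError(f"residue absent: {r}")
            shared = set(c.params["set1"]) & set(c.params["set2"])
            return ConstraintResult(
                c, "pass" if not shared else "fail", -float(len(shared)),
                f"{len(shared)} shared residues",
            )
        if c.kind == "symmetric":
            ch_a, ch_b = c.params["chain_pair"]
            rmsd = _symmetry_rmsd(structure, ch_a, ch_b)
            margin = c.params["max_rmsd"] - rmsd
            return ConstraintResult(
                c, "pass" if margin >= 0 else "fail", margin,
                f"superposition RMSD {rmsd:.4f} Å (max {c.params['max_rmsd']:.2f})",
            )
        raise ValueError(f"unknown constraint kind {c.kind!r}")
    except (ValueError, KeyError) as exc:
        return ConstraintResult(c, "unevaluable", None, str(exc))


def audit_constraints(
    structure: StructureModel,
    constraints: list[Constraint],
    probe: float = 1.4,
    n_points: int = 960,
    radii_set: str | dict[str, float] = "chothia",
) -> ConstraintReport:
    """Evaluate a declarative constraint set against a structure.

    A constraint referencing an absent residue or chain is reported as
    *unevaluable*, never as a failure; the report is deterministic and
    independent of constraint order.
    """
    results = tuple(
        _eval_constraint(structure, c, probe, n_points, radii_set)
        for c in constraints
    )
    return ConstraintReport(results)
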