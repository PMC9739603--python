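"""Shrake-Rupley solvent-accessible surface areas and the buried-surface score.

The score of a complex is half the surface buried on binding,

    (ligand_sasa + protein_sasa - complex_sasa) / 2,

with a 1.0 A probe by default.  Sphere points come from a deterministic
golden-spiral (Fibonacci) set; the default of 960 points per atom is the
documented mapping of a "dot density 3" quadrature and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

# Bondi (1964) van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "HE": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NE": 1.54,
    "SI": 2.10,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "AR": 1.88,
    "AS": 1.85,
    "SE": 1.90,
    "BR": 1.85,
    "KR": 2.02,
    "TE": 2.06,
    "I": 1.98,
    "XE": 2.16,
    "ZN": 1.39,
    "CU": 1.40,
    "NI": 1.63,
    "GA": 1.87,
    "CD": 1.58,
    "HG": 1.55,
    "PB": 2.02,
    "SN": 2.17,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "LI": 1.82,
}

_WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP", "SOL"})


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.strip().upper()]
    except KeyError:
        raise KeyError(f"no vdW radius for element {element!r}") from None


@dataclass
class AtomSet:
    """3D atoms: element symbols, coordinates (A), vdW radii (A)."""

    elements: list[str]
    coords: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.elements) == 0:
            raise ValueError("empty AtomSet")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(f"bad coords shape {self.coords.shape}")
        if self.radii.shape != (len(self.elements),):
            raise ValueError(f"bad radii shape {self.radii.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    def __len__(self) -> int:
        return len(self.elements)

    @classmethod
    def from_elements(cls, elements: Sequence[str], coords) -> "AtomSet":
        radii = np.array([vdw_radius(e) for e in elements])
        return cls(list(elements), np.asarray(coords, dtype=float), radii)

    def without_hydrogens(self) -> "AtomSet":
        keep = [i for i, e in enumerate(self.elements)
                if e.strip().upper() != "H"]
        if not keep:
            raise ValueError("AtomSet contains only hydrogens")
        return AtomSet(
            [self.elements[i] for i in keep],
            self.coords[keep],
            self.radii[keep],
        )

    def union(self, other: "AtomSet") -> "AtomSet":
        return AtomSet(
            self.elements + other.elements,
            np.vstack([self.coords, other.coords]),
            np.concatenate([self.radii, other.radii]),
        )


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.0
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 12:
            raise ValueError("need at least 12 sphere points")


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (Fibonacci spiral)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa_per_atom(
    atoms: AtomSet, params: SasaParams = SasaParams()
) -> np.ndarray:
    """Per-atom Shrake-Rupley accessible areas, A^2."""
    n = len(atoms)
    ext = atoms.radii + params.probe_radius
    unit = golden_spiral_points(params.n_sphere_points)
    tree = cKDTree(atoms.coords)
    cutoff = 2.0 * ext.max()
    areas = np.empty(n)
    for i in range(n):
        neighbors = [
            j for j in tree.query_ball_point(atoms.coords[i], cutoff)
            if j != i
            and np.linalg.norm(atoms.coords[j] - atoms.coords[i]) < ext[i] + ext[j]
        ]
        area_i = 4.0 * np.pi * ext[i] ** 2
        if not neighbors:
            areas[i] = area_i
            continue
        pts = atoms.coords[i] + ext[i] * unit  # (P, 3)
        centers = atoms.coords[neighbors]  # (K, 3)
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        blocked = (d2 < (ext[neighbors] ** 2)[None, :]).any(axis=1)
        areas[i] = (1.0 - blocked.mean()) * area_i
    return areas


def sasa(atoms: AtomSet, params: SasaParams = SasaParams()) -> float:
    """Shrake-Rupley solvent-accessible surface area, A^2."""
    return float(sasa_per_atom(atoms, params).sum())


def delta_sas(
    ligand: AtomSet, protein: AtomSet, params: SasaParams = SasaParams()
) -> float:
    """Half the surface area buried on complex formation, A^2."""
    ligand_sasa = sasa(ligand, params)
    protein_sasa = sasa(protein, params)
    complex_sasa = sasa(ligand.union(protein), params)
    return (ligand_sasa + protein_sasa - complex_sasa) / 2.0


# ---------------------------------------------------------------------------
# Structure I/O


def load_structure(
    path: str | Path,
    format: Optional[str] = None,
    *,
    strip_waters: bool = False,
    keep_hydrogens: bool = True,
) -> AtomSet:
    """Read an AtomSet from a PDB or MOL2 file; radii from the Bondi table."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format == "pdb":
        atoms = _load_pdb(path, strip_waters=strip_waters)
    elif format == "mol2":
        atoms = _load_mol2(path)
    else:
        raise ValueError(f"unsupported structure format {format!r}")
    if not keep_hydrogens:
        atoms = atoms.without_hydrogens()
    return atoms


def _load_pdb(path: Path, *, strip_waters: bool) -> AtomSet:
    import warnings

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    elements, coords = [], []
    for atom in structure.get_atoms():
        resname = atom.get_parent().get_resname().strip().upper()
        if strip_waters and resname in _WATER_RESNAMES:
            continue
        element = (atom.element or "").strip()
        if not element:  # fall back to the first letter of the atom name
            element = atom.get_name().strip()[0]
        elements.append(element)
        coords.append(atom.get_coord())
    if not elements:
        raise ValueError(f"{path}: no atoms")
    return AtomSet.from_elements(elements, np.array(coords, dtype=float))


def _load_mol2(path: Path) -> AtomSet:
    from rdkit import Chem

    mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    if mol is None or mol.GetNumConformers() == 0:
        raise ValueError(f"{path}: unparsable MOL2 structure")
    conf = mol.GetConformer()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = conf.GetPositions()
    return AtomSet.from_elements(elements, coords)


def write_pdb(atoms: AtomSet, path: str | Path, *, resname: str = "LIG") -> None:
    """Minimal single-residue PDB writer for fixtures."""
    with open(path, "w") as fh:
        for i, (el, xyz) in enumerate(zip(atoms.elements, atoms.coords), 1):
            name = el.upper()[:4]
            fh.write(
                f"HETATM{i:>5} {name:<4}{resname:<4}A{1:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {el.upper():>2}\n"
            )
        fh.write("END\n")
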