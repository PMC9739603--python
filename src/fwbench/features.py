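"""Ligand reading, sanitization patches, and fragment counting.

Interaction-motif fragments are defined as SMARTS patterns (shipped as a
plain-text table, treated as data).  Counting collapses symmetry-duplicate
atom orderings, so each distinct fragment instance is counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

INTERACTION_CLASSES = frozenset(
    {"hydrogen-bond", "hydrophobic", "aromatic", "ionic", "halogen"}
)

SANITIZE_RULES = ("phosphate", "sulfate", "amidine")


@dataclass(frozen=True)
class FeatureDefinition:
    """One named interaction-motif fragment with its SMARTS pattern."""

    name: str
    smarts: str
    interaction_class: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be non-empty")
        if self.interaction_class not in INTERACTION_CLASSES:
            raise ValueError(
                f"unknown interaction class {self.interaction_class!r}"
            )
        if Chem.MolFromSmarts(self.smarts) is None:
            raise ValueError(f"invalid SMARTS for {self.name!r}: {self.smarts!r}")

    @property
    def query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.smarts)


@dataclass
class LigandRecord:
    """A parsed ligand: identifier plus an RDKit connection table."""

    id: str
    molecule: Chem.Mol
    source_format: str = "smiles"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ligand id must be non-empty")
        if self.molecule is None:
            raise ValueError(f"ligand {self.id!r} has no molecule")


@dataclass
class FeatureMatrix:
    """Ligands x features table of non-negative integer fragment counts."""

    ligand_ids: list[str]
    feature_names: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.ligand_ids), len(self.feature_names)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.ligand_ids)} ligands x {len(self.feature_names)} features"
            )
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise ValueError("duplicate ligand ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("non-integer counts")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.counts[:, j]

    def occurrence(self, name: str) -> int:
        """Number of ligands containing the fragment at least once."""
        return int(np.count_nonzero(self.column(name)))

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            ligand_ids=list(self.ligand_ids),
            feature_names=list(names),
            counts=self.counts[:, idx].copy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ligand_id\t" + "\t".join(self.feature_names) + "\n")
            for lid, row in zip(self.ligand_ids, self.counts):
                fh.write(lid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 2:
                raise ValueError(f"{path}: expected id column plus features")
            ids, rows = [], []
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([int(v) for v in parts[1:]])
        return cls(ligand_ids=ids, feature_names=header[1:],
                   counts=np.array(rows, dtype=np.int64))


def load_feature_definitions(path: str | Path) -> list[FeatureDefinition]:
    """Read feature definitions from a TSV table (name, smarts, class)."""
    defs: list[FeatureDefinition] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["name", "smarts", "interaction_class"]
        if header[:3] != required:
            raise ValueError(f"{path}: header must start with {required}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, smarts, klass = line.rstrip("\n").split("\t")[:3]
            defs.append(FeatureDefinition(name, smarts, klass))
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in definition file")
    return defs


def default_features() -> list[FeatureDefinition]:
    """The versioned default fragment set shipped with the package."""
    ref = resources.files("fwbench").joinpath("data/features_default.tsv")
    with resources.as_file(ref) as path:
        return load_feature_definitions(path)


# ---------------------------------------------------------------------------
# Ligand input


def _iter_mol2_blocks(text: str) -> Iterable[str]:
    marker = "@<TRIPOS>MOLECULE"
    chunks = text.split(marker)
    for chunk in chunks[1:]:
        yield marker + chunk


def load_ligands(
    path: str | Path, format: str
) -> tuple[list[LigandRecord], list[tuple[str, str]]]:
    """Read ligands from a SMILES, SDF, or MOL2 file.

    Returns ``(records, failures)`` where *failures* lists ``(id, reason)``
    for entries that could not be parsed.  Order is preserved and parse
    failures never raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    format = format.lower()
    records: list[LigandRecord] = []
    failures: list[tuple[str, str]] = []

    RDLogger.DisableLog("rdApp.error")
    try:
        if format == "smiles":
            with open(path) as fh:
                lines = [ln.strip() for ln in fh if ln.strip()]
            if not lines:
                raise ValueError(f"{path}: empty SMILES file")
            for i, line in enumerate(lines):
                parts = line.split()
                smiles = parts[0]
                lid = parts[1] if len(parts) > 1 else f"mol{i + 1}"
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    failures.append((lid, f"unparsable SMILES {smiles!r}"))
                else:
                    records.append(LigandRecord(lid, mol, "smiles"))
        elif format == "sdf":
            supplier = Chem.SDMolSupplier(str(path), removeHs=False)
            if len(supplier) == 0:
                raise ValueError(f"{path}: empty SDF file")
            for i, mol in enumerate(supplier):
                if mol is None:
                    failures.append((f"entry{i + 1}", "unparsable SDF record"))
                    continue
                lid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
                records.append(LigandRecord(lid or f"entry{i + 1}", mol, "sdf"))
        elif format == "mol2":
            text = path.read_text()
            blocks = list(_iter_mol2_blocks(text))
            if not blocks:
                raise ValueError(f"{path}: no MOL2 molecule records")
            for i, block in enumerate(blocks):
                name_line = block.splitlines()[1].strip() if len(
                    block.splitlines()) > 1 else ""
                lid = name_line or f"entry{i + 1}"
                mol = Chem.MolFromMol2Block(block, removeHs=False)
                if mol is None:
                    failures.append((lid, "unparsable MOL2 record"))
                else:
                    records.append(LigandRecord(lid, mol, "mol2"))
        else:
            raise ValueError(f"unsupported ligand format {format!r}")
    finally:
        RDLogger.EnableLog("rdApp.error")

    for lid, reason in failures:
        logger.warning("dropped ligand %s: %s", lid, reason)
    return records, failures


# ---------------------------------------------------------------------------
# Sanitization patches
#
# Upstream toolchains sometimes mis-perceive delocalized charges: terminal
# oxygens on phosphate/sulfate groups, and protonated amidines drawn as
# carbocations.  Each rule canonicalizes one such motif; total formal charge
# of the molecule is preserved.


_MAX_DOUBLE_OXO = {"P": 1, "S": 2}


def _fix_terminal_oxo(mol: Chem.RWMol, center_symbol: str) -> bool:
    """Canonicalize terminal oxygens on P or S centers.

    Among H-free terminal oxygens (degree 1, no hydrogens) the number of
    double bonds is set to ``t + q`` — *t* their count, *q* the total formal
    charge of the center plus those oxygens — capped at one P=O / two S=O;
    the remainder become single-bonded O(-1).  Within the cap the group
    charge is preserved; when the input encodes more double-bonded oxygens
    than the center allows (the delocalized-charge mis-perception), the
    extras are demoted to anionic oxygens, which restores the missing
    negative charge.  That is the one documented charge correction.
    """
    changed = False
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != center_symbol:
            continue
        terminal = [
            nb for nb in atom.GetNeighbors()
            if nb.GetSymbol() == "O" and nb.GetDegree() == 1
            and nb.GetTotalNumHs() == 0
        ]
        if len(terminal) < 2:
            continue
        q = atom.GetFormalCharge() + sum(o.GetFormalCharge() for o in terminal)
        n_double = len(terminal) + q
        n_double = max(0, min(len(terminal), n_double,
                              _MAX_DOUBLE_OXO[center_symbol]))
        want = ([Chem.BondType.DOUBLE] * n_double
                + [Chem.BondType.SINGLE] * (len(terminal) - n_double))
        # deterministic order: by atom index
        terminal = sorted(terminal, key=lambda a: a.GetIdx())
        for o, btype in zip(terminal, want):
            bond = mol.GetBondBetweenAtoms(atom.GetIdx(), o.GetIdx())
            charge = 0 if btype is Chem.BondType.DOUBLE else -1
            if bond.GetBondType() is not btype or o.GetFormalCharge() != charge:
                bond.SetBondType(btype)
                o.SetFormalCharge(charge)
                changed = True
        if atom.GetFormalCharge() != 0:
            atom.SetFormalCharge(0)
            changed = True
    return changed


_AMIDINE_MISASSIGNED = Chem.MolFromSmarts("[C+;X3](-[N;X3])-[N;X3]")


def _fix_amidine(mol: Chem.RWMol) -> bool:
    """Convert carbocation-form amidines to the N-protonated canonical form."""
    changed = False
    for match in mol.GetSubstructMatches(_AMIDINE_MISASSIGNED):
        c_idx, n1_idx, _ = match
        carbon = mol.GetAtomWithIdx(c_idx)
        if carbon.GetFormalCharge() != 1:
            continue  # already fixed via an overlapping match
        nitrogen = mol.GetAtomWithIdx(n1_idx)
        bond = mol.GetBondBetweenAtoms(c_idx, n1_idx)
        bond.SetBondType(Chem.BondType.DOUBLE)
        nitrogen.SetFormalCharge(1)
        nitrogen.SetNoImplicit(False)
        carbon.SetFormalCharge(0)
        changed = True
    return changed


def sanitize_ligand(
    rec: LigandRecord, rules: Sequence[str] = SANITIZE_RULES
) -> LigandRecord:
    """Apply charge/bond-order patch rules; idempotent by construction."""
    for rule in rules:
        if rule not in SANITIZE_RULES:
            raise ValueError(f"unknown sanitize rule {rule!r}")
    mol = Chem.RWMol(rec.molecule)
    changed = False
    if "phosphate" in rules:
        changed |= _fix_terminal_oxo(mol, "P")
    if "sulfate" in rules:
        changed |= _fix_terminal_oxo(mol, "S")
    if "amidine" in rules:
        changed |= _fix_amidine(mol)
    if not changed:
        return rec
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return replace(rec, molecule=out)


# ---------------------------------------------------------------------------
# Counting


def count_feature(rec: LigandRecord, fd: FeatureDefinition) -> int:
    """Number of distinct atom-set matches of the fragment in the ligand.

    Symmetry-duplicate atom orderings of the same atom set are collapsed,
    so a whole-ring pattern counts each ring once.
    """
    query = fd.query
    if query is None:
        raise ValueError(f"invalid SMARTS {fd.smarts!r}")
    matches = rec.molecule.GetSubstructMatches(query, uniquify=True)
    distinct = {frozenset(m) for m in matches}
    return len(distinct)


def build_feature_table(
    recs: Sequence[LigandRecord], fds: Sequence[FeatureDefinition]
) -> FeatureMatrix:
    """Count every fragment in every ligand; the Free-Wilson count matrix."""
    if not recs:
        raise ValueError("no ligands")
    if not fds:
        raise ValueError("no feature definitions")
    ids = [r.id for r in recs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ligand ids")
    names = [f.name for f in fds]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    counts = np.zeros((len(recs), len(fds)), dtype=np.int64)
    for i, rec in enumerate(recs):
        for j, fd in enumerate(fds):
            counts[i, j] = count_feature(rec, fd)
    return FeatureMatrix(ligand_ids=ids, feature_names=names, counts=counts)
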