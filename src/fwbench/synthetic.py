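"""Synthetic datasets with known ground truth.

Fragment-count matrices follow a zero-inflated shifted Poisson: feature j
is present in a ligand with probability ``occurrence_prob`` and, when
present, counts are ``1 + Poisson(count_mean - 1)``.  Affinities are a
sparse linear model over *standardized* features plus Gaussian noise; SF
scores are a linear transform of true affinity distorted by per-feature
bias terms acting on *raw* counts plus noise.  Because biases act on raw
counts, the correction recovered by the combined model on standardized
features is ``-bias_j * sd_j`` in expectation.

All generators are pure functions of their parameters and one integer
seed; each generator draws from its own named substream so that datasets
stay reproducible when unrelated parameters change.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from fwbench.features import FeatureMatrix
from fwbench.sasa import AtomSet

DEFAULT_N_LIGANDS = 273  # size of the study this emulates


@dataclass(frozen=True)
class FeatureSpec:
    """Occurrence statistics for one synthetic fragment feature."""

    name: str
    occurrence_prob: float
    count_mean: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occurrence_prob <= 1.0:
            raise ValueError(f"occurrence_prob out of [0,1]: {self.occurrence_prob}")
        if self.count_mean <= 0.0:
            raise ValueError(f"count_mean must be > 0: {self.count_mean}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters behind a synthetic dataset."""

    true_coefficients: Mapping[str, float]
    intercept: float
    affinity_noise_sd: float
    sf_slope: float
    sf_offset: float
    sf_biases: Mapping[str, float]
    sf_noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.affinity_noise_sd < 0 or self.sf_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")


def default_feature_specs() -> list[FeatureSpec]:
    """Ten features shaped like a post-exclusion interaction-motif set."""
    return [
        FeatureSpec("HBD1", 0.90, 3.0),
        FeatureSpec("HBA", 0.95, 4.0),
        FeatureSpec("HP1", 0.85, 5.0),
        FeatureSpec("HP2", 0.30, 1.5),
        FeatureSpec("HP3", 0.05, 1.2),
        FeatureSpec("PIPI", 0.70, 2.0),
        FeatureSpec("PICat", 0.15, 1.2),
        FeatureSpec("SaltBridge", 0.25, 1.3),
        FeatureSpec("Hal", 0.15, 1.5),
        FeatureSpec("F", 0.20, 2.0),
    ]


def default_truth(seed: int = 0) -> SyntheticTruth:
    return SyntheticTruth(
        true_coefficients={
            "HP1": 0.60, "PIPI": 0.45, "HP2": 0.20, "HP3": -0.15,
            "PICat": -0.20, "SaltBridge": -0.15, "Hal": 0.15, "F": 0.25,
            "HBD1": 0.05, "HBA": 0.05,
        },
        intercept=6.0,
        affinity_noise_sd=0.5,
        sf_slope=1.0,
        sf_offset=0.0,
        sf_biases={},
        sf_noise_sd=0.3,
        seed=seed,
    )


def _rng(seed: int, label: str) -> np.random.Generator:
    """Named substream: independent generator per (seed, label)."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(key,)))


def gen_feature_matrix(
    n_ligands: int, specs: Sequence[FeatureSpec], seed: int
) -> FeatureMatrix:
    """Zero-inflated shifted-Poisson count matrix with per-feature stats."""
    if n_ligands < 1:
        raise ValueError("n_ligands must be >= 1")
    if not specs:
        raise ValueError("empty feature specs")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    rng = _rng(seed, "feature_matrix")
    counts = np.zeros((n_ligands, len(specs)), dtype=np.int64)
    for j, spec in enumerate(specs):
        present = rng.random(n_ligands) < spec.occurrence_prob
        lam = max(spec.count_mean - 1.0, 0.0)
        counts[:, j] = present * (1 + rng.poisson(lam, size=n_ligands))
    width = len(str(n_ligands))
    ids = [f"L{i + 1:0{width}d}" for i in range(n_ligands)]
    return FeatureMatrix(ligand_ids=ids, feature_names=names, counts=counts)


def _standardized_columns(fm: FeatureMatrix, names: Sequence[str]) -> np.ndarray:
    x = np.column_stack([fm.column(n).astype(float) for n in names])
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    if np.any(sds == 0.0):
        bad = [n for n, s in zip(names, sds) if s == 0.0]
        raise ValueError(f"constant columns cannot carry a coefficient: {bad}")
    return (x - means) / sds


def gen_affinities(fm: FeatureMatrix, truth: SyntheticTruth) -> np.ndarray:
    """Reference affinities: linear in standardized features plus noise."""
    unknown = set(truth.true_coefficients) - set(fm.feature_names)
    if unknown:
        raise KeyError(f"unknown feature keys in truth: {sorted(unknown)}")
    names = [n for n in fm.feature_names if n in truth.true_coefficients]
    pk = np.full(fm.n_ligands, truth.intercept, dtype=float)
    if names:
        z = _standardized_columns(fm, names)
        coef = np.array([truth.true_coefficients[n] for n in names])
        pk = pk + z @ coef
    if truth.affinity_noise_sd > 0:
        rng = _rng(truth.seed, "affinities")
        pk = pk + rng.normal(0.0, truth.affinity_noise_sd, size=fm.n_ligands)
    return pk


def gen_sf_scores(
    fm: FeatureMatrix, pk_ref: np.ndarray, truth: SyntheticTruth
) -> np.ndarray:
    """Biased SF scores: affine in pk_ref plus raw-count bias terms and noise."""
    pk_ref = np.asarray(pk_ref, dtype=float)
    if pk_ref.shape != (fm.n_ligands,):
        raise ValueError(
            f"length mismatch: {pk_ref.shape} vs {fm.n_ligands} ligands")
    unknown = set(truth.sf_biases) - set(fm.feature_names)
    if unknown:
        raise KeyError(f"unknown bias keys: {sorted(unknown)}")
    pk_sf = truth.sf_offset + truth.sf_slope * pk_ref
    for name, delta in truth.sf_biases.items():
        pk_sf = pk_sf + delta * fm.column(name).astype(float)
    if truth.sf_noise_sd > 0:
        rng = _rng(truth.seed, "sf_scores")
        pk_sf = pk_sf + rng.normal(0.0, truth.sf_noise_sd, size=fm.n_ligands)
    return pk_sf


# ---------------------------------------------------------------------------
# Fixture molecules
#
# Expected counts are fixed by construction against the default fragment
# set; molecules were chosen so each count can be read off the structure.

_ALL_FEATURES = ("HBD1", "HBD2", "HBA", "HP1", "HP2", "HP3", "PIPI",
                 "PICat", "SaltBridge", "Hal", "F")


@dataclass(frozen=True)
class ToyLigand:
    id: str
    smiles: str
    expected_counts: Mapping[str, int]


def _toy(id_: str, smiles: str, **nonzero: int) -> ToyLigand:
    counts = {name: 0 for name in _ALL_FEATURES}
    counts.update(nonzero)
    return ToyLigand(id_, smiles, counts)


def gen_toy_ligands() -> list[ToyLigand]:
    """Fixed fixture molecules with hand-derived per-feature counts."""
    return [
        _toy("CF4-like", "FC(F)(F)F", F=4),
        _toy("benzene", "c1ccccc1", PIPI=1),
        _toy("halobenzene", "Clc1ccccc1Br", PIPI=1, Hal=2),
        _toy("ethane", "CC", HP1=2),
        _toy("ethene", "C=C", HP2=1),
        _toy("ethyne", "C#C", HP3=1),
        _toy("ethanol", "CCO", HBD1=1, HBD2=1, HP1=1),
        _toy("acetate", "CC(=O)[O-]", HBA=2, HP1=1, SaltBridge=1),
        _toy("methylammonium", "C[NH3+]", HBD1=1, HBD2=1, PICat=1),
        _toy("pyridine", "c1ccncc1", HBA=1, PIPI=1),
        _toy("methanol", "CO", HBD1=1, HBD2=1),
        _toy("acetamidinium", "CC(=[NH2+])N", HBD1=2, HBD2=2, HP1=1, PICat=1),
        _toy("hexane", "CCCCCC", HP1=6),
        _toy("butadiene", "C=CC=C", HP2=2),
        _toy("dimethyl-ether", "COC", HBA=1),
        _toy("cyclohexane", "C1CCCCC1", HP1=6),
    ]


def write_toy_smiles(path: str | Path) -> None:
    with open(path, "w") as fh:
        for lig in gen_toy_ligands():
            fh.write(f"{lig.smiles}\t{lig.id}\n")


# ---------------------------------------------------------------------------
# Toy 3D complexes for the buried-surface score

TOY_COMPLEX_KINDS = ("distant_pair", "buried_ligand", "overlap_pair")


def gen_toy_complex(kind: str) -> tuple[AtomSet, AtomSet]:
    """Deterministic (ligand, protein) atom pairs with known geometry.

    distant_pair: separation exceeds the sum of solvent-extended radii.
    buried_ligand: ligand atom strictly inside a much larger sphere.
    overlap_pair: partial overlap of the two extended spheres.
    """
    if kind == "distant_pair":
        ligand = AtomSet(["C"], np.array([[0.0, 0.0, 0.0]]), np.array([1.7]))
        protein = AtomSet(["C"], np.array([[50.0, 0.0, 0.0]]), np.array([1.7]))
    elif kind == "buried_ligand":
        ligand = AtomSet(["C"], np.array([[0.0, 0.0, 0.0]]), np.array([1.5]))
        protein = AtomSet(["X"], np.array([[0.0, 0.0, 0.0]]), np.array([10.0]))
    elif kind == "overlap_pair":
        ligand = AtomSet(["C"], np.array([[0.0, 0.0, 0.0]]), np.array([1.7]))
        protein = AtomSet(["O"], np.array([[2.0, 0.0, 0.0]]), np.array([1.52]))
    else:
        raise ValueError(f"unknown toy complex kind {kind!r}")
    return ligand, protein


# ---------------------------------------------------------------------------
# Dataset bundling


@dataclass
class SyntheticDataset:
    feature_matrix: FeatureMatrix
    pk_ref: np.ndarray
    sf_scores: dict[str, np.ndarray]
    truths: dict[str, SyntheticTruth]

    def write_scores(self, path: str | Path) -> None:
        names = sorted(self.sf_scores)
        with open(path, "w") as fh:
            fh.write("id\tpk_ref\t" + "\t".join(names) + "\n")
            for i, lid in enumerate(self.feature_matrix.ligand_ids):
                row = [lid, f"{self.pk_ref[i]:.6f}"]
                row += [f"{self.sf_scores[n][i]:.6f}" for n in names]
                fh.write("\t".join(row) + "\n")


def gen_dataset(
    n_ligands: int = DEFAULT_N_LIGANDS,
    seed: int = 0,
    *,
    specs: Optional[Sequence[FeatureSpec]] = None,
    bias_feature: str = "HP1",
    bias: float = -0.4,
) -> SyntheticDataset:
    """A full synthetic study: one well-calibrated SF and one biased SF."""
    specs = list(specs) if specs is not None else default_feature_specs()
    fm = gen_feature_matrix(n_ligands, specs, seed)
    base = default_truth(seed)
    truth_good = SyntheticTruth(
        true_coefficients=base.true_coefficients,
        intercept=base.intercept,
        affinity_noise_sd=base.affinity_noise_sd,
        sf_slope=1.0, sf_offset=0.2, sf_biases={}, sf_noise_sd=0.3,
        seed=seed,
    )
    truth_biased = SyntheticTruth(
        true_coefficients=base.true_coefficients,
        intercept=base.intercept,
        affinity_noise_sd=base.affinity_noise_sd,
        sf_slope=1.0, sf_offset=0.0,
        sf_biases={bias_feature: bias}, sf_noise_sd=0.3,
        seed=seed + 1,
    )
    pk_ref = gen_affinities(fm, truth_good)
    sf_good = gen_sf_scores(fm, pk_ref, truth_good)
    sf_biased = gen_sf_scores(fm, pk_ref, truth_biased)
    return SyntheticDataset(
        feature_matrix=fm,
        pk_ref=pk_ref,
        sf_scores={"SF_good": sf_good, "SF_biased": sf_biased},
        truths={"SF_good": truth_good, "SF_biased": truth_biased},
    )
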