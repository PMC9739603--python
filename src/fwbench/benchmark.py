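"""Scoring-power evaluation and the three fragment-regression schemes.

scheme_ref   : experimental pK regressed on standardized fragment features.
scheme_sf    : an SF's predicted pK regressed on the same features.
scheme_combined : experimental pK regressed on the features PLUS the raw
    (unstandardized) SF prediction column; a coefficient near 1 on the SF
    column with small feature coefficients indicates a well-calibrated SF,
    while large feature coefficients are the corrections the SF needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from fwbench.features import FeatureMatrix
from fwbench.regression import (
    ExclusionRecord,
    LassoPath,
    StandardizedMatrix,
    correlation_filter,
    default_lambda_grid,
    fit_linear,
    lasso_path,
    standardize,
)

logger = logging.getLogger(__name__)

SF_COLUMN = "pK_SF"


@dataclass
class ScoreTable:
    """Per-complex experimental pK plus one score column per SF."""

    complex_ids: list[str]
    pk_ref: np.ndarray
    sf_scores: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.pk_ref = np.asarray(self.pk_ref, dtype=float)
        n = len(self.complex_ids)
        if len(set(self.complex_ids)) != n:
            raise ValueError("duplicate complex ids")
        if self.pk_ref.shape != (n,):
            raise ValueError("pk_ref length mismatch")
        for name, col in self.sf_scores.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (n,):
                raise ValueError(f"score column {name!r} length mismatch")
            self.sf_scores[name] = col

    @property
    def sf_names(self) -> list[str]:
        return list(self.sf_scores)

    def subset(self, ids: Sequence[str]) -> "ScoreTable":
        index = {cid: i for i, cid in enumerate(self.complex_ids)}
        rows = [index[c] for c in ids]
        return ScoreTable(
            complex_ids=list(ids),
            pk_ref=self.pk_ref[rows],
            sf_scores={k: v[rows] for k, v in self.sf_scores.items()},
        )

    @classmethod
    def from_file(
        cls, path: str | Path, *, negate: Sequence[str] = ()
    ) -> "ScoreTable":
        """Read a delimited score table (header: id, pk_ref, one col per SF).

        ``negate`` lists SF columns whose sign must be flipped at ingestion
        so that larger always means stronger predicted binding (e.g. raw
        DSX scores).  Rows with any missing value are dropped listwise.
        """
        df = pd.read_csv(path, sep=None, engine="python")
        cols = list(df.columns)
        if len(cols) < 2 or cols[0] != "id" or cols[1] != "pk_ref":
            raise ValueError(
                f"{path}: header must be 'id', 'pk_ref', then SF columns")
        n_before = len(df)
        df = df.dropna()
        if len(df) < n_before:
            logger.warning("dropped %d rows with missing values",
                           n_before - len(df))
        if df.empty:
            raise ValueError(f"{path}: no complete rows")
        sf_scores = {}
        for name in cols[2:]:
            col = df[name].to_numpy(dtype=float)
            sf_scores[name] = -col if name in negate else col
        return cls(
            complex_ids=[str(v) for v in df["id"]],
            pk_ref=df["pk_ref"].to_numpy(dtype=float),
            sf_scores=sf_scores,
        )


# ---------------------------------------------------------------------------
# Schemes


def _check_alignment(z: StandardizedMatrix, *vectors: np.ndarray) -> None:
    for v in vectors:
        if np.asarray(v).shape != (z.n_rows,):
            raise ValueError(
                f"row alignment failure: matrix has {z.n_rows} rows, "
                f"vector has shape {np.asarray(v).shape}")


def scheme_ref(
    Z: StandardizedMatrix, pk_ref, lambdas: Sequence[float]
) -> LassoPath:
    """Lasso path of experimental pK on standardized features."""
    _check_alignment(Z, pk_ref)
    return lasso_path(Z.values, pk_ref, lambdas,
                      feature_names=Z.feature_names)


def scheme_sf(
    Z: StandardizedMatrix, pk_sf, lambdas: Sequence[float]
) -> LassoPath:
    """Lasso path of an SF's predictions on standardized features."""
    _check_alignment(Z, pk_sf)
    return lasso_path(Z.values, pk_sf, lambdas,
                      feature_names=Z.feature_names)


def scheme_combined(
    Z: StandardizedMatrix,
    pk_sf,
    pk_ref,
    lambdas: Sequence[float],
    *,
    penalize_sf: bool = True,
) -> LassoPath:
    """Lasso path of experimental pK on features plus the raw SF column.

    The SF prediction column enters unstandardized.  Each fit's
    ``sf_coefficient`` holds the coefficient on that column; by default it
    is subject to the l1 penalty like the feature coefficients.
    """
    _check_alignment(Z, pk_sf, pk_ref)
    pk_sf = np.asarray(pk_sf, dtype=float)
    X = np.hstack([Z.values, pk_sf[:, None]])
    names = [*Z.feature_names, SF_COLUMN]
    flags = [True] * len(Z.feature_names) + [penalize_sf]
    path = lasso_path(X, pk_ref, lambdas, flags, feature_names=names)
    for fit in path.fits:
        fit.sf_coefficient = fit.coefficients.pop(SF_COLUMN)
    return path


def scoring_power(score_table: ScoreTable, sf_name: str) -> tuple[float, float]:
    """(r2, sd) of the linear fit of experimental pK on the SF's scores."""
    if sf_name not in score_table.sf_scores:
        raise KeyError(f"unknown scoring function {sf_name!r}")
    _, _, r2, sd = fit_linear(score_table.sf_scores[sf_name],
                              score_table.pk_ref)
    return r2, sd


def pk_delta_to_fold(delta_pk: float) -> float:
    """Fold-change in Kd/Ki equivalent to a pK difference."""
    return float(10.0 ** delta_pk)


# ---------------------------------------------------------------------------
# Full report


@dataclass
class SfSection:
    name: str
    scoring_r2: float
    scoring_sd: float
    sf_path: LassoPath
    combined_path: LassoPath


@dataclass
class BenchmarkReport:
    complex_ids: list[str]
    feature_names: list[str]  # survivors of the correlation filter
    exclusions: list[ExclusionRecord]
    lambdas: list[float]
    ref_path: LassoPath
    sf_sections: dict[str, SfSection]

    def feature_importance(self) -> list[tuple[str, float]]:
        """Features ranked by |coefficient| in the smallest-lambda ref fit."""
        fit = self.ref_path.fits[0]
        ranked = sorted(fit.coefficients.items(),
                        key=lambda kv: (-abs(kv[1]), kv[0]))
        return [(k, v) for k, v in ranked]

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def _path(name: str) -> Path:
            p = outdir / name
            written.append(p)
            return p

        with open(_path("exclusions.tsv"), "w") as fh:
            fh.write("dropped\tkept\tr\treason\n")
            for rec in self.exclusions:
                kept = rec.kept if rec.kept is not None else "-"
                fh.write(f"{rec.dropped}\t{kept}\t{rec.r:.6f}\t{rec.reason}\n")

        with open(_path("scoring_power.tsv"), "w") as fh:
            fh.write("sf\tr2\tsd\n")
            for name, sec in self.sf_sections.items():
                fh.write(f"{name}\t{sec.scoring_r2:.6f}\t{sec.scoring_sd:.6f}\n")

        self.ref_path.to_tsv(_path("scheme_ref.tsv"), self.feature_names)
        for name, sec in self.sf_sections.items():
            sec.sf_path.to_tsv(_path(f"scheme_sf_{name}.tsv"),
                               self.feature_names)
            combined = _path(f"scheme_combined_{name}.tsv")
            with open(combined, "w") as fh:
                cols = ["lambda", "intercept", "beta_SF",
                        *self.feature_names, "r2", "sd"]
                fh.write("\t".join(cols) + "\n")
                for lam, fit in zip(sec.combined_path.lambdas,
                                    sec.combined_path.fits):
                    row = [f"{lam:.10g}", f"{fit.intercept:.10g}",
                           f"{fit.sf_coefficient:.10g}"]
                    row += [f"{fit.coefficients.get(n, 0.0):.10g}"
                            for n in self.feature_names]
                    row += [f"{fit.r2:.10g}", f"{fit.sd:.10g}"]
                    fh.write("\t".join(row) + "\n")

        with open(_path("summary.txt"), "w") as fh:
            fh.write(f"complexes used: {len(self.complex_ids)}\n")
            fh.write(f"features kept: {', '.join(self.feature_names)}\n")
            fh.write(f"lambda grid: {', '.join(f'{l:.6g}' for l in self.lambdas)}\n")
            fh.write("\nfeature importance (smallest lambda):\n")
            for name, coef in self.feature_importance():
                fh.write(f"  {name}\t{coef:+.4f}\n")
            fh.write("\nscoring power and combined-model fit:\n")
            for name, sec in self.sf_sections.items():
                combined_r2 = sec.combined_path.fits[0].r2
                beta_sf = sec.combined_path.fits[0].sf_coefficient
                fh.write(
                    f"  {name}\tscoring r2={sec.scoring_r2:.4f} "
                    f"sd={sec.scoring_sd:.4f}\tcombined r2={combined_r2:.4f} "
                    f"beta_SF={beta_sf:.4f}\n")
        return written


def build_report(
    fm: FeatureMatrix,
    score_table: ScoreTable,
    lambdas: Optional[Sequence[float]] = None,
    *,
    threshold: float = 0.9,
    centered: bool = False,
    penalize_sf: bool = True,
) -> BenchmarkReport:
    """Run the full pipeline: filter, standardize, all schemes, all SFs."""
    common = [cid for cid in fm.ligand_ids if cid in set(score_table.complex_ids)]
    missing = [cid for cid in score_table.complex_ids
               if cid not in set(fm.ligand_ids)]
    if missing:
        logger.warning("ids in scores but not in ligands (dropped): %s",
                       ", ".join(missing))
    if not common:
        raise ValueError("no complexes shared between features and scores")
    if len(common) < fm.n_ligands:
        logger.warning("using %d of %d ligands with scores",
                       len(common), fm.n_ligands)
    row_idx = [fm.ligand_ids.index(c) for c in common]
    fm = FeatureMatrix(
        ligand_ids=common,
        feature_names=list(fm.feature_names),
        counts=fm.counts[row_idx],
    )
    scores = score_table.subset(common)

    filtered, exclusions = correlation_filter(fm, threshold, centered=centered)
    for rec in exclusions:
        logger.info("excluded feature %s (%s, r=%.3f)",
                    rec.dropped, rec.reason, rec.r)
    Z = standardize(filtered)

    if lambdas is None:
        lambdas = default_lambda_grid(Z.values, scores.pk_ref)
    lambdas = [float(l) for l in lambdas]

    ref_path = scheme_ref(Z, scores.pk_ref, lambdas)
    sections: dict[str, SfSection] = {}
    for name in scores.sf_names:
        r2, sd = scoring_power(scores, name)
        sections[name] = SfSection(
            name=name,
            scoring_r2=r2,
            scoring_sd=sd,
            sf_path=scheme_sf(Z, scores.sf_scores[name], lambdas),
            combined_path=scheme_combined(
                Z, scores.sf_scores[name], scores.pk_ref, lambdas,
                penalize_sf=penalize_sf),
        )
    return BenchmarkReport(
        complex_ids=common,
        feature_names=list(filtered.feature_names),
        exclusions=exclusions,
        lambdas=lambdas,
        ref_path=ref_path,
        sf_sections=sections,
    )
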