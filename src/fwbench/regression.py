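"""Correlation filtering, standardization, and the Lasso estimator.

The inter-feature "correlation" here is the uncentered cosine
r = a.b / (|a| |b|) on raw count vectors, deliberately not Pearson; a
Pearson variant is available behind a flag for sensitivity analysis.

The Lasso objective carries an explicit 1/N factor on the squared loss,

    min_(b0, b)  (1/N) ||y - b0*1 - X b||_2^2 + lambda ||b||_1,

so lambda here equals twice the ``alpha`` of solvers using the common
1/(2N) convention.  The solver is cyclic coordinate descent with
covariance updates; the intercept is never penalized and individual
columns can be exempted from the l1 term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from fwbench.features import FeatureMatrix

_DEFAULT_TOL = 1e-8
_DEFAULT_MAX_ITER = 100_000


# ---------------------------------------------------------------------------
# Correlation


def cosine_correlation(a, b, *, centered: bool = False) -> float:
    """Uncentered cosine similarity of two feature vectors.

    With ``centered=True`` this becomes the Pearson correlation instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if centered:
        a = a - a.mean()
        b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm vector has no defined correlation")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass(frozen=True)
class ExclusionRecord:
    """One feature dropped during correlation filtering."""

    dropped: str
    kept: Optional[str]  # None when dropped for being all-zero
    r: float
    reason: str  # "correlated" | "all_zero"


def correlation_filter(
    fm: FeatureMatrix,
    threshold: float = 0.9,
    *,
    centered: bool = False,
) -> tuple[FeatureMatrix, list[ExclusionRecord]]:
    """Drop features until no pair correlates above *threshold*.

    All-zero columns are removed first (reported).  Then, repeatedly, the
    worst remaining pair (largest r) loses the feature present in fewer
    molecules; on a tie the later column is dropped.  Deterministic given
    column order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if fm.n_features < 2:
        raise ValueError("need at least 2 features to filter")

    report: list[ExclusionRecord] = []
    names = list(fm.feature_names)
    for name in names[:]:
        if fm.occurrence(name) == 0:
            report.append(ExclusionRecord(name, None, float("nan"), "all_zero"))
            names.remove(name)

    def worst_pair(active: list[str]):
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                r = cosine_correlation(
                    fm.column(active[i]), fm.column(active[j]),
                    centered=centered,
                )
                if r > threshold and (best is None or r > best[2]):
                    best = (active[i], active[j], r)
        return best

    while len(names) >= 2:
        pair = worst_pair(names)
        if pair is None:
            break
        a, b, r = pair
        occ_a, occ_b = fm.occurrence(a), fm.occurrence(b)
        # keep the feature present in more molecules; tie -> keep earlier
        if occ_a >= occ_b:
            kept, dropped = a, b
        else:
            kept, dropped = b, a
        report.append(ExclusionRecord(dropped, kept, r, "correlated"))
        names.remove(dropped)

    return fm.select_features(names), report


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class StandardizedMatrix:
    """Column-standardized design with the transform stored for inversion."""

    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    feature_names: list[str]

    def inverse(self) -> np.ndarray:
        return self.values * self.sds + self.means

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def standardize(fm: FeatureMatrix) -> StandardizedMatrix:
    """Per-column standard scores, population sd (divisor N)."""
    x = fm.counts.astype(float)
    means = x.mean(axis=0)
    sds = x.std(axis=0)  # ddof=0, matching sklearn's StandardScaler
    bad = np.flatnonzero(sds == 0.0)
    if bad.size:
        offenders = [fm.feature_names[j] for j in bad]
        raise ValueError(f"constant columns cannot be standardized: {offenders}")
    return StandardizedMatrix(
        values=(x - means) / sds,
        means=means,
        sds=sds,
        feature_names=list(fm.feature_names),
    )


# ---------------------------------------------------------------------------
# Lasso


@dataclass
class LassoFit:
    lambda_: float
    intercept: float
    coefficients: dict[str, float]
    r2: float
    sd: float
    converged: bool
    n_iter: int
    sf_coefficient: Optional[float] = None
    r2_sse: float = field(default=float("nan"))

    def coef_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.coefficients[n] for n in names])

    @property
    def l1_norm(self) -> float:
        return float(sum(abs(v) for v in self.coefficients.values()))


@dataclass
class LassoPath:
    lambdas: list[float]
    fits: list[LassoFit]

    def __post_init__(self) -> None:
        if len(self.lambdas) != len(self.fits):
            raise ValueError("lambdas and fits length mismatch")

    def coefficient_trace(self, name: str) -> np.ndarray:
        return np.array([f.coefficients.get(name, 0.0) for f in self.fits])

    def to_tsv(self, path: str | Path, feature_names: Sequence[str]) -> None:
        with open(path, "w") as fh:
            cols = ["lambda", "intercept", *feature_names, "r2", "sd"]
            fh.write("\t".join(cols) + "\n")
            for lam, fit in zip(self.lambdas, self.fits):
                row = [f"{lam:.10g}", f"{fit.intercept:.10g}"]
                row += [f"{fit.coefficients.get(n, 0.0):.10g}"
                        for n in feature_names]
                row += [f"{fit.r2:.10g}", f"{fit.sd:.10g}"]
                fh.write("\t".join(row) + "\n")


def lambda_max(X, y) -> float:
    """Smallest lambda at which all penalized coefficients vanish.

    Equals (2/N) max_j |x_j^T (y - mean(y))| for the 1/N objective.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    return float(2.0 / n * np.max(np.abs(X.T @ (y - y.mean()))))


def _fit_stats(y: np.ndarray, fitted: np.ndarray, n_params: int = 2):
    resid = y - fitted
    dof = max(len(y) - n_params, 1)
    sd = float(np.sqrt(resid @ resid / dof))
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(resid @ resid)
    r2_sse = 1.0 - sse / sst if sst > 0 else 0.0
    if np.std(fitted) == 0.0 or np.std(y) == 0.0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return r2, sd, r2_sse


def fit_lasso(
    X,
    y,
    lambda_: float,
    penalize_flags: Optional[Sequence[bool]] = None,
    *,
    feature_names: Optional[Sequence[str]] = None,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
    warm_start: Optional[np.ndarray] = None,
) -> LassoFit:
    """Coordinate-descent solution of the 1/N-scaled Lasso objective.

    The intercept is never penalized; columns with ``penalize_flags[j]``
    False are excluded from the l1 term.  Convergence is declared when the
    largest coefficient change in a sweep falls below *tol*.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in design or response")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if penalize_flags is None:
        penalize_flags = [True] * p
    penalize_flags = list(penalize_flags)
    if len(penalize_flags) != p:
        raise ValueError("penalize_flags length mismatch")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    feature_names = list(feature_names)

    # center out the (unpenalized) intercept
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    gram = Xc.T @ Xc
    xty = Xc.T @ yc
    diag = np.diag(gram).copy()
    thresh = n * lambda_ / 2.0

    beta = (np.zeros(p) if warm_start is None
            else np.asarray(warm_start, dtype=float).copy())
    if beta.shape != (p,):
        raise ValueError("warm_start shape mismatch")

    converged = False
    n_iter = 0
    if lambda_ == 0.0 and all(penalize_flags):
        # unpenalized problem: solve the normal equations directly
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        converged = True
        n_iter = 1
    else:
        grad = gram @ beta  # maintained as gram . beta
        for sweep in range(max_iter):
            max_delta = 0.0
            for j in range(p):
                if diag[j] == 0.0:
                    continue
                rho = xty[j] - grad[j] + diag[j] * beta[j]
                if penalize_flags[j]:
                    # tiny relative slack so lambda >= lambda_max yields
                    # exact zeros despite rounding in the inner products
                    mag = abs(rho) - thresh
                    if mag <= 1e-10 * max(thresh, 1.0):
                        mag = 0.0
                    new = np.sign(rho) * mag / diag[j]
                else:
                    new = rho / diag[j]
                delta = new - beta[j]
                if delta != 0.0:
                    grad += gram[:, j] * delta
                    beta[j] = new
                    max_delta = max(max_delta, abs(delta))
            n_iter = sweep + 1
            if max_delta <= tol:
                converged = True
                break

    intercept = float(y_mean - x_mean @ beta)
    fitted = X @ beta + intercept
    r2, sd, r2_sse = _fit_stats(y, fitted, n_params=2)
    return LassoFit(
        lambda_=float(lambda_),
        intercept=intercept,
        coefficients={name: float(b) for name, b in zip(feature_names, beta)},
        r2=r2,
        sd=sd,
        converged=converged,
        n_iter=n_iter,
        r2_sse=r2_sse,
    )


def kkt_residual(
    X,
    y,
    fit: LassoFit,
    penalize_flags: Optional[Sequence[bool]] = None,
    *,
    feature_names: Optional[Sequence[str]] = None,
) -> float:
    """Largest violation of the Lasso stationarity conditions at *fit*.

    Independent of the solver: uses only the objective's subgradient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if penalize_flags is None:
        penalize_flags = [True] * p
    beta = fit.coef_array(feature_names)
    resid = y - fit.intercept - X @ beta
    grad = 2.0 / n * (X.T @ resid)  # = -d/d beta of the smooth part
    worst = abs(float(np.mean(resid))) * 2.0  # intercept stationarity
    for j in range(p):
        if not penalize_flags[j]:
            worst = max(worst, abs(grad[j]))
        elif beta[j] != 0.0:
            worst = max(worst, abs(grad[j] - fit.lambda_ * np.sign(beta[j])))
        else:
            worst = max(worst, max(abs(grad[j]) - fit.lambda_, 0.0))
    return worst


def lasso_path(
    X,
    y,
    lambdas: Sequence[float],
    penalize_flags: Optional[Sequence[bool]] = None,
    *,
    feature_names: Optional[Sequence[str]] = None,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
) -> LassoPath:
    """One fit per lambda, warm-started from the previous solution."""
    lambdas = [float(l) for l in lambdas]
    if any(l < 0 for l in lambdas):
        raise ValueError("lambdas must be >= 0")
    if any(b <= a for a, b in zip(lambdas, lambdas[1:])):
        raise ValueError("lambdas must be strictly increasing")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    fits: list[LassoFit] = []
    warm = np.zeros(p)
    for lam in lambdas:
        fit = fit_lasso(
            X, y, lam, penalize_flags,
            feature_names=feature_names, tol=tol, max_iter=max_iter,
            warm_start=warm,
        )
        warm = fit.coef_array(feature_names)
        fits.append(fit)
    return LassoPath(lambdas=lambdas, fits=fits)


def default_lambda_grid(X, y, n_points: int = 16, lo: float = 1e-3) -> list[float]:
    """Log-spaced grid from *lo* up to the data's lambda_max."""
    hi = lambda_max(X, y)
    if hi <= lo:
        hi = lo * 10.0
    return list(np.geomspace(lo, hi, n_points))


def fit_linear(x, y) -> tuple[float, float, float, float]:
    """OLS of y on x: returns (slope, intercept, r2, sd).

    r2 is the squared Pearson correlation; sd uses an N-2 denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0.0:
        raise ValueError("x is constant")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    resid = y - fitted
    sd = float(np.sqrt(resid @ resid / (len(x) - 2)))
    return float(res.slope), float(res.intercept), float(res.rvalue**2), sd
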