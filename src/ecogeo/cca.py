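"""Canonical correlation analysis between a climate block and a soil block.

Given standardized blocks X (n x p) and Y (n x q), CCA finds paired linear
combinations (canonical variates) u_k = X a_k, v_k = Y b_k maximizing
corr(u_k, v_k), each pair uncorrelated with the previous ones.  The canonical
correlations r_1 >= ... >= r_s (s = min(p, q)) are the singular values of

    K = Rxx^{-1/2} Rxy Ryy^{-1/2}

where Rxx, Ryy, Rxy are the sample correlation matrices; symmetric inverse
square roots come from eigendecompositions with a small eigenvalue floor.

Reported alongside: eigenvalues lambda_k = r_k^2 / (1 - r_k^2) and their
percentage shares lambda_k / sum(lambda); structure (loadings: correlation of
each original variable with its own block's variate) and cross-loadings
(correlation with the opposite block's variate); and the sequential
likelihood-ratio tests of "all correlations from k onward are zero" via
Wilks' Lambda with Bartlett's chi-square approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CCAResult",
    "standardize",
    "fit_cca",
    "eigen_proportions",
    "wilks_tests",
]

_EIG_FLOOR = 1e-10


def standardize(block: pd.DataFrame) -> pd.DataFrame:
    """Center to mean 0 and scale to sample standard deviation 1 (ddof=1)."""
    sd = block.std(ddof=1)
    dead = sd[(sd == 0) | sd.isna()].index.tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    return (block - block.mean()) / sd


def _inv_sqrt(mat: np.ndarray, ridge: float) -> tuple[np.ndarray, bool]:
    """Symmetric inverse square root; returns (matrix, was_deficient)."""
    m = mat.copy()
    if ridge > 0:
        m[np.diag_indices_from(m)] += ridge
    w, v = np.linalg.eigh(m)
    deficient = bool(np.any(w < _EIG_FLOOR))
    w = np.maximum(w, _EIG_FLOOR)
    return (v * (1.0 / np.sqrt(w))) @ v.T, deficient


def eigen_proportions(r: np.ndarray) -> np.ndarray:
    """Percentage of explained variation per canonical pair.

    p_k = 100 * lambda_k / sum(lambda), lambda_k = r_k^2 / (1 - r_k^2).
    Requires r sorted descending with every r_k in [0, 1).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r >= 1.0):
        raise ValueError("canonical correlation of 1 gives an infinite eigenvalue")
    if np.any(r < 0):
        raise ValueError("canonical correlations must be nonnegative")
    if np.any(np.diff(r) > 1e-12):
        raise ValueError("canonical correlations must be sorted descending")
    lam = r**2 / (1.0 - r**2)
    total = lam.sum()
    if total == 0:
        return np.zeros_like(lam)
    return 100.0 * lam / total


def wilks_tests(r: np.ndarray, n: int, p: int, q: int) -> pd.DataFrame:
    """Sequential likelihood-ratio tests that r_k, ..., r_s are all zero.

    Wilks Lambda_k = prod_{i>=k} (1 - r_i^2); Bartlett's chi-square
    -(n - 1 - (p + q + 1)/2) * ln(Lambda_k) on (p-k+1)(q-k+1) degrees of
    freedom, upper-tail p-value.
    """
    r = np.asarray(r, dtype=float)
    s = len(r)
    rows = []
    scale = n - 1 - (p + q + 1) / 2.0
    for k in range(1, s + 1):
        lam = float(np.prod(1.0 - r[k - 1 :] ** 2))
        chi2 = -scale * np.log(lam) if lam > 0 else np.inf
        df = (p - k + 1) * (q - k + 1)
        pval = float(stats.chi2.sf(chi2, df)) if np.isfinite(chi2) else 0.0
        rows.append({"k": k, "wilks_lambda": lam, "chi2": chi2, "df": df, "p_value": pval})
    return pd.DataFrame(rows)


@dataclass
class CCAResult:
    """Fitted canonical correlation analysis.

    Coefficient matrices apply to the standardized blocks; loadings and
    cross-loadings are sample correlations of the original (standardized)
    variables with the canonical scores.
    """

    correlations: np.ndarray  # (s,) descending in [0, 1]
    eigenvalues: np.ndarray  # r^2/(1-r^2)
    proportions: np.ndarray  # percent, sums to 100
    x_coef: pd.DataFrame  # p x s
    y_coef: pd.DataFrame  # q x s
    x_scores: pd.DataFrame  # n x s (CLIMATE1..s style variates)
    y_scores: pd.DataFrame
    x_loadings: pd.DataFrame  # p x s, own-block structure correlations
    y_loadings: pd.DataFrame
    x_cross_loadings: pd.DataFrame  # p x s vs opposite block scores
    y_cross_loadings: pd.DataFrame
    tests: pd.DataFrame
    n: int = 0
    ridge: float = 0.0

    def write(self, out_dir: str | Path, x_name: str = "CLIMATE", y_name: str = "SOIL") -> None:
        out = Path(out_dir)
        s = len(self.correlations)
        summary = pd.DataFrame(
            {
                "k": np.arange(1, s + 1),
                "canonical_correlation": self.correlations,
                "eigenvalue": self.eigenvalues,
                "proportion_pct": self.proportions,
            }
        ).merge(self.tests, on="k")
        summary.to_csv(out / "cca_summary.csv", index=False)
        axes = [f"{x_name}{k}" for k in range(1, s + 1)]
        yaxes = [f"{y_name}{k}" for k in range(1, s + 1)]
        self.x_loadings.set_axis(axes, axis=1).to_csv(out / "cca_x_loadings.csv")
        self.y_loadings.set_axis(yaxes, axis=1).to_csv(out / "cca_y_loadings.csv")
        self.x_cross_loadings.set_axis(yaxes, axis=1).to_csv(out / "cca_x_cross_loadings.csv")
        self.y_cross_loadings.set_axis(axes, axis=1).to_csv(out / "cca_y_cross_loadings.csv")
        scores = pd.concat(
            [
                self.x_scores.set_axis(axes, axis=1),
                self.y_scores.set_axis(yaxes, axis=1),
            ],
            axis=1,
        )
        scores.to_csv(out / "cca_scores.csv")


def _corr_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-by-column correlation matrix between two centered arrays."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (a.T @ b) / np.outer(na, nb)


def fit_cca(X: pd.DataFrame, Y: pd.DataFrame, ridge: float = 0.0) -> CCAResult:
    """Fit correlation-based CCA on standardized blocks.

    Parameters
    ----------
    X, Y
        Standardized blocks sharing the same row index (complete cases).
    ridge
        Nonnegative value added to the diagonal of each block correlation
        matrix only when the block is numerically rank-deficient; a deficient
        block with ``ridge=0`` is a hard error advising one.

    Notes
    -----
    Sign convention: each X variate is oriented so its largest-|loading|
    variable loads positively, and each Y variate follows so that the
    canonical pair correlates nonnegatively — removes platform-dependent
    sign flips.
    """
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    if list(X.index) != list(Y.index):
        raise ValueError("X and Y must share the same row index")
    n, p = X.shape
    q = Y.shape[1]
    s = min(p, q)
    if n <= max(p, q):
        raise ValueError(f"need n > max(p, q); have n={n}, p={p}, q={q}")
    if n <= p + q:
        import warnings

        warnings.warn(
            f"n={n} <= p+q={p+q}: canonical correlations will be unstable",
            stacklevel=2,
        )
    Xv = X.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    Rxx = np.corrcoef(Xv, rowvar=False).reshape(p, p)
    Ryy = np.corrcoef(Yv, rowvar=False).reshape(q, q)
    Rxy = _corr_cols(Xv, Yv)

    # rank check before inversion
    for name, R in (("X", Rxx), ("Y", Ryy)):
        w = np.linalg.eigvalsh(R)
        if w.min() < _EIG_FLOOR and ridge == 0:
            raise np.linalg.LinAlgError(
                f"{name} block correlation matrix is numerically singular "
                f"(min eigenvalue {w.min():.2e}); pass ridge > 0"
            )
    Rxx_is, _ = _inv_sqrt(Rxx, ridge)
    Ryy_is, _ = _inv_sqrt(Ryy, ridge)
    K = Rxx_is @ Rxy @ Ryy_is
    U, svals, Vt = np.linalg.svd(K)
    r = np.clip(svals[:s], 0.0, 1.0)
    a = Rxx_is @ U[:, :s]  # weights for standardized X
    b = Ryy_is @ Vt.T[:, :s]

    u = Xv @ a
    v = Yv @ b
    x_load = _corr_cols(Xv, u)
    # orient: largest-|loading| X variable positive, then Y follows the pair
    for k in range(s):
        jmax = int(np.argmax(np.abs(x_load[:, k])))
        if x_load[jmax, k] < 0:
            a[:, k] *= -1
            u[:, k] *= -1
        rho = float(_corr_cols(u[:, [k]], v[:, [k]])[0, 0])
        if rho < 0:
            b[:, k] *= -1
            v[:, k] *= -1
    x_load = _corr_cols(Xv, u)
    y_load = _corr_cols(Yv, v)
    x_cross = _corr_cols(Xv, v)
    y_cross = _corr_cols(Yv, u)

    with np.errstate(divide="ignore"):
        lam = r**2 / np.maximum(1.0 - r**2, 1e-300)
    props = 100.0 * lam / lam.sum() if lam.sum() > 0 else np.zeros_like(lam)
    ks = [f"can{k}" for k in range(1, s + 1)]
    return CCAResult(
        correlations=r,
        eigenvalues=lam,
        proportions=props,
        x_coef=pd.DataFrame(a, index=X.columns, columns=ks),
        y_coef=pd.DataFrame(b, index=Y.columns, columns=ks),
        x_scores=pd.DataFrame(u, index=X.index, columns=ks),
        y_scores=pd.DataFrame(v, index=Y.index, columns=ks),
        x_loadings=pd.DataFrame(x_load, index=X.columns, columns=ks),
        y_loadings=pd.DataFrame(y_load, index=Y.columns, columns=ks),
        x_cross_loadings=pd.DataFrame(x_cross, index=X.columns, columns=ks),
        y_cross_loadings=pd.DataFrame(y_cross, index=Y.columns, columns=ks),
        tests=wilks_tests(r, n, p, q),
        n=n,
        ridge=ridge,
    )
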