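"""PCA with varimax rotation and sampling-adequacy diagnostics for the
seven pandemic-attitude items.

Components are retained by the Kaiser criterion (eigenvalue strictly > 1 of
the item correlation matrix) and rotated with varimax under Kaiser row
normalization. Sampling adequacy is checked with the Kaiser-Meyer-Olkin
measure (overall and per item) and Bartlett's test of sphericity;
internal consistency with Cronbach's alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AdequacyDiagnostics",
    "PCAResult",
    "kmo",
    "bartlett_sphericity",
    "varimax",
    "pca_varimax",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class AdequacyDiagnostics:
    kmo_overall: float | None = None
    kmo_per_item: np.ndarray | None = None
    bartlett_chi2: float | None = None
    bartlett_df: int | None = None
    bartlett_p: float | None = None


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray          # all p eigenvalues, descending
    retained_components: int         # Kaiser: eigenvalue > 1 (strict)
    loadings: np.ndarray             # unrotated loadings of retained set
    rotated_loadings: np.ndarray     # varimax-rotated retained loadings
    communalities: np.ndarray        # per item, retained set
    cumulative_explained_variance: float  # percent, retained set
    items: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.retained_components)]
        idx = list(self.items) if self.items else list(range(len(self.communalities)))
        out = pd.DataFrame(self.rotated_loadings, index=idx, columns=cols)
        out["communality"] = self.communalities
        return out


def _as_correlation(data=None, corr=None):
    if (data is None) == (corr is None):
        raise ValueError("pass exactly one of data or corr")
    if corr is not None:
        R = np.asarray(corr, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        return R
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("data must be n x p with p >= 2")
    return np.corrcoef(X, rowvar=False)


def kmo(corr: np.ndarray, items: tuple[str, ...] | None = None) -> AdequacyDiagnostics:
    """Kaiser-Meyer-Olkin sampling adequacy, overall and per item.

    KMO compares squared zero-order correlations against squared
    anti-image partial correlations; values near 1 indicate compact
    correlation structure suitable for factoring.
    """
    R = _as_correlation(corr=corr)
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular correlation matrix: {err}") from err
    if np.linalg.cond(R) > 1e12:
        bad = items if items else "matrix"
        raise ValueError(f"correlation matrix numerically singular ({bad})")
    d = np.sqrt(np.diag(Rinv))
    partial = -Rinv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = R[off].reshape(p, p - 1) ** 2
    q2 = partial[off].reshape(p, p - 1) ** 2
    per_item = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    overall = r2.sum() / (r2.sum() + q2.sum())
    return AdequacyDiagnostics(kmo_overall=float(overall), kmo_per_item=per_item)


def bartlett_sphericity(corr: np.ndarray, n: int) -> AdequacyDiagnostics:
    """Bartlett's test that the correlation matrix is the identity."""
    R = _as_correlation(corr=corr)
    p = R.shape[0]
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    chi2 = max(chi2, 0.0)
    df = p * (p - 1) // 2
    return AdequacyDiagnostics(
        bartlett_chi2=float(chi2), bartlett_df=df,
        bartlett_p=float(stats.chi2.sf(chi2, df)),
    )


def varimax(loadings: np.ndarray, normalize: bool = True,
            tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Varimax rotation (Kaiser normalization by default).

    Columns are sign-flipped so each component's largest-magnitude loading
    is positive, then ordered by explained variance, for a reproducible
    orientation.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        R = L
    else:
        h = np.sqrt((L ** 2).sum(axis=1))
        if normalize:
            h_safe = np.where(h > 0, h, 1.0)
            L = L / h_safe[:, None]
        T = np.eye(k)
        var = 0.0
        for _ in range(max_iter):
            Lr = L @ T
            u, s, vt = np.linalg.svd(
                L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
            )
            T = u @ vt
            new_var = s.sum()
            if new_var <= var * (1 + tol):
                break
            var = new_var
        L = L @ T
        if normalize:
            L = L * h[:, None]
        R = L
    # canonical orientation
    for j in range(R.shape[1]):
        if R[np.argmax(np.abs(R[:, j])), j] < 0:
            R[:, j] = -R[:, j]
    order = np.argsort(-(R ** 2).sum(axis=0), kind="stable")
    return R[:, order]


def pca_varimax(data=None, corr=None,
                items: tuple[str, ...] | None = None) -> PCAResult:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation."""
    R = _as_correlation(data=data, corr=corr)
    p = R.shape[0]
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = int((eigval > 1.0).sum())
    if retained == 0:
        warnings.warn("no eigenvalue exceeds 1; nothing retained", stacklevel=2)
        empty = np.zeros((p, 0))
        return PCAResult(eigval, 0, empty, empty, np.zeros(p), 0.0,
                         items or ())
    L = eigvec[:, :retained] * np.sqrt(eigval[:retained])
    rotated = varimax(L) if retained >= 2 else varimax(L.copy())
    communalities = (L ** 2).sum(axis=1)
    cum = 100.0 * eigval[:retained].sum() / p
    return PCAResult(
        eigenvalues=eigval,
        retained_components=retained,
        loadings=L,
        rotated_loadings=rotated,
        communalities=communalities,
        cumulative_explained_variance=float(cum),
        items=items or (),
    )


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance)."""
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 respondents and >= 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
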