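"""Factor-analysis diagnostics and PCA-derived indicator weights.

KMO sampling adequacy, Bartlett's test of sphericity, and a
correlation-matrix eigendecomposition with loadings are the standard
pre-checks and weighting machinery for a membership-function composite
index. All three operate on an observations x variables data matrix
(here: varieties x indicators).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DegenerateInputError


def _corr(data: pd.DataFrame) -> pd.DataFrame:
    if data.shape[0] < 3:
        raise DegenerateInputError("need at least 3 observations")
    sd = data.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise DegenerateInputError(
            f"constant column(s): {list(sd.index[sd == 0])}"
        )
    return data.corr()


def _invert_corr(R: np.ndarray) -> np.ndarray:
    # refuse near-singular matrices outright; a pseudo-inverse would
    # silently change the partial-correlation structure
    if np.linalg.cond(R) > 1e12:
        raise DegenerateInputError("correlation matrix is numerically singular")
    return np.linalg.inv(R)


def anti_image_partial_correlations(data: pd.DataFrame) -> pd.DataFrame:
    """Matrix of partial correlations between each pair of variables,
    controlling for all remaining variables (off-diagonal of the scaled
    negative inverse correlation matrix)."""
    R = _corr(data).to_numpy()
    Rinv = _invert_corr(R)
    d = 1.0 / np.sqrt(np.diag(Rinv))
    Q = -Rinv * np.outer(d, d)
    np.fill_diagonal(Q, 1.0)
    return pd.DataFrame(Q, index=data.columns, columns=data.columns)


@dataclass(frozen=True)
class SphericityDiagnostics:
    """KMO and Bartlett-sphericity summary for one data matrix."""

    kmo_overall: float
    kmo_per_variable: pd.Series
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def kmo(data: pd.DataFrame) -> tuple[float, pd.Series]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    overall = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where
    q_ij are the anti-image partial correlations; the per-variable measure
    restricts both sums to row i. Values near 1 indicate the correlation
    structure is dominated by shared (factorable) variance.
    """
    R = _corr(data).to_numpy()
    Q = anti_image_partial_correlations(data).to_numpy()
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.where(off, R**2, 0.0)
    q2 = np.where(off, Q**2, 0.0)
    overall = r2.sum() / (r2.sum() + q2.sum())
    per_var = pd.Series(
        r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1)),
        index=data.columns,
        name="kmo",
    )
    return float(overall), per_var


def bartlett_sphericity(data: pd.DataFrame) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -[(n-1) - (2p+5)/6] * ln det(R), df = p(p-1)/2.
    """
    n, p = data.shape
    if n <= p:
        raise DegenerateInputError(f"need n > p (got n={n}, p={p})")
    R = _corr(data).to_numpy()
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise DegenerateInputError("correlation matrix not positive definite")
    chi2 = -((n - 1) - (2 * p + 5) / 6.0) * logdet
    chi2 = max(chi2, 0.0)
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def sphericity_diagnostics(data: pd.DataFrame) -> SphericityDiagnostics:
    overall, per_var = kmo(data)
    chi2, df, pval = bartlett_sphericity(data)
    return SphericityDiagnostics(overall, per_var, chi2, df, pval)


@dataclass(frozen=True)
class FactorModel:
    """Eigenstructure of a correlation matrix with retained components.

    ``loadings`` are correlations between variables and components
    (eigenvector columns scaled by sqrt(eigenvalue)), restricted to the
    retained components (eigenvalue >= retention_threshold). Variance
    contributions are 100 * lambda / p.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    variance_contribution_pct: np.ndarray
    cumulative_pct: np.ndarray
    retained_k: int
    retention_threshold: float = 1.0
    indicators: list = field(default_factory=list)


def pca_factors(data: pd.DataFrame, retention_threshold: float = 1.0) -> FactorModel:
    """Eigendecomposition of the Pearson correlation matrix.

    Components are ordered by descending eigenvalue. Each loading column's
    sign is flipped so its largest-magnitude entry is positive (eigenvector
    signs are arbitrary).
    """
    R = _corr(data).to_numpy()
    p = R.shape[0]
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for a in range(p):
        j = np.argmax(np.abs(evecs[:, a]))
        if evecs[j, a] < 0:
            evecs[:, a] = -evecs[:, a]
    k = int((evals >= retention_threshold).sum())
    load = evecs[:, :k] * np.sqrt(evals[:k])
    vc = 100.0 * evals / p
    return FactorModel(
        eigenvalues=evals,
        loadings=pd.DataFrame(
            load, index=data.columns, columns=[f"PC{i+1}" for i in range(k)]
        ),
        variance_contribution_pct=vc,
        cumulative_pct=np.cumsum(vc),
        retained_k=k,
        retention_threshold=retention_threshold,
        indicators=list(data.columns),
    )


def derive_weights(fm: FactorModel, method: str = "composite_coefficient") -> pd.Series:
    """Nonnegative per-indicator weights (sum 1) from a factor model.

    ``composite_coefficient``: w_j ∝ sum_k loading_jk * vc_k / vc_retained;
    ``communality``: w_j ∝ sum_k loading_jk^2. Both are clipped at zero
    before normalization. Neither variant is canonical — composite indices
    in the germplasm-screening literature use several, so published weight
    vectors can also be supplied directly via :func:`normalize_weights`.
    """
    if fm.retained_k < 1:
        raise DegenerateInputError("no retained components")
    L = fm.loadings.to_numpy()
    vc = fm.variance_contribution_pct[: fm.retained_k]
    if method == "composite_coefficient":
        raw = L @ (vc / vc.sum())
    elif method == "communality":
        raw = (L**2).sum(axis=1)
    else:
        raise ConfigError(f"unknown weight method: {method!r}")
    raw = np.clip(raw, 0.0, None)
    if raw.sum() == 0:
        raise DegenerateInputError("all weights zero after clipping")
    return pd.Series(raw / raw.sum(), index=fm.loadings.index, name="weight")


def normalize_weights(weights: pd.Series) -> pd.Series:
    """Validate and renormalize a user-supplied weight vector to sum 1.

    Published weight tables are often rounded (e.g. printed values summing
    to 0.99); renormalization restores the convex-combination property."""
    w = weights.astype(float)
    if (w < 0).any():
        raise ConfigError(f"negative weight(s): {list(w.index[w < 0])}")
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("weights sum to zero")
    return w / total
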