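"""PLS-DA via NIPALS, with VIP scores and cross-validated VIP averaging.

For a two-class response the NIPALS deflation scheme reduces to PLS1:
per component a, the X-weight w_a = X'y / ||X'y||, scores t_a = X w_a,
X-loadings p_a = X't_a / t_a't_a, y-loading q_a = y't_a / t_a't_a, then X
and y are deflated by the rank-one component. SSY_a = q_a^2 * t_a't_a is
the y sum of squares captured by component a.

VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ), so sum_j VIP_j^2 = p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigError, DegenerateInputError


@dataclass(frozen=True)
class PLSDAModel:
    """Fitted PLS-DA components on autoscaled X and centered two-class y."""

    weights: np.ndarray        # p x A, each column unit norm
    scores: np.ndarray         # n x A
    x_loadings: np.ndarray     # p x A
    y_loadings: np.ndarray     # A
    ssy: np.ndarray            # A, y sum of squares per component
    features: pd.Index


def _encode_y(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ConfigError(f"need exactly two classes, got {list(classes)}")
    return np.where(y == classes[0], -1.0, 1.0)


def pls_da_fit(X: pd.DataFrame, y, ncomp: int = 2, scale: bool = True) -> PLSDAModel:
    """Fit a PLS-DA model with ``ncomp`` components.

    X is column-centered and (by default) scaled to unit variance; y is
    coded ±1 and centered. Zero-variance columns are an error — drop or
    impute upstream.
    """
    Xm = np.asarray(X, dtype=float)
    n, p = Xm.shape
    yv = _encode_y(y)
    if len(yv) != n:
        raise ConfigError("X and y length mismatch")
    if ncomp < 1 or ncomp > min(n - 1, p):
        raise ConfigError(f"ncomp must be in [1, {min(n - 1, p)}]")
    sd = Xm.std(axis=0, ddof=1)
    if scale and (sd == 0).any():
        bad = list(pd.Index(X.columns)[sd == 0]) if hasattr(X, "columns") else list(np.where(sd == 0)[0])
        raise DegenerateInputError(f"zero-variance column(s): {bad[:5]}")
    Xc = Xm - Xm.mean(axis=0)
    if scale:
        Xc = Xc / sd
    yc = yv - yv.mean()

    W = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    P = np.zeros((p, ncomp))
    Q = np.zeros(ncomp)
    SSY = np.zeros(ncomp)
    Xa, ya = Xc.copy(), yc.copy()
    for a in range(ncomp):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm == 0:
            break  # y fully explained; remaining components are null
        w /= norm
        t = Xa @ w
        tt = t @ t
        if tt == 0:
            break
        pa = Xa.T @ t / tt
        qa = ya @ t / tt
        W[:, a], T[:, a], P[:, a], Q[a] = w, t, pa, qa
        SSY[a] = qa**2 * tt
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
    features = X.columns if hasattr(X, "columns") else pd.RangeIndex(p)
    return PLSDAModel(W, T, P, Q, SSY, pd.Index(features))


def vip(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection; satisfies sum VIP^2 = p."""
    ssy = model.ssy
    if ssy.sum() <= 0:
        raise DegenerateInputError("model explains no y variance")
    p = model.weights.shape[0]
    w2 = model.weights**2  # columns already unit norm
    v = np.sqrt(p * (w2 @ ssy) / ssy.sum())
    return pd.Series(v, index=model.features, name="vip")


def cv_vip(
    X: pd.DataFrame,
    y,
    folds: int = 7,
    repeats: int = 10,
    ncomp: int = 2,
    seed: int = 0,
) -> pd.Series:
    """VIP averaged over repeated stratified cross-validation training splits.

    Each training split refits the PLS-DA model and its VIP; the mean over
    folds x repeats is returned. When ``folds`` reaches the sample count the
    scheme degenerates to leave-one-out, which is deterministic, so repeats
    collapse; stratified splitting otherwise caps the fold count at the
    minority class size so every training split keeps both classes.
    """
    yv = np.asarray(y)
    n = len(yv)
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    _, counts = np.unique(yv, return_counts=True)
    vips = []
    if folds >= n:  # leave-one-out, no randomness left
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            m = pls_da_fit(X.iloc[mask], yv[mask], ncomp=ncomp)
            vips.append(vip(m))
    else:
        n_splits = min(folds, counts.min())
        if n_splits < 2:
            raise ConfigError("minority class too small for stratified CV")
        rng = np.random.default_rng(seed)
        for _ in range(repeats):
            skf = StratifiedKFold(
                n_splits=n_splits,
                shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            for train, _test in skf.split(np.zeros(n), yv):
                m = pls_da_fit(X.iloc[train], yv[train], ncomp=ncomp)
                vips.append(vip(m))
    return pd.concat(vips, axis=1).mean(axis=1).rename("vip")
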