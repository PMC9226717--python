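"""Differential-metabolite screening from LC-MS peak-area matrices.

Stages: total-peak-area normalization per sample, half-minimum imputation
of missing areas, Welch t-tests, PLS-DA VIP (optionally averaged over
repeated stratified cross-validation), and the fold-change + VIP gates
(FC >= 1.5 or <= 1/1.5, VIP >= 1 by default). A QC-repeatability report
(sample-space PCA + pairwise Spearman) covers instrument drift checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DegenerateInputError, SchemaError
from .pls import cv_vip, pls_da_fit, vip


def total_area_normalize(peaks: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its total observed peak area.

    Missing cells stay missing and are excluded from the totals; observed
    cells of each output column sum to 1."""
    totals = peaks.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        raise DegenerateInputError(
            f"zero total area in sample(s): {list(totals.index[totals <= 0])}"
        )
    return peaks.div(totals, axis=1)


def impute_missing(
    peaks: pd.DataFrame, strategy: str = "half_min"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing peak areas; returns (matrix, imputation log).

    ``half_min``: half of the metabolite's minimum observed value (common
    LC-MS practice for below-detection-limit features); ``zero``: plain 0.
    Fully-missing metabolites are dropped and recorded in the log.
    """
    if strategy not in ("half_min", "zero"):
        raise ConfigError(f"unknown imputation strategy: {strategy!r}")
    out = peaks.copy()
    entries = []
    all_missing = out.isna().all(axis=1)
    for mid in out.index[all_missing]:
        entries.append({"metabolite": mid, "action": "dropped", "fill": np.nan})
    out = out.loc[~all_missing]
    n_missing = out.isna().sum(axis=1)
    for mid in out.index[n_missing > 0]:
        fill = 0.0 if strategy == "zero" else out.loc[mid].min() / 2.0
        entries.append(
            {"metabolite": mid, "action": f"imputed_{strategy}", "fill": fill}
        )
        out.loc[mid] = out.loc[mid].fillna(fill)
    log = pd.DataFrame(entries, columns=["metabolite", "action", "fill"])
    return out, log


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance two-sided t-test with Satterthwaite df."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("need >=2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # degenerate-by-convention cases
        return (0.0, float(len(a) + len(b) - 2), 1.0) if a.mean() == b.mean() else (
            np.inf if a.mean() > b.mean() else -np.inf,
            float(len(a) + len(b) - 2),
            0.0,
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def fold_change(normalized: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Treatment-over-control ratio of group means per metabolite."""
    ctrl = [c for c in normalized.columns if groups.get(c) == "control"]
    trt = [c for c in normalized.columns if groups.get(c) == "treatment"]
    if not ctrl or not trt:
        raise SchemaError("both control and treatment samples required")
    return (normalized[trt].mean(axis=1) / normalized[ctrl].mean(axis=1)).rename("fc")


@dataclass(frozen=True)
class DEMCallSummary:
    total: int
    up: int
    down: int


def call_dems(
    fc: pd.Series,
    vip_scores: pd.Series,
    fc_cut: float = 1.5,
    vip_cut: float = 1.0,
) -> tuple[pd.Series, DEMCallSummary]:
    """up if FC >= fc_cut & VIP >= vip_cut; down if FC <= 1/fc_cut & VIP >= vip_cut."""
    if (fc <= 0).any():
        raise ConfigError("fold changes must be positive")
    v = vip_scores.reindex(fc.index)
    call = pd.Series("unchanged", index=fc.index, name="call")
    call[(fc >= fc_cut) & (v >= vip_cut)] = "up"
    call[(fc <= 1.0 / fc_cut) & (v >= vip_cut)] = "down"
    up = int((call == "up").sum())
    down = int((call == "down").sum())
    return call, DEMCallSummary(total=up + down, up=up, down=down)


@dataclass(frozen=True)
class QCReport:
    """Sample-space PCA coordinates and pairwise Spearman correlations."""

    pca_coordinates: pd.DataFrame          # samples x <=3 components
    explained_variance_ratio: np.ndarray
    spearman: pd.DataFrame                 # samples x samples
    qc_min_spearman: float | None
    qc_median_spearman: float | None


def qc_repeatability(peaks: pd.DataFrame, qc_samples=()) -> QCReport:
    """Repeatability diagnostics over samples.

    PCA is computed on autoscaled metabolite features (constant features
    ignored); the Spearman matrix is over raw sample columns. If QC
    replicate columns are flagged, their pairwise-correlation minimum and
    median summarize injection repeatability.
    """
    if peaks.shape[1] < 2:
        raise SchemaError("need >=2 samples")
    X = peaks.T.to_numpy(float)  # samples x features
    keep = np.nanstd(X, axis=0) > 0
    Xs = X[:, keep]
    Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0, ddof=0)
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    k = min(3, len(s))
    coords = pd.DataFrame(
        U[:, :k] * s[:k],
        index=peaks.columns,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    evr = (s**2 / (s**2).sum())[:k]
    rho = stats.spearmanr(peaks.to_numpy(float)).statistic
    rho = np.atleast_2d(rho)
    spearman = pd.DataFrame(rho, index=peaks.columns, columns=peaks.columns)
    qc_min = qc_med = None
    qc = [c for c in qc_samples if c in peaks.columns]
    if len(qc) >= 2:
        sub = spearman.loc[qc, qc].to_numpy()
        off = sub[~np.eye(len(qc), dtype=bool)]
        qc_min, qc_med = float(off.min()), float(np.median(off))
    return QCReport(coords, evr, spearman, qc_min, qc_med)


def dem_pipeline(
    peaks: pd.DataFrame,
    groups: pd.Series,
    fc_cut: float = 1.5,
    vip_cut: float = 1.0,
    ncomp: int = 2,
    folds: int = 7,
    repeats: int = 10,
    seed: int = 0,
    impute_strategy: str = "half_min",
    use_cv: bool = True,
) -> tuple[pd.DataFrame, DEMCallSummary]:
    """Peak areas -> per-metabolite table (FC, t-test p, VIP, call)."""
    norm = total_area_normalize(peaks)
    norm, _log = impute_missing(norm, strategy=impute_strategy)
    ctrl = [c for c in norm.columns if groups.get(c) == "control"]
    trt = [c for c in norm.columns if groups.get(c) == "treatment"]
    fc = fold_change(norm, groups)
    pvals = pd.Series(
        [welch_t(norm.loc[m, ctrl], norm.loc[m, trt])[2] for m in norm.index],
        index=norm.index,
        name="pvalue",
    )
    X = norm[ctrl + trt].T  # samples x metabolites
    keep = X.std(axis=0, ddof=1) > 0
    y = np.array(["control"] * len(ctrl) + ["treatment"] * len(trt))
    if use_cv:
        v = cv_vip(X.loc[:, keep], y, folds=folds, repeats=repeats, ncomp=ncomp, seed=seed)
    else:
        v = vip(pls_da_fit(X.loc[:, keep], y, ncomp=ncomp))
    v = v.reindex(norm.index).fillna(0.0)
    call, summary = call_dems(fc, v, fc_cut, vip_cut)
    return pd.DataFrame({"fc": fc, "pvalue": pvals, "vip": v, "call": call}), summary
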