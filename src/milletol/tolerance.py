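"""Composite stress-tolerance screening for germplasm panels.

The screen turns replicated treatment/control measurements of a panel of
varieties into a single comprehensive tolerance value ``T`` per variety:

1. relative value  r_ij = mean(treatment) / mean(control) per variety i,
   indicator j (removes genotype baseline differences);
2. orientation — cost indicators (lower is better, e.g. malondialdehyde
   content) are replaced by their reciprocal so every column reads
   "higher is more tolerant";
3. membership (subordinate-function) scores
   U_ij = (r_ij - min_j) / (max_j - min_j), column-wise min-max to [0, 1];
4. T_i = sum_j w_j * U_ij with nonnegative indicator weights summing to 1.

Varieties are ranked by descending unrounded T (rank 1 = most tolerant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DegenerateInputError, SchemaError

PHENOTYPE_COLUMNS = ("variety", "indicator", "condition", "replicate", "value")
CONDITIONS = ("control", "treatment")


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table.

    Required columns: variety, indicator, condition (control|treatment),
    replicate, value (> 0). Every variety must carry the same indicator set
    and every (variety, indicator, condition) at least one replicate.
    """
    missing = set(PHENOTYPE_COLUMNS) - set(pheno.columns)
    if missing:
        raise SchemaError(f"phenotype table missing columns: {sorted(missing)}")
    bad_cond = set(pheno["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"unknown condition labels: {sorted(bad_cond)}")
    if (pheno["value"] <= 0).any():
        rows = pheno.loc[pheno["value"] <= 0, ["variety", "indicator"]]
        raise DegenerateInputError(
            f"non-positive measurements, e.g. {rows.iloc[0].tolist()}"
        )
    if pheno["variety"].nunique() < 2:
        raise SchemaError("need at least 2 varieties")
    cells = pheno.groupby(["variety", "indicator"])["condition"].agg(set)
    incomplete = cells[cells != set(CONDITIONS)]
    if len(incomplete):
        raise SchemaError(
            f"missing condition for {incomplete.index[0]}; every "
            "(variety, indicator) needs both control and treatment"
        )
    per_var = pheno.groupby("variety")["indicator"].agg(lambda s: frozenset(s))
    if per_var.nunique() != 1:
        raise SchemaError("indicator sets differ between varieties")
    return pheno


def relative_values(pheno: pd.DataFrame) -> pd.DataFrame:
    """Variety x indicator matrix of mean(treatment)/mean(control) ratios."""
    validate_phenotypes(pheno)
    means = (
        pheno.groupby(["variety", "indicator", "condition"], sort=False)["value"]
        .mean()
        .unstack("condition")
    )
    if (means["control"] <= 0).any():
        where = means.index[means["control"] <= 0][0]
        raise DegenerateInputError(
            f"zero/negative control mean for variety={where[0]!r} "
            f"indicator={where[1]!r}"
        )
    rel = (means["treatment"] / means["control"]).unstack("indicator")
    # preserve first-appearance order of varieties and indicators
    var_order = pheno["variety"].drop_duplicates().tolist()
    ind_order = pheno["indicator"].drop_duplicates().tolist()
    return rel.reindex(index=var_order, columns=ind_order)


def orient_indicators(rel: pd.DataFrame, cost_indicators=()) -> pd.DataFrame:
    """Replace cost-indicator columns (lower is better) by their reciprocal."""
    cost = set(cost_indicators)
    unknown = cost - set(rel.columns)
    if unknown:
        raise ConfigError(f"unknown cost indicators: {sorted(unknown)}")
    out = rel.copy()
    for c in cost:
        out[c] = 1.0 / out[c]
    return out


def membership_normalize(rel: pd.DataFrame) -> pd.DataFrame:
    """Column-wise min-max (subordinate function) scores in [0, 1].

    Raises :class:`DegenerateInputError` for a constant indicator column —
    such a column carries no discriminating information and silently
    dropping it would change the indicator set, PCA dimensionality and
    weights downstream.
    """
    lo, hi = rel.min(axis=0), rel.max(axis=0)
    span = hi - lo
    flat = span[span == 0]
    if len(flat):
        raise DegenerateInputError(
            f"constant indicator column(s): {list(flat.index)}"
        )
    return (rel - lo) / span


def anti_membership(members: pd.DataFrame, cost_indicators=()) -> pd.DataFrame:
    """Alternative cost handling: 1 - U on cost columns of a membership matrix.

    Provided as an option; the default pipeline uses the reciprocal at the
    relative-value stage instead.
    """
    cost = set(cost_indicators)
    unknown = cost - set(members.columns)
    if unknown:
        raise ConfigError(f"unknown cost indicators: {sorted(unknown)}")
    out = members.copy()
    for c in cost:
        out[c] = 1.0 - out[c]
    return out


@dataclass(frozen=True)
class ToleranceResult:
    """Per-variety comprehensive tolerance value and rank (1 = most tolerant)."""

    T: pd.Series
    rank: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T": self.T, "rank": self.rank})


def tolerance_index(members: pd.DataFrame, weights: pd.Series) -> ToleranceResult:
    """Weighted-sum tolerance value T_i = sum_j w_j U_ij with ranking.

    Weights must cover exactly the membership indicator set and sum to 1.
    Ranks are assigned by descending unrounded T; ties broken by row order.
    """
    if set(weights.index) != set(members.columns):
        raise SchemaError(
            "weight indicators do not match membership indicators: "
            f"{sorted(set(weights.index) ^ set(members.columns))}"
        )
    w = weights.reindex(members.columns)
    if (w < 0).any():
        raise ConfigError("negative weights")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError(f"weights must sum to 1 (got {w.sum():.6f})")
    T = members.mul(w, axis=1).sum(axis=1)
    order = np.argsort(-T.to_numpy(), kind="stable")
    rank = pd.Series(0, index=T.index, dtype=int)
    rank.iloc[order] = np.arange(1, len(T) + 1)
    return ToleranceResult(T=T, rank=rank)


def screen(
    pheno: pd.DataFrame,
    weights: pd.Series,
    cost_indicators=(),
    cost_handling: str = "reciprocal",
) -> ToleranceResult:
    """Full screen from a long phenotype table to ranked tolerance values."""
    rel = relative_values(pheno)
    if cost_handling == "reciprocal":
        members = membership_normalize(orient_indicators(rel, cost_indicators))
    elif cost_handling == "anti_membership":
        members = anti_membership(membership_normalize(rel), cost_indicators)
    else:
        raise ConfigError(f"unknown cost_handling: {cost_handling!r}")
    return tolerance_index(members, weights)
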