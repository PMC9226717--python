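"""Signed gene-metabolite co-expression network under double gates.

Feature profiles (replicate abundance vectors over shared samples) are
z-scored, all gene x metabolite Pearson correlations are tested, and an
edge is kept iff r^2 > r2_cut AND p < p_cut (raw p by default; a BH option
exists). Edges carry the correlation sign for network coloring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, SchemaError
from .deg import bh_fdr


def z_transform(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (mean 0, sample sd 1). Constant rows are an error."""
    mat = profiles.astype(float)
    sd = mat.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise DegenerateInputError(
            f"constant profile(s): {list(sd.index[sd == 0])[:5]}"
        )
    return mat.sub(mat.mean(axis=1), axis=0).div(sd, axis=0)


def drop_constant_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Split off constant rows (unusable for correlation) with a log."""
    sd = profiles.std(axis=1, ddof=1)
    dropped = list(sd.index[sd == 0])
    return profiles.loc[sd > 0], dropped


def correlation_test(x, y) -> tuple[float, float, float]:
    """Pearson r, r^2 and the two-sided p from the t transform
    t = r sqrt((n-2)/(1-r^2)) with n-2 df; |r| = 1 gives p = 0."""
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if len(xv) != len(yv) or len(xv) < 3:
        raise SchemaError("profiles must share length n >= 3")
    if xv.std() == 0 or yv.std() == 0:
        raise DegenerateInputError("constant profile")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(r**2), float(p)


def _pairwise_correlations(genes: pd.DataFrame, mets: pd.DataFrame):
    n = genes.shape[1]
    Zg = z_transform(genes).to_numpy()
    Zm = z_transform(mets).to_numpy()
    R = Zg @ Zm.T / (n - 1)
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1 - R**2))
    P = np.where(np.abs(R) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return R, P


def build_network(
    genes: pd.DataFrame,
    metabolites: pd.DataFrame,
    r2_cut: float = 0.8,
    p_cut: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Edge list over all gene x metabolite pairs passing both gates.

    Inputs are feature x sample matrices sharing the same sample columns in
    the same order. With ``adjust=True`` the p gate is applied to BH-
    adjusted p-values instead of raw ones (off by default).
    """
    if list(genes.columns) != list(metabolites.columns):
        raise SchemaError("gene and metabolite matrices must share sample order")
    if genes.shape[1] < 3:
        raise SchemaError("need n >= 3 shared samples")
    R, P = _pairwise_correlations(genes, metabolites)
    p_eff = bh_fdr(P.ravel()).reshape(P.shape) if adjust else P
    gi, mi = np.where((R**2 > r2_cut) & (p_eff < p_cut))
    edges = pd.DataFrame(
        {
            "gene": genes.index[gi],
            "metabolite": metabolites.index[mi],
            "r": R[gi, mi],
            "r_squared": R[gi, mi] ** 2,
            "p": p_eff[gi, mi],
        }
    )
    edges["sign"] = np.where(edges["r"] >= 0, "positive", "negative")
    return edges.sort_values("p", kind="stable", ignore_index=True)


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Write the bipartite edge list as GraphML (via networkx)."""
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.gene, kind="gene")
        g.add_node(row.metabolite, kind="metabolite")
        g.add_edge(
            row.gene,
            row.metabolite,
            r=float(row.r),
            r_squared=float(row.r_squared),
            p=float(row.p),
            sign=row.sign,
        )
    nx.write_graphml(g, path)
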