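"""Packaged reference tables from the published millet atrazine screen.

``load_membership_table`` is the 20-variety x 8-indicator membership
(subordinate-function) matrix with the published comprehensive tolerance
values and ranking; ``load_factor_weights`` carries the published loading
matrix and indicator weight vector; ``load_published_diagnostics`` the
published KMO/Bartlett/eigenvalue statistics. All values are transcribed
verbatim at their printed precision (2-3 decimals), including two known
oddities of the published table: one membership cell above 1 (CG,
stomatal conductance, 1.02) and one row (JG40) whose printed composite
value is not consistent with its printed memberships.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

COST_INDICATORS = ("MDA",)


def _data_path(name: str):
    return resources.files("milletol").joinpath("data", name)


def load_membership_table() -> pd.DataFrame:
    """Membership matrix with ``T_printed`` and ``rank_printed`` columns,
    indexed by variety."""
    with resources.as_file(_data_path("table4_membership.csv")) as p:
        return pd.read_csv(p, index_col="variety")


def load_membership_matrix() -> pd.DataFrame:
    """Just the 20 x 8 membership scores (published columns excluded)."""
    tab = load_membership_table()
    return tab.drop(columns=["T_printed", "rank_printed"])


def load_factor_weights() -> pd.DataFrame:
    """Published loadings (PC1-PC3) and indicator weights, indexed by indicator."""
    with resources.as_file(_data_path("table3_factor_weights.csv")) as p:
        return pd.read_csv(p, index_col="indicator")


def load_weight_vector() -> pd.Series:
    """The published indicator weight vector (sums to 0.99 as printed)."""
    return load_factor_weights()["weight"]


def load_published_diagnostics() -> pd.Series:
    """Published KMO, Bartlett and eigenvalue statistics as a Series."""
    with resources.as_file(_data_path("table2_sphericity.csv")) as p:
        return pd.read_csv(p, index_col="statistic")["value"]
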