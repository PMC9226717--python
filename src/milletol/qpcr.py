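"""Relative expression by the 2^-ddCt method and RNA-seq concordance.

Each Ct record carries the target and reference-gene cycle thresholds for
one replicate of one condition. dCt = Ct_target - Ct_reference per
replicate; ddCt = mean dCt(treatment) - mean dCt(control) per gene;
relative expression = 2^-ddCt (log2 ratio = -ddCt).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SchemaError

CT_COLUMNS = ("gene", "sample", "condition", "replicate", "ct_target", "ct_reference")


def ddct_relative_expression(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ddCt table with relative expression and log2 ratio."""
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise SchemaError(f"Ct table missing columns: {sorted(missing)}")
    if records["ct_reference"].isna().any() or records["ct_target"].isna().any():
        raise SchemaError("missing Ct values")
    df = records.assign(dct=records["ct_target"] - records["ct_reference"])
    mean_dct = df.groupby(["gene", "condition"], sort=False)["dct"].mean().unstack()
    for cond in ("control", "treatment"):
        if cond not in mean_dct.columns or mean_dct[cond].isna().any():
            raise SchemaError(f"every gene needs >=1 {cond} replicate")
    ddct = mean_dct["treatment"] - mean_dct["control"]
    return pd.DataFrame(
        {
            "ddct": ddct,
            "relative_expression": 2.0**-ddct,
            "log2_ratio": -ddct,
        }
    )


def concordance(qpcr_log2: pd.Series, rnaseq_log2fc: pd.Series) -> tuple[float, float]:
    """Pearson r and sign-agreement fraction between qPCR and RNA-seq log2FC."""
    shared = qpcr_log2.index.intersection(rnaseq_log2fc.index)
    if len(shared) < 3:
        raise SchemaError(f"need >=3 shared genes, got {len(shared)}")
    a = qpcr_log2.loc[shared].to_numpy(float)
    b = rnaseq_log2fc.loc[shared].to_numpy(float)
    r = float(np.corrcoef(a, b)[0, 1])
    sign_agree = float(np.mean(np.sign(a) == np.sign(b)))
    return r, sign_agree
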