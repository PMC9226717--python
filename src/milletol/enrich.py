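"""Hypergeometric set enrichment over user-supplied pathway collections.

Pathway membership comes in as GMT (tab-separated: set id, description,
member ids). For a selected feature list against a background, each
pathway's upper-tail hypergeometric p = P(X >= k | N, K, n) is computed
and BH-adjusted across pathways.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .exceptions import SchemaError
from .deg import bh_fdr


def read_gmt(path) -> dict[str, dict]:
    """Parse a GMT file into {set_id: {"description": ..., "members": set}}."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"GMT line with <3 fields: {line[:50]!r}")
            sets[fields[0]] = {
                "description": fields[1],
                "members": set(fields[2:]) - {""},
            }
    return sets


def write_gmt(sets: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        for sid, rec in sets.items():
            members = "\t".join(sorted(rec["members"]))
            fh.write(f"{sid}\t{rec.get('description', '')}\t{members}\n")


def hypergeom_enrich(selected, background, pathways: dict[str, dict]) -> pd.DataFrame:
    """Per-pathway enrichment table sorted by p.

    Pathways are intersected with the background; k = |selected ∩ pathway|,
    K = |pathway ∩ background|, n = |selected ∩ background|, N = |background|.
    """
    bg = set(background)
    if not bg:
        raise SchemaError("empty background")
    sel = set(selected)
    if not sel <= bg:
        raise SchemaError(
            f"selected features outside background, e.g. {sorted(sel - bg)[:3]}"
        )
    N, n = len(bg), len(sel)
    rows = []
    for sid, rec in pathways.items():
        members = rec["members"] & bg
        K = len(members)
        if K == 0:
            continue
        k = len(sel & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "pathway": sid,
                "description": rec.get("description", ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows, columns=["pathway", "description", "k", "K", "n", "N", "pvalue"]
    )
    if len(table):
        table["qvalue"] = bh_fdr(table["pvalue"])
        table = table.sort_values("pvalue", kind="stable", ignore_index=True)
    return table
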