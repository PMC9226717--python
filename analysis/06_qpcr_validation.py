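#!/usr/bin/env python
"""Validate DEG fold changes with simulated qPCR and the 2^-ddCt method.

Takes the 34 strongest DEG calls from 03_deg_screen.py, simulates a Ct
table whose expected log2 ratios equal the RNA-seq estimates plus cycle
noise, computes relative expression by 2^-ddCt, and quantifies
concordance (Pearson r, sign agreement).

Writes results/qpcr/{ct_table,relative_expression,concordance}.csv.
"""

from pathlib import Path

import pandas as pd

from milletol import qpcr, simulate

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "qpcr"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260921


def main() -> None:
    deg_table = pd.read_csv(
        ROOT / "results" / "deg" / "deg_table.csv", index_col="gene"
    )
    called = deg_table[deg_table["call"] != "unchanged"]
    panel = called.reindex(
        called["log2fc"].abs().sort_values(ascending=False).index
    ).head(34)

    records, _ = simulate.simulate_ct_table(panel["log2fc"], noise_sd=0.3, seed=SEED)
    records.round(3).to_csv(OUT / "ct_table.csv", index=False)

    rel = qpcr.ddct_relative_expression(records)
    rel.round(4).to_csv(OUT / "relative_expression.csv", index_label="gene")

    r, sign_agree = qpcr.concordance(rel["log2_ratio"], panel["log2fc"])
    pd.DataFrame(
        [{"genes": len(panel), "pearson_r": round(r, 3), "sign_agreement": sign_agree}]
    ).to_csv(OUT / "concordance.csv", index=False)

    print(f"validation panel: {len(panel)} genes")
    print(f"qPCR vs RNA-seq log2 fold change: r = {r:.3f}, "
          f"sign agreement = {sign_agree:.2f}")


if __name__ == "__main__":
    main()
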