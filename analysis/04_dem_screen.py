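#!/usr/bin/env python
"""Call differential metabolites on the simulated peak-area matrix.

Total-area normalization, half-minimum imputation, Welch t-tests,
cross-validated PLS-DA VIP, then the FC >= 1.5 / VIP >= 1 gates; recovery
is scored against the planted truth, and the QC-repeatability report is
produced for the sample columns.

Writes results/dem/{dem_table,summary,qc_spearman}.csv.
"""

from pathlib import Path

import pandas as pd

from milletol import dem, io, simulate

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated" / "metabolites"
OUT = ROOT / "results" / "dem"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    peaks = io.read_matrix(SIM / "peaks.csv")
    groups = io.read_sample_sheet(SIM / "samples.csv")
    truth = simulate.SimTruth.from_dir(SIM / "truth")

    res, summary = dem.dem_pipeline(peaks, groups, seed=1)
    res.round(4).to_csv(OUT / "dem_table.csv", index_label="metabolite")

    planted = set(truth.tables["dem_metabolites"]["metabolite"])
    called = set(res.index[res["call"] != "unchanged"])
    recall = len(called & planted) / len(planted)
    fdp = len(called - planted) / max(len(called), 1)
    pd.DataFrame(
        [
            {
                "total_called": summary.total,
                "up": summary.up,
                "down": summary.down,
                "planted": len(planted),
                "recall": round(recall, 3),
                "false_discovery_proportion": round(fdp, 3),
            }
        ]
    ).to_csv(OUT / "summary.csv", index=False)

    qc = dem.qc_repeatability(peaks.dropna())
    qc.spearman.round(3).to_csv(OUT / "qc_spearman.csv")

    print(f"DEMs called: {summary.total} ({summary.up} up, {summary.down} down) "
          f"of {len(res)} metabolites")
    print(f"planted-truth recall = {recall:.2f}, "
          f"false-discovery proportion = {fdp:.2f}")
    print("note: at 3 replicates/group the fold-change gate alone admits "
          "~10% of null metabolites, so the false-discovery proportion of "
          "the FC+VIP screen is high by construction; see docs/methods.md")


if __name__ == "__main__":
    main()
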