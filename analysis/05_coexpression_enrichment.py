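#!/usr/bin/env python
"""Build the gene-metabolite co-expression network and run enrichment.

Applies the r^2 > 0.8 and p < 0.05 double gate to all gene x metabolite
pairs of the simulated coupled profiles, scores planted-edge recovery, and
runs hypergeometric enrichment of the network genes against a toy pathway
collection built around the planted pairs.

Writes results/network/{edges.csv,network.graphml,enrichment.csv}.
"""

from pathlib import Path

from milletol import enrich, io, network, simulate

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated" / "coupled"
OUT = ROOT / "results" / "network"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    genes = io.read_matrix(SIM / "gene_profiles.csv")
    mets = io.read_matrix(SIM / "metabolite_profiles.csv")
    truth = simulate.SimTruth.from_dir(SIM / "truth")

    edges = network.build_network(genes, mets)
    edges.round(4).to_csv(OUT / "edges.csv", index=False)
    network.to_graphml(edges, OUT / "network.graphml")

    planted = set(zip(truth.tables["edges"]["gene"], truth.tables["edges"]["metabolite"]))
    found = set(zip(edges["gene"], edges["metabolite"]))
    recall = len(found & planted) / len(planted)
    spurious = len(found - planted)
    null_rate = spurious / (len(genes) * len(mets) - len(planted))

    # toy pathway collection: planted-pair genes vs null genes
    pair_genes = {g for g, _ in planted}
    background = set(genes.index)
    pathways = {
        "planted_module": {"description": "planted coupled pairs", "members": pair_genes},
        "null_module": {
            "description": "independent genes",
            "members": set(list(background - pair_genes)[:40]),
        },
    }
    selected = {g for g, _ in found}
    table = enrich.hypergeom_enrich(selected, background, pathways)
    table.to_csv(OUT / "enrichment.csv", index=False)

    print(f"edges passing r^2 > 0.8 and p < 0.05: {len(edges)} "
          f"({(edges['sign'] == 'positive').sum()} positive)")
    print(f"planted-edge recall = {recall:.2f}; spurious edges = {spurious} "
          f"({100 * null_rate:.1f}% of the {len(genes) * len(mets) - len(planted)} "
          "null pairs — at n = 6 the double gate admits ~1.5% of null pairs)")
    top = table.iloc[0]
    print(f"top enriched set: {top['pathway']} "
          f"(k={top['k']}/{top['K']}, p={top['pvalue']:.2e}, q={top['qvalue']:.2e})")


if __name__ == "__main__":
    main()
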