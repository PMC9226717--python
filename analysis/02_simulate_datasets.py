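#!/usr/bin/env python
"""Generate the synthetic study datasets used by the downstream drivers.

Seed-controlled generators emulate the study's data shapes: a 20-variety
phenotype panel driven by a latent tolerance factor, a 2000-gene count
matrix with 5% planted differential genes, a 300-metabolite peak-area
matrix with 10% planted differential metabolites, and coupled
gene-metabolite profiles with 20 planted correlated pairs. Ground truth
is written next to each dataset for the recovery analyses.

Writes results/simulated/<dataset>/... (data + truth).
"""

from pathlib import Path

from milletol import simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 20260921


def main() -> None:
    pheno, t_pheno = simulate.simulate_phenotypes(seed=SEED)
    d = OUT / "phenotypes"
    d.mkdir(parents=True, exist_ok=True)
    pheno.to_csv(d / "phenotypes.csv", index=False)
    t_pheno.to_dir(d / "truth")

    counts, lengths, groups, t_counts = simulate.simulate_counts(
        n_per_group=5, seed=SEED
    )
    d = OUT / "counts"
    d.mkdir(parents=True, exist_ok=True)
    counts.to_csv(d / "counts.csv", index_label="gene")
    lengths.rename_axis("gene").to_csv(d / "lengths.csv")
    groups.rename_axis("sample").to_csv(d / "samples.csv")
    t_counts.to_dir(d / "truth")

    peaks, m_groups, t_mets = simulate.simulate_metabolites(seed=SEED)
    d = OUT / "metabolites"
    d.mkdir(parents=True, exist_ok=True)
    peaks.to_csv(d / "peaks.csv", index_label="metabolite")
    m_groups.rename_axis("sample").to_csv(d / "samples.csv")
    t_mets.to_dir(d / "truth")

    genes, mets, t_pairs = simulate.simulate_coupled(seed=SEED)
    d = OUT / "coupled"
    d.mkdir(parents=True, exist_ok=True)
    genes.to_csv(d / "gene_profiles.csv", index_label="gene")
    mets.to_csv(d / "metabolite_profiles.csv", index_label="metabolite")
    t_pairs.to_dir(d / "truth")

    print(f"phenotypes: {pheno['variety'].nunique()} varieties, "
          f"{pheno['indicator'].nunique()} indicators, 3 replicates/condition")
    print(f"counts:     {counts.shape[0]} genes x {counts.shape[1]} samples, "
          f"{len(t_counts.tables['de_genes'])} planted DEGs")
    print(f"peaks:      {peaks.shape[0]} metabolites x {peaks.shape[1]} samples, "
          f"{len(t_mets.tables['dem_metabolites'])} planted DEMs")
    print(f"coupled:    {genes.shape[0]} genes / {mets.shape[0]} metabolites, "
          f"{len(t_pairs.tables['edges'])} planted pairs")


if __name__ == "__main__":
    main()
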