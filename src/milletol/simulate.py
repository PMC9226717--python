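"""Seed-controlled synthetic data with planted ground truth.

Each generator is a pure function of (parameters, seed) and returns the
data in the exact shape the corresponding pipeline stage consumes, plus a
:class:`SimTruth` recording what was planted (latent tolerance scores,
differential features, correlated pairs) for recovery testing. Default
shapes mirror a 20-variety / 8-indicator field screen with 3 biological
replicates, a ~2000-gene count matrix and a ~300-metabolite peak table —
the same statistical regime as the study design this package emulates, at
desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError

DEFAULT_INDICATORS = (
    "MDA",
    "soluble_protein",
    "chlorophyll",
    "net_photosynthetic_rate",
    "transpiration_rate",
    "stomatal_conductance",
    "dry_matter",
    "grain_weight_per_panicle",
)
DEFAULT_COST_INDICATORS = ("MDA",)


@dataclass
class SimTruth:
    """Planted ground truth plus the full parameter set and seed."""

    kind: str
    params: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "params.txt", "w") as fh:
            fh.write(f"kind: {self.kind}\n")
            for k, v in sorted(self.params.items()):
                fh.write(f"{k}: {v}\n")
        for name, tab in self.tables.items():
            tab.to_csv(path / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, path) -> "SimTruth":
        path = Path(path)
        params: dict = {}
        kind = ""
        with open(path / "params.txt") as fh:
            for line in fh:
                key, _, val = line.strip().partition(": ")
                if key == "kind":
                    kind = val
                else:
                    try:
                        params[key] = int(val)
                    except ValueError:
                        try:
                            params[key] = float(val)
                        except ValueError:
                            params[key] = val
        tables = {
            p.stem: pd.read_csv(p)
            for p in sorted(path.glob("*.csv"))
        }
        return cls(kind=kind, params=params, tables=tables)


def simulate_phenotypes(
    n_varieties: int = 20,
    indicators=DEFAULT_INDICATORS,
    cost_indicators=DEFAULT_COST_INDICATORS,
    loading_strength: float = 0.8,
    noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotype panel driven by a single latent tolerance factor.

    Latent tolerance z_i ~ N(0,1). The treatment/control relative effect on
    indicator j of variety i is baseline_j * exp(loading_strength*lambda_j*z_i
    + eps_ij), lambda_j = +1 for benefit indicators, -1 for cost indicators
    (stress raises them), eps ~ N(0, noise_sd^2). Stress baselines: benefit
    indicators drop to 0.6 of control, cost indicators rise 1.6-fold —
    typical magnitudes for herbicide-stressed seedlings. Replicates scatter
    log-normally (sd = noise_sd) around each condition mean.
    """
    if not 0 <= loading_strength <= 1:
        raise ConfigError("loading_strength must be in [0, 1]")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if n_varieties < 2 or replicates < 1:
        raise ConfigError("need >=2 varieties and >=1 replicate")
    indicators = list(indicators)
    cost = set(cost_indicators)
    unknown = cost - set(indicators)
    if unknown:
        raise ConfigError(f"cost indicators not in indicator list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    varieties = [f"V{i+1:02d}" for i in range(n_varieties)]
    z = rng.standard_normal(n_varieties)
    # per-indicator measurement scale (assay units differ wildly in practice)
    scales = np.exp(rng.normal(3.0, 0.5, size=len(indicators)))
    rows = []
    for j, ind in enumerate(indicators):
        lam = -1.0 if ind in cost else 1.0
        baseline = 1.6 if ind in cost else 0.6
        eps = rng.normal(0.0, noise_sd, size=n_varieties)
        effect = baseline * np.exp(loading_strength * lam * z + eps)
        ctrl_mean = scales[j] * np.exp(rng.normal(0.0, 0.1, size=n_varieties))
        trt_mean = ctrl_mean * effect
        for i, var in enumerate(varieties):
            for cond, mean in (("control", ctrl_mean[i]), ("treatment", trt_mean[i])):
                reps = mean * np.exp(rng.normal(0.0, noise_sd, size=replicates))
                for rep, val in enumerate(reps, start=1):
                    rows.append((var, ind, cond, rep, val))
    pheno = pd.DataFrame(
        rows, columns=["variety", "indicator", "condition", "replicate", "value"]
    )
    truth = SimTruth(
        kind="phenotypes",
        params={
            "n_varieties": n_varieties,
            "loading_strength": loading_strength,
            "noise_sd": noise_sd,
            "replicates": replicates,
            "seed": seed,
            "cost_indicators": ",".join(sorted(cost)),
        },
        tables={
            "latent_tolerance": pd.DataFrame({"variety": varieties, "z": z})
        },
    )
    return pheno, truth


def simulate_counts(
    n_genes: int = 2000,
    n_per_group: int = 3,
    dispersion: float = 0.1,
    de_fraction: float = 0.05,
    de_log2fc: float = 2.0,
    mean_log_mu: float = 5.0,
    sd_log_mu: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, SimTruth]:
    """Negative-binomial count matrix with planted differential genes.

    Gene base means are log-normal (ln mu ~ N(mean_log_mu, sd_log_mu));
    counts are NB with variance mu + dispersion*mu^2; a de_fraction subset
    is shifted by ±de_log2fc in the treatment group (half up, half down).
    Returns (counts, lengths, groups, truth); lengths uniform 500-5000 bp.
    """
    if not 0 <= de_fraction <= 1:
        raise ConfigError("de_fraction must be in [0, 1]")
    if dispersion < 0 or n_per_group < 2 or n_genes < 1:
        raise ConfigError("invalid simulation parameters")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i+1:05d}" for i in range(n_genes)]
    mu = np.exp(rng.normal(mean_log_mu, sd_log_mu, size=n_genes))
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    true_lfc = np.zeros(n_genes)
    half = n_de // 2
    true_lfc[de_idx[:half]] = de_log2fc
    true_lfc[de_idx[half:]] = -de_log2fc
    mu_trt = mu * 2.0**true_lfc

    def draw(mean_vec, n_cols):
        mean = np.tile(mean_vec[:, None], (1, n_cols))
        if dispersion == 0:
            return rng.poisson(mean)
        r = 1.0 / dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    ctrl = draw(mu, n_per_group)
    trt = draw(mu_trt, n_per_group)
    samples = [f"C{i+1}" for i in range(n_per_group)] + [
        f"T{i+1}" for i in range(n_per_group)
    ]
    counts = pd.DataFrame(
        np.hstack([ctrl, trt]), index=genes, columns=samples, dtype=int
    )
    lengths = pd.Series(
        rng.integers(500, 5001, size=n_genes), index=genes, name="length"
    )
    groups = pd.Series(
        ["control"] * n_per_group + ["treatment"] * n_per_group,
        index=samples,
        name="group",
    )
    truth = SimTruth(
        kind="counts",
        params={
            "n_genes": n_genes,
            "n_per_group": n_per_group,
            "dispersion": dispersion,
            "de_fraction": de_fraction,
            "de_log2fc": de_log2fc,
            "mean_log_mu": mean_log_mu,
            "sd_log_mu": sd_log_mu,
            "seed": seed,
        },
        tables={
            "de_genes": pd.DataFrame(
                {
                    "gene": np.array(genes)[de_idx],
                    "true_log2fc": true_lfc[de_idx],
                }
            )
        },
    )
    return counts, lengths, groups, truth


def simulate_metabolites(
    n_metabolites: int = 300,
    n_per_group: int = 3,
    noise_sd_log: float = 0.3,
    dem_fraction: float = 0.1,
    dem_fc: float = 2.5,
    missing_rate: float = 0.05,
    mean_log_area: float = 13.0,
    sd_log_area: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Log-normal peak-area matrix with planted differential metabolites.

    Base abundances are log-normal; each sample value scatters log-normally
    (sd = noise_sd_log); planted DEMs are multiplied (up) or divided (down)
    by dem_fc in the treatment group; cells go missing at random at
    ``missing_rate`` (at least one observation per metabolite is kept).
    Returns (peaks, groups, truth).
    """
    if not 0 <= dem_fraction <= 1 or not 0 <= missing_rate < 1:
        raise ConfigError("fractions must be in [0, 1)")
    if n_per_group < 2:
        raise ConfigError("need >=2 samples per group")
    rng = np.random.default_rng(seed)
    mets = [f"met{i+1:04d}" for i in range(n_metabolites)]
    base = np.exp(rng.normal(mean_log_area, sd_log_area, size=n_metabolites))
    n_dem = int(round(dem_fraction * n_metabolites))
    dem_idx = rng.choice(n_metabolites, size=n_dem, replace=False)
    direction = np.zeros(n_metabolites)
    half = n_dem // 2
    direction[dem_idx[:half]] = 1.0
    direction[dem_idx[half:]] = -1.0
    fc = dem_fc**direction

    n_tot = 2 * n_per_group
    noise = np.exp(rng.normal(0.0, noise_sd_log, size=(n_metabolites, n_tot)))
    areas = base[:, None] * noise
    areas[:, n_per_group:] *= fc[:, None]
    mask = rng.random((n_metabolites, n_tot)) < missing_rate
    # keep every metabolite observed at least once
    all_gone = mask.all(axis=1)
    mask[all_gone, 0] = False
    areas = np.where(mask, np.nan, areas)
    samples = [f"C{i+1}" for i in range(n_per_group)] + [
        f"T{i+1}" for i in range(n_per_group)
    ]
    peaks = pd.DataFrame(areas, index=mets, columns=samples)
    groups = pd.Series(
        ["control"] * n_per_group + ["treatment"] * n_per_group,
        index=samples,
        name="group",
    )
    truth = SimTruth(
        kind="metabolites",
        params={
            "n_metabolites": n_metabolites,
            "n_per_group": n_per_group,
            "noise_sd_log": noise_sd_log,
            "dem_fraction": dem_fraction,
            "dem_fc": dem_fc,
            "missing_rate": missing_rate,
            "mean_log_area": mean_log_area,
            "sd_log_area": sd_log_area,
            "seed": seed,
        },
        tables={
            "dem_metabolites": pd.DataFrame(
                {
                    "metabolite": np.array(mets)[dem_idx],
                    "true_fc": fc[dem_idx],
                }
            )
        },
    )
    return peaks, groups, truth


def simulate_coupled(
    n_pairs: int = 20,
    n_null_genes: int = 80,
    n_null_metabolites: int = 80,
    pair_correlation: float = 0.95,
    n_samples: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Gene and metabolite profiles with planted correlated pairs.

    Each planted (gene, metabolite) pair is drawn from a bivariate standard
    normal with the stated correlation across the shared samples; null
    features are independent standard normals. Returns
    (gene profiles, metabolite profiles, truth).
    """
    if not -1 < pair_correlation < 1:
        raise ConfigError("pair_correlation must be in (-1, 1)")
    if n_samples < 3:
        raise ConfigError("need n_samples >= 3")
    rng = np.random.default_rng(seed)
    samples = [f"S{i+1}" for i in range(n_samples)]
    rho = pair_correlation
    g_pair = rng.standard_normal((n_pairs, n_samples))
    m_pair = rho * g_pair + np.sqrt(1 - rho**2) * rng.standard_normal(
        (n_pairs, n_samples)
    )
    g_null = rng.standard_normal((n_null_genes, n_samples))
    m_null = rng.standard_normal((n_null_metabolites, n_samples))
    gene_ids = [f"pair_gene{i+1:03d}" for i in range(n_pairs)] + [
        f"null_gene{i+1:03d}" for i in range(n_null_genes)
    ]
    met_ids = [f"pair_met{i+1:03d}" for i in range(n_pairs)] + [
        f"null_met{i+1:03d}" for i in range(n_null_metabolites)
    ]
    genes = pd.DataFrame(np.vstack([g_pair, g_null]), index=gene_ids, columns=samples)
    mets = pd.DataFrame(np.vstack([m_pair, m_null]), index=met_ids, columns=samples)
    truth = SimTruth(
        kind="coupled",
        params={
            "n_pairs": n_pairs,
            "n_null_genes": n_null_genes,
            "n_null_metabolites": n_null_metabolites,
            "pair_correlation": pair_correlation,
            "n_samples": n_samples,
            "seed": seed,
        },
        tables={
            "edges": pd.DataFrame(
                {
                    "gene": gene_ids[:n_pairs],
                    "metabolite": met_ids[:n_pairs],
                    "true_correlation": rho,
                }
            )
        },
    )
    return genes, mets, truth


def simulate_ct_table(
    rnaseq_log2fc: pd.Series,
    noise_sd: float = 0.3,
    replicates: int = 3,
    reference_ct: float = 18.0,
    base_target_ct: float = 26.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """qPCR Ct table whose expected log2 ratios equal the given RNA-seq
    log2 fold changes plus technical noise (sd in log2/cycle units)."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene, lfc in rnaseq_log2fc.items():
        for cond, shift in (("control", 0.0), ("treatment", -lfc)):
            for rep in range(1, replicates + 1):
                ct_t = base_target_ct + shift + rng.normal(0.0, noise_sd)
                ct_r = reference_ct + rng.normal(0.0, noise_sd / 3)
                rows.append((gene, f"{cond[:1]}{rep}", cond, rep, ct_t, ct_r))
    records = pd.DataFrame(
        rows,
        columns=["gene", "sample", "condition", "replicate", "ct_target", "ct_reference"],
    )
    truth = SimTruth(
        kind="ct",
        params={"noise_sd": noise_sd, "replicates": replicates, "seed": seed},
        tables={
            "true_log2fc": rnaseq_log2fc.rename("true_log2fc")
            .rename_axis("gene")
            .reset_index()
        },
    )
    return records, truth
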