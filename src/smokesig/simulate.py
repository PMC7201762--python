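"""Synthetic study generator with planted, recoverable structure.

Emulates the shape of a two-cohort smoking methylation study: a probe x
sample beta-value matrix with a block of signature probes whose mean
beta is shifted in current-smokers; a gene x sample expression matrix in
which a subset of signature probes is linearly coupled to a gene in one
smoking group only (the differential-correlation ground truth); a probe
manifest with 450K-style CpG zone labels; clinical metadata; and a
scale-free-ish weighted PPI graph in which planted bridge proteins carry
most seed-pair shortest paths.

Beta-values follow Beta(mu*kappa, (1-mu)*kappa) with probe-level mu from
a bimodal mixture, reproducing the methylated/unmethylated modes of real
arrays. Probe-level parameters are drawn from the config seed alone, so
a validation cohort generated with a fresh sample seed shares the same
probe distributions — the train/validate design of a two-cohort study.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import FEATURE_TYPES
from .ppi import PPIGraph, score_to_distance

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_methylation",
    "simulate_expression_with_coupling",
    "simulate_ppi",
    "generate_study",
    "write_study",
]

#: CpG zone sampling proportions (open sea, island, shore, shelf) matching
#: the published signature's distribution; N/S sides split evenly.
ZONE_PROPORTIONS = {
    "OpenSea": 0.457,
    "Island": 0.257,
    "N_Shore": 0.0955,
    "S_Shore": 0.0955,
    "N_Shelf": 0.0475,
    "S_Shelf": 0.0475,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate a 102/43 cohort."""

    n_current: int = 102
    n_never: int = 43
    n_probes: int = 2000
    n_genes: int = 1000
    n_signature: int = 50
    delta_beta: float = 0.25
    beta_precision: float = 30.0
    n_dcs_pairs: int = 25
    r_high: float = 0.9
    r_low: float = 0.0
    ppi_n_proteins: int = 300
    ppi_edges_per_node: int = 3
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_signature > self.n_probes:
            raise ValueError("n_signature exceeds n_probes")
        if self.n_dcs_pairs > self.n_signature:
            raise ValueError("n_dcs_pairs exceeds n_signature")
        if not 0 <= self.delta_beta < 1:
            raise ValueError("delta_beta must be in [0, 1)")
        if not 0 <= self.r_low < self.r_high <= 1:
            raise ValueError("need 0 <= r_low < r_high <= 1")
        if self.delta_beta >= 0.75:
            raise ValueError(
                "delta_beta too large: shifted signature means leave (0, 1)"
            )


@dataclass
class SyntheticStudy:
    """One generated study with its planted ground truth."""

    config: SimulationConfig
    methylation: pd.DataFrame  # probes x samples
    expression: pd.DataFrame  # genes x samples
    manifest: pd.DataFrame
    metadata: pd.DataFrame
    ppi_edges: pd.DataFrame
    id_map: pd.DataFrame
    truth_signature_probes: set
    truth_dcs_pairs: set  # {(probe_id, gene_id)}
    truth_ppi_intermediates: set
    dcs_detail: pd.DataFrame = None
    validation_methylation: pd.DataFrame = None
    validation_metadata: pd.DataFrame = None


def _sample_ids(config: SimulationConfig, prefix: str = "S") -> list:
    n = config.n_current + config.n_never
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _probe_params(config: SimulationConfig):
    """Probe-level mean/shift parameters, a pure function of the config seed."""
    rng = np.random.default_rng(config.rng_seed)
    p = config.n_probes
    # bimodal mixture of mostly-unmethylated and mostly-methylated probes
    low = rng.beta(2.0, 10.0, size=p)
    high = rng.beta(10.0, 2.0, size=p)
    pick_high = rng.random(p) < 0.4
    mu = np.where(pick_high, high, low)
    mu = np.clip(mu, 0.03, 0.97)

    sig_idx = rng.choice(p, size=config.n_signature, replace=False)
    # signature probes get a central baseline so the shifted mean stays inside (0,1)
    margin = 0.02
    lo = config.delta_beta + margin
    hi = 1.0 - config.delta_beta - margin
    if lo >= hi:
        raise ValueError("delta_beta pushes signature means outside (0, 1)")
    mu[sig_idx] = rng.uniform(max(lo, 0.2), min(hi, 0.8), size=config.n_signature)
    signs = np.where(np.arange(config.n_signature) % 2 == 0, 1.0, -1.0)
    rng.shuffle(signs)

    mu_current = mu.copy()
    mu_current[sig_idx] = np.clip(
        mu[sig_idx] + signs * config.delta_beta, margin, 1 - margin
    )
    return mu, mu_current, sig_idx


def simulate_methylation(
    config: SimulationConfig, sample_seed: int | None = None
) -> tuple[pd.DataFrame, set]:
    """Generate the beta-value matrix and the planted signature probe ids.

    Non-signature probes share one Beta law across groups; each signature
    probe's mean is shifted by ±delta_beta in the current-smoker group.
    ``sample_seed`` controls the sample-level noise only, so a fresh seed
    yields an independent cohort with identical probe distributions.
    """
    mu_never, mu_current, sig_idx = _probe_params(config)
    rng = np.random.default_rng(
        config.rng_seed + 1 if sample_seed is None else sample_seed
    )
    k = config.beta_precision
    nc, nn = config.n_current, config.n_never

    def draw(mu, n):
        a = np.clip(mu * k, 1e-3, None)[:, None]
        b = np.clip((1 - mu) * k, 1e-3, None)[:, None]
        return rng.beta(a, b, size=(config.n_probes, n))

    values = np.concatenate([draw(mu_current, nc), draw(mu_never, nn)], axis=1)
    values = np.clip(values, 0.0, 1.0)
    probes = [f"cgS{i:05d}" for i in range(1, config.n_probes + 1)]
    samples = _sample_ids(config)
    meth = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    truth = {probes[i] for i in sig_idx}
    return meth, truth


def simulate_expression_with_coupling(
    config: SimulationConfig,
    methylation: pd.DataFrame,
    truth_signature_probes: set,
    sample_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate expression with group-specific probe–gene coupling.

    Background genes are independent Gaussians on the log2 scale. Each of
    the ``n_dcs_pairs`` planted pairs couples one signature probe to one
    gene linearly (noise tuned so the within-group correlation targets
    ``r_high``) in a randomly chosen smoking group, and at ``r_low`` (pure
    noise when 0) in the other. Returns (expression, detail frame with
    columns probe_id, gene_id, coupled_group).
    """
    if config.n_dcs_pairs > len(truth_signature_probes):
        raise ValueError("more DCS pairs requested than signature probes available")
    rng = np.random.default_rng(
        (config.rng_seed + 2 if sample_seed is None else sample_seed) + 10_000
    )
    samples = list(methylation.columns)
    nc = config.n_current
    groups = {"current": np.arange(0, nc), "never": np.arange(nc, len(samples))}

    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    base = rng.uniform(4.0, 12.0, size=config.n_genes)
    expr = base[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, len(samples)))

    sig_probes = sorted(truth_signature_probes)
    chosen_probes = rng.choice(len(sig_probes), size=config.n_dcs_pairs, replace=False)
    chosen_genes = rng.choice(config.n_genes, size=config.n_dcs_pairs, replace=False)

    def couple(z_beta, r):
        if r <= 0:
            return rng.normal(0.0, 1.0, size=z_beta.size)
        sigma = np.sqrt(1.0 / r**2 - 1.0)
        return z_beta + sigma * rng.normal(0.0, 1.0, size=z_beta.size)

    detail = []
    for pi, gi in zip(chosen_probes, chosen_genes):
        probe = sig_probes[pi]
        coupled = "current" if rng.random() < 0.5 else "never"
        other = "never" if coupled == "current" else "current"
        beta_row = methylation.loc[probe].to_numpy(dtype=float)
        for grp, r in ((coupled, config.r_high), (other, config.r_low)):
            idx = groups[grp]
            b = beta_row[idx]
            sd = b.std()
            z = (b - b.mean()) / sd if sd > 0 else np.zeros_like(b)
            expr[gi, idx] = base[gi] + couple(z, r)
        detail.append((probe, genes[gi], coupled))

    expression = pd.DataFrame(
        expr, index=pd.Index(genes, name="gene_id"), columns=samples
    )
    detail = pd.DataFrame(detail, columns=["probe_id", "gene_id", "coupled_group"])
    return expression, detail


def simulate_ppi(
    config: SimulationConfig, seed_proteins, n_bridges: int = 5
) -> tuple[pd.DataFrame, set]:
    """Generate a weighted PPI edge list with planted bridge proteins.

    The backbone is a preferential-attachment graph with background
    scores capped at 950 (distance >= 51). Seeds are partitioned across
    the bridge proteins; each seed links to its bridge, and bridges form
    a clique, all at score 1000 (distance 1). Seed-pair shortest paths
    therefore run through one or two bridges (cost 2–3), far cheaper
    than any backbone route, so every bridge carries the paths of its
    own seed block. Returns (edge frame, bridge protein set).
    """
    n = config.ppi_n_proteins
    proteins = [f"P{i:04d}" for i in range(1, n + 1)]
    seed_proteins = sorted(s for s in seed_proteins if s in set(proteins))
    rng = np.random.default_rng(config.rng_seed + 3)
    g = nx.barabasi_albert_graph(n, config.ppi_edges_per_node, seed=int(config.rng_seed % 2**31))
    rows = []
    for u, v in g.edges():
        rows.append((proteins[u], proteins[v], int(rng.integers(401, 951))))

    non_seed = [p for p in proteins if p not in set(seed_proteins)]
    bridge_pick = rng.choice(len(non_seed), size=min(n_bridges, len(non_seed)), replace=False)
    bridges = sorted(non_seed[i] for i in bridge_pick)
    for i, s in enumerate(seed_proteins):
        rows.append((bridges[i % len(bridges)], s, 1000))
    for i, b1 in enumerate(bridges):
        for b2 in bridges[i + 1:]:
            rows.append((b1, b2, 1000))

    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    # dedupe undirected edges keeping the max score
    key = edges.apply(lambda r: tuple(sorted((r.protein1, r.protein2))), axis=1)
    edges = (
        edges.assign(_key=key)
        .sort_values("combined_score")
        .drop_duplicates("_key", keep="last")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    return edges, set(bridges)


def _make_manifest(config: SimulationConfig, probes, truth_probes, genes) -> pd.DataFrame:
    rng = np.random.default_rng(config.rng_seed + 4)
    zones = list(ZONE_PROPORTIONS)
    probs = np.array([ZONE_PROPORTIONS[z] for z in zones])
    probs = probs / probs.sum()
    feats = rng.choice(zones, size=len(probes), p=probs)

    autosomes = [f"chr{i}" for i in range(1, 23)]
    chroms = rng.choice(autosomes, size=len(probes))
    truth = set(truth_probes)
    background = [i for i, p in enumerate(probes) if p not in truth]
    n_sex = max(1, int(0.02 * len(probes)))
    sexy = rng.choice(len(background), size=min(n_sex, len(background)), replace=False)
    for j in sexy:
        chroms[background[j]] = "chrX" if rng.random() < 0.5 else "chrY"

    gene_lists = []
    for i, probe in enumerate(probes):
        if probe not in truth and rng.random() < 0.2:
            gene_lists.append("")  # open-sea style gene-less probe
            continue
        k = 1 + (rng.random() < 0.15)
        pick = rng.choice(len(genes), size=k, replace=False)
        gene_lists.append(";".join(genes[j] for j in pick))
    return pd.DataFrame(
        {
            "probe_id": probes,
            "chromosome": chroms,
            "gene_symbols": gene_lists,
            "feature_type": feats,
        }
    )


def _make_metadata(config: SimulationConfig, samples, seed_shift: int = 5) -> pd.DataFrame:
    rng = np.random.default_rng(config.rng_seed + seed_shift)
    nc = config.n_current
    status = ["current"] * nc + ["never"] * (len(samples) - nc)
    n = len(samples)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "smoking_status": status,
            "age": rng.integers(40, 91, size=n),
            "gender": rng.choice(["female", "male"], size=n),
            "stage": rng.choice(
                ["I", "II", "III", "IV"], size=n, p=[0.55, 0.2, 0.2, 0.05]
            ),
            "vital_status": rng.choice(["alive", "dead"], size=n, p=[0.7, 0.3]),
            "survival_days": rng.integers(30, 4000, size=n),
        }
    ).set_index("sample_id")


def generate_study(
    config: SimulationConfig,
    out_dir=None,
    include_validation: bool = True,
) -> SyntheticStudy:
    """Generate the full paired study (and optionally write it to disk).

    The validation cohort reuses the probe-level parameters with a fresh
    sample seed, mirroring a two-cohort train/validate design.
    """
    meth, truth_probes = simulate_methylation(config)
    expr, dcs_detail = simulate_expression_with_coupling(config, meth, truth_probes)
    genes = list(expr.index)
    manifest = _make_manifest(config, list(meth.index), truth_probes, genes)
    metadata = _make_metadata(config, list(meth.columns))

    # gene <-> protein id map: the first ppi_n_proteins genes have proteins
    n_map = min(config.n_genes, config.ppi_n_proteins)
    id_map = pd.DataFrame(
        {
            "gene_symbol": genes[:n_map],
            "protein_id": [f"P{i:04d}" for i in range(1, n_map + 1)],
        }
    )
    sym_to_prot = dict(zip(id_map["gene_symbol"], id_map["protein_id"]))
    seed_proteins = sorted(
        {sym_to_prot[g] for g in dcs_detail["gene_id"] if g in sym_to_prot}
    )
    ppi_edges, bridges = simulate_ppi(config, seed_proteins)

    study = SyntheticStudy(
        config=config,
        methylation=meth,
        expression=expr,
        manifest=manifest,
        metadata=metadata,
        ppi_edges=ppi_edges,
        id_map=id_map,
        truth_signature_probes=truth_probes,
        truth_dcs_pairs=set(
            zip(dcs_detail["probe_id"], dcs_detail["gene_id"])
        ),
        truth_ppi_intermediates=bridges,
        dcs_detail=dcs_detail,
    )
    if include_validation:
        val_seed = (config.rng_seed + 777_001) % 2**31
        study.validation_methylation, _ = simulate_methylation(
            config, sample_seed=val_seed
        )
        study.validation_methylation.columns = [
            f"V{i:04d}" for i in range(1, len(study.validation_methylation.columns) + 1)
        ]
        study.validation_metadata = _make_metadata(
            config, list(study.validation_methylation.columns), seed_shift=6
        )
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Write every standard-format file of the study to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.methylation.to_csv(out / "methylation.tsv", sep="\t")
    study.expression.to_csv(out / "expression.tsv", sep="\t")
    study.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    study.metadata.to_csv(out / "metadata.tsv", sep="\t")
    study.ppi_edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
    study.id_map.to_csv(out / "id_map.tsv", sep="\t", index=False)
    if study.validation_methylation is not None:
        study.validation_methylation.to_csv(out / "validation_methylation.tsv", sep="\t")
        study.validation_metadata.to_csv(out / "validation_metadata.tsv", sep="\t")
    truth = {
        "config": asdict(study.config),
        "signature_probes": sorted(study.truth_signature_probes),
        "dcs_pairs": sorted(map(list, study.truth_dcs_pairs)),
        "ppi_intermediates": sorted(study.truth_ppi_intermediates),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
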