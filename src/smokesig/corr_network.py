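"""Probe–gene differential correlation and the gene weight network.

Signature probes are linked to genes by computing, within each smoking
group, either the biweight midcorrelation (robust to outliers) or
Spearman's rank correlation between the probe's beta-values and every
gene's expression. The Differential Correlation Strategy (DCS) then keeps
pairs whose correlation magnitude is high (>= TS2) in one group and low
(<= TS1) in the other — methylation–expression coupling that switches
with smoking status. Genes linked this way feed a soft-threshold
co-expression weight network whose most connected nodes are called hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bicor",
    "spearman_rho",
    "correlate_probes_genes",
    "DCSConfig",
    "dcs_select",
    "GeneNetwork",
    "build_weight_network",
    "pick_soft_threshold",
    "RelatedGeneSets",
    "intersect_sets",
]


def _bicor_normalize(x: np.ndarray, zero_mad: str = "pearson") -> np.ndarray:
    """Tukey-biweight normalised deviations; unit Euclidean norm.

    bicor(x, y) is the inner product of the normalised vectors. MAD is the
    unscaled median absolute deviation, with the classical 9*MAD tuning
    constant. A zero-MAD vector falls back to the Pearson normalisation
    (with a warning) or raises, per ``zero_mad``.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        if zero_mad == "error":
            raise ValueError("zero MAD: biweight weights undefined")
        warnings.warn("zero MAD; falling back to Pearson normalisation")
        d = x - x.mean()
        norm = np.sqrt(np.sum(d**2))
        if norm == 0:
            raise ValueError("constant vector: correlation undefined")
        return d / norm
    u = (x - med) / (9.0 * mad)
    a = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    d = a * (x - med)
    norm = np.sqrt(np.sum(d**2))
    if norm == 0:
        raise ValueError("all biweight weights vanished")
    return d / norm


def bicor(x, y, zero_mad: str = "pearson") -> float:
    """Biweight midcorrelation of two vectors (length >= 4), clipped to [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    if x.size < 4:
        raise ValueError("bicor needs at least 4 observations")
    xt = _bicor_normalize(x, zero_mad)
    yt = _bicor_normalize(y, zero_mad)
    return float(np.clip(np.dot(xt, yt), -1.0, 1.0))


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation (Pearson on midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("spearman needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def _rank_normalize(M: np.ndarray) -> np.ndarray:
    """Row-wise midranks, centred and unit-normalised (for fast Spearman)."""
    R = stats.rankdata(M, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(R**2, axis=1))
    norms[norms == 0] = np.nan  # constant rows: undefined
    return R / norms[:, None]


def _bicor_rows(M: np.ndarray) -> np.ndarray:
    out = np.empty_like(M, dtype=float)
    for i in range(M.shape[0]):
        row = M[i]
        try:
            out[i] = _bicor_normalize(row)
        except ValueError:
            out[i] = np.nan
    return out


def correlate_probes_genes(
    signature_methylation: pd.DataFrame,
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    method: str = "bicor",
) -> pd.DataFrame:
    """Within-group probe–gene correlations for every (signature probe, gene) pair.

    Returns a long-format frame with columns ``probe_id``, ``gene_id``,
    ``method``, ``r_current``, ``r_never``. Pairs involving a vector that
    is constant within a group are reported as NaN with a warning (they
    can never satisfy the DCS rule).
    """
    from .prescreen import split_groups

    if method not in ("bicor", "spearman"):
        raise ValueError("method must be 'bicor' or 'spearman'")
    shared = [s for s in signature_methylation.columns if s in expression.columns]
    if not shared:
        raise ValueError("no shared samples between methylation and expression")
    current, never = split_groups(metadata, shared)
    for name, grp in (("current", current), ("never", never)):
        if len(grp) < 4:
            raise ValueError(f"need >= 4 samples in the {name} group, got {len(grp)}")

    normalize = _bicor_rows if method == "bicor" else _rank_normalize
    r = {}
    for gname, grp in (("r_current", current), ("r_never", never)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-row fallbacks summarised below
            P = normalize(signature_methylation[grp].to_numpy(dtype=float))
            G = normalize(expression[grp].to_numpy(dtype=float))
        r[gname] = np.clip(P @ G.T, -1.0, 1.0)  # probes x genes

    probes = signature_methylation.index
    genes = expression.index
    n_bad = int(np.isnan(r["r_current"]).any(axis=1).sum() + np.isnan(r["r_never"]).any(axis=1).sum())
    table = pd.DataFrame(
        {
            "probe_id": np.repeat(probes, len(genes)),
            "gene_id": np.tile(genes, len(probes)),
            "method": method,
            "r_current": r["r_current"].ravel(),
            "r_never": r["r_never"].ravel(),
        }
    )
    n_skipped = int(table[["r_current", "r_never"]].isna().any(axis=1).sum())
    if n_skipped:
        warnings.warn(
            f"{n_skipped} pair(s) skipped (constant vector within a group)"
        )
    return table


@dataclass(frozen=True)
class DCSConfig:
    """Two-threshold differential-correlation rule.

    ts1: low-magnitude threshold (a pair must be <= ts1 in one group);
    ts2: high-magnitude threshold (and >= ts2 in the other). Both
    comparisons are inclusive.
    """

    ts1: float = 0.3
    ts2: float = 0.6
    rule: str = "cross"

    def __post_init__(self):
        if not 0 <= self.ts1 < self.ts2 <= 1:
            raise ValueError("need 0 <= TS1 < TS2 <= 1")
        if self.rule not in _DCS_RULES:
            raise ValueError(f"unknown DCS rule {self.rule!r}")


def _rule_cross(rc: np.ndarray, rn: np.ndarray, ts1: float, ts2: float) -> np.ndarray:
    ac, an = np.abs(rc), np.abs(rn)
    return ((ac >= ts2) & (an <= ts1)) | ((an >= ts2) & (ac <= ts1))


_DCS_RULES = {"cross": _rule_cross}


def dcs_select(
    table: pd.DataFrame, config: DCSConfig | None = None
) -> tuple[pd.DataFrame, list]:
    """Apply the DCS rule to a correlation table.

    Returns (selected pairs frame, sorted union of their genes). Pairs
    with NaN correlations are never selected.
    """
    cfg = config or DCSConfig()
    rc = table["r_current"].to_numpy(dtype=float)
    rn = table["r_never"].to_numpy(dtype=float)
    ok = np.isfinite(rc) & np.isfinite(rn)
    mask = np.zeros(len(table), dtype=bool)
    mask[ok] = _DCS_RULES[cfg.rule](rc[ok], rn[ok], cfg.ts1, cfg.ts2)
    selected = table.loc[mask].copy()
    genes = sorted(selected["gene_id"].unique())
    return selected, genes


@dataclass
class GeneNetwork:
    """Soft-threshold weighted gene co-expression network with hub calls."""

    genes: list
    adjacency: pd.DataFrame  # symmetric, a_ij in [0,1], zero diagonal
    beta_soft: float
    connectivity: pd.Series  # k_i = sum_{j != i} a_ij
    hub_threshold: float
    hubs: list  # genes with k_i > hub_threshold


def build_weight_network(
    expression: pd.DataFrame,
    beta_soft: float = 6.0,
    hub_threshold: float = 10.75,
    method: str = "pearson",
) -> GeneNetwork:
    """Weight network over genes: a_ij = |cor(GE_i, GE_j)|^beta_soft.

    Connectivity is the off-diagonal adjacency row sum; genes whose
    connectivity exceeds ``hub_threshold`` are flagged as hubs. Constant
    genes are excluded with a warning.
    """
    if len(expression) < 3:
        raise ValueError("need at least 3 genes")
    M = expression.to_numpy(dtype=float)
    const = np.ptp(M, axis=1) == 0
    if const.any():
        warnings.warn(
            f"excluding {int(const.sum())} constant gene(s) from the network"
        )
        expression = expression.loc[~const]
        M = expression.to_numpy(dtype=float)
    genes = expression.index.tolist()
    if method == "pearson":
        C = np.corrcoef(M)
    elif method == "bicor":
        B = _bicor_rows(M)
        C = np.clip(B @ B.T, -1.0, 1.0)
    else:
        raise ValueError("method must be 'pearson' or 'bicor'")
    A = np.abs(C) ** beta_soft
    np.fill_diagonal(A, 0.0)
    adjacency = pd.DataFrame(A, index=genes, columns=genes)
    k = adjacency.sum(axis=1)
    hubs = k.index[k > hub_threshold].tolist()
    return GeneNetwork(
        genes=genes,
        adjacency=adjacency,
        beta_soft=beta_soft,
        connectivity=k,
        hub_threshold=hub_threshold,
        hubs=hubs,
    )


def pick_soft_threshold(
    expression: pd.DataFrame, powers=range(1, 13), r2_target: float = 0.8
) -> int:
    """Smallest power whose connectivity distribution is scale-free-ish.

    Fits log10 p(k) ~ log10 k on binned connectivities and returns the
    first power reaching ``r2_target``, else the power with maximal R².
    """
    best_power, best_r2 = None, -np.inf
    for b in powers:
        net = build_weight_network(expression, beta_soft=float(b), hub_threshold=np.inf)
        k = net.connectivity.to_numpy()
        k = k[k > 0]
        if k.size < 5:
            continue
        hist, edges = np.histogram(k, bins=min(10, k.size // 2))
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        if keep.sum() < 3:
            continue
        lx, ly = np.log10(centers[keep]), np.log10(hist[keep])
        r = np.corrcoef(lx, ly)[0, 1]
        r2 = r * r
        if r2 > best_r2:
            best_power, best_r2 = b, r2
        if r2 >= r2_target:
            return b
    if best_power is None:
        raise ValueError("could not assess scale-free fit on this matrix")
    return best_power


@dataclass(frozen=True)
class RelatedGeneSets:
    """Genes called by each correlation method and their overlap."""

    bimc_genes: tuple
    src_genes: tuple
    common_genes: tuple


def intersect_sets(bimc_genes, src_genes) -> RelatedGeneSets:
    """Stable sorted intersection of the bicor- and Spearman-derived gene sets."""
    b = tuple(sorted(set(bimc_genes)))
    s = tuple(sorted(set(src_genes)))
    return RelatedGeneSets(
        bimc_genes=b,
        src_genes=s,
        common_genes=tuple(sorted(set(b) & set(s))),
    )
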