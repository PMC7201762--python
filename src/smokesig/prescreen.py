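"""Epigenome-wide prescreen: Wilcoxon rank-sum per probe with BH FDR control.

The contrast is current-smokers versus never-smokers; records whose only
status is "ever" carry no usable side of the contrast and are dropped
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["wilcoxon_rank_sum", "bh_adjust", "PrescreenResult", "prescreen_probes"]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Mann–Whitney–Wilcoxon p-value for two independent samples.

    The exact null distribution is used when n1 + n2 <= 20 and the pooled
    data carry no ties; otherwise the normal approximation with midrank
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PrescreenResult:
    """Per-probe test results with the BH-selected probe set."""

    table: pd.DataFrame  # columns: p, p_adj, median_current, median_never, selected
    q_threshold: float

    @property
    def selected_probes(self) -> list:
        return self.table.index[self.table["selected"]].tolist()


def split_groups(metadata: pd.DataFrame, samples) -> tuple[list, list]:
    """Partition sample ids into (current, never), warning on 'ever'-only records."""
    meta = metadata.loc[metadata.index.intersection(samples)]
    status = meta["smoking_status"]
    n_ever = int((status == "ever").sum())
    if n_ever:
        warnings.warn(
            f"excluding {n_ever} sample(s) with status 'ever' from the "
            "current-vs-never contrast"
        )
    current = meta.index[status == "current"].tolist()
    never = meta.index[status == "never"].tolist()
    return current, never


def prescreen_probes(
    methylation: pd.DataFrame,
    metadata: pd.DataFrame,
    q: float = 0.05,
) -> PrescreenResult:
    """Test every probe for a current-vs-never methylation shift.

    Per-probe two-sided Wilcoxon rank-sum p-values are BH-adjusted across
    all tested probes; a probe is selected when its adjusted p <= ``q``.
    Group medians are reported alongside. Probe order is preserved.
    """
    current, never = split_groups(metadata, methylation.columns)
    if len(current) < 3 or len(never) < 3:
        raise ValueError(
            f"need at least 3 samples per group, got {len(current)} current "
            f"/ {len(never)} never"
        )
    X = methylation[current].to_numpy(dtype=float)
    Y = methylation[never].to_numpy(dtype=float)

    n_total = len(current) + len(never)
    if n_total <= 20:
        pvals = np.array(
            [wilcoxon_rank_sum(X[i], Y[i]) for i in range(X.shape[0])]
        )
    else:
        # vectorised normal approximation (tie + continuity corrected)
        res = stats.mannwhitneyu(
            X, Y, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
        pvals = np.asarray(res.pvalue, dtype=float)

    p_adj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "p": pvals,
            "p_adj": p_adj,
            "median_current": np.median(X, axis=1),
            "median_never": np.median(Y, axis=1),
            "selected": p_adj <= q,
        },
        index=methylation.index.copy(),
    )
    return PrescreenResult(table=table, q_threshold=q)
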