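"""Dataset filtering, normality auditing and annotation summaries.

The filtering rules mirror standard EWAS practice for 450K cohorts:
all-missing features go first, then samples with incomplete clinical
records, then everything on the sex chromosomes (smoking cohorts are
mixed-sex, and X/Y probes confound the contrast).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .io import REQUIRED_CLINICAL, VALID_CHROMOSOMES, FEATURE_TYPES, ValidationError

__all__ = [
    "FilterLog",
    "FilteredBundle",
    "filter_dataset",
    "jarque_bera_test",
    "NormalityReport",
    "normality_audit",
    "AnnotationSummary",
    "summarize_annotations",
]


@dataclass
class FilterLog:
    """Ordered record of how many entities each filtering rule removed."""

    steps: list = field(default_factory=list)

    def record(self, rule: str, removed_ids) -> None:
        self.steps.append((rule, len(removed_ids), list(removed_ids)))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, n) for r, n, _ in self.steps], columns=["rule", "n_removed"]
        )


@dataclass
class FilteredBundle:
    methylation: pd.DataFrame
    expression: pd.DataFrame | None
    manifest: pd.DataFrame | None
    metadata: pd.DataFrame | None
    log: FilterLog


def _gene_chromosomes(manifest: pd.DataFrame) -> dict:
    """Map each gene symbol to the chromosome of the probes that carry it."""
    out: dict = {}
    for chrom, genes in zip(manifest["chromosome"], manifest["gene_symbols"]):
        for g in genes:
            out.setdefault(g, chrom)
    return out


def filter_dataset(
    methylation: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    log2_transform: bool = False,
) -> FilteredBundle:
    """Apply the cohort filters, in order, and log what each removed.

    1. probes / genes whose values are missing in **all** samples;
    2. samples lacking any required clinical field
       (age, gender, stage, vital status, survival time);
    3. probes and genes on chrX / chrY (gene chromosomes are inferred from
       the manifest; genes absent from it are retained).

    If ``log2_transform`` is set the expression matrix is replaced by
    ``log2(x + 1)`` before filtering (GEO-style matrices arrive on the
    linear scale; the offset keeps zeros finite).

    The operation is idempotent: running it on its own output is a no-op.
    """
    log = FilterLog()
    meth = methylation.copy()
    expr = expression.copy() if expression is not None else None

    if expr is not None and log2_transform:
        expr = np.log2(expr + 1.0)

    if manifest is not None:
        unknown = manifest.loc[~manifest["chromosome"].isin(VALID_CHROMOSOMES)]
        if len(unknown):
            raise ValidationError(
                f"unknown chromosome labels for probes {unknown.index.tolist()[:10]}"
            )

    # rule (a): all-missing features
    dead_probes = meth.index[meth.isna().all(axis=1)]
    meth = meth.drop(index=dead_probes)
    log.record("probes_all_missing", dead_probes)
    if expr is not None:
        dead_genes = expr.index[expr.isna().all(axis=1)]
        expr = expr.drop(index=dead_genes)
        log.record("genes_all_missing", dead_genes)

    # rule (b): samples with incomplete clinical records
    meta = metadata
    if metadata is not None:
        present = [c for c in REQUIRED_CLINICAL if c in metadata.columns]
        absent_cols = [c for c in REQUIRED_CLINICAL if c not in metadata.columns]
        incomplete = metadata.index[metadata[present].isna().any(axis=1)]
        if absent_cols:
            warnings.warn(
                f"metadata lacks clinical columns {absent_cols}; "
                "completeness rule applied to the available ones"
            )
        meta = metadata.drop(index=incomplete)
        log.record("samples_incomplete_clinical", incomplete)
        keep = [s for s in meth.columns if s in meta.index]
        meth = meth[keep]
        if expr is not None:
            expr = expr[[s for s in expr.columns if s in meta.index]]

    # rule (c): sex chromosomes
    man = manifest
    if manifest is not None:
        sexy = manifest.index[manifest["chromosome"].isin(["chrX", "chrY"])]
        drop_probes = meth.index.intersection(sexy)
        meth = meth.drop(index=drop_probes)
        log.record("probes_sex_chromosome", drop_probes)
        man = manifest.drop(index=manifest.index.intersection(sexy))
        if expr is not None:
            gene_chrom = _gene_chromosomes(manifest)
            drop_genes = [
                g for g in expr.index if gene_chrom.get(g) in ("chrX", "chrY")
            ]
            expr = expr.drop(index=drop_genes)
            log.record("genes_sex_chromosome", drop_genes)

    return FilteredBundle(meth, expr, man, meta, log)


def jarque_bera_test(x) -> tuple[float, float]:
    """Jarque–Bera normality test: JB = (n/6)(S^2 + (K-3)^2/4).

    Skewness S and kurtosis K use biased (1/n) central moments; the
    p-value is the chi-square(2) asymptotic tail. Requires n >= 8 and a
    non-constant sample (skewness is undefined at zero variance).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-d sample")
    if arr.size < 8:
        raise ValueError("Jarque–Bera needs at least 8 observations")
    if np.ptp(arr) == 0:
        raise ValueError("constant sample: skewness undefined")
    res = stats.jarque_bera(arr)
    return float(res.statistic), float(res.pvalue)


@dataclass
class NormalityReport:
    """Per-probe Jarque–Bera results and the share that look normal."""

    table: pd.DataFrame  # columns: jb, p, normal
    alpha: float
    fraction_normal: float


def normality_audit(methylation: pd.DataFrame, alpha: float = 0.05) -> NormalityReport:
    """Test every probe's beta distribution for normality.

    ``fraction_normal`` is the share of probes with an uncorrected
    p >= alpha; beta-values are typically strongly bimodal, so on real
    arrays this fraction is small.
    """
    rows = {}
    for probe, values in methylation.iterrows():
        v = values.dropna().to_numpy()
        jb, p = jarque_bera_test(v)
        rows[probe] = (jb, p, p >= alpha)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["jb", "p", "normal"]
    )
    table.index.name = "probe_id"
    frac = float(table["normal"].mean()) if len(table) else float("nan")
    return NormalityReport(table=table, alpha=alpha, fraction_normal=frac)


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (printed-percentage style)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_ZONE_OF = {
    "Island": "Island",
    "N_Shore": "Shore",
    "S_Shore": "Shore",
    "N_Shelf": "Shelf",
    "S_Shelf": "Shelf",
    "OpenSea": "OpenSea",
}


@dataclass
class AnnotationSummary:
    """Feature-type distribution and gene mapping of a probe set."""

    n_probes: int
    feature_counts: dict
    feature_percentages: dict
    zone_counts: dict
    zone_percentages: dict
    n_probes_without_gene: int
    first_gene_map: pd.Series
    n_mapped_probes: int
    n_distinct_first_genes: int
    multi_probe_genes: tuple


def summarize_annotations(manifest: pd.DataFrame) -> AnnotationSummary:
    """Summarise a probe annotation set: where probes sit and what they map to.

    Probes with multiple gene symbols are attributed to the first symbol
    listed (the manifest orders symbols by likelihood). Zones aggregate the
    N_/S_ sides: shore = N_Shore + S_Shore, shelf likewise. Percentages are
    100*count/total rounded half-away-from-zero to one decimal.
    """
    if len(manifest) == 0:
        raise ValueError("empty annotation set")
    total = len(manifest)
    feats = manifest["feature_type"]
    feature_counts = {ft: int((feats == ft).sum()) for ft in FEATURE_TYPES}
    zone_counts = Counter(_ZONE_OF[f] for f in feats)
    zone_counts = {z: int(zone_counts.get(z, 0)) for z in ("OpenSea", "Island", "Shore", "Shelf")}

    first = manifest["gene_symbols"].map(lambda gs: gs[0] if gs else None)
    mapped = first.dropna()
    gene_counts = Counter(mapped)
    multi = tuple(sorted(g for g, c in gene_counts.items() if c >= 2))

    return AnnotationSummary(
        n_probes=total,
        feature_counts=feature_counts,
        feature_percentages={
            ft: _round1(100.0 * c / total) for ft, c in feature_counts.items()
        },
        zone_counts=zone_counts,
        zone_percentages={
            z: _round1(100.0 * c / total) for z, c in zone_counts.items()
        },
        n_probes_without_gene=int(first.isna().sum()),
        first_gene_map=mapped,
        n_mapped_probes=int(len(mapped)),
        n_distinct_first_genes=int(mapped.nunique()),
        multi_probe_genes=multi,
    )
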