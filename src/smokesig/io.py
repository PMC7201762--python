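"""Readers and validators for the pipeline's tabular input formats.

All matrices travel as :class:`pandas.DataFrame`: methylation is probe x
sample (beta-values in [0, 1]), expression is gene x sample (log2 scale),
and the probe manifest / sample metadata are row-per-entity tables indexed
by probe or sample id.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: Closed vocabulary of CpG annotation zones on 450K-style manifests.
FEATURE_TYPES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Chromosome labels accepted in manifests (autosomes plus sex chromosomes).
VALID_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

SMOKING_STATUSES = ("current", "never", "ever")

#: Clinical fields a sample must carry to survive filtering.
REQUIRED_CLINICAL = ("age", "gender", "stage", "vital_status", "survival_days")

_MISSING_TOKENS = {"", "-", "—", "NA", "nan"}


class ValidationError(ValueError):
    """An input file violates the format contract."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:10]}")


def load_methylation(path) -> pd.DataFrame:
    """Load a probe x sample beta-value matrix from TSV.

    Values must lie in [0, 1]; missing entries (empty / NA) are permitted
    and handled later by :func:`smokesig.preprocess.filter_dataset`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "probe")
    _check_unique(df.columns, "sample")
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValidationError("beta-values must lie in [0, 1]")
    return df.astype(float)


def load_expression(path) -> pd.DataFrame:
    """Load a gene x sample expression matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    return df.astype(float)


def _parse_genes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if text in _MISSING_TOKENS:
        return []
    return [g.strip() for g in text.split(";") if g.strip()]


def _parse_feature(cell) -> str:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return "OpenSea"
    text = str(cell).strip()
    if text in _MISSING_TOKENS:
        # dash convention: un-annotated probes sit in the open sea
        return "OpenSea"
    if text not in FEATURE_TYPES:
        raise ValidationError(f"unknown feature type {text!r}")
    return text


def load_manifest(path) -> pd.DataFrame:
    """Load a probe annotation manifest.

    Expected columns: ``probe_id``, ``chromosome``, ``gene_symbols``
    (semicolon-joined, dash or empty for none), ``feature_type``.
    Returns a frame indexed by probe id with ``gene_symbols`` parsed into
    ordered lists and ``feature_type`` normalised to the closed vocabulary.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "chromosome", "gene_symbols", "feature_type"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    df = pd.DataFrame(
        {
            "chromosome": raw["chromosome"].str.strip().to_numpy(),
            "gene_symbols": raw["gene_symbols"].map(_parse_genes).to_numpy(),
            "feature_type": raw["feature_type"].map(_parse_feature).to_numpy(),
        },
        index=pd.Index(raw["probe_id"].str.strip(), name="probe_id"),
    )
    _check_unique(df.index, "probe")
    bad = df.loc[~df["chromosome"].isin(VALID_CHROMOSOMES)]
    if len(bad):
        raise ValidationError(
            f"unknown chromosome labels for probes {bad.index.tolist()[:10]}"
        )
    return df


def load_metadata(path) -> pd.DataFrame:
    """Load sample metadata (smoking status plus clinical covariates)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    _check_unique(df.index, "sample")
    status = df["smoking_status"].astype(str).str.strip().str.lower()
    bad = status[~status.isin(SMOKING_STATUSES)]
    if len(bad):
        raise ValidationError(
            f"unknown smoking_status values: {sorted(bad.unique())}"
        )
    df = df.copy()
    df["smoking_status"] = status
    return df


def load_signature_annotation() -> pd.DataFrame:
    """Load the packaged 105-probe tobacco-exposure signature annotation.

    The published lung-adenocarcinoma smoking signature: probe id,
    chromosome, ordered gene symbols and CpG feature type for each of the
    105 signature probes.
    """
    ref = resources.files("smokesig.data").joinpath("signature_probes_105.tsv")
    with resources.as_file(ref) as p:
        return load_manifest(p)


def load_ppi_edges(path) -> pd.DataFrame:
    """Read a STRING-style weighted edge list (protein1, protein2, combined_score)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"edge list missing columns: {sorted(missing)}")
    bad_lines = []
    scores = []
    for i, raw in enumerate(df["combined_score"]):
        try:
            s = int(raw)
            if not 0 <= s <= 1000:
                raise ValueError
            scores.append(s)
        except ValueError:
            bad_lines.append(i + 2)  # 1-based, plus header line
            scores.append(-1)
    if bad_lines:
        raise ValidationError(
            f"malformed combined_score at lines {bad_lines[:10]}"
        )
    out = df[["protein1", "protein2"]].copy()
    out["combined_score"] = scores
    return out


def load_id_map(path) -> pd.DataFrame:
    """Read a gene-symbol to protein-id mapping TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_symbol", "protein_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"id map missing columns: {sorted(missing)}")
    return df
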