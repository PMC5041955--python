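"""Reading and filtering of expression and clinical tables.

The preprocessing rules mirror a standard bulk-sequencing workflow for
paired miRNA/mRNA cohorts: sum splice variants to gene level, drop features
whose maximum abundance never reaches a floor (default 10 RPKM/RPM), drop
hyper-variable outlier features (coefficient of variation > 5), then
log2-transform with a pseudo-value replacing zeros.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, VariantMap

logger = logging.getLogger(__name__)


def load_expression(path, feature_kind: str, unit: str) -> ExpressionMatrix:
    """Read a tab-separated features x samples table.

    First column holds feature ids, header row holds sample ids.
    Duplicate ids and non-numeric cells are hard errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for sid in header:  # pandas silently renames duplicate columns; check raw header
        if sid in seen:
            raise ValueError(f"{path}: repeated sample column {sid!r}")
        seen.add(sid)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: repeated feature id {dup!r}")
    try:
        numeric = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} at feature {row!r}, sample {col!r}"
                ) from None
        raise
    return ExpressionMatrix(numeric, unit=unit, feature_kind=feature_kind)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t")


def load_clinical(path) -> ClinicalTable:
    """Read a CSV with columns sample_id, os_time, os_event[, pfs_time, pfs_event]."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table must have a 'sample_id' column")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def sum_splice_variants(m: ExpressionMatrix, variant_map: VariantMap) -> ExpressionMatrix:
    """Collapse a transcript-level matrix to gene level by summing variants."""
    if m.feature_kind != "mRNA-transcript":
        raise ValueError("sum_splice_variants expects a transcript-level matrix")
    missing = [t for t in m.feature_ids if t not in variant_map]
    if missing:
        raise ValueError(f"transcripts absent from variant map: {missing[:10]}")
    genes = pd.Index([variant_map.gene_of(t) for t in m.feature_ids], name=m.data.index.name)
    summed = m.data.groupby(genes, sort=False).sum()
    return ExpressionMatrix(summed, unit=m.unit, feature_kind="mRNA-gene")


def filter_low_abundance(m: ExpressionMatrix, min_max: float = 10.0) -> ExpressionMatrix:
    """Remove features whose row maximum is strictly below ``min_max``.

    Defined on raw abundance only; a feature peaking at exactly ``min_max``
    is retained.
    """
    if m.unit == "log2":
        raise ValueError("abundance filter is defined on raw RPKM/RPM, not log2")
    keep = m.data.max(axis=1) >= min_max
    logger.info("abundance filter: kept %d/%d features", int(keep.sum()), m.n_features)
    return ExpressionMatrix(m.data.loc[keep].copy(), m.unit, m.feature_kind)


def filter_cv_outliers(m: ExpressionMatrix, cv_max: float = 5.0) -> ExpressionMatrix:
    """Remove outlier features with coefficient of variation (sd/mean) above ``cv_max``.

    Computed on the raw scale with the (n-1)-denominator standard deviation.
    Features with zero mean carry no signal and an undefined CV; they are
    removed.
    """
    if m.unit == "log2":
        raise ValueError("CV filter is defined on raw RPKM/RPM, not log2")
    mean = m.data.mean(axis=1)
    sd = m.data.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    keep = (mean > 0) & (cv <= cv_max)
    logger.info("CV filter: kept %d/%d features", int(keep.sum()), m.n_features)
    return ExpressionMatrix(m.data.loc[keep].copy(), m.unit, m.feature_kind)


def log2_with_pseudo(m: ExpressionMatrix, pseudo: float = 0.01) -> ExpressionMatrix:
    """log2-transform, substituting ``pseudo`` for values below it."""
    if m.unit == "log2":
        raise ValueError("matrix is already log2-transformed")
    if pseudo <= 0:
        raise ValueError("pseudo-value must be positive")
    out = np.log2(np.maximum(m.values, pseudo))
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        unit="log2",
        feature_kind=m.feature_kind,
    )


def align_samples(
    *matrices: ExpressionMatrix, clinical: ClinicalTable | None = None
) -> tuple:
    """Restrict matrices (and optionally a clinical table) to shared samples.

    The intersection keeps the sample order of the first matrix. Counts of
    dropped samples are logged, never raised.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    shared = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        shared &= set(m.sample_ids)
    if clinical is not None:
        shared &= set(clinical.sample_ids)
    order = [s for s in matrices[0].sample_ids if s in shared]
    if not order:
        raise ValueError("no shared samples between inputs")
    for m in matrices:
        dropped = m.n_samples - len(order)
        if dropped:
            logger.info("dropping %d samples not shared across inputs", dropped)
    out = [m.subset_samples(order) for m in matrices]
    if clinical is not None:
        out.append(clinical.subset(order))
    return tuple(out)
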