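"""Core in-memory containers for paired expression / clinical analyses.

An :class:`ExpressionMatrix` is a thin, validated wrapper around a pandas
DataFrame holding a features x samples abundance table together with its
unit (RPKM, RPM or log2) and the kind of feature it rows
(mRNA transcripts, mRNA genes, or mature miRNA strands).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

VALID_UNITS = ("RPKM", "RPM", "log2")
VALID_KINDS = ("mRNA-transcript", "mRNA-gene", "miRNA-strand")


@dataclass
class ExpressionMatrix:
    """Features x samples abundance matrix with unit and feature-kind tags.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with sample ids as columns.
    unit
        ``"RPKM"``, ``"RPM"`` or ``"log2"``. Raw-abundance units must be
        non-negative; log2 values may be negative.
    feature_kind
        ``"mRNA-transcript"``, ``"mRNA-gene"`` or ``"miRNA-strand"``.
    """

    data: pd.DataFrame
    unit: str
    feature_kind: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.feature_kind not in VALID_KINDS:
            raise ValueError(
                f"unknown feature_kind {self.feature_kind!r}; expected one of {VALID_KINDS}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.unit != "log2" and values.size and values.min() < 0:
            raise ValueError(f"negative abundance in {self.unit} matrix")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Restrict to the given samples, in the given order."""
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.unit, self.feature_kind)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)].copy(), self.unit, self.feature_kind)


@dataclass
class ClinicalTable:
    """Right-censored outcome table keyed by sample id.

    ``os_time``/``os_event`` are overall survival; ``pfs_time``/``pfs_event``
    (progression-free survival) are optional and may hold NaN.
    """

    data: pd.DataFrame  # index = sample_id

    REQUIRED = ("os_time", "os_event")
    OPTIONAL = ("pfs_time", "pfs_event")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in clinical table: {dup!r}")
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        for tcol, ecol in (("os_time", "os_event"), ("pfs_time", "pfs_event")):
            if tcol not in self.data.columns:
                continue
            t = self.data[tcol].to_numpy(dtype=float)
            e = self.data[ecol].to_numpy(dtype=float)
            ok = np.isnan(t) | (t >= 0)
            if not ok.all():
                raise ValueError(f"negative times in column {tcol!r}")
            ok = np.isnan(e) | np.isin(e, (0.0, 1.0))
            if not ok.all():
                raise ValueError(f"non-binary event indicator in column {ecol!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def outcome(self, which: str = "OS") -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (times, events, sample_ids) for samples with complete data.

        ``which`` is ``"OS"`` (overall survival) or ``"PFS"`` (progression).
        """
        which = which.upper()
        if which == "OS":
            tcol, ecol = "os_time", "os_event"
        elif which == "PFS":
            tcol, ecol = "pfs_time", "pfs_event"
        else:
            raise ValueError(f"unknown outcome {which!r}; expected 'OS' or 'PFS'")
        if tcol not in self.data.columns:
            raise ValueError(f"clinical table has no {which} columns")
        sub = self.data[[tcol, ecol]].dropna()
        return (
            sub[tcol].to_numpy(dtype=float),
            sub[ecol].to_numpy(dtype=int),
            list(sub.index),
        )

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class VariantMap:
    """Many-to-one transcript -> gene mapping."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def gene_of(self, transcript_id: str) -> str:
        return self.mapping[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.mapping
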