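"""In-memory containers shared across stages.

The abundance matrix is a thin wrapper around a species x samples pandas
DataFrame that makes two pieces of state explicit: missingness (NaN cells)
and the measurement scale (``raw`` intensities vs ``log10``), so that the
filter -> impute -> transform order can be enforced rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DuplicateIdError, PipelineStateError

RAW = "raw"
LOG10 = "log10"


@dataclass
class AbundanceMatrix:
    """Species x samples abundance matrix with explicit missingness.

    Parameters
    ----------
    data:
        DataFrame, rows = species, columns = samples, NaN = missing.
    scale:
        ``"raw"`` (non-negative intensities) or ``"log10"``.
    sample_groups:
        Optional map sample id -> group label (normal/tumor, subtype A/B...).
    """

    data: pd.DataFrame
    scale: str = RAW
    sample_groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG10):
            raise PipelineStateError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate species ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dupes[:5]}")
        self.data = self.data.astype(float)
        if self.scale == RAW and (self.data.values < 0).any():
            raise ValueError("raw-scale abundances must be non-negative")
        if self.sample_groups is not None and not isinstance(self.sample_groups, pd.Series):
            self.sample_groups = pd.Series(dict(self.sample_groups))

    # -- views -----------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    @property
    def missing_rate(self) -> pd.Series:
        """Per-species fraction of missing cells across all samples."""
        return self.data.isna().mean(axis=1)

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        return replace(self, data=data, scale=self.scale if scale is None else scale)

    def groups_for(self, samples=None) -> pd.Series:
        if self.sample_groups is None:
            raise PipelineStateError("matrix carries no sample_groups")
        cols = self.sample_ids if samples is None else list(samples)
        return self.sample_groups.reindex(cols)


@dataclass
class ClinicalTable:
    """Per-sample right-censored survival data.

    ``time`` is follow-up in days (> 0); ``event`` True when death was
    observed, False when the subject was censored.  Optional binary
    covariates (0/1) may ride along but are not used by the lipid screen.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise DuplicateIdError("duplicate sample ids in clinical table")
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValueError(f"clinical table lacks column {col!r}")
        if (t["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        bad = ~t["event"].isin([0, 1, True, False])
        if bad.any():
            raise ValueError("event must be coded 0/1")
        t["time"] = t["time"].astype(float)
        t["event"] = t["event"].astype(bool)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time(self) -> pd.Series:
        return self.table["time"]

    @property
    def event(self) -> pd.Series:
        return self.table["event"]

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)].copy())


def make_matrix(
    values: Mapping[str, Mapping[str, float]] | pd.DataFrame | np.ndarray,
    species_ids=None,
    sample_ids=None,
    scale: str = RAW,
    sample_groups=None,
) -> AbundanceMatrix:
    """Convenience constructor from a raw array / nested mapping."""
    if isinstance(values, pd.DataFrame):
        df = values.copy()
    else:
        df = pd.DataFrame(values, index=species_ids, columns=sample_ids)
    return AbundanceMatrix(df, scale=scale, sample_groups=sample_groups)
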