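"""Preprocessing: missingness filter, half-minimum imputation, log10 transform.

The canonical order is filter -> impute -> transform.  Shotgun lipidomics
missingness is dominated by below-detection-limit cells (missing not at
random), which motivates the conservative half-of-observed-minimum
imputation.  The scale/missingness state carried by
:class:`~lipidprog.containers.AbundanceMatrix` makes out-of-order calls
fail loudly instead of silently producing doubly transformed values.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import LOG10, RAW, AbundanceMatrix
from .errors import (
    AllMissingSpeciesError,
    EmptyMatrixError,
    NonPositiveValueError,
    PipelineStateError,
)

logger = logging.getLogger(__name__)


def filter_missing(m: AbundanceMatrix, max_missing_rate: float = 0.70) -> AbundanceMatrix:
    """Drop species whose missing fraction strictly exceeds ``max_missing_rate``.

    The denominator is all samples in the matrix; a species missing in
    exactly the threshold fraction is retained.  Raises
    :class:`EmptyMatrixError` when nothing survives.
    """
    if m.scale != RAW:
        raise PipelineStateError("filter_missing expects a raw-scale matrix")
    if not 0 <= max_missing_rate < 1:
        raise ValueError("max_missing_rate must be in [0, 1)")
    rate = m.missing_rate
    keep = rate <= max_missing_rate
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyMatrixError(
            f"all {len(rate)} species exceed missing rate {max_missing_rate}"
        )
    if n_removed:
        logger.info(
            "filter_missing: removed %d/%d species (missing rate > %.2f)",
            n_removed, len(rate), max_missing_rate,
        )
    return m.with_data(m.data.loc[keep].copy())


def impute_half_min(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace each missing cell with half the species' observed minimum.

    Observed cells are untouched; the output has no missing cells.  A
    species with no observed value at all (never the case after
    :func:`filter_missing` with a rate < 1) raises
    :class:`AllMissingSpeciesError`.
    """
    if m.scale != RAW:
        raise PipelineStateError("impute_half_min expects a raw-scale matrix")
    data = m.data
    n_missing = m.n_missing
    if n_missing == 0:
        return m.with_data(data.copy())
    all_missing = data.isna().all(axis=1)
    if all_missing.any():
        raise AllMissingSpeciesError(
            f"species with no observed value: {list(data.index[all_missing])[:5]}"
        )
    fill = data.min(axis=1, skipna=True) / 2.0
    out = data.T.fillna(fill).T
    logger.info("impute_half_min: imputed %d cells", n_missing)
    return m.with_data(out)


def log_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Element-wise log10; marks the matrix as log-scale.

    Requires a complete (imputed) raw matrix with strictly positive values:
    a zero can only arise when a species' observed minimum is 0, which the
    zeros-as-missing ingest convention prevents.
    """
    if m.scale == LOG10:
        raise PipelineStateError("matrix is already log10-transformed")
    if m.n_missing:
        raise PipelineStateError("log_transform requires an imputed (complete) matrix")
    bad = m.data <= 0
    if bad.values.any():
        cells = [
            (sp, sa)
            for sp in m.data.index[bad.any(axis=1)]
            for sa in m.data.columns[bad.loc[sp]]
        ]
        raise NonPositiveValueError(f"non-positive cells: {cells[:5]}")
    return m.with_data(np.log10(m.data), scale=LOG10)


def preprocess(m: AbundanceMatrix, max_missing_rate: float = 0.70) -> AbundanceMatrix:
    """The full filter -> impute -> log10 chain with the standard defaults."""
    return log_transform(impute_half_min(filter_missing(m, max_missing_rate)))
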