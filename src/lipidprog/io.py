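"""Reading and writing the pipeline's tabular formats.

Wide matrices are TSV/CSV with the identifier in the first column and one
column per sample; empty cells, ``NA``-style tokens and (for lipid
matrices) exact zeros count as missing — zeros are below-detection-limit
readouts in shotgun lipidomics.  The delimiter is sniffed from the header
line and can be overridden.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, ClinicalTable
from .errors import DuplicateIdError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null")


def _sniff_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_wide(path: str | Path, sep: str | None, missing_tokens) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = sep or _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(missing_tokens),
                         keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns (wrong delimiter?)")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateIdError(f"{path}: duplicate row ids {dupes[:5]}")
    if df.columns.has_duplicates:
        raise DuplicateIdError(f"{path}: duplicate sample columns")
    non_numeric = df.columns[df.dtypes == object]
    if len(non_numeric):
        raise ParseError(f"{path}: non-numeric values in columns {list(non_numeric)[:5]}")
    return df.astype(float)


def read_matrix(
    path: str | Path,
    sep: str | None = None,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    zeros_missing: bool = True,
    sample_groups=None,
) -> AbundanceMatrix:
    """Read a wide lipid abundance matrix (species x samples, raw scale)."""
    df = _read_wide(path, sep, missing_tokens)
    if zeros_missing:
        n_zero = int((df.values == 0).sum())
        if n_zero:
            logger.info("read_matrix: %d zero cells treated as missing", n_zero)
        df = df.where(df != 0)
    return AbundanceMatrix(df, scale="raw", sample_groups=sample_groups)


def read_expression(path: str | Path, sep: str | None = None,
                    missing_tokens=DEFAULT_MISSING_TOKENS) -> pd.DataFrame:
    """Read a wide gene expression matrix (genes x samples)."""
    return _read_wide(path, sep, missing_tokens)


def read_clinical(path: str | Path, sep: str | None = None) -> tuple[ClinicalTable, pd.Series | None]:
    """Read a clinical table (sample_id, time, event, optional covariates).

    Returns the table and, when a ``group`` column is present, the sample
    group labels as a separate Series.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    groups = None
    if "group" in df.columns:
        groups = df.pop("group")
    return ClinicalTable(df), groups


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name <tab> description <tab> genes...)."""
    sets: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"GMT line {ln}: fewer than 3 fields")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a result table as TSV (floats at 6 significant digits).

    ``metadata`` (parameters, seed) is written next to the table as
    ``<name>.meta.json`` so every output records what produced it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if metadata is not None:
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta_path.write_text(json.dumps(_jsonable(metadata), indent=1, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
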