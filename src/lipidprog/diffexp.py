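"""Two-group differential lipid expression.

Student's two-tailed t-tests run on log10 abundances; fold changes are
computed on the imputed raw scale (log2 of the ratio of raw group means),
so the significance rule "BH-adjusted p < 0.05 and |log2 FC| >= 1" mixes
the two scales exactly as stated.  Benjamini-Hochberg controls the FDR
across all tested species.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LOG10, AbundanceMatrix
from .errors import DegenerateGroupError, GroupCountError, PipelineStateError, ValueRangeError

logger = logging.getLogger(__name__)


def t_test_two_group(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Two-sided Student's (pooled-variance) t-test on log-scale values.

    Returns ``(t, p)``.  Degenerate inputs — zero pooled variance, or
    all-zero paired differences — return ``(0.0, 1.0)`` with a warning;
    groups with fewer than two values raise :class:`DegenerateGroupError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateGroupError(f"group sizes {len(x)}/{len(y)} < 2")
    if paired:
        if len(x) != len(y):
            raise DegenerateGroupError("paired test requires equal group sizes")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_rel(x, y)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_ind(x, y, equal_var=True)
    if np.isnan(t) or np.isnan(p):
        logger.warning("degenerate t-test (zero variance); returning p=1")
        return 0.0, 1.0
    return float(t), float(p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueRangeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_lipids(
    m: AbundanceMatrix,
    groups: pd.Series | dict | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    paired: bool = False,
    group_a: str | None = None,
) -> pd.DataFrame:
    """Per-species two-group differential expression table.

    Parameters
    ----------
    m:
        log10-scale matrix (post preprocessing).
    groups:
        sample -> label map with exactly two labels; defaults to the
        matrix's own ``sample_groups``.
    group_a:
        which label is the numerator of the fold change; defaults to the
        first label in sorted order.
    paired:
        matched-sample test (labels must pair samples in column order
        within each group).

    Returns a DataFrame with one row per species: raw-scale group means,
    ``log2_fold_change`` (A over B), ``p_value``, ``adj_p_value`` and the
    ``significant`` flag (adj p < alpha and |log2 FC| >= lfc_threshold).
    """
    if m.scale != LOG10:
        raise PipelineStateError("differential_lipids expects a log10 matrix")
    g = m.groups_for() if groups is None else pd.Series(dict(groups) if isinstance(groups, dict) else groups)
    g = g.reindex(m.sample_ids).dropna()
    labels = sorted(g.unique().tolist())
    if len(labels) != 2:
        raise GroupCountError(f"need exactly 2 group labels, got {labels}")
    if group_a is None:
        group_a = labels[0]
    elif group_a not in labels:
        raise GroupCountError(f"group_a {group_a!r} not among labels {labels}")
    group_b = labels[1] if group_a == labels[0] else labels[0]

    a_cols = g.index[g == group_a]
    b_cols = g.index[g == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise DegenerateGroupError("each group needs >= 2 samples")

    log_a = m.data[a_cols].values
    log_b = m.data[b_cols].values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if paired:
            if log_a.shape[1] != log_b.shape[1]:
                raise DegenerateGroupError("paired test requires equal group sizes")
            t, p = stats.ttest_rel(log_a, log_b, axis=1)
        else:
            t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=True)
    degenerate = np.isnan(p)
    if degenerate.any():
        logger.warning("%d species with zero variance; p set to 1", int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)

    # fold change on the imputed raw scale
    raw_a = np.power(10.0, log_a).mean(axis=1)
    raw_b = np.power(10.0, log_b).mean(axis=1)
    log2fc = np.log2(raw_a / raw_b)

    adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "species_id": m.species_ids,
            "mean_a": raw_a,
            "mean_b": raw_b,
            "log2_fold_change": log2fc,
            "p_value": p,
            "adj_p_value": adj,
        }
    )
    out["significant"] = (out["adj_p_value"] < alpha) & (out["log2_fold_change"].abs() >= lfc_threshold)
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    return out


def significant_sets(de: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(up-regulated, down-regulated) significant species id sets, A relative to B."""
    sig = de[de["significant"]]
    up = set(sig.loc[sig["log2_fold_change"] > 0, "species_id"])
    down = set(sig.loc[sig["log2_fold_change"] < 0, "species_id"])
    return up, down
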