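"""Lipid-gene trans-omics integration by Spearman correlation.

Every (lipid species, gene) pair over the shared samples gets a Spearman
rho and p-value; a pair is significant at |rho| > 0.4 and p < 0.05 (raw,
no grid-wide correction — the thresholds are deliberately joint).  Genes
are then rolled up to lipid classes: a gene belongs to a class's set when
it is significantly correlated (either sign) with at least one species of
that class, classes are ranked by set size, and intersections across the
named (typically ether) classes give the shared gene list.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LOG10, AbundanceMatrix
from .errors import ConstantVectorError, NoSharedSamplesError, PipelineStateError, UnknownClassError

logger = logging.getLogger(__name__)

#: sample sizes at or below which the exact permutation p-value is used
EXACT_PERMUTATION_MAX_N = 9


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx * rx).sum() * (ry * ry).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks.  For n <= 9 the p-value
    is exact — the fraction of the n! permutations of one vector whose
    |rho| reaches the observed |rho| — otherwise the usual t-distribution
    approximation with n - 2 df.  Constant vectors raise
    :class:`ConstantVectorError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise ValueError("spearman needs >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("constant vector: rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        obs = abs(rho) - 1e-12
        count = sum(
            1 for perm in itertools.permutations(ry) if abs(_rho_of_ranks(rx, np.array(perm))) >= obs
        )
        return rho, count / math.factorial(n)
    with np.errstate(divide="ignore"):
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def _maybe_log_genes(genes: pd.DataFrame, log_genes: bool | None) -> pd.DataFrame:
    """log2(x+1) when the matrix looks like raw counts/TPM (max > 50)."""
    if log_genes is None:
        log_genes = float(np.nanmax(genes.values)) > 50
    if log_genes:
        if (genes.values < 0).any():
            raise ValueError("cannot log2(x+1)-transform a matrix with negatives")
        logger.info("gene matrix log2(x+1)-transformed on ingest")
        return np.log2(genes + 1.0)
    return genes


def correlate_all(
    lipids: AbundanceMatrix,
    genes: pd.DataFrame,
    rho_threshold: float = 0.4,
    alpha: float = 0.05,
    significant_only: bool = False,
    log_genes: bool | None = None,
    class_aggregate: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spearman rho/p for every (lipid, gene) pair over shared samples.

    The whole grid is computed via rank transformation and one matrix
    product (Spearman rho = Pearson on mid-ranks), with the t-approximation
    p-value; rows/columns with zero variance are skipped with a warning.

    ``class_aggregate``: pass a characteristic table to correlate per-class
    summed raw abundances instead of individual species (``lipid_id`` then
    holds class names).

    Returns a long DataFrame with columns ``lipid_id``, ``gene_id``,
    ``rho``, ``p_value``, ``significant``.
    """
    if lipids.scale != LOG10:
        raise PipelineStateError("correlate_all expects a log10 lipid matrix")
    shared = [s for s in lipids.sample_ids if s in set(genes.columns)]
    if len(shared) < 4:
        raise NoSharedSamplesError(f"only {len(shared)} shared samples (need >= 4)")
    L = lipids.data[shared]
    if class_aggregate is not None:
        cls = class_aggregate["class"].reindex(L.index)
        raw = np.power(10.0, L)
        L = np.log10(raw.groupby(cls).sum())
    G = _maybe_log_genes(genes[shared], log_genes)

    def ranks_z(df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
        keep = df.nunique(axis=1) > 1
        if (~keep).any():
            logger.warning("%d constant rows skipped in correlation", int((~keep).sum()))
        df = df.loc[keep]
        r = df.rank(axis=1).to_numpy(float)
        r -= r.mean(axis=1, keepdims=True)
        norm = np.sqrt((r * r).sum(axis=1, keepdims=True))
        return df, r / norm

    L, zl = ranks_z(L)
    G, zg = ranks_z(G)
    rho = zl @ zg.T  # lipids x genes
    n = len(shared)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    sig = (np.abs(rho) > rho_threshold) & (p < alpha)

    if significant_only:
        li, gi = np.nonzero(sig)
    else:
        li, gi = np.unravel_index(np.arange(rho.size), rho.shape)
    out = pd.DataFrame(
        {
            "lipid_id": L.index.to_numpy()[li],
            "gene_id": G.index.to_numpy()[gi],
            "rho": rho[li, gi],
            "p_value": p[li, gi],
            "significant": sig[li, gi],
        }
    )
    out.attrs["n_samples"] = n
    return out


def class_gene_sets(correlations: pd.DataFrame, species_table: pd.DataFrame) -> dict[str, set[str]]:
    """Gene sets per lipid class: genes significantly correlated with >= 1 species.

    Classes with no significant correlation map to the empty set.  Order of
    the returned dict is by decreasing set size (ties alphabetical).
    """
    sig = correlations[correlations["significant"]]
    cls = species_table["class"]
    sets: dict[str, set[str]] = {c: set() for c in cls.unique()}
    if not sig.empty:
        mapped = sig.assign(cls=sig["lipid_id"].map(cls)).dropna(subset=["cls"])
        for c, sub in mapped.groupby("cls"):
            sets[c] = set(sub["gene_id"])
    order = sorted(sets, key=lambda c: (-len(sets[c]), c))
    return {c: sets[c] for c in order}


def rank_classes(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Class ranking by correlated-gene count (descending)."""
    rows = sorted(((c, len(s)) for c, s in sets.items()), key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(rows, columns=["class", "n_genes"])


def overlap_genes(sets: dict[str, set[str]], classes: list[str]) -> set[str]:
    """Exact intersection of the named classes' gene sets."""
    missing = [c for c in classes if c not in sets]
    if missing:
        raise UnknownClassError(", ".join(missing))
    if not classes:
        return set()
    out = set(sets[classes[0]])
    for c in classes[1:]:
        out &= sets[c]
    return out
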