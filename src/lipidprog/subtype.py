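"""Lipidome-based molecular subtyping: t-SNE embedding + 2-means clustering.

Samples are embedded into two dimensions by t-SNE on their log10 lipid
profiles (Euclidean distances, no feature selection) and partitioned by
K-means with k = 2 on the embedded coordinates.  The cluster with the
higher mean abundance over ether-linked species is labelled "A" — the
ether-high, poor-prognosis analogue — and the other "B".
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .containers import LOG10, AbundanceMatrix
from .errors import DegenerateInputError, PipelineStateError, TooFewSamplesError

logger = logging.getLogger(__name__)


def tsne_embed(
    m: AbundanceMatrix,
    perplexity: float = 15.0,
    iterations: int = 3000,
    dims: int = 2,
    seed: int = 42,
) -> pd.DataFrame:
    """Embed samples (matrix columns) into ``dims`` dimensions with t-SNE.

    The perplexity is lowered (with a warning) when the cohort is smaller
    than 3x the requested perplexity.  Deterministic for a fixed seed.
    Returns a DataFrame indexed by sample id with columns ``x``/``y``.
    """
    if m.scale != LOG10:
        raise PipelineStateError("tsne_embed expects a log10 matrix")
    if m.n_missing:
        raise PipelineStateError("tsne_embed requires a complete matrix")
    X = m.data.T.to_numpy(float)
    n = X.shape[0]
    if n < 5:
        raise TooFewSamplesError(f"{n} samples < 5")
    if n <= 3 * perplexity:
        new_p = max(2.0, (n - 1) / 3.0)
        logger.warning("perplexity %.0f too large for n=%d; lowered to %.1f", perplexity, n, new_p)
        perplexity = new_p
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tsne = TSNE(
            n_components=dims,
            perplexity=perplexity,
            max_iter=iterations,
            random_state=seed,
            init="pca",
        )
        coords = tsne.fit_transform(X)
    cols = ["x", "y", "z"][:dims] if dims <= 3 else [f"d{i}" for i in range(dims)]
    out = pd.DataFrame(coords, index=m.data.columns, columns=cols)
    if out.isna().values.any():
        raise RuntimeError("t-SNE produced NaN coordinates")
    return out


def kmeans_two(coords: pd.DataFrame, seed: int = 42, restarts: int = 10) -> pd.Series:
    """k=2 K-means partition of embedded points; returns sample -> {0,1}.

    Best of ``restarts`` initialisations by within-cluster sum of squares;
    deterministic given the seed.  All-identical points raise
    :class:`DegenerateInputError`.
    """
    X = np.asarray(coords, dtype=float)
    if len(X) < 2 or np.ptp(X, axis=0).max() == 0:
        raise DegenerateInputError("K-means needs >= 2 distinct points")
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    index = coords.index if isinstance(coords, pd.DataFrame) else pd.RangeIndex(len(X))
    return pd.Series(labels, index=index)


def assign_subtypes(
    m: AbundanceMatrix,
    species_table: pd.DataFrame,
    seed: int = 42,
    perplexity: float = 15.0,
    iterations: int = 3000,
    restarts: int = 10,
) -> pd.DataFrame:
    """Full subtyping: embed, cluster, and label clusters A/B.

    ``species_table`` is the characteristic table (must cover the matrix
    species and carry ``ether_linked``).  The cluster whose samples have
    the higher mean log10 abundance over ether-linked species becomes
    subtype "A".  Returns a DataFrame indexed by sample id with columns
    ``x``, ``y``, ``cluster``.
    """
    coords = tsne_embed(m, perplexity=perplexity, iterations=iterations, seed=seed)
    clusters = kmeans_two(coords, seed=seed, restarts=restarts)

    ether_ids = species_table.index[species_table["ether_linked"].astype(bool)]
    ether_ids = [s for s in ether_ids if s in m.data.index]
    if not ether_ids:
        raise ValueError("no ether-linked species available for the A/B labelling rule")
    ether_mean = m.data.loc[ether_ids].mean(axis=0)  # per sample
    mean_by_cluster = ether_mean.groupby(clusters).mean()
    a_cluster = int(mean_by_cluster.idxmax())

    out = coords.copy()
    out["cluster"] = np.where(clusters == a_cluster, "A", "B")
    out.index.name = "sample_id"
    return out
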