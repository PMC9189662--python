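"""How well do tDR vs miRNA profiles separate samples by condition?

The qualitative tools are PCA on log2-normalized counts (first two
components) and an optional UMAP embedding; the pairwise structure is
summarized with Spearman correlation matrices.  The quantitative surrogate
for "better discrimination" is a mean silhouette score with distance
``1 - Spearman correlation``, computed per feature kind on the same samples,
so a tDR score can be compared directly with a miRNA score.  Under random
labels the silhouette is centered at zero, which gives a permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "EmbeddingResult",
    "normalize_log",
    "pca_project",
    "embed_2d",
    "correlation_matrix",
    "spearman_distance",
    "separability_score",
    "separability_null",
]


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame  # samples x (x, y)
    method: str
    explained_variance: tuple[float, ...] = ()


def normalize_log(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1); removes per-sample depth differences."""
    return np.log2(counts / sf + 1.0)


def pca_project(matrix: pd.DataFrame, n_components: int = 2) -> EmbeddingResult:
    """Project samples (columns) onto the first principal components.

    The feature-filtered matrix is transposed to samples x features and
    centered by the PCA fit.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA projection needs at least 3 samples")
    X = matrix.to_numpy(dtype=float).T
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components)
    with np.errstate(invalid="ignore"):  # 0/0 variance ratio for constant input
        coords = pca.fit_transform(X)
        ev = np.nan_to_num(pca.explained_variance_ratio_)
    return EmbeddingResult(
        coords=pd.DataFrame(
            coords[:, :2], index=matrix.columns, columns=["x", "y"][: coords.shape[1]]
        ),
        method="pca",
        explained_variance=tuple(float(v) for v in ev),
    )


def embed_2d(matrix: pd.DataFrame, method: str = "umap", seed: int = 0) -> EmbeddingResult:
    """2-D nonlinear embedding of samples; reproducible given the seed.

    Treated as qualitative output: no geometric guarantees beyond finiteness
    and determinism.
    """
    if method != "umap":
        raise ValueError(f"unknown embedding method {method!r}")
    import umap  # deferred: numba compilation is expensive at import time

    X = matrix.to_numpy(dtype=float).T
    n_neighbors = max(2, min(15, X.shape[0] - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, random_state=int(seed), n_jobs=1
        )
        coords = reducer.fit_transform(X)
    return EmbeddingResult(
        coords=pd.DataFrame(coords, index=matrix.columns, columns=["x", "y"]),
        method="umap",
    )


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between samples (columns).

    A constant sample has no rank variance; its correlations are reported as
    missing (NaN), never as zero.
    """
    if matrix.shape[1] < 2:
        raise ValueError("correlation matrix needs at least 2 samples")
    return matrix.corr(method="spearman")


def spearman_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    return 1.0 - correlation_matrix(matrix)


def separability_score(matrix: pd.DataFrame, labels: pd.Series) -> float:
    """Mean silhouette over samples with distance = 1 - Spearman correlation.

    Labels with a single sample are excluded (with a warning), as are samples
    whose correlation is undefined.
    """
    labels = labels.reindex(matrix.columns)
    sizes = labels.value_counts()
    singletons = sizes[sizes < 2].index
    if len(singletons):
        warnings.warn(f"excluding single-sample labels: {list(singletons)}")
        keep = labels[~labels.isin(singletons)].index
        matrix, labels = matrix[keep], labels[keep]
    if labels.nunique() < 2:
        raise ValueError("separability needs >= 2 labels with >= 2 samples each")
    D = spearman_distance(matrix)
    ok = D.notna().all(axis=0)
    if not ok.all():
        keep = D.index[ok]
        D, labels = D.loc[keep, keep], labels[keep]
    return float(
        silhouette_score(D.to_numpy(), labels.to_numpy(), metric="precomputed")
    )


def separability_null(
    matrix: pd.DataFrame, labels: pd.Series, n_permutations: int = 200, seed: int = 0
) -> np.ndarray:
    """Permutation null of the separability score (labels shuffled).

    The Spearman distance matrix does not depend on labels, so it is computed
    once and only the silhouette is re-evaluated per permutation.
    """
    rng = np.random.default_rng(seed)
    labels = labels.reindex(matrix.columns)
    D = spearman_distance(matrix).to_numpy()
    values = labels.to_numpy()
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(values)
        while pd.Series(perm).value_counts().min() < 2 or len(set(perm)) < 2:
            perm = rng.permutation(values)  # unreachable for balanced designs
        out[i] = float(silhouette_score(D, perm, metric="precomputed"))
    return out
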