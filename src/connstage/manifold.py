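"""PCA manifold over graph embeddings.

The trained encoder maps each connectome to a D-dimensional vector;
PCA fit on the two-extreme-group embeddings defines a fixed linear
manifold onto which held-out subjects (the intermediate group, or
controls) are projected without refitting.  Intrinsic dimensionality is
read off the eigenvalue spectrum as the number of components needed to
reach a cumulative explained-variance threshold.

Sign conventions make projections reproducible: PC1 is oriented so the
anchor group (the most advanced stage by default) has nonnegative mean
coordinate, later components so their largest-magnitude loading is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .training import EmbeddingSet


@dataclass(frozen=True)
class ManifoldModel:
    mean: np.ndarray
    components: np.ndarray  # (k, D), row-orthonormal
    explained_variance_ratios: np.ndarray  # (k,)
    full_spectrum: np.ndarray  # (D,), sums to 1, non-increasing
    sign_anchor: str | None = None

    @property
    def k(self) -> int:
        return self.components.shape[0]


def _as_matrix(embeddings) -> np.ndarray:
    if isinstance(embeddings, EmbeddingSet):
        return embeddings.matrix
    m = np.asarray(embeddings, dtype=float)
    if m.ndim != 2:
        raise ValueError("embeddings must be a 2-D matrix")
    return m


def fit_pca(embeddings: EmbeddingSet | np.ndarray, k: int = 2,
            anchor_label: str | None = "G2") -> ManifoldModel:
    """Fit a k-component PCA manifold on an embedding set.

    Uses the sample covariance (1/(n−1)); the full eigenvalue-ratio
    spectrum is retained (zero-padded to D) for dimensionality
    accounting.  ``anchor_label`` (requires an :class:`EmbeddingSet`)
    orients PC1; pass ``None`` to orient every component by its largest
    loading instead.
    """
    x = _as_matrix(embeddings)
    n, d = x.shape
    if n < 2:
        raise ValueError(f"need at least 2 samples to fit PCA, got {n}")
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k={k} out of range [1, {min(n - 1, d)}]")
    pca = PCA(n_components=min(n - 1, d), svd_solver="full")
    pca.fit(x)
    spectrum = np.zeros(d)
    spectrum[: pca.explained_variance_ratio_.size] = \
        pca.explained_variance_ratio_
    components = pca.components_[:k].copy()

    start = 0
    if anchor_label is not None:
        if not isinstance(embeddings, EmbeddingSet):
            raise ValueError("anchor_label requires an EmbeddingSet "
                             "with group labels")
        anchor_rows = [i for i, g in enumerate(embeddings.labels)
                       if g == anchor_label]
        if anchor_rows:
            centered = x[anchor_rows] - pca.mean_
            if (centered @ components[0]).mean() < 0:
                components[0] *= -1
            start = 1
    for i in range(start, k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1
    return ManifoldModel(
        mean=pca.mean_.copy(),
        components=components,
        explained_variance_ratios=spectrum[:k].copy(),
        full_spectrum=spectrum,
        sign_anchor=anchor_label,
    )


def project(model: ManifoldModel,
            embeddings: EmbeddingSet | np.ndarray) -> np.ndarray:
    """Project embeddings onto the manifold: ``(x − mean)·componentsᵀ``."""
    x = _as_matrix(embeddings)
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"embedding dim {x.shape[1]} != manifold dim "
            f"{model.mean.shape[0]}"
        )
    return (x - model.mean) @ model.components.T


def project_table(model: ManifoldModel,
                  embeddings: EmbeddingSet) -> pd.DataFrame:
    """Tidy coordinates: subject_id, group, pc1..pck."""
    coords = project(model, embeddings)
    table = pd.DataFrame({
        "subject_id": embeddings.subject_ids,
        "group": embeddings.labels,
    })
    for i in range(model.k):
        table[f"pc{i + 1}"] = coords[:, i]
    return table


def explained_variance_2d(model: ManifoldModel) -> float:
    """Cumulative explained-variance fraction of the first two PCs."""
    return float(model.full_spectrum[:2].sum())


def save_manifold(model: ManifoldModel, path) -> None:
    """Persist a fitted manifold as a key→array .npz container."""
    np.savez(path, mean=model.mean, components=model.components,
             explained_variance_ratios=model.explained_variance_ratios,
             full_spectrum=model.full_spectrum,
             sign_anchor=np.array([model.sign_anchor or ""]))


def load_manifold(path) -> ManifoldModel:
    with np.load(path, allow_pickle=False) as data:
        anchor = str(data["sign_anchor"][0]) or None
        return ManifoldModel(
            mean=data["mean"].copy(),
            components=data["components"].copy(),
            explained_variance_ratios=
            data["explained_variance_ratios"].copy(),
            full_spectrum=data["full_spectrum"].copy(),
            sign_anchor=anchor)


def intrinsic_dim(embeddings: EmbeddingSet | np.ndarray,
                  variance_threshold: float = 0.99) -> int:
    """Smallest k whose cumulative explained variance ≥ threshold."""
    if not 0 < variance_threshold <= 1:
        raise ValueError(
            f"variance_threshold must be in (0, 1], got {variance_threshold}"
        )
    x = _as_matrix(embeddings)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    model = fit_pca(x if not isinstance(embeddings, EmbeddingSet)
                    else embeddings.matrix, k=1, anchor_label=None)
    cumulative = np.cumsum(model.full_spectrum)
    return int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
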