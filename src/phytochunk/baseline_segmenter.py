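"""Pluggable segmenter contract plus a deliberately simple baseline.

A segmenter consumes chunk *views*: the chunk members' six raw features
(x, y, z, r, g, b) with positions re-centred on the anchor, plus each
member's height above the cloud minimum.  Any model honouring
:class:`Segmenter` can drive the pipeline; deep point-cloud networks are the
intended production fit.

The built-in baseline is a Gaussian prototype classifier: per point it
computes a small hand-crafted feature vector (height, colour, and local
covariance eigenvalue shape descriptors over the 16 nearest members within
the chunk), standardises it with training statistics, and assigns the class
whose centroid scores highest under an isotropic-Gaussian model with
empirical class priors.  The prior term makes the classifier sensitive to
the class composition of its training chunks — the property under study —
in the same way a network trained with unweighted cross-entropy is.  It is
intentionally weak and fast: it exists to make sampling effects measurable,
not to rival a deep segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.spatial import cKDTree

from .cloud_io import UNLABELLED, Chunk, ClassScheme, LabeledPointCloud

_SHAPE_NEIGHBOURS = 16  # members per local covariance neighbourhood


@dataclass
class ChunkView:
    """What a segmenter sees of one chunk: per-member features, no indices."""

    positions: np.ndarray  # (m, 3) re-centred on the anchor, mm
    colours: np.ndarray  # (m, 3) 0-255
    heights: np.ndarray  # (m,) height above the source cloud's minimum z
    labels: np.ndarray | None = None  # (m,) class indices; None at test time


def make_chunk_view(
    cloud: LabeledPointCloud, chunk: Chunk, with_labels: bool = True
) -> ChunkView:
    """Materialise the segmenter's view of a chunk (anchor-centred)."""
    idx = chunk.member_indices
    positions = cloud.positions[idx] - cloud.positions[chunk.anchor_index]
    heights = cloud.positions[idx, 2] - cloud.positions[:, 2].min()
    labels = None
    if with_labels and cloud.is_labelled:
        labels = cloud.labels[idx].copy()
    return ChunkView(
        positions=positions,
        colours=cloud.colours[idx].copy(),
        heights=heights,
        labels=labels,
    )


@runtime_checkable
class Segmenter(Protocol):
    """Contract for pluggable chunk segmenters."""

    def fit(self, views: Sequence[ChunkView]) -> "Segmenter": ...

    def predict(self, view: ChunkView) -> np.ndarray: ...


def _shape_descriptors(positions: np.ndarray) -> np.ndarray:
    """Per-point linearity/planarity/sphericity from local covariance spectra.

    Eigenvalues l1 >= l2 >= l3 of the covariance over each point's
    ``_SHAPE_NEIGHBOURS`` nearest members (within the chunk) give
    linearity (l1-l2)/l1, planarity (l2-l3)/l1 and sphericity l3/l1.
    """
    m = len(positions)
    kk = min(_SHAPE_NEIGHBOURS, m)
    tree = cKDTree(positions)
    _, nbr = tree.query(positions, k=kk)
    nbr = np.atleast_2d(nbr)
    if nbr.shape[0] != m:  # kk == 1 edge case: query returns (m,)
        nbr = nbr.reshape(m, kk)
    local = positions[nbr]  # (m, kk, 3)
    centred = local - local.mean(axis=1, keepdims=True)
    cov = np.einsum("mki,mkj->mij", centred, centred) / kk
    eig = np.linalg.eigvalsh(cov)[:, ::-1]  # descending
    l1 = np.maximum(eig[:, 0], 1e-12)
    return np.column_stack(
        [(eig[:, 0] - eig[:, 1]) / l1, (eig[:, 1] - eig[:, 2]) / l1, eig[:, 2] / l1]
    )


def chunk_features(view: ChunkView) -> np.ndarray:
    """Per-member feature matrix: height, RGB, and 3 local shape descriptors."""
    return np.column_stack(
        [
            view.heights,
            view.colours.astype(np.float64),
            _shape_descriptors(view.positions),
        ]
    )


@dataclass
class BaselineSegmenter:
    """Nearest-class-centroid on standardised features, with class priors.

    ``prior_weight`` scales the log-prior term added to the negative squared
    centroid distance; 0 gives a plain nearest-centroid rule that ignores
    training composition entirely.
    """

    prior_weight: float = 1.0
    scheme: ClassScheme = field(default_factory=ClassScheme)
    centroids_: np.ndarray | None = None  # (C, d); NaN rows for unseen classes
    log_priors_: np.ndarray | None = None
    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None

    def fit(self, views: Sequence[ChunkView]) -> "BaselineSegmenter":
        if not views:
            raise ValueError("no training chunks")
        feats, labels = [], []
        for view in views:
            if view.labels is None:
                raise ValueError("training chunk views must carry labels")
            keep = view.labels != UNLABELLED
            feats.append(chunk_features(view)[keep])
            labels.append(view.labels[keep])
        X = np.vstack(feats)
        y = np.concatenate(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        self.mean_ = X.mean(axis=0)
        self.std_ = np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0)
        Xs = (X - self.mean_) / self.std_
        C, d = self.scheme.n_classes, X.shape[1]
        self.centroids_ = np.full((C, d), np.nan)
        counts = np.bincount(y, minlength=C)
        for c in np.flatnonzero(counts):
            self.centroids_[c] = Xs[y == c].mean(axis=0)
        with np.errstate(divide="ignore"):
            self.log_priors_ = np.where(
                counts > 0, np.log(np.maximum(counts, 1) / counts.sum()), -np.inf
            )
        return self

    def predict(self, view: ChunkView) -> np.ndarray:
        if self.centroids_ is None:
            raise ValueError("segmenter is not fitted")
        Xs = (chunk_features(view) - self.mean_) / self.std_
        # score_c = -0.5 ||x - mu_c||^2 + w * log pi_c; unseen classes -inf
        seen = ~np.isnan(self.centroids_[:, 0])
        scores = np.full((len(Xs), len(seen)), -np.inf)
        for c in np.flatnonzero(seen):
            d2 = ((Xs - self.centroids_[c]) ** 2).sum(axis=1)
            scores[:, c] = -0.5 * d2 + self.prior_weight * self.log_priors_[c]
        return np.argmax(scores, axis=1).astype(np.int64)


@dataclass
class OracleSegmenter:
    """Returns the ground-truth labels; an upper bound for pipeline tests."""

    def fit(self, views: Sequence[ChunkView]) -> "OracleSegmenter":
        return self

    def predict(self, view: ChunkView) -> np.ndarray:
        if view.labels is None:
            raise ValueError("oracle needs labelled views")
        return view.labels.copy()
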