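"""Test-time coverage chunking and majority-vote merging.

At prediction time a cloud has no labels, so chunks cannot be allocated per
class.  Instead anchors are drawn uniformly from the points not yet covered
by any chunk, and chunking repeats until every point belongs to at least one
chunk.  Neighbour search always runs over the full cloud, so chunks overlap
and most points collect several predictions; the merged labelling takes the
majority vote per point, breaking ties uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .cloud_io import Chunk, LabeledPointCloud
from .chunk_sampler import extract_chunk


@dataclass
class ChunkPrediction:
    """Per-member predicted labels for one chunk."""

    member_indices: np.ndarray
    predicted_labels: np.ndarray

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        self.predicted_labels = np.asarray(self.predicted_labels, dtype=np.int64)
        if len(self.member_indices) != len(self.predicted_labels):
            raise ValueError("one predicted label per member required")
        if np.any(self.predicted_labels < 0):
            raise ValueError("predicted labels must be valid class indices")


@dataclass
class VoteTally:
    """Vote audit for a merged cloud: per-point per-class counts and ties."""

    votes: np.ndarray  # (n, C) int
    resolved: np.ndarray  # (n,) chosen label
    tie_mask: np.ndarray  # (n,) True where the winning count was shared


def cover_cloud(
    cloud: LabeledPointCloud,
    k: int,
    rng: np.random.Generator | int = 0,
    batch_size: int = 1,
) -> list[Chunk]:
    """Chunk a cloud until every point is covered at least once.

    Anchors are drawn uniformly at random from the uncovered set, one per
    iteration (``batch_size`` anchors at a time if raised above 1 — faster on
    large clouds, at the cost of occasionally redundant chunks).  Each
    chunk's k nearest neighbours are searched over *all* points so local
    structure and density are preserved.  Terminates in at most n iterations
    because every chunk covers its own anchor.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = cloud.n_points
    tree = cKDTree(cloud.positions)
    covered = np.zeros(n, dtype=bool)
    chunks: list[Chunk] = []
    while not covered.all():
        uncovered = np.flatnonzero(~covered)
        take = min(batch_size, uncovered.size)
        anchors = rng.choice(uncovered, size=take, replace=False)
        for anchor in anchors:
            chunk = extract_chunk(cloud, int(anchor), k, tree=tree)
            covered[chunk.member_indices] = True
            chunks.append(chunk)
    return chunks


def merge_predictions(
    n: int,
    predictions: Sequence[ChunkPrediction],
    rng: np.random.Generator | int = 0,
    n_classes: int | None = None,
) -> tuple[np.ndarray, VoteTally]:
    """Fuse overlapping chunk predictions into one label per point.

    Every point must appear in at least one prediction.  The label with the
    most votes wins; when several classes share the maximum, one of them is
    drawn uniformly at random from the seeded stream.  Without ties the
    result is independent of the seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if not predictions:
        raise ValueError("no predictions to merge")
    C = n_classes or int(max(p.predicted_labels.max() for p in predictions)) + 1
    votes = np.zeros((n, C), dtype=np.int64)
    for pred in predictions:
        if np.any(pred.member_indices >= n) or np.any(pred.member_indices < 0):
            raise ValueError("prediction references points outside [0, n)")
        np.add.at(votes, (pred.member_indices, pred.predicted_labels), 1)
    total = votes.sum(axis=1)
    if np.any(total == 0):
        missing = np.flatnonzero(total == 0)
        head = ", ".join(map(str, missing[:10]))
        raise ValueError(
            f"{missing.size} points received no prediction (indices {head}"
            + ("..." if missing.size > 10 else "")
            + ")"
        )
    best = votes.max(axis=1)
    resolved = np.argmax(votes, axis=1)
    n_best = (votes == best[:, None]).sum(axis=1)
    tie_mask = n_best > 1
    for i in np.flatnonzero(tie_mask):
        tied = np.flatnonzero(votes[i] == best[i])
        resolved[i] = rng.choice(tied)
    return resolved, VoteTally(votes=votes, resolved=resolved, tie_mask=tie_mask)
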