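"""Class-distribution statistics and imbalance diagnostics.

The degree of class imbalance in a labelled cloud (or in a training set
assembled from chunks) is summarised by the Shannon entropy of the class
fractions, h = -sum_c p_c log2 p_c, in bits: 0 for a single-class dataset,
log2 C for a perfectly balanced one.  Chunk composition (how many distinct
organ classes a chunk spans) is summarised box-plot style with 1.5*IQR
whiskers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cloud_io import UNLABELLED, Chunk, ClassScheme, LabeledPointCloud


@dataclass
class ClassDistribution:
    """Per-class point counts and fractions over one or more labelled clouds."""

    counts: np.ndarray  # (C,) non-negative integers
    scheme: ClassScheme = field(default_factory=ClassScheme)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.scheme.n_classes,):
            raise ValueError(
                f"counts must have length C={self.scheme.n_classes}, "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("empty distribution: no labelled points")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def n_present(self) -> int:
        """Number of classes with at least one point."""
        return int(np.count_nonzero(self.counts))

    @classmethod
    def from_fractions(
        cls,
        fractions: Sequence[float],
        n: int = 1_000_000,
        scheme: ClassScheme | None = None,
    ) -> "ClassDistribution":
        """Build a distribution with counts approximating ``fractions`` at size n.

        Counts are integerised by largest remainder so they sum to n exactly.
        """
        from .chunk_sampler import largest_remainder_round

        scheme = scheme or ClassScheme()
        fractions = np.asarray(fractions, dtype=np.float64)
        if fractions.shape != (scheme.n_classes,):
            raise ValueError("one fraction per class required")
        if np.any(fractions < 0) or not np.isclose(fractions.sum(), 1.0):
            raise ValueError("fractions must be non-negative and sum to 1")
        return cls(largest_remainder_round(fractions * n, n), scheme=scheme)


@dataclass
class ChunkCompositionSummary:
    """Box-plot summary of the distinct-classes-per-chunk statistic."""

    classes_per_chunk: np.ndarray  # (n_chunks,) ints in [1, C]
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float  # lowest observation within q1 - 1.5*IQR
    whisker_high: float  # highest observation within q3 + 1.5*IQR
    outliers: np.ndarray  # observations outside the whiskers


def class_distribution(
    cloud_or_labels: LabeledPointCloud | np.ndarray,
    scheme: ClassScheme | None = None,
) -> ClassDistribution:
    """Count labels per class, ignoring :data:`UNLABELLED` points.

    Raises if every label is the sentinel.
    """
    if isinstance(cloud_or_labels, LabeledPointCloud):
        labels = cloud_or_labels.labels
        scheme = cloud_or_labels.scheme
    else:
        labels = np.asarray(cloud_or_labels, dtype=np.int64)
        scheme = scheme or ClassScheme()
    labelled = labels[labels != UNLABELLED]
    if labelled.size == 0:
        raise ValueError("cloud has no labelled points")
    counts = np.bincount(labelled, minlength=scheme.n_classes)
    return ClassDistribution(counts, scheme=scheme)


def shannon_entropy(dist: ClassDistribution | Sequence[float]) -> float:
    """Shannon entropy in bits of a class distribution, with 0*log2(0) := 0.

    Accepts a :class:`ClassDistribution` or a bare fraction vector.  Bounded
    by [0, log2 C]; the upper bound is attained only by the uniform
    distribution over all C classes.
    """
    if isinstance(dist, ClassDistribution):
        p = dist.fractions
    else:
        p = np.asarray(dist, dtype=np.float64)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("fractions must be non-negative and sum to 1")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def chunk_composition(
    chunks: Sequence[Chunk], cloud: LabeledPointCloud
) -> ChunkCompositionSummary:
    """Distinct-classes-per-chunk statistic with a 1.5*IQR box-plot summary."""
    if not chunks:
        raise ValueError("no chunks given")
    if not cloud.is_labelled:
        raise ValueError("chunk composition requires a labelled cloud")
    n = cloud.n_points
    cpc = np.empty(len(chunks), dtype=np.int64)
    for j, chunk in enumerate(chunks):
        if np.any(chunk.member_indices >= n) or np.any(chunk.member_indices < 0):
            raise ValueError(f"chunk {j} references points outside the cloud")
        member_labels = cloud.labels[chunk.member_indices]
        cpc[j] = len(np.unique(member_labels[member_labels != UNLABELLED]))
    q1, med, q3 = np.percentile(cpc, [25, 50, 75])
    iqr = q3 - q1
    in_lo = cpc[cpc >= q1 - 1.5 * iqr]
    in_hi = cpc[cpc <= q3 + 1.5 * iqr]
    whisker_low = float(in_lo.min()) if in_lo.size else float(q1)
    whisker_high = float(in_hi.max()) if in_hi.size else float(q3)
    outliers = cpc[(cpc < whisker_low) | (cpc > whisker_high)]
    return ChunkCompositionSummary(
        classes_per_chunk=cpc,
        mean=float(cpc.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )


def trainingset_distribution(
    chunk_sets: Sequence[Sequence[Chunk]] | Sequence[Chunk],
    clouds: Sequence[LabeledPointCloud] | LabeledPointCloud,
) -> ClassDistribution:
    """Pooled label distribution over all chunk members.

    A point contributes once per chunk containing it, so overlapping chunks
    double-count points — matching how an overlapping training set is
    actually fed to a segmenter.
    """
    if isinstance(clouds, LabeledPointCloud):
        clouds = [clouds]
        chunk_sets = [chunk_sets]  # type: ignore[list-item]
    if len(chunk_sets) != len(clouds):
        raise ValueError("one chunk list per cloud required")
    scheme = clouds[0].scheme
    counts = np.zeros(scheme.n_classes, dtype=np.int64)
    for chunks, cloud in zip(chunk_sets, clouds):
        for chunk in chunks:
            labels = cloud.labels[chunk.member_indices]
            labels = labels[labels != UNLABELLED]
            counts += np.bincount(labels, minlength=scheme.n_classes)
    return ClassDistribution(counts, scheme=scheme)
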