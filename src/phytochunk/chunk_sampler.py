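"""Anchor allocation and k-nearest-neighbour chunk extraction.

Training sets are built by sampling ``a`` anchor points per cloud and cutting
out the ``k`` nearest neighbours of each anchor as one chunk.  Two allocation
strategies decide how the ``a`` anchors are shared among the organ classes:

* class-independent: a_c = (n_c / n) * a — anchors follow the original class
  distribution, so the training set mirrors the cloud's imbalance;
* class-dependent: a_c proportional to (1 - n_c / n) — anchors follow the
  inverse distribution, concentrating chunks on minority organs and raising
  the entropy (class balance) of the resulting training set.

Both real-valued allocations are integerised by largest-remainder (Hamilton)
rounding so that the per-class counts sum to ``a`` exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .class_stats import ClassDistribution, class_distribution, shannon_entropy, trainingset_distribution
from .cloud_io import UNLABELLED, Chunk, LabeledPointCloud

logger = logging.getLogger(__name__)

Strategy = Literal["class_independent", "class_dependent"]


@dataclass
class SamplingPlan:
    """Per-class anchor counts a_c for one cloud, with sum(a_c) == a."""

    strategy: Strategy
    a: int
    a_c: np.ndarray  # (C,) non-negative integers
    k: int = 4096

    def __post_init__(self) -> None:
        self.a_c = np.asarray(self.a_c, dtype=np.int64)
        if np.any(self.a_c < 0):
            raise ValueError("anchor counts must be non-negative")
        if int(self.a_c.sum()) != self.a:
            raise ValueError(f"anchor counts sum to {self.a_c.sum()}, expected {self.a}")


def largest_remainder_round(raw: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing to ``total`` (Hamilton).

    Each entry gets floor(raw); the remaining units go to the largest
    fractional remainders, ties broken by ascending index.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if np.any(raw < 0):
        raise ValueError("raw allocations must be non-negative")
    base = np.floor(raw).astype(np.int64)
    short = total - int(base.sum())
    if short < 0:
        raise ValueError("raw allocations exceed the total")
    if short > len(raw):
        raise ValueError("total unreachable: it exceeds sum(ceil(raw))")
    if short > 0:
        remainders = raw - base
        # stable sort on -remainder keeps ascending-index order among ties
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def allocate_anchors_independent(
    dist: ClassDistribution, a: int, k: int = 4096
) -> SamplingPlan:
    """Anchors proportional to the class distribution: a_c = (n_c / n) * a."""
    if a < 1:
        raise ValueError("need at least one anchor")
    raw = dist.fractions * a
    return SamplingPlan("class_independent", a, largest_remainder_round(raw, a), k)


def allocate_anchors_dependent(
    dist: ClassDistribution, a: int, k: int = 4096
) -> SamplingPlan:
    """Anchors proportional to the inverse distribution, 1 - n_c / n.

    Classes absent from the cloud are excluded from the normalising sum and
    receive zero anchors (an anchor cannot be drawn from an empty class).
    Requires at least two present classes, else the inverse fractions all
    vanish.
    """
    if a < 1:
        raise ValueError("need at least one anchor")
    if dist.n_present < 2:
        raise ValueError(
            "class-dependent allocation needs >= 2 present classes "
            "(inverse fractions sum to zero otherwise)"
        )
    present = dist.counts > 0
    inverse = np.where(present, 1.0 - dist.fractions, 0.0)
    raw = inverse / inverse.sum() * a
    return SamplingPlan("class_dependent", a, largest_remainder_round(raw, a), k)


def sample_anchor_points(
    cloud: LabeledPointCloud,
    plan: SamplingPlan,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Draw a_c anchor indices uniformly from each class's points.

    Sampling is without replacement; if a class is asked for more anchors
    than it has points, sampling falls back to with-replacement and a warning
    is logged.  Returns (point index, class) pairs in class order.
    """
    anchors: list[tuple[int, int]] = []
    for c in range(cloud.scheme.n_classes):
        a_c = int(plan.a_c[c])
        if a_c == 0:
            continue
        pool = np.flatnonzero(cloud.labels == c)
        if pool.size == 0:
            raise ValueError(
                f"plan requests {a_c} anchors for class "
                f"'{cloud.scheme.names[c]}' absent from cloud '{cloud.cloud_id}'"
            )
        replace = a_c > pool.size
        if replace:
            logger.warning(
                "class '%s' has %d points but %d anchors requested; "
                "sampling with replacement",
                cloud.scheme.names[c],
                pool.size,
                a_c,
            )
        chosen = rng.choice(pool, size=a_c, replace=replace)
        anchors.extend((int(i), c) for i in chosen)
    return anchors


def extract_chunk(
    cloud: LabeledPointCloud,
    anchor_index: int,
    k: int,
    tree: cKDTree | None = None,
) -> Chunk:
    """Cut out the min(k, n) nearest neighbours of an anchor point.

    Distances are Euclidean on x, y, z only (colour is a feature, not
    geometry); the anchor itself is always a member at distance 0.  Exact
    distance ties are broken by ascending point index, so the result is
    platform-deterministic.  Pass a prebuilt ``cKDTree`` over
    ``cloud.positions`` to amortise tree construction over many chunks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = cloud.n_points
    if not (0 <= anchor_index < n):
        raise ValueError(f"anchor {anchor_index} outside cloud of size {n}")
    kk = min(k, n)
    if tree is None:
        tree = cKDTree(cloud.positions)
    dists, idx = tree.query(cloud.positions[anchor_index], k=kk)
    dists = np.atleast_1d(dists)
    idx = np.atleast_1d(idx)
    # resolve ties at the kth-neighbour boundary deterministically
    r = float(dists[-1])
    ball = tree.query_ball_point(cloud.positions[anchor_index], r * (1 + 1e-12))
    if len(ball) > kk:
        cand = np.asarray(ball, dtype=np.int64)
        cd = np.linalg.norm(cloud.positions[cand] - cloud.positions[anchor_index], axis=1)
        order = np.lexsort((cand, cd))
        idx = cand[order][:kk]
        dists = cd[order][:kk]
    else:
        order = np.lexsort((idx, dists))
        idx, dists = idx[order], dists[order]
    anchor_class = int(cloud.labels[anchor_index])
    return Chunk(
        anchor_index=int(anchor_index),
        anchor_class=anchor_class if anchor_class != UNLABELLED else UNLABELLED,
        member_indices=idx,
        k=k,
    )


@dataclass
class TrainingSet:
    """Chunks per cloud plus the pooled composition of their members."""

    chunk_sets: list[list[Chunk]]
    plans: list[SamplingPlan]
    distribution: ClassDistribution
    entropy_bits: float

    @property
    def n_chunks(self) -> int:
        return sum(len(cs) for cs in self.chunk_sets)


def build_training_set(
    clouds: Sequence[LabeledPointCloud],
    strategy: Strategy,
    a: int = 100,
    k: int = 4096,
    seed: int | np.random.SeedSequence = 0,
) -> TrainingSet:
    """Run distribution -> allocation -> anchor sampling -> chunk extraction.

    Each cloud gets its own deterministic random substream derived from
    ``seed`` and the cloud's position in the list, so adding a cloud does not
    perturb the chunks of the others.
    """
    if strategy not in ("class_independent", "class_dependent"):
        raise ValueError(f"unknown strategy {strategy!r}")
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    chunk_sets: list[list[Chunk]] = []
    plans: list[SamplingPlan] = []
    for i, cloud in enumerate(clouds):
        rng = np.random.default_rng(np.random.SeedSequence((root.entropy, i)))
        dist = class_distribution(cloud)
        if strategy == "class_independent":
            plan = allocate_anchors_independent(dist, a, k)
        else:
            plan = allocate_anchors_dependent(dist, a, k)
        anchors = sample_anchor_points(cloud, plan, rng)
        tree = cKDTree(cloud.positions)
        chunks = [extract_chunk(cloud, idx, k, tree=tree) for idx, _ in anchors]
        chunk_sets.append(chunks)
        plans.append(plan)
    dist = trainingset_distribution(chunk_sets, list(clouds))
    return TrainingSet(
        chunk_sets=chunk_sets,
        plans=plans,
        distribution=dist,
        entropy_bits=shannon_entropy(dist),
    )
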