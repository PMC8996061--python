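"""Procedural generation of labelled cucumber-like point clouds.

No public scanner dataset exists for the high-wire cucumber setting, so this
module builds stylised single-plant clouds with the key properties the
sampling and evaluation machinery cares about:

* an imbalance profile matching a mature greenhouse cucumber scan
  (leaf ~78.9%, non-plant ~15.0%, stem ~2.7%, petiole ~1.5%, and under 1%
  each for growing point, node, ovary and tendril) — hit exactly per cloud
  by largest-remainder integerisation of the target fractions;
* local geometric structure per organ (linear stem/petiole/tendril/wire,
  planar leaves and gutter, compact node/ovary/growing-point blobs) and
  organ-typical colours with Gaussian noise, so that simple per-point
  features carry signal;
* realistic adjacency: nodes, ovaries and tendrils sit directly on or next
  to the stem, reproducing the node/stem confusability of real scans.

Geometry is stylised, not botanically accurate; coordinates are millimetres
with z the vertical growth axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chunk_sampler import largest_remainder_round
from .cloud_io import ClassScheme, LabeledPointCloud, write_cloud

#: Fractions observed in a manually labelled greenhouse cucumber dataset:
#: leaf 78.9%, non-plant 15.0%, stem 2.7%, petiole 1.5%; the remaining 1.9%
#: split evenly over growing point, node, ovary and tendril.
DEFAULT_FRACTIONS: dict[str, float] = {
    "stem": 0.027,
    "petiole": 0.015,
    "leaf": 0.789,
    "growing_point": 0.00475,
    "node": 0.00475,
    "ovary": 0.00475,
    "tendril": 0.00475,
    "non_plant": 0.150,
}

# organ-typical RGB means; plant organs share a green gamut (deliberately
# overlapping), non-plant material is grey/brown
_BASE_COLOURS: dict[str, tuple[int, int, int]] = {
    "stem": (90, 150, 80),
    "petiole": (100, 155, 85),
    "leaf": (60, 140, 60),
    "growing_point": (140, 185, 95),
    "node": (95, 145, 75),
    "ovary": (175, 200, 90),
    "tendril": (120, 165, 100),
    "non_plant": (120, 110, 100),
}

_STEM_RADIUS = 5.0  # mm
_PETIOLE_RADIUS = 2.5  # mm
_PETIOLE_LENGTH = 85.0  # mm
_LEAF_SEMI_AXES = (95.0, 70.0)  # mm
_TENDRIL_LENGTH = 95.0  # mm


@dataclass
class PlantParams:
    """Knobs of the plant generator; defaults emulate a mature scan."""

    n_points: int = 50_000
    target_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    n_leaves: int | None = None  # drawn uniformly in [8, 12] when None
    plant_height: float | None = None  # mm; drawn in [760, 1950] when None
    colour_noise_sd: float = 12.0  # RGB units
    position_noise_sd: float = 0.8  # mm
    seed: int = 0
    scheme: ClassScheme = field(default_factory=ClassScheme)

    def __post_init__(self) -> None:
        fr = np.array([self.target_fractions[n] for n in self.scheme.names])
        if np.any(fr <= 0) or np.any(fr >= 1):
            raise ValueError("all target fractions must lie in (0, 1)")
        if not np.isclose(fr.sum(), 1.0):
            raise ValueError(f"target fractions sum to {fr.sum():.4f}, expected 1")
        if self.n_points < 8 * self.scheme.n_classes:
            raise ValueError("n_points must be at least 8 points per class")

    @property
    def fraction_vector(self) -> np.ndarray:
        return np.array([self.target_fractions[n] for n in self.scheme.names])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``normal``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(normal, helper))
    return u, np.cross(normal, u)


class _StemCurve:
    """Smooth wobbling vertical centreline z -> (x, y, z)."""

    def __init__(self, height: float, rng: np.random.Generator):
        self.height = height
        n_ctrl = 12
        self._zs = np.linspace(0.0, height, n_ctrl)
        wobble = rng.normal(0, 8.0, size=(n_ctrl, 2)).cumsum(axis=0)
        self._xy = wobble - wobble[0]

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=np.float64))
        x = np.interp(z, self._zs, self._xy[:, 0])
        y = np.interp(z, self._zs, self._xy[:, 1])
        return np.column_stack([x, y, z])


def _sample_cylinder(
    start: np.ndarray,
    end: np.ndarray,
    radius: float,
    count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    axis = end - start
    u, v = _orthonormal_frame(_unit(axis))
    t = rng.uniform(0, 1, count)
    theta = rng.uniform(0, 2 * np.pi, count)
    return (
        start
        + t[:, None] * axis
        + radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
    )


def _sample_blob(
    centre: np.ndarray, sd: Sequence[float], count: int, rng: np.random.Generator
) -> np.ndarray:
    return centre + rng.normal(0, 1, size=(count, 3)) * np.asarray(sd)


def _split_count(total: int, parts: int) -> np.ndarray:
    """Spread ``total`` points over ``parts`` structures as evenly as possible."""
    return largest_remainder_round(np.full(parts, total / parts), total)


def generate_plant(params: PlantParams) -> LabeledPointCloud:
    """Generate one labelled plant cloud, deterministic in ``params.seed``.

    Per-class point counts are the largest-remainder integerisation of
    ``target_fractions * n_points``, so achieved fractions deviate from the
    targets by less than 1/n_points and every class is non-empty.
    """
    rng = np.random.default_rng(params.seed)
    scheme = params.scheme
    counts = largest_remainder_round(
        params.fraction_vector * params.n_points, params.n_points
    )
    if np.any(counts < 1):
        bad = scheme.names[int(np.argmin(counts))]
        raise ValueError(
            f"infeasible fractions: class '{bad}' would receive no points at "
            f"n_points={params.n_points}"
        )

    height = (
        params.plant_height
        if params.plant_height is not None
        else float(rng.uniform(760.0, 1950.0))
    )
    n_leaves = (
        params.n_leaves if params.n_leaves is not None else int(rng.integers(8, 13))
    )
    stem = _StemCurve(height, rng)

    # one node (leaf attachment) per leaf, evenly spaced internodes
    node_z = height * (np.arange(1, n_leaves + 1) / (n_leaves + 1))
    node_centres = stem(node_z)
    azimuths = rng.uniform(0, 2 * np.pi, n_leaves) + np.arange(n_leaves) * 2.4
    petiole_dirs = np.column_stack(
        [np.cos(azimuths), np.sin(azimuths), np.full(n_leaves, 0.45)]
    )
    petiole_dirs /= np.linalg.norm(petiole_dirs, axis=1, keepdims=True)

    organ_points: dict[str, np.ndarray] = {}

    # --- stem: points on a cylinder around the wobbling centreline
    c = counts[scheme.index("stem")]
    z = rng.uniform(0, height, c)
    theta = rng.uniform(0, 2 * np.pi, c)
    centres = stem(z)
    organ_points["stem"] = centres + _STEM_RADIUS * np.column_stack(
        [np.cos(theta), np.sin(theta), np.zeros(c)]
    )

    # --- nodes: compact bulges on the stem at each attachment point
    per_node = _split_count(counts[scheme.index("node")], n_leaves)
    organ_points["node"] = np.vstack(
        [
            _sample_blob(node_centres[i], (6.0, 6.0, 4.0), per_node[i], rng)
            for i in range(n_leaves)
        ]
    )

    # --- petioles: thin cylinders from node to leaf attachment
    per_pet = _split_count(counts[scheme.index("petiole")], n_leaves)
    leaf_attach = node_centres + _PETIOLE_LENGTH * petiole_dirs
    organ_points["petiole"] = np.vstack(
        [
            _sample_cylinder(
                node_centres[i], leaf_attach[i], _PETIOLE_RADIUS, per_pet[i], rng
            )
            for i in range(n_leaves)
        ]
    )

    # --- leaves: planar elliptical blades at the petiole ends
    per_leaf = _split_count(counts[scheme.index("leaf")], n_leaves)
    leaf_pts = []
    for i in range(n_leaves):
        normal = _unit(
            np.array([0.35 * np.cos(azimuths[i]), 0.35 * np.sin(azimuths[i]), 1.0])
            + rng.normal(0, 0.08, 3)
        )
        u, v = _orthonormal_frame(normal)
        r = np.sqrt(rng.uniform(0, 1, per_leaf[i]))
        phi = rng.uniform(0, 2 * np.pi, per_leaf[i])
        a, b = _LEAF_SEMI_AXES
        centre = leaf_attach[i] + petiole_dirs[i] * a * 0.8
        leaf_pts.append(
            centre
            + (r * a * np.cos(phi))[:, None] * u
            + (r * b * np.sin(phi))[:, None] * v
        )
    organ_points["leaf"] = np.vstack(leaf_pts)

    # --- tendrils: helical curls starting at nodes, between the petioles
    n_tendrils = max(2, n_leaves // 2)
    per_ten = _split_count(counts[scheme.index("tendril")], n_tendrils)
    tendril_pts = []
    for j in range(n_tendrils):
        i = (2 * j + 1) % n_leaves
        direction = _unit(
            np.array(
                [np.cos(azimuths[i] + 1.2), np.sin(azimuths[i] + 1.2), 0.25]
            )
        )
        u, v = _orthonormal_frame(direction)
        t = rng.uniform(0, 1, per_ten[j])
        curl = 8.0
        tendril_pts.append(
            node_centres[i]
            + t[:, None] * direction * _TENDRIL_LENGTH
            + curl * (np.cos(6 * np.pi * t)[:, None] * u + np.sin(6 * np.pi * t)[:, None] * v)
        )
    organ_points["tendril"] = np.vstack(tendril_pts)

    # --- ovaries: ellipsoidal fruitlets hanging at a few lower nodes
    n_ovaries = min(3, n_leaves)
    per_ov = _split_count(counts[scheme.index("ovary")], n_ovaries)
    ovary_pts = []
    for j in range(n_ovaries):
        i = j  # lowest nodes carry the fruitlets
        offset = 18.0 * np.array(
            [np.cos(azimuths[i] - 1.0), np.sin(azimuths[i] - 1.0), -0.8]
        )
        ovary_pts.append(
            _sample_blob(node_centres[i] + offset, (6.0, 6.0, 14.0), per_ov[j], rng)
        )
    organ_points["ovary"] = np.vstack(ovary_pts)

    # --- growing point: dense apical cluster
    apex = stem(np.array([height]))[0]
    organ_points["growing_point"] = _sample_blob(
        apex, (12.0, 12.0, 10.0), counts[scheme.index("growing_point")], rng
    )

    # --- non-plant: pot disc + gutter plane + vertical support wire
    c_np = counts[scheme.index("non_plant")]
    c_pot, c_gutter, c_wire = largest_remainder_round(
        np.array([0.45, 0.35, 0.20]) * c_np, c_np
    )
    r = 70.0 * np.sqrt(rng.uniform(0, 1, c_pot))
    th = rng.uniform(0, 2 * np.pi, c_pot)
    pot = np.column_stack([r * np.cos(th), r * np.sin(th), rng.uniform(-25, 0, c_pot)])
    gutter = np.column_stack(
        [
            rng.uniform(-320, 320, c_gutter),
            rng.uniform(-110, 110, c_gutter),
            np.full(c_gutter, -30.0) + rng.normal(0, 1.0, c_gutter),
        ]
    )
    wire_top = apex + np.array([12.0, 12.0, 0.0])
    wire = _sample_cylinder(
        np.array([wire_top[0], wire_top[1], 0.0]),
        wire_top + np.array([0.0, 0.0, 120.0]),
        1.0,
        c_wire,
        rng,
    )
    organ_points["non_plant"] = np.vstack([pot, gutter, wire])

    # --- assemble, add noise and colours, shuffle point order
    positions = np.vstack([organ_points[name] for name in scheme.names])
    labels = np.concatenate(
        [
            np.full(len(organ_points[name]), scheme.index(name), dtype=np.int64)
            for name in scheme.names
        ]
    )
    positions = positions + rng.normal(0, params.position_noise_sd, positions.shape)
    base = np.array([_BASE_COLOURS[name] for name in scheme.names], dtype=np.float64)
    colours = base[labels] + rng.normal(0, params.colour_noise_sd, (len(labels), 3))
    colours = np.clip(np.round(colours), 0, 255).astype(np.int64)

    perm = rng.permutation(len(labels))
    return LabeledPointCloud(
        positions=positions[perm],
        colours=colours[perm],
        labels=labels[perm],
        cloud_id=f"synthetic_plant_{params.seed}",
        scheme=scheme,
    )


@dataclass
class DatasetSplit:
    """Plant-level train/validation/test split (disjoint by construction)."""

    train: list[LabeledPointCloud]
    validation: list[LabeledPointCloud]
    test: list[LabeledPointCloud]

    @property
    def all_clouds(self) -> list[LabeledPointCloud]:
        return self.train + self.validation + self.test


def generate_dataset(
    n_plants: int,
    params: PlantParams | None = None,
    master_seed: int = 0,
    split: tuple[int, int, int] | None = None,
    out_dir: str | Path | None = None,
) -> list[LabeledPointCloud] | DatasetSplit:
    """Generate i.i.d. plants with per-plant seeds derived from ``master_seed``.

    With ``split=(n_train, n_val, n_test)`` the plants are partitioned by
    plant identity (never by scan), mirroring how real phenotyping datasets
    must be split to avoid leakage.  With ``out_dir`` set, each plant is also
    written as ASCII PLY next to a JSON manifest.
    """
    if n_plants < 1:
        raise ValueError("need at least one plant")
    params = params or PlantParams()
    seeds = np.random.SeedSequence(master_seed).generate_state(n_plants) % (2**31)
    clouds = []
    for i in range(n_plants):
        p = PlantParams(
            n_points=params.n_points,
            target_fractions=dict(params.target_fractions),
            n_leaves=params.n_leaves,
            plant_height=params.plant_height,
            colour_noise_sd=params.colour_noise_sd,
            position_noise_sd=params.position_noise_sd,
            seed=int(seeds[i]),
            scheme=params.scheme,
        )
        cloud = generate_plant(p)
        cloud.cloud_id = f"plant_{i:03d}"
        clouds.append(cloud)

    if out_dir is not None:
        import json

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"master_seed": master_seed, "plants": []}
        for cloud in clouds:
            path = out_dir / f"{cloud.cloud_id}.ply"
            write_cloud(cloud, path, format="ply_ascii")
            manifest["plants"].append(
                {"cloud_id": cloud.cloud_id, "file": path.name, "n_points": cloud.n_points}
            )
        (out_dir / "dataset.json").write_text(json.dumps(manifest, indent=1))

    if split is None:
        return clouds
    n_train, n_val, n_test = split
    if n_train + n_val + n_test != n_plants:
        raise ValueError("split sizes must sum to n_plants")
    return DatasetSplit(
        train=clouds[:n_train],
        validation=clouds[n_train : n_train + n_val],
        test=clouds[n_train + n_val :],
    )
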