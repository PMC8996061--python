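"""Point-cloud and chunk-manifest I/O.

Clouds are plain structured arrays of per-point features: a 3D position in
millimetres, an 8-bit RGB colour and an optional integer organ label.  Two
on-disk forms are supported: ASCII PLY (the CloudCompare labelling
convention, with the label stored as an integer scalar property, named
``scalar_label`` by default) and whitespace/comma delimited text with 6 or 7
columns (``x y z r g b [label]``).  Chunk sets are serialised as JSON
manifests.  Binary PLY is deliberately unsupported.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Label value meaning "no manual label available".
UNLABELLED: int = -1

DEFAULT_CLASS_NAMES = (
    "stem",
    "petiole",
    "leaf",
    "growing_point",
    "node",
    "ovary",
    "tendril",
    "non_plant",
)


class CloudFormatError(ValueError):
    """Raised when an on-disk cloud or manifest violates the format contract."""


@dataclass(frozen=True)
class ClassScheme:
    """Ordered set of semantic class names; index in ``names`` is the label code."""

    names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("class scheme needs at least one class")
        if len(set(self.names)) != len(self.names) or any(not n for n in self.names):
            raise ValueError("class names must be unique and non-empty")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class LabeledPointCloud:
    """A single plant scan: positions (mm), colours (0-255) and organ labels.

    ``labels`` uses :data:`UNLABELLED` (-1) for points without a manual label;
    all other values must be valid indices into ``scheme.names``.
    """

    positions: np.ndarray  # (n, 3) float64, millimetres
    colours: np.ndarray  # (n, 3) int, 0-255
    labels: np.ndarray  # (n,) int, in [0, C) or UNLABELLED
    cloud_id: str = ""
    scheme: ClassScheme = field(default_factory=ClassScheme)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.colours = np.asarray(self.colours, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n = len(self.positions)
        if n < 1:
            raise ValueError("cloud must contain at least one point")
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")
        if self.colours.shape != (n, 3):
            raise ValueError(f"colours must be (n, 3), got {self.colours.shape}")
        if self.labels.shape != (n,):
            raise ValueError(f"labels must be (n,), got {self.labels.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if np.any((self.colours < 0) | (self.colours > 255)):
            raise ValueError("colours must lie in 0..255")
        bad = (self.labels != UNLABELLED) & (
            (self.labels < 0) | (self.labels >= self.scheme.n_classes)
        )
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"label {self.labels[idx]} at point {idx} outside "
                f"[0, {self.scheme.n_classes})"
            )

    @property
    def n_points(self) -> int:
        return len(self.positions)

    @property
    def is_labelled(self) -> bool:
        return bool(np.any(self.labels != UNLABELLED))


@dataclass
class Chunk:
    """An anchor point plus its k nearest neighbours (anchor included).

    ``member_indices`` is ordered nearest-first, so the anchor (distance 0)
    is always ``member_indices[0]``.
    """

    anchor_index: int
    anchor_class: int  # class index or UNLABELLED
    member_indices: np.ndarray  # ordered point indices into the source cloud
    k: int  # requested neighbourhood size (len(members) == min(k, n))

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        if self.anchor_index not in self.member_indices:
            raise ValueError("chunk members must contain the anchor")
        if len(np.unique(self.member_indices)) != len(self.member_indices):
            raise ValueError("chunk members contain duplicates")

    def __len__(self) -> int:
        return len(self.member_indices)


# ---------------------------------------------------------------------------
# ASCII PLY
# ---------------------------------------------------------------------------

_PLY_POSITION_PROPS = ("x", "y", "z")
_PLY_COLOUR_PROPS = ("red", "green", "blue")


def _parse_ply_header(lines: list[str], path: str) -> tuple[int, list[str], int]:
    """Return (n_vertices, property names, index of first data line)."""
    if not lines or lines[0].strip() != "ply":
        raise CloudFormatError(f"{path}: not a PLY file (missing 'ply' magic)")
    n_vertex = None
    props: list[str] = []
    in_vertex = False
    for i, raw in enumerate(lines[1:], start=1):
        line = raw.strip()
        if line.startswith("format"):
            if "ascii" not in line:
                raise CloudFormatError(f"{path}: only ASCII PLY is supported")
        elif line.startswith("element"):
            parts = line.split()
            in_vertex = parts[1] == "vertex"
            if in_vertex:
                n_vertex = int(parts[2])
        elif line.startswith("property") and in_vertex:
            props.append(line.split()[-1])
        elif line == "end_header":
            if n_vertex is None:
                raise CloudFormatError(f"{path}: no vertex element in header")
            return n_vertex, props, i + 1
    raise CloudFormatError(f"{path}: missing end_header")


def _read_ply(
    path: Path, scheme: ClassScheme, label_property: str | None
) -> LabeledPointCloud:
    lines = path.read_text().splitlines()
    n_vertex, props, start = _parse_ply_header(lines, str(path))
    for needed in _PLY_POSITION_PROPS + _PLY_COLOUR_PROPS:
        if needed not in props:
            raise CloudFormatError(f"{path}: missing vertex property '{needed}'")
    if label_property is None:
        # auto-detect: prefer the CloudCompare convention, else any *label* prop
        candidates = [p for p in props if re.search("label", p)]
        label_property = (
            "scalar_label" if "scalar_label" in props else (candidates[0] if candidates else "")
        )
    elif label_property not in props:
        raise CloudFormatError(f"{path}: no property '{label_property}' in header")

    data_lines = lines[start : start + n_vertex]
    if len(data_lines) < n_vertex:
        raise CloudFormatError(
            f"{path}: header promises {n_vertex} vertices, found {len(data_lines)}"
        )
    try:
        data = np.loadtxt(data_lines, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise CloudFormatError(f"{path}: malformed vertex data ({exc})") from exc
    if data.shape[1] != len(props):
        raise CloudFormatError(
            f"{path}: rows have {data.shape[1]} fields, header declares {len(props)}"
        )
    col = {p: j for j, p in enumerate(props)}
    positions = data[:, [col[p] for p in _PLY_POSITION_PROPS]]
    colours = data[:, [col[p] for p in _PLY_COLOUR_PROPS]].astype(np.int64)
    if label_property:
        labels = data[:, col[label_property]].astype(np.int64)
        bad = (labels != UNLABELLED) & (labels >= scheme.n_classes)
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise CloudFormatError(
                f"{path}: vertex {idx} has label {labels[idx]} >= C={scheme.n_classes}"
            )
    else:
        labels = np.full(len(data), UNLABELLED, dtype=np.int64)
    return LabeledPointCloud(positions, colours, labels, cloud_id=path.stem, scheme=scheme)


def _write_ply(cloud: LabeledPointCloud, path: Path, label_property: str) -> None:
    write_labels = cloud.is_labelled
    header = [
        "ply",
        "format ascii 1.0",
        f"element vertex {cloud.n_points}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
    ]
    if write_labels:
        header.append(f"property int {label_property}")
    header.append("end_header")
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        for i in range(cloud.n_points):
            x, y, z = cloud.positions[i]
            r, g, b = cloud.colours[i]
            row = f"{x:.6f} {y:.6f} {z:.6f} {r} {g} {b}"
            if write_labels:
                row += f" {cloud.labels[i]}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Delimited text ("x y z r g b [label]")
# ---------------------------------------------------------------------------

def _read_table(path: Path, scheme: ClassScheme) -> LabeledPointCloud:
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        data = np.loadtxt(text.splitlines(), delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise CloudFormatError(f"{path}: ragged or non-numeric rows ({exc})") from exc
    if data.shape[1] not in (6, 7):
        raise CloudFormatError(
            f"{path}: expected 6 or 7 columns, found {data.shape[1]}"
        )
    positions = data[:, :3]
    colours = data[:, 3:6].astype(np.int64)
    if data.shape[1] == 7:
        labels = data[:, 6].astype(np.int64)
        bad = (labels != UNLABELLED) & (labels >= scheme.n_classes)
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise CloudFormatError(
                f"{path}: row {idx} has label {labels[idx]} >= C={scheme.n_classes}"
            )
    else:
        labels = np.full(len(data), UNLABELLED, dtype=np.int64)
    return LabeledPointCloud(positions, colours, labels, cloud_id=path.stem, scheme=scheme)


def _write_table(cloud: LabeledPointCloud, path: Path) -> None:
    with path.open("w") as fh:
        write_labels = cloud.is_labelled
        for i in range(cloud.n_points):
            x, y, z = cloud.positions[i]
            r, g, b = cloud.colours[i]
            row = f"{x:.6f} {y:.6f} {z:.6f} {r} {g} {b}"
            if write_labels:
                row += f" {cloud.labels[i]}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_cloud(
    path: str | Path,
    format: str | None = None,
    scheme: ClassScheme | None = None,
    label_property: str | None = None,
) -> LabeledPointCloud:
    """Read a labelled point cloud from ASCII PLY or delimited text.

    Parameters
    ----------
    path
        Input file.
    format
        ``"ply_ascii"`` or ``"xyz_table"``; inferred from the suffix when None
        (``.ply`` vs anything else).
    scheme
        Class scheme for label validation; the 8-organ default when None.
    label_property
        Name of the PLY scalar property holding the label.  When None, the
        CloudCompare-style ``scalar_label`` is used if present, else any
        property whose name contains ``label``; a missing label column yields
        all-:data:`UNLABELLED` labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scheme = scheme or ClassScheme()
    if format is None:
        format = "ply_ascii" if path.suffix.lower() == ".ply" else "xyz_table"
    if format == "ply_ascii":
        return _read_ply(path, scheme, label_property)
    if format == "xyz_table":
        return _read_table(path, scheme)
    raise ValueError(f"unknown format {format!r}")


def write_cloud(
    cloud: LabeledPointCloud,
    path: str | Path,
    format: str | None = None,
    label_property: str = "scalar_label",
) -> Path:
    """Write a cloud; re-reading yields identical content (positions to 1e-6 mm)."""
    path = Path(path)
    if format is None:
        format = "ply_ascii" if path.suffix.lower() == ".ply" else "xyz_table"
    if format == "ply_ascii":
        _write_ply(cloud, path, label_property)
    elif format == "xyz_table":
        _write_table(cloud, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def write_chunkset(
    chunks: Sequence[Chunk],
    cloud_id: str,
    path: str | Path,
    n_points: int | None = None,
) -> Path:
    """Serialise a chunk set as a JSON manifest tied to ``cloud_id``."""
    doc = {
        "cloud_id": cloud_id,
        "n_points": n_points,
        "chunks": [
            {
                "anchor_index": int(c.anchor_index),
                "anchor_class": int(c.anchor_class),
                "k": int(c.k),
                "member_indices": [int(i) for i in c.member_indices],
            }
            for c in chunks
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def read_chunkset(
    path: str | Path, n_points: int | None = None
) -> tuple[list[Chunk], str]:
    """Read a chunk manifest; returns (chunks, cloud_id).

    When ``n_points`` is given (or recorded in the manifest), member indices
    are bounds-checked against it.
    """
    doc = json.loads(Path(path).read_text())
    n = n_points if n_points is not None else doc.get("n_points")
    chunks = []
    for j, c in enumerate(doc["chunks"]):
        members = np.asarray(c["member_indices"], dtype=np.int64)
        if n is not None and (np.any(members < 0) or np.any(members >= n)):
            bad = members[(members < 0) | (members >= n)][0]
            raise CloudFormatError(
                f"{path}: chunk {j} references point {bad} outside cloud of size {n}"
            )
        chunks.append(
            Chunk(
                anchor_index=int(c["anchor_index"]),
                anchor_class=int(c["anchor_class"]),
                member_indices=members,
                k=int(c["k"]),
            )
        )
    return chunks, doc["cloud_id"]
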