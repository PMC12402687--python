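"""Labelled streamline bundles: data model, I/O, resampling, tangents, mirroring.

Fibres are ordered 3-D polylines in millimetres (RAS orientation) carrying a
pathway label and a hemisphere tag.  A :class:`PathwayAtlas` groups fibres by
pathway and stands in for a structural connectivity atlas.  The native on-disk
format is a TSV of points (columns ``x, y, z, fiber_id``) plus a JSON sidecar
mapping each ``fiber_id`` to its pathway, hemisphere and flagged status —
plain-text, diff-able, and exactly round-tripping.  MRtrix ``.tck`` track
files can be read through :mod:`nibabel.streamlines`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Sequence

import numpy as np

__all__ = [
    "Fiber",
    "PathwayAtlas",
    "FiberError",
    "load_fibers",
    "save_fibers",
    "resample_fiber",
    "fiber_tangents",
    "mirror_fibers",
    "MIRROR_ID_OFFSET",
]

#: fiber_id offset applied by :func:`mirror_fibers` so mirrored copies stay
#: unique atlas-wide while the homologous original remains recoverable.
MIRROR_ID_OFFSET = 1_000_000


class FiberError(ValueError):
    """Raised for malformed fibre data (parsing, labelling, geometry)."""


@dataclass(frozen=True)
class Fiber:
    """An ordered 3-D polyline (mm, RAS) with pathway and hemisphere labels.

    Parameters
    ----------
    fiber_id
        Integer identifier, unique within an atlas.
    points
        ``(n, 3)`` float array of vertex coordinates in millimetres; at least
        two points, consecutive points distinct, all coordinates finite.
    pathway
        Pathway (bundle) label.
    hemisphere
        ``"left"`` or ``"right"``.
    flagged
        True if the fibre intersects the electrode body; such fibres are not
        simulated directly but receive an activation verdict from a
        Euclidean-distance heuristic.
    """

    fiber_id: int
    points: np.ndarray
    pathway: str
    hemisphere: str
    flagged: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise FiberError(f"fiber {self.fiber_id}: points must be (n, 3)")
        if pts.shape[0] < 2:
            raise FiberError(f"fiber {self.fiber_id}: needs >= 2 points")
        if not np.all(np.isfinite(pts)):
            raise FiberError(f"fiber {self.fiber_id}: non-finite coordinates")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise FiberError(
                f"fiber {self.fiber_id}: consecutive duplicate points"
            )
        if self.hemisphere not in ("left", "right"):
            raise FiberError(
                f"fiber {self.fiber_id}: hemisphere must be left/right, "
                f"got {self.hemisphere!r}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0 (mm)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        """Total arc length in mm."""
        return float(self.arc_lengths()[-1])


@dataclass
class PathwayAtlas:
    """Fibres grouped by pathway label, plus a coordinate-frame tag."""

    pathways: Dict[str, List[Fiber]] = field(default_factory=dict)
    space_tag: str = "synthetic-RAS"

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, fibers in self.pathways.items():
            for f in fibers:
                if f.pathway != label:
                    raise FiberError(
                        f"fiber {f.fiber_id} labelled {f.pathway!r} stored "
                        f"under pathway {label!r}"
                    )
                if f.fiber_id in seen:
                    raise FiberError(f"duplicate fiber_id {f.fiber_id}")
                seen.add(f.fiber_id)

    def __iter__(self) -> Iterator[Fiber]:
        for fibers in self.pathways.values():
            yield from fibers

    def __len__(self) -> int:
        return sum(len(v) for v in self.pathways.values())

    @property
    def fiber_ids(self) -> List[int]:
        return [f.fiber_id for f in self]

    def get(self, fiber_id: int) -> Fiber:
        for f in self:
            if f.fiber_id == fiber_id:
                return f
        raise KeyError(fiber_id)

    @classmethod
    def from_fibers(
        cls, fibers: Sequence[Fiber], space_tag: str = "synthetic-RAS"
    ) -> "PathwayAtlas":
        pathways: Dict[str, List[Fiber]] = {}
        for f in fibers:
            pathways.setdefault(f.pathway, []).append(f)
        return cls(pathways=pathways, space_tag=space_tag)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _paths(path: Path) -> tuple[Path, Path]:
    """Resolve ``<name>.fib.tsv`` / ``<name>.fib.json`` from a base path."""
    path = Path(path)
    s = str(path)
    if s.endswith(".fib.tsv"):
        base = s[: -len(".fib.tsv")]
    elif s.endswith(".fib.json"):
        base = s[: -len(".fib.json")]
    else:
        base = s
    return Path(base + ".fib.tsv"), Path(base + ".fib.json")


def save_fibers(atlas: PathwayAtlas, path: Path) -> Path:
    """Write an atlas in the native TSV + JSON-sidecar format.

    ``path`` may be a base name or either component file name; both files are
    derived from it.  Coordinates are printed with 9 significant digits so a
    save/load round trip is exact to well below 1e-6 mm.  Returns the TSV path.
    """
    if len(atlas) == 0:
        raise FiberError("cannot save an empty atlas")
    tsv_path, json_path = _paths(path)
    lines = ["x\ty\tz\tfiber_id"]
    sidecar: Dict[str, dict] = {}
    for f in atlas:
        for x, y, z in f.points:
            lines.append(f"{x:.9g}\t{y:.9g}\t{z:.9g}\t{f.fiber_id}")
        sidecar[str(f.fiber_id)] = {
            "pathway": f.pathway,
            "hemisphere": f.hemisphere,
            "flagged": f.flagged,
        }
    tsv_path.write_text("\n".join(lines) + "\n")
    json_path.write_text(
        json.dumps(
            {"space_tag": atlas.space_tag, "fibers": sidecar},
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    return tsv_path


def _load_native(path: Path) -> PathwayAtlas:
    tsv_path, json_path = _paths(Path(path))
    if not tsv_path.exists():
        raise FileNotFoundError(tsv_path)
    if not json_path.exists():
        raise FileNotFoundError(json_path)
    meta = json.loads(json_path.read_text())
    sidecar = meta.get("fibers", {})

    ids: List[int] = []
    coords: List[List[float]] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["x", "y", "z", "fiber_id"]:
            raise FiberError(f"{tsv_path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FiberError(f"{tsv_path}:{lineno}: expected 4 columns")
            try:
                coords.append([float(parts[0]), float(parts[1]), float(parts[2])])
                ids.append(int(parts[3]))
            except ValueError as e:
                raise FiberError(f"{tsv_path}:{lineno}: {e}") from None

    id_arr = np.asarray(ids)
    pt_arr = np.asarray(coords)
    fibers: List[Fiber] = []
    # preserve first-appearance order of fiber_ids
    _, first = np.unique(id_arr, return_index=True)
    for fid in id_arr[np.sort(first)]:
        key = str(int(fid))
        if key not in sidecar:
            raise FiberError(
                f"fiber_id {fid} present in {tsv_path.name} but missing "
                f"from sidecar {json_path.name}"
            )
        info = sidecar[key]
        fibers.append(
            Fiber(
                fiber_id=int(fid),
                points=pt_arr[id_arr == fid],
                pathway=info["pathway"],
                hemisphere=info["hemisphere"],
                flagged=bool(info.get("flagged", False)),
            )
        )
    return PathwayAtlas.from_fibers(
        fibers, space_tag=meta.get("space_tag", "unknown")
    )


def _load_tck(path: Path, pathway: str, hemisphere: str) -> PathwayAtlas:
    import nibabel as nib

    tracto = nib.streamlines.load(str(path))
    fibers = [
        Fiber(fiber_id=i, points=np.asarray(s, dtype=float),
              pathway=pathway, hemisphere=hemisphere)
        for i, s in enumerate(tracto.streamlines)
    ]
    if not fibers:
        raise FiberError(f"{path}: no streamlines")
    return PathwayAtlas.from_fibers(fibers, space_tag="tck-RAS")


def load_fibers(
    path: Path,
    format: str = "native",
    pathway: str = "unlabelled",
    hemisphere: str = "right",
) -> PathwayAtlas:
    """Load a :class:`PathwayAtlas`.

    ``format="native"`` reads the TSV + JSON pair; ``format="tck"`` reads an
    MRtrix track file (all streamlines assigned the given ``pathway`` and
    ``hemisphere``, since TCK carries no labels).
    """
    if format == "native":
        return _load_native(Path(path))
    if format == "tck":
        return _load_tck(Path(path), pathway, hemisphere)
    raise ValueError(f"unknown fibre format {format!r}")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def resample_fiber(fiber: Fiber, step: float) -> Fiber:
    """Resample to (approximately) equal arc-length spacing.

    Points are placed at arc positions ``0, step, 2*step, ...`` by linear
    interpolation along the polyline; the original end point is always kept,
    so the last segment may be shorter than ``step``.  If ``step`` is at
    least the fibre length only the two endpoints remain.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    s = fiber.arc_lengths()
    total = s[-1]
    targets = np.arange(0.0, total, step)
    if targets[-1] < total - 1e-12:
        targets = np.concatenate([targets, [total]])
    else:
        targets[-1] = total
    new_pts = np.column_stack(
        [np.interp(targets, s, fiber.points[:, k]) for k in range(3)]
    )
    # collapse numerically-duplicate trailing point
    if len(new_pts) >= 2 and np.allclose(new_pts[-1], new_pts[-2], atol=1e-12):
        new_pts = new_pts[:-1]
    return replace(fiber, points=new_pts)


def fiber_tangents(fiber: Fiber) -> np.ndarray:
    """Unit tangent vector at each vertex.

    Central differences at interior vertices, one-sided at the two ends.
    Each returned row has unit norm to 1e-9.
    """
    pts = fiber.points
    t = np.empty_like(pts)
    t[0] = pts[1] - pts[0]
    t[-1] = pts[-1] - pts[-2]
    if pts.shape[0] > 2:
        t[1:-1] = pts[2:] - pts[:-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise FiberError(
            f"fiber {fiber.fiber_id}: degenerate geometry (zero tangent)"
        )
    return t / norms


def mirror_fibers(atlas: PathwayAtlas) -> PathwayAtlas:
    """Reflect the atlas across the mid-sagittal plane x = 0.

    All x coordinates are negated, hemisphere labels swap, and fiber_ids are
    offset by :data:`MIRROR_ID_OFFSET` (or un-offset, if already mirrored) so
    mirroring twice restores the original ids — the map is an involution.
    """
    swap = {"left": "right", "right": "left"}
    out: List[Fiber] = []
    for f in atlas:
        pts = f.points.copy()
        pts[:, 0] = -pts[:, 0]
        new_id = (
            f.fiber_id - MIRROR_ID_OFFSET
            if f.fiber_id >= MIRROR_ID_OFFSET
            else f.fiber_id + MIRROR_ID_OFFSET
        )
        out.append(
            Fiber(
                fiber_id=new_id,
                points=pts,
                pathway=f.pathway,
                hemisphere=swap[f.hemisphere],
                flagged=f.flagged,
            )
        )
    return PathwayAtlas.from_fibers(out, space_tag=atlas.space_tag)
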