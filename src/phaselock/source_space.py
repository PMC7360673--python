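"""Source grids, seed/RSN definitions and spatial adjacency.

All coordinates are millimetres in a right-handed MNI-like frame. Label
volumes carry their own affine; voxel indices never cross this module's
boundary. Sphere membership uses the closed ball (``distance <= radius``)
so that boundary sources are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SourceGrid",
    "SeedROI",
    "RSNSpec",
    "Adjacency",
    "build_regular_grid",
    "sources_in_sphere",
    "build_rsn",
    "build_adjacency",
    "roi_from_label_volume",
    "load_roi_definitions",
    "default_rsn_coordinates",
]

_LATERALITIES = ("left", "right", "bilateral")


@dataclass(frozen=True)
class SourceGrid:
    """Regular grid of candidate neural sources.

    Parameters
    ----------
    positions
        ``(n, 3)`` float array of source coordinates in mm, ordered
        lexicographically by ``(x, y, z)``.
    spacing
        Grid step in mm.
    """

    positions: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValueError("positions must be unique")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "positions", pos)

    @property
    def n_sources(self) -> int:
        return len(self.positions)

    def __len__(self) -> int:
        return self.n_sources


@dataclass(frozen=True)
class SeedROI:
    """Named set of grid sources acting as a connectivity seed."""

    name: str
    laterality: str
    source_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.laterality not in _LATERALITIES:
            raise ValueError(f"laterality must be one of {_LATERALITIES}")
        idx = np.asarray(self.source_indices, dtype=np.intp)
        if idx.size == 0:
            raise ValueError(f"seed ROI {self.name!r} is empty")
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"seed ROI {self.name!r} has duplicate indices")
        if np.any(idx < 0):
            raise ValueError(f"seed ROI {self.name!r} has negative indices")
        object.__setattr__(self, "source_indices", np.sort(idx))


@dataclass(frozen=True)
class RSNSpec:
    """Resting-state network as a union of spheres around MNI centers.

    ``center_membership[c]`` lists the sources inside center ``c``'s sphere;
    ``source_indices`` is their deduplicated union.
    """

    name: str
    centers: np.ndarray
    radius: float
    source_indices: np.ndarray
    center_membership: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class Adjacency:
    """Symmetric, irreflexive neighbour structure over grid sources."""

    neighbors: tuple[np.ndarray, ...]
    max_dist: float

    @property
    def n_sources(self) -> int:
        return len(self.neighbors)

    def edges(self) -> np.ndarray:
        """Return unique undirected edges as an ``(E, 2)`` array with i < j."""
        pairs = [
            (i, j) for i, nb in enumerate(self.neighbors) for j in nb if i < j
        ]
        return np.asarray(pairs, dtype=np.intp).reshape(-1, 2)

    def to_sparse(self):
        from scipy import sparse

        e = self.edges()
        n = self.n_sources
        if len(e) == 0:
            return sparse.csr_matrix((n, n), dtype=np.int8)
        data = np.ones(2 * len(e), dtype=np.int8)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_regular_grid(
    extent,
    spacing: float,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> SourceGrid:
    """Enumerate the regular lattice of sources inside ``extent``.

    ``extent`` may be an axis-aligned box ``((x0, x1), (y0, y1), (z0, z1))``
    in mm, a predicate ``f(points) -> bool mask`` evaluated on candidate
    lattice points together with a bounding ``box`` attribute or explicit
    ``bounds`` keyword semantics, or a ``(mask_volume, affine)`` pair where
    the boolean volume selects voxels whose centers are kept. Points are
    ordered lexicographically by ``(x, y, z)``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    origin = np.asarray(origin, dtype=np.float64)

    predicate: Callable[[np.ndarray], np.ndarray] | None = None
    if isinstance(extent, tuple) and len(extent) == 2 and hasattr(extent[0], "ndim"):
        mask, affine = extent
        mask = np.asarray(mask, dtype=bool)
        affine = np.asarray(affine, dtype=np.float64)
        vox = np.argwhere(mask)
        if vox.size == 0:
            raise ValueError("extent contains no grid points")
        corners = vox[:, None, :] + np.array(
            [[-0.5, -0.5, -0.5], [0.5, 0.5, 0.5]]
        )
        world = corners.reshape(-1, 3) @ affine[:3, :3].T + affine[:3, 3]
        box = np.stack([world.min(axis=0), world.max(axis=0)], axis=1)
        inv = np.linalg.inv(affine)

        def predicate(points: np.ndarray) -> np.ndarray:
            ijk = np.rint(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            ok = np.all((ijk >= 0) & (ijk < mask.shape), axis=1)
            out = np.zeros(len(points), dtype=bool)
            out[ok] = mask[tuple(ijk[ok].T)]
            return out

    elif callable(extent):
        raise TypeError(
            "callable extents need explicit bounds; pass (mask, affine) or a box"
        )
    else:
        box = np.asarray(extent, dtype=np.float64)
        if box.shape != (3, 2):
            raise ValueError("box extent must be ((x0,x1),(y0,y1),(z0,z1))")

    axes = []
    for d in range(3):
        lo, hi = box[d]
        k0 = int(np.ceil((lo - origin[d]) / spacing - 1e-9))
        k1 = int(np.floor((hi - origin[d]) / spacing + 1e-9))
        axes.append(origin[d] + spacing * np.arange(k0, k1 + 1))
    if any(len(a) == 0 for a in axes):
        raise ValueError("extent contains no grid points")
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if predicate is not None:
        pts = pts[predicate(pts)]
    if len(pts) == 0:
        raise ValueError("extent contains no grid points")
    # meshgrid with indexing="ij" already yields lexicographic (x, y, z) order
    return SourceGrid(positions=pts, spacing=float(spacing))


def sources_in_sphere(
    grid: SourceGrid, center: Sequence[float], radius: float
) -> np.ndarray:
    """Indices of sources within the closed ball of ``radius`` mm of ``center``."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    center = np.asarray(center, dtype=np.float64)
    d2 = np.sum((grid.positions - center) ** 2, axis=1)
    return np.flatnonzero(d2 <= radius * radius + 1e-9)


def build_rsn(
    grid: SourceGrid,
    name: str,
    centers,
    radius: float = 15.0,
) -> RSNSpec:
    """Assemble an RSN as the union of spheres around its MNI centers.

    The default 15 mm radius follows the convention of defining network
    nodes as 1.5 cm spheres around literature coordinates.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    if centers.shape[0] < 1 or centers.shape[1] != 3:
        raise ValueError("need at least one 3-D center")
    membership = tuple(
        sources_in_sphere(grid, c, radius) for c in centers
    )
    union = np.unique(np.concatenate(membership)) if membership else np.array([], dtype=np.intp)
    if union.size == 0:
        raise ValueError(f"RSN {name!r} covers no sources")
    return RSNSpec(
        name=name,
        centers=centers,
        radius=float(radius),
        source_indices=union.astype(np.intp),
        center_membership=membership,
    )


def build_adjacency(grid: SourceGrid, max_dist: float | None = None) -> Adjacency:
    """Neighbour lists of all source pairs closer than ``max_dist`` mm.

    Defaults to ``1.1 * spacing`` (face connectivity on a regular grid),
    the most conservative notion of spatial contiguity.
    """
    if max_dist is None:
        max_dist = 1.1 * grid.spacing
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    from scipy.spatial import cKDTree

    tree = cKDTree(grid.positions)
    pairs = tree.query_pairs(max_dist + 1e-9, output_type="ndarray")
    nbrs: list[list[int]] = [[] for _ in range(grid.n_sources)]
    for i, j in pairs:
        nbrs[i].append(j)
        nbrs[j].append(i)
    return Adjacency(
        neighbors=tuple(np.sort(np.asarray(n, dtype=np.intp)) for n in nbrs),
        max_dist=float(max_dist),
    )


def roi_from_label_volume(
    grid: SourceGrid,
    label_volume: np.ndarray,
    affine: np.ndarray,
    labels,
    name: str,
    laterality: str = "bilateral",
) -> SeedROI:
    """Seed ROI from an integer atlas volume (e.g. a Harvard-Oxford export).

    Each source position is mapped through the inverse affine to its nearest
    voxel; sources landing outside the volume are dropped with a warning.
    """
    affine = np.asarray(affine, dtype=np.float64)
    inv = np.linalg.inv(affine)
    labels = set(int(x) for x in np.atleast_1d(list(labels)))
    vol = np.asarray(label_volume)
    ijk = np.rint(grid.positions @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    inside = np.all((ijk >= 0) & (ijk < vol.shape), axis=1)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning(
            "%d source position(s) fall outside the label volume and were excluded",
            n_out,
        )
    hit = np.zeros(grid.n_sources, dtype=bool)
    sel = np.flatnonzero(inside)
    vals = vol[tuple(ijk[sel].T)]
    hit[sel] = np.isin(vals, list(labels))
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        raise ValueError(f"no sources map to labels {sorted(labels)}")
    return SeedROI(name=name, laterality=laterality, source_indices=idx)


def default_rsn_coordinates() -> dict:
    """Load the package's editable default RSN center file.

    These are convenience defaults in the style of the resting-state
    literature, intended to be replaced by study-specific coordinates.
    """
    path = Path(__file__).parent / "data" / "rsn_coordinates.json"
    with open(path) as fh:
        return json.load(fh)


def load_roi_definitions(path, grid: SourceGrid) -> list:
    """Read seed/RSN definitions from a JSON file.

    Each entry is either ``{"name", "laterality"?, "centers": [[x,y,z],...],
    "radius"}`` (resolved against ``grid`` into an :class:`RSNSpec`) or
    ``{"name", "laterality"?, "source_indices": [...]}`` (a :class:`SeedROI`).
    """
    with open(path) as fh:
        entries = json.load(fh)
    if isinstance(entries, dict):
        entries = entries.get("rois", entries.get("networks", []))
    out = []
    for e in entries:
        if "source_indices" in e:
            out.append(
                SeedROI(
                    name=e["name"],
                    laterality=e.get("laterality", "bilateral"),
                    source_indices=np.asarray(e["source_indices"], dtype=np.intp),
                )
            )
        else:
            out.append(
                build_rsn(grid, e["name"], e["centers"], e.get("radius", 15.0))
            )
    return out
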