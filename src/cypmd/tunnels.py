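"""Ligand-tunnel bottleneck analysis and egress-pathway classification.

Mammalian CYP active sites are buried; ligands enter and leave through
transient tunnels named by the standard CYP taxonomy (2b between the
B-C loop, F-G loop, and beta-4 sheet; 2f between helix A and the F-G
loop; 2c nearby).  The narrowest cross-section of a tunnel in a frame
is its bottleneck radius r_B.

This module

* parses CAVER-style per-frame bottleneck profile tables,
* compares bottleneck radii between two conditions with a Welch t-test
  from summary statistics (two-sided, alpha = 0.1 by default),
* provides a simplified grid-based widest-path bottleneck finder as a
  desk-scale geometric stand-in (it is *not* a CAVER re-implementation:
  no Voronoi diagram, no inter-frame clustering), and
* classifies which tunnel a dissociating ligand used, by nearest tunnel
  anchor at the first surface-crossing frame.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import LabeledTrajectory, Role
from .stats_report import SummaryStats, welch_ttest_from_stats

__all__ = [
    "BottleneckSeries",
    "TunnelOutcome",
    "ClearanceGrid",
    "GridBottleneckResult",
    "parse_caver_profiles",
    "compare_bottlenecks",
    "grid_bottleneck",
    "clearance_grid_from_atoms",
    "ligand_com_trace",
    "first_surface_crossing",
    "classify_egress_pathway",
]


@dataclass
class BottleneckSeries:
    """Per-frame bottleneck radii of one tunnel across a trajectory.

    ``n`` counts only the frames in which the tunnel was found; frames
    where CAVER reports no tunnel simply do not appear.
    """

    tunnel_id: str
    frames: np.ndarray
    r_b: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.r_b = np.asarray(self.r_b, dtype=float)
        if len(self.frames) != len(self.r_b):
            raise ValueError("frames and radii must have equal length")
        if np.any(self.r_b <= 0):
            raise ValueError("bottleneck radii must be positive where the tunnel is present")

    @property
    def n(self) -> int:
        return len(self.r_b)

    @property
    def mean(self) -> float:
        return float(np.mean(self.r_b))

    @property
    def sd(self) -> float:
        return float(np.std(self.r_b, ddof=1)) if self.n > 1 else 0.0

    def summary(self) -> SummaryStats:
        return SummaryStats(mean=self.mean, sd=self.sd, n=self.n)


@dataclass(frozen=True)
class TunnelOutcome:
    """Direction and significance of a bottleneck-radius change.

    ``direction`` is "+" / "-" when the first condition's mean radius is
    significantly larger / smaller at level alpha, "=" otherwise, and
    "n/a" when the tunnel is absent in either condition.
    """

    tunnel_id: str
    direction: str
    p_value: float | None


def parse_caver_profiles(path: str | Path) -> list[BottleneckSeries]:
    """Parse a CAVER-style CSV of per-frame tunnel bottleneck radii.

    Required columns (case-insensitive, aliases accepted): ``frame``,
    ``tunnel`` (or ``cluster``/``tunnel_id``), and ``bottleneck_radius``
    (or ``r_b``/``radius``).  Duplicate (frame, tunnel) rows are an
    error rather than being silently averaged.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    frame_col = cols.get("frame")
    tunnel_col = next((cols[k] for k in ("tunnel", "tunnel_id", "cluster") if k in cols), None)
    radius_col = next(
        (cols[k] for k in ("bottleneck_radius", "r_b", "radius") if k in cols), None
    )
    missing = [
        name
        for name, col in (
            ("frame", frame_col),
            ("tunnel/cluster", tunnel_col),
            ("bottleneck_radius", radius_col),
        )
        if col is None
    ]
    if missing:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")
    dupes = df.duplicated(subset=[frame_col, tunnel_col])
    if dupes.any():
        first = df[dupes].iloc[0]
        raise ValueError(
            f"{path}: duplicate row for frame {first[frame_col]}, "
            f"tunnel {first[tunnel_col]}"
        )
    series = []
    for tunnel_id, group in df.groupby(tunnel_col, sort=True):
        group = group.sort_values(frame_col)
        series.append(
            BottleneckSeries(
                tunnel_id=str(tunnel_id),
                frames=group[frame_col].to_numpy(),
                r_b=group[radius_col].to_numpy(),
            )
        )
    return series


def compare_bottlenecks(
    a: BottleneckSeries | None,
    b: BottleneckSeries | None,
    alpha: float = 0.1,
) -> TunnelOutcome:
    """Welch two-sided t-test on two bottleneck-radius series.

    Returns "+" when mean(a) > mean(b) with p < alpha, "-" for the
    opposite significant direction, "=" otherwise.  A tunnel absent
    (``None`` or zero frames) in either condition yields "n/a".
    """
    absent = lambda s: s is None or s.n == 0
    tunnel_id = (a or b).tunnel_id if (a or b) else "?"
    if absent(a) or absent(b):
        return TunnelOutcome(tunnel_id=tunnel_id, direction="n/a", p_value=None)
    if a.n < 2 or b.n < 2:
        raise ValueError("bottleneck comparison requires n >= 2 in both conditions")
    result = welch_ttest_from_stats(a.summary(), b.summary())
    if result.p < alpha:
        direction = "+" if a.mean > b.mean else "-"
    else:
        direction = "="
    return TunnelOutcome(tunnel_id=a.tunnel_id, direction=direction, p_value=result.p)


@dataclass
class ClearanceGrid:
    """Regular 3D grid of clearance values (angstrom).

    The clearance of a voxel is the distance from its center to the
    nearest protein atom minus the probe radius; non-positive clearance
    means the probe does not fit.
    """

    values: np.ndarray
    spacing: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("clearance grid must be 3-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("clearance values must be finite")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    def boundary_voxels(self) -> set[tuple[int, int, int]]:
        nx, ny, nz = self.values.shape
        out = set()
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if i in (0, nx - 1) or j in (0, ny - 1) or k in (0, nz - 1):
                        out.add((i, j, k))
        return out


@dataclass
class GridBottleneckResult:
    """Outcome of the widest-path search: absence is a value, not an error."""

    found: bool
    bottleneck: float | None
    path: list[tuple[int, int, int]] | None

    def __bool__(self) -> bool:
        return self.found


_NO_TUNNEL = GridBottleneckResult(found=False, bottleneck=None, path=None)

_NEIGHBORS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def grid_bottleneck(
    grid: ClearanceGrid,
    start: tuple[int, int, int],
    goals: set[tuple[int, int, int]] | None = None,
) -> GridBottleneckResult:
    """Maximin (widest) path from ``start`` to any goal voxel.

    Finds the path over 6-connected (face-adjacent) voxels that
    maximizes the minimum clearance along the way; that minimum is the
    bottleneck.  ``goals`` defaults to all boundary voxels of the grid
    (the tunnel mouth can open anywhere on the box surface).  Voxels of
    non-positive clearance are impassable; if no positive-clearance
    path exists the result reports "no tunnel" rather than raising.

    The search is a priority-queue variant of Dijkstra where the path
    value is ``min`` instead of ``sum`` and the queue is keyed on the
    largest value seen so far.
    """
    values = grid.values
    shape = values.shape
    start = tuple(int(x) for x in start)
    if any(not (0 <= s < n) for s, n in zip(start, shape)):
        raise ValueError(f"start voxel {start} outside grid of shape {shape}")
    if values[start] <= 0:
        raise ValueError(f"start voxel {start} has non-positive clearance")
    if goals is None:
        goals = grid.boundary_voxels()
    best: dict[tuple[int, int, int], float] = {start: values[start]}
    parent: dict[tuple[int, int, int], tuple[int, int, int] | None] = {start: None}
    heap = [(-values[start], start)]
    while heap:
        neg_width, voxel = heapq.heappop(heap)
        width = -neg_width
        if width < best.get(voxel, -np.inf):
            continue
        if voxel in goals:
            path = [voxel]
            while parent[voxel] is not None:
                voxel = parent[voxel]
                path.append(voxel)
            path.reverse()
            return GridBottleneckResult(found=True, bottleneck=float(width), path=path)
        for d in _NEIGHBORS:
            nb = (voxel[0] + d[0], voxel[1] + d[1], voxel[2] + d[2])
            if any(not (0 <= c < n) for c, n in zip(nb, shape)):
                continue
            clearance = values[nb]
            if clearance <= 0:
                continue
            new_width = min(width, clearance)
            if new_width > best.get(nb, -np.inf):
                best[nb] = new_width
                parent[nb] = voxel
                heapq.heappush(heap, (-new_width, nb))
    return _NO_TUNNEL


def clearance_grid_from_atoms(
    atom_coords: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    spacing: float = 1.0,
    probe_radius: float = 1.4,
) -> ClearanceGrid:
    """Clearance field of a protein: nearest-atom distance minus probe radius."""
    tree = cKDTree(np.asarray(atom_coords, dtype=float))
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1) * spacing + np.asarray(origin)
    dist, _ = tree.query(centers)
    values = dist.reshape(shape) - probe_radius
    return ClearanceGrid(values=values, spacing=spacing, origin=np.asarray(origin, dtype=float))


def ligand_com_trace(traj: LabeledTrajectory) -> np.ndarray:
    """(n_frames, 3) center of the ligand heavy atoms (unweighted)."""
    lig = traj.coordinates(Role.LIGAND_HEAVY)
    if lig.shape[1] == 0:
        raise ValueError("trajectory has no ligand heavy atoms")
    return lig.mean(axis=1)


def first_surface_crossing(
    com_trace: np.ndarray,
    protein_coords: np.ndarray,
    threshold: float = 5.0,
) -> int | None:
    """First frame whose ligand center is > ``threshold`` from every protein atom.

    ``protein_coords`` is (n_frames, n_atoms, 3) or a static (n_atoms, 3)
    array.  Returns None when the ligand never leaves the surface.
    """
    com = np.asarray(com_trace, dtype=float)
    prot = np.asarray(protein_coords, dtype=float)
    for f in range(len(com)):
        frame_atoms = prot[f] if prot.ndim == 3 else prot
        if np.min(np.linalg.norm(frame_atoms - com[f], axis=1)) > threshold:
            return f
    return None


def classify_egress_pathway(
    com_trace: np.ndarray,
    anchors: dict[str, np.ndarray],
    protein_coords: np.ndarray,
    threshold: float = 5.0,
) -> str:
    """Tunnel label of a dissociation event.

    The ligand's exit point is its center at the first frame where its
    minimum distance to the protein exceeds ``threshold`` (the same
    criterion used for dissociation detection); the returned label is
    the nearest tunnel anchor (Euclidean), with ties broken
    lexicographically on the tunnel id so the call is deterministic.
    """
    if not anchors:
        raise ValueError("at least one tunnel anchor required")
    crossing = first_surface_crossing(com_trace, protein_coords, threshold)
    if crossing is None:
        raise ValueError("ligand never crosses the protein surface; no egress to classify")
    exit_point = np.asarray(com_trace, dtype=float)[crossing]
    ranked = sorted(
        anchors.items(),
        key=lambda kv: (float(np.linalg.norm(np.asarray(kv[1], dtype=float) - exit_point)), kv[0]),
    )
    return ranked[0][0]
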