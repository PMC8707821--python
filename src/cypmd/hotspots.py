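"""Small-molecule association hotspots and probe occupancy grids.

Two complementary readouts locate where small molecules concentrate on
a protein surface during MD:

* a per-residue association score — the cumulative number of ligand
  heavy atoms within a distance cutoff (default 5 A) of each residue's
  alpha-carbon, summed over frames and normalized by the total number
  of ligand heavy atoms; and
* a voxelized occupancy map of cosolvent-probe positions, expressed as
  a z-score per voxel relative to the basal occupancy level, so dense
  sites can be displayed at a sigma isolevel (e.g. 15 sigma).

When several ligand copies are present (the 20-copy association setup)
they are pooled: the normalization uses the total heavy-atom count over
all copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .io import LabeledTrajectory, Role

__all__ = [
    "AssociationProfile",
    "OccupancyGrid",
    "association_scores",
    "occupancy_zscore_grid",
    "write_opendx",
]


@dataclass
class AssociationProfile:
    """Cumulative normalized ligand-contact count per protein residue."""

    residue_numbers: np.ndarray
    scores: np.ndarray
    cutoff: float
    n_frames: int
    n_ligand_heavy: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue_number": self.residue_numbers, "score": self.scores}
        )


@dataclass
class OccupancyGrid:
    """Probe-occupancy counts and z-scores on a regular 3D grid.

    The z-score of a voxel is ``(count - mean) / sd`` where the mean and
    standard deviation are taken over every voxel of the grid box (the
    protein bounding box plus margin), which operationalizes the "basal
    level of occupancy".  ``z_defined`` is False when the counts have
    zero variance, in which case ``zscores`` is all-NaN.
    """

    origin: np.ndarray
    voxel_size: float
    counts: np.ndarray
    zscores: np.ndarray
    z_defined: bool

    @property
    def total_observations(self) -> int:
        return int(self.counts.sum())

    def voxels_above(self, sigma: float) -> np.ndarray:
        """(k, 3) integer indices of voxels with z-score >= ``sigma``."""
        if not self.z_defined:
            return np.empty((0, 3), dtype=int)
        return np.argwhere(self.zscores >= sigma)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(indices) + 0.5) * self.voxel_size


def association_scores(
    trajectory: LabeledTrajectory, cutoff: float = 5.0
) -> AssociationProfile:
    """Per-residue cumulative ligand association over a trajectory.

    For every frame, each residue accumulates the number of ligand heavy
    atoms within ``cutoff`` of its alpha-carbon; the final score divides
    that cumulative count by the total number of ligand heavy atoms, so
    a residue permanently contacted by one full ligand copy scores about
    ``n_frames / n_copies``.
    """
    ca_idx = trajectory.system.indices(Role.PROTEIN_CA)
    lig_idx = trajectory.system.indices(Role.LIGAND_HEAVY)
    if len(ca_idx) == 0:
        raise ValueError("association scores require protein alpha-carbons")
    if len(lig_idx) == 0:
        raise ValueError("association scores require ligand heavy atoms")
    counts = np.zeros(len(ca_idx), dtype=float)
    for frame in trajectory.frames:
        tree = cKDTree(frame[lig_idx])
        n_within = tree.query_ball_point(frame[ca_idx], r=cutoff, return_length=True)
        counts += n_within
    return AssociationProfile(
        residue_numbers=trajectory.system.ca_residue_numbers(),
        scores=counts / len(lig_idx),
        cutoff=float(cutoff),
        n_frames=trajectory.n_frames,
        n_ligand_heavy=int(len(lig_idx)),
    )


def occupancy_zscore_grid(
    trajectories: LabeledTrajectory | list[LabeledTrajectory],
    probe_role: Role = Role.LIGAND_HEAVY,
    voxel_size: float = 1.0,
    margin: float = 5.0,
    superpose: bool = True,
) -> OccupancyGrid:
    """Bin probe heavy-atom positions into a z-scored occupancy grid.

    Frames are superposed on the first frame's alpha-carbons before
    binning (densities are meaningful only on a fixed structure).  The
    grid covers the first frame's protein bounding box plus ``margin``
    on every side; probe observations falling outside are discarded.
    """
    if isinstance(trajectories, LabeledTrajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("at least one trajectory required")
    ref_traj = trajectories[0]
    ref_ca_idx = ref_traj.system.indices(Role.PROTEIN_CA)
    ref_ca = ref_traj.frames[0][ref_ca_idx]
    lo = ref_ca.min(axis=0) - margin
    hi = ref_ca.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 1)
    counts = np.zeros(shape, dtype=np.int64)
    for traj in trajectories:
        ca_idx = traj.system.indices(Role.PROTEIN_CA)
        probe_idx = traj.system.indices(probe_role)
        if len(probe_idx) == 0:
            raise ValueError(f"no probe atoms with role {probe_role} present")
        for frame in traj.frames:
            probes = frame[probe_idx]
            if superpose:
                ca = frame[ca_idx]
                mob_center = ca.mean(axis=0)
                # same rigid transform as the Ca superposition, applied to probes
                rot, _ = Rotation.align_vectors(
                    ref_ca - ref_ca.mean(axis=0), ca - mob_center
                )
                probes = rot.apply(probes - mob_center) + ref_ca.mean(axis=0)
            idx = np.floor((probes - lo) / voxel_size).astype(int)
            inside = np.all((idx >= 0) & (idx < shape), axis=1)
            np.add.at(counts, tuple(idx[inside].T), 1)
    mean = counts.mean()
    sd = counts.std()
    if sd == 0:
        z = np.full(counts.shape, np.nan)
        defined = False
    else:
        z = (counts - mean) / sd
        defined = True
    return OccupancyGrid(
        origin=lo,
        voxel_size=float(voxel_size),
        counts=counts,
        zscores=z,
        z_defined=defined,
    )


def write_opendx(grid: OccupancyGrid, path: str | Path, which: str = "zscore") -> None:
    """Write the grid as OpenDX volumetric text (for PyMOL/VMD display)."""
    data = grid.zscores if which == "zscore" else grid.counts.astype(float)
    nx, ny, nz = data.shape
    ox, oy, oz = grid.origin
    d = grid.voxel_size
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.4f} {oy:.4f} {oz:.4f}\n")
        fh.write(f"delta {d:.4f} 0 0\ndelta 0 {d:.4f} 0\ndelta 0 0 {d:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {data.size} data follows\n"
        )
        flat = data.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
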