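"""Synthetic systems with known ground truth for every pipeline stage.

The study's microsecond membrane trajectories are not publicly
deposited, so each analysis is exercised on generated data whose target
quantity is known by construction: a membrane slab of POPC C1 beads at
a controllable leaflet height, a pseudo-globular Ca bead protein with a
planar four-nitrogen heme proxy at a controllable tilt, ligand walks
with a scripted egress frame and exit direction, hills schedules with
exact Gaussian parameters, and alignments whose per-position identity
plan fixes the expected conservation matrix.

Every generator is deterministic under a fixed seed.  The membrane
normal is the +z axis by construction; tilted boxes are never emitted.
The protein is a Ca-only bead model — the downstream analyses are
purely geometric and statistical, so no force field or physical packing
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import ConservationMatrix, GroupScheme, SiteDefinition
from .io import (
    HillsTable,
    LabeledSystem,
    LabeledTrajectory,
    Role,
    write_hills,
)
from .tunnels import ClearanceGrid

__all__ = [
    "MembraneSystemSpec",
    "EgressSpec",
    "SyntheticAlignment",
    "TunnelGridFixture",
    "make_membrane_system",
    "make_ligand_walk",
    "make_alignment",
    "make_hills",
    "make_tunnel_grid",
]

# Fe-N distance in a heme is ~2.0 A, so the porphyrin N square has
# half-diagonal 2.0 A.
_HEME_N_RADIUS = 2.0


@dataclass(frozen=True)
class MembraneSystemSpec:
    """Target geometry of a synthetic membrane-anchored system.

    ``tilt_deg`` is the heme-plane-versus-z-axis angle the generator
    realizes exactly before noise; ``bury_depth`` the Ca-centroid to
    C1-plane separation (angstrom); ``noise_sd`` the isotropic Gaussian
    jitter applied independently to every atom in every frame.
    """

    tilt_deg: float = 60.0
    bury_depth: float = 37.0
    n_lipids: int = 50
    n_residues: int = 120
    noise_sd: float = 0.0
    n_frames: int = 10
    frame_interval: float = 50.0  # ps between stored frames
    protein_radius: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt_deg <= 90.0):
            raise ValueError("tilt_deg must be in [0, 90]")
        if self.bury_depth < 0:
            raise ValueError("bury_depth must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_lipids < 1 or self.n_residues < 3:
            raise ValueError("need >=1 lipid and >=3 protein residues")
        if self.n_frames < 1 or self.frame_interval <= 0:
            raise ValueError("need >=1 frame and positive frame interval")


@dataclass(frozen=True)
class EgressSpec:
    """Scripted ligand dissociation.

    The ligand stays buried until ``egress_frame``, then leaves through
    the surface point nearest ``exit_anchor`` and keeps a
    protein-to-ligand minimum distance above any dissociation cutoff up
    to ``threshold_clearance`` beyond it for at least
    ``persistence_frames``.  ``excursion_frame`` optionally places a
    single-frame outside excursion before the real egress, to exercise
    persistence filtering.
    """

    exit_anchor: tuple[float, float, float]
    egress_frame: int
    persistence_frames: int = 10
    n_frames: int = 60
    n_heavy_atoms: int = 5
    threshold_clearance: float = 3.0
    excursion_frame: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.egress_frame < self.n_frames):
            raise ValueError("egress_frame must lie inside the trajectory")
        if self.n_frames - self.egress_frame < self.persistence_frames:
            raise ValueError("not enough frames after egress for the persistence window")
        if self.excursion_frame is not None and not (
            0 <= self.excursion_frame < self.egress_frame - 1
        ):
            raise ValueError("excursion_frame must precede egress_frame - 1")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere (deterministic)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r_xy = np.sqrt(1.0 - z**2)
    return radius * np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)


def _heme_square(tilt_deg: float) -> np.ndarray:
    """Four porphyrin-N positions whose plane makes ``tilt_deg`` with z.

    A square in the xy-plane is perpendicular to z (tilt 90 deg);
    rotating it about x by (90 - tilt) brings the plane-versus-z angle
    to the target exactly.
    """
    square = _HEME_N_RADIUS * np.array(
        [[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]]
    )
    phi = np.radians(90.0 - tilt_deg)
    c, s = np.cos(phi), np.sin(phi)
    rot_x = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    return square @ rot_x.T


def _membrane_layout(
    spec: MembraneSystemSpec, rng: np.random.Generator
) -> tuple[np.ndarray, LabeledSystem]:
    # protein Ca beads on a sphere shell with radial jitter; centroid
    # forced exactly to the origin
    ca = _fibonacci_sphere(spec.n_residues, spec.protein_radius)
    ca *= rng.uniform(0.7, 1.0, size=(spec.n_residues, 1))
    ca -= ca.mean(axis=0)
    heme = _heme_square(spec.tilt_deg)
    # lipid C1 beads on a square lattice exactly at z = bury_depth
    side = int(np.ceil(np.sqrt(spec.n_lipids)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    lattice = np.stack([gx.ravel(), gy.ravel()], axis=1)[: spec.n_lipids] * 8.0
    lattice = lattice - lattice.mean(axis=0)
    lipids = np.column_stack([lattice, np.full(spec.n_lipids, spec.bury_depth)])
    coords = np.vstack([ca, heme, lipids])

    names = (
        ["CA"] * spec.n_residues
        + ["NA", "NB", "NC", "ND"]
        + ["C1"] * spec.n_lipids
    )
    resnames = (
        ["ALA"] * spec.n_residues + ["HEM"] * 4 + ["POPC"] * spec.n_lipids
    )
    resnums = (
        list(range(1, spec.n_residues + 1))
        + [spec.n_residues + 1] * 4
        + list(range(spec.n_residues + 2, spec.n_residues + 2 + spec.n_lipids))
    )
    elements = ["C"] * spec.n_residues + ["N"] * 4 + ["C"] * spec.n_lipids
    roles = (
        [Role.PROTEIN_CA] * spec.n_residues
        + [Role.PORPHYRIN_N] * 4
        + [Role.LIPID_C1] * spec.n_lipids
    )
    system = LabeledSystem(
        atom_names=np.array(names, dtype=object),
        residue_numbers=np.array(resnums, dtype=int),
        residue_names=np.array(resnames, dtype=object),
        chains=np.array(["A"] * len(names), dtype=object),
        elements=np.array(elements, dtype=object),
        roles=np.array(roles, dtype=object),
    )
    return coords, system


def make_membrane_system(spec: MembraneSystemSpec) -> LabeledTrajectory:
    """Build a membrane-anchored pseudo-protein trajectory.

    At ``noise_sd=0`` the heme tilt, burying depth, and lipid plane are
    realized exactly; with noise, each frame adds independent isotropic
    Gaussian jitter to every atom.
    """
    rng = np.random.default_rng(spec.seed)
    coords, system = _membrane_layout(spec, rng)
    frames = np.repeat(coords[None, :, :], spec.n_frames, axis=0)
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    return LabeledTrajectory(system, frames, spec.frame_interval)


def make_ligand_walk(
    spec: EgressSpec,
    base: LabeledTrajectory,
    threshold: float = 5.0,
) -> LabeledTrajectory:
    """Append a scripted dissociating ligand to a membrane system.

    Before ``egress_frame`` the ligand jitters near the protein center
    (minimum distance to the protein well below ``threshold``); from
    ``egress_frame`` on it sits beyond the protein surface along the
    direction of ``exit_anchor``, at least ``threshold +
    threshold_clearance`` away from every protein atom, receding
    steadily.  The base trajectory is tiled/truncated to
    ``spec.n_frames`` frames.
    """
    rng = np.random.default_rng(spec.seed)
    system = base.system
    prot_idx = np.concatenate(
        [system.indices(Role.PROTEIN_CA), system.indices(Role.PORPHYRIN_N)]
    ).astype(int)
    n_base = base.n_frames
    base_frames = base.frames[np.arange(spec.n_frames) % n_base]

    anchor = np.asarray(spec.exit_anchor, dtype=float)
    direction = anchor / np.linalg.norm(anchor)
    # ligand heavy atoms: a tight fixed cluster around the walk center
    offsets = rng.normal(0.0, 0.3, size=(spec.n_heavy_atoms, 3))
    offsets -= offsets.mean(axis=0)
    max_offset = float(np.linalg.norm(offsets, axis=1).max())

    prot_radius = float(
        max(np.linalg.norm(f[prot_idx], axis=1).max() for f in base_frames)
    )
    out_base = prot_radius + threshold + spec.threshold_clearance + max_offset + 1.0

    centers = np.empty((spec.n_frames, 3))
    for f in range(spec.n_frames):
        if f >= spec.egress_frame:
            dist = out_base + 0.5 * (f - spec.egress_frame)
            centers[f] = direction * dist
        elif spec.excursion_frame is not None and f == spec.excursion_frame:
            centers[f] = direction * out_base
        else:
            # buried: hug the alpha-carbon nearest the core, so the
            # pre-egress minimum distance stays well below any dissociation
            # cutoff and the contact registers in association scoring
            frame_prot = base_frames[f][system.indices(Role.PROTEIN_CA)]
            contact = frame_prot[np.argmin(np.linalg.norm(frame_prot, axis=1))]
            centers[f] = contact + rng.normal(0.0, 0.5, size=3)

    lig_names = [f"C{i+1}" for i in range(spec.n_heavy_atoms)]
    lig_resnum = int(system.residue_numbers.max()) + 1
    new_system = LabeledSystem(
        atom_names=np.concatenate([system.atom_names, np.array(lig_names, dtype=object)]),
        residue_numbers=np.concatenate(
            [system.residue_numbers, np.full(spec.n_heavy_atoms, lig_resnum, dtype=int)]
        ),
        residue_names=np.concatenate(
            [system.residue_names, np.array(["LIG"] * spec.n_heavy_atoms, dtype=object)]
        ),
        chains=np.concatenate(
            [system.chains, np.array(["L"] * spec.n_heavy_atoms, dtype=object)]
        ),
        elements=np.concatenate(
            [system.elements, np.array(["C"] * spec.n_heavy_atoms, dtype=object)]
        ),
        roles=np.concatenate(
            [system.roles, np.array([Role.LIGAND_HEAVY] * spec.n_heavy_atoms, dtype=object)]
        ),
    )
    lig_frames = centers[:, None, :] + offsets[None, :, :]
    frames = np.concatenate([base_frames, lig_frames], axis=1)
    return LabeledTrajectory(new_system, frames, base.frame_interval)


@dataclass
class SyntheticAlignment:
    """An alignment plus the conservation ground truth it encodes."""

    alignment: MultipleSeqAlignment
    site: SiteDefinition
    expected: ConservationMatrix

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for record in self.alignment:
                fh.write(f">{record.id}\n{record.seq}\n")


def make_alignment(
    n_seqs: int,
    site_positions: list[int],
    identity_plan: list[str],
    seed: int = 0,
    scheme: GroupScheme | None = None,
) -> SyntheticAlignment:
    """Build an ungapped alignment with a known conservation matrix.

    ``identity_plan`` assigns each site position one of ``identical``,
    ``group`` (different residue, same physicochemical group), or
    ``different`` (residue from another group), describing every
    non-reference sequence relative to the reference.  All
    non-reference sequences are identical to each other, so the
    expected matrix is: reference rows/columns at the plan's scheme
    average, 1.0 elsewhere.
    """
    if len(site_positions) != len(identity_plan):
        raise ValueError("identity_plan must match site_positions in length")
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    if sorted(site_positions) != list(site_positions) or len(set(site_positions)) != len(
        site_positions
    ):
        raise ValueError("site positions must be strictly increasing")
    scheme = scheme or GroupScheme()
    rng = np.random.default_rng(seed)
    groups = [sorted(members) for _, members in scheme.groups]
    alphabet = sorted({r for g in groups for r in g})

    length = max(site_positions) + 5
    ref = [alphabet[i] for i in rng.integers(0, len(alphabet), size=length)]
    other = list(ref)
    scores = []
    for pos, mode in zip(site_positions, identity_plan):
        r = ref[pos - 1]
        group = next(sorted(m) for _, m in scheme.groups if r in m)
        if mode == "identical":
            other[pos - 1] = r
            scores.append(1.0)
        elif mode == "group":
            candidates = [x for x in group if x != r]
            if not candidates:
                raise ValueError(f"residue {r} has no same-group partner")
            other[pos - 1] = candidates[int(rng.integers(0, len(candidates)))]
            scores.append(0.5)
        elif mode == "different":
            candidates = [x for x in alphabet if x not in group]
            other[pos - 1] = candidates[int(rng.integers(0, len(candidates)))]
            scores.append(0.0)
        else:
            raise ValueError(f"unknown identity plan entry: {mode!r}")

    labels = ["REF"] + [f"SEQ{i}" for i in range(1, n_seqs)]
    records = [SeqRecord(Seq("".join(ref)), id="REF", description="")]
    records += [
        SeqRecord(Seq("".join(other)), id=label, description="") for label in labels[1:]
    ]
    site = SiteDefinition(
        reference_id="REF",
        residues=tuple((p, ref[p - 1]) for p in site_positions),
    )
    c_ref = float(np.mean(scores))
    ident_ref = 100.0 * identity_plan.count("identical") / len(identity_plan)
    n = n_seqs
    c = np.ones((n, n))
    identity = np.full((n, n), 100.0)
    c[0, 1:] = c[1:, 0] = c_ref
    identity[0, 1:] = identity[1:, 0] = ident_ref
    expected = ConservationMatrix(labels=labels, c=c, identity=identity)
    return SyntheticAlignment(
        alignment=MultipleSeqAlignment(records), site=site, expected=expected
    )


def make_hills(
    schedule: list[tuple[float, float, float, float]],
    path: str | Path | None = None,
) -> HillsTable:
    """Hills table from an explicit (time, center, width, height) schedule.

    Optionally also written to ``path`` in the four-column text dialect,
    which round-trips exactly through ``read_hills`` at the 1e-6
    precision of the writer.
    """
    if schedule:
        arr = np.array(schedule, dtype=float)
        table = HillsTable(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
    else:
        table = HillsTable(np.array([]), np.array([]), np.array([]), np.array([]))
    if path is not None:
        write_hills(table, path)
    return table


@dataclass
class TunnelGridFixture:
    """A clearance grid with its exact maximin bottleneck."""

    grid: ClearanceGrid
    start: tuple[int, int, int]
    true_bottleneck: float


def make_tunnel_grid(
    shape: tuple[int, int, int],
    corridors: list[tuple[list[tuple[int, int, int]], list[float] | float]],
    start: tuple[int, int, int],
    background: float = -1.0,
) -> TunnelGridFixture:
    """Carve corridors of known clearance into a walled grid.

    Each corridor is a voxel path from ``start`` to the grid boundary
    with a clearance value (scalar or per-voxel).  Corridors must be
    disjoint except at the shared start voxel and may touch the
    boundary only at their final voxel; under those conditions the
    maximin bottleneck of the grid equals the maximum over corridors of
    the minimum clearance along each, which is returned as ground
    truth.  A corridor that fails to reach the boundary is an error.
    """
    values = np.full(shape, background, dtype=float)
    start = tuple(int(x) for x in start)
    occupied: set[tuple[int, int, int]] = set()
    per_corridor_min: list[float] = []
    for path_voxels, clearance in corridors:
        path_voxels = [tuple(int(x) for x in v) for v in path_voxels]
        if path_voxels[0] != start:
            raise ValueError("every corridor must begin at the start voxel")
        clearances = (
            [float(clearance)] * len(path_voxels)
            if np.isscalar(clearance)
            else [float(c) for c in clearance]
        )
        if len(clearances) != len(path_voxels):
            raise ValueError("per-voxel clearance list must match path length")
        if any(c <= 0 for c in clearances):
            raise ValueError("corridor clearances must be positive")
        def on_boundary(v: tuple[int, int, int]) -> bool:
            return any(c == 0 or c == n - 1 for c, n in zip(v, shape))
        if not on_boundary(path_voxels[-1]):
            raise ValueError("corridor does not reach the grid boundary (disconnected)")
        for i, (v, prev) in enumerate(zip(path_voxels[1:], path_voxels[:-1]), start=1):
            if sum(abs(a - b) for a, b in zip(v, prev)) != 1:
                raise ValueError("corridor voxels must be 6-connected")
            if on_boundary(v) and i != len(path_voxels) - 1:
                raise ValueError("corridor touches the boundary before its final voxel")
            if v in occupied:
                raise ValueError("corridors may share only the start voxel")
            occupied.add(v)
        for v, c in zip(path_voxels, clearances):
            values[v] = max(values[v], c)
        per_corridor_min.append(min(clearances))
    if not per_corridor_min:
        raise ValueError("at least one corridor required")
    grid = ClearanceGrid(values=values, spacing=1.0)
    return TunnelGridFixture(
        grid=grid, start=start, true_bottleneck=max(per_corridor_min)
    )
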