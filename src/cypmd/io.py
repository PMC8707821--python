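"""Structure, trajectory, and hills-file I/O with role labeling.

All analyses downstream operate on a small number of atom roles rather
than full chemical topologies: protein alpha-carbons, the four porphyrin
nitrogens of the heme, the C1 carbons of POPC lipids (the leaflet
reference plane), and ligand heavy atoms.  This module reads the standard
formats (PDB structures, DCD/XTC or multi-model PDB trajectories,
whitespace-delimited metadynamics hills records) and attaches those role
labels once, at the boundary.

Units are fixed at the boundary: coordinates in angstrom, times in
picoseconds, energies in kcal/mol.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

__all__ = [
    "Role",
    "RoleRules",
    "LabeledSystem",
    "LabeledTrajectory",
    "HillsTable",
    "read_structure",
    "read_trajectory",
    "read_hills",
    "write_structure",
    "write_trajectory",
    "write_hills",
]

# Three-letter codes treated as protein residues when labeling CA atoms.
_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
}


class Role(enum.Enum):
    """Functional role of an atom in the analysis pipeline."""

    PROTEIN_CA = "protein_ca"
    PORPHYRIN_N = "porphyrin_n"
    LIPID_C1 = "lipid_c1"
    LIGAND_HEAVY = "ligand_heavy"
    OTHER = "other"


@dataclass(frozen=True)
class RoleRules:
    """Atom-name/residue-name patterns that assign roles.

    The defaults cover conventional PDB naming: ``CA`` atoms of standard
    amino-acid residues, the ``NA/NB/NC/ND`` nitrogens of a ``HEM`` group,
    the ``C1`` carbon of ``POPC``, and heavy atoms of residues whose name
    appears in ``ligand_resnames``.  Every rule is a plain set so studies
    with non-standard naming can supply their own.
    """

    heme_resnames: frozenset[str] = frozenset({"HEM", "HEC", "HEB"})
    porphyrin_n_names: frozenset[str] = frozenset({"NA", "NB", "NC", "ND"})
    lipid_resnames: frozenset[str] = frozenset({"POPC", "POPE", "POPS"})
    lipid_c1_names: frozenset[str] = frozenset({"C1"})
    ligand_resnames: frozenset[str] = frozenset({"LIG", "UNK", "MOL", "DRG"})
    protein_resnames: frozenset[str] = frozenset(_PROTEIN_RESNAMES)

    def assign(self, atom_name: str, residue_name: str, element: str) -> Role:
        name = atom_name.strip().upper()
        resname = residue_name.strip().upper()
        if resname in self.protein_resnames and name == "CA":
            return Role.PROTEIN_CA
        if resname in self.heme_resnames and name in self.porphyrin_n_names:
            return Role.PORPHYRIN_N
        if resname in self.lipid_resnames and name in self.lipid_c1_names:
            return Role.LIPID_C1
        if resname in self.ligand_resnames and element.upper() != "H":
            return Role.LIGAND_HEAVY
        return Role.OTHER


class LabelingError(ValueError):
    """Raised when role assignment produces an unusable labeling."""


@dataclass
class LabeledSystem:
    """A static topology with one role label per atom.

    Residue numbers follow the PDB field verbatim (1-based, author
    numbering); no renumbering is performed.
    """

    atom_names: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chains: np.ndarray
    elements: np.ndarray
    roles: np.ndarray  # array of Role

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for attr in ("residue_numbers", "residue_names", "chains", "elements", "roles"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"field {attr!r} length does not match atom count {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def indices(self, role: Role) -> np.ndarray:
        """Indices of atoms carrying ``role``, in file order."""
        return np.flatnonzero(np.array([r is role for r in self.roles]))

    def role_counts(self) -> dict[Role, int]:
        return {role: int(len(self.indices(role))) for role in Role}

    def ca_residue_numbers(self) -> np.ndarray:
        """Residue numbers of the alpha-carbon atoms, in file order."""
        return self.residue_numbers[self.indices(Role.PROTEIN_CA)]


@dataclass
class LabeledTrajectory:
    """Coordinate frames (angstrom) over a :class:`LabeledSystem`.

    ``frame_interval`` is the time between consecutive frames in ps.
    """

    system: LabeledSystem
    frames: np.ndarray  # (n_frames, n_atoms, 3), angstrom
    frame_interval: float  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.system.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"system atom count {self.system.n_atoms}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def coordinates(self, role: Role) -> np.ndarray:
        """(n_frames, n_role_atoms, 3) slice for one role."""
        return self.frames[:, self.system.indices(role), :]


@dataclass
class HillsTable:
    """Deposited metadynamics Gaussians, sorted by time.

    Columns: deposit time (ps), CV center (angstrom), width sigma
    (angstrom), height (kcal/mol).  Widths and heights are strictly
    positive.
    """

    time: np.ndarray
    center: np.ndarray
    width: np.ndarray
    height: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.time, self.center, self.width, self.height)]
        self.time, self.center, self.width, self.height = arrays
        n = len(self.time)
        if any(len(a) != n for a in arrays[1:]):
            raise ValueError("hills columns must have equal length")
        if n:
            if np.any(self.width <= 0):
                raise ValueError("hill widths must be strictly positive")
            if np.any(self.height <= 0):
                raise ValueError("hill heights must be strictly positive")
            order = np.argsort(self.time, kind="stable")
            for name in ("time", "center", "width", "height"):
                setattr(self, name, getattr(self, name)[order])

    @property
    def n_hills(self) -> int:
        return len(self.time)


def _universe_fields(u: "mda.Universe") -> tuple[np.ndarray, ...]:
    atoms = u.atoms
    names = np.array([a.name for a in atoms], dtype=object)
    resnums = np.array([a.resid for a in atoms], dtype=int)
    resnames = np.array([a.resname for a in atoms], dtype=object)
    try:
        chains = np.array([a.chainID for a in atoms], dtype=object)
    except mda.exceptions.NoDataError:
        chains = np.array(["A"] * len(atoms), dtype=object)
    elements = []
    for a in atoms:
        try:
            el = a.element
        except mda.exceptions.NoDataError:
            el = ""
        if not el:
            # PDB convention: first alphabetic character of the atom name.
            el = next((c for c in a.name if c.isalpha()), "X")
        elements.append(el.upper())
    return names, resnums, resnames, chains, np.array(elements, dtype=object)


def read_structure(path: str | Path, rules: RoleRules | None = None) -> LabeledSystem:
    """Read a PDB file and assign one role per atom.

    Atoms matching no rule are labeled :data:`Role.OTHER`.  A structure
    with zero alpha-carbons cannot anchor any downstream analysis and
    raises :class:`LabelingError`.
    """
    rules = rules or RoleRules()
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    names, resnums, resnames, chains, elements = _universe_fields(u)
    roles = np.array(
        [rules.assign(n, rn, el) for n, rn, el in zip(names, resnames, elements)],
        dtype=object,
    )
    system = LabeledSystem(names, resnums, resnames, chains, elements, roles)
    if len(system.indices(Role.PROTEIN_CA)) == 0:
        raise LabelingError(f"no protein alpha-carbon atoms labeled in {path}")
    n_porph = len(system.indices(Role.PORPHYRIN_N))
    if n_porph not in (0, 4):
        raise LabelingError(
            f"expected 0 or 4 porphyrin nitrogens, found {n_porph} in {path}"
        )
    return system


def read_trajectory(
    path: str | Path,
    system: LabeledSystem,
    frame_interval: float | None = None,
) -> LabeledTrajectory:
    """Read a DCD/XTC or multi-model PDB trajectory over ``system``.

    ``frame_interval`` (ps) overrides whatever the file header declares;
    multi-model PDB files carry no time information, so the interval
    defaults to 1 ps there.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix == ".pdb":
            u = mda.Universe(str(path))
        else:
            if suffix == ".dcd":
                reader_cls = mda.coordinates.DCD.DCDReader
            elif suffix == ".xtc":
                reader_cls = mda.coordinates.XTC.XTCReader
            else:
                raise ValueError(f"unsupported trajectory format: {path.suffix}")
            reader = reader_cls(str(path))
            if reader.n_atoms != system.n_atoms:
                raise ValueError(
                    f"trajectory atom count {reader.n_atoms} does not match "
                    f"system atom count {system.n_atoms}"
                )
            frames = np.array([ts.positions.copy() for ts in reader], dtype=float)
            dt = frame_interval if frame_interval is not None else float(reader.dt or 1.0)
            reader.close()
            return LabeledTrajectory(system, frames, dt)
    if u.atoms.n_atoms != system.n_atoms:
        raise ValueError(
            f"trajectory atom count {u.atoms.n_atoms} does not match "
            f"system atom count {system.n_atoms}"
        )
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return LabeledTrajectory(system, frames, frame_interval or 1.0)


def _build_universe(system: LabeledSystem, coords: np.ndarray) -> "mda.Universe":
    n = system.n_atoms
    resnums = system.residue_numbers
    # contiguous runs of equal residue number form residues
    boundaries = np.flatnonzero(np.diff(resnums) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    n_res = len(starts)
    residx = np.zeros(n, dtype=int)
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < n_res else n
        residx[s:e] = i
    u = mda.Universe.empty(
        n_atoms=n, n_residues=n_res, atom_resindex=residx,
        n_segments=1, trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in system.atom_names])
    u.add_TopologyAttr("resids", [int(resnums[s]) for s in starts])
    u.add_TopologyAttr("resnames", [str(system.residue_names[s]) for s in starts])
    u.add_TopologyAttr("elements", [str(x) for x in system.elements])
    u.add_TopologyAttr("chainIDs", [str(x) for x in system.chains])
    u.atoms.positions = np.asarray(coords, dtype=float)
    return u


def write_structure(system: LabeledSystem, coords: np.ndarray, path: str | Path) -> None:
    """Write a single-frame PDB for ``system`` at ``coords`` (angstrom)."""
    u = _build_universe(system, coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: LabeledTrajectory, path: str | Path) -> None:
    """Write a trajectory as DCD or multi-model PDB, by file extension."""
    path = Path(path)
    u = _build_universe(traj.system, traj.frames[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.system.n_atoms, multiframe=True) as w:
            for frame in traj.frames:
                u.atoms.positions = frame
                w.write(u.atoms)


def read_hills(path: str | Path) -> HillsTable:
    """Parse a whitespace-delimited hills record.

    The first four columns are time (ps), CV center (angstrom), width
    sigma (angstrom), and height (kcal/mol); extra columns are ignored,
    which covers both PLUMED-style HILLS files and exported tables.
    Lines starting with ``#`` or ``@`` are comments.  Rows are returned
    sorted by deposit time.
    """
    path = Path(path)
    rows: list[tuple[float, float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "@")):
                continue
            parts = stripped.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 columns "
                    f"(time center width height), got {len(parts)}"
                )
            try:
                t, c, w, h = (float(x) for x in parts[:4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            if w <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive hill width {w}")
            if h <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive hill height {h}")
            rows.append((t, c, w, h))
    if not rows:
        return HillsTable(np.array([]), np.array([]), np.array([]), np.array([]))
    arr = np.array(rows, dtype=float)
    return HillsTable(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def write_hills(table: HillsTable, path: str | Path) -> None:
    """Write a hills table in the four-column whitespace dialect."""
    with open(path, "w") as fh:
        fh.write("# time_ps center_A sigma_A height_kcal_mol\n")
        for t, c, w, h in zip(table.time, table.center, table.width, table.height):
            fh.write(f"{t:.6f} {c:.6f} {w:.6f} {h:.6f}\n")
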