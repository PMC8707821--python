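"""Metadynamics bias reconstruction and ligand-egress readouts.

The egress simulations bias the distance between the ligand centroid
and the heme iron with repulsive Gaussians (default height 0.03
kcal/mol, width sigma 0.05 A, wall at 45 A).  From the deposited hills
and the trajectory, three readouts characterize each replica:

* ``delta_t`` — the simulation time until the ligand completely
  dissociates, automated here as the first frame opening a persistent
  run (default 10 frames) of ligand-to-protein minimum distances above
  5 A;
* ``p_max`` — the maximum of the reconstructed bias potential V(s, t)
  over the CV range [0, wall] at t = delta_t; and
* the egress pathway, classified by the tunnels module.

The Gaussian convention is PLUMED-like: the stated width enters the
exponent as 2*sigma^2.  An FWHM convention is available for hills files
produced under the other parameterization.  Plain (non-well-tempered)
heights are summed; no rescaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HillsTable, LabeledTrajectory, Role
from .stats_report import ALPHA, WelchResult, summarize, welch_ttest_from_stats
from .tunnels import classify_egress_pathway, ligand_com_trace

__all__ = [
    "EgressReadout",
    "EgressComparison",
    "bias_potential",
    "min_protein_ligand_distance",
    "detect_egress_time",
    "p_max",
    "p_max_along_path",
    "analyze_egress",
    "egress_group_compare",
    "DEFAULT_WALL",
    "DEFAULT_HILL_HEIGHT",
    "DEFAULT_HILL_WIDTH",
]

DEFAULT_WALL = 45.0  # A, upper bound of the CV range
DEFAULT_HILL_HEIGHT = 0.03  # kcal/mol
DEFAULT_HILL_WIDTH = 0.05  # A (sigma)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class EgressReadout:
    """Per-replica egress summary.

    ``delta_t_ps`` is None (and ``egressed`` False) for replicas in
    which the ligand never dissociates within the simulated time; for
    those, ``p_max_kcal_mol`` is evaluated at the final time and must
    be read as a lower bound on the potential an egress would need.
    """

    delta_t_ps: float | None
    p_max_kcal_mol: float
    pathway: str | None
    egressed: bool
    wall: float = DEFAULT_WALL

    @property
    def delta_t_ns(self) -> float | None:
        return None if self.delta_t_ps is None else self.delta_t_ps / 1000.0


def _sigma(width: np.ndarray, width_convention: str) -> np.ndarray:
    if width_convention == "sigma":
        return width
    if width_convention == "fwhm":
        return width * _FWHM_TO_SIGMA
    raise ValueError(f"unknown width convention: {width_convention!r}")


def bias_potential(
    hills: HillsTable,
    s: float | np.ndarray,
    t: float = np.inf,
    width_convention: str = "sigma",
) -> float | np.ndarray:
    """Reconstructed bias V(s, t) = sum over hills with t_i <= t of
    h_i * exp(-(s - s_i)^2 / (2 sigma_i^2)), in kcal/mol.

    Monotone non-decreasing in t at every fixed s, and zero before the
    first deposit.
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if hills.n_hills == 0:
        out = np.zeros(s_arr.shape)
        return float(out[0]) if np.isscalar(s) or np.ndim(s) == 0 else out
    mask = hills.time <= t
    centers = hills.center[mask]
    sigmas = _sigma(hills.width[mask], width_convention)
    heights = hills.height[mask]
    diff = s_arr[:, None] - centers[None, :]
    v = np.sum(heights[None, :] * np.exp(-(diff**2) / (2.0 * sigmas[None, :] ** 2)), axis=1)
    return float(v[0]) if np.isscalar(s) or np.ndim(s) == 0 else v


def min_protein_ligand_distance(traj: LabeledTrajectory) -> np.ndarray:
    """Per-frame minimum distance from any ligand heavy atom to the protein.

    The protein is represented by its labeled alpha-carbons plus the
    porphyrin nitrogens of the heme.
    """
    lig_idx = traj.system.indices(Role.LIGAND_HEAVY)
    prot_idx = np.concatenate(
        [traj.system.indices(Role.PROTEIN_CA), traj.system.indices(Role.PORPHYRIN_N)]
    ).astype(int)
    if len(lig_idx) == 0:
        raise ValueError("trajectory has no ligand heavy atoms")
    out = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        d = np.linalg.norm(frame[lig_idx][:, None, :] - frame[prot_idx][None, :, :], axis=2)
        out[f] = d.min()
    return out


def detect_egress_time(
    min_distance: np.ndarray,
    times: np.ndarray,
    threshold: float = 5.0,
    persistence: int = 10,
) -> float | None:
    """Time of complete ligand dissociation, or None if it never occurs.

    Dissociation is the first frame that opens a run of at least
    ``persistence`` consecutive frames whose ligand-to-protein minimum
    distance all exceed ``threshold``; brief excursions shorter than
    the persistence window are ignored.
    """
    d = np.asarray(min_distance, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(d) == 0:
        raise ValueError("empty distance series")
    if len(d) != len(times):
        raise ValueError("distance and time series must have equal length")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    above = d > threshold
    run_start = None
    count = 0
    for i, flag in enumerate(above):
        if flag:
            if count == 0:
                run_start = i
            count += 1
            if count >= persistence:
                return float(times[run_start])
        else:
            count = 0
            run_start = None
    return None


def p_max(
    hills: HillsTable,
    delta_t: float,
    wall: float = DEFAULT_WALL,
    grid_spacing: float | None = None,
    width_convention: str = "sigma",
) -> float:
    """Maximal deposited bias over the CV range [0, wall] at time ``delta_t``.

    The CV grid spacing defaults to a quarter of the narrowest hill
    width, comfortably below the sigma/2 needed to resolve every
    Gaussian peak.
    """
    if hills.n_hills == 0:
        return 0.0
    mask = hills.time <= delta_t
    if not mask.any():
        return 0.0
    sigmas = _sigma(hills.width, width_convention)
    spacing = grid_spacing if grid_spacing is not None else float(sigmas.min()) / 4.0
    if spacing > float(sigmas.min()) / 2.0:
        raise ValueError("grid spacing must be at most half the narrowest hill width")
    grid = np.arange(0.0, wall + spacing, spacing)
    return float(np.max(bias_potential(hills, grid, delta_t, width_convention)))


def p_max_along_path(
    hills: HillsTable,
    cv_series: np.ndarray,
    times: np.ndarray,
    width_convention: str = "sigma",
) -> float:
    """Maximum bias actually experienced along the trajectory.

    Alternative readout: instead of scanning the full CV range at the
    dissociation time, evaluate V(s(t), t) at every frame and take the
    maximum.  Always bounded above by :func:`p_max` at the final time.
    """
    cv = np.asarray(cv_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(cv) != len(times):
        raise ValueError("cv and time series must have equal length")
    return float(max(bias_potential(hills, s, t, width_convention) for s, t in zip(cv, times)))


def analyze_egress(
    traj: LabeledTrajectory,
    hills: HillsTable,
    anchors: dict[str, np.ndarray] | None = None,
    threshold: float = 5.0,
    persistence: int = 10,
    wall: float = DEFAULT_WALL,
) -> EgressReadout:
    """Full per-replica readout: delta_t, P_max, and egress pathway.

    Replicas without an egress get ``delta_t_ps=None``, a P_max
    evaluated at the final frame time, and no pathway.
    """
    dist = min_protein_ligand_distance(traj)
    times = traj.times
    delta_t = detect_egress_time(dist, times, threshold, persistence)
    if delta_t is None:
        return EgressReadout(
            delta_t_ps=None,
            p_max_kcal_mol=p_max(hills, float(times[-1]), wall),
            pathway=None,
            egressed=False,
            wall=wall,
        )
    pathway = None
    if anchors:
        prot_idx = traj.system.indices(Role.PROTEIN_CA)
        pathway = classify_egress_pathway(
            ligand_com_trace(traj), anchors, traj.frames[:, prot_idx, :], threshold
        )
    return EgressReadout(
        delta_t_ps=float(delta_t),
        p_max_kcal_mol=p_max(hills, float(delta_t), wall),
        pathway=pathway,
        egressed=True,
        wall=wall,
    )


@dataclass(frozen=True)
class EgressComparison:
    """Group comparison of one egress metric between two conditions.

    ``label`` names the condition with the lower mean ("H1" for the
    allosteric-ligand group, "WAT" for the water control); the
    comparison is significant when p < alpha.
    """

    metric: str
    label: str
    p: float
    t: float
    significant: bool


def egress_group_compare(
    readouts_allosteric: list[EgressReadout],
    readouts_control: list[EgressReadout],
    alpha: float = ALPHA,
) -> dict[str, EgressComparison]:
    """Welch-compare delta_t and P_max between allosteric and control groups.

    Only replicas with an actual egress contribute to the delta_t
    comparison; P_max uses all replicas.  At least two contributing
    replicas per group per metric are required.
    """
    out: dict[str, EgressComparison] = {}
    for metric in ("delta_t", "p_max"):
        if metric == "delta_t":
            a_vals = [r.delta_t_ps for r in readouts_allosteric if r.egressed]
            b_vals = [r.delta_t_ps for r in readouts_control if r.egressed]
        else:
            a_vals = [r.p_max_kcal_mol for r in readouts_allosteric]
            b_vals = [r.p_max_kcal_mol for r in readouts_control]
        if len(a_vals) < 2 or len(b_vals) < 2:
            raise ValueError(f"metric {metric!r}: need >=2 contributing replicas per group")
        result: WelchResult = welch_ttest_from_stats(summarize(a_vals), summarize(b_vals))
        label = "H1" if np.mean(a_vals) < np.mean(b_vals) else "WAT"
        out[metric] = EgressComparison(
            metric=metric, label=label, p=result.p, t=result.t,
            significant=result.p < alpha,
        )
    return out
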