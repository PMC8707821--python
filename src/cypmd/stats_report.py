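"""Summary-statistics t-tests, outcome tables, and simulation accounting.

All hypothesis tests in the pipeline are Welch two-sided t-tests run
from summary statistics (mean, sample sd, n) at a significance level of
p = 0.1, matching how trajectory-level readouts (egress times, maximal
potentials, bottleneck radii) are compared when only per-replica
summaries are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "WelchResult",
    "PlanRow",
    "SimulationPlan",
    "CosolventAccounting",
    "welch_ttest_from_stats",
    "summarize",
    "build_outcome_table",
    "plan_total_time",
    "table1_plan",
    "cosolvent_accounting",
    "ALPHA",
]

ALPHA = 0.1


@dataclass(frozen=True)
class SummaryStats:
    """Group summary: mean, sample standard deviation (ddof=1), and n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary statistics require n >= 2")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def summarize(values: np.ndarray) -> SummaryStats:
    """Summary statistics of a sample (sample sd, ddof=1)."""
    v = np.asarray(values, dtype=float)
    return SummaryStats(mean=float(np.mean(v)), sd=float(np.std(v, ddof=1)), n=len(v))


def welch_ttest_from_stats(a: SummaryStats, b: SummaryStats) -> WelchResult:
    """Welch's unequal-variance t-test from summary statistics, two-sided.

    Degrees of freedom follow Welch–Satterthwaite.  The degenerate case
    of zero variance in both groups with equal means is defined as
    t = 0, p = 1 (no evidence of a difference); zero variance in both
    groups with different means has no finite t and raises.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return WelchResult(t=0.0, df=float(a.n + b.n - 2), p=1.0)
        raise ValueError("degenerate variance: both groups have sd=0 with different means")
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return WelchResult(t=float(t), df=float(df), p=float(p))


def build_outcome_table(
    tunnel_outcomes: dict[str, dict[str, "object"]],
    egress_outcomes: dict[str, dict[str, "object"]],
    alpha: float = ALPHA,
    tunnel_order: tuple[str, ...] = ("2b", "2c", "2f"),
) -> pd.DataFrame:
    """Assemble the per-enzyme outcome table.

    ``tunnel_outcomes`` maps enzyme -> tunnel id -> TunnelOutcome;
    ``egress_outcomes`` maps enzyme -> metric ("delta_t", "p_max") ->
    an object with ``label`` and ``p`` attributes (see
    :func:`cypmd.metadynamics.egress_group_compare`).  The Significance
    column is "yes" when *either* egress metric falls below alpha.
    Every enzyme present in one input must be present in the other.
    """
    enzymes = sorted(egress_outcomes)
    if set(tunnel_outcomes) != set(enzymes):
        missing = set(tunnel_outcomes) ^ set(enzymes)
        raise ValueError(f"enzymes missing from one input: {sorted(missing)}")
    rows = []
    for enzyme in enzymes:
        egress = egress_outcomes[enzyme]
        for metric in ("delta_t", "p_max"):
            if metric not in egress:
                raise ValueError(f"{enzyme}: missing egress metric {metric!r}")
        significant = any(egress[m].p < alpha for m in ("delta_t", "p_max"))
        row = {
            "enzyme": enzyme,
            "outcome_delta_t": f"{egress['delta_t'].label} ({egress['delta_t'].p:.3f})",
            "outcome_p_max": f"{egress['p_max'].label} ({egress['p_max'].p:.3f})",
            "significance": "yes" if significant else "no",
        }
        for tunnel_id in tunnel_order:
            outcome = tunnel_outcomes[enzyme].get(tunnel_id)
            row[f"r_b_{tunnel_id}"] = outcome.direction if outcome is not None else "n/a"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PlanRow:
    """One simulation type in a study plan (durations in ns, per replica)."""

    sim_type: str
    membrane: bool
    duration_ns: float
    replicas: int
    ligand_orthosteric: bool = False
    ligand_allosteric: bool = False

    def __post_init__(self) -> None:
        if self.duration_ns <= 0:
            raise ValueError("duration must be positive")
        if self.replicas < 1:
            raise ValueError("replicas must be >= 1")


@dataclass(frozen=True)
class SimulationPlan:
    rows: tuple[PlanRow, ...]
    n_enzymes: int = 1


def table1_plan(n_enzymes: int = 9) -> SimulationPlan:
    """The study's simulation plan across the nine major drug-metabolizing CYPs.

    Per enzyme: cosolvent MD (10 x 60 ns, soluble), small-molecule
    association (1 x 500 ns, soluble, 20 ligand copies), membrane
    equilibration (1 x 300 ns), membrane sampling with allosteric ligand
    (3 x 1005 ns), and metadynamics with and without the allosteric
    ligand (10 x 50 ns each).
    """
    return SimulationPlan(
        rows=(
            PlanRow("cosolvent", False, 60.0, 10),
            PlanRow("association", False, 500.0, 1, ligand_allosteric=True),
            PlanRow("equilibration", True, 300.0, 1, ligand_orthosteric=True),
            PlanRow("sampling", True, 1005.0, 3, ligand_allosteric=True),
            PlanRow("metadynamics", True, 50.0, 10, ligand_orthosteric=True),
            PlanRow(
                "metadynamics_allosteric", True, 50.0, 10,
                ligand_orthosteric=True, ligand_allosteric=True,
            ),
        ),
        n_enzymes=n_enzymes,
    )


def plan_total_time(plan: SimulationPlan) -> tuple[float, dict[str, float]]:
    """Total simulated time (ns) and per-type subtotals across all enzymes."""
    breakdown = {
        row.sim_type: row.duration_ns * row.replicas * plan.n_enzymes
        for row in plan.rows
    }
    return float(sum(breakdown.values())), breakdown


@dataclass(frozen=True)
class CosolventAccounting:
    n_simulations: int
    total_ns: float


def cosolvent_accounting(
    n_probes: int = 3,
    replicas_per_probe: int = 10,
    equilibration_ns: float = 15.0,
    sampling_ns: float = 5.0,
) -> CosolventAccounting:
    """Per-enzyme cosolvent-MD bookkeeping.

    Three probe species (isopropanol, acetonitrile, pyridine) at 10
    replicas each give 30 individual simulations; 15 ns equilibration
    plus 5 ns of sampled association per replica totals 600 ns per
    system.
    """
    n_sims = n_probes * replicas_per_probe
    return CosolventAccounting(
        n_simulations=n_sims,
        total_ns=float(n_sims * (equilibration_ns + sampling_ns)),
    )
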