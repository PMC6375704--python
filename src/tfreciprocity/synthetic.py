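"""Synthetic data: ground-truth locus models, residence-time datasets, trajectories.

No raw single-molecule data are deposited for this analysis beyond the
printed summary table, so every pipeline stage is exercised against data
generated from a known ground truth: a pair of rate tables (one per cell
line), alpha ratios and induced concentrations, from which the true kappas,
rho and Gamma follow through the same bridge equations the analysis uses.

``simulate_residence_dataset`` inverts the bridge — per scenario, a chosen
unbinding rate fixes the bound time and the true kappa fixes the search time —
and adds normal measurement error on the time scale, matching the sampling
model used for significance.  ``simulate_trajectory`` is a standard
continuous-time Markov-chain (Gillespie) simulation used as a stochastic
oracle for steady states, binding order and time-reversal symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bridge import (
    AlphaRatios,
    KappaSet,
    ResidenceTimeTable,
    ScenarioTimes,
    kappa_from_fraction,
)
from .graph import RateGraph
from .locus import RateTable, cooperativities, cycle_R
from .reciprocity import gamma_from_fractions, scenario_fractions

__all__ = [
    "GroundTruth",
    "Trajectory",
    "generate_locus_model",
    "simulate_residence_dataset",
    "simulate_trajectory",
    "first_passage_routes",
    "occupancy_fractions",
    "net_edge_winding",
]

#: Default per-scenario bound times (s), on the scale of real measurements.
_DEFAULT_BOUND_TIMES = (12.0, 8.0, 9.0, 14.0)


@dataclass(frozen=True)
class GroundTruth:
    """A fully specified study: tables, alphas, induced concentrations.

    Derived true kappas, rho and Gamma are computed through the bridge
    equations, so they are consistent with the tables by construction.
    """

    sox2_line: RateTable
    oct4_line: RateTable
    alphas: AlphaRatios
    sox2_induced_conc: float
    oct4_induced_conc: float
    fractions: tuple = field(init=False)
    kappas: KappaSet = field(init=False)
    rho: float = field(init=False)
    gamma: float = field(init=False)

    def __post_init__(self) -> None:
        P1, P2, P3, P4 = scenario_fractions(
            self.sox2_line,
            self.oct4_line,
            self.sox2_induced_conc,
            self.oct4_induced_conc,
        )
        a_S, a_O = self.alphas.alpha_S, self.alphas.alpha_O
        ks = KappaSet(
            kappa1=kappa_from_fraction(P1, a_S),
            kappa2=kappa_from_fraction(P2, a_O),
            kappa3=kappa_from_fraction(P3, a_O),
            kappa4=kappa_from_fraction(P4, a_S),
        )
        k1, k2, k3, k4 = ks.as_tuple()
        object.__setattr__(self, "fractions", (P1, P2, P3, P4))
        object.__setattr__(self, "kappas", ks)
        object.__setattr__(self, "rho", (k1 * k3) / (k2 * k4))
        object.__setattr__(self, "gamma", gamma_from_fractions(P1, P2, P3, P4))


@dataclass
class Trajectory:
    """A continuous-time path: visited microstates with their dwell times."""

    states: list
    dwell_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.dwell_times = np.asarray(self.dwell_times, dtype=float)
        if (self.dwell_times <= 0).any():
            raise ValueError("dwell times must be positive")


def generate_locus_model(
    seed: int,
    equilibrium: bool = True,
    omega_target: float | tuple[float, float] | None = None,
    r_target: float | None = None,
    conc_S: float = 1.0,
    conc_O: float = 1.0,
) -> RateTable:
    """Random positive rate table with controlled cooperativity and cycle ratio.

    Rates are drawn log-uniformly in [0.1, 10].  ``omega_target`` (a value or
    a (low, high) range to draw from) sets both cooperativities by solving for
    k3_on and k4_on, which makes the cycle ratio exactly 1; a non-equilibrium
    table is then produced by scaling k4_off so the cycle ratio equals
    ``r_target`` (drawn log-uniformly in [2, 50] if not given).
    """
    rng = np.random.default_rng(seed)

    def draw() -> float:
        return float(10 ** rng.uniform(-1, 1))

    if omega_target is None:
        omega = float(10 ** rng.uniform(-1, 1))
    elif isinstance(omega_target, tuple):
        lo, hi = omega_target
        if not (0 < lo <= hi):
            raise ValueError("invalid omega_target range")
        omega = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        if not omega_target > 0:
            raise ValueError("omega_target must be positive")
        omega = float(omega_target)

    k1_on, k2_on = draw(), draw()
    k1_off, k2_off, k3_off, k4_off = draw(), draw(), draw(), draw()
    # omega_SO = k4_on k1_off / (k4_off k1_on); omega_OS = k3_on k2_off / (k3_off k2_on)
    k4_on = omega * k4_off * k1_on / k1_off
    k3_on = omega * k3_off * k2_on / k2_off
    if not equilibrium:
        if r_target is None:
            r_target = float(np.exp(rng.uniform(np.log(2.0), np.log(50.0))))
        if not r_target > 0:
            raise ValueError("r_target must be positive")
        k4_off = k4_off * r_target  # R = omega_OS / omega_SO scales with k4_off
    table = RateTable(
        k1_on=k1_on,
        k2_on=k2_on,
        k3_on=k3_on,
        k4_on=k4_on,
        k1_off=k1_off,
        k2_off=k2_off,
        k3_off=k3_off,
        k4_off=k4_off,
        conc_S=conc_S,
        conc_O=conc_O,
    )
    if equilibrium and omega_target is not None and not isinstance(omega_target, tuple):
        got = cooperativities(table)
        if not np.isclose(got.omega_SO, omega, rtol=1e-9):
            raise ValueError("omega_target infeasible with the constrained rates")
    return table


def simulate_residence_dataset(
    truth: GroundTruth,
    noise_cv: float,
    n_samples: int = 3,
    seed: int = 0,
    bound_times: tuple = _DEFAULT_BOUND_TIMES,
) -> ResidenceTimeTable:
    """Residence-time table implied by a ground truth, with measurement noise.

    Per scenario i the bound time is ``bound_times[i-1]`` (reciprocal of a
    chosen unbinding rate) and the search time is bound_time / kappa_i.
    Each reported mean is the average of ``n_samples`` replicates drawn from
    Normal(true, noise_cv * true) (nonpositive draws rejected); reported SDs
    equal noise_cv * true mean.  With noise_cv = 0 the full pipeline recovers
    the true kappas, rho and Gamma to numerical precision.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    kappas = truth.kappas.as_tuple()
    scenarios = {}
    for idx, i in enumerate((1, 2, 3, 4)):
        bound_true = float(bound_times[idx])
        search_true = bound_true / kappas[idx]
        if not (bound_true > 0 and search_true > 0):
            raise ValueError("derived residence times must be positive")

        def noisy_mean(true: float) -> float:
            if noise_cv == 0:
                return true
            reps = rng.normal(true, noise_cv * true, size=n_samples)
            while (reps <= 0).any():
                bad = reps <= 0
                reps[bad] = rng.normal(true, noise_cv * true, size=int(bad.sum()))
            return float(reps.mean())

        scenarios[i] = ScenarioTimes(
            search_mean=noisy_mean(search_true),
            search_sd=noise_cv * search_true,
            bound_mean=noisy_mean(bound_true),
            bound_sd=noise_cv * bound_true,
            n_samples=n_samples,
        )
    return ResidenceTimeTable(scenarios)


# ---------------------------------------------------------------------------
# continuous-time Markov-chain simulation
# ---------------------------------------------------------------------------


def _jump_structure(graph: RateGraph):
    """Per vertex: (targets, total outflux, cumulative jump probabilities)."""
    values = graph.edge_values()
    out: dict = {v: ([], []) for v in graph.vertices}
    for (u, v), a in values.items():
        if a > 0:
            out[u][0].append(v)
            out[u][1].append(a)
    jumps = {}
    for u, (targets, rates) in out.items():
        rates = np.asarray(rates, dtype=float)
        total = float(rates.sum())
        cum = np.cumsum(rates) / total if total > 0 else np.array([])
        jumps[u] = (targets, total, cum)
    return jumps


def simulate_trajectory(
    graph: RateGraph, duration: float, seed: int = 0, start=None
) -> Trajectory:
    """Gillespie simulation: exponential dwells, label-proportional jumps."""
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    jumps = _jump_structure(graph)
    state = graph.vertices[0] if start is None else start
    t = 0.0
    states: list = []
    dwells: list[float] = []
    while t < duration:
        targets, total, cum = jumps[state]
        if total == 0:
            dwell = duration - t  # absorbing under the zero-label pattern
        else:
            dwell = rng.exponential(1.0 / total)
        dwell = min(dwell, duration - t)
        states.append(state)
        dwells.append(dwell)
        t += dwell
        if t >= duration or total == 0:
            break
        state = targets[int(np.searchsorted(cum, rng.random()))]
    return Trajectory(states=states, dwell_times=np.array(dwells), duration=duration)


def occupancy_fractions(traj: Trajectory) -> dict:
    """Fraction of time spent in each microstate."""
    occ: dict = {}
    for s, d in zip(traj.states, traj.dwell_times):
        occ[s] = occ.get(s, 0.0) + d
    total = sum(occ.values())
    return {s: d / total for s, d in occ.items()}


def first_passage_routes(
    graph: RateGraph, n_trials: int, seed: int = 0, start="e", target="so"
) -> tuple[int, int]:
    """Count first-passage routes start -> target via 's' vs via 'o'.

    Uses the embedded jump chain (dwell times are irrelevant to route choice).
    Returns (n_via_s, n_via_o), the stochastic oracle for the binding-order
    asymmetry formula.
    """
    rng = np.random.default_rng(seed)
    jumps = _jump_structure(graph)
    via_s = via_o = 0
    for _ in range(n_trials):
        state = start
        last_intermediate = None
        while state != target:
            targets, _, cum = jumps[state]
            state = targets[int(np.searchsorted(cum, rng.random()))]
            if state in ("s", "o"):
                last_intermediate = state
        if last_intermediate == "s":
            via_s += 1
        else:
            via_o += 1
    return via_s, via_o


def net_edge_winding(traj: Trajectory, source, target) -> tuple[int, int]:
    """Counts of source->target and target->source transitions along a path.

    Their difference measures the net probability current through the edge; at
    detailed balance it is zero in expectation, while a non-equilibrium cycle
    drives a systematic circulation.
    """
    fwd = rev = 0
    for u, v in zip(traj.states[:-1], traj.states[1:]):
        if (u, v) == (source, target):
            fwd += 1
        elif (u, v) == (target, source):
            rev += 1
    return fwd, rev
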