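"""Scenario bound-fractions, the statistic rho, and the reciprocity Gamma.

Four experimental scenarios drive the analysis: scenario 1 measures Sox2 with
Oct4 absent, scenario 4 with Oct4 induced; scenarios 2 and 3 measure Oct4
with Sox2 absent/induced.  With P_i the fraction of the measured TF's
specific sites bound in scenario i,

    rho   = kappa1 kappa3 / (kappa2 kappa4)
    Gamma = (P4/P1 - 1)(P3/P2 - 1)

The unknown alpha ratios cancel in P4/P1 and P3/P2, so Gamma is computable
directly from the measured kappas.  At thermodynamic equilibrium the
single-locus model forces both ratios to the same side of 1 (the sign is set
by the cooperativity omega), hence Gamma > 0; a negative Gamma therefore
requires either energy expenditure (broken detailed balance) or genomic
diversity with mixed cooperativities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bridge import AlphaRatios, KappaSet
from .graph import EquilibriumLocusParams, steady_state
from .locus import RateTable, build_pair_graph

__all__ = [
    "ScenarioSpec",
    "ReciprocityResult",
    "SurfaceGrid",
    "single_locus_fraction",
    "kappa_ratio_pair",
    "rho",
    "gamma_from_kappas",
    "gamma_from_fractions",
    "scenario_fractions",
    "gamma_surface",
    "truncate_toward_zero",
    "default_grid",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One experimental scenario: which cell line, and the induction state."""

    cell_line: str  # "sox2_measured" or "oct4_measured"
    induced: bool
    induced_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_line not in ("sox2_measured", "oct4_measured"):
            raise ValueError(f"unknown cell line {self.cell_line!r}")
        if self.induced and not self.induced_concentration > 0:
            raise ValueError("induced scenario needs a positive induced concentration")
        if not self.induced and self.induced_concentration != 0:
            raise ValueError("non-induced scenario must have induced_concentration 0")


@dataclass(frozen=True)
class ReciprocityResult:
    """P1..P4, their ratios, Gamma, and (when kappas are known) rho."""

    P1: float
    P2: float
    P3: float
    P4: float
    ratio_S: float
    ratio_O: float
    gamma: float
    rho: float | None = None


def _result_from_fractions(
    P1: float, P2: float, P3: float, P4: float, rho_value: float | None = None
) -> ReciprocityResult:
    ratio_S = P4 / P1
    ratio_O = P3 / P2
    return ReciprocityResult(
        P1=P1,
        P2=P2,
        P3=P3,
        P4=P4,
        ratio_S=ratio_S,
        ratio_O=ratio_O,
        gamma=(ratio_S - 1.0) * (ratio_O - 1.0),
        rho=rho_value,
    )


@dataclass
class SurfaceGrid:
    """Gamma evaluated over a grid of induced concentrations.

    ``gamma[i, j]`` corresponds to sox2i[i], oct4i[j].
    """

    sox2i: np.ndarray
    oct4i: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.sox2i = np.asarray(self.sox2i, dtype=float)
        self.oct4i = np.asarray(self.oct4i, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (self.sox2i.size, self.oct4i.size):
            raise ValueError("gamma matrix shape does not match the axes")
        if not np.isfinite(self.gamma).all():
            raise ValueError("Gamma must be finite at every grid point")

    def min(self) -> float:
        return float(self.gamma.min())

    def max(self) -> float:
        return float(self.gamma.max())

    def argmin(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmin(self.gamma), self.gamma.shape)
        return float(self.sox2i[i]), float(self.oct4i[j])

    def min_on_boundary(self) -> bool:
        """True if the grid minimum sits on the edge of the grid."""
        i, j = np.unravel_index(np.argmin(self.gamma), self.gamma.shape)
        return i in (0, self.sox2i.size - 1) or j in (0, self.oct4i.size - 1)

    def to_dataframe(self) -> pd.DataFrame:
        s, o = np.meshgrid(self.sox2i, self.oct4i, indexing="ij")
        return pd.DataFrame(
            {"sox2i": s.ravel(), "oct4i": o.ravel(), "gamma": self.gamma.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def default_grid(
    low: float = 0.01, high: float = 100.0, n: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced default axes for the induced concentrations."""
    axis = np.logspace(math.log10(low), math.log10(high), n)
    return axis, axis.copy()


# ---------------------------------------------------------------------------
# closed forms at equilibrium
# ---------------------------------------------------------------------------


def single_locus_fraction(K_meas: float, K_other: float, omega: float) -> float:
    """Equilibrium bound fraction of the measured TF at a single locus.

    B/(A+B) with A = 1 + K_other and B = K_meas (1 + omega K_other); K_other
    may be 0 (the non-induced scenarios), reducing to K_meas/(1+K_meas).
    """
    if not K_meas > 0:
        raise ValueError("K_meas must be strictly positive")
    if K_other < 0:
        raise ValueError("K_other must be nonnegative")
    if not omega > 0:
        raise ValueError("omega must be strictly positive")
    A = 1.0 + K_other
    B = K_meas * (1.0 + omega * K_other)
    return B / (A + B)


def kappa_ratio_pair(
    params: EquilibriumLocusParams, alphas: AlphaRatios
) -> tuple[float, float]:
    """(kappa4/kappa1, kappa3/kappa2) at equilibrium.

    kappa4/kappa1 = [1 + w K_O^i + K_S (1 + w K_O^i)(1-a_S)]
                  / [1 + K_O^i + K_S (1 + w K_O^i)(1-a_S)],
    and symmetrically for kappa3/kappa2 with S and O exchanged.  Numerator and
    denominator differ only in the omega factor on the induced K, so both
    ratios sit on the same side of 1 as omega does.
    """
    if params.K_O_i is None or params.K_S_i is None:
        raise ValueError("induced K_S_i and K_O_i are required for the kappa ratios")
    w = params.omega

    def one_ratio(K_meas: float, K_other_i: float, alpha: float) -> float:
        common = K_meas * (1.0 + w * K_other_i) * (1.0 - alpha)
        den = 1.0 + K_other_i + common
        if den <= 0:
            raise ValueError(
                f"alpha = {alpha} is outside the valid range for these parameters"
            )
        return (1.0 + w * K_other_i + common) / den

    return (
        one_ratio(params.K_S, params.K_O_i, alphas.alpha_S),
        one_ratio(params.K_O, params.K_S_i, alphas.alpha_O),
    )


# ---------------------------------------------------------------------------
# statistics from measured kappas
# ---------------------------------------------------------------------------


def rho(kappas: KappaSet) -> float:
    """rho = kappa1 kappa3 / (kappa2 kappa4)."""
    k1, k2, k3, k4 = kappas.as_tuple()
    return (k1 * k3) / (k2 * k4)


def gamma_from_kappas(kappas: KappaSet) -> float:
    """Gamma in kappa form, with the alpha ratios cancelled:

    [k4 (1+k1) / (k1 (1+k4)) - 1] * [k3 (1+k2) / (k2 (1+k3)) - 1].
    """
    k1, k2, k3, k4 = kappas.as_tuple()
    f1 = k4 * (1.0 + k1) / (k1 * (1.0 + k4)) - 1.0
    f2 = k3 * (1.0 + k2) / (k2 * (1.0 + k3)) - 1.0
    return f1 * f2


def gamma_from_fractions(P1: float, P2: float, P3: float, P4: float) -> float:
    """Gamma = (P4/P1 - 1)(P3/P2 - 1) from bound fractions directly."""
    for name, P in (("P1", P1), ("P2", P2), ("P3", P3), ("P4", P4)):
        if not (0 < P <= 1):
            raise ValueError(f"{name} must lie in (0, 1], got {P}")
    return (P4 / P1 - 1.0) * (P3 / P2 - 1.0)


def kappa_result(kappas: KappaSet) -> ReciprocityResult:
    """Bundle the kappa-form ratios, Gamma and rho into a ReciprocityResult.

    The P-ratios are reported through their alpha-free kappa forms; individual
    P_i require alpha and are reported as the alpha=1 values (P-ratio
    invariant under the choice).
    """
    k1, k2, k3, k4 = kappas.as_tuple()
    P = [k / (1.0 + k) for k in (k1, k2, k3, k4)]
    return _result_from_fractions(P[0], P[1], P[2], P[3], rho_value=rho(kappas))


# ---------------------------------------------------------------------------
# scenario fractions via Matrix-Tree steady states
# ---------------------------------------------------------------------------


def _bound_fraction(table: RateTable, tf: str) -> float:
    """Steady-state bound fraction of ``tf`` ('S' or 'O') for a rate table."""
    ss = steady_state(build_pair_graph(table))
    if tf == "S":
        return ss["s"] + ss["so"]
    if tf == "O":
        return ss["o"] + ss["so"]
    raise ValueError(f"unknown TF {tf!r}")


def scenario_fractions(
    sox2_line: RateTable,
    oct4_line: RateTable,
    sox2_induced_conc: float,
    oct4_induced_conc: float,
) -> tuple[float, float, float, float]:
    """(P1, P2, P3, P4) from Matrix-Tree steady states of the four scenarios.

    The Sox2-measured cell line keeps its constitutive [S]; Oct4 is absent
    (P1) or at the induced concentration (P4).  Symmetrically for the
    Oct4-measured line (P2, P3).  Valid at and away from equilibrium.
    """
    if sox2_induced_conc < 0 or oct4_induced_conc < 0:
        raise ValueError("induced concentrations must be nonnegative")
    P1 = _bound_fraction(sox2_line.with_concentrations(conc_O=0.0), "S")
    P4 = _bound_fraction(sox2_line.with_concentrations(conc_O=oct4_induced_conc), "S")
    P2 = _bound_fraction(oct4_line.with_concentrations(conc_S=0.0), "O")
    P3 = _bound_fraction(oct4_line.with_concentrations(conc_S=sox2_induced_conc), "O")
    return P1, P2, P3, P4


def gamma_surface(
    model: RateTable | tuple[RateTable, RateTable],
    sox2i_axis=None,
    oct4i_axis=None,
) -> SurfaceGrid:
    """Gamma over a grid of induced concentrations for a single-locus model.

    ``model`` is one rate table used for both cell lines, or a (sox2_line,
    oct4_line) pair.  P1 and P2 do not depend on the induced concentrations,
    P4 only on [Oct4i] and P3 only on [Sox2i], so the grid costs one steady
    state per axis value rather than per grid point.
    """
    if sox2i_axis is None or oct4i_axis is None:
        default_s, default_o = default_grid()
        sox2i_axis = default_s if sox2i_axis is None else np.asarray(sox2i_axis, float)
        oct4i_axis = default_o if oct4i_axis is None else np.asarray(oct4i_axis, float)
    sox2i_axis = np.asarray(sox2i_axis, dtype=float)
    oct4i_axis = np.asarray(oct4i_axis, dtype=float)
    if (sox2i_axis <= 0).any() or (oct4i_axis <= 0).any():
        raise ValueError("grid axes must be strictly positive")
    if isinstance(model, RateTable):
        sox2_line, oct4_line = model, model
    else:
        sox2_line, oct4_line = model

    P1 = _bound_fraction(sox2_line.with_concentrations(conc_O=0.0), "S")
    P2 = _bound_fraction(oct4_line.with_concentrations(conc_S=0.0), "O")
    P4 = np.array(
        [
            _bound_fraction(sox2_line.with_concentrations(conc_O=o), "S")
            for o in oct4i_axis
        ]
    )
    P3 = np.array(
        [
            _bound_fraction(oct4_line.with_concentrations(conc_S=s), "O")
            for s in sox2i_axis
        ]
    )
    gamma = np.outer(P3 / P2 - 1.0, P4 / P1 - 1.0)
    return SurfaceGrid(sox2i=sox2i_axis, oct4i=oct4i_axis, gamma=gamma)


def truncate_toward_zero(x: float, decimals: int = 2) -> float:
    """Truncate toward zero at ``decimals`` places (e.g. -0.2259 -> -0.22).

    Published two-decimal summaries of Gamma are consistent with truncation
    rather than rounding, so both conventions are offered.
    """
    factor = 10**decimals
    return math.trunc(x * factor) / factor
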