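"""The four-state two-TF locus: rate tables, cooperativities, R and binding order.

A single DNA locus with one Sox2 site and one Oct4 site has microstates
e (empty), s (Sox2 bound), o (Oct4 bound) and so (both bound), connected in a
cycle by binding/unbinding transitions:

    e -> s : k1_on [S]     s -> e : k1_off
    e -> o : k2_on [O]     o -> e : k2_off
    s -> so: k3_on [O]     so -> s: k3_off
    o -> so: k4_on [S]     so -> o: k4_off

The cycle statistic R (clockwise over anticlockwise label product, with the
concentrations cancelling) is 1 if and only if the locus can sit at
thermodynamic equilibrium; it does not measure binding order.  Binding-order
asymmetry is a separate, kinetic quantity computed from the embedded jump
chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .graph import Edge, EquilibriumLocusParams, RateGraph

__all__ = [
    "RateTable",
    "CooperativityPair",
    "build_pair_graph",
    "cooperativities",
    "cycle_R",
    "binding_order_ratio",
    "equilibrium_params_from_table",
]

_RATE_FIELDS = (
    "k1_on",
    "k2_on",
    "k3_on",
    "k4_on",
    "k1_off",
    "k2_off",
    "k3_off",
    "k4_off",
)


@dataclass(frozen=True)
class RateTable:
    """The eight rate constants of a two-TF locus plus the TF concentrations.

    On-rates have dimensions 1/(concentration x time), off-rates 1/time, and
    concentrations are in arbitrary (but consistent) concentration units.
    """

    k1_on: float
    k2_on: float
    k3_on: float
    k4_on: float
    k1_off: float
    k2_off: float
    k3_off: float
    k4_off: float
    conc_S: float = 1.0
    conc_O: float = 1.0

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("conc_S", "conc_O"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    def with_concentrations(
        self, conc_S: float | None = None, conc_O: float | None = None
    ) -> "RateTable":
        kw = {}
        if conc_S is not None:
            kw["conc_S"] = conc_S
        if conc_O is not None:
            kw["conc_O"] = conc_O
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in _RATE_FIELDS + ("conc_S", "conc_O")}

    @classmethod
    def from_dict(cls, d: dict) -> "RateTable":
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path) -> "RateTable":
        """Read a flat JSON or YAML rate-table file (ten named fields)."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path) -> None:
        p = Path(path)
        if str(path).endswith((".yaml", ".yml")):
            p.write_text(yaml.safe_dump(self.to_dict()))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=1))


@dataclass(frozen=True)
class CooperativityPair:
    """omega_SO (Oct4's effect on Sox2 binding) and omega_OS (the converse).

    The two agree exactly when the rate table satisfies the cycle condition;
    their common value is then the cooperativity omega.
    """

    omega_SO: float
    omega_OS: float


def build_pair_graph(table: RateTable) -> RateGraph:
    """Linear-framework graph of the locus with the standard edge labeling.

    Binding edges carry (on_rate, species) so that concentrations can be
    changed without rebuilding; with a concentration of 0 the corresponding
    transitions vanish and the steady state is supported on the reachable
    microstates (e.g. [O]=0 reduces the locus to {e, s}).
    """
    edges = [
        Edge("e", "s", on_rate=table.k1_on, species="S"),
        Edge("s", "e", rate=table.k1_off),
        Edge("e", "o", on_rate=table.k2_on, species="O"),
        Edge("o", "e", rate=table.k2_off),
        Edge("s", "so", on_rate=table.k3_on, species="O"),
        Edge("so", "s", rate=table.k3_off),
        Edge("o", "so", on_rate=table.k4_on, species="S"),
        Edge("so", "o", rate=table.k4_off),
    ]
    return RateGraph(
        vertices=["e", "s", "o", "so"],
        edges=edges,
        concentrations={"S": table.conc_S, "O": table.conc_O},
    )


def cooperativities(table: RateTable) -> CooperativityPair:
    """Concentration-independent pairwise cooperativities.

    omega_SO compares Sox2's label ratio with Oct4 present vs absent:
    (k4_on [S]/k4_off) / (k1_on [S]/k1_off) = k4_on k1_off / (k4_off k1_on);
    omega_OS symmetrically for Oct4: k3_on k2_off / (k3_off k2_on).
    """
    return CooperativityPair(
        omega_SO=table.k4_on * table.k1_off / (table.k4_off * table.k1_on),
        omega_OS=table.k3_on * table.k2_off / (table.k3_off * table.k2_on),
    )


def cycle_R(table: RateTable) -> float:
    """Cycle statistic R = k1_on k3_on k4_off k2_off / (k3_off k1_off k2_on k4_on).

    The product of the rate constants clockwise around the cycle
    e -> s -> so -> o -> e divided by the anticlockwise product; the
    concentrations cancel.  R equals omega_OS / omega_SO, and R = 1 iff the
    cooperativities are symmetric iff the table admits thermodynamic
    equilibrium.
    """
    return (table.k1_on * table.k3_on * table.k4_off * table.k2_off) / (
        table.k3_off * table.k1_off * table.k2_on * table.k4_on
    )


def binding_order_ratio(table: RateTable) -> float:
    """Steady-state probability ratio of Sox2-first over Oct4-first assembly.

    The probability of reaching so from e through s, over that of reaching so
    through o, computed from the embedded jump chain.  The leading
    concentration factors cancel, leaving

        k1_on k3_on (k2_off + k4_on [S]) / (k2_on k4_on (k1_off + k3_on [O])).

    This is a kinetic quantity: it depends on concentrations and on barrier
    heights, and is unrelated to the thermodynamic statistic R (witness: the
    single off-rate k4_off does not appear).
    """
    num = table.k1_on * table.k3_on * (table.k2_off + table.k4_on * table.conc_S)
    den = table.k2_on * table.k4_on * (table.k1_off + table.k3_on * table.conc_O)
    if den == 0:
        raise ZeroDivisionError("binding-order denominator is zero")
    return num / den


def equilibrium_params_from_table(
    table: RateTable,
    sox2_induced_conc: float | None = None,
    oct4_induced_conc: float | None = None,
    tol: float = 1e-9,
) -> EquilibriumLocusParams:
    """Label-ratio parameterisation, valid only under the cycle condition.

    K_S = k1_on [S] / k1_off and K_O = k2_on [O] / k2_off, with omega the
    common cooperativity.  Induced variants use the supplied induced
    concentrations of the same TF.  Raises if R deviates from 1 by more than
    ``tol``, since the equilibrium prescription is then invalid.
    """
    R = cycle_R(table)
    if abs(R - 1.0) > tol:
        raise ValueError(
            f"cycle condition violated (R={R:.6g}): equilibrium "
            "parameterization is not valid for this rate table"
        )
    K_S = table.k1_on * table.conc_S / table.k1_off
    K_O = table.k2_on * table.conc_O / table.k2_off
    omega = cooperativities(table).omega_SO
    K_S_i = (
        table.k1_on * sox2_induced_conc / table.k1_off
        if sox2_induced_conc is not None
        else None
    )
    K_O_i = (
        table.k2_on * oct4_induced_conc / table.k2_off
        if oct4_induced_conc is not None
        else None
    )
    return EquilibriumLocusParams(K_S=K_S, K_O=K_O, omega=omega, K_S_i=K_S_i, K_O_i=K_O_i)
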