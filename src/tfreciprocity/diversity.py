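"""Genomic diversity: two locus types, product graphs, and mixture reciprocity.

Sox2 and Oct4 bind genome-wide at loci with differing strengths and
cooperativities.  The genomic-diversity model keeps two locus types, in
proportions l and 1-l, each following the single-locus model.  Loci are
assumed independent, so the joint graph is a product graph whose steady state
factorizes, and the bound-site count (an additive occupancy function) averages
additively.  The genome-wide bound fraction is therefore the mixture

    P_i = l P_{i,1} + (1 - l) P_{i,2},

never requiring the 4^N-state product graph; the product-graph machinery here
exists to validate that shortcut.  At equilibrium with both omegas on the
same side of 1 the mixture reciprocity stays positive; mixed cooperativities
(or broken detailed balance at either type) can drive it negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph import Edge, EquilibriumLocusParams, RateGraph, SteadyState
from .locus import RateTable
from .reciprocity import (
    ReciprocityResult,
    SurfaceGrid,
    _bound_fraction,
    _result_from_fractions,
    default_grid,
    single_locus_fraction,
)

__all__ = [
    "GenomeMixture",
    "product_graph",
    "average_occupancy",
    "mixture_fraction",
    "equilibrium_type_fractions",
    "diversity_fractions",
    "diversity_gamma",
    "diversity_surface",
]


@dataclass(frozen=True)
class GenomeMixture:
    """Two locus types in proportions l and 1-l, sharing the TF concentrations."""

    type1: RateTable
    type2: RateTable
    l: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.l <= 1.0):
            raise ValueError(f"l must lie in [0, 1], got {self.l}")

    def to_dict(self) -> dict:
        return {"l": self.l, "type1": self.type1.to_dict(), "type2": self.type2.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeMixture":
        return cls(
            type1=RateTable.from_dict(d["type1"]),
            type2=RateTable.from_dict(d["type2"]),
            l=float(d["l"]),
        )

    @classmethod
    def from_json(cls, path) -> "GenomeMixture":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def product_graph(g1: RateGraph, g2: RateGraph) -> RateGraph:
    """Graph of two independent systems considered jointly.

    Vertices are ordered pairs; every edge of one factor is replicated across
    every vertex of the other with its (numeric) label.  The steady state
    factorizes, Pr(i, j) = Pr_1(i) Pr_2(j), whether or not either factor
    satisfies detailed balance.
    """
    vertices = [(i, j) for i in g1.vertices for j in g2.vertices]
    edges: list[Edge] = []
    for e in g1.edges:
        a = e.value(g1.concentrations)
        for j in g2.vertices:
            edges.append(Edge((e.source, j), (e.target, j), rate=a))
    for e in g2.edges:
        b = e.value(g2.concentrations)
        for i in g1.vertices:
            edges.append(Edge((i, e.source), (i, e.target), rate=b))
    return RateGraph(vertices=vertices, edges=edges)


def average_occupancy(state: SteadyState, eta: dict) -> float:
    """<eta> = sum_i eta(i) Pr(i); for a single locus, the TF's bound fraction.

    ``eta`` maps each vertex to the number of measured-TF-specific sites bound
    in that microstate; it must be defined on every vertex.  On a product
    graph an additive eta gives <eta>_{G1xG2} = <eta>_{G1} + <eta>_{G2}.
    """
    missing = [v for v in state.probabilities if v not in eta]
    if missing:
        raise ValueError(f"occupancy function undefined on vertices {missing}")
    return sum(eta[v] * p for v, p in state.probabilities.items())


def mixture_fraction(l: float, f1: float, f2: float) -> float:
    """Genome-wide bound fraction l f1 + (1-l) f2."""
    if not (0.0 <= l <= 1.0):
        raise ValueError(f"l must lie in [0, 1], got {l}")
    for name, f in (("f1", f1), ("f2", f2)):
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    return l * f1 + (1.0 - l) * f2


def equilibrium_type_fractions(
    params: EquilibriumLocusParams,
) -> tuple[float, float, float, float]:
    """Closed-form (P1, P2, P3, P4) for one locus type at equilibrium.

    P1 = K_S/(1+K_S), P2 = K_O/(1+K_O),
    P3 = K_O (1 + w K_S^i) / (1 + K_S^i + K_O (1 + w K_S^i)),
    P4 = K_S (1 + w K_O^i) / (1 + K_O^i + K_S (1 + w K_O^i)).
    With omega > 1, P4 > P1 and P3 > P2; with omega < 1, both reversed.
    """
    if params.K_S_i is None or params.K_O_i is None:
        raise ValueError("induced K_S_i and K_O_i are required")
    P1 = params.K_S / (1.0 + params.K_S)
    P2 = params.K_O / (1.0 + params.K_O)
    P3 = single_locus_fraction(params.K_O, params.K_S_i, params.omega)
    P4 = single_locus_fraction(params.K_S, params.K_O_i, params.omega)
    return P1, P2, P3, P4


def _type_fractions(
    table: RateTable, sox2_induced_conc: float, oct4_induced_conc: float
) -> tuple[float, float, float, float]:
    """Per-type (P1..P4) via Matrix-Tree steady states (general, any regime)."""
    P1 = _bound_fraction(table.with_concentrations(conc_O=0.0), "S")
    P4 = _bound_fraction(table.with_concentrations(conc_O=oct4_induced_conc), "S")
    P2 = _bound_fraction(table.with_concentrations(conc_S=0.0), "O")
    P3 = _bound_fraction(table.with_concentrations(conc_S=sox2_induced_conc), "O")
    return P1, P2, P3, P4


def diversity_fractions(
    mixture: GenomeMixture, sox2_induced_conc: float, oct4_induced_conc: float
) -> tuple[float, float, float, float]:
    """Genome-wide (P1, P2, P3, P4) for the mixture."""
    f1 = _type_fractions(mixture.type1, sox2_induced_conc, oct4_induced_conc)
    f2 = _type_fractions(mixture.type2, sox2_induced_conc, oct4_induced_conc)
    return tuple(
        mixture_fraction(mixture.l, a, b) for a, b in zip(f1, f2)
    )  # type: ignore[return-value]


def diversity_gamma(
    mixture: GenomeMixture, sox2_induced_conc: float, oct4_induced_conc: float
) -> ReciprocityResult:
    """Mixture P_i and the resulting reciprocity Gamma."""
    P1, P2, P3, P4 = diversity_fractions(mixture, sox2_induced_conc, oct4_induced_conc)
    return _result_from_fractions(P1, P2, P3, P4)


def diversity_surface(
    mixture: GenomeMixture, sox2i_axis=None, oct4i_axis=None
) -> SurfaceGrid:
    """Gamma for the mixture over a grid of induced concentrations.

    Per type, P1/P2 are grid-independent and P4/P3 depend on one axis each,
    so the cost is linear in the axis lengths.
    """
    if sox2i_axis is None or oct4i_axis is None:
        ds, do = default_grid()
        sox2i_axis = ds if sox2i_axis is None else np.asarray(sox2i_axis, float)
        oct4i_axis = do if oct4i_axis is None else np.asarray(oct4i_axis, float)
    sox2i_axis = np.asarray(sox2i_axis, dtype=float)
    oct4i_axis = np.asarray(oct4i_axis, dtype=float)
    if (sox2i_axis <= 0).any() or (oct4i_axis <= 0).any():
        raise ValueError("grid axes must be strictly positive")

    l = mixture.l
    parts = {}
    for name, table in (("1", mixture.type1), ("2", mixture.type2)):
        parts[name] = {
            "P1": _bound_fraction(table.with_concentrations(conc_O=0.0), "S"),
            "P2": _bound_fraction(table.with_concentrations(conc_S=0.0), "O"),
            "P4": np.array(
                [
                    _bound_fraction(table.with_concentrations(conc_O=o), "S")
                    for o in oct4i_axis
                ]
            ),
            "P3": np.array(
                [
                    _bound_fraction(table.with_concentrations(conc_S=s), "O")
                    for s in sox2i_axis
                ]
            ),
        }

    def mix(key):
        return l * parts["1"][key] + (1.0 - l) * parts["2"][key]

    P1, P2, P3, P4 = mix("P1"), mix("P2"), mix("P3"), mix("P4")
    gamma = np.outer(P3 / P2 - 1.0, P4 / P1 - 1.0)
    return SurfaceGrid(sox2i=sox2i_axis, oct4i=oct4i_axis, gamma=gamma)
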