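"""Linear-framework graphs and their steady states.

A biochemical system at single-molecule resolution is described by a labeled
directed graph: vertices are microstates (e.g. which transcription factors are
bound at a DNA locus), edges are stochastic transitions, and edge labels are
transition rates with dimensions of 1/time.  A binding label is the product of
an on-rate (1/(concentration x time)) and a free concentration; an unbinding
label is a plain off-rate.

The stationary distribution of the associated Markov process exists whether or
not the system satisfies detailed balance.  By the Matrix-Tree theorem the
probability of microstate j is proportional to zeta_j, the sum over spanning
trees rooted at j of the product of the tree's edge labels.  The sum of the
zeta_j plays the role of a (generally non-equilibrium) partition function.  At
thermodynamic equilibrium this prescription reduces to multiplying label ratios
along any path from a reference microstate, and every cycle of reversible
edges has label-product ratio 1 (the cycle condition / detailed balance).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Edge",
    "RateGraph",
    "SteadyState",
    "EquilibriumLocusParams",
    "enumerate_rooted_spanning_trees",
    "zeta",
    "steady_state",
    "cycle_ratio",
    "is_detailed_balanced",
    "equilibrium_probabilities",
    "free_energy_delta",
]


@dataclass(frozen=True)
class Edge:
    """A directed transition with either a plain rate or on_rate x [species].

    Exactly one of ``rate`` or (``on_rate``, ``species``) must be given.  The
    distinction matters because single-molecule data give access to binding
    labels (rates) but not to on-rates, for which the concentration must be
    known separately.
    """

    source: object
    target: object
    rate: float | None = None
    on_rate: float | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if self.rate is not None:
            if self.on_rate is not None or self.species is not None:
                raise ValueError("give either rate or (on_rate, species), not both")
            if self.rate < 0:
                raise ValueError(f"negative rate on edge {self.source}->{self.target}")
        else:
            if self.on_rate is None or self.species is None:
                raise ValueError("edge needs either rate or (on_rate, species)")
            if self.on_rate < 0:
                raise ValueError(
                    f"negative on_rate on edge {self.source}->{self.target}"
                )

    def value(self, concentrations: dict[str, float]) -> float:
        """Numeric label; requires the concentration map for on_rate edges."""
        if self.rate is not None:
            return self.rate
        if self.species not in concentrations:
            raise KeyError(
                f"edge {self.source}->{self.target} needs concentration "
                f"of {self.species!r}"
            )
        conc = concentrations[self.species]
        if conc < 0:
            raise ValueError(f"negative concentration for {self.species!r}")
        return self.on_rate * conc


@dataclass
class RateGraph:
    """Labeled directed graph of microstates.

    Every edge must have a reverse edge (all systems considered can in
    principle reach equilibrium, so graphs are reversible), though a label may
    evaluate to 0 when its concentration factor is 0 — such edges are treated
    as absent transitions.
    """

    vertices: list
    edges: list[Edge]
    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("duplicate vertices")
        vset = set(self.vertices)
        pairs = set()
        for e in self.edges:
            if e.source not in vset or e.target not in vset:
                raise ValueError(f"edge {e.source}->{e.target} uses unknown vertex")
            if e.source == e.target:
                raise ValueError("self-loops are not allowed")
            if (e.source, e.target) in pairs:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            pairs.add((e.source, e.target))
        for u, v in pairs:
            if (v, u) not in pairs:
                raise ValueError(f"edge {u}->{v} has no reverse edge (irreversible)")

    # -- basic accessors -------------------------------------------------

    def edge_values(self) -> dict[tuple, float]:
        """Map (source, target) -> numeric label."""
        return {(e.source, e.target): e.value(self.concentrations) for e in self.edges}

    def label(self, source, target) -> float:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e.value(self.concentrations)
        raise KeyError(f"no edge {source}->{target}")

    def with_concentrations(self, **concentrations: float) -> "RateGraph":
        merged = {**self.concentrations, **concentrations}
        return replace(self, concentrations=merged)

    def laplacian(self) -> np.ndarray:
        """Column-based generator: L[i,j] = rate j->i (i != j), columns sum to 0.

        d/dt p = L p, so the steady state spans the null space of L.
        """
        n = len(self.vertices)
        idx = {v: k for k, v in enumerate(self.vertices)}
        L = np.zeros((n, n))
        for (u, v), a in self.edge_values().items():
            L[idx[v], idx[u]] += a
            L[idx[u], idx[u]] -= a
        return L

    # -- (de)serialisation -----------------------------------------------

    def to_dict(self) -> dict:
        edges = []
        for e in self.edges:
            if e.rate is not None:
                edges.append({"from": e.source, "to": e.target, "rate": e.rate})
            else:
                edges.append(
                    {
                        "from": e.source,
                        "to": e.target,
                        "on_rate": e.on_rate,
                        "species": e.species,
                    }
                )
        return {
            "vertices": list(self.vertices),
            "edges": edges,
            "concentrations": dict(self.concentrations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateGraph":
        edges = []
        for e in d["edges"]:
            if "rate" in e:
                edges.append(Edge(e["from"], e["to"], rate=e["rate"]))
            else:
                edges.append(
                    Edge(e["from"], e["to"], on_rate=e["on_rate"], species=e["species"])
                )
        return cls(list(d["vertices"]), edges, dict(d.get("concentrations", {})))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RateGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SteadyState:
    """Stationary microstate probabilities with their spanning-tree weights."""

    probabilities: dict
    zetas: dict

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-12):
            raise ValueError(f"probabilities sum to {total}, not 1")

    def __getitem__(self, vertex) -> float:
        return self.probabilities[vertex]


@dataclass(frozen=True)
class EquilibriumLocusParams:
    """Equilibrium description of a two-TF locus by label ratios.

    K quantities are binding-label over unbinding-label (concentration folded
    in, so dimensionless); omega is the concentration-independent pairwise
    cooperativity, symmetric between the TFs at equilibrium.  The induced
    variants K_S_i / K_O_i carry the induced concentration of the same TF.
    """

    K_S: float
    K_O: float
    omega: float
    K_S_i: float | None = None
    K_O_i: float | None = None

    def __post_init__(self) -> None:
        for name in ("K_S", "K_O", "omega"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("K_S_i", "K_O_i"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


# ---------------------------------------------------------------------------
# spanning trees and the Matrix-Tree weight zeta
# ---------------------------------------------------------------------------


def enumerate_rooted_spanning_trees(graph: RateGraph, root) -> list[frozenset]:
    """All spanning trees rooted at ``root``, as frozensets of (source, target).

    A spanning tree rooted at j contains every vertex, has no cycle ignoring
    direction, and j is the unique vertex with no outgoing edge (all edges are
    directed toward the root).  Exhaustive; intended for small graphs and as
    the oracle against which the determinant-based ``zeta`` is validated.
    """
    if root not in graph.vertices:
        raise ValueError(f"unknown root vertex {root!r}")
    out_edges: dict[object, list] = {v: [] for v in graph.vertices}
    for e in graph.edges:
        out_edges[e.source].append((e.source, e.target))
    others = [v for v in graph.vertices if v != root]
    trees = []
    for choice in itertools.product(*(out_edges[v] for v in others)):
        # each non-root vertex has exactly one outgoing edge; valid iff every
        # vertex reaches the root (no cycle among the chosen edges)
        succ = {u: v for (u, v) in choice}
        ok = True
        for v in others:
            seen = set()
            w = v
            while w != root:
                if w in seen:
                    ok = False
                    break
                seen.add(w)
                w = succ[w]
            if not ok:
                break
        if ok:
            trees.append(frozenset(choice))
    return trees


def tree_weight(graph: RateGraph, tree: frozenset) -> float:
    values = graph.edge_values()
    w = 1.0
    for uv in tree:
        w *= values[uv]
    return w


def zeta(graph: RateGraph, vertex) -> float:
    """Spanning-tree weight of ``vertex`` via the all-minors Matrix-Tree theorem.

    zeta_j is the determinant of the (negated) generator with row and column j
    deleted; it equals the sum over spanning trees rooted at j of the product
    of edge labels.  May legitimately be 0 when every rooted tree contains a
    zero-labeled edge (vertex unreachable under the zero-label pattern).
    """
    if vertex not in graph.vertices:
        raise ValueError(f"unknown vertex {vertex!r}")
    n = len(graph.vertices)
    if n == 1:
        return 1.0
    idx = {v: k for k, v in enumerate(graph.vertices)}
    # out-degree Laplacian M = diag(outflux) - A, minor at (j, j)
    M = np.zeros((n, n))
    for (u, v), a in graph.edge_values().items():
        M[idx[u], idx[v]] -= a
        M[idx[u], idx[u]] += a
    j = idx[vertex]
    keep = [k for k in range(n) if k != j]
    val = float(np.linalg.det(M[np.ix_(keep, keep)]))
    # determinants of nonnegative tree sums: clip tiny negative round-off
    return max(val, 0.0)


def steady_state(graph: RateGraph) -> SteadyState:
    """Stationary distribution Pr(j) = zeta_j / sum_i zeta_i.

    Valid at and away from thermodynamic equilibrium.  Raises if every zeta is
    0, i.e. no recurrent microstate is reachable under the zero-label pattern.
    """
    zetas = {v: zeta(graph, v) for v in graph.vertices}
    total = sum(zetas.values())
    if total <= 0:
        raise ValueError("all spanning-tree weights are zero: no steady state")
    probs = {v: z / total for v, z in zetas.items()}
    return SteadyState(probabilities=probs, zetas=zetas)


def steady_state_nullspace(graph: RateGraph) -> dict:
    """Independent oracle: dense null-space solve of the stationary condition.

    Solves L p = 0 with sum(p) = 1 by SVD; used in tests to validate the
    Matrix-Tree route, never as the production path.
    """
    L = graph.laplacian()
    _, _, vt = np.linalg.svd(L)
    p = vt[-1]
    p = p / p.sum()
    if (p < -1e-9).any():
        raise ValueError("null-space vector is not a probability distribution")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    return {v: float(p[k]) for k, v in enumerate(graph.vertices)}


# ---------------------------------------------------------------------------
# cycle condition and detailed balance
# ---------------------------------------------------------------------------


def cycle_ratio(graph: RateGraph, cycle: list) -> float:
    """Forward over reverse label product around a closed walk.

    For binding/unbinding cycles the concentrations cancel, so the ratio is a
    pure function of the rate constants; it equals 1 for every cycle iff the
    graph can be at thermodynamic equilibrium.
    """
    if len(cycle) < 2 or cycle[0] != cycle[-1]:
        raise ValueError("cycle must be a closed vertex sequence (first == last)")
    values = graph.edge_values()
    fwd = 1.0
    rev = 1.0
    for u, v in zip(cycle[:-1], cycle[1:]):
        if (u, v) not in values or (v, u) not in values:
            raise KeyError(f"no reversible edge pair between {u!r} and {v!r}")
        fwd *= values[(u, v)]
        rev *= values[(v, u)]
    if rev == 0:
        raise ZeroDivisionError("reverse product is zero along the cycle")
    return fwd / rev


def is_detailed_balanced(graph: RateGraph, tol: float = 1e-9) -> tuple[bool, float]:
    """Check edgewise flux balance at the steady state.

    Returns (balanced, max relative flux imbalance).  Balanced means, for every
    reversible edge pair i<->j, label(i->j) Pr(i) == label(j->i) Pr(j) within
    relative tolerance ``tol`` — equivalently, every cycle ratio is 1
    (Kolmogorov's criterion).
    """
    ss = steady_state(graph)
    values = graph.edge_values()
    worst = 0.0
    seen = set()
    for (u, v), a in values.items():
        if (v, u) in seen:
            continue
        seen.add((u, v))
        f_fwd = a * ss[u]
        f_rev = values[(v, u)] * ss[v]
        scale = max(f_fwd, f_rev)
        if scale == 0:
            continue
        worst = max(worst, abs(f_fwd - f_rev) / scale)
    return worst <= tol, worst


# ---------------------------------------------------------------------------
# equilibrium closed forms
# ---------------------------------------------------------------------------


def equilibrium_probabilities(params: EquilibriumLocusParams) -> SteadyState:
    """Equilibrium steady state of the four-state locus {e, s, o, so}.

    Uses the path prescription Pr(x) = (product of K's along a path e -> x)
    x Pr(e), valid only under the cycle condition: Pr(s) = K_S Pr(e),
    Pr(o) = K_O^i Pr(e), Pr(so) = omega K_S K_O^i Pr(e).  Identical to the
    Matrix-Tree steady state whenever the underlying rate table satisfies
    R = 1.  The induced K_O_i is used if set, else K_O.
    """
    K_S = params.K_S
    K_O = params.K_O_i if params.K_O_i is not None else params.K_O
    w = params.omega
    weights = {"e": 1.0, "s": K_S, "o": K_O, "so": w * K_S * K_O}
    Z = sum(weights.values())
    probs = {v: x / Z for v, x in weights.items()}
    return SteadyState(probabilities=probs, zetas=weights)


def free_energy_delta(label_ratio: float) -> float:
    """Free-energy difference (units of kB*T) implied by a label ratio.

    At equilibrium the ratio of a binding label to its unbinding label is
    exp(dPhi / kB T), so dPhi = ln(ratio); the individual labels are kinetic
    quantities, but their ratio is thermodynamic.
    """
    if not label_ratio > 0:
        raise ValueError(f"label ratio must be positive, got {label_ratio}")
    return math.log(label_ratio)
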