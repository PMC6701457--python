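"""Structured rate matrices for discrete phenotypic characters.

A morphological character is treated as a continuous-time Markov chain over a
finite set of state labels; its transition-intensity (rate) matrix fully
characterises the character.  Several elementary characters can be merged
("amalgamated") into one character whose state space is the Cartesian product
of the elementary state spaces.  Depending on how the traits interact, the
amalgamated matrix is structured differently:

* independent evolution — the Kronecker sum of the component matrices
  (``SMM-ind``); only one component may change per infinitesimal interval;
* "switch-on" dependency — an anatomically downstream trait (e.g. tail color)
  evolves only while its controller (tail presence) is in a switched-on state
  (``SMM-sw``);
* synchronous change — redundantly coded, mutually exclusive traits change
  simultaneously (``SMM-syn``);
* general correlation — every off-diagonal rate free (``SMM-gen``).

The amalgamated chain is typically observed only partially: several product
states can be indistinguishable to a scorer (a tailless animal shows no tail
color).  The many-to-one observable-symbol -> hidden-state mapping is recorded
in an :class:`ObservationMap`, which is exactly the hidden-Markov-model layer
used by the likelihood machinery.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ElementaryCharacter",
    "RateMatrix",
    "ObservationMap",
    "DependencyEdge",
    "DependencyGraph",
    "StructuralStats",
    "kron_sum_amalgamate",
    "switch_amalgamate",
    "synchronous_amalgamate",
    "general_smm",
    "build_from_dependency_graph",
    "structural_stats",
]

logger = logging.getLogger(__name__)

_ROWSUM_ATOL = 1e-9


class ModelError(ValueError):
    """Invalid model construction input."""


@dataclass(frozen=True)
class ElementaryCharacter:
    """A single trait with an ordered set of state labels.

    ``rates`` optionally carries the character's own intensity matrix; if
    omitted, all state-to-state rates default to 1 (symmetric one-rate
    character), which is the usual starting template.
    """

    name: str
    states: tuple[str, ...]
    rates: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ModelError(f"character {self.name!r} needs at least one state")
        if len(set(self.states)) != len(self.states):
            raise ModelError(f"duplicate state labels in character {self.name!r}")
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if self.rates is not None:
            arr = np.asarray(self.rates, dtype=float)
            if arr.shape != (len(self.states),) * 2:
                raise ModelError(f"rate matrix shape mismatch for {self.name!r}")
            object.__setattr__(self, "rates", tuple(map(tuple, arr)))

    @property
    def rate_matrix(self) -> "RateMatrix":
        k = len(self.states)
        if self.rates is None:
            off = np.ones((k, k))
        else:
            off = np.asarray(self.rates, dtype=float)
        return RateMatrix.from_offdiag(self.states, off)


class RateMatrix:
    """Labeled transition-intensity matrix of a continuous-time Markov chain.

    Off-diagonal entries are nonnegative per-unit-time rates; each diagonal
    entry equals minus the sum of its row's off-diagonal entries so that rows
    sum to zero.
    """

    __slots__ = ("states", "rates")

    def __init__(self, states: Sequence[str], rates: np.ndarray):
        states = tuple(str(s) for s in states)
        rates = np.array(rates, dtype=float)
        if rates.ndim != 2 or rates.shape[0] != rates.shape[1]:
            raise ModelError("rate matrix must be square")
        if len(states) != rates.shape[0]:
            raise ModelError(
                f"{len(states)} labels for a {rates.shape[0]}x{rates.shape[1]} matrix"
            )
        if len(set(states)) != len(states):
            raise ModelError("duplicate state labels")
        if not np.all(np.isfinite(rates)):
            raise ModelError("non-finite rates")
        off = rates.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < -1e-12):
            raise ModelError("negative off-diagonal rate")
        off[off < 0] = 0.0
        scale = max(off.max(initial=0.0), 1.0)
        resid = np.abs(rates.sum(axis=1))
        if np.any(resid > _ROWSUM_ATOL * scale + _ROWSUM_ATOL):
            raise ModelError("rows of a rate matrix must sum to zero")
        np.fill_diagonal(off, -off.sum(axis=1))
        off.flags.writeable = False
        self.states = states
        self.rates = off

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_offdiag(cls, states: Sequence[str], offdiag: np.ndarray) -> "RateMatrix":
        """Build from off-diagonal rates only; the diagonal is derived."""
        q = np.array(offdiag, dtype=float)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return cls(states, q)

    @classmethod
    def binary(
        cls, forward: float, backward: float, states: Sequence[str] = ("0", "1")
    ) -> "RateMatrix":
        """Two-state chain with gain rate ``forward`` and loss rate ``backward``."""
        if len(states) != 2:
            raise ModelError("binary() needs exactly two state labels")
        return cls.from_offdiag(states, [[0.0, forward], [backward, 0.0]])

    # -- basic protocol ---------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}") from None

    def __getitem__(self, key: tuple[str, str]) -> float:
        i, j = key
        return float(self.rates[self.index(i), self.index(j)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RateMatrix)
            and self.states == other.states
            and np.array_equal(self.rates, other.rates)
        )

    def __repr__(self) -> str:
        return f"RateMatrix(states={self.states}, dim={self.n_states})"

    def allclose(self, other: "RateMatrix", atol: float = 1e-12) -> bool:
        return self.states == other.states and np.allclose(
            self.rates, other.rates, atol=atol
        )

    def relabel(self, mapping: Mapping[str, str]) -> "RateMatrix":
        return RateMatrix([mapping.get(s, s) for s in self.states], self.rates)

    def reorder(self, states: Sequence[str]) -> "RateMatrix":
        """Return the same chain with rows/columns permuted into ``states`` order."""
        idx = [self.index(s) for s in states]
        if sorted(idx) != list(range(self.n_states)):
            raise ModelError("reorder() needs a permutation of the state set")
        return RateMatrix(states, self.rates[np.ix_(idx, idx)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rates, index=list(self.states), columns=list(self.states))


@dataclass(frozen=True)
class ObservationMap:
    """Observable symbol -> set of hidden states (the HMM layer).

    A one-to-one map degenerates to a plain Markov model.  ``inapplicable``
    optionally names the observable symbol that an inapplicable score ("-")
    resolves to, e.g. the "no tail" symbol for a tail-color column.
    """

    symbol_sets: tuple[tuple[str, frozenset[str]], ...]
    inapplicable: str | None = None

    @classmethod
    def from_dict(
        cls,
        mapping: Mapping[str, Iterable[str]],
        inapplicable: str | None = None,
    ) -> "ObservationMap":
        items = tuple((str(k), frozenset(map(str, v))) for k, v in mapping.items())
        for sym, hid in items:
            if not hid:
                raise ModelError(f"symbol {sym!r} maps to an empty hidden set")
        if inapplicable is not None and inapplicable not in dict(items):
            raise ModelError(f"inapplicable symbol {inapplicable!r} not in map")
        return cls(items, inapplicable)

    @classmethod
    def identity(cls, states: Sequence[str]) -> "ObservationMap":
        return cls.from_dict({s: {s} for s in states})

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(sym for sym, _ in self.symbol_sets)

    @property
    def hidden_states(self) -> frozenset[str]:
        out: set[str] = set()
        for _, hid in self.symbol_sets:
            out |= hid
        return frozenset(out)

    def __getitem__(self, symbol: str) -> frozenset[str]:
        for sym, hid in self.symbol_sets:
            if sym == symbol:
                return hid
        raise KeyError(f"unknown observable symbol {symbol!r}")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def is_partition(self) -> bool:
        seen: set[str] = set()
        for _, hid in self.symbol_sets:
            if seen & hid:
                return False
            seen |= hid
        return True

    def hidden_to_symbol(self) -> dict[str, str]:
        """Inverse lookup; requires disjoint symbol sets."""
        if not self.is_partition():
            raise ModelError("hidden state shared by two symbols; inverse undefined")
        return {h: sym for sym, hid in self.symbol_sets for h in hid}

    def to_dict(self) -> dict[str, list[str]]:
        return {sym: sorted(hid) for sym, hid in self.symbol_sets}


@dataclass(frozen=True)
class DependencyEdge:
    """controller --(kind)--> dependent.

    ``on_states`` (switch_on): controller states in which the dependent is
    allowed to evolve.  ``exclusive`` (synchronous): bijective pairing of the
    two characters' states giving the jointly admissible combinations.
    """

    controller: str
    dependent: str
    kind: str = "switch_on"
    on_states: frozenset[str] = frozenset()
    exclusive: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("switch_on", "synchronous"):
            raise ModelError(f"unknown edge type {self.kind!r}")
        object.__setattr__(self, "on_states", frozenset(self.on_states))
        if self.kind == "switch_on" and not self.on_states:
            raise ModelError("switch_on edge needs nonempty on_states")


@dataclass
class DependencyGraph:
    """Acyclic graph of elementary characters with typed dependency edges."""

    characters: list[ElementaryCharacter]
    edges: list[DependencyEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.characters]
        if len(set(names)) != len(names):
            raise ModelError("duplicate character names")
        by_name = {c.name: c for c in self.characters}
        g = nx.DiGraph()
        g.add_nodes_from(names)
        sw_targets: set[str] = set()
        for e in self.edges:
            if e.controller not in by_name or e.dependent not in by_name:
                raise ModelError(f"edge references unknown character: {e}")
            if e.kind == "switch_on":
                if not e.on_states <= set(by_name[e.controller].states):
                    raise ModelError(
                        f"on_states {sorted(e.on_states)} not states of {e.controller!r}"
                    )
                if e.dependent in sw_targets:
                    raise ModelError(
                        f"{e.dependent!r} is the dependent of two switch_on edges"
                    )
                sw_targets.add(e.dependent)
            g.add_edge(e.controller, e.dependent)
        if not nx.is_directed_acyclic_graph(g):
            raise ModelError("dependency graph has a cycle")
        self._nx = g

    def character(self, name: str) -> ElementaryCharacter:
        for c in self.characters:
            if c.name == name:
                return c
        raise KeyError(name)

    def topological_order(self) -> list[str]:
        # stable: keep declaration order among independent characters
        declared = [c.name for c in self.characters]
        return list(nx.lexicographical_topological_sort(self._nx, key=declared.index))

    # -- JSON round trip --------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "characters": [
                    {
                        "name": c.name,
                        "states": list(c.states),
                        **({"rates": [list(r) for r in c.rates]} if c.rates else {}),
                    }
                    for c in self.characters
                ],
                "edges": [
                    {
                        "controller": e.controller,
                        "dependent": e.dependent,
                        "type": e.kind,
                        "on_states": sorted(e.on_states),
                        "exclusive": [list(p) for p in e.exclusive],
                    }
                    for e in self.edges
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DependencyGraph":
        obj = json.loads(text)
        chars = [
            ElementaryCharacter(
                c["name"],
                tuple(c["states"]),
                tuple(map(tuple, c["rates"])) if c.get("rates") else None,
            )
            for c in obj["characters"]
        ]
        edges = [
            DependencyEdge(
                e["controller"],
                e["dependent"],
                e.get("type", "switch_on"),
                frozenset(e.get("on_states", ())),
                tuple(tuple(p) for p in e.get("exclusive", ())),
            )
            for e in obj.get("edges", ())
        ]
        return cls(chars, edges)


@dataclass(frozen=True)
class StructuralStats:
    """Closed-form sparsity statistics of an amalgamated matrix.

    For ``n`` amalgamated characters with ``omega`` states each, the fraction
    of structurally nonzero cells is ``[1 + n*(omega-1)] / omega**n`` and the
    rates sit on ``n*(omega-1)`` secondary diagonals.
    """

    n: int
    omega: int
    nonzero_proportion: float
    n_secondary_diagonals: int


# ---------------------------------------------------------------------------
# amalgamation operators
# ---------------------------------------------------------------------------


def _product_labels(groups: Sequence[Sequence[str]], sep: str) -> list[str]:
    return [sep.join(combo) for combo in itertools.product(*groups)]


def kron_sum_amalgamate(
    components: Sequence[RateMatrix], sep: str = ""
) -> RateMatrix:
    """Amalgamate independently evolving characters (SMM-ind).

    The result is the Kronecker sum ``Q1 (+) Q2 (+) ...`` over the Cartesian
    product of the component state spaces, with the first component varying
    slowest.  Off-diagonal cells are nonzero only where exactly one component
    changes state; simultaneous changes get structural zeros.
    """
    components = list(components)
    if not components:
        raise ModelError("need at least one component matrix")
    q = components[0].rates.copy()
    labels: list[list[str]] = [list(components[0].states)]
    for comp in components[1:]:
        q = np.kron(q, np.eye(comp.n_states)) + np.kron(
            np.eye(q.shape[0]), comp.rates
        )
        labels.append(list(comp.states))
    return RateMatrix(_product_labels(labels, sep), q)


def switch_amalgamate(
    controller: RateMatrix,
    dependent: RateMatrix,
    on_states: Iterable[str],
    sep: str = "",
) -> RateMatrix:
    """Amalgamate with a "switch-on" dependency (SMM-sw).

    Identical to the independent amalgamation except that the dependent
    character's transitions are zeroed whenever the controller is not in one
    of ``on_states``; realized as ``kron(T, I) + kron(D, C)`` with ``D`` the
    diagonal 0/1 indicator of ``on_states``.
    """
    on = frozenset(on_states)
    if not on:
        raise ModelError("on_states must be nonempty")
    unknown = on - set(controller.states)
    if unknown:
        raise ModelError(f"on_states not in controller states: {sorted(unknown)}")
    d = np.diag([1.0 if s in on else 0.0 for s in controller.states])
    q = np.kron(controller.rates, np.eye(dependent.n_states)) + np.kron(
        d, dependent.rates
    )
    labels = _product_labels([controller.states, dependent.states], sep)
    return RateMatrix(labels, q)


def synchronous_amalgamate(
    q1: RateMatrix,
    q2: RateMatrix,
    exclusive: Iterable[tuple[str, str]],
    sep: str = "",
) -> RateMatrix:
    """Amalgamate two mutually exclusive characters (SMM-syn).

    ``exclusive`` is a bijective pairing (s1, s2) of the two state sets: the
    jointly admissible product states.  Only simultaneous two-component
    changes receive nonzero rates (taken from ``q1``); product states outside
    the pairing are never visited by the chain and are pruned, which is logged.
    """
    pairs = [(str(a), str(b)) for a, b in exclusive]
    if (
        sorted(a for a, _ in pairs) != sorted(q1.states)
        or sorted(b for _, b in pairs) != sorted(q2.states)
    ):
        raise ModelError("exclusivity pairing must cover both state sets exactly once")
    if q1.n_states != q2.n_states:
        raise ModelError("synchronous amalgamation needs equal dimensions")
    pair_of = dict(pairs)
    kept = [(a, pair_of[a]) for a in q1.states]
    pruned = [
        (a, b)
        for a in q1.states
        for b in q2.states
        if pair_of[a] != b
    ]
    if pruned:
        logger.info(
            "synchronous_amalgamate pruned %d structurally unreachable states: %s",
            len(pruned),
            [sep.join(p) for p in pruned],
        )
    k = len(kept)
    q = np.zeros((k, k))
    for i, (a1, _b1) in enumerate(kept):
        for j, (a2, _b2) in enumerate(kept):
            if i != j:
                q[i, j] = q1[a1, a2]
    labels = [sep.join(p) for p in kept]
    return RateMatrix.from_offdiag(labels, q)


def general_smm(
    states: Sequence[str],
    rates: Mapping[tuple[str, str], float] | np.ndarray,
    tying: Mapping[tuple[str, str], str] | None = None,
) -> RateMatrix:
    """Fully general correlated model (SMM-gen): every off-diagonal cell free.

    ``rates`` is either a cell -> value mapping (missing cells are structural
    zeros), a full array of off-diagonal values, or — when ``tying`` is given —
    a parameter-name -> value mapping applied through the cell -> parameter
    tying map.
    """
    states = tuple(str(s) for s in states)
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    q = np.zeros((k, k))
    if tying is not None:
        for (a, b), pname in tying.items():
            if a == b:
                raise ModelError("tying map may only address off-diagonal cells")
            q[idx[a], idx[b]] = float(rates[pname])  # type: ignore[index]
    elif isinstance(rates, Mapping):
        for (a, b), v in rates.items():
            if a == b:
                raise ModelError("only off-diagonal cells may be set")
            q[idx[a], idx[b]] = float(v)
    else:
        q = np.array(rates, dtype=float)
        if q.shape != (k, k):
            raise ModelError("rate array shape mismatch")
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ModelError("negative rates")
    return RateMatrix.from_offdiag(states, off)


# ---------------------------------------------------------------------------
# dependency-graph builder
# ---------------------------------------------------------------------------


def build_from_dependency_graph(
    graph: DependencyGraph, sep: str = ""
) -> tuple[RateMatrix, ObservationMap]:
    """Amalgamate all characters of a dependency graph into one hidden chain.

    Characters are combined in topological order.  A character may change
    state only while it is *active*: every controller along its switch_on
    chain sits in that edge's ``on_states``.  Synchronous edges are resolved
    first by merging the two characters via :func:`synchronous_amalgamate`.

    The observable symbol of a hidden product state shows each character's
    state except (i) inactive characters — a switched-off trait cannot be
    scored — and (ii) controllers whose single switched-on state is implied by
    a visible active dependent.  For the tail/color chain this yields the
    familiar three observable symbols {a, r, b} over four hidden states.
    """
    order = graph.topological_order()
    sync_edges = [e for e in graph.edges if e.kind == "synchronous"]
    sw_edges = [e for e in graph.edges if e.kind == "switch_on"]

    # Merge synchronous pairs into single pseudo-characters first.
    merged: dict[str, tuple[str, ...]] = {}
    units: list[tuple[str, RateMatrix]] = []
    consumed: set[str] = set()
    for e in sync_edges:
        for nm in (e.controller, e.dependent):
            if any(
                se is not e and nm in (se.controller, se.dependent)
                for se in graph.edges
            ):
                raise ModelError(
                    "synchronous characters may not participate in other edges"
                )
        c1 = graph.character(e.controller)
        c2 = graph.character(e.dependent)
        qm = synchronous_amalgamate(
            c1.rate_matrix, c2.rate_matrix, e.exclusive or
            tuple(zip(c1.states, c2.states)), sep=sep
        )
        units.append((e.controller, qm))
        consumed |= {e.controller, e.dependent}
        merged[e.controller] = qm.states
    for name in order:
        if name in consumed:
            continue
        units.append((name, graph.character(name).rate_matrix))

    unit_names = [nm for nm, _ in units]
    unit_states = [list(q.states) for _, q in units]
    unit_rates = [q.rates for _, q in units]
    sw_by_dep = {e.dependent: e for e in sw_edges}

    combos = list(itertools.product(*unit_states))
    labels = [sep.join(c) for c in combos]
    pos = {nm: i for i, nm in enumerate(unit_names)}

    def active(name: str, combo: tuple[str, ...]) -> bool:
        e = sw_by_dep.get(name)
        while e is not None:
            if combo[pos[e.controller]] not in e.on_states:
                return False
            name = e.controller
            e = sw_by_dep.get(name)
        return True

    n = len(combos)
    combo_index = {c: i for i, c in enumerate(combos)}
    q = np.zeros((n, n))
    for i, ci in enumerate(combos):
        for u, (nm, _) in enumerate(units):
            if not active(nm, ci):
                continue
            si = unit_states[u].index(ci[u])
            for sj, tgt in enumerate(unit_states[u]):
                if sj == si:
                    continue
                cj = list(ci)
                cj[u] = tgt
                j = combo_index[tuple(cj)]
                q[i, j] = unit_rates[u][si, sj]
    matrix = RateMatrix.from_offdiag(labels, q)

    # Observable layer.
    dep_of = {e.controller: e for e in sw_edges}
    symbol_sets: dict[str, set[str]] = {}
    for combo, label in zip(combos, labels):
        shown = []
        for u, nm in enumerate(unit_names):
            if not active(nm, combo):
                continue
            e = dep_of.get(nm)
            if (
                e is not None
                and len(e.on_states) == 1
                and e.dependent not in consumed
                and active(e.dependent, combo)
            ):
                continue  # state implied by the visible dependent
            shown.append(combo[u])
        symbol = sep.join(shown)
        symbol_sets.setdefault(symbol, set()).add(label)
    return matrix, ObservationMap.from_dict(symbol_sets)


def structural_stats(n: int, omega: int) -> StructuralStats:
    """Sparsity of the amalgam of ``n`` independent ``omega``-state characters."""
    if n < 1:
        raise ModelError("n must be >= 1")
    if omega < 2 and n > 1:
        raise ModelError("omega must be >= 2")
    prop = (1 + n * (omega - 1)) / omega**n
    return StructuralStats(n, omega, prop, n * (omega - 1))
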