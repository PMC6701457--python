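"""Simulation of trees and characters under structured Markov models.

Contains the exact continuous-time simulator (exponential waiting times and
embedded jumps along every branch), a pure-birth tree sampler, the packaged
benchmark data sets for the tail-color problem and the tail-armor case, and
the replicated two-scientist experiment in which two independently evolving
binary genes are recoded by two scorers and the plain Markov model is pitted
against a hidden-state model by AIC.

Randomness: one master seed; per-replicate substreams are spawned by counter
so the same seed reproduces every replicate bitwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes_infer import FreeClade, TopologyConstraint
from .hmm_likelihood import (
    CharacterMatrix,
    DiscreteTraitModel,
    MkSMM,
    PhyloTree,
    to_mk,
)
from .smm_core import (
    DependencyEdge,
    DependencyGraph,
    ElementaryCharacter,
    ModelError,
    ObservationMap,
    RateMatrix,
    build_from_dependency_graph,
    kron_sum_amalgamate,
)

__all__ = [
    "SimReplicate",
    "Fixture",
    "sim_tree",
    "sim_character",
    "two_scientist_replicates",
    "fixture",
    "tcp_models",
    "tail_armor_models",
]

logger = logging.getLogger(__name__)


@dataclass
class SimReplicate:
    """One simulated data set: tree, observable matrix, hidden tip states."""

    tree: PhyloTree
    matrix: CharacterMatrix
    hidden: pd.DataFrame
    rates: RateMatrix
    seed: object = None


@dataclass
class Fixture:
    """A packaged benchmark data set with its topology constraint and models."""

    name: str
    tree: PhyloTree | None
    constraint: TopologyConstraint
    matrix: CharacterMatrix
    models: dict[str, dict[str, tuple[MkSMM, ObservationMap]]]
    notes: str = ""
    mirrored_resolutions: tuple = ()
    expected_clades: tuple[frozenset[str], ...] = ()

    def model_assignment(
        self, variant: str
    ) -> dict[str, tuple[MkSMM, ObservationMap]]:
        """Character -> (Mk model, observation map) for a model variant."""
        return self.models[variant]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def sim_tree(n_tips: int, seed=None, height: float = 1.0) -> PhyloTree:
    """Pure-birth (Yule) tree rescaled to the given mean root-to-tip height."""
    if n_tips < 3:
        raise ModelError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    start = [0.0, 0.0, 0.0]  # per-node birth time; node 0 is the root
    children: list[tuple[int, int] | None] = [(1, 2), None, None]
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        a, b = len(start), len(start) + 1
        start.extend([t, t])
        children[node] = (a, b)
        children.extend([None, None])
        active.extend([a, b])
    t_end = t + rng.exponential(1.0 / n_tips)

    # renumber: tips first, in left-to-right traversal order
    tip_ids = []
    stack = [0]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        if children[u] is not None:
            stack.extend(reversed(children[u]))
        else:
            tip_ids.append(u)
    newid = {}
    for i, u in enumerate(tip_ids):
        newid[u] = i
    nxt = len(tip_ids)
    for u in order:
        if children[u] is not None:
            newid[u] = nxt
            nxt += 1
    n_nodes = len(start)
    ch: list[list[int]] = [[] for _ in range(n_nodes)]
    lengths = [0.0] * n_nodes
    for u in range(n_nodes):
        end = start[children[u][0]] if children[u] is not None else t_end
        lengths[newid[u]] = end - start[u]
        if children[u] is not None:
            ch[newid[u]] = [newid[c] for c in children[u]]
    root = newid[0]
    lengths[root] = 0.0
    labels = [f"t{i + 1}" for i in range(len(tip_ids))]
    tree = PhyloTree(labels, ch, lengths, root)
    return tree.rescaled(height)


# ---------------------------------------------------------------------------
# character simulation
# ---------------------------------------------------------------------------


def _simulate_branch(
    state: int, q: np.ndarray, t: float, rng: np.random.Generator
) -> int:
    """Exact CTMC endpoint: exponential waits and embedded-chain jumps."""
    while True:
        out_rate = -q[state, state]
        if out_rate <= 0:
            return state
        wait = rng.exponential(1.0 / out_rate)
        if wait > t:
            return state
        t -= wait
        probs = q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(len(probs), p=probs))


def sim_character(
    tree: PhyloTree,
    q: RateMatrix,
    root: Sequence[float],
    obs_map: ObservationMap | None = None,
    seed=None,
    n_chars: int = 1,
    name: str = "char",
) -> SimReplicate:
    """Simulate ``n_chars`` i.i.d. characters along the tree under ``q``."""
    rng = np.random.default_rng(seed)
    root = np.asarray(root, dtype=float)
    if abs(root.sum() - 1.0) > 1e-8:
        raise ModelError("root vector must sum to 1")
    if obs_map is None:
        obs_map = ObservationMap.identity(q.states)
    hid2sym = obs_map.hidden_to_symbol()
    if root[root > 0].size == 0:
        raise ModelError("root vector has no mass")
    hidden_cols = {}
    obs_cols = {}
    for c in range(n_chars):
        state_at = np.empty(tree.n_nodes, dtype=int)
        state_at[tree.root] = rng.choice(q.n_states, p=root)
        for u in tree.postorder[::-1]:
            for child in tree.children[u]:
                state_at[child] = _simulate_branch(
                    state_at[u], q.rates, tree.lengths[child], rng
                )
        tip_states = [q.states[state_at[i]] for i in range(tree.n_tips)]
        cname = name if n_chars == 1 else f"{name}{c + 1}"
        hidden_cols[cname] = tip_states
        obs_cols[cname] = [hid2sym[s] for s in tip_states]
    hidden = pd.DataFrame(hidden_cols, index=list(tree.tip_labels))
    matrix = CharacterMatrix(pd.DataFrame(obs_cols, index=list(tree.tip_labels)))
    return SimReplicate(tree=tree, matrix=matrix, hidden=hidden, rates=q, seed=seed)


# ---------------------------------------------------------------------------
# the two-scientist experiment
# ---------------------------------------------------------------------------


def _binary(rate_fwd: float, rate_bwd: float, labels=("0", "1")) -> RateMatrix:
    return RateMatrix.binary(rate_fwd, rate_bwd, labels)


_ARD_MM_TYING = {("0", "1"): "r01", ("1", "0"): "r10"}
# SMM-ind amalgam of two all-rates-different binary genes; product labels are
# (gene1 state)(gene2 state) with gene1 varying slowest.
_ARD_HMM_TYING = {
    ("00", "10"): "g1_01",
    ("01", "11"): "g1_01",
    ("10", "00"): "g1_10",
    ("11", "01"): "g1_10",
    ("00", "01"): "g2_01",
    ("10", "11"): "g2_01",
    ("01", "00"): "g2_10",
    ("11", "10"): "g2_10",
}

_HIDDEN4 = ("00", "01", "10", "11")


def _hidden4_template() -> RateMatrix:
    return kron_sum_amalgamate(
        [_binary(1.0, 1.0), _binary(1.0, 1.0)], sep=""
    )


def two_scientist_replicates(
    n_reps: int = 100,
    n_tips: int = 100,
    rate: float = 0.05,
    seed=None,
    n_chars: int = 50,
    height: float | None = None,
    starts: int = 2,
    codings: Sequence[str] = ("color", "shape", "joint", "scientist2"),
) -> pd.DataFrame:
    """Replicated comparison of coding schemes for two independent genes.

    Per replicate, ``n_chars`` i.i.d. draws of two binary genes ("color",
    "shape") with all transition rates equal to ``rate`` evolve on a fresh
    pure-birth tree (unit-birth-rate time scale by default, i.e. height
    ``ln(n_tips)``).  Scientist 1 scores color, shape, and the joint
    four-state character; scientist 2 scores a single binary character — red
    AND triangular versus anything else.  For each two-observable coding a
    plain Markov model and a hidden-state model (four hidden states
    structured as two independent all-rates-different binary genes) are
    fitted by maximum likelihood and compared with
    ``delta_aic = AIC(MM) - AIC(HMM)``; the joint four-state coding is fitted
    as the structured (one-to-one) Markov model.  Mean squared errors of the
    fitted rates against the generating rate are recorded per model.

    Constant codings (likely at very low rates) are flagged per replicate
    and their fits skipped rather than silently performed.
    """
    if n_reps < 1:
        raise ModelError("n_reps must be >= 1")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_reps)
    q_gen = _binary(rate, rate)
    hidden4 = _hidden4_template()
    omaps = {
        "color": ObservationMap.from_dict({"0": {"00", "01"}, "1": {"10", "11"}}),
        "shape": ObservationMap.from_dict({"0": {"00", "10"}, "1": {"01", "11"}}),
        "scientist2": ObservationMap.from_dict(
            {"0": {"00", "01", "10"}, "1": {"11"}}
        ),
    }
    rows = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        tree = sim_tree(
            n_tips, seed=rng, height=np.log(n_tips) if height is None else height
        )
        color = sim_character(
            tree, q_gen, [0.5, 0.5], seed=rng, n_chars=n_chars, name="c"
        ).hidden
        shape = sim_character(
            tree, q_gen, [0.5, 0.5], seed=rng, n_chars=n_chars, name="s"
        ).hidden
        scored = {}
        for i in range(n_chars):
            c = color.iloc[:, i]
            s = shape.iloc[:, i]
            scored.setdefault("color", {})[f"x{i}"] = c
            scored.setdefault("shape", {})[f"x{i}"] = s
            scored.setdefault("joint", {})[f"x{i}"] = c.str.cat(s)
            scored.setdefault("scientist2", {})[f"x{i}"] = pd.Series(
                np.where((c == "1") & (s == "1"), "1", "0"), index=c.index
            )
        row: dict = {"rep": rep}
        fit_seed = int(rng.integers(2**31 - 1))

        def fit_pair(data: CharacterMatrix, omap) -> tuple[float, object, object]:
            """(delta_aic, mm_fit, hmm_fit) for a two-observable coding."""
            mm = DiscreteTraitModel(
                data=data,
                tree=tree,
                template=_binary(1.0, 1.0),
                tying=_ARD_MM_TYING,
            ).fit(starts=starts, seed=fit_seed, compute_se=False, ftol=1e-6)
            hmm = DiscreteTraitModel(
                data=data,
                tree=tree,
                template=hidden4,
                obs_map=omap,
                tying=_ARD_HMM_TYING,
            ).fit(starts=starts, seed=fit_seed, compute_se=False, ftol=1e-6)
            return mm.aic - hmm.aic, mm, hmm

        for nm in codings:
            data = CharacterMatrix(pd.DataFrame(scored[nm]))
            constant = bool(
                all(data.column(i).nunique() == 1 for i in range(data.n_characters))
            )
            row[f"constant_{nm}"] = constant
            if constant:
                continue
            if nm == "joint":
                mm_joint = DiscreteTraitModel(
                    data=data,
                    tree=tree,
                    template=hidden4,
                    tying=_ARD_HMM_TYING,
                ).fit(starts=starts, seed=fit_seed, compute_se=False, ftol=1e-6)
                row["mse_mm_joint"] = float(np.mean((mm_joint.params - rate) ** 2))
                row["joint_converged"] = mm_joint.converged
                continue
            daic, mm_fit, hmm_fit = fit_pair(data, omaps[nm])
            row[f"delta_aic_{'s2' if nm == 'scientist2' else nm}"] = daic
            if nm == "scientist2":
                row["mse_hmm"] = float(np.mean((hmm_fit.params - rate) ** 2))
                row["mse_mm"] = float(np.mean((mm_fit.params - rate) ** 2))
                row["hmm_converged"] = hmm_fit.converged
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# benchmark fixtures
# ---------------------------------------------------------------------------


def _tcp_graph(switch: bool) -> DependencyGraph:
    chars = [
        ElementaryCharacter("tail", ("a", "p")),
        ElementaryCharacter("color", ("r", "b")),
    ]
    edges = [DependencyEdge("tail", "color", "switch_on", frozenset({"p"}))]
    return DependencyGraph(chars, edges if switch else [])


def tcp_models() -> dict[str, tuple[MkSMM, ObservationMap]]:
    """Mk-type tail/color models: independent and switch-on amalgams.

    Both share the observation layer {a -> {ar, ab}, r -> {pr}, b -> {pb}}:
    three observable symbols over four hidden states.
    """
    q_sw, omap = build_from_dependency_graph(_tcp_graph(True))
    chars = [ElementaryCharacter("tail", ("a", "p")), ElementaryCharacter("color", ("r", "b"))]
    q_ind = kron_sum_amalgamate([c.rate_matrix for c in chars], sep="")
    omap = ObservationMap.from_dict(omap.to_dict(), inapplicable="a")
    return {
        "ind": (to_mk(q_ind), omap),
        "sw": (to_mk(q_sw), omap),
    }


def tail_armor_models() -> dict[str, tuple[MkSMM, ObservationMap]]:
    """Two-level hierarchy tail -> armor -> armor color: 8 hidden, 4 observable."""
    chars = [
        ElementaryCharacter("tail", ("a", "p")),
        ElementaryCharacter("armor", ("n", "y")),
        ElementaryCharacter("acolor", ("r", "b")),
    ]
    edges = [
        DependencyEdge("tail", "armor", "switch_on", frozenset({"p"})),
        DependencyEdge("armor", "acolor", "switch_on", frozenset({"y"})),
    ]
    q_sw, omap = build_from_dependency_graph(DependencyGraph(chars, edges))
    q_ind = kron_sum_amalgamate([c.rate_matrix for c in chars], sep="")
    omap = ObservationMap.from_dict(omap.to_dict(), inapplicable="a")
    return {
        "ind": (to_mk(q_ind), omap),
        "sw": (to_mk(q_sw), omap),
    }


def _binary_mk() -> tuple[MkSMM, ObservationMap]:
    mk = to_mk(_binary(1.0, 1.0))
    return mk, ObservationMap.identity(("0", "1"))


_TCP_TAXA = {
    "tailless_left": ("L1", "L2", "L3"),
    "tailless_right": ("R1", "R2", "R3"),
    "ltc": ("lr1", "lr2", "lb1", "lb2"),
    "rtc": ("rr1", "rr2", "rb1", "rb2"),
}


def _tcp_maddison_fixture(n_tail_chars: int, n_synapomorphies: int) -> Fixture:
    L1, L2, L3 = _TCP_TAXA["tailless_left"]
    R1, R2, R3 = _TCP_TAXA["tailless_right"]
    ltc = _TCP_TAXA["ltc"]
    rtc = _TCP_TAXA["rtc"]
    rtc_resolved = (rtc[0], (rtc[1], (rtc[2], rtc[3])))
    free = FreeClade(*ltc)
    backbone = (
        (L1, (L2, (L3, free))),
        (R1, (R2, (R3, rtc_resolved))),
    )
    constraint = TopologyConstraint(backbone)
    # mirrored resolutions of the left tailed clade: pectinate, colors swapped
    res_parsimonious = ("lr1", ("lr2", ("lb1", "lb2")))
    res_swapped = ("lb1", ("lb2", ("lr1", "lr2")))

    taxa = list(constraint.taxa())
    tail_state = {}
    for t in taxa:
        if t in (L1, L2, L3, R1, R2, R3):
            tail_state[t] = "a"
        elif "r" in t[1:]:
            tail_state[t] = "r"
        else:
            tail_state[t] = "b"
    # one binary synapomorphy per constrained clade (avoids zero-length
    # branches); the left tailed clade gets n_synapomorphies of them
    clades: list[tuple[str, tuple[str, ...], int]] = [
        ("left", (L1, L2, L3) + ltc, 1),
        ("left_in1", (L2, L3) + ltc, 1),
        ("left_in2", (L3,) + ltc, 1),
        ("ltc", ltc, n_synapomorphies),
        ("right", (R1, R2, R3) + rtc, 1),
        ("right_in1", (R2, R3) + rtc, 1),
        ("right_in2", (R3,) + rtc, 1),
        ("rtc", rtc, 1),
        ("rtc_in1", rtc[1:], 1),
        ("rtc_in2", rtc[2:], 1),
    ]
    cols: dict[str, list[str]] = {}
    for cname, members, copies in clades:
        for k in range(copies):
            col = ["1" if t in members else "0" for t in taxa]
            cols[f"syn_{cname}" + (f"_{k + 1}" if copies > 1 else "")] = col
    for k in range(n_tail_chars):
        cols[f"tail_{k + 1}"] = [tail_state[t] for t in taxa]
    matrix = CharacterMatrix(pd.DataFrame(cols, index=taxa))

    bin_mk, bin_map = _binary_mk()
    tcp = tcp_models()
    models = {}
    for variant, (mk, omap) in tcp.items():
        assignment: dict[str, tuple[MkSMM, ObservationMap]] = {}
        for name in matrix.characters:
            if name.startswith("tail_"):
                assignment[name] = (mk, omap)
            else:
                assignment[name] = (bin_mk, bin_map)
        models[variant] = assignment
    return Fixture(
        name="tcp_maddison",
        tree=None,
        constraint=constraint,
        matrix=matrix,
        models=models,
        notes=(
            "14 species; tailed clades nested inside two tailless grades; all "
            "relationships constrained except the internal resolution of the "
            "left tailed clade (LTC). The two mirrored pectinate resolutions "
            "of the LTC should receive near-equal posterior support."
        ),
        mirrored_resolutions=(
            _substitute(backbone, free, res_parsimonious),
            _substitute(backbone, free, res_swapped),
        ),
        expected_clades=(
            frozenset({"lr1", "lr2"}),
            frozenset({"lb1", "lb2"}),
        ),
    )


def _substitute(backbone, free: FreeClade, resolution):
    def walk(t):
        if t is free:
            return resolution
        if isinstance(t, tuple):
            return tuple(walk(x) for x in t)
        return t

    return walk(backbone)


def _tcp_modified_fixture(n_chars: int) -> Fixture:
    taxa = ["nt1", "nt2", "bt1", "bt2", "rt1", "rt2"]
    symbol = {"nt1": "a", "nt2": "a", "bt1": "b", "bt2": "b", "rt1": "r", "rt2": "r"}
    cols = {
        f"tail_{k + 1}": [symbol[t] for t in taxa] for k in range(n_chars)
    }
    matrix = CharacterMatrix(pd.DataFrame(cols, index=taxa))
    tcp = tcp_models()
    models = {
        variant: {name: (mk, omap) for name in matrix.characters}
        for variant, (mk, omap) in tcp.items()
    }
    return Fixture(
        name="tcp_modified",
        tree=None,
        constraint=TopologyConstraint.free(taxa),
        matrix=matrix,
        models=models,
        notes=(
            "Three pairs of species with identical scores (no tail, blue, "
            "red); the expected topology groups the identical pairs."
        ),
        expected_clades=(
            frozenset({"nt1", "nt2"}),
            frozenset({"bt1", "bt2"}),
            frozenset({"rt1", "rt2"}),
        ),
    )


def _tail_armor_fixture(n_chars: int) -> Fixture:
    taxa = ["no_tail", "tail_only", "blue_armor", "red_armor"]
    symbol = {
        "no_tail": "a",
        "tail_only": "n",
        "blue_armor": "b",
        "red_armor": "r",
    }
    cols = {f"armor_{k + 1}": [symbol[t] for t in taxa] for k in range(n_chars)}
    matrix = CharacterMatrix(pd.DataFrame(cols, index=taxa))
    models = {
        variant: {name: (mk, omap) for name in matrix.characters}
        for variant, (mk, omap) in tail_armor_models().items()
    }
    return Fixture(
        name="tail_armor",
        tree=None,
        constraint=TopologyConstraint.free(taxa),
        matrix=matrix,
        models=models,
        notes=(
            "Four species spanning a two-level hierarchy (tail -> armor -> "
            "armor color); the expected tree groups the armored species."
        ),
        expected_clades=(frozenset({"blue_armor", "red_armor"}),),
    )


def fixture(name: str, **kwargs) -> Fixture:
    """Build one of the packaged benchmark data sets.

    ``tcp_maddison`` accepts ``n_tail_chars`` (1 or 50) and
    ``n_synapomorphies`` (1 or 11); ``tcp_modified`` and ``tail_armor``
    accept ``n_chars`` (1, 10 or 50).
    """
    if name == "tcp_maddison":
        return _tcp_maddison_fixture(
            kwargs.pop("n_tail_chars", 1), kwargs.pop("n_synapomorphies", 1)
        )
    if name == "tcp_modified":
        return _tcp_modified_fixture(kwargs.pop("n_chars", 1))
    if name == "tail_armor":
        return _tail_armor_fixture(kwargs.pop("n_chars", 1))
    raise ModelError(f"unknown fixture {name!r}")
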