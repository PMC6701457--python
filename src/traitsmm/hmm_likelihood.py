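"""Hidden-state likelihoods for discrete characters on phylogenies.

The observable symbols of a character map many-to-one onto the hidden states
of a structured Markov chain (:class:`~traitsmm.smm_core.ObservationMap`);
in model formalism this hidden layer is exactly equivalent to ambiguous /
polymorphic coding of the tips.  Likelihoods are computed with Felsenstein's
pruning algorithm over the hidden state space, with per-node rescaling and
site-pattern compression.

The fitting surface follows the statsmodels convention: a
:class:`DiscreteTraitModel` is built from a tree, a character matrix and a
rate-matrix structure; ``.fit()`` maximizes the log-likelihood over log-rates
by multi-start bounded quasi-Newton and returns a :class:`DiscreteTraitFit`
carrying the estimates, their standard errors, AIC and a ``summary()`` table.

Mk-type conversion (:func:`to_mk`) constrains a structured matrix to one free
rate parameter, places the equilibrium distribution at the root and corrects
the likelihood for the ascertainment of variable characters, i.e. conditions
on not observing the same observable symbol at every tip.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.special
from scipy.sparse.csgraph import connected_components

from .smm_core import ModelError, ObservationMap, RateMatrix

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "PhyloTree",
    "CharacterMatrix",
    "MkSMM",
    "tip_vector",
    "transition_probs",
    "prune_loglik",
    "constant_pattern_logprob",
    "to_mk",
    "DiscreteTraitModel",
    "DiscreteTraitFit",
    "fit_ml",
    "ObservationMap",
]

logger = logging.getLogger(__name__)

MISSING = "?"
INAPPLICABLE = "-"


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class PhyloTree:
    """Rooted tree with branch lengths in expected-change units.

    Nodes are indexed ``0 .. n_nodes-1`` with tips first (in ``tip_labels``
    order); ``lengths[i]`` is the length of the edge above node ``i`` (0 for
    the root).  The class is an array-backed container tuned for repeated
    likelihood evaluation; Newick parsing/serialisation goes through dendropy.
    """

    __slots__ = ("tip_labels", "children", "parent", "lengths", "postorder", "root")

    def __init__(
        self,
        tip_labels: Sequence[str],
        children: Sequence[Sequence[int]],
        lengths: Sequence[float],
        root: int,
    ):
        self.tip_labels = tuple(map(str, tip_labels))
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ModelError("duplicate tip labels")
        self.children = tuple(tuple(c) for c in children)
        self.lengths = np.asarray(lengths, dtype=float)
        if np.any(self.lengths < 0) or not np.all(np.isfinite(self.lengths)):
            raise ModelError("branch lengths must be finite and >= 0")
        self.root = int(root)
        n = len(self.children)
        parent = np.full(n, -1, dtype=int)
        for u, ch in enumerate(self.children):
            for c in ch:
                parent[c] = u
        self.parent = parent
        # iterative post-order
        order: list[int] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(self.children[u])
        order.reverse()
        self.postorder = np.asarray(order, dtype=int)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import dendropy

        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree) -> "PhyloTree":
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        tip_index = {lbl: i for i, lbl in enumerate(tips)}
        n_tips = len(tips)
        counter = itertools.count(n_tips)
        children: list[list[int]] = [[] for _ in range(n_tips)]
        lengths: list[float] = [0.0] * n_tips

        def visit(node) -> int:
            if node.is_leaf():
                idx = tip_index[node.taxon.label]
            else:
                kids = [visit(c) for c in node.child_nodes()]
                idx = next(counter)
                children.append(kids)
                lengths.append(0.0)
            lengths[idx] = float(node.edge.length or 0.0)
            return idx

        root = visit(tree.seed_node)
        lengths[root] = 0.0
        return cls(tips, children, lengths, root)

    @classmethod
    def from_nested(
        cls, topology, lengths: Mapping[int, float] | Sequence[float] | float = 1.0
    ) -> "PhyloTree":
        """Build from nested tuples of tip labels.

        ``lengths`` is a scalar (all edges equal), or a sequence indexed by the
        canonical edge order: non-root nodes in depth-first, left-to-right
        creation order (tips and internals interleaved as encountered).
        """
        tip_labels: list[str] = []

        def collect(t) -> None:
            if isinstance(t, (tuple, list)):
                for x in t:
                    collect(x)
            else:
                tip_labels.append(str(t))

        collect(topology)
        tip_index = {lbl: i for i, lbl in enumerate(tip_labels)}
        n_tips = len(tip_labels)
        counter = itertools.count(n_tips)
        children: list[list[int]] = [[] for _ in range(n_tips)]
        len_store: list[float] = [0.0] * n_tips
        edge_counter = itertools.count()

        def edge_len(k: int) -> float:
            if isinstance(lengths, (int, float)):
                return float(lengths)
            return float(lengths[k])

        def build(t, is_root: bool) -> int:
            if isinstance(t, (tuple, list)):
                idx = next(counter)
                children.append([])
                len_store.append(0.0)
                if not is_root:
                    len_store[idx] = edge_len(next(edge_counter))
                for x in t:
                    children[idx].append(build(x, False))
                return idx
            idx = tip_index[str(t)]
            len_store[idx] = edge_len(next(edge_counter))
            return idx

        root = build(topology, True)
        return cls(tip_labels, children, len_store, root)

    # -- properties -------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def tip_index(self, label: str) -> int:
        return self.tip_labels.index(label)

    def root_to_tip_distances(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes)
        for u in self.postorder[::-1]:
            for c in self.children[u]:
                depth[c] = depth[u] + self.lengths[c]
        return depth[: self.n_tips]

    def rescaled(self, height: float) -> "PhyloTree":
        """Rescale all branch lengths so the mean root-to-tip distance is ``height``."""
        mean = float(self.root_to_tip_distances().mean())
        if mean <= 0:
            raise ModelError("cannot rescale a zero-height tree")
        return PhyloTree(
            self.tip_labels, self.children, self.lengths * (height / mean), self.root
        )

    def with_lengths(self, lengths: Sequence[float]) -> "PhyloTree":
        """Same topology, new branch lengths (cheap: traversals are reused)."""
        lens = np.array(lengths, dtype=float)
        lens[self.root] = 0.0
        out = object.__new__(PhyloTree)
        out.tip_labels = self.tip_labels
        out.children = self.children
        out.lengths = lens
        out.parent = self.parent
        out.postorder = self.postorder
        out.root = self.root
        return out

    # -- serialisation ----------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        def fmt(u: int) -> str:
            if not self.children[u]:
                lbl = self.tip_labels[u]
            else:
                lbl = "(" + ",".join(fmt(c) for c in self.children[u]) + ")"
            if u == self.root:
                return lbl
            return f"{lbl}:{self.lengths[u]:.{precision}g}"

        return fmt(self.root) + ";"

    def to_dendropy(self, taxon_namespace=None):
        import dendropy

        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )

    def bipartitions(self) -> set[frozenset[str]]:
        """Tip sets of all non-trivial clades (rooted sense)."""
        out: set[frozenset[str]] = set()
        below: dict[int, set[str]] = {}
        for u in self.postorder:
            if not self.children[u]:
                below[u] = {self.tip_labels[u]}
            else:
                acc: set[str] = set()
                for c in self.children[u]:
                    acc |= below[c]
                below[u] = acc
                if u != self.root and 1 < len(acc) < self.n_tips:
                    out.add(frozenset(acc))
        return out


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------


class CharacterMatrix:
    """Taxa x characters table of observable scores.

    Cells are observable symbols (str), polymorphic symbol sets (frozenset),
    the missing score ``"?"`` or the inapplicable score ``"-"``.
    """

    def __init__(self, df: pd.DataFrame):
        cells = df.copy()
        cells.index = cells.index.map(str)
        if cells.index.duplicated().any():
            raise ModelError("duplicate taxa")
        self.df = cells.map(self._canonical)

    @staticmethod
    def _canonical(cell):
        if isinstance(cell, (set, frozenset, list, tuple)):
            return frozenset(map(str, cell))
        return str(cell)

    @classmethod
    def from_dict(cls, data: Mapping[str, Sequence], taxa: Sequence[str] | None = None):
        """``data`` maps character name -> per-taxon scores (aligned with ``taxa``)."""
        df = pd.DataFrame(dict(data))
        if taxa is not None:
            df.index = list(taxa)
        return cls(df)

    @classmethod
    def single(cls, scores: Mapping[str, object], name: str = "char1"):
        return cls(pd.DataFrame({name: pd.Series(dict(scores))}))

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.df.index)

    @property
    def characters(self) -> tuple[str, ...]:
        return tuple(map(str, self.df.columns))

    @property
    def n_characters(self) -> int:
        return self.df.shape[1]

    def column(self, i: int) -> pd.Series:
        return self.df.iloc[:, i]

    def symbols_used(self) -> set[str]:
        out: set[str] = set()
        for cell in self.df.values.ravel():
            if isinstance(cell, frozenset):
                out |= cell
            elif cell not in (MISSING, INAPPLICABLE):
                out.add(cell)
        return out

    def replicate(self, counts: Mapping[str, int]) -> "CharacterMatrix":
        """Duplicate columns per ``counts`` (e.g. 50 identical tail characters)."""
        cols = {}
        for name in self.df.columns:
            k = counts.get(str(name), 1)
            if k == 1:
                cols[name] = self.df[name]
            else:
                for r in range(k):
                    cols[f"{name}_{r + 1}"] = self.df[name]
        return CharacterMatrix(pd.DataFrame(cols))

    def __eq__(self, other) -> bool:
        return isinstance(other, CharacterMatrix) and self.df.equals(other.df)

    def fingerprint(self) -> str:
        """Deterministic content hash (polymorphic sets serialized sorted)."""
        import hashlib

        rows = []
        for taxon, row in self.df.iterrows():
            cells = [
                "{" + " ".join(sorted(c)) + "}" if isinstance(c, frozenset) else c
                for c in row
            ]
            rows.append(taxon + ":" + ",".join(cells))
        return hashlib.sha256("\n".join(rows).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# tip vectors and transition probabilities
# ---------------------------------------------------------------------------


def tip_vector(
    cell, obs_map: ObservationMap, states: Sequence[str]
) -> np.ndarray:
    """Indicator over hidden ``states`` of the hidden sets compatible with ``cell``.

    ``"?"`` is compatible with every hidden state.  ``"-"`` (inapplicable)
    resolves to the hidden set of the map's designated switched-off symbol or,
    when the map designates none, is treated like missing data — the standard
    reading of inapplicable scores.
    """
    k = len(states)
    if isinstance(cell, str) and cell == MISSING:
        return np.ones(k)
    if isinstance(cell, str) and cell == INAPPLICABLE:
        if obs_map.inapplicable is None:
            return np.ones(k)
        allowed = obs_map[obs_map.inapplicable]
    elif isinstance(cell, (set, frozenset, list, tuple)):
        allowed = set()
        for sym in cell:
            allowed |= obs_map[str(sym)]
    else:
        allowed = obs_map[str(cell)]
    vec = np.array([1.0 if s in allowed else 0.0 for s in states])
    if not vec.any():
        raise ModelError(f"observation {cell!r} compatible with no hidden state")
    return vec


def transition_probs(q: RateMatrix, t: float) -> np.ndarray:
    """Stochastic matrix ``expm(Q t)``."""
    if t < 0:
        raise ModelError("t must be >= 0")
    return scipy.linalg.expm(q.rates * t)


def _pmats(q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """expm(Q t) for a batch of times.

    Eigendecomposition fast path with a reconstruction check; falls back to
    scaling-and-squaring (scipy expm) per unique time for defective or
    ill-conditioned matrices.
    """
    k = q.shape[0]
    scale = max(np.abs(q).max(), 1.0)
    try:
        w, v = np.linalg.eig(q)
        vinv = np.linalg.inv(v)
        recon = (v * w) @ vinv
        if np.abs(recon - q).max() < 1e-10 * scale and np.linalg.cond(v) < 1e8:
            ew = np.exp(np.multiply.outer(ts, w))
            p = np.einsum("ij,tj,jk->tik", v, ew, vinv).real
            np.clip(p, 0.0, None, out=p)
            rs = p.sum(axis=2, keepdims=True)
            if np.abs(rs - 1.0).max() < 1e-8:
                return p / rs
    except np.linalg.LinAlgError:
        pass
    uniq, inv = np.unique(ts, return_inverse=True)
    mats = np.empty((len(uniq), k, k))
    for i, t in enumerate(uniq):
        mats[i] = scipy.linalg.expm(q * t)
    return mats[inv]


class EigPropagator:
    """Cached spectral decomposition of a fixed Q for fast expm(Q t) batches.

    Falls back to scaling-and-squaring when the matrix is defective or the
    eigenvector basis is ill-conditioned.
    """

    def __init__(self, qarr: np.ndarray):
        self.q = np.asarray(qarr, dtype=float)
        self._ok = False
        scale = max(np.abs(self.q).max(), 1.0)
        try:
            w, v = np.linalg.eig(self.q)
            vinv = np.linalg.inv(v)
            if (
                np.abs((v * w) @ vinv - self.q).max() < 1e-10 * scale
                and np.linalg.cond(v) < 1e8
            ):
                self.w, self.v, self.vinv = w, v, vinv
                self._ok = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, ts: np.ndarray) -> np.ndarray:
        if not self._ok:
            return _pmats(self.q, ts)
        ew = np.exp(np.multiply.outer(np.asarray(ts, dtype=float), self.w))
        p = np.einsum("ij,tj,jk->tik", self.v, ew, self.vinv).real
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=2, keepdims=True)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def _tip_partials(
    tree: PhyloTree,
    obs_map: ObservationMap,
    data: CharacterMatrix,
    states: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-character tip indicators compressed to unique patterns.

    Returns (patterns, char_to_pattern, weights): patterns has shape
    (n_patterns, n_tips, k).
    """
    if set(data.taxa) != set(tree.tip_labels):
        raise ModelError("taxa of the matrix do not match the tree tips")
    row_of = {t: i for i, t in enumerate(data.taxa)}
    tip_rows = [row_of[t] for t in tree.tip_labels]
    cols = []
    for ci in range(data.n_characters):
        col = data.column(ci)
        mat = np.stack(
            [tip_vector(col.iloc[r], obs_map, states) for r in tip_rows]
        )
        cols.append(mat)
    keys = [c.tobytes() for c in cols]
    uniq: dict[bytes, int] = {}
    patterns = []
    char_to_pattern = np.empty(len(cols), dtype=int)
    for i, key in enumerate(keys):
        if key not in uniq:
            uniq[key] = len(patterns)
            patterns.append(cols[i])
        char_to_pattern[i] = uniq[key]
    pat = np.stack(patterns) if patterns else np.zeros((0, tree.n_tips, len(states)))
    weights = np.bincount(char_to_pattern, minlength=len(patterns)).astype(float)
    return pat, char_to_pattern, weights


def _prune_patterns(
    tree: PhyloTree,
    qarr: np.ndarray,
    patterns: np.ndarray,
    root: np.ndarray,
    pmats: np.ndarray | None = None,
) -> np.ndarray:
    """Log-likelihood of each tip pattern (vectorized over patterns)."""
    npat, n_tips, k = patterns.shape
    if npat == 0:
        return np.zeros(0)
    p = _pmats(qarr, tree.lengths) if pmats is None else pmats
    partial = np.ones((npat, tree.n_nodes, k))
    partial[:, :n_tips, :] = patterns
    logscale = np.zeros(npat)
    for u in tree.postorder:
        ch = tree.children[u]
        if not ch:
            continue
        for c in ch:
            partial[:, u, :] *= partial[:, c, :] @ p[c].T
        mx = partial[:, u, :].max(axis=1)
        mx[mx == 0] = 1.0
        partial[:, u, :] /= mx[:, None]
        logscale += np.log(mx)
    like = (partial[:, tree.root, :] * root).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(like) + logscale


def prune_loglik(
    tree: PhyloTree,
    q: RateMatrix,
    obs_map: ObservationMap,
    data: CharacterMatrix,
    root: Sequence[float],
) -> tuple[np.ndarray, float]:
    """Felsenstein pruning over hidden states.

    Returns (per-character log-likelihoods, total).
    """
    root = np.asarray(root, dtype=float)
    if root.shape != (q.n_states,) or abs(root.sum() - 1.0) > 1e-8:
        raise ModelError("root vector must sum to 1 over the hidden states")
    patterns, char_to_pattern, _ = _tip_partials(tree, obs_map, data, q.states)
    lnl = _prune_patterns(tree, q.rates, patterns, root)
    per_char = lnl[char_to_pattern]
    return per_char, float(per_char.sum())


def constant_pattern_logprob(
    tree: PhyloTree,
    q: RateMatrix,
    obs_map: ObservationMap,
    root: Sequence[float],
) -> float:
    """log P(every tip shows the same observable symbol).

    "Constant" is defined at the observable level — what a scorer can see —
    regardless of hidden-level variation.
    """
    root = np.asarray(root, dtype=float)
    k = q.n_states
    pats = np.empty((len(obs_map.symbols), tree.n_tips, k))
    for i, sym in enumerate(obs_map.symbols):
        vec = tip_vector(sym, obs_map, q.states)
        pats[i] = np.tile(vec, (tree.n_tips, 1))
    lnl = _prune_patterns(tree, q.rates, pats, root)
    return float(scipy.special.logsumexp(lnl))


# ---------------------------------------------------------------------------
# Mk conversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MkSMM:
    """A structured matrix constrained to one free rate parameter.

    ``template`` holds the structure and relative rates, normalized so that
    the expected number of changes per unit time at equilibrium is 1; ``rate``
    is the single global scalar; ``root`` is the equilibrium distribution;
    the likelihood is conditioned on observing variable characters.
    """

    template: RateMatrix
    rate: float = 1.0
    root: tuple[float, ...] = ()
    condition_on_variable: bool = True

    @property
    def matrix(self) -> RateMatrix:
        return RateMatrix(self.template.states, self.template.rates * self.rate)

    @property
    def root_vector(self) -> np.ndarray:
        return np.asarray(self.root, dtype=float)


def stationary_distribution(q: RateMatrix) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1 for an irreducible chain."""
    off = (q.rates > 0).astype(int)
    np.fill_diagonal(off, 0)
    ncomp, _ = connected_components(off, directed=True, connection="strong")
    if ncomp != 1:
        raise ModelError(
            "rate matrix is reducible: no unique stationary distribution"
        )
    ns = scipy.linalg.null_space(q.rates.T)
    if ns.shape[1] != 1:
        raise ModelError("stationary distribution is not unique")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-10):
        raise ModelError("negative stationary probability")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def to_mk(template: RateMatrix, condition_on_variable: bool = True) -> MkSMM:
    """Convert a structured matrix into its one-parameter Mk-type model."""
    pi = stationary_distribution(template)
    mean_rate = float(-(pi * np.diag(template.rates)).sum())
    if mean_rate <= 0:
        raise ModelError("degenerate template: zero mean rate")
    norm = RateMatrix(template.states, template.rates / mean_rate)
    return MkSMM(
        template=norm,
        rate=1.0,
        root=tuple(pi),
        condition_on_variable=condition_on_variable,
    )


# ---------------------------------------------------------------------------
# maximum-likelihood fitting (Model / Results)
# ---------------------------------------------------------------------------

_LOG10_BOUNDS = (-9.0, 2.0)


class DiscreteTraitModel:
    """Maximum-likelihood model for characters evolving on a fixed tree.

    Parameters
    ----------
    tree, data : the phylogeny and the observable character matrix.
    template : RateMatrix
        Structure of the hidden chain.  Cells with equal positive template
        values are tied to one free parameter (pass ``tying`` to override);
        zero cells are structural zeros.
    obs_map : ObservationMap, optional
        Observable -> hidden mapping; defaults to the identity (plain MM).
    tying : mapping (from_label, to_label) -> parameter name, optional
    root : "uniform" (default), "equilibrium", or an explicit vector.
    condition_on_variable : bool
        Apply the variable-characters-only ascertainment correction.
    """

    def __init__(
        self,
        tree: PhyloTree,
        data: CharacterMatrix,
        template: RateMatrix,
        obs_map: ObservationMap | None = None,
        *,
        tying: Mapping[tuple[str, str], str] | None = None,
        root: str | Sequence[float] = "uniform",
        condition_on_variable: bool = False,
    ):
        self.tree = tree
        self.data = data
        self.template = template
        self.obs_map = obs_map or ObservationMap.identity(template.states)
        if not self.obs_map.hidden_states <= set(template.states):
            raise ModelError("observation map refers to unknown hidden states")
        self.root_spec = root
        self.condition_on_variable = condition_on_variable
        self._build_tying(tying)
        self._patterns, self._char_to_pattern, _ = _tip_partials(
            tree, self.obs_map, data, template.states
        )

    def _build_tying(self, tying) -> None:
        k = self.template.n_states
        index = np.full((k, k), -1, dtype=int)
        if tying is None:
            names: list[str] = []
            values: list[float] = []
            for i in range(k):
                for j in range(k):
                    if i == j or self.template.rates[i, j] <= 0:
                        continue
                    v = self.template.rates[i, j]
                    for pi, pv in enumerate(values):
                        if math.isclose(v, pv, rel_tol=1e-12):
                            index[i, j] = pi
                            break
                    else:
                        index[i, j] = len(values)
                        values.append(v)
                        names.append(f"q{len(values)}")
        else:
            names = []
            for (a, b), pname in tying.items():
                i, j = self.template.index(a), self.template.index(b)
                if i == j:
                    raise ModelError("tying may only address off-diagonal cells")
                if pname not in names:
                    names.append(pname)
                index[i, j] = names.index(pname)
        if not names:
            raise ModelError("model has no free rate parameters")
        self.param_names = tuple(names)
        self._param_index = index

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    def rate_matrix(self, params: Sequence[float]) -> RateMatrix:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.k_params,):
            raise ModelError(f"expected {self.k_params} rate parameters")
        q = np.zeros_like(self._param_index, dtype=float)
        mask = self._param_index >= 0
        q[mask] = params[self._param_index[mask]]
        return RateMatrix.from_offdiag(self.template.states, q)

    def _root_vector(self, q: RateMatrix) -> np.ndarray:
        if isinstance(self.root_spec, str):
            if self.root_spec == "uniform":
                return np.full(q.n_states, 1.0 / q.n_states)
            if self.root_spec == "equilibrium":
                return stationary_distribution(q)
            raise ModelError(f"unknown root spec {self.root_spec!r}")
        vec = np.asarray(self.root_spec, dtype=float)
        if vec.shape != (q.n_states,) or abs(vec.sum() - 1.0) > 1e-8:
            raise ModelError("root vector must sum to 1")
        return vec

    def loglike(self, params: Sequence[float]) -> float:
        q = self.rate_matrix(params)
        root = self._root_vector(q)
        lnl = _prune_patterns(self.tree, q.rates, self._patterns, root)
        total = float(lnl[self._char_to_pattern].sum())
        if self.condition_on_variable:
            log_pc = constant_pattern_logprob(self.tree, q, self.obs_map, root)
            total -= self.data.n_characters * float(np.log1p(-np.exp(log_pc)))
        return total

    def fit(
        self,
        starts: int = 10,
        seed: int | None = None,
        bounds: tuple[float, float] = _LOG10_BOUNDS,
        compute_se: bool = True,
        ftol: float = 1e-8,
    ) -> "DiscreteTraitFit":
        """Multi-start bounded quasi-Newton maximization over log10-rates."""
        rng = np.random.default_rng(seed)
        lo, hi = bounds

        def negll(logp: np.ndarray) -> float:
            val = self.loglike(10.0**logp)
            if not np.isfinite(val):
                return 1e300
            return -val

        start_points = [np.zeros(self.k_params)]
        for _ in range(max(0, starts - 1)):
            start_points.append(rng.uniform(-2.0, 1.0, size=self.k_params))
        best = None
        n_ok = 0
        for x0 in start_points:
            res = scipy.optimize.minimize(
                negll,
                np.clip(x0, lo, hi),
                method="L-BFGS-B",
                bounds=[(lo, hi)] * self.k_params,
                options={"ftol": ftol},
            )
            if res.success:
                n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        converged = n_ok > 0
        if not converged:
            logger.warning("optimizer did not converge in any of %d starts", starts)
        params = 10.0 ** best.x
        lnl = -float(best.fun)
        se = None
        if compute_se and converged:
            se = self._param_se(params)
        return DiscreteTraitFit(
            model=self,
            params=params,
            lnl=lnl,
            converged=converged,
            n_starts=len(start_points),
            n_converged=n_ok,
            se=se,
        )

    def _param_se(self, params: np.ndarray) -> np.ndarray | None:
        """Delta-method SEs from a central-difference Hessian on log-rates."""
        kp = self.k_params
        h = 1e-4
        logp = np.log(params)

        def f(lp):
            return self.loglike(np.exp(lp))

        hess = np.zeros((kp, kp))
        f0 = f(logp)
        for i in range(kp):
            for j in range(i, kp):
                ei = np.eye(kp)[i] * h
                ej = np.eye(kp)[j] * h
                if i == j:
                    val = (f(logp + ei) - 2 * f0 + f(logp - ei)) / h**2
                else:
                    val = (
                        f(logp + ei + ej)
                        - f(logp + ei - ej)
                        - f(logp - ei + ej)
                        + f(logp - ei - ej)
                    ) / (4 * h**2)
                hess[i, j] = hess[j, i] = val
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            return None
        var = np.diag(cov)
        if np.any(var < 0):
            return None
        # delta method: Var(rate) = rate^2 * Var(log rate)
        return params * np.sqrt(var)


@dataclass
class DiscreteTraitFit:
    """Maximum-likelihood results: estimates, uncertainties, AIC, summary."""

    model: DiscreteTraitModel
    params: np.ndarray
    lnl: float
    converged: bool
    n_starts: int
    n_converged: int
    se: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.model.k_params

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.lnl

    @property
    def rate_matrix(self) -> RateMatrix:
        return self.model.rate_matrix(self.params)

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=list(self.model.param_names))

    def summary(self) -> str:
        lines = [
            "Discrete trait model fit",
            "=" * 46,
            f"{'log-likelihood':<24}{self.lnl: .6f}",
            f"{'free parameters':<24}{self.k}",
            f"{'AIC':<24}{self.aic: .6f}",
            f"{'converged':<24}{self.converged} "
            f"({self.n_converged}/{self.n_starts} starts)",
            "-" * 46,
            f"{'parameter':<12}{'rate':>14}{'std err':>14}",
        ]
        for i, name in enumerate(self.model.param_names):
            se = f"{self.se[i]:.5g}" if self.se is not None else "--"
            lines.append(f"{name:<12}{self.params[i]:>14.6g}{se:>14}")
        return "\n".join(lines)


def fit_ml(
    tree: PhyloTree,
    data: CharacterMatrix,
    template: RateMatrix,
    obs_map: ObservationMap | None = None,
    *,
    tying: Mapping[tuple[str, str], str] | None = None,
    root: str | Sequence[float] = "uniform",
    condition_on_variable: bool = False,
    starts: int = 10,
    seed: int | None = None,
) -> DiscreteTraitFit:
    """Convenience wrapper: build a :class:`DiscreteTraitModel` and fit it."""
    model = DiscreteTraitModel(
        tree,
        data,
        template,
        obs_map,
        tying=tying,
        root=root,
        condition_on_variable=condition_on_variable,
    )
    return model.fit(starts=starts, seed=seed)
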