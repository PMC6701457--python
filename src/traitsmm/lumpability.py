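"""Lumpability testing and state aggregation for Markov characters.

Aggregating (lumping) states of a Markov chain yields another Markov chain
only when the chain is *lumpable* with respect to the chosen partition.  The
necessary and sufficient condition for strong lumpability (Kemeny-Snell) is
the row-wise sum rule: within every source block, the summed rates into each
target block must be equal across the block's rows.  When it holds, the
aggregated intensity matrix is ``N P M P^T``, with ``P`` the block-membership
0/1 matrix and ``N`` the diagonal of reciprocal block sizes (uniform
within-block weights).

Strongly lumpable aggregation is exact: the aggregated chain reproduces the
block-level transition probabilities of the original chain for every time
horizon, so likelihoods computed at the aggregated level are unbiased.  A
chain that is not lumpable can still be *nearly* lumpable; the scalar
returned by :func:`lumpability_error` (the worst within-block spread of
row sums) quantifies the violation and shrinks as many i.i.d.-rate characters
are amalgamated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .smm_core import ModelError, RateMatrix

__all__ = [
    "Partition",
    "MembershipMatrices",
    "membership_matrices",
    "is_strongly_lumpable",
    "aggregate",
    "lumpability_error",
    "lift",
    "weak_lumpability",
]

DEFAULT_REL_TOL = 1e-9


@dataclass(frozen=True)
class Partition:
    """Disjoint, covering blocks over a state set."""

    blocks: tuple[frozenset[str], ...]
    names: tuple[str, ...] = ()

    @classmethod
    def of(
        cls,
        blocks: Iterable[Iterable[str]],
        names: Iterable[str] | None = None,
    ) -> "Partition":
        bl = tuple(frozenset(map(str, b)) for b in blocks)
        if any(not b for b in bl):
            raise ModelError("empty partition block")
        seen: set[str] = set()
        for b in bl:
            if seen & b:
                raise ModelError("overlapping partition blocks")
            seen |= b
        if names is None:
            nm = tuple("+".join(sorted(b)) for b in bl)
        else:
            nm = tuple(map(str, names))
            if len(nm) != len(bl):
                raise ModelError("one name per block required")
        return cls(bl, nm)

    @classmethod
    def singletons(cls, states: Sequence[str]) -> "Partition":
        return cls.of([[s] for s in states], names=states)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def states(self) -> frozenset[str]:
        out: set[str] = set()
        for b in self.blocks:
            out |= b
        return frozenset(out)

    def block_of(self, state: str) -> int:
        for i, b in enumerate(self.blocks):
            if state in b:
                return i
        raise KeyError(state)

    def validate_over(self, states: Sequence[str]) -> None:
        if self.states() != set(states):
            missing = set(states) - self.states()
            extra = self.states() - set(states)
            raise ModelError(
                f"partition does not cover the state set exactly "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )


@dataclass(frozen=True)
class MembershipMatrices:
    """P: block x state 0/1 membership; N: diagonal of reciprocal block sizes."""

    P: np.ndarray
    N: np.ndarray


def membership_matrices(
    partition: Partition, states: Sequence[str]
) -> MembershipMatrices:
    """Build the aggregation matrices so that ``N @ P`` row-averages blocks."""
    partition.validate_over(states)
    k, n = partition.n_blocks, len(states)
    p = np.zeros((k, n))
    for j, s in enumerate(states):
        p[partition.block_of(s), j] = 1.0
    nmat = np.diag(1.0 / p.sum(axis=1))
    return MembershipMatrices(P=p, N=nmat)


def _block_row_sums(
    q: RateMatrix, partition: Partition
) -> dict[tuple[int, int], np.ndarray]:
    """For each ordered block pair (I, J), I != J: per-row sums of rates I -> J."""
    partition.validate_over(q.states)
    idx = [
        [q.index(s) for s in sorted(b)] for b in partition.blocks
    ]
    out: dict[tuple[int, int], np.ndarray] = {}
    for i, rows in enumerate(idx):
        for j, cols in enumerate(idx):
            if i == j:
                continue
            out[(i, j)] = q.rates[np.ix_(rows, cols)].sum(axis=1)
    return out


def is_strongly_lumpable(
    q: RateMatrix,
    partition: Partition,
    tol: float | None = None,
) -> tuple[bool, dict[tuple[str, str], float]]:
    """Row-wise sum rule check.

    Returns the verdict and, per ordered block pair, the spread (max - min)
    of the within-block row sums.  ``tol`` is relative, scaled by the largest
    off-diagonal rate; defaults to 1e-9.
    """
    if tol is None:
        tol = DEFAULT_REL_TOL
    if tol <= 0:
        raise ModelError("tol must be positive")
    off = q.rates.copy()
    np.fill_diagonal(off, 0.0)
    scale = max(off.max(initial=0.0), np.finfo(float).tiny)
    spreads: dict[tuple[str, str], float] = {}
    ok = True
    for (i, j), sums in _block_row_sums(q, partition).items():
        spread = float(sums.max() - sums.min())
        spreads[(partition.names[i], partition.names[j])] = spread
        if spread > tol * scale:
            ok = False
    return ok, spreads


def aggregate(
    q: RateMatrix,
    partition: Partition,
    force: bool = False,
    tol: float | None = None,
) -> RateMatrix:
    """Aggregate states block-wise: ``N P M P^T`` with uniform block weights.

    Refuses non-lumpable input (naming the worst block pair) unless ``force``
    is set, in which case the result is the row-averaged approximation.
    """
    ok, spreads = is_strongly_lumpable(q, partition, tol)
    if not ok and not force:
        worst = max(spreads, key=spreads.get)  # type: ignore[arg-type]
        raise ModelError(
            f"not strongly lumpable: row sums from block {worst[0]!r} into "
            f"block {worst[1]!r} spread by {spreads[worst]:.3g}; "
            f"pass force=True to aggregate anyway"
        )
    m = membership_matrices(partition, q.states)
    agg = m.N @ m.P @ q.rates @ m.P.T
    return RateMatrix(partition.names, agg)


def lumpability_error(q: RateMatrix, partition: Partition) -> float:
    """Worst within-block spread of block row sums; 0 iff strongly lumpable."""
    sums = _block_row_sums(q, partition)
    if not sums:
        return 0.0
    return max(float(v.max() - v.min()) for v in sums.values())


def lift(
    q: RateMatrix,
    partition: Partition,
    rng: np.random.Generator | None = None,
) -> RateMatrix:
    """Expand an aggregated chain back to a finer, strongly lumpable chain.

    Each fine state of block I sends total rate ``q[I, J]`` into block J,
    split across J's members (uniformly, or by random weights when ``rng`` is
    given).  ``aggregate(lift(q, partition), partition)`` recovers ``q``.
    ``partition`` blocks must be named after ``q``'s states.
    """
    if set(partition.names) != set(q.states):
        raise ModelError("partition block names must match the aggregated states")
    fine_states = [s for b in partition.blocks for s in sorted(b)]
    nfine = len(fine_states)
    pos = {s: i for i, s in enumerate(fine_states)}
    out = np.zeros((nfine, nfine))
    for bi, block_i in enumerate(partition.blocks):
        for bj, block_j in enumerate(partition.blocks):
            if bi == bj:
                continue
            total = q[partition.names[bi], partition.names[bj]]
            members_j = sorted(block_j)
            for s in block_i:
                if rng is None:
                    w = np.full(len(members_j), 1.0 / len(members_j))
                else:
                    w = rng.dirichlet(np.ones(len(members_j)))
                for t, wt in zip(members_j, w):
                    out[pos[s], pos[t]] = total * wt
    return RateMatrix.from_offdiag(fine_states, out)


def weak_lumpability(*_args, **_kwargs):
    """Reserved: lumpability under particular initial vectors only.

    Not supported — the pruning-algorithm likelihood does not preserve weak
    lumpability, so the package deliberately implements strong lumpability
    only.
    """
    raise NotImplementedError("weak lumpability is unsupported")
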