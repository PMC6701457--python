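"""Marginal ancestral state reconstruction under structured / hidden models.

The two-pass (up-down) algorithm yields, for every node, the posterior
probability of each hidden state given all tip observations.  When the model
carries a many-to-one observation layer, hidden-state posteriors can be
aggregated to the observable symbols by summation — for a strongly lumpable
model this matches reconstruction performed directly under the aggregated
matrix, while for non-lumpable models (the usual case for anatomically
dependent or hidden-process traits) only the hidden-level reconstruction is
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hmm_likelihood import (
    CharacterMatrix,
    PhyloTree,
    _pmats,
    _tip_partials,
)
from .smm_core import ModelError, ObservationMap, RateMatrix

__all__ = ["NodeMarginals", "marginal_asr", "aggregate_marginals"]


@dataclass
class NodeMarginals:
    """Posterior state probabilities per node and character.

    ``probs`` has shape (n_characters, n_nodes, n_states); nodes are labeled
    by tip name or ``nd<i>`` for internal nodes (root included).
    """

    states: tuple[str, ...]
    node_labels: tuple[str, ...]
    characters: tuple[str, ...]
    probs: np.ndarray

    def table(self, character: int | str = 0) -> pd.DataFrame:
        if isinstance(character, str):
            character = self.characters.index(character)
        return pd.DataFrame(
            self.probs[character],
            index=list(self.node_labels),
            columns=list(self.states),
        )

    def map_states(self, character: int | str = 0) -> pd.DataFrame:
        """MAP state per node; ties broken by lowest state index and reported."""
        tab = self.table(character)
        arr = tab.to_numpy()
        best = arr.argmax(axis=1)
        is_tie = [
            bool((np.isclose(arr[i], arr[i, best[i]], atol=1e-12)).sum() > 1)
            for i in range(arr.shape[0])
        ]
        return pd.DataFrame(
            {
                "state": [self.states[b] for b in best],
                "probability": arr[np.arange(len(best)), best],
                "tie": is_tie,
            },
            index=tab.index,
        )

    def to_csv(self, path, character: int | str = 0) -> None:
        self.table(character).to_csv(path)


def _node_labels(tree: PhyloTree) -> tuple[str, ...]:
    labels = list(tree.tip_labels)
    labels += [f"nd{i}" for i in range(tree.n_tips, tree.n_nodes)]
    return tuple(labels)


def marginal_asr(
    tree: PhyloTree,
    q: RateMatrix,
    obs_map: ObservationMap | None,
    data: CharacterMatrix,
    root: Sequence[float],
) -> NodeMarginals:
    """Marginal posteriors over hidden states at every node (up-down pass)."""
    if obs_map is None:
        obs_map = ObservationMap.identity(q.states)
    root = np.asarray(root, dtype=float)
    if root.shape != (q.n_states,) or abs(root.sum() - 1.0) > 1e-8:
        raise ModelError("root vector must sum to 1")
    patterns, char_to_pat, _ = _tip_partials(tree, obs_map, data, q.states)
    npat, n_tips, k = patterns.shape
    p = _pmats(q.rates, tree.lengths)

    down = np.ones((npat, tree.n_nodes, k))
    down[:, :n_tips, :] = patterns
    msg = np.ones((npat, tree.n_nodes, k))  # child -> parent messages
    for u in tree.postorder:
        for c in tree.children[u]:
            msg[:, c, :] = down[:, c, :] @ p[c].T
            down[:, u, :] *= msg[:, c, :]
        mx = down[:, u, :].max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
        down[:, u, :] /= mx

    up = np.ones((npat, tree.n_nodes, k))
    up[:, tree.root, :] = root
    for u in tree.postorder[::-1]:
        for c in tree.children[u]:
            # everything at u except the subtree below c
            other = up[:, u, :].copy()
            for c2 in tree.children[u]:
                if c2 != c:
                    other *= msg[:, c2, :]
            up[:, c, :] = other @ p[c]
            mx = up[:, c, :].max(axis=1, keepdims=True)
            mx[mx == 0] = 1.0
            up[:, c, :] /= mx

    joint = down * up
    norm = joint.sum(axis=2, keepdims=True)
    if np.any(norm == 0):
        raise ModelError("zero total likelihood: data impossible under the model")
    marg = joint / norm
    probs = marg[char_to_pat]
    return NodeMarginals(
        states=q.states,
        node_labels=_node_labels(tree),
        characters=data.characters,
        probs=probs,
    )


def aggregate_marginals(
    marginals: NodeMarginals, obs_map: ObservationMap
) -> NodeMarginals:
    """Collapse hidden-state posteriors to observable symbols by summation."""
    if not obs_map.is_partition():
        raise ModelError(
            "overlapping symbol sets: a hidden state belongs to two symbols"
        )
    covered = obs_map.hidden_states
    if not set(marginals.states) <= covered:
        raise ModelError("observation map does not cover the hidden space")
    symbols = obs_map.symbols
    sel = np.zeros((len(marginals.states), len(symbols)))
    for j, sym in enumerate(symbols):
        for h in obs_map[sym]:
            if h in marginals.states:
                sel[marginals.states.index(h), j] = 1.0
    return NodeMarginals(
        states=symbols,
        node_labels=marginals.node_labels,
        characters=marginals.characters,
        probs=marginals.probs @ sel,
    )
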