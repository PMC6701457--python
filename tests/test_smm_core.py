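"""Amalgamation operators and structural properties of structured matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitsmm import (
    DependencyEdge,
    DependencyGraph,
    ElementaryCharacter,
    ModelError,
    RateMatrix,
    build_from_dependency_graph,
    general_smm,
    kron_sum_amalgamate,
    structural_stats,
    switch_amalgamate,
    synchronous_amalgamate,
)
from traitsmm.lumpability import Partition, is_strongly_lumpable

from conftest import random_rate_matrix


def count_structural_nonzeros(q: RateMatrix) -> int:
    off = q.rates.copy()
    np.fill_diagonal(off, 0.0)
    return int((off > 0).sum()) + q.n_states  # diagonal counts as nonzero


class TestRateMatrix:
    def test_rows_sum_to_zero_and_labels_align(self, smm_ind):
        assert np.allclose(smm_ind.rates.sum(axis=1), 0.0, atol=1e-12)
        assert smm_ind.states == ("ar", "ab", "pr", "pb")

    def test_rejects_negative_offdiagonal(self):
        with pytest.raises(ModelError):
            RateMatrix(["x", "y"], np.array([[1.0, -1.0], [2.0, -2.0]]))

    def test_rejects_label_mismatch(self):
        with pytest.raises(ModelError):
            RateMatrix(["x"], np.zeros((2, 2)))

    def test_reorder_is_similarity_transform(self, smm_ind):
        back = smm_ind.reorder(("pb", "ar", "pr", "ab")).reorder(smm_ind.states)
        assert back.allclose(smm_ind)


class TestKronSum:
    def test_tail_color_amalgam_zero_pattern(self, tail_matrix, color_matrix):
        """Double changes (ar<->pb, ab<->pr) are structural zeros; single
        changes copy the elementary rates."""
        q = kron_sum_amalgamate([tail_matrix, color_matrix])
        assert q["ar", "pb"] == q["pb", "ar"] == 0.0
        assert q["ab", "pr"] == q["pr", "ab"] == 0.0
        alpha, beta = tail_matrix["a", "p"], tail_matrix["p", "a"]
        assert q["ar", "pr"] == q["ab", "pb"] == alpha
        assert q["pr", "ar"] == q["pb", "ab"] == beta
        assert q["ar", "ab"] == color_matrix["r", "b"]

    def test_one_state_character_is_identity(self, tail_matrix):
        one = RateMatrix(["x"], np.zeros((1, 1)))
        q = kron_sum_amalgamate([tail_matrix, one])
        assert np.allclose(q.rates, tail_matrix.rates)
        assert q.states == ("ax", "px")

    def test_ten_binary_characters_dimension_and_sparsity(self):
        comps = [RateMatrix.binary(1.0, 1.0, (f"a{i}", f"b{i}")) for i in range(10)]
        q = kron_sum_amalgamate(comps, sep="|")
        assert q.n_states == 1024
        # brute-force count of structurally nonzero cells over all 1024^2
        assert count_structural_nonzeros(q) == 1024 * 11
        assert count_structural_nonzeros(q) / 1024**2 == pytest.approx(11 / 1024)

    def test_empty_component_list_rejected(self):
        with pytest.raises(ModelError):
            kron_sum_amalgamate([])

    def test_associative_up_to_reordering(self):
        rng = np.random.default_rng(0)
        a = random_rate_matrix(rng, 2, ["a0", "a1"])
        b = random_rate_matrix(rng, 3, ["b0", "b1", "b2"])
        c = random_rate_matrix(rng, 2, ["c0", "c1"])
        left = kron_sum_amalgamate([kron_sum_amalgamate([a, b], "|"), c], "|")
        right = kron_sum_amalgamate([a, kron_sum_amalgamate([b, c], "|")], "|")
        assert left.reorder(right.states).allclose(right, atol=1e-12)

    def test_transition_probabilities_factorize(self):
        """expm((A (+) B) t) = expm(At) kron expm(Bt) for independent parts."""
        import scipy.linalg

        rng = np.random.default_rng(1)
        a = random_rate_matrix(rng, 2)
        b = random_rate_matrix(rng, 3)
        t = 0.73
        joint = scipy.linalg.expm(kron_sum_amalgamate([a, b]).rates * t)
        prod = np.kron(scipy.linalg.expm(a.rates * t), scipy.linalg.expm(b.rates * t))
        assert np.allclose(joint, prod, atol=1e-9)


class TestSwitchAmalgamate:
    def test_differs_from_independent_in_exactly_two_cells(
        self, tail_matrix, color_matrix
    ):
        q_ind = kron_sum_amalgamate([tail_matrix, color_matrix])
        q_sw = switch_amalgamate(tail_matrix, color_matrix, {"p"})
        assert q_sw["ar", "ab"] == q_sw["ab", "ar"] == 0.0
        diff = q_sw.rates - q_ind.rates
        np.fill_diagonal(diff, 0.0)
        changed = {
            (q_ind.states[i], q_ind.states[j])
            for i, j in zip(*np.nonzero(diff))
        }
        assert changed == {("ar", "ab"), ("ab", "ar")}

    def test_all_on_states_equals_kron_sum(self, tail_matrix, color_matrix):
        q_sw = switch_amalgamate(tail_matrix, color_matrix, {"a", "p"})
        assert q_sw.allclose(kron_sum_amalgamate([tail_matrix, color_matrix]))

    def test_empty_or_unknown_on_states_rejected(self, tail_matrix, color_matrix):
        with pytest.raises(ModelError):
            switch_amalgamate(tail_matrix, color_matrix, set())
        with pytest.raises(ModelError):
            switch_amalgamate(tail_matrix, color_matrix, {"zz"})

    def test_chained_switches_match_move_enumeration(self):
        """Tail -> armor -> color chain: the set of allowed single-step moves
        equals a brute-force enumeration respecting both switches."""
        tail = ElementaryCharacter("tail", ("a", "p"))
        armor = ElementaryCharacter("armor", ("n", "y"))
        color = ElementaryCharacter("color", ("r", "b"))
        graph = DependencyGraph(
            [tail, armor, color],
            [
                DependencyEdge("tail", "armor", "switch_on", {"p"}),
                DependencyEdge("armor", "color", "switch_on", {"y"}),
            ],
        )
        q, _ = build_from_dependency_graph(graph)
        assert q.n_states == 8

        def allowed(src, dst):
            diffs = [i for i in range(3) if src[i] != dst[i]]
            if len(diffs) != 1:
                return False
            i = diffs[0]
            if i == 1 and src[0] != "p":  # armor moves only with a tail
                return False
            if i == 2 and not (src[0] == "p" and src[1] == "y"):
                return False  # color moves only with armor on a tail
            return True

        for i, si in enumerate(q.states):
            for j, sj in enumerate(q.states):
                if i == j:
                    continue
                assert (q.rates[i, j] > 0) == allowed(si, sj), (si, sj)


class TestSynchronousAmalgamate:
    def test_redundant_binary_pair_collapses_to_color_matrix(self, color_matrix):
        """Red-present/blue-present redundant coding, after pruning the
        jointly impossible states, equals the plain two-state color matrix."""
        red = RateMatrix.from_offdiag(
            ("a_r", "p_r"),
            [[0.0, color_matrix["b", "r"]], [color_matrix["r", "b"], 0.0]],
        )
        blue = RateMatrix.from_offdiag(
            ("a_b", "p_b"),
            [[0.0, color_matrix["r", "b"]], [color_matrix["b", "r"], 0.0]],
        )
        q = synchronous_amalgamate(
            red, blue, [("a_r", "p_b"), ("p_r", "a_b")], sep="|"
        )
        assert q.n_states == 2
        # (p_r, a_b) is "red", (a_r, p_b) is "blue"
        assert q["p_r|a_b", "a_r|p_b"] == color_matrix["r", "b"]
        assert q["a_r|p_b", "p_r|a_b"] == color_matrix["b", "r"]

    def test_every_offdiagonal_changes_both_components(self):
        rng = np.random.default_rng(3)
        q1 = random_rate_matrix(rng, 3, ["x0", "x1", "x2"])
        q2 = random_rate_matrix(rng, 3, ["y0", "y1", "y2"])
        q = synchronous_amalgamate(
            q1, q2, [("x0", "y2"), ("x1", "y0"), ("x2", "y1")], sep="|"
        )
        for i, si in enumerate(q.states):
            for j, sj in enumerate(q.states):
                if i != j and q.rates[i, j] > 0:
                    a1, b1 = si.split("|")
                    a2, b2 = sj.split("|")
                    assert a1 != a2 and b1 != b2

    def test_retained_rates_are_submatrix_of_q1(self):
        rng = np.random.default_rng(4)
        q1 = random_rate_matrix(rng, 2, ["x0", "x1"])
        q2 = random_rate_matrix(rng, 2, ["y0", "y1"])
        q = synchronous_amalgamate(q1, q2, [("x0", "y1"), ("x1", "y0")], sep="|")
        assert q["x0|y1", "x1|y0"] == q1["x0", "x1"]
        assert q["x1|y0", "x0|y1"] == q1["x1", "x0"]

    def test_inconsistent_pairing_rejected(self):
        q1 = RateMatrix.binary(1, 1, ("x0", "x1"))
        q2 = RateMatrix.binary(1, 1, ("y0", "y1"))
        with pytest.raises(ModelError):
            synchronous_amalgamate(q1, q2, [("x0", "y0"), ("x0", "y1")])


class TestGeneralSMM:
    def test_four_states_have_twelve_free_cells(self):
        rng = np.random.default_rng(5)
        states = ["s1", "s2", "s3", "s4"]
        rates = {
            (a, b): rng.uniform(0.1, 1.0)
            for a in states
            for b in states
            if a != b
        }
        q = general_smm(states, rates)
        off = q.rates.copy()
        np.fill_diagonal(off, 0.0)
        assert (off > 0).sum() == 12

    def test_tied_to_independent_pattern_recovers_kron_sum(
        self, tail_matrix, color_matrix
    ):
        q_ind = kron_sum_amalgamate([tail_matrix, color_matrix])
        cells = {}
        for i, a in enumerate(q_ind.states):
            for j, b in enumerate(q_ind.states):
                if i != j and q_ind.rates[i, j] > 0:
                    cells[(a, b)] = q_ind.rates[i, j]
        assert general_smm(q_ind.states, cells).allclose(q_ind)

    def test_random_rates_never_lumpable_for_two_blocks(self):
        """All-rates-different violates the row-wise sum rule under every
        2-block partition of four states (exhaustive scan)."""
        rng = np.random.default_rng(6)
        states = ["s1", "s2", "s3", "s4"]
        q = general_smm(
            states,
            {
                (a, b): rng.uniform(0.5, 3.0)
                for a in states
                for b in states
                if a != b
            },
        )
        import itertools

        n_checked = 0
        for r in (1, 2):
            for block in itertools.combinations(states, r):
                rest = [s for s in states if s not in block]
                if not rest or (r == 2 and states.index(block[0]) != 0):
                    continue
                part = Partition.of([list(block), rest])
                ok, _ = is_strongly_lumpable(q, part)
                assert not ok, part
                n_checked += 1
        assert n_checked == 7  # all distinct 2-block partitions of 4 states

    def test_negative_rate_rejected(self):
        with pytest.raises(ModelError):
            general_smm(["a", "b"], {("a", "b"): -1.0})


class TestDependencyGraphBuilder:
    def test_tcp_graph_three_observable_four_hidden(self):
        graph = DependencyGraph(
            [
                ElementaryCharacter("tail", ("a", "p")),
                ElementaryCharacter("color", ("r", "b")),
            ],
            [DependencyEdge("tail", "color", "switch_on", {"p"})],
        )
        q, omap = build_from_dependency_graph(graph)
        assert q.n_states == 4
        assert set(omap.symbols) == {"a", "r", "b"}
        assert omap["a"] == frozenset({"ar", "ab"})

    def test_tail_armor_chain_four_observable_eight_hidden(self):
        graph = DependencyGraph(
            [
                ElementaryCharacter("tail", ("a", "p")),
                ElementaryCharacter("armor", ("n", "y")),
                ElementaryCharacter("color", ("r", "b")),
            ],
            [
                DependencyEdge("tail", "armor", "switch_on", {"p"}),
                DependencyEdge("armor", "color", "switch_on", {"y"}),
            ],
        )
        q, omap = build_from_dependency_graph(graph)
        assert q.n_states == 8
        assert len(omap.symbols) == 4
        assert omap["a"] == frozenset({"anr", "anb", "ayr", "ayb"})

    def test_edgeless_graph_is_plain_kron_sum_with_identity_map(
        self, tail_matrix, color_matrix
    ):
        graph = DependencyGraph(
            [
                ElementaryCharacter("tail", ("a", "p"), tuple(map(tuple, tail_matrix.rates))),
                ElementaryCharacter("color", ("r", "b"), tuple(map(tuple, color_matrix.rates))),
            ]
        )
        q, omap = build_from_dependency_graph(graph)
        assert q.allclose(kron_sum_amalgamate([tail_matrix, color_matrix]))
        assert all(len(omap[s]) == 1 for s in omap.symbols)

    def test_cyclic_graph_rejected(self):
        with pytest.raises(ModelError):
            DependencyGraph(
                [
                    ElementaryCharacter("x", ("0", "1")),
                    ElementaryCharacter("y", ("0", "1")),
                ],
                [
                    DependencyEdge("x", "y", "switch_on", {"1"}),
                    DependencyEdge("y", "x", "switch_on", {"1"}),
                ],
            )

    def test_json_round_trip(self):
        graph = DependencyGraph(
            [
                ElementaryCharacter("tail", ("a", "p")),
                ElementaryCharacter("color", ("r", "b")),
            ],
            [DependencyEdge("tail", "color", "switch_on", {"p"})],
        )
        back = DependencyGraph.from_json(graph.to_json())
        q1, m1 = build_from_dependency_graph(graph)
        q2, m2 = build_from_dependency_graph(back)
        assert q1.allclose(q2)
        assert m1.to_dict() == m2.to_dict()


class TestStructuralStats:
    @pytest.mark.parametrize(
        "n,omega", [(n, w) for n in range(1, 7) for w in (2, 3, 4) if w**n <= 1024]
    )
    def test_formulas_match_exhaustive_count(self, n, omega):
        stats = structural_stats(n, omega)
        comps = [
            RateMatrix.from_offdiag(
                [f"c{i}s{j}" for j in range(omega)],
                np.full((omega, omega), 1.0),
            )
            for i in range(n)
        ]
        q = kron_sum_amalgamate(comps, sep="|")
        assert count_structural_nonzeros(q) / q.n_states**2 == pytest.approx(
            stats.nonzero_proportion
        )

    def test_single_character_has_full_matrix(self):
        assert structural_stats(1, 3).nonzero_proportion == 1.0

    def test_secondary_diagonal_count_matches_pattern_scan(self):
        """n=2, omega=2: rates occupy exactly n(omega-1)=2 secondary diagonals."""
        q = kron_sum_amalgamate(
            [RateMatrix.binary(1, 1, ("a0", "a1")), RateMatrix.binary(1, 1, ("b0", "b1"))]
        )
        off = q.rates.copy()
        np.fill_diagonal(off, 0.0)
        offsets = {abs(i - j) for i, j in zip(*np.nonzero(off))}
        assert offsets == {1, 2}
        assert structural_stats(2, 2).n_secondary_diagonals == len(offsets)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 4), st.integers(2, 4))
def test_amalgam_rows_always_sum_to_zero(seed, k1, k2):
    rng = np.random.default_rng(seed)
    a = random_rate_matrix(rng, k1, [f"a{i}" for i in range(k1)])
    b = random_rate_matrix(rng, k2, [f"b{i}" for i in range(k2)])
    q = kron_sum_amalgamate([a, b], sep="|")
    assert np.abs(q.rates.sum(axis=1)).max() < 1e-12
    on = {a.states[i] for i in range(k1 - 1)}
    q_sw = switch_amalgamate(a, b, on, sep="|")
    assert np.abs(q_sw.rates.sum(axis=1)).max() < 1e-12
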