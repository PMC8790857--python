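import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgnet import (
    ConfirmedNetwork,
    DirectedValuedNetwork,
    DyadicReport,
    binarize,
    build_directed,
    confirm_binary,
    confirm_ordinal,
    get_layer,
)
from orgnet.errors import ValidationError

from conftest import make_roster
from oracles import random_ordinal_matrix

FREQ = get_layer("knowledge")


def directed(values, nonrespondents=(), layer=FREQ):
    nodes = tuple(f"ORG{k:02d}" for k in range(len(values)))
    return DirectedValuedNetwork(
        nodes, np.asarray(values), layer, frozenset(nonrespondents)
    )


class TestBuildDirected:
    def test_single_report(self):
        roster = make_roster(3)
        net = build_directed(
            [DyadicReport("ORG00", "ORG01", "policy", 3)], "policy", roster
        )
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 1] = 3
        assert np.array_equal(net.values, expected)

    def test_no_reports_zero_matrix(self):
        roster = make_roster(4)
        net = build_directed([], "policy", roster)
        assert not net.values.any()
        assert not net.missing_mask.any()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        roster = make_roster(8)
        ids = roster.ids
        reports = []
        for _ in range(20):
            i, j = rng.choice(8, size=2, replace=False)
            reports.append(
                DyadicReport(ids[i], ids[j], "knowledge", int(rng.integers(1, 5)))
            )
        net = build_directed(reports, "knowledge", roster)
        oracle = np.zeros((8, 8), dtype=int)
        for r in reports:
            for a, src in enumerate(ids):
                for b, tgt in enumerate(ids):
                    if r.source == src and r.target == tgt:
                        oracle[a, b] = max(oracle[a, b], r.value)
        assert np.array_equal(net.values, oracle)

    def test_nonrespondent_rows_flagged_missing(self):
        roster = make_roster(4, n_nonrespondents=1)
        net = build_directed([], "policy", roster)
        assert net.missing_mask[0, 1:].all()
        assert not net.missing_mask[1:, :].any()


class TestConfirmBinary:
    def test_unreciprocated_report_not_confirmed(self):
        values = [[0, 1], [0, 0]]
        net = confirm_binary(directed(values, layer=get_layer("overall")))
        assert not net.values.any()

    def test_mutual_reports_confirmed(self):
        values = [[0, 1], [1, 0]]
        net = confirm_binary(directed(values, layer=get_layer("overall")))
        assert net.values[0, 1] == net.values[1, 0] == 1

    def test_equals_transpose_and_oracle(self):
        rng = np.random.default_rng(3)
        m = (rng.random((12, 12)) < 0.4).astype(int)
        np.fill_diagonal(m, 0)
        net = confirm_binary(directed(m, layer=get_layer("overall")))
        assert np.array_equal(net.values, ((m > 0) & (m.T > 0)).astype(int))


class TestConfirmOrdinal:
    def test_often_vs_sometimes_confirms_sometimes(self):
        """A reports 'often' (3), B reports 'sometimes' (2): the
        confirmed frequency of contact is 'sometimes'."""
        values = [[0, 3], [2, 0]]
        net = confirm_ordinal(directed(values))
        assert net.values[0, 1] == net.values[1, 0] == 2

    def test_unreciprocated_very_often_confirms_nothing(self):
        values = [[0, 4], [0, 0]]
        net = confirm_ordinal(directed(values))
        assert not net.values.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_transpose_min_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_ordinal_matrix(10, 4, rng)
        net = confirm_ordinal(directed(m))
        assert np.array_equal(net.values, np.minimum(m, m.T))

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        m = random_ordinal_matrix(9, 4, rng)
        once = confirm_ordinal(directed(m))
        twice = confirm_ordinal(
            DirectedValuedNetwork(once.nodes, once.values, once.layer)
        )
        assert np.array_equal(once.values, twice.values)

    def test_commutes_with_node_permutation(self):
        rng = np.random.default_rng(6)
        m = random_ordinal_matrix(8, 4, rng)
        perm = rng.permutation(8)
        net = confirm_ordinal(directed(m))
        net_perm = confirm_ordinal(directed(m[np.ix_(perm, perm)]))
        assert np.array_equal(net_perm.values, net.values[np.ix_(perm, perm)])

    def test_dominance_and_binary_consistency(self):
        rng = np.random.default_rng(7)
        m = random_ordinal_matrix(10, 4, rng)
        conf = confirm_ordinal(directed(m))
        assert (conf.values <= m).all() and (conf.values <= m.T).all()
        via_binarize = binarize(conf, 1)
        via_binary = confirm_binary(directed(m))
        assert np.array_equal(via_binarize.values, via_binary.values)

    @given(st.integers(0, 2**31 - 1), st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raising_a_report_never_lowers_confirmed_values(self, seed, data):
        rng = np.random.default_rng(seed)
        m = random_ordinal_matrix(6, 4, rng)
        i = data.draw(st.integers(0, 5))
        j = data.draw(st.integers(0, 5).filter(lambda x: x != i))
        before = confirm_ordinal(directed(m)).values
        m2 = m.copy()
        m2[i, j] = min(4, m2[i, j] + 1)
        after = confirm_ordinal(directed(m2)).values
        assert (after >= before).all()


class TestMissingSides:
    def test_nonrespondent_dyads_unconfirmable_and_counted(self):
        # ORG00 did not respond; ORG01's report about it cannot confirm
        values = [[0, 0, 0], [3, 0, 2], [0, 2, 0]]
        net = confirm_ordinal(directed(values, nonrespondents={"ORG00"}),
                              node_policy="all-as-isolates")
        assert net.nodes == ("ORG00", "ORG01", "ORG02")
        assert net.values[0].sum() == 0 and net.values[:, 0].sum() == 0
        assert net.values[1, 2] == 2
        assert net.n_unconfirmable == 1

    def test_respondents_policy_drops_nonrespondents(self):
        values = [[0, 0, 0], [3, 0, 2], [0, 2, 0]]
        net = confirm_ordinal(directed(values, nonrespondents={"ORG00"}))
        assert net.nodes == ("ORG01", "ORG02")
        assert net.values[0, 1] == 2
        assert net.n_unconfirmable == 1


class TestBinarize:
    def test_threshold_one_keeps_all_positive_levels(self):
        vals = np.array([[0, 0], [0, 0]])
        net = ConfirmedNetwork(("A", "B"), vals, FREQ)
        for level in (1, 2, 3, 4):
            m = np.array([[0, level], [level, 0]])
            b = binarize(ConfirmedNetwork(("A", "B"), m, FREQ), 1)
            assert b.values[0, 1] == 1

    def test_top_threshold_keeps_only_very_often(self):
        m = np.zeros((5, 5), dtype=int)
        levels = [1, 2, 3, 4]
        for k, lv in enumerate(levels):
            m[k, 4] = m[4, k] = lv
        b = binarize(ConfirmedNetwork(tuple("ABCDE"), m, FREQ), 4)
        assert b.values.sum() == 2  # the single very-often dyad, both triangles

    def test_random_matrix_matches_comparison_oracle(self):
        rng = np.random.default_rng(9)
        m = random_ordinal_matrix(10, 4, rng)
        m = np.minimum(m, m.T)
        b = binarize(ConfirmedNetwork(tuple(f"N{k}" for k in range(10)), m, FREQ), 2)
        assert np.array_equal(b.values, (m >= 2).astype(int))

    def test_zero_threshold_rejected(self):
        m = np.zeros((3, 3), dtype=int)
        with pytest.raises(ValidationError):
            binarize(ConfirmedNetwork(("A", "B", "C"), m, FREQ), 0)
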