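"""Core estimators: joint tables, local (c)MI, lAIS/lTE/pAIS, bias
correction and surrogate testing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import infodyn as idy
from infodyn.errors import (
    DegenerateInputError,
    InputError,
    UndefinedLocalError,
)
from helpers_oracles import (
    brute_average_mi_from_samples,
    brute_predictive_locals,
)


class TestJointTable:
    def test_hand_enumerated_lagged_pairs(self):
        # series 0,1,0,1,0,1 with lag 1: the 5 valid pairs are
        # (1,0),(0,1),(1,0),(0,1),(1,0)
        s = idy.BinnedSeries(np.array([0, 1, 0, 1, 0, 1]))
        t = idy.build_joint_table([s], [(0, 1)], 0)
        assert t.probs[1, 0] == pytest.approx(3 / 5, abs=0)
        assert t.probs[0, 1] == pytest.approx(2 / 5, abs=0)
        assert t.probs[0, 0] == 0 and t.probs[1, 1] == 0
        assert t.n_samples == 5

    def test_independent_coins_near_uniform(self, rng):
        n = 100_000
        a = idy.BinnedSeries(rng.integers(0, 2, n))
        t = idy.build_joint_table([a, idy.BinnedSeries(rng.integers(0, 2, n))],
                                  [(1, 1)], 0)
        # each cell within 3 SD of 1/4
        sd = math.sqrt(0.25 * 0.75 / (n - 1))
        assert np.all(np.abs(t.probs - 0.25) < 3 * sd)

    def test_normalization_and_positivity(self, rng):
        s = [idy.BinnedSeries(rng.integers(0, 3, 77)) for _ in range(2)]
        t = idy.build_joint_table(s, [(0, 2), (1, 0), (1, 3)], 1)
        assert np.all(t.probs >= 0)
        assert t.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_errors(self, rng):
        a = idy.BinnedSeries(rng.integers(0, 2, 10))
        b = idy.BinnedSeries(rng.integers(0, 2, 11))
        with pytest.raises(InputError):
            idy.build_joint_table([a, b], [(1, 1)], 0)
        with pytest.raises(DegenerateInputError):
            idy.build_joint_table([a], [(0, 10)], 0)

    def test_json_round_trip(self, rng):
        s = idy.BinnedSeries(rng.integers(0, 2, 50))
        t = idy.build_joint_table([s], [(0, 1), (0, 2)], 0)
        t2 = idy.JointTable.from_json(t.to_json())
        assert t2.variable_names == t.variable_names
        np.testing.assert_array_equal(t2.probs, t.probs)


class TestLocalMI:
    TABLE = idy.JointTable(
        ("x", "y"), (2, 2), np.array([[0.4, 0.1], [0.1, 0.4]]), 1000
    )

    def test_hand_values(self):
        assert idy.local_mi(self.TABLE, 0, 0) == pytest.approx(
            math.log2(0.4 / 0.25), abs=1e-12
        )
        assert idy.local_mi(self.TABLE, 0, 1) == pytest.approx(
            math.log2(0.4), abs=1e-12
        )

    def test_independent_table_all_zero(self):
        t = idy.JointTable(
            ("x", "y"), (2, 2),
            np.outer([0.3, 0.7], [0.6, 0.4]), 100,
        )
        for x in range(2):
            for y in range(2):
                assert idy.local_mi(t, x, y) == pytest.approx(0.0, abs=1e-12)

    def test_weighted_average_equals_mi(self):
        avg = sum(
            self.TABLE.probs[x, y] * idy.local_mi(self.TABLE, x, y)
            for x in range(2)
            for y in range(2)
        )
        assert avg == pytest.approx(idy.average_mi(self.TABLE), abs=1e-12)
        assert avg == pytest.approx(0.2780719051126377, abs=1e-10)

    def test_unobserved_configuration_raises(self):
        t = idy.JointTable(("x", "y"), (2, 2),
                           np.array([[0.5, 0.0], [0.0, 0.5]]), 10)
        with pytest.raises(UndefinedLocalError):
            idy.local_mi(t, 0, 1)


class TestLocalCMI:
    def test_irrelevant_conditioning_variable(self, rng):
        # Z independent of (X, Y): i(x:y|z) == i(x:y) for every realization
        p_xy = np.array([[0.4, 0.1], [0.1, 0.4]])
        p = np.einsum("xy,z->xyz", p_xy, [0.5, 0.5])
        t3 = idy.JointTable(("x", "y", "z"), (2, 2, 2), p, 1000)
        t2 = idy.JointTable(("x", "y"), (2, 2), p_xy, 1000)
        for x in range(2):
            for y in range(2):
                for z in range(2):
                    assert idy.local_cmi(t3, x, y, (z,)) == pytest.approx(
                        idy.local_mi(t2, x, y), abs=1e-12
                    )

    def test_xor_conditioning_reveals_one_bit(self):
        # X, Y iid uniform, Z = X xor Y: i(x:y) = 0 but i(x:y|z) = 1 bit
        p = np.zeros((2, 2, 2))
        for x in range(2):
            for y in range(2):
                p[x, y, x ^ y] = 0.25
        t = idy.JointTable(("x", "y", "z"), (2, 2, 2), p, 1000)
        for x in range(2):
            for y in range(2):
                assert idy.local_cmi(t, x, y, (x ^ y,)) == pytest.approx(
                    1.0, abs=1e-12
                )
        t2 = idy.JointTable(("x", "y"), (2, 2), p.sum(axis=2), 1000)
        assert idy.average_mi(t2) == pytest.approx(0.0, abs=1e-12)

    def test_weighted_average_equals_chain_rule(self, rng):
        # E[i(x:y|z)] = I(X:Y,Z) - I(X:Z)
        p = rng.random((2, 3, 2))
        p /= p.sum()
        t = idy.JointTable(("x", "y", "z"), (2, 3, 2), p, 100)
        avg = sum(
            p[x, y, z] * idy.local_cmi(t, x, y, (z,))
            for x in range(2) for y in range(3) for z in range(2)
            if p[x, y, z] > 0
        )
        i_x_yz = idy.average_mi(t)  # var0 vs rest
        t_xz = idy.JointTable(("x", "z"), (2, 2), p.sum(axis=1), 100)
        assert avg == pytest.approx(i_x_yz - idy.average_mi(t_xz), abs=1e-12)


class TestLAIS:
    def test_iid_mean_near_zero(self, rng):
        x = idy.BinnedSeries(rng.integers(0, 2, 100_000))
        res = idy.lais(x, (1,))
        assert abs(res.mean) < 5e-4  # within plug-in bias of zero

    def test_deterministic_alternation_one_bit(self):
        # odd length makes the valid-window marginal exactly uniform
        x = idy.BinnedSeries(np.array([0, 1, 0, 1, 0]))
        res = idy.lais(x, (1,))
        np.testing.assert_allclose(res.values[res.valid], 1.0, atol=1e-12)
        assert not res.valid[0]

    def test_markov_chain_closed_form(self):
        # stay-probability 0.9: mean lAIS -> 1 - H_b(0.9)
        x = idy.simulate_markov_binary(1, np.array([0.1, 0.9]), 10**6, seed=7)
        res = idy.lais(x, (1,))
        h_b = -(0.9 * math.log2(0.9) + 0.1 * math.log2(0.1))
        assert res.mean == pytest.approx(1 - h_b, abs=0.01)

    def test_empty_embedding_warns_and_returns_zero(self, rng):
        x = idy.BinnedSeries(rng.integers(0, 2, 100))
        with pytest.warns(UserWarning, match="memoryless"):
            res = idy.lais(x, ())
        assert res.mean == 0.0
        assert np.all(res.values == 0)


class TestLTE:
    def test_copy_coupling_one_bit(self):
        from conftest import make_copy_pair

        x, y = make_copy_pair(100_000, 1, seed=3)
        res = idy.lte(x, y, (1,), (1,))
        # copy limit: exactly 1 bit in the infinite-data limit
        assert res.mean == pytest.approx(1.0, abs=0.02)
        assert np.all(np.abs(res.values[res.valid] - 1.0) < 0.01)

    def test_independent_near_zero(self, iid_pair):
        x, y = iid_pair
        assert abs(idy.lte(x, y, (1,), (1,)).mean) < 5e-3

    def test_xor_coupling_hidden_from_plain_mi(self, rng):
        n = 100_000
        xv = rng.integers(0, 2, n)
        yv = np.zeros(n, dtype=int)
        yv[1:] = np.bitwise_xor.accumulate(xv[:-1])  # y_t = x_{t-1} ^ y_{t-1}
        x, y = idy.BinnedSeries(xv), idy.BinnedSeries(yv)
        assert idy.lte(x, y, (1,), (1,)).mean == pytest.approx(1.0, abs=0.01)
        t = idy.build_joint_table([y, x], [(1, 1)], 0)
        assert idy.average_mi(t) < 1e-3

    def test_self_transfer_rejected(self, rng):
        x = idy.BinnedSeries(rng.integers(0, 2, 100))
        with pytest.raises(InputError):
            idy.lte(x, x, (1,), (1,))


class TestPAIS:
    def test_reduces_to_lais_without_extras(self, rng):
        x = idy.BinnedSeries(rng.integers(0, 2, 2000))
        a = idy.lais(x, (1, 2))
        b = idy.pais(x, [], [(1, 2)])
        np.testing.assert_array_equal(a.values[a.valid], b.values[b.valid])

    def test_copy_from_extra_source(self, rng):
        # s_t = n_{t-1}: own past useless, joint past fully predictive
        n = 50_000
        nv = rng.integers(0, 2, n)
        sv = np.roll(nv, 1)
        sv[0] = rng.integers(0, 2)
        s = idy.BinnedSeries(sv)
        extra = idy.BinnedSeries(nv)
        assert abs(idy.lais(s, (1,)).mean) < 5e-3
        assert idy.pais(s, [extra], [(1,), (1,)]).mean == pytest.approx(
            1.0, abs=0.02
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_under_added_sources(self, seed):
        rng = np.random.default_rng(seed)
        n = 3000
        s = idy.BinnedSeries(rng.integers(0, 2, n))
        extra = idy.BinnedSeries(rng.integers(0, 2, n))
        base = idy.lais(s, (1,)).mean
        joint = idy.pais(s, [extra], [(1,), (1,)]).mean
        assert joint >= base - 1e-12  # plug-in MI grows under refinement


class TestBiasCorrection:
    def test_correction_shrinks_independent_mi(self):
        # raw plug-in MI of an independent pair is positively biased
        raws, corrs = [], []
        for seed in range(200):
            r = np.random.default_rng(seed)
            a = idy.BinnedSeries(r.integers(0, 2, 500))
            t = idy.build_joint_table(
                [a, idy.BinnedSeries(r.integers(0, 2, 500))], [(1, 0)], 0
            )
            raws.append(idy.average_mi(t))
            corrs.append(idy.bias_corrected_mean(t, "mi"))
        assert abs(np.mean(corrs)) < abs(np.mean(raws))
        assert np.mean(raws) > 0

    def test_correction_vanishes_for_large_n(self):
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        small = idy.JointTable(("x", "y"), (2, 2), p, 100)
        big = idy.JointTable(("x", "y"), (2, 2), p, 10**9)
        mi = idy.average_mi(small)
        assert abs(idy.bias_corrected_mean(big, "mi") - mi) < 1e-8
        assert abs(idy.bias_corrected_mean(small, "mi") - mi) > 1e-4

    def test_single_occupied_cell_is_zero(self):
        p = np.zeros((2, 2))
        p[1, 1] = 1.0
        t = idy.JointTable(("x", "y"), (2, 2), p, 50)
        assert idy.bias_corrected_mean(t, "mi") == 0.0


class TestSurrogateTest:
    def test_perfect_coupling_minimal_p(self):
        from conftest import make_copy_pair

        x, y = make_copy_pair(5000, 1, seed=1)
        res = idy.surrogate_test(
            lambda xs: idy.lte(xs, y, (1,), (1,)).mean,
            x, n_perm=200, alpha=0.05, seed=0, min_shift=1,
        )
        assert res.p_value == pytest.approx(1 / 201)
        assert res.significant

    def test_determinism(self, iid_pair):
        x, y = iid_pair
        f = lambda xs: idy.lte(xs, y, (1,), (1,)).mean
        r1 = idy.surrogate_test(f, x, n_perm=50, seed=9)
        r2 = idy.surrogate_test(f, x, n_perm=50, seed=9)
        np.testing.assert_array_equal(r1.null_values, r2.null_values)

    def test_short_series_rejected(self):
        x = idy.BinnedSeries(np.array([0, 1, 0, 1]))
        with pytest.raises(DegenerateInputError):
            idy.surrogate_test(lambda s: 0.0, x, n_perm=10, min_shift=5)

    def test_fast_te_test_matches_p_bound(self):
        from conftest import make_copy_pair

        x, y = make_copy_pair(5000, 2, seed=4)
        res = idy.te_surrogate_test(x, y, (2,), (1,), n_perm=100, seed=0)
        assert res.p_value == pytest.approx(1 / 101)
        res2 = idy.ais_surrogate_test(
            idy.simulate_markov_binary(1, np.array([0.1, 0.9]), 5000, seed=0),
            (1,), n_perm=100, seed=0,
        )
        assert res2.significant


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    data=st.lists(st.integers(0, 1), min_size=8, max_size=60),
    lag=st.integers(1, 3),
)
def test_conservation_property(data, lag):
    """Mean of local AIS over valid samples equals the plug-in average MI
    between present and embedded past, for arbitrary binary series."""
    if len(set(data)) < 2 or len(data) <= lag:
        return
    x = idy.BinnedSeries(np.array(data))
    res = idy.lais(x, (lag,))
    _, brute_mean = brute_predictive_locals(data, (lag,))
    assert res.mean == pytest.approx(brute_mean, abs=1e-12)
    # averages are non-negative even though locals may not be
    t = idy.build_joint_table([x], [(0, lag)], 0)
    assert idy.average_mi(t) >= -1e-15


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_local_sign_freedom_average_nonnegative(seed):
    """Locals may be negative, their probability-weighted average never is."""
    rng = np.random.default_rng(seed)
    p = rng.random((2, 2))
    p /= p.sum()
    t = idy.JointTable(("x", "y"), (2, 2), p, 100)
    locs = [idy.local_mi(t, x, y) for x in range(2) for y in range(2)
            if p[x, y] > 0]
    avg = idy.average_mi(t)
    assert avg >= -1e-12
    assert min(locs) <= avg + 1e-12


def test_average_mi_matches_dict_oracle(rng):
    s = idy.BinnedSeries(rng.integers(0, 2, 500))
    t = idy.build_joint_table([s], [(0, 1), (0, 3)], 0)
    samples = [
        (s.values[i], (s.values[i - 1], s.values[i - 3]))
        for i in range(3, 500)
    ]
    assert idy.average_mi(t) == pytest.approx(
        brute_average_mi_from_samples(samples), abs=1e-12
    )
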