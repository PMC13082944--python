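"""Unit and property tests for the MCW test family."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hecpipe.mcw import (
    MCWConfig,
    bmcw_test,
    count_rearrangements,
    mbmcw_test,
    signed_ranks,
    umcw_test,
    umcw_test_many,
)
from oracles import (
    oracle_bmcw_subset,
    oracle_bmcw_whole,
    oracle_mbmcw,
    oracle_umcw,
)

finite_floats = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


@pytest.mark.parametrize(
    "diffs, expected",
    [
        ([3, -1, 0, 3], [2, -1, 0, 2]),
        ([0, 0, 0], [0, 0, 0]),
        ([5], [1]),
        ([-2, -2, -2], [-1, -1, -1]),
        ([1, 2, 3], [1, 2, 3]),
        ([0.5, -0.5, 2.0], [1, -1, 3]),
    ],
)
def test_signed_ranks_rules(diffs, expected):
    """Zeros rank 0; ties take the lowest would-be rank; signs follow the diff."""
    assert signed_ranks(diffs).tolist() == expected


def test_signed_ranks_rejects_non_finite():
    with pytest.raises(ValueError):
        signed_ranks([1.0, float("nan")])


@given(st.lists(finite_floats, min_size=1, max_size=20))
@settings(max_examples=200, deadline=None)
def test_signed_ranks_matches_oracle(diffs):
    from oracles import oracle_signed_ranks

    assert signed_ranks(diffs).tolist() == oracle_signed_ranks(diffs)


@pytest.mark.parametrize(
    "kind, sizes, expected",
    [
        ("umcw", {"n_a": 2, "n_b": 2}, 6),
        ("mbmcw", {"n_a": 3, "n_b": 2}, 10),
        ("bmcw_whole", {"n": 3}, 8),
        ("bmcw_subset", {"n": 5, "subset_size": 2}, 10),
    ],
)
def test_count_rearrangements(kind, sizes, expected):
    assert count_rearrangements(kind, **sizes) == expected


class TestUmcw:
    def test_complete_separation_gives_bi_one(self):
        assert umcw_test([2, 3], [0, 1]).bias_index == 1.0

    def test_symmetric_sets_give_bi_zero(self):
        assert umcw_test([1, 2], [1, 2]).bias_index == 0.0

    def test_identical_constant_sets(self):
        res = umcw_test([5.0, 5.0], [5.0, 5.0])
        assert res.bias_index == 0.0
        assert res.p_upper == 1.0 and res.p_lower == 1.0

    def test_worked_example_exact_path(self):
        res = umcw_test([3, 1], [2, 0])
        assert res.bias_index == pytest.approx(5 / 7)
        assert res.path == "exact"
        assert res.n_rearrangements_used == 6

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            umcw_test([], [1.0])

    @given(
        st.lists(finite_floats, min_size=1, max_size=4),
        st.lists(finite_floats, min_size=1, max_size=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_path_matches_exhaustive_oracle(self, a, b):
        res = umcw_test(a, b)
        bi, pu, pl, n = oracle_umcw(a, b)
        assert res.path == "exact"
        assert res.bias_index == pytest.approx(bi, abs=1e-12)
        assert res.p_upper == pytest.approx(pu, abs=1e-12)
        assert res.p_lower == pytest.approx(pl, abs=1e-12)
        assert res.n_rearrangements_used == n

    @given(
        st.lists(finite_floats, min_size=1, max_size=5),
        st.lists(finite_floats, min_size=1, max_size=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_and_bounds(self, a, b):
        fwd = umcw_test(a, b)
        rev = umcw_test(b, a)
        assert fwd.bias_index == pytest.approx(-rev.bias_index, abs=1e-12)
        assert -1.0 <= fwd.bias_index <= 1.0
        assert fwd.p_upper + fwd.p_lower >= 1.0 - 1e-12

    def test_monte_carlo_consistent_with_exact(self):
        """MC p-values converge to exact ones within binomial error."""
        rng = np.random.default_rng(7)
        a = rng.normal(0.8, 1, size=7).tolist()
        b = rng.normal(0, 1, size=7).tolist()
        exact = umcw_test(a, b, MCWConfig(max_rearrangements=100_000))
        assert exact.path == "exact"  # C(14,7) = 3432 enumerable
        n_draws = 2_000  # below C(14,7), forcing the Monte-Carlo path
        mc = umcw_test(a, b, MCWConfig(max_rearrangements=n_draws, seed=5))
        assert mc.path == "approximate"
        for p_mc, p_ex in [(mc.p_upper, exact.p_upper), (mc.p_lower, exact.p_lower)]:
            se = np.sqrt(p_ex * (1 - p_ex) / n_draws)
            assert abs(p_mc - p_ex) < 3 * se + 1e-9

    def test_seed_determinism(self):
        a = list(range(9))
        b = [x + 0.5 for x in range(9)]
        cfg = MCWConfig(max_rearrangements=500, seed=42)
        assert umcw_test(a, b, cfg) == umcw_test(a, b, cfg)
        other = umcw_test(a, b, MCWConfig(max_rearrangements=500, seed=43))
        assert other != umcw_test(a, b, cfg)


class TestMbmcw:
    def test_opposite_pair_sets_give_bi_one(self):
        res = mbmcw_test([(5, 1), (6, 1)], [(1, 5), (1, 6)])
        assert res.bias_index == 1.0

    def test_identical_sets_give_bi_zero(self):
        assert mbmcw_test([(2, 1), (3, 1)], [(2, 1), (3, 1)]).bias_index == 0.0

    def test_worked_example(self):
        res = mbmcw_test([(4, 1)], [(2, 1)])
        assert res.bias_index == pytest.approx(1 / 3)
        assert res.n_rearrangements_used == 2

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mbmcw_test([], [(1, 2)])

    @given(
        st.lists(st.tuples(finite_floats, finite_floats), min_size=1, max_size=4),
        st.lists(st.tuples(finite_floats, finite_floats), min_size=1, max_size=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_path_matches_exhaustive_oracle(self, x, y):
        res = mbmcw_test(x, y)
        bi, pu, pl, n = oracle_mbmcw(x, y)
        assert res.bias_index == pytest.approx(bi, abs=1e-12)
        assert res.p_upper == pytest.approx(pu, abs=1e-12)
        assert res.p_lower == pytest.approx(pl, abs=1e-12)

    @given(
        st.lists(st.tuples(finite_floats, finite_floats), min_size=1, max_size=4),
        st.lists(st.tuples(finite_floats, finite_floats), min_size=1, max_size=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_swap_symmetry(self, x, y):
        assert mbmcw_test(x, y).bias_index == pytest.approx(
            -mbmcw_test(y, x).bias_index, abs=1e-12
        )


class TestBmcw:
    def test_all_positive_gives_wbi_one(self):
        res = bmcw_test([0.1, 0.5, 2.0])
        assert res.whole_set.bias_index == 1.0

    def test_antisymmetric_values_give_wbi_zero(self):
        assert bmcw_test([0.7, -0.7]).whole_set.bias_index == 0.0

    def test_worked_example(self):
        res = bmcw_test([0.5, -0.2, 0.9], subsets={"s": [0, 2]})
        assert res.whole_set.bias_index == pytest.approx(4 / 6)
        assert res.per_subset["s"].bias_index == pytest.approx(1.0)

    def test_subset_by_element_ids(self):
        res = bmcw_test(
            [0.5, -0.2, 0.9], subsets={"s": ["e1", "e3"]},
            element_ids=["e1", "e2", "e3"],
        )
        assert res.per_subset["s"].bias_index == pytest.approx(1.0)

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError):
            bmcw_test([1.0, 2.0], subsets={"s": [0, 1, 0]})

    @given(st.lists(finite_floats, min_size=1, max_size=10), st.data())
    @settings(max_examples=80, deadline=None)
    def test_exact_paths_match_exhaustive_oracles(self, values, data):
        k = data.draw(st.integers(1, len(values)))
        subset = sorted(
            data.draw(
                st.sets(st.integers(0, len(values) - 1), min_size=k, max_size=k)
            )
        )
        res = bmcw_test(values, subsets={"s": subset}, config=MCWConfig(100_000))
        wbi, wpu, wpl, _ = oracle_bmcw_whole(values)
        sbi, spu, spl, _ = oracle_bmcw_subset(values, subset)
        assert res.whole_set.bias_index == pytest.approx(wbi, abs=1e-12)
        assert res.whole_set.p_upper == pytest.approx(wpu, abs=1e-12)
        assert res.whole_set.p_lower == pytest.approx(wpl, abs=1e-12)
        assert res.per_subset["s"].bias_index == pytest.approx(sbi, abs=1e-12)
        assert res.per_subset["s"].p_upper == pytest.approx(spu, abs=1e-12)
        assert res.per_subset["s"].p_lower == pytest.approx(spl, abs=1e-12)

    def test_monte_carlo_paths_deterministic_under_seed(self):
        values = np.linspace(-1, 1, 20).tolist()
        cfg = MCWConfig(max_rearrangements=2000, seed=3)
        r1 = bmcw_test(values, subsets={"s": list(range(8))}, config=cfg)
        r2 = bmcw_test(values, subsets={"s": list(range(8))}, config=cfg)
        assert r1.whole_set == r2.whole_set
        assert r1.per_subset["s"] == r2.per_subset["s"]
        assert r1.whole_set.path == "approximate"


def test_umcw_test_many_agrees_with_scalar_tests():
    """The vectorised per-gene path must reproduce one-at-a-time results."""
    rng = np.random.default_rng(0)
    a = rng.poisson(50, size=(12, 5)).astype(float)
    b = rng.poisson(40, size=(12, 5)).astype(float)
    bi, pu, pl, path = umcw_test_many(a, b)
    assert path == "exact"
    for g in range(12):
        res = umcw_test(a[g], b[g])
        assert bi[g] == pytest.approx(res.bias_index, abs=1e-12)
        assert pu[g] == pytest.approx(res.p_upper, abs=1e-12)
        assert pl[g] == pytest.approx(res.p_lower, abs=1e-12)
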