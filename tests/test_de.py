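"""Exact two-library test, normalization, fold-change and the DE caller."""

from math import factorial

import numpy as np
import pytest
from scipy import stats

from srnakit.de import (
    ac_point_mass,
    ac_tail_lower,
    ac_tail_upper,
    call_differential,
    ddct,
    exact_p,
    filter_low,
    fold_change,
    normalize,
)
from srnakit.simulate import simulate_counts


class TestNormalize:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(50, 10_000_000, 5.0), (0, 12345, 0.01), (777, 777, 1_000_000.0)],
    )
    def test_values(self, count, total, expected):
        assert normalize(count, total) == pytest.approx(expected)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            normalize(1, 0)


class TestFilterAndFoldChange:
    @pytest.mark.parametrize(
        "ne_a, ne_b, keep",
        [(0.5, 0.9, False), (0.5, 3.0, True), (1.0, 0.01, True)],
    )
    def test_low_expression_filter(self, ne_a, ne_b, keep):
        assert filter_low(ne_a, ne_b) is keep

    @pytest.mark.parametrize(
        "ne_a, ne_b, expected",
        [(20, 5, 2.0), (5, 20, -2.0), (10, 0.01, np.log2(1000))],
    )
    def test_fold_change(self, ne_a, ne_b, expected):
        assert fold_change(ne_a, ne_b) == pytest.approx(expected, abs=1e-3)


class TestExactTest:
    def test_point_mass_against_factorial_oracle(self):
        # brute-force factorial evaluation is exact for x + y <= 20
        for n1, n2 in [(10_000, 5_000), (7_000, 7_000), (5_000, 10_000)]:
            r = n2 / n1
            for x in range(0, 21):
                for y in range(0, 21 - x):
                    oracle = (
                        r**y
                        * factorial(x + y)
                        / (factorial(x) * factorial(y) * (1 + r) ** (x + y + 1))
                    )
                    assert ac_point_mass(x, y, n1, n2) == pytest.approx(
                        oracle, abs=1e-12
                    )

    def test_point_mass_examples(self):
        assert ac_point_mass(0, 0, 1000, 1000) == pytest.approx(0.5, abs=1e-12)
        # C(10,5)/2^11 by direct evaluation
        assert ac_point_mass(5, 5, 1000, 1000) == pytest.approx(0.123047, abs=1e-6)

    def test_upper_tail_geometric_series(self):
        # x=0, N1=N2: p(y|0) = 2^-(y+1), so D(y>=1) = 0.5
        assert ac_tail_upper(0, 1, 5000, 5000) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("ratio", [(2000, 1000), (1000, 1000), (1000, 2000)])
    @pytest.mark.parametrize("x", [0, 3, 17, 50])
    def test_distribution_normalizes(self, ratio, x):
        n1, n2 = ratio
        total = sum(ac_point_mass(x, y, n1, n2) for y in range(0, 4000))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_negative_binomial_oracle(self):
        # p(y|x) is NB(x+1, N1/(N1+N2)) in y: an independent scipy route
        for n1, n2 in [(3000, 1000), (1000, 3000)]:
            p_success = n1 / (n1 + n2)
            for x in [0, 2, 9]:
                for y in [0, 1, 5, 20]:
                    assert ac_point_mass(x, y, n1, n2) == pytest.approx(
                        stats.nbinom.pmf(y, x + 1, p_success), abs=1e-12
                    )

    def test_tail_equals_point_mass_summation(self):
        # the beta-function tail must agree with direct summation of the
        # (factorial-verified) point masses
        for n1, n2 in [(3000, 1000), (2000, 2000), (1000, 3000)]:
            for x in [0, 2, 9, 40]:
                for y in [0, 1, 5, 20, 100]:
                    direct = sum(ac_point_mass(x, k, n1, n2) for k in range(y + 1))
                    assert ac_tail_lower(x, y, n1, n2) == pytest.approx(
                        direct, abs=1e-10
                    )

    def test_symmetry_under_library_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x, y = (int(v) for v in rng.integers(0, 300, 2))
            n1, n2 = (int(v) for v in rng.integers(1_000, 100_000, 2))
            assert exact_p(x, y, n1, n2) == pytest.approx(
                exact_p(y, x, n2, n1), abs=1e-12
            )

    def test_upper_tail_monotone_in_threshold(self):
        x, n = 10, 10_000
        tails = [ac_tail_upper(x, k, n, n) for k in range(0, 40)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            exact_p(-1, 0, 100, 100)


class TestCallDifferential:
    def test_equal_counts_not_significant(self):
        df = call_differential([("m1", 500, 500)], 100_000, 100_000)
        row = df.iloc[0]
        assert row["log2fc"] == 0.0 and not row["significant"]

    def test_low_expression_removed(self):
        # 1 read in 10M is NE 0.1 < 1 in both libraries
        df = call_differential([("m1", 1, 1)], 10_000_000, 10_000_000)
        assert df.empty

    def test_alpha_one_degeneracy(self):
        df = call_differential(
            [("m1", 400, 100), ("m2", 300, 290)], 100_000, 100_000, alpha=1.0
        )
        by_id = df.set_index("mirna_id")
        assert bool(by_id.loc["m1", "significant"])  # |lfc|=2
        assert not bool(by_id.loc["m2", "significant"])  # |lfc|<1

    def test_direction_labels(self):
        df = call_differential(
            [("up_a", 800, 100), ("up_b", 100, 800)], 100_000, 100_000
        )
        by_id = df.set_index("mirna_id")
        assert by_id.loc["up_a", "direction"] == "up_in_A"
        assert by_id.loc["up_b", "direction"] == "up_in_B"

    def test_sorted_by_p(self):
        df = call_differential(
            [("a", 500, 500), ("b", 900, 100), ("c", 520, 480)],
            100_000, 100_000,
        )
        assert list(df["p"]) == sorted(df["p"])

    def test_null_simulation_type_one_error(self):
        rejected, total = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            base = rng.lognormal(0, 1.5, 200)
            x, y = simulate_counts(base, 100_000, rng=rng)
            df = call_differential(
                [(f"m{i}", int(x[i]), int(y[i])) for i in range(200)],
                100_000, 100_000,
            )
            rejected += int((df["p"] < 0.05).sum())
            total += len(df)
        assert 0.02 <= rejected / total <= 0.08

    def test_planted_effect_recovered_with_direction(self):
        rng = np.random.default_rng(7)
        base = np.full(50, 1.0)
        lfc = np.zeros(50)
        lfc[0] = 2.0  # up in condition B
        x, y = simulate_counts(base, 100_000, lfc, rng=rng)
        df = call_differential(
            [(f"m{i}", int(x[i]), int(y[i])) for i in range(50)], 100_000, 100_000
        )
        row = df.set_index("mirna_id").loc["m0"]
        assert row["significant"] and row["direction"] == "up_in_B"


class TestDdct:
    @pytest.mark.parametrize(
        "ct_mirna, ct_ref, calib, expected",
        [(25.0, 20.0, 5.0, 1.0), (26.0, 20.0, 5.0, 0.5), (23.0, 20.0, 5.0, 4.0)],
    )
    def test_relative_expression(self, ct_mirna, ct_ref, calib, expected):
        assert ddct(ct_mirna, ct_ref, calib) == pytest.approx(expected)
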