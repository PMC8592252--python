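from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirnakit.diffexpr import (
    benjamini_hochberg,
    call_status,
    de_test_binomial,
    de_test_fisher,
    differential_expression,
    expression_floor,
    log2_ratio,
    set_intersections,
    tpm_normalize,
)
from sirnakit.utils import COMPARISONS


def exact_binomial_oracle(kt, kc, st_, sc):
    """Minlike two-sided binomial test with exact rational arithmetic."""
    k = kt + kc
    if k == 0:
        return 1.0
    p = Fraction(st_, st_ + sc)
    pmf = [comb(k, x) * p**x * (1 - p) ** (k - x) for x in range(k + 1)]
    obs = pmf[kt]
    return float(sum(q for q in pmf if q <= obs))


class TestTpmNormalize:
    def test_basic_value(self):
        tpm = tpm_normalize(np.array([[5]]), np.array([10]))
        assert tpm[0, 0] == pytest.approx(500_000.0)

    def test_all_zero_row(self):
        tpm = tpm_normalize(np.zeros((3, 4)), np.full(4, 100.0))
        assert np.all(tpm == 0)

    def test_zero_library_size_raises(self):
        with pytest.raises(ValueError):
            tpm_normalize(np.ones((2, 4)), np.array([10, 0, 10, 10]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_column_sums_are_1e6(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.integers(0, 1000, size=(50, 4)).astype(float)
        raw[0] += 1  # avoid an all-zero library
        sizes = raw.sum(axis=0)
        tpm = tpm_normalize(raw, sizes)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)


class TestExpressionFloor:
    def test_all_below_excluded(self):
        mask = expression_floor(np.array([[29.9, 29.9, 29.9, 29.9]]))
        assert not mask[0]

    def test_boundary_inclusive_keep(self):
        mask = expression_floor(np.array([[30.0, 0, 0, 0]]))
        assert mask[0]

    def test_empty_input(self):
        assert expression_floor(np.empty((0, 4))).tolist() == []


class TestDeTestBinomial:
    def test_both_zero_convention(self):
        assert de_test_binomial(0, 0, 100, 100) == 1.0

    def test_modal_outcome_p_is_one(self):
        assert de_test_binomial(10, 10, 1000, 1000) == pytest.approx(1.0, abs=1e-12)

    def test_extreme_outcome_equal_sizes(self):
        # enumeration of Binomial(20, 1/2): only outcomes 0 and 20 are as
        # unlikely as the observed one
        expected = exact_binomial_oracle(20, 0, 1000, 1000)
        assert expected == pytest.approx(2 * 0.5**20)
        assert de_test_binomial(20, 0, 1000, 1000) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("kt,kc,st_,sc", [
        (3, 9, 100, 100), (0, 7, 50, 150), (12, 12, 300, 100),
        (1, 0, 100, 100), (25, 5, 500, 400), (2, 30, 1000, 2000),
    ])
    def test_matches_exact_enumeration_oracle(self, kt, kc, st_, sc):
        assert de_test_binomial(kt, kc, st_, sc) == pytest.approx(
            exact_binomial_oracle(kt, kc, st_, sc), rel=1e-9
        )

    def test_symmetry_in_swap(self):
        p1 = de_test_binomial(8, 21, 120, 90)
        p2 = de_test_binomial(21, 8, 90, 120)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            de_test_binomial(-1, 0, 1, 1)
        with pytest.raises(ValueError):
            de_test_binomial(1, 1, 0, 1)


def test_fisher_alternative_behaves():
    assert de_test_fisher(0, 0, 100, 100) == 1.0
    # strong imbalance is significant under both tests
    assert de_test_fisher(100, 5, 10_000, 10_000) < 0.001
    assert de_test_binomial(100, 5, 10_000, 10_000) < 0.001


class TestCallStatus:
    def test_clear_up(self):
        assert call_status(log2_ratio(100, 25), 0.001) == "up"

    def test_lfc_boundary_is_inclusive_ge(self):
        assert call_status(0.99, 0.001) == "ns"
        assert call_status(1.0, 0.001) == "up"

    def test_p_boundary_is_strict(self):
        assert call_status(3.0, 0.05) == "ns"
        assert call_status(3.0, 0.049) == "up"

    def test_down(self):
        assert call_status(-1.5, 0.01) == "down"


def test_log2_ratio_symmetry():
    rng = np.random.default_rng(8)
    for _ in range(50):
        a, b = rng.uniform(0, 500, 2)
        assert log2_ratio(a, b) == pytest.approx(-log2_ratio(b, a), abs=1e-12)


def test_null_calibration_binomial():
    # equal-rate Poisson counts, equal sizes: rejection rate at 0.05 stays
    # at or below 0.06 (exact test is conservative)
    rng = np.random.default_rng(2026)
    n_reject = 0
    reps = 2000
    for _ in range(reps):
        kt, kc = rng.poisson(50, size=2)
        if de_test_binomial(int(kt), int(kc), 100_000, 100_000) < 0.05:
            n_reject += 1
    assert n_reject / reps <= 0.06


class TestSetIntersections:
    def test_hand_enumeration(self):
        report = set_intersections(
            {"1h": {"a", "b"}, "6h": {"b", "c"}, "12h": {"b"}}
        )
        assert report.common == 1
        assert report.regions["100"] == 1  # a
        assert report.regions["010"] == 1  # c
        assert report.regions["110"] == 0
        assert report.union == 3

    def test_identical_sets(self):
        s = {"x", "y", "z"}
        report = set_intersections({c: set(s) for c in COMPARISONS})
        assert report.common == 3
        assert report.union == 3
        assert sum(v for k, v in report.regions.items() if k != "111") == 0

    def test_totals_cover_regions(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(100)]
        sets = {
            c: {i for i in ids if rng.random() < 0.4} for c in COMPARISONS
        }
        report = set_intersections(sets)
        # set total = sum of its 4 covering regions
        for pos, comp in enumerate(COMPARISONS):
            covering = sum(
                v for k, v in report.regions.items() if k[pos] == "1"
            )
            assert covering == report.totals[comp]

    def test_random_sets_match_bit_signature_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            ids = [f"s{i}" for i in range(int(rng.integers(1, 100)))]
            sets = {c: {i for i in ids if rng.random() < 0.5}
                    for c in COMPARISONS}
            report = set_intersections(sets)
            oracle = {}
            for i in ids:
                sig = "".join("1" if i in sets[c] else "0" for c in COMPARISONS)
                if sig != "000":
                    oracle[sig] = oracle.get(sig, 0) + 1
            for sig, count in report.regions.items():
                assert count == oracle.get(sig, 0)


class TestDifferentialExpression:
    def test_swap_symmetry_of_status(self):
        # swapping treatment/control flips direction at equal sizes
        raw = np.array([[10, 100, 100, 100], [100, 10, 10, 10]])
        sizes = np.full(4, 10_000.0)
        table = differential_expression(["s1", "s2"], raw, sizes, floor=0.0)
        assert table.loc[0, "status_1h"] == "up"
        assert table.loc[1, "status_1h"] == "down"
        assert table.loc[0, "p_1h"] == pytest.approx(table.loc[1, "p_1h"], rel=1e-12)

    def test_floor_removes_low_records(self):
        raw = np.array([[1, 1, 1, 1], [500, 500, 500, 500]])
        sizes = np.full(4, 1_000_000.0)
        table = differential_expression(["lo", "hi"], raw, sizes, floor=30.0)
        assert table["sirna_id"].tolist() == ["hi"]

    def test_planted_direction_recovery(self, small_pipeline, small_truth):
        truth_by_pos = {(r.chrom, *r.plus_interval): r for r in small_truth}
        pos = {
            s.sirna_id: (s.chrom, s.plus_hit.start, s.plus_hit.end)
            for s in small_pipeline.sirnas
        }
        table = small_pipeline.de_table
        correct = wrong = 0
        for _, row in table.iterrows():
            rec = truth_by_pos.get(pos[row["sirna_id"]])
            if rec is None:
                continue
            for comp in COMPARISONS:
                want = rec.planted_status[comp]
                got = row[f"status_{comp}"]
                if want in ("up", "down"):
                    correct += got == want
                    wrong += got != want
                elif got != "ns":
                    wrong += 1
        assert correct / (correct + wrong) >= 0.9


class TestBenjaminiHochberg:
    def test_single_value_unchanged(self):
        assert benjamini_hochberg(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_hand_stepup(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 40)
        assert np.all(benjamini_hochberg(p) >= p - 1e-15)
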