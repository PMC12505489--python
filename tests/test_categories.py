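import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldlkit import (
    CLINICAL_CATEGORY_LABELS,
    TG_STRATUM_LABELS,
    CrossTab,
    assign_clinical_category,
    assign_tg_stratum,
    category_crosstab,
    cohen_kappa,
    kappa_strength,
    percent_difference,
    stratified_difference_summary,
)
from ldlkit.categories import (
    EmptyCrossTabError,
    ExcludedTgError,
    UndefinedDifferenceError,
    UndefinedKappaError,
    category_label,
    tg_stratum_label,
)
from ldlkit.units import InvalidInputError


def kappa_bruteforce(counts):
    """Explicit double-loop kappa oracle, independent of the implementation."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.shape[0]
    p_o = sum(counts[i, i] for i in range(k)) / n
    p_e = 0.0
    for i in range(k):
        row = sum(counts[i, j] for j in range(k))
        col = sum(counts[j, i] for j in range(k))
        p_e += row * col / n**2
    return (p_o - p_e) / (1 - p_e)


class TestClinicalCategory:
    @pytest.mark.parametrize(
        "ldl,expected",
        [
            (1.80, 1), (1.81, 2), (2.56, 2), (2.57, 3), (3.34, 3), (3.35, 4),
            (4.11, 4), (4.12, 5), (4.89, 5), (4.90, 6), (10.0, 6), (0.0, 1),
        ],
    )
    def test_boundaries(self, ldl, expected):
        assert assign_clinical_category(ldl) == expected

    def test_negative_maps_to_lowest(self):
        assert assign_clinical_category(-0.3) == 1

    def test_absent_scalar_raises(self):
        with pytest.raises(InvalidInputError):
            assign_clinical_category(float("nan"))

    def test_absent_vector_unclassified(self):
        out = assign_clinical_category(np.array([1.0, np.nan]))
        assert list(out) == [1, 0]

    def test_labels(self):
        assert category_label(1) == "<1.81"
        assert category_label(6) == ">=4.90"

    def test_partition_over_dense_grid(self):
        grid = np.concatenate(
            [np.linspace(0, 12, 5001), [1.81, 2.57, 3.35, 4.12, 4.90]]
        )
        cats = assign_clinical_category(grid)
        assert np.all((cats >= 1) & (cats <= 6))
        # order-preserving: sorted inputs give nondecreasing categories
        order = np.argsort(grid)
        assert np.all(np.diff(cats[order]) >= 0)


class TestTgStratum:
    @pytest.mark.parametrize(
        "tg,expected_label",
        [
            (0.40, "<0.57"), (0.96, "0.57-1.12"), (1.13, "1.13-1.68"),
            (4.52, "4.52-9.04"), (9.04, "4.52-9.04"),
        ],
    )
    def test_assignments(self, tg, expected_label):
        assert tg_stratum_label(assign_tg_stratum(tg)) == expected_label

    def test_above_904_excluded(self):
        with pytest.raises(ExcludedTgError):
            assign_tg_stratum(9.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            assign_tg_stratum(0.0)

    def test_partition_over_dense_grid(self):
        grid = np.concatenate(
            [
                np.linspace(0.001, 9.04, 5001),
                [0.57, 1.13, 1.69, 2.26, 2.82, 3.39, 3.95, 4.52, 9.04],
            ]
        )
        strata = assign_tg_stratum(grid)
        assert np.all((strata >= 1) & (strata <= 9))
        order = np.argsort(grid)
        assert np.all(np.diff(strata[order]) >= 0)


class TestPercentDifference:
    def test_equal(self):
        assert percent_difference(2.0, 2.0) == 0.0

    def test_arithmetic(self):
        assert percent_difference(2.2, 2.0) == pytest.approx(10.0, abs=1e-12)

    def test_sign_convention(self):
        assert percent_difference(1.9, 2.0) == pytest.approx(-5.0, abs=1e-12)

    def test_zero_denominator(self):
        with pytest.raises(UndefinedDifferenceError):
            percent_difference(1.0, 0.0)

    @given(a=st.floats(0.1, 100), b=st.floats(0.1, 100))
    @settings(max_examples=200, deadline=None)
    def test_algebraic_identity(self, a, b):
        # pd(a,b) = -pd(b,a) * a/b
        lhs = percent_difference(a, b)
        rhs = -percent_difference(b, a) * a / b
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


def _records(tg, a, b, names=("ldl_a", "ldl_b")):
    return pd.DataFrame({"tg": tg, names[0]: a, names[1]: b})


class TestStratifiedSummary:
    def test_identical_estimates(self):
        df = _records([0.4, 0.8, 2.0], [2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        out = stratified_difference_summary(df, ("ldl_a", "ldl_b"))
        nonempty = out[out["n"] > 0]
        assert np.all(nonempty["median"] == 0.0)
        assert nonempty["p"].isna().all()  # degenerate test

    def test_hand_built_stratum(self):
        # three records in one stratum with differences {-5, 0, 10} %
        b = np.array([2.0, 2.0, 2.0])
        a = b * np.array([0.95, 1.0, 1.10])
        out = stratified_difference_summary(_records([0.3] * 3, a, b), ("ldl_a", "ldl_b"))
        row = out[out["stratum"] == 1].iloc[0]
        assert row["n"] == 3
        assert row["median"] == pytest.approx(0.0, abs=1e-12)
        # linear-interpolation quartiles of {-5, 0, 10}: Q1=-2.5, Q3=5.0
        assert row["iqr"] == pytest.approx(7.5, abs=1e-9)

    def test_empty_strata_emitted(self):
        df = _records([0.4], [2.0], [2.1])
        out = stratified_difference_summary(df, ("ldl_a", "ldl_b"))
        assert len(out) == 9
        assert list(out["stratum_label"]) == list(TG_STRATUM_LABELS)
        empty = out[out["n"] == 0]
        assert empty["median"].isna().all()

    def test_pairwise_exclusion_of_absent(self):
        df = _records([0.4, 0.4], [2.0, np.nan], [2.2, 2.2])
        out = stratified_difference_summary(df, ("ldl_a", "ldl_b"))
        assert out[out["stratum"] == 1].iloc[0]["n"] == 1

    def test_resolves_short_names(self):
        df = pd.DataFrame({"tg": [0.4], "ldl_ff": [2.0], "ldl_mh": [2.1]})
        out = stratified_difference_summary(df, ("ff", "mh"))
        assert out[out["stratum"] == 1].iloc[0]["n"] == 1


class TestCrossTab:
    def test_diagonal_only(self):
        df = pd.DataFrame(
            {"tg": [2.0] * 10, "ldl_a": [1.0] * 10, "ldl_b": [1.5] * 10}
        )
        ct = category_crosstab(df, "ldl_a", "ldl_b")
        assert ct.counts[0, 0] == 10
        assert ct.n == 10

    def test_hand_built_six_records(self):
        a = [1.0, 1.9, 2.6, 3.4, 4.2, 5.0]  # categories 1..6
        b = [1.9, 1.9, 2.6, 3.4, 4.2, 5.0]  # first reclassified up
        df = pd.DataFrame({"tg": [2.0] * 6, "ldl_a": a, "ldl_b": b})
        ct = category_crosstab(df, "ldl_a", "ldl_b")
        expected = np.zeros((6, 6), dtype=int)
        expected[0, 1] = 1
        for i in range(1, 6):
            expected[i, i] = 1
        np.testing.assert_array_equal(ct.counts, expected)

    def test_window_restriction(self):
        df = pd.DataFrame(
            {"tg": [1.0, 1.69, 4.51, 5.0], "ldl_a": [2.0] * 4, "ldl_b": [2.0] * 4}
        )
        ct = category_crosstab(df, "ldl_a", "ldl_b", tg_window=(1.69, 4.51))
        assert ct.n == 2  # closed window

    def test_empty_raises(self):
        df = pd.DataFrame({"tg": [0.5], "ldl_a": [np.nan], "ldl_b": [2.0]})
        with pytest.raises(EmptyCrossTabError):
            category_crosstab(df, "ldl_a", "ldl_b", tg_window=None)

    def test_row_percentages_sum_to_100(self, rng):
        counts = rng.integers(0, 50, size=(6, 6))
        counts[2] = 0  # an empty row stays NaN
        ct = CrossTab(counts)
        pct = ct.row_percentages()
        sums = np.nansum(pct, axis=1)
        nonempty = counts.sum(axis=1) > 0
        np.testing.assert_allclose(sums[nonempty], 100.0, atol=1e-9)
        assert np.all(np.isnan(pct[~nonempty]))

    def test_frame_round_trip(self):
        ct = CrossTab(np.arange(36).reshape(6, 6))
        back = CrossTab.from_frame(ct.to_frame())
        np.testing.assert_array_equal(back.counts, ct.counts)


class TestCohenKappa:
    def test_perfect_agreement(self):
        ct = CrossTab(np.diag([5, 3, 2, 1, 1, 1]))
        res = cohen_kappa(ct)
        assert res.kappa == pytest.approx(1.0, abs=1e-12)
        assert res.p_o == 1.0

    def test_hand_2x2(self):
        ct = CrossTab(np.array([[20, 5], [10, 15]]), labels=("x", "y"))
        res = cohen_kappa(ct)
        assert res.p_o == pytest.approx(0.70, abs=1e-12)
        assert res.p_e == pytest.approx(0.50, abs=1e-12)
        assert res.kappa == pytest.approx(0.40, abs=1e-12)

    def test_margin_product_table_gives_zero(self):
        # counts proportional to the product of the margins -> p_o == p_e
        ct = CrossTab(np.array([[1, 2], [2, 4]]), labels=("x", "y"))
        assert cohen_kappa(ct).kappa == pytest.approx(0.0, abs=1e-12)

    def test_bruteforce_oracle_500_random_tables(self, rng):
        for _ in range(500):
            k = int(rng.integers(2, 7))
            counts = rng.integers(0, 30, size=(k, k))
            counts[0, 0] += 1  # avoid fully empty tables
            ct = CrossTab(counts, labels=tuple(str(i) for i in range(k)))
            try:
                res = cohen_kappa(ct)
            except UndefinedKappaError:
                continue
            assert res.kappa == pytest.approx(kappa_bruteforce(counts), abs=1e-12)

    def test_sklearn_cross_check(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, 300)
        b = np.where(rng.random(300) < 0.7, a, rng.integers(0, 4, 300))
        counts = np.zeros((4, 4), dtype=int)
        np.add.at(counts, (a, b), 1)
        ours = cohen_kappa(CrossTab(counts, labels=("0", "1", "2", "3"))).kappa
        theirs = sklearn_metrics.cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_invariant_to_count_scaling(self, rng):
        counts = rng.integers(1, 20, size=(4, 4))
        labels = tuple("abcd")
        k1 = cohen_kappa(CrossTab(counts, labels=labels)).kappa
        k7 = cohen_kappa(CrossTab(counts * 7, labels=labels)).kappa
        assert k1 == pytest.approx(k7, abs=1e-12)

    def test_degenerate_table(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 1] = 42  # all mass in one cell of both margins
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(CrossTab(counts, labels=("a", "b", "c")))

    def test_weighted_option(self):
        ct = CrossTab(np.array([[20, 5], [10, 15]]), labels=("x", "y"))
        res = cohen_kappa(ct, weights="quadratic")
        assert -1.0 <= res.kappa <= 1.0


class TestKappaStrength:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.715, "substantial"), (0.81, "almost perfect"), (0.336, "fair"),
            (-0.5, "poor"), (0.0, "poor"), (0.1, "slight"), (0.5, "moderate"),
            (1.0, "almost perfect"),
        ],
    )
    def test_bands(self, kappa, label):
        assert kappa_strength(kappa) == label

    def test_out_of_range(self):
        with pytest.raises(InvalidInputError):
            kappa_strength(1.5)
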