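"""Correlation statistic, FDR, classification rule, and pattern grammar."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmpv.core import (
    bh_adjust,
    classify_pair,
    correlation_p_value,
    detect_mmpvs,
    encode_pattern,
    mmpv_table,
    pearson_r,
    stratified_pair_correlations,
)
from mmpv.errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
)
from mmpv.io_model import ExpressionMatrix, TargetPair
from mmpv.synth import DatasetSpec, simulate_dataset

from conftest import make_pair_specs

PATTERN_GRAMMAR = re.compile(r"^[UD]_[UD]\*?_[UD]\*?$")


def brute_force_pcc(x, y):
    """Definitional covariance/variance formula, no shortcuts."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx**0.5 * vy**0.5)


class TestPearsonR:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # cov-sum 4, variance-sums 5,5
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=3, max_size=30
        ),
        st.integers(0, 2**32 - 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_definition(self, xs, seed):
        rng = np.random.default_rng(seed)
        ys = rng.normal(size=len(xs)).tolist()
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return
        n = len(xs)
        if sum((a - sum(xs) / n) ** 2 for a in xs) < 1e-100:
            return  # variance underflows; the definitional oracle divides by 0
        expected = brute_force_pcc(xs, ys)
        if abs(expected) > 1:  # float overshoot in the oracle itself
            expected = np.sign(expected)
        assert pearson_r(xs, ys) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_single_point_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            pearson_r([1], [2])


class TestCorrelationP:
    def test_zero_correlation_gives_p_one(self):
        for n in (3, 10, 100):
            assert correlation_p_value(0.0, n) == 1.0

    def test_perfect_correlation_gives_p_zero(self):
        assert correlation_p_value(1.0, 5) == 0.0
        assert correlation_p_value(-1.0, 5) == 0.0

    def test_df2_closed_form(self):
        # at n=4 the t survival function has the closed form
        # sf(t) = (1 - t/sqrt(2+t^2))/2; r=0.8 gives t = 0.8*sqrt(2/0.36)
        t = 0.8 * np.sqrt(2 / 0.36)
        expected = 2 * 0.5 * (1 - t / np.sqrt(2 + t * t))
        assert correlation_p_value(0.8, 4) == pytest.approx(expected, abs=1e-12)
        assert correlation_p_value(0.8, 4) == pytest.approx(0.2, abs=1e-6)

    def test_matches_scipy_pearsonr(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=15)
            y = 0.4 * x + rng.normal(size=15)
            r = pearson_r(x, y)
            assert correlation_p_value(r, 15) == pytest.approx(
                stats.pearsonr(x, y).pvalue, rel=1e-9
            )

    def test_tiny_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlation_p_value(0.5, 2)


def step_up_oracle(pvals):
    """Literal B-H recursion: sort, q(i) = min_{j>=i} p(j)*m/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    qs = [0.0] * m
    best = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pvals[i] * m / rank)
        qs[i] = min(best, 1.0)
    return qs


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_independent_oracles(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = bh_adjust(pvals)
        assert q == pytest.approx(step_up_oracle(pvals), abs=1e-12)
        q_sm = multipletests(pvals, method="fdr_bh")[1]
        assert q == pytest.approx(q_sm, abs=1e-10)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=17)
        perm = rng.permutation(17)
        assert bh_adjust(p[perm]) == pytest.approx(bh_adjust(p)[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestClassifyPair:
    @pytest.mark.parametrize(
        "r1, r2, q1, q2, label",
        [
            (0.5, -0.5, 0.01, 0.5, "sign_change"),
            (0.6, 0.2, 0.01, 0.6, "fold_change"),
            (0.5, 0.4, 0.01, 0.01, "none"),  # ratio 1.25 inside (0.5, 2)
            (0.9, -0.9, 0.2, 0.9, "none"),  # both insignificant -> removed
            (-0.2, -0.6, 0.01, 0.01, "fold_change"),  # ratio 1/3
            (0.0, 0.4, 0.01, 0.01, "fold_change"),  # infinite-ratio convention
            (0.0, 0.0, 0.01, 0.01, "none"),
        ],
    )
    def test_decision_rule(self, r1, r2, q1, q2, label):
        assert classify_pair(r1, r2, q1, q2) == label

    def test_exhaustive_partition_on_grid(self):
        rs = np.arange(-0.9, 0.95, 0.1)
        qs = [0.0, 0.01, 0.05, 0.2, 1.0]
        labels = {"sign_change", "fold_change", "none"}
        for r1 in rs:
            for r2 in rs:
                for q1 in qs:
                    for q2 in qs:
                        label = classify_pair(r1, r2, q1, q2)
                        assert label in labels
                        if q1 >= 0.05 and q2 >= 0.05:
                            assert label == "none"

    def test_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            classify_pair(0.5, 0.25, 0.01, 0.01, fold=1.0)


class TestEncodePattern:
    @pytest.mark.parametrize(
        "sign, r1, q1, r2, q2, expected",
        [
            ("D", 0.1, 0.3, 0.6, 0.001, "D_U_U*"),
            ("D", 0.1, 0.3, -0.6, 0.001, "D_U_D*"),
            ("U", 0.5, 0.01, 0.5, 0.01, "U_U*_U*"),
        ],
    )
    def test_worked_patterns(self, sign, r1, q1, r2, q2, expected):
        assert encode_pattern(sign, r1, q1, r2, q2) == expected

    def test_grammar(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            s = rng.choice(["U", "D"])
            r1, r2 = rng.uniform(-1, 1, 2)
            q1, q2 = rng.uniform(0, 1, 2)
            assert PATTERN_GRAMMAR.match(encode_pattern(s, r1, q1, r2, q2))

    def test_bad_sign_rejected(self):
        with pytest.raises(ValueError):
            encode_pattern("X", 0.5, 0.01, 0.5, 0.01)


class TestStratifiedCorrelations:
    def test_matches_brute_force_on_toy(self, toy_annotation):
        import pandas as pd

        mirna = ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2, 3, 1, 3, 5]],
                index=["m1"],
                columns=[f"s{i}" for i in range(1, 7)],
            )
        )
        mrna = ExpressionMatrix(
            pd.DataFrame(
                [[2.0, 3, 5, 6, 4, 1]],
                index=["g1"],
                columns=[f"s{i}" for i in range(1, 7)],
            )
        )
        pairs = [TargetPair("m1", "g1", "D")]
        table, counters = stratified_pair_correlations(
            mirna, mrna, toy_annotation, "ER", pairs
        )
        assert counters == {
            "unresolved_pairs": 0,
            "insufficient_pairs": 0,
            "degenerate_pairs": 0,
        }
        assert table.loc[0, "r_status1"] == pytest.approx(
            brute_force_pcc([1, 2, 3], [2, 3, 5]), abs=1e-12
        )
        assert table.loc[0, "r_status2"] == pytest.approx(
            brute_force_pcc([1, 3, 5], [6, 4, 1]), abs=1e-12
        )

    def test_sample_order_irrelevant(self, small_dataset):
        spec, mirna, mrna, annotation, _ = small_dataset
        pairs = [s.pair for s in spec.pair_specs]
        base, _ = stratified_pair_correlations(
            mirna, mrna, annotation, spec.feature_name, pairs
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(mirna.col_ids))
        shuffled_mirna = ExpressionMatrix(mirna.data.iloc[:, perm])
        shuffled_mrna = ExpressionMatrix(mrna.data.iloc[:, perm])
        again, _ = stratified_pair_correlations(
            shuffled_mirna, shuffled_mrna, annotation, spec.feature_name, pairs
        )
        for col in ("r_status1", "r_status2", "p_status1", "p_status2"):
            assert again[col].to_numpy() == pytest.approx(
                base[col].to_numpy(), abs=1e-12
            )

    def test_constant_mirna_drops_pair_with_counter(self, small_dataset):
        spec, mirna, mrna, annotation, _ = small_dataset
        pairs = [s.pair for s in spec.pair_specs]
        flat = mirna.data.copy()
        flat.loc[pairs[0].mirna_id] = 5.0
        table, counters = stratified_pair_correlations(
            ExpressionMatrix(flat), mrna, annotation, spec.feature_name, pairs
        )
        assert counters["degenerate_pairs"] == 1
        assert pairs[0].mirna_id not in set(table["mirna_id"])

    def test_unknown_feature_is_configuration_error(self, small_dataset):
        spec, mirna, mrna, annotation, _ = small_dataset
        with pytest.raises(ConfigurationError):
            stratified_pair_correlations(
                mirna, mrna, annotation, "HER2", [s.pair for s in spec.pair_specs]
            )

    def test_missing_cells_use_pairwise_complete_samples(self, small_dataset):
        spec, mirna, mrna, annotation, _ = small_dataset
        pairs = [s.pair for s in spec.pair_specs]
        holed = mirna.data.copy()
        holed.iloc[0, 0:3] = np.nan
        table, _ = stratified_pair_correlations(
            ExpressionMatrix(holed), mrna, annotation, spec.feature_name, pairs
        )
        assert table.loc[0, "n_status1"] == 57
        assert table.loc[0, "n_status2"] == 60


class TestDetectMMPVs:
    def test_all_equal_rho_dataset_yields_empty_result(self):
        specs = make_pair_specs([{"rho1": 0.5, "rho2": 0.5} for _ in range(6)])
        spec = DatasetSpec(n_status1=40, n_status2=40, pair_specs=specs, seed=21)
        mirna, mrna, annotation, _ = simulate_dataset(spec)
        records, summary = detect_mmpvs(
            mirna, mrna, annotation, spec.feature_name, [s.pair for s in specs]
        )
        # equal population rho: sign changes impossible at this coupling, and
        # the ratio rule only trips on sampling noise (none at these seeds)
        assert summary["n_total"] == summary["n_fold_change"] + summary["n_sign_change"]
        assert len(records) == summary["n_total"]
        assert summary["n_sign_change"] == 0

    def test_sign_change_power_and_null_rejection(self, small_dataset):
        spec, mirna, mrna, annotation, truth = small_dataset
        records, summary = detect_mmpvs(
            mirna, mrna, annotation, spec.feature_name,
            [s.pair for s in spec.pair_specs],
        )
        truth_map = dict(
            zip(truth["mirna_id"], truth["expected_class"])
        )
        detected_sign = {
            r.pair.mirna_id for r in records if r.mmpv_class == "sign_change"
        }
        true_sign = {m for m, c in truth_map.items() if c == "sign_change"}
        assert len(detected_sign & true_sign) >= 4  # >= 4 of 5 at |rho|=0.8, n=60
        null_hits = {r.pair.mirna_id for r in records} - true_sign
        assert len(null_hits) <= 1

    def test_every_emitted_pattern_is_grammatical_with_significance(
        self, small_dataset
    ):
        spec, mirna, mrna, annotation, _ = small_dataset
        records, _ = detect_mmpvs(
            mirna, mrna, annotation, spec.feature_name,
            [s.pair for s in spec.pair_specs],
        )
        assert records
        for rec in records:
            assert PATTERN_GRAMMAR.match(rec.pattern)
            assert "*" in rec.pattern
            assert rec.pattern[0] == rec.pair.healthy_sign

    def test_registry_swap_swaps_tokens_but_not_class(self, small_dataset):
        spec, mirna, mrna, annotation, _ = small_dataset
        pairs = [s.pair for s in spec.pair_specs]
        fwd, _ = detect_mmpvs(mirna, mrna, annotation, spec.feature_name, pairs)
        swapped_ann = annotation.with_swapped_statuses(spec.feature_name)
        rev, _ = detect_mmpvs(mirna, mrna, swapped_ann, spec.feature_name, pairs)
        fwd_by_pair = {r.pair: r for r in fwd}
        rev_by_pair = {r.pair: r for r in rev}
        assert set(fwd_by_pair) == set(rev_by_pair)
        for pair, f in fwd_by_pair.items():
            r = rev_by_pair[pair]
            assert r.mmpv_class == f.mmpv_class
            head, s1, s2 = f.pattern.split("_")
            assert r.pattern == f"{head}_{s2}_{s1}"
            assert r.corr_status1.r == pytest.approx(f.corr_status2.r)
            assert r.corr_status2.r == pytest.approx(f.corr_status1.r)

    def test_table_layout(self, small_dataset):
        spec, mirna, mrna, annotation, _ = small_dataset
        records, _ = detect_mmpvs(
            mirna, mrna, annotation, spec.feature_name,
            [s.pair for s in spec.pair_specs],
        )
        table = mmpv_table(records)
        assert list(table["feature"].unique()) == [spec.feature_name]
        assert set(table["mmpv_class"]) <= {"sign_change", "fold_change"}
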