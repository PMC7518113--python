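"""Two-stage feature selection: normality-routed testing, the Fv and F
screening statistics, GLCM redundancy reduction, and median thresholding —
including replay of the published selection table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbradiomics import (
    GroupSummary,
    SelectionRecord,
    build_selection_records,
    family_medians,
    first_stage_select,
    fisher_ratio,
    fisher_ratio_from_summary,
    second_stage_select,
    summarize_feature,
    univariate_test,
    z_score_separation,
    z_score_separation_from_summary,
)
from gbradiomics.reference import (
    SELECTED_MORPHOLOGICAL,
    SELECTED_SPATIAL,
    reference_stage1_records,
)


class TestUnivariateTest:
    def test_identical_samples_not_significant(self):
        x = np.arange(30, dtype=float)
        p, *_ = univariate_test(x, x.copy())
        assert p > 0.99

    def test_constant_equal_groups_p_one_by_convention(self):
        p, n0, n1 = univariate_test(np.full(10, 3.0), np.full(12, 3.0))
        assert p == 1.0

    def test_large_known_effect_detected(self):
        rng = np.random.default_rng(0)
        p, n0, n1 = univariate_test(rng.normal(0, 1, 50), rng.normal(2, 1, 50))
        assert p < 1e-3
        assert n0 and n1  # both Gaussian groups routed through the t-test

    def test_skewed_group_routed_to_rank_test(self):
        rng = np.random.default_rng(1)
        x0 = rng.lognormal(0, 1.2, 60)
        x1 = rng.normal(3, 1, 60)
        p, n0, n1 = univariate_test(x0, x1)
        assert not n0  # log-normal flagged non-normal

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(2)
        reps = 2000
        rejections = sum(
            univariate_test(rng.normal(0, 1, 30), rng.normal(0, 1, 30))[0] < 0.05
            for _ in range(reps)
        )
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            univariate_test(np.array([1.0, 2.0]), np.arange(5.0))


class TestScreeningStatistics:
    @pytest.mark.parametrize(
        "m0,s0,m1,s1,expected",
        [
            (4.063, 1.682, 2.715, 1.867, 0.536),  # GLCM contrast at offset 14
            (0.818, 0.393, 1.438, 0.650, 0.816),  # equivalent diameter
            (2.637, 1.281, 5.033, 2.353, 0.894),  # perimeter
        ],
    )
    def test_fisher_ratio_reproduces_published_values(self, m0, s0, m1, s1, expected):
        assert fisher_ratio_from_summary(m0, s0, m1, s1) == pytest.approx(expected, abs=0.01)

    def test_fisher_ratio_zero_for_equal_means(self):
        s = GroupSummary(10, 10, mean0=5.0, sd0=1.0, mean1=5.0, sd1=2.0)
        assert fisher_ratio(s) == 0.0

    def test_fisher_ratio_undefined_for_zero_variances(self):
        with pytest.raises(ValueError):
            fisher_ratio_from_summary(1.0, 0.0, 2.0, 0.0)

    def test_pooled_z_separation_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x0 = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(5, 60))
            x1 = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(5, 60))
            pooled = np.concatenate([x0, x1])
            z = (pooled - pooled.mean()) / pooled.std(ddof=1)
            brute = abs(z[: len(x0)].mean() - z[len(x0) :].mean())
            assert z_score_separation(x0, x1) == pytest.approx(brute)
            assert brute == pytest.approx(
                abs(x0.mean() - x1.mean()) / pooled.std(ddof=1)
            )

    def test_pooled_z_identical_groups_zero(self):
        x = np.arange(20, dtype=float)
        assert z_score_separation(x, x.copy()) == pytest.approx(0.0)

    def test_summary_form_matches_sample_form(self):
        rng = np.random.default_rng(4)
        x0, x1 = rng.normal(0, 1, 40), rng.normal(1, 2, 25)
        from_sum = z_score_separation_from_summary(
            len(x0), x0.mean(), x0.std(ddof=1), len(x1), x1.mean(), x1.std(ddof=1)
        )
        assert from_sum == pytest.approx(z_score_separation(x0, x1))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        shift=st.floats(min_value=-100, max_value=100),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_scale_and_shift_invariance(self, scale, shift, seed):
        """p, Fv and F are invariant under positive affine rescaling."""
        rng = np.random.default_rng(seed)
        x0 = rng.normal(0, 1, 25)
        x1 = rng.normal(0.8, 1.3, 20)
        p_a, *_ = univariate_test(x0, x1)
        p_b, *_ = univariate_test(x0 * scale + shift, x1 * scale + shift)
        assert p_b == pytest.approx(p_a, rel=1e-6, abs=1e-9)
        fv_a = fisher_ratio(GroupSummary.from_samples(x0, x1))
        fv_b = fisher_ratio(GroupSummary.from_samples(x0 * scale + shift, x1 * scale + shift))
        assert fv_b == pytest.approx(fv_a, rel=1e-9)
        assert z_score_separation(x0 * scale + shift, x1 * scale + shift) == pytest.approx(
            z_score_separation(x0, x1), rel=1e-9
        )


def _rec(feature, family, p, fv, f, gtype=None):
    gtype = gtype or (feature[:4] if feature[:4] in ("Ener", "Cont", "Entr", "Homo") else "none")
    return SelectionRecord(feature=feature, family=family, glcm_type=gtype, p=p, Fv=fv, F=f)


class TestFirstStage:
    def test_glcm_representative_has_largest_fv(self):
        records = [
            _rec(f"Cont{d}", "spatial", 0.01 if d in (5, 14) else 0.2, 0.3 + 0.02 * d, 0.5)
            for d in range(1, 16)
        ] + [_rec("IMean", "spatial", 0.03, 0.4, 0.5)]
        kept = first_stage_select(records)
        names = {r.feature for r in kept}
        # only the significant members compete; d=14 has the larger Fv
        assert names == {"Cont14", "IMean"}

    def test_tie_broken_toward_smallest_offset(self):
        records = [
            _rec("Ener3", "spatial", 0.01, 0.5, 0.5),
            _rec("Ener9", "spatial", 0.01, 0.5, 0.5),
        ]
        kept = first_stage_select(records)
        assert [r.feature for r in kept] == ["Ener3"]

    def test_single_significant_non_glcm_feature_survives_alone(self):
        records = [_rec("Sol", "morphological", 0.04, 0.3, 0.2)] + [
            _rec("Area", "morphological", 0.2, 0.9, 0.9),
            _rec("Homo2", "spatial", 0.6, 0.8, 0.8),
        ]
        kept = first_stage_select(records)
        assert [r.feature for r in kept] == ["Sol"]
        assert kept[0].stage1_kept

    def test_null_table_keeps_only_chance_survivors(self):
        rng = np.random.default_rng(8)
        cols = {f"Cont{d}": rng.normal(0, 1, 60) for d in range(1, 16)}
        cols.update({n: rng.normal(0, 1, 60) for n in ("IMean", "Sol", "AR", "DD")})
        table = pd.DataFrame(cols)
        labels = np.repeat([0, 1], 30)
        records = build_selection_records(
            table, labels, {n: "spatial" for n in table.columns}
        )
        kept = first_stage_select(records)
        assert all(r.p < 0.05 for r in kept)
        assert len(kept) <= 3  # chance survivors only


class TestSecondStage:
    def test_published_table_replay_retains_exactly_eight(self):
        records = reference_stage1_records()
        med_fv_sp, med_f_sp = family_medians(records, "spatial")
        med_fv_mo, med_f_mo = family_medians(records, "morphological")
        assert (med_fv_sp, med_f_sp) == pytest.approx((0.396, 0.564))
        assert (med_fv_mo, med_f_mo) == pytest.approx((0.740, 0.964))
        kept = second_stage_select(records)
        assert {r.feature for r in kept if r.family == "spatial"} == SELECTED_SPATIAL
        assert {r.feature for r in kept if r.family == "morphological"} == SELECTED_MORPHOLOGICAL
        assert len(kept) == 8

    def test_feature_exactly_at_median_is_retained(self):
        # inclusive comparison: the published set keeps features sitting at
        # the medians (e.g. GLCM entropy rep with Fv = spatial median)
        records = reference_stage1_records()
        kept = {r.feature for r in second_stage_select(records)}
        assert "Entr6" in kept and "DD" in kept

    def test_single_member_family_retained(self):
        records = [_rec("Sol", "morphological", 0.01, 0.3, 0.2)]
        kept = second_stage_select(records)
        assert [r.feature for r in kept] == ["Sol"]
        assert kept[0].stage2_kept


class TestSummaries:
    def test_normal_class_displays_mean_sd(self):
        s = GroupSummary.from_samples(
            np.random.default_rng(0).normal(5, 1, 50), np.arange(10.0)
        )
        assert "±" in summarize_feature(s, 0)
        assert not summarize_feature(s, 0).endswith("*")

    def test_skewed_class_displays_median_iqr_with_marker(self):
        rng = np.random.default_rng(1)
        s = GroupSummary.from_samples(rng.lognormal(0, 1.5, 80), rng.normal(0, 1, 30))
        assert summarize_feature(s, 0).endswith("*")

    def test_quartile_rule_on_small_sample(self):
        # {1..5}: median 3, quartiles by linear interpolation -> IQR = 2
        s = GroupSummary.from_samples(np.array([1.0, 2, 3, 4, 5]), np.arange(6.0))
        assert s.median0 == 3.0
        assert s.iqr0 == pytest.approx(2.0)


class TestRecordBuilding:
    def test_missing_values_excluded_and_flags_consistent(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            {
                "IMean": np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)]),
                "Cont14": np.concatenate([rng.normal(5, 1, 30), rng.normal(5, 1, 30)]),
            }
        )
        table.loc[3, "IMean"] = np.nan
        labels = np.repeat([0, 1], 30)
        records = build_selection_records(table, labels, {"IMean": "spatial", "Cont14": "spatial"})
        by_name = {r.feature: r for r in records}
        assert by_name["IMean"].p < 0.001
        first_stage_select(records)
        second_stage_select([r for r in records if r.stage1_kept])
        for r in records:
            if r.stage2_kept:
                assert r.stage1_kept
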