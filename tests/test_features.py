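import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from stagepath.features import (
    GeneVariationStats,
    anova_screen,
    compute_cv,
    tukey_assign,
    tukey_pvalues,
    two_tail_filter,
)
from stagepath.io import STAGES, StageCohort, ValidationError


def _frame(rows, samples=None):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=samples or [f"s{i}" for i in range(arr.shape[1])])


class TestComputeCv:
    def test_zero_variance_flagged(self):
        stats_ = compute_cv(_frame([[1.0, 1.0, 1.0]]))
        assert stats_.zero_sd_genes == ["g0"]
        assert "g0" not in stats_.cv.index

    def test_symmetric_values_give_zero_cv(self):
        stats_ = compute_cv(_frame([[-1.0, 0.0, 1.0]]))
        assert stats_.cv["g0"] == 0.0

    def test_hand_computed_cv(self):
        # mean 1.0, sample SD 0.5 -> CV = 2.0
        stats_ = compute_cv(_frame([[0.5, 1.0, 1.5]]))
        assert stats_.cv["g0"] == pytest.approx(2.0)


class TestTwoTailFilter:
    def _stats(self, cvs):
        s = pd.Series(cvs, index=[f"g{i}" for i in range(len(cvs))], name="cv")
        return GeneVariationStats(mean=s * 0, sd=s * 0 + 1, cv=s, zero_sd_genes=[])

    def test_quartile_cut_is_strict(self):
        kept = two_tail_filter(self._stats([-2.0, -1.0, 0.0, 1.0, 2.0]), 0.25, 0.75)
        assert kept == {"g0", "g4"}  # quantiles at -1 and 1; strict inequality

    def test_full_range_keeps_nothing(self):
        assert two_tail_filter(self._stats([-2.0, -1.0, 1.0, 2.0]), 0.0, 1.0) == set()

    def test_quartiles_keep_about_half(self):
        rng = np.random.default_rng(8)
        kept = two_tail_filter(self._stats(rng.standard_normal(10_000)), 0.25, 0.75)
        assert abs(len(kept) / 10_000 - 0.5) < 0.01

    def test_too_few_genes_errors(self):
        with pytest.raises(ValidationError):
            two_tail_filter(self._stats([0.0, 1.0]), 0.25, 0.75)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=200))
    def test_matches_brute_force(self, cvs):
        stats_ = self._stats(cvs)
        kept = two_tail_filter(stats_, 0.25, 0.75)
        lo, hi = np.quantile(np.asarray(cvs), [0.25, 0.75])
        brute = {f"g{i}" for i, v in enumerate(cvs) if v < lo or v > hi}
        assert kept == brute


class TestAnovaScreen:
    def test_constant_gene_not_selected(self, four_group_frame):
        frame, cohort = four_group_frame
        frame = frame.copy()
        frame.loc["g0"] = 1.0
        res = anova_screen(frame, cohort)
        assert "g0" not in res.selected
        assert res.pvalue["g0"] == 1.0

    def test_strong_group_shift_selected(self, four_group_frame):
        frame, cohort = four_group_frame
        frame = frame.copy()
        rng = np.random.default_rng(1)
        row = rng.normal(0, 0.1, 80)
        row[60:] += 5.0  # stage IV shifted by 5 with within-SD 0.1
        frame.loc["g1"] = row
        res = anova_screen(frame, cohort)
        assert "g1" in res.selected
        assert res.pvalue["g1"] < 1e-20

    def test_pvalues_match_scipy_f_oneway(self, four_group_frame):
        frame, cohort = four_group_frame
        res = anova_screen(frame, cohort)
        groups = cohort.groups()
        for gene in frame.index:
            ref = sps.f_oneway(*[frame.loc[gene, groups[s]].to_numpy() for s in STAGES])
            assert res.pvalue[gene] == pytest.approx(ref.pvalue, abs=1e-10)
            assert res.fstat[gene] == pytest.approx(ref.statistic, rel=1e-10)

    def test_restricting_gene_set(self, four_group_frame):
        frame, cohort = four_group_frame
        res = anova_screen(frame, cohort, genes={"g0", "g1"})
        assert set(res.pvalue.index) == {"g0", "g1"}

    def test_stage_with_one_sample_errors(self):
        rng = np.random.default_rng(0)
        frame = _frame(rng.standard_normal((3, 7)))
        labels = dict(zip(frame.columns, ["I", "I", "II", "II", "III", "III", "IV"]))
        with pytest.raises(ValidationError):
            anova_screen(frame, StageCohort(labels=labels))


class TestTukey:
    def test_pvalues_match_scipy_tukey_hsd_unequal_groups(self):
        rng = np.random.default_rng(12)
        ns = (12, 8, 6, 4)  # unequal sizes exercise the Tukey-Kramer SE
        samples, labels = [], {}
        for stage, n in zip(STAGES, ns):
            for i in range(n):
                s = f"{stage}_{i}"
                samples.append(s)
                labels[s] = stage
        frame = _frame(rng.standard_normal((20, len(samples))), samples=samples)
        cohort = StageCohort(labels=labels)
        mine = tukey_pvalues(frame, cohort, set(frame.index))
        groups = cohort.groups()
        for gene in frame.index:
            ref = sps.tukey_hsd(*[frame.loc[gene, groups[s]].to_numpy() for s in STAGES])
            for (a, b) in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]:
                col = f"{STAGES[a]}-{STAGES[b]}"
                assert mine.loc[gene, col] == pytest.approx(ref.pvalue[a, b], abs=1e-8)

    def test_single_significant_pair_assigns_two_stages(self):
        rng = np.random.default_rng(7)
        ns = (15, 15, 15, 15)
        samples, labels = [], {}
        for stage, n in zip(STAGES, ns):
            for i in range(n):
                s = f"{stage}_{i}"
                samples.append(s)
                labels[s] = stage
        cohort = StageCohort(labels=labels)
        # noise centered per group and scaled to MSE = 1, so the group means
        # are exactly (0, .5, .5, 1): only the I-IV contrast (diff 1.0,
        # q = 1.0/sqrt(1/15) ≈ 3.87 > q_crit) is Tukey-significant; every
        # other pair has diff <= 0.5 (q ≈ 1.94 or 0).
        noise = rng.standard_normal(60).reshape(4, 15)
        noise -= noise.mean(axis=1, keepdims=True)
        noise /= np.sqrt((noise**2).sum() / (60 - 4))  # pooled within-group SD -> 1
        shifts = np.repeat([0.0, 0.5, 0.5, 1.0], 15)
        frame = _frame((noise.ravel() + shifts)[None, :], samples=samples)
        sets = tukey_assign(frame, cohort, {"g0"}, alpha=0.05)
        sig_pairs = {
            pair for pair in sets.tukey_pvalues.columns if sets.tukey_pvalues.loc["g0", pair] < 0.05
        }
        assert sig_pairs == {"I-IV"}
        assert "g0" in sets.per_stage["I"] and "g0" in sets.per_stage["IV"]
        assert "g0" not in sets.per_stage["II"] and "g0" not in sets.per_stage["III"]

    def test_all_pairs_significant_puts_gene_in_shared(self):
        rng = np.random.default_rng(3)
        samples, labels = [], {}
        for stage, n in zip(STAGES, (10, 10, 10, 10)):
            for i in range(n):
                s = f"{stage}_{i}"
                samples.append(s)
                labels[s] = stage
        shifts = np.repeat([0.0, 10.0, 20.0, 30.0], 10)
        frame = _frame((rng.standard_normal(40) * 0.2 + shifts)[None, :], samples=samples)
        sets = tukey_assign(frame, StageCohort(labels=labels), {"g0"}, alpha=0.05)
        assert (sets.tukey_pvalues.loc["g0"] < 0.05).all()
        assert "g0" in sets.shared

    def test_per_stage_sets_nested_in_anova_genes(self, four_group_frame):
        frame, cohort = four_group_frame
        res = anova_screen(frame, cohort, alpha=0.5)  # permissive, so sets are non-trivial
        if not res.selected:
            pytest.skip("no gene passed the permissive screen")
        sets = tukey_assign(frame, cohort, res.selected, alpha=0.5)
        for stage in STAGES:
            assert sets.per_stage[stage] <= sets.anova_genes
            assert sets.shared <= sets.per_stage[stage]

    def test_raising_alpha_never_shrinks_sets(self, four_group_frame):
        frame, cohort = four_group_frame
        res = anova_screen(frame, cohort, alpha=0.9)
        tight = tukey_assign(frame, cohort, res.selected, alpha=0.1)
        loose = tukey_assign(frame, cohort, res.selected, alpha=0.5)
        for stage in STAGES:
            assert tight.per_stage[stage] <= loose.per_stage[stage]
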