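import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutcog.cohort_prep import (
    classify_subjects,
    cognitive_stability_lmm,
    composite_zscore,
    diversity_lmm,
    diversity_per_sample,
    fit_random_intercept_lmm,
    inverse_simpson,
)
from gutcog.io_formats import VisitRecord


def make_record(
    subject="A",
    visit=1,
    days=0.0,
    cdr=0.0,
    dementia=False,
    normal_fn=True,
    delayed_recall=2.0,
    memory=(3, 2, 1, 0, 4),
    ef_adas=(2.0, 1.0),
    toolbox=(7.0, 8.0),
    sample=None,
):
    mem_keys = (
        "word_recall",
        "word_recognition",
        "orientation",
        "remember_instructions",
        "delayed_recall",
    )
    adas = dict(zip(mem_keys, memory))
    if delayed_recall is not None:
        adas["delayed_recall"] = delayed_recall
    adas["maze_time"], adas["maze_mistakes"] = ef_adas
    return VisitRecord(
        subject_id=subject,
        visit_index=visit,
        days_since_enrollment=days,
        sample_id=sample,
        sex="female",
        age=72.0,
        education_years=16.0,
        antibiotics_6mo=False,
        hospitalized_6mo=False,
        polypharmacy=False,
        medications=frozenset(),
        cfs=2.0,
        mis=1.2,
        cdr=cdr,
        dementia_diagnosis=dementia,
        normal_daily_function=normal_fn,
        adas_subtests=adas,
        toolbox_subtests={"card_sort": toolbox[0], "pattern_comparison": toolbox[1]},
        adas_total=12.0,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


class TestClassifySubjects:
    def test_dementia_diagnosis_is_ad(self):
        [status] = classify_subjects([make_record(dementia=True, normal_fn=False)])
        assert status.status == "AD"

    def test_mci_threshold_recall_four(self):
        [status] = classify_subjects(
            [make_record(cdr=0.5, delayed_recall=4.0)]
        )
        assert status.status == "MCI"

    def test_hc_complement(self):
        [status] = classify_subjects([make_record(cdr=0.0, delayed_recall=3.0)])
        assert status.status == "HC"

    def test_missing_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            classify_subjects([make_record(visit=2, days=90.0)])

    def test_missing_recall_for_non_ad_errors(self):
        record = make_record()
        del record.adas_subtests["delayed_recall"]
        with pytest.raises(ValueError, match="delayed_recall"):
            classify_subjects([record])

    def test_partition(self, small_cohort):
        statuses = classify_subjects(small_cohort.records)
        subjects = {r.subject_id for r in small_cohort.records}
        assert {s.subject_id for s in statuses} == subjects
        assert len(statuses) == len(subjects)
        assert all(s.status in {"HC", "MCI", "AD"} for s in statuses)


# ---------------------------------------------------------------------------
# composite z-scores
# ---------------------------------------------------------------------------


class TestCompositeZscore:
    def test_memory_raw_sum(self):
        records = [
            make_record(subject="A", memory=(3, 2, 1, 0, 4), delayed_recall=None),
            make_record(subject="B", memory=(1, 1, 1, 1, 1), delayed_recall=None),
        ]
        scores = composite_zscore(records, "memory")
        by_subject = {s.subject_id: s for s in scores}
        assert by_subject["A"].raw_sum == pytest.approx(10.0)
        assert by_subject["B"].raw_sum == pytest.approx(5.0)

    def test_sample_sd_standardization(self):
        records = [
            make_record(subject=s, memory=(m, 0, 0, 0, 0), delayed_recall=None)
            for s, m in zip("ABC", (2, 4, 6))
        ]
        scores = composite_zscore(records, "memory")
        zs = {s.subject_id: s.z for s in scores}
        assert zs == pytest.approx({"A": -1.0, "B": 0.0, "C": 1.0})

    def test_zero_sd_visit_errors(self):
        records = [
            make_record(subject=s, memory=(5, 0, 0, 0, 0), delayed_recall=None)
            for s in "ABC"
        ]
        with pytest.raises(ValueError, match="zero SD"):
            composite_zscore(records, "memory")

    def test_singleton_visit_errors(self):
        with pytest.raises(ValueError, match="1 record"):
            composite_zscore([make_record()], "memory")

    def test_ef_toolbox_sign_flip(self):
        # better toolbox performance (higher) must lower the EF raw sum
        good = make_record(subject="A", toolbox=(9.0, 9.0))
        bad = make_record(subject="B", toolbox=(2.0, 2.0))
        scores = composite_zscore([good, bad], "executive_function")
        by = {s.subject_id: s for s in scores}
        assert by["A"].raw_sum < by["B"].raw_sum
        assert by["A"].z < 0 < by["B"].z  # higher z = worse

    def test_missing_subtest_errors(self):
        record = make_record()
        del record.adas_subtests["orientation"]
        with pytest.raises(ValueError, match="orientation"):
            composite_zscore([record, make_record(subject="B")], "memory")

    def test_drop_policy_skips_singleton_visits(self):
        records = [
            make_record(subject="A", memory=(3, 2, 1, 0, 4)),
            make_record(subject="B", memory=(1, 1, 1, 1, 1)),
            make_record(subject="A", visit=2, days=90.0),
        ]
        scores = composite_zscore(records, "memory", on_small_group="drop")
        assert {(s.subject_id, s.visit_index) for s in scores} == {("A", 1), ("B", 1)}

    def test_per_visit_mean0_sd1_on_cohort(self, small_cohort):
        for domain in ("memory", "executive_function"):
            scores = composite_zscore(
                small_cohort.records, domain, on_small_group="drop"
            )
            frame = pd.DataFrame(
                {"visit": [s.visit_index for s in scores], "z": [s.z for s in scores]}
            )
            for _, group in frame.groupby("visit"):
                if len(group) > 1:
                    assert abs(group["z"].mean()) < 1e-9
                    assert abs(group["z"].std(ddof=1) - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# inverse Simpson
# ---------------------------------------------------------------------------


class TestInverseSimpson:
    def test_uniform_equals_richness(self):
        for s in (1, 4, 25):
            assert inverse_simpson(np.full(s, 1.0 / s)) == pytest.approx(float(s))

    def test_single_species(self):
        assert inverse_simpson([1.0]) == pytest.approx(1.0)

    def test_derived_value(self):
        # direct evaluation 1/(0.25+0.09+0.04)
        assert inverse_simpson([0.5, 0.3, 0.2]) == pytest.approx(1 / 0.38)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            inverse_simpson([])

    def test_unclosed_errors(self):
        with pytest.raises(ValueError, match="sum"):
            inverse_simpson([0.5, 0.4])

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_bounded(self, raw):
        p = np.array(raw) / np.sum(raw)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(p)
        assert inverse_simpson(p) == pytest.approx(inverse_simpson(shuffled))
        assert inverse_simpson(p) <= np.count_nonzero(p) + 1e-9

    def test_diversity_per_sample_matches(self, small_cohort):
        table = small_cohort.tables["species"]
        div = diversity_per_sample(table)
        assert div[table.sample_ids[0]] == pytest.approx(
            inverse_simpson(table.values[0])
        )


# ---------------------------------------------------------------------------
# random-intercept LMM
# ---------------------------------------------------------------------------


def _sim_lmm(seed, m=40, ni=4, beta=(1.0, 0.7), s2b=1.0, s2e=1.0):
    rng = np.random.default_rng(seed)
    n = m * ni
    x = rng.normal(0, 1, n)
    clusters = np.repeat([f"c{i}" for i in range(m)], ni)
    y = beta[0] + beta[1] * x + np.repeat(rng.normal(0, np.sqrt(s2b), m), ni)
    y = y + rng.normal(0, np.sqrt(s2e), n)
    return x, y, clusters


class TestRandomInterceptLMM:
    def test_zero_variance_reproduces_ols(self):
        rng = np.random.default_rng(1)
        m, ni = 20, 4
        n = m * ni
        X = rng.normal(0, 1, (n, 2))
        clusters = np.repeat([f"c{i}" for i in range(m)], ni)
        e = rng.normal(0, 1, n)
        for cid in set(clusters):
            idx = clusters == cid
            e[idx] -= e[idx].mean()  # no between-cluster residual variance
        y = 1.0 + 2.0 * X[:, 0] - X[:, 1] + e
        fit = fit_random_intercept_lmm(
            y, pd.DataFrame({"a": X[:, 0], "b": X[:, 1]}), clusters
        )
        beta_ols = np.linalg.lstsq(
            np.column_stack([np.ones(n), X]), y, rcond=None
        )[0]
        assert fit.sigma2_b < 1e-6
        np.testing.assert_allclose(fit.estimates, beta_ols, atol=1e-6)

    def test_agrees_with_statsmodels_reml(self):
        # independent reference implementation on an interior solution
        import statsmodels.api as sm

        x, y, clusters = _sim_lmm(5)
        fit = fit_random_intercept_lmm(y, pd.DataFrame({"x": x}), clusters)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(
                y, np.column_stack([np.ones(len(y)), x]), groups=clusters
            ).fit(reml=True)
        np.testing.assert_allclose(fit.estimates, np.asarray(ref.params)[:2], atol=1e-4)
        np.testing.assert_allclose(fit.std_errors, np.asarray(ref.bse)[:2], atol=1e-3)
        assert fit.sigma2_b == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-3)
        assert fit.sigma2_e == pytest.approx(float(ref.scale), abs=1e-3)

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError, match="clusters"):
            fit_random_intercept_lmm(
                np.arange(4.0), pd.DataFrame({"x": np.arange(4.0)}), ["c"] * 4
            )

    def test_rank_deficiency_errors(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match="rank"):
            fit_random_intercept_lmm(
                x, pd.DataFrame({"a": x, "b": 2 * x}), ["c1"] * 4 + ["c2"] * 4
            )

    def test_beta_within_2se_most_replicates(self):
        hits = 0
        for rep in range(12):
            x, y, clusters = _sim_lmm(rep, m=60)
            fit = fit_random_intercept_lmm(y, pd.DataFrame({"x": x}), clusters)
            i = fit.fixed_names.index("x")
            hits += abs(fit.estimates[i] - 0.7) <= 2 * fit.std_errors[i]
        assert hits >= 10

    def test_sigma2_b_recovery_average(self):
        # average estimate over replicates near truth (100 clusters x 4)
        estimates = []
        for rep in range(30):
            rng = np.random.default_rng(200 + rep)
            m, ni = 100, 4
            n = m * ni
            x = rng.normal(0, 1, n)
            clusters = np.repeat([f"c{i}" for i in range(m)], ni)
            y = 0.5 * x + np.repeat(rng.normal(0, 1, m), ni) + rng.normal(0, 1, n)
            fit = fit_random_intercept_lmm(y, pd.DataFrame({"x": x}), clusters)
            estimates.append(fit.sigma2_b)
        assert np.mean(estimates) == pytest.approx(1.0, rel=0.15)

    def test_categorical_treatment_coding_hc_reference(self):
        rng = np.random.default_rng(3)
        n = 60
        status = np.array(["HC", "MCI", "AD"] * (n // 3))
        clusters = np.repeat([f"c{i}" for i in range(n // 3)], 3)
        y = rng.normal(0, 1, n)
        fit = fit_random_intercept_lmm(
            y, pd.DataFrame({"cog_status": status}), clusters
        )
        assert "cog_status[MCI]" in fit.fixed_names
        assert "cog_status[AD]" in fit.fixed_names
        assert not any("HC" in name for name in fit.fixed_names)

    def test_diversity_and_stability_wrappers(self, small_cohort):
        statuses = {
            s.subject_id: s.status
            for s in classify_subjects(small_cohort.records)
        }
        frame, fit = diversity_lmm(
            small_cohort.records, small_cohort.tables["species"], statuses
        )
        assert {"sex[male]", "age", "education_years"} <= set(fit.fixed_names)
        assert fit.sigma2_b >= 0 and fit.sigma2_e > 0
        scores = {
            (r.subject_id, r.visit_index): r.adas_total
            for r in small_cohort.records
        }
        fit2 = cognitive_stability_lmm(small_cohort.records, scores, statuses)
        assert "time_days" in fit2.fixed_names
        assert "cog_status[MCI]" in fit2.fixed_names
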