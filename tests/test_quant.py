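"""Measurement, normalization and replicate-statistics tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from centroquant import (
    LabelMap,
    Projection,
    estimate_fold_change,
    measure_foci,
    normalize_to_reference,
    qc_sampling,
    summarize_replicates,
    welch_test,
)
from centroquant.quant import ReplicateSummary
from conftest import noiseless_params
from oracles import brute_force_region_means, welch_closed_form


def _projection(arrs, source="s"):
    return Projection(channels=arrs, source_id=source)


class TestMeasureFoci:
    def test_mean_of_known_pixels(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, 0] = labels[1, 1] = labels[2, 2] = 1
        img = np.zeros((4, 4))
        img[0, 0], img[1, 1], img[2, 2] = 10, 20, 30
        lm = LabelMap.from_labels(labels)
        out = measure_foci(lm, _projection({"target": img}), background="none")
        assert out["mean_target"].iloc[0] == pytest.approx(20.0)

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            labels = rng.integers(0, 5, size=(16, 16)).astype(np.int32)
            img = rng.random((16, 16)) * 100
            lm = LabelMap.from_labels(labels)
            out = measure_foci(lm, _projection({"target": img}), background="none")
            expected = brute_force_region_means(labels, img)
            for row in out.itertuples():
                assert row.mean_target == pytest.approx(expected[row.label])

    def test_missing_channel_rejected(self):
        lm = LabelMap.from_labels(np.ones((4, 4), dtype=np.int32))
        with pytest.raises(KeyError, match="ghost"):
            measure_foci(lm, _projection({"target": np.ones((4, 4))}),
                         channels=["ghost"])

    def test_noiseless_measurement_tracks_truth_amplitude(self):
        # constant marker amplitude fixes the segmented footprint, so the
        # background-subtracted target mean must be proportional to the
        # planted target amplitude
        from centroquant import render_truth, segment_stack

        p = noiseless_params(seed=12, background_level=20.0, dna_amplitude=0.0)
        n = 16
        pos = np.linspace(20, 172, n).round()
        amps = np.linspace(400, 4000, n)
        truth = pd.DataFrame(
            {"x": pos, "y": pos, "z": np.full(n, 2.0),
             "amplitude_marker": np.full(n, 2000.0),
             "amplitude_target": amps}
        )
        stack = render_truth(p, truth)
        foci, nuclei, proj = segment_stack(stack)
        out = measure_foci(foci, proj)
        assert len(out) == n
        by_pos = {
            (int(round(r.y)), int(round(r.x))): r.amplitude_target
            for r in truth.itertuples()
        }
        net, amp = [], []
        for row in out.itertuples():
            key = (int(round(row.centroid_y)), int(round(row.centroid_x)))
            assert key in by_pos
            net.append(row.mean_target - row.bg_target)
            amp.append(by_pos[key])
        r = np.corrcoef(net, amp)[0, 1]
        assert r > 0.999


class TestNormalization:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["condition", "replicate", "mean_target", "nucleus_id"]
        )

    def test_uniform_intensities_normalize_to_one(self):
        t = self._table([("WT", 1, 5.0, 1), ("WT", 2, 5.0, 1),
                         ("mut", 1, 5.0, 1), ("mut", 2, 5.0, 1)])
        q = normalize_to_reference(t, background="none")
        assert np.allclose(q["normalized_value"], 1.0)

    def test_pooled_forced_arithmetic(self):
        t = self._table([("WT", 1, 2.0, 1), ("WT", 1, 4.0, 1), ("mut", 1, 6.0, 1)])
        q = normalize_to_reference(t, scope="pooled", background="none")
        assert q.loc[q["condition"] == "mut", "normalized_value"].iloc[0] \
            == pytest.approx(2.0)

    @pytest.mark.parametrize("scope", ["per_replicate", "pooled"])
    def test_reference_mean_is_exactly_one(self, scope):
        rng = np.random.default_rng(0)
        rows = [("WT", r, v, 1) for r in (1, 2, 3)
                for v in rng.lognormal(3, 0.4, 40)]
        rows += [("mut", r, v, 1) for r in (1, 2, 3)
                 for v in rng.lognormal(2, 0.4, 40)]
        q = normalize_to_reference(self._table(rows), scope=scope,
                                   background="none")
        ref = q[q["condition"] == "WT"]
        if scope == "pooled":
            assert ref["normalized_value"].mean() == pytest.approx(1.0, abs=1e-12)
        else:
            for _, sub in ref.groupby("replicate"):
                assert sub["normalized_value"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_missing_reference_in_replicate_names_it(self):
        t = self._table([("WT", 1, 2.0, 1), ("mut", 1, 3.0, 1), ("mut", 2, 3.0, 1)])
        with pytest.raises(ValueError, match=r"\[2\]"):
            normalize_to_reference(t, background="none")


class TestSummaries:
    def _quant(self, cond_rep_vals):
        rows = [
            {"condition": c, "replicate": r, "normalized_value": v, "nucleus_id": 1}
            for c, r, vals in cond_rep_vals for v in vals
        ]
        return pd.DataFrame(rows)

    def test_closed_form_grand_mean_and_sem(self):
        q = self._quant([("WT", 1, [1.0]), ("WT", 2, [0.9]), ("WT", 3, [1.1])])
        s = summarize_replicates(q)
        row = s.conditions.iloc[0]
        assert row["grand_mean"] == pytest.approx(1.0)
        assert row["sem"] == pytest.approx(0.1 / np.sqrt(3))

    def test_constant_values_have_zero_sem(self):
        q = self._quant([("WT", 1, [2.0, 2.0]), ("WT", 2, [2.0])])
        assert summarize_replicates(q).conditions["sem"].iloc[0] == 0.0

    def test_single_replicate_condition_rejected(self):
        q = self._quant([("WT", 1, [1.0]), ("WT", 2, [1.0]), ("mut", 1, [0.5])])
        with pytest.raises(ValueError, match="mut"):
            summarize_replicates(q)


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_worked_example_against_closed_form_and_scipy(self):
        a, b = [1.0, 0.9, 1.1], [0.4, 0.5, 0.3]
        res = welch_test(a, b)
        t, df, p = welch_closed_form(a, b)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)
        sp = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(sp.statistic, abs=1e-10)
        assert res.p == pytest.approx(sp.pvalue, abs=1e-10)

    def test_random_inputs_match_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            na, nb = rng.integers(2, 8, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(0.5, 2, nb)
            res = welch_test(a, b)
            sp = stats.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(sp.statistic, abs=1e-10)
            assert res.p == pytest.approx(sp.pvalue, abs=1e-10)
            assert min(na, nb) - 1 - 1e-9 < res.df <= na + nb - 2 + 1e-9

    def test_degenerate_zero_variance_conventions(self):
        assert welch_test([1.0, 1.0], [1.0, 1.0]).p == 1.0
        with pytest.warns(RuntimeWarning):
            res = welch_test([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0

    def test_one_degenerate_group_reduces_to_one_sample(self):
        res = welch_test([1.0, 1.0, 1.0], [0.8, 0.9, 1.0])
        assert res.df == pytest.approx(2.0)
        assert 0 < res.p < 1

    def test_equal_variance_large_n_agrees_with_pooled_t(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 500)
        b = rng.normal(0.1, 1, 500)
        res = welch_test(a, b)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        assert res.p == pytest.approx(pooled.pvalue, abs=1e-3)

    def test_pseudo_replication_immunity(self):
        q = pd.DataFrame(
            [
                {"condition": c, "replicate": r, "normalized_value": v,
                 "nucleus_id": 1}
                for (c, r, v) in [
                    ("WT", 1, 1.0), ("WT", 2, 0.9), ("WT", 3, 1.1),
                    ("mut", 1, 0.5), ("mut", 2, 0.45), ("mut", 3, 0.42),
                ]
            ]
        )
        def p_of(frame):
            s = summarize_replicates(frame)
            return welch_test(s.replicate_means("mut"),
                              s.replicate_means("WT")).p
        duplicated = pd.concat([q] * 10, ignore_index=True)
        assert p_of(duplicated) == pytest.approx(p_of(q), abs=1e-15)


class TestQC:
    def _quant(self, n_foci, n_nuclei):
        return pd.DataFrame(
            {
                "condition": "WT",
                "replicate": 1,
                "normalized_value": 1.0,
                "nucleus_id": (np.arange(n_foci) % n_nuclei) + 1,
            }
        )

    @pytest.mark.parametrize(
        "n_foci,n_nuclei,expected",
        [(100, 10, True), (99, 10, False), (100, 9, False)],
    )
    def test_minimum_counting_rule_boundaries(self, n_foci, n_nuclei, expected):
        report = qc_sampling(self._quant(n_foci, n_nuclei))
        assert bool(report["passed"].iloc[0]) is expected

    def test_empty_table_reports_nothing_passed(self):
        report = qc_sampling(pd.DataFrame(
            columns=["condition", "replicate", "normalized_value", "nucleus_id"]))
        assert report.empty or not report["passed"].any()


class TestFoldChange:
    def _summary(self, means_by_condition):
        reps = pd.DataFrame(
            [
                {"condition": c, "replicate": i + 1, "replicate_mean": m,
                 "n_foci": 100, "n_nuclei": 10}
                for c, ms in means_by_condition.items()
                for i, m in enumerate(ms)
            ]
        )
        conds = pd.DataFrame(
            [
                {"condition": c, "grand_mean": np.mean(ms),
                 "sem": np.std(ms, ddof=1) / np.sqrt(len(ms)),
                 "n_replicates": len(ms)}
                for c, ms in means_by_condition.items()
            ]
        )
        return ReplicateSummary(replicates=reps, conditions=conds)

    def test_condition_vs_itself_is_one(self):
        s = self._summary({"WT": [1.0, 0.9, 1.1]})
        fc = estimate_fold_change(s, "WT", "WT")
        assert fc.fold == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        s = self._summary({"WT": [0.0, 0.0], "mut": [1.0, 1.0]})
        with pytest.raises(ValueError, match="reference"):
            estimate_fold_change(s, "mut", "WT")

    def test_interval_coverage_under_the_null(self):
        # replicate means ~ N(1, tau); reference fixed at 1 (per-replicate
        # normalization makes reference means constant) — the t-interval
        # should cover the true ratio 1.0 in about 95% of draws
        rng = np.random.default_rng(21)
        covered = 0
        n = 200
        for _ in range(n):
            s = self._summary(
                {"WT": [1.0, 1.0, 1.0], "mut": list(rng.normal(1.0, 0.05, 3))}
            )
            fc = estimate_fold_change(s, "mut", "WT")
            covered += fc.ci_low <= 1.0 <= fc.ci_high
        assert covered / n >= 0.90
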