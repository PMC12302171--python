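"""Per-beat metrics, paired testing, Bonferroni and cohort summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from afloop.stats import (
    BeatMetrics,
    beat_metrics,
    bonferroni_adjust,
    paired_t,
    summarize_cohort,
)


def textbook_paired_t(a, b):
    """Independent re-implementation of the paired t test from the
    textbook formula (mean difference over its standard error, two-sided
    p from the t distribution with n-1 degrees of freedom)."""
    from scipy.stats import t as tdist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    sd = math.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * tdist.sf(abs(t), n - 1)
    return t, p


class TestBeatMetrics:
    def test_sinusoid_extrema(self):
        t = np.linspace(0, 1, 1001)
        v = 90 + 20 * np.sin(2 * np.pi * t)
        p = np.full_like(v, 100.0)
        m = beat_metrics(v, p, (0, v.size))
        assert m.edv == pytest.approx(110, abs=1e-3)
        assert m.esv == pytest.approx(70, abs=1e-3)
        assert m.ef == pytest.approx(100 * 40 / 110, abs=1e-2)

    def test_constant_trace_is_non_ejecting(self):
        v = np.full(100, 80.0)
        m = beat_metrics(v, v, (0, 100))
        assert m.sv == 0.0 and m.ef == 0.0

    def test_window_start_mode(self):
        v = np.array([100.0, 60.0, 50.0, 90.0, 105.0])
        m = beat_metrics(v, v, (0, 5), edv_mode="start")
        assert m.edv == 100.0 and m.esv == 50.0 and m.sv == 50.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            beat_metrics(np.ones(10), np.ones(10), (5, 5))

    def test_identity_invariants(self):
        m = BeatMetrics.from_extrema(0, edv=100.0, esv=50.0, sys_p=120.0, dia_p=80.0)
        assert m.sv == m.edv - m.esv
        assert m.ef == pytest.approx(100.0 * m.sv / m.edv)


class TestPairedT:
    def test_matches_textbook_oracle_on_random_inputs(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            a = rng.normal(50, 10, size=10)
            b = a + rng.normal(1, 3, size=10)
            t, p, md = paired_t(a, b)
            t_ref, p_ref = textbook_paired_t(a, b)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)
            assert md == pytest.approx(float((a - b).mean()), abs=1e-12)

    def test_identical_samples_convention(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p, md = paired_t(a, a)
        assert (t, p, md) == (0.0, 1.0, 0.0)

    def test_constant_shift_convention(self):
        t, p, md = paired_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert md == -1.0
        assert p == 0.0
        assert t == -math.inf

    def test_errors(self):
        with pytest.raises(ValueError):
            paired_t([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestBonferroni:
    def test_worked_examples(self):
        adj, sig = bonferroni_adjust([0.004], m=3)
        assert adj[0] == pytest.approx(0.012)
        assert not sig[0]
        adj, _ = bonferroni_adjust([0.5], m=10)
        assert adj[0] == 1.0
        adj, _ = bonferroni_adjust([0.123], m=1)
        assert adj[0] == pytest.approx(0.123)

    def test_monotone_in_raw_p(self):
        p = np.sort(np.random.default_rng(0).uniform(size=30))
        adj, _ = bonferroni_adjust(p, m=30)
        assert np.all(np.diff(adj) >= 0)

    def test_errors(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2, 0.3], m=2)
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2], m=2)


def _toy_results(sv_by_scenario, ef_by_scenario, patients=("A", "B")):
    labels = {
        "physiological_regular_yes": "Successfully restored sinus rhythm",
        "physiological_regular_no": "Paced rate-controlled AF",
        "physiological_irregular_yes": "Sinus rhythm with irregularity",
        "physiological_irregular_no": "Pharmacologically rate-controlled AF",
        "rapid_regular_yes": "Exercise",
        "rapid_regular_no": "",
        "rapid_irregular_yes": "",
        "rapid_irregular_no": "Rapidly conducted AF",
    }
    rows = []
    for i, pid in enumerate(patients):
        for key, label in labels.items():
            rows.append(
                {
                    "patient_id": pid,
                    "scenario_key": key,
                    "clinical_label": label,
                    "lvsv": sv_by_scenario[key][i],
                    "lvef": ef_by_scenario[key][i],
                }
            )
    return pd.DataFrame(rows)


class TestSummarize:
    def _defaults(self):
        sv = {k: [50.0, 50.0] for k in [
            "physiological_regular_yes", "physiological_regular_no",
            "physiological_irregular_yes", "physiological_irregular_no",
            "rapid_regular_yes", "rapid_regular_no", "rapid_irregular_yes",
            "rapid_irregular_no",
        ]}
        ef = {k: [48.0, 48.0] for k in sv}
        return sv, ef

    def test_percent_change_arithmetic(self):
        sv, ef = self._defaults()
        sv["physiological_regular_yes"] = [60.0, 55.0]
        res = _toy_results(sv, ef)
        summary = summarize_cohort(res).set_index("scenario_key")
        assert summary.loc[
            "physiological_regular_yes", "pct_sv_vs_af_mean"
        ] == pytest.approx(15.0)

    def test_delta_ef_is_absolute_percentage_points(self):
        sv, ef = self._defaults()
        ef["physiological_regular_yes"] = [53.0, 53.0]
        res = _toy_results(sv, ef)
        summary = summarize_cohort(res).set_index("scenario_key")
        # 48 -> 53 is +5 percentage points, not a relative change
        assert summary.loc[
            "physiological_regular_yes", "delta_ef_vs_af_mean_pp"
        ] == pytest.approx(5.0)

    def test_reference_row_is_self_comparison(self):
        sv, ef = self._defaults()
        summary = summarize_cohort(_toy_results(sv, ef)).set_index("scenario_key")
        ref = summary.loc["rapid_irregular_no"]
        assert ref.pct_sv_vs_af_mean == 0.0
        assert ref.delta_ef_vs_af_mean_pp == 0.0
        assert ref.p_raw == 1.0

    def test_family_size_is_four_management_arms(self):
        sv, ef = self._defaults()
        summary = summarize_cohort(_toy_results(sv, ef))
        assert (summary.bonferroni_m == 4).all()
        tested = summary[summary.p_adjusted.notna()]
        assert len(tested) == 5  # 4 arms + reference row

    def test_permutation_invariance_in_patient_order(self, results_wide, trial):
        res = trial["results"]
        shuffled = res.sample(frac=1.0, random_state=0).reset_index(drop=True)
        s1 = summarize_cohort(res).set_index("scenario_key").sort_index()
        s2 = summarize_cohort(shuffled).set_index("scenario_key").sort_index()
        pd.testing.assert_frame_equal(s1, s2)

    def test_regenerated_report_is_byte_identical(self, trial):
        res = trial["results"]
        a = summarize_cohort(res).to_csv(index=False)
        b = summarize_cohort(res.copy()).to_csv(index=False)
        assert a == b

    def test_summary_stable_through_csv_round_trip(self, trial, tmp_path):
        # unlabeled arms become NaN in CSV; the summary must not let them
        # leak into the Bonferroni family
        res = trial["results"]
        path = tmp_path / "results.csv"
        res.to_csv(path, index=False)
        back = pd.read_csv(path)
        s1 = summarize_cohort(res)
        s2 = summarize_cohort(back)
        assert (s2.bonferroni_m == 4).all()
        pd.testing.assert_series_equal(s1.p_adjusted, s2.p_adjusted)

    def test_missing_cell_aborts(self):
        sv, ef = self._defaults()
        res = _toy_results(sv, ef).iloc[:-1]
        with pytest.raises(ValueError):
            summarize_cohort(res)
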