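import numpy as np
import pandas as pd
import pytest

from spafnirs.glm import (
    block_average,
    build_design_matrix,
    canonical_hrf,
    cosine_drift_basis,
    fit_glm,
    group_summary,
    roi_weighted_beta,
    task_regressors,
)
from spafnirs.preprocess import HemoglobinSeries
from spafnirs.synthetic import EventSchedule


class TestHRF:
    def test_zero_at_origin(self):
        assert canonical_hrf(np.array([0.0, 1.0]))[0] == 0.0

    def test_peak_location_and_height(self):
        t = np.linspace(0, 32, 32001)
        h = canonical_hrf(t)
        assert 4.5 <= t[np.argmax(h)] <= 6.5
        assert h.max() == pytest.approx(1.0, abs=1e-6)

    def test_zero_beyond_support(self):
        h = canonical_hrf(np.array([1.0, 33.0, 40.0]))
        assert h[1] == 0.0 and h[2] == 0.0

    def test_rejects_decreasing_grid(self):
        with pytest.raises(ValueError):
            canonical_hrf(np.array([1.0, 0.5]))


class TestTaskRegressors:
    def test_empty_schedule_zero_columns(self):
        reg = task_regressors(EventSchedule([]), 0.6, 100)
        assert np.allclose(reg.to_numpy(), 0.0)

    def test_single_event_peak_location(self):
        """Column peak should sit at onset + (approx) boxcar-midpoint + HRF
        peak; cross-checked against a direct dense convolution oracle."""
        fs = 5.1
        n = int(120 * fs)
        ev = EventSchedule([(30.0, 6.0, "speech")])
        reg = task_regressors(ev, fs, n)["speech"].to_numpy()
        t = np.arange(n) / fs
        # oracle: dense numerical convolution of boxcar with the HRF
        dt = 1e-3
        tt = np.arange(0, 120, dt)
        box = ((tt >= 30.0) & (tt < 36.0)).astype(float)
        ker = canonical_hrf(np.arange(0, 32, dt))
        dense = np.convolve(box, ker)[: len(tt)] * dt
        t_peak_oracle = tt[np.argmax(dense)]
        assert abs(t[np.argmax(reg)] - t_peak_oracle) <= 1.0 / fs + 1e-9
        assert reg.max() == pytest.approx(1.0, rel=1e-2)  # peak-normalized response

    def test_linearity_two_events(self):
        fs = 0.6
        n = int(400 * fs)
        one = task_regressors(EventSchedule([(30.0, 6.0, "speech")]), fs, n)["speech"]
        other = task_regressors(EventSchedule([(200.0, 6.0, "speech")]), fs, n)["speech"]
        both = task_regressors(
            EventSchedule([(30.0, 6.0, "speech"), (200.0, 6.0, "speech")]), fs, n
        )["speech"]
        np.testing.assert_allclose(both, one + other, atol=1e-10)

    def test_event_past_end_rejected(self):
        with pytest.raises(ValueError, match="past the end"):
            task_regressors(EventSchedule([(500.0, 6.0, "speech")]), 0.6, 60)


class TestDriftBasis:
    def test_column_count_28min(self):
        n = int(1680 * 0.6)
        assert cosine_drift_basis(n, 0.6, 0.015).shape[1] == 50

    def test_short_duration_no_columns(self):
        assert cosine_drift_basis(int(30 * 0.6), 0.6, 0.015).shape[1] == 0

    def test_orthogonality(self):
        d = cosine_drift_basis(1008, 0.6, 0.015).to_numpy()
        gram = d.T @ d
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestDesignMatrix:
    def _blocks(self, n=100):
        task = pd.DataFrame({"speech": np.zeros(n), "silence": np.zeros(n)})
        drift = cosine_drift_basis(n, 0.6)
        return task, drift

    def test_none_model_columns(self):
        task, drift = self._blocks()
        X = build_design_matrix(task, drift)
        assert X.columns[:2] == ["speech", "silence"]
        assert X.columns[-1] == "constant"
        assert X.column_kind["constant"] == "constant"

    def test_ss_model_adds_two_columns(self):
        task, drift = self._blocks()
        nuis = pd.DataFrame({"ss_mean_hbo": np.random.default_rng(0).normal(size=100),
                             "ss_mean_hbr": np.random.default_rng(1).normal(size=100)})
        X = build_design_matrix(task, drift, nuis)
        base = build_design_matrix(task, drift)
        assert len(X.columns) == len(base.columns) + 2
        assert X.columns[-2:] == ["ss_mean_hbo", "ss_mean_hbr"]

    def test_duplicate_label_rejected(self):
        task, drift = self._blocks()
        nuis = pd.DataFrame({"speech": np.ones(100)})
        with pytest.raises(ValueError, match="duplicate"):
            build_design_matrix(task, drift, nuis)

    def test_length_mismatch_rejected(self):
        task, drift = self._blocks()
        with pytest.raises(ValueError):
            build_design_matrix(task.iloc[:50], drift)


class TestFitGLM:
    def test_exact_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 5))
        b = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        betas, ses, df, s2 = fit_glm(X @ b, X)
        np.testing.assert_allclose(betas, b, atol=1e-10)
        np.testing.assert_allclose(ses, 0.0, atol=1e-10)

    def test_se_calibration_monte_carlo(self):
        """Reported standard errors match the empirical sampling sd of the
        estimator over 500 noise replicates (within 10%)."""
        rng = np.random.default_rng(1)
        n, p, sigma = 300, 4, 0.7
        X = rng.normal(size=(n, p))
        b = rng.normal(size=p)
        Y = (X @ b)[:, None] + sigma * rng.normal(size=(n, 500))
        betas, ses, df, s2 = fit_glm(Y, X)
        emp_sd = betas.std(axis=1, ddof=1)
        np.testing.assert_allclose(emp_sd, ses.mean(axis=1), rtol=0.10)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 3))
        y = X @ [1.0, 2.0, 3.0] + rng.normal(size=80)
        perm = rng.permutation(80)
        b1, *_ = fit_glm(y, X)
        b2, *_ = fit_glm(y[perm], X[perm])
        np.testing.assert_allclose(b1, b2, atol=1e-10)

    def test_rank_deficiency_warns(self):
        X = np.ones((50, 2))
        with pytest.warns(RuntimeWarning, match="ridge"):
            fit_glm(np.ones(50), X)

    def test_nonfinite_rejected(self):
        X = np.ones((10, 1))
        y = np.ones(10)
        y[3] = np.nan
        with pytest.raises(ValueError):
            fit_glm(y, X)


class TestRoiWeighting:
    def _table(self, betas, ses):
        return pd.DataFrame({
            "subject": "S01", "session": 1, "model": "none",
            "channel": [f"c{i}" for i in range(len(betas))],
            "chromophore": "HbO", "condition": "speech",
            "beta": betas, "se": ses,
        })

    def test_equal_ses_give_plain_mean(self):
        tab = self._table([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        out = roi_weighted_beta(tab, {f"c{i}": "A1_L" for i in range(3)})
        assert out["beta"].iloc[0] == pytest.approx(2.0)

    def test_dominant_weight(self):
        tab = self._table([2.0, 4.0], [1.0, 1e9])
        out = roi_weighted_beta(tab, {"c0": "A1_L", "c1": "A1_L"})
        assert out["beta"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_hand_computed_value(self):
        # (1/0.5*1 + 1/1*2 + 1/2*3) / (2 + 1 + 0.5) = 5.5/3.5 = 11/7
        tab = self._table([1.0, 2.0, 3.0], [0.5, 1.0, 2.0])
        out = roi_weighted_beta(tab, {f"c{i}": "A1_L" for i in range(3)})
        assert out["beta"].iloc[0] == pytest.approx(11 / 7)

    def test_unmapped_channels_dropped(self):
        tab = self._table([1.0, 99.0], [1.0, 1.0])
        out = roi_weighted_beta(tab, {"c0": "A1_L"})
        assert len(out) == 1 and out["beta"].iloc[0] == 1.0


class TestGroupSummary:
    def _roi_table(self, betas):
        return pd.DataFrame({
            "subject": [f"S{i}" for i in range(len(betas))],
            "session": 1, "model": "none", "roi": "A1_L",
            "chromophore": "HbO", "condition": "speech", "beta": betas,
        })

    def test_constant_betas(self):
        out = group_summary(self._roi_table([2.0] * 5))
        assert out["estimate"].iloc[0] == 2.0 and out["se"].iloc[0] == 0.0

    def test_sign_flip_symmetry(self):
        b = [0.5, 1.0, 1.5, -0.2, 0.8]
        a = group_summary(self._roi_table(b))
        c = group_summary(self._roi_table([-x for x in b]))
        assert a["estimate"].iloc[0] == -c["estimate"].iloc[0]
        assert a["p"].iloc[0] == pytest.approx(c["p"].iloc[0])

    def test_sampling_distribution(self):
        """Two-stage mean over 15 subjects recovers the true effect across
        200 replicates (subject sd tau): mean within 2*tau/sqrt(15*200)."""
        rng = np.random.default_rng(5)
        b_true, tau, n, reps = 1.3, 0.6, 15, 200
        means = []
        for _ in range(reps):
            out = group_summary(self._roi_table(b_true + tau * rng.standard_normal(n)))
            means.append(out["estimate"].iloc[0])
        assert abs(np.mean(means) - b_true) < 3 * tau / np.sqrt(n * reps)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            group_summary(self._roi_table([1.0]))


class TestBlockAverage:
    def _hb(self, series, fs=0.6):
        arr = np.tile(series, (2, 2, 1)).astype(float)
        return HemoglobinSeries(arr, fs, ["c0", "c1"])

    def test_constant_signal_zero_average(self):
        hb = self._hb(np.full(600, 5.0))
        ev = EventSchedule([(100.0, 6.0, "speech"), (300.0, 6.0, "speech")])
        out = block_average(hb, ev)
        np.testing.assert_allclose(out["speech"]["mean"], 0.0, atol=1e-12)

    def test_noise_free_response_peak(self, noise_free_betas):
        """Epoch-averaging a noise-free synthetic session recovers the
        injected amplitude at the peak within 10%."""
        import spafnirs as sp
        from spafnirs.pipeline import RunConfig, process_session

        betas, truth, montage = noise_free_betas
        ev = sp.sample_events(seed=1)
        rec = sp.simulate_session(montage, ev, truth, 7)
        feats = process_session(rec, montage, RunConfig(sci_threshold=None))
        out = block_average(feats.hb, ev)
        # strongest ROI: primary auditory, amplitude 1.2 uM; epoch averages
        # overlap with adjacent trials, so check peak within 10%
        idx = [feats.hb.channel_names.index(c.name) for c in montage.long_channels
               if montage.roi_map[c.name] == "A1_L"]
        peak = out["speech"]["mean"][idx, 0, :].mean(axis=0).max()
        assert peak == pytest.approx(truth.beta_speech_hbo["A1_L"], rel=0.10)

    def test_zero_epochs_rejected(self):
        hb = self._hb(np.zeros(100))
        with pytest.raises(ValueError, match="epochs"):
            block_average(hb, EventSchedule([(1000.0, 6.0, "speech")]))


def test_drift_columns_do_not_disturb_task_betas():
    """On drift-free data the DCT drift block is (near) orthogonal to the
    fitted task effect: betas change by < 1e-8."""
    n, fs = 1008, 0.6
    ev = EventSchedule(
        [(o, 6.0, "speech" if i % 2 else "silence")
         for i, o in enumerate(np.arange(60, 1500, 60.0))]
    )
    task = task_regressors(ev, fs, n)
    y = 1.7 * task["speech"].to_numpy()
    X0 = build_design_matrix(task, pd.DataFrame(index=range(n)))
    X1 = build_design_matrix(task, cosine_drift_basis(n, fs))
    b0, *_ = fit_glm(y, X0)
    b1, *_ = fit_glm(y, X1)
    assert abs(b0[0] - b1[0]) < 1e-8
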