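"""BRET normalisation and AUC, 4PL and Langmuir fits, screening calls."""

import numpy as np
import pandas as pd
import pytest

from vhhsuite.pharmacology import (
    FourPLModel,
    FourPLParams,
    LangmuirModel,
    LangmuirParams,
    auc,
    bli_double_subtract,
    classify_reporter,
    compare_fits,
    fourpl,
    nanobit_competition,
    normalize_percent_max,
    sensorgram,
)
from vhhsuite.synthetic import (
    simulate_bli_traces,
    simulate_bret_trace,
    simulate_dose_response,
    fsh_dose_grid,
)


def long_traces(**by_condition):
    frames = []
    for cond, (t, y) in by_condition.items():
        frames.append(pd.DataFrame({"time": t, "signal": y, "condition": cond}))
    return pd.concat(frames, ignore_index=True)


class TestNormalizePercentMax:
    def test_reference_maps_to_100(self):
        t = np.arange(10.0)
        traces = long_traces(ref=(t, 2.0 * t), other=(t, t))
        out = normalize_percent_max(traces, "ref")
        assert out.loc[out["condition"] == "ref", "signal"].max() == pytest.approx(100)
        assert out.loc[out["condition"] == "other", "signal"].max() == pytest.approx(50)

    def test_trace_identical_to_reference_matches_it(self):
        t = np.arange(10.0)
        traces = long_traces(ref=(t, t + 1), same=(t, t + 1))
        out = normalize_percent_max(traces, "ref")
        ref = out[out["condition"] == "ref"]["signal"].to_numpy()
        same = out[out["condition"] == "same"]["signal"].to_numpy()
        np.testing.assert_allclose(ref, same)

    def test_scaled_trace_scales_linearly(self):
        t = np.arange(20.0)
        ref = simulate_bret_trace(55.0, t, tau=5.0)
        out = normalize_percent_max(long_traces(ref=(t, ref), boosted=(t, 1.8 * ref)),
                                    "ref")
        boosted = out[out["condition"] == "boosted"]["signal"]
        assert boosted.max() == pytest.approx(180.0)

    def test_idempotent_on_normalized_reference(self):
        t = np.arange(10.0)
        traces = long_traces(ref=(t, 10 * t))
        once = normalize_percent_max(traces, "ref")
        twice = normalize_percent_max(once, "ref")
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_or_degenerate_reference(self):
        t = np.arange(5.0)
        traces = long_traces(a=(t, t))
        with pytest.raises(KeyError):
            normalize_percent_max(traces, "nope")
        with pytest.raises(ValueError):
            normalize_percent_max(long_traces(z=(t, np.zeros(5))), "z")


class TestAuc:
    def test_zero_trace(self):
        t = np.linspace(0, 600, 11)
        assert auc(t, np.zeros(11)) == 0.0

    def test_rectangle(self):
        t = np.linspace(0, 600, 601)
        assert auc(t, np.full(601, 100.0)) == pytest.approx(60_000)

    def test_triangle(self):
        t = np.linspace(0, 600, 601)
        assert auc(t, np.linspace(0, 100, 601)) == pytest.approx(30_000)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 100, 40)
        y = rng.normal(size=40)
        assert auc(t, 3.5 * y) == pytest.approx(3.5 * auc(t, y))

    def test_additive_over_concatenated_windows(self):
        t = np.linspace(0, 100, 101)
        y = np.sin(t / 10)
        total = auc(t, y, baseline_subtract=False)
        left = auc(t[:51], y[:51], baseline_subtract=False)
        right = auc(t[50:], y[50:], baseline_subtract=False)
        assert total == pytest.approx(left + right)

    def test_baseline_subtraction(self):
        t = np.linspace(-100, 100, 201)
        y = np.where(t < 0, 5.0, 15.0)
        got = auc(t, y, from_stimulation=0.0)
        assert got == pytest.approx(10.0 * 100)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            auc([0.0], [1.0])


class TestFourPL:
    @pytest.mark.parametrize("truth", [
        FourPLParams(0.0, 100.0, 1e-9, 1.0),
        FourPLParams(5.0, 60.0, 3e-8, 1.7),
    ])
    def test_noiseless_recovery_exact(self, truth):
        df = simulate_dose_response(truth, fsh_dose_grid(9), n_replicates=1,
                                    noise_sd=0.0)
        res = FourPLModel(df["dose"].to_numpy(), df["response"].to_numpy()).fit()
        assert res.ec50 == pytest.approx(truth.ec50, rel=1e-6)
        assert res.emax == pytest.approx(truth.emax, rel=1e-6)
        assert res.hill == pytest.approx(truth.hill, rel=1e-6)
        assert res.bottom == pytest.approx(truth.bottom, abs=1e-6 * truth.emax)

    def test_fixed_bottom_recovery(self):
        truth = FourPLParams(0.0, 34.52, 0.15e-9, 1.0)
        df = simulate_dose_response(truth, fsh_dose_grid(), n_replicates=1,
                                    noise_sd=0.0)
        res = FourPLModel(df["dose"].to_numpy(), df["response"].to_numpy()) \
            .fit(fix_bottom=0.0)
        assert res.bottom == 0.0
        assert res.ec50 == pytest.approx(truth.ec50, rel=1e-6)

    def test_few_doses_warns(self):
        x = np.array([1e-9, 1e-8, 1e-7])
        with pytest.warns(UserWarning):
            FourPLModel(x, fourpl(x, 0, 1, 1e-8, 1))

    def test_summary_mentions_parameters(self):
        truth = FourPLParams(0.0, 50.0, 1e-8, 1.0)
        df = simulate_dose_response(truth, fsh_dose_grid(9), n_replicates=2,
                                    noise_sd=0.5, seed=2)
        s = FourPLModel(df["dose"].to_numpy(), df["response"].to_numpy()).fit().summary()
        for word in ("ec50", "emax", "hill", "residual"):
            assert word in s


class TestCompareFits:
    def fit(self, params, seed=0, noise=0.0):
        df = simulate_dose_response(params, fsh_dose_grid(9), n_replicates=4,
                                    noise_sd=noise, seed=seed)
        return FourPLModel(df["dose"].to_numpy(), df["response"].to_numpy()) \
            .fit(fix_bottom=0.0)

    def test_identical_fits(self):
        a = self.fit(FourPLParams(0.0, 50.0, 1e-9, 1.0))
        cmp = compare_fits(a, a)
        assert cmp.ec50_fold_shift == pytest.approx(1.0)
        assert cmp.emax_ratio == pytest.approx(1.0)

    def test_reported_potency_and_efficacy_shift(self):
        """Control vs potentiated fits reproduce the reported 4.2-fold EC50
        shift (0.63 -> 0.15 nM) and 2.4x Emax gain (14.11 -> 34.52)."""
        control = self.fit(FourPLParams(0.0, 14.11, 0.63e-9, 1.0))
        treated = self.fit(FourPLParams(0.0, 34.52, 0.15e-9, 1.0))
        cmp = compare_fits(control, treated)
        assert round(cmp.emax_ratio, 1) == 2.4
        assert round(cmp.ec50_fold_shift, 1) == 4.2


class TestLangmuir:
    PARAMS = LangmuirParams(3.19e4, 1.59e-3, 1.2)
    CONCS = np.array([12.5e-9, 25e-9, 50e-9, 100e-9, 200e-9])
    TIME = np.arange(0.0, 251.0, 1.0)
    T_DISSOC = 100.0

    def test_kd_identity(self):
        for kon, koff in [(1e4, 1e-3), (3.19e4, 1.59e-3), (2e6, 0.3)]:
            p = LangmuirParams(kon, koff, 1.0)
            assert abs(p.kd * p.kon - p.koff) <= 1e-12 * p.koff

    def test_reported_rates_give_reported_kd(self):
        kd = LangmuirParams(3.19e4, 1.59e-3, 1.0).kd
        assert kd == pytest.approx(49.9e-9, rel=5e-3)

    def test_noiseless_global_fit_exact(self):
        traces = simulate_bli_traces(self.PARAMS, self.CONCS, self.TIME, self.T_DISSOC)
        res = LangmuirModel(self.TIME, traces, self.CONCS, self.T_DISSOC).fit()
        assert res.kon == pytest.approx(self.PARAMS.kon, rel=1e-6)
        assert res.koff == pytest.approx(self.PARAMS.koff, rel=1e-6)
        assert res.rmax == pytest.approx(self.PARAMS.rmax, rel=1e-6)

    def test_noisy_kd_within_15_percent(self):
        traces = simulate_bli_traces(self.PARAMS, self.CONCS, self.TIME, self.T_DISSOC,
                                     noise_sd=0.02 * self.PARAMS.rmax, seed=12)
        res = LangmuirModel(self.TIME, traces, self.CONCS, self.T_DISSOC).fit()
        assert res.kd == pytest.approx(self.PARAMS.kd, rel=0.15)

    def test_summary_reports_kd(self):
        traces = simulate_bli_traces(self.PARAMS, self.CONCS, self.TIME, self.T_DISSOC)
        s = LangmuirModel(self.TIME, traces, self.CONCS, self.T_DISSOC).fit().summary()
        assert "K_D" in s and "k_on" in s

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            LangmuirModel(self.TIME, np.zeros((2, self.TIME.size)), [1e-9], 100.0)
        with pytest.raises(ValueError):
            LangmuirParams(-1.0, 1e-3, 1.0)


class TestDoubleSubtract:
    def test_sample_equal_to_references_zeroes(self):
        t = np.linspace(0, 10, 11)
        nr, blank = np.sin(t), np.cos(t)
        out = bli_double_subtract(nr + blank, nr, blank, rezero_index=None)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_zero_references_identity(self):
        y = np.array([0.0, 1.0, 2.0])
        out = bli_double_subtract(y, np.zeros(3), np.zeros(3), rezero_index=None)
        np.testing.assert_array_equal(out, y)

    def test_drift_removed_and_kinetics_recovered(self):
        p = LangmuirParams(1e5, 2e-3, 1.0)
        t = np.arange(0.0, 181.0, 1.0)
        clean = sensorgram(t, 5e-8, p, t_dissoc=90.0)
        drift = 0.01 * t
        referenced = bli_double_subtract(clean + drift, np.zeros_like(t), drift)
        np.testing.assert_allclose(referenced, clean, atol=1e-12)
        res = LangmuirModel(t, referenced[None, :], [5e-8], 90.0).fit()
        assert res.koff == pytest.approx(p.koff, rel=1e-6)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bli_double_subtract(np.zeros(3), np.zeros(4), np.zeros(3))


class TestReporterClassification:
    def test_identical_to_control_is_neutral(self):
        nr = np.array([1000.0, 1020, 980, 1005])
        out = classify_reporter({"cand": nr.copy()}, nr)
        assert out[0].label == "neutral"
        assert out[0].percent_of_control == pytest.approx(100, rel=0.01)

    def test_doubled_response_positive(self):
        rng = np.random.default_rng(0)
        nr = 1000 + rng.normal(0, 10, size=6)
        cand = 2000 + rng.normal(0, 10, size=6)
        assert classify_reporter({"c": cand}, nr)[0].label == "positive"

    def test_halved_response_negative(self):
        rng = np.random.default_rng(0)
        nr = 1000 + rng.normal(0, 10, size=6)
        cand = 500 + rng.normal(0, 10, size=6)
        assert classify_reporter({"c": cand}, nr)[0].label == "negative"


class TestNanobitCompetition:
    def plateau_traces(self, level, n=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 65 * 60, 60.0)
        base = level * (1 - np.exp(-t / 300))
        return np.vstack([base + rng.normal(0, noise, size=t.size) for _ in range(n)])

    def test_identical_traces_no_competition(self):
        tr = self.plateau_traces(100.0)
        v = nanobit_competition(tr, tr)
        assert v.ratio == pytest.approx(1.0)
        assert not v.competes

    def test_reduced_plateau_competes(self):
        v = nanobit_competition(self.plateau_traces(30.0, noise=1.0, seed=1),
                                self.plateau_traces(100.0, noise=1.0, seed=2))
        assert v.competes
        assert v.ratio < 0.5

    def test_equal_plateaus_with_noise_no_competition(self):
        """The allosteric-binder scenario: competitor leaves the ligand
        signal unchanged; six noisy replicates give a CI containing 1."""
        v = nanobit_competition(self.plateau_traces(100.0, noise=2.0, seed=3),
                                self.plateau_traces(100.0, noise=2.0, seed=4))
        assert not v.competes
        assert v.ci_low <= 1.0 <= v.ci_high
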