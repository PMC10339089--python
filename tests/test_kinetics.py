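"""Transition metrics: analytic identities, fits, plateaus, walking speed."""

import dataclasses
import math

import numpy as np
import pytest

import nirskinetics as nk
from nirskinetics.kinetics import (
    _log_curve,
    fit_stand_tau,
    plateau_deltas,
    time_to_95_nadir,
    walking_speed,
)
from nirskinetics.preprocess import segment
from nirskinetics.synthetic import QUIET

LN20 = math.log(20.0)


def unfiltered_segmented(truth, tissue="tibia"):
    """Segment the raw simulator output without any filtering."""
    conc = nk.simulate_concentrations(truth, tissue)
    return segment(conc, truth.protocol)


class TestT95Nadir:
    def test_analytic_identity_tau_ln20(self, quiet_truth):
        """On unfiltered mono-exponential input, t95 = tau * ln 20."""
        for tissue in ("tibia", "gastrocnemius"):
            seg = unfiltered_segmented(quiet_truth, tissue)
            r = time_to_95_nadir(seg, "TSI")
            expected = quiet_truth.tissues[tissue].walk_desaturation_tau * LN20
            assert r.t95_nadir == pytest.approx(expected, rel=1e-3)
            # monotone approach: the minimum sits at the search edge, which
            # is flagged but does not invalidate the crossing time
            assert "no_desaturation" not in r.flags

    def test_step_to_nadir_crosses_at_first_sample(self, quiet_truth):
        tt = dataclasses.replace(nk.TIBIA_PRE, walk_desaturation_tau=1e-6)
        truth = nk.SimulationTruth(tissues={"tibia": tt}, noise=QUIET)
        seg = unfiltered_segmented(truth)
        r = time_to_95_nadir(seg, "TSI")
        assert r.t95_nadir == pytest.approx(0.0, abs=1.0 / 50.0)

    def test_rising_signal_flagged_no_desaturation(self):
        tt = dataclasses.replace(nk.TIBIA_PRE, walk_d_tsi=+5.0)
        truth = nk.SimulationTruth(tissues={"tibia": tt}, noise=QUIET)
        r = time_to_95_nadir(unfiltered_segmented(truth), "TSI")
        assert "no_desaturation" in r.flags
        assert r.t95_nadir is None


class TestStandTau:
    def test_exponential_fit_exact_on_noiseless_input(self, quiet_truth):
        seg = unfiltered_segmented(quiet_truth)
        for ch, true_tau in (("tHb", 37.5), ("O2Hb", 44.8)):
            fit = fit_stand_tau(seg, ch)["exponential"]
            assert fit.tau == pytest.approx(true_tau, rel=1e-3)
            assert fit.fit_r2 > 0.999999

    def test_log_curve_self_consistency(self):
        """Exact a + b ln(t + t0) input returns the generating parameters."""
        fs = 50.0
        n = int(1500 * fs)
        t = np.arange(n) / fs
        a, b, t0 = 40.0, 2.5, 8.0
        y = np.full(n, a + b * math.log(t0))
        stand = (t >= 900) & (t < 1200)
        y[stand] = _log_curve(t[stand] - 900 + 1.0 / fs, a, b, t0)
        series = nk.ChromophoreSeries(
            tissue="tibia", time=t, o2hb=y, hhb=np.zeros(n),
            tsi=np.full(n, 60.0), sample_rate_hz=fs,
        )
        seg = segment(series, nk.DEFAULT_PROTOCOL)
        fit = fit_stand_tau(seg, "O2Hb")["log_curve"]
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-9)
        # the fitted curve's 1-1/e crossing is reproducible analytically
        y_first = _log_curve(1.0 / fs, a, b, t0)
        y_end = _log_curve(120.0, a, b, t0)
        target = y_first + (1 - 1 / math.e) * (y_end - y_first)
        tau_expected = math.exp((target - a) / b) - t0
        assert fit.tau == pytest.approx(tau_expected, rel=1e-4)

    def test_log_curve_tracks_exponential_tau_within_ten_percent(self, quiet_truth):
        seg = unfiltered_segmented(quiet_truth)
        fit = fit_stand_tau(seg, "tHb")["log_curve"]
        assert fit.tau == pytest.approx(37.5, rel=0.10)

    def test_estimated_tau_strictly_increases_with_true_tau(self):
        """Monotonicity of the exponential estimate over tau in 10..120 s."""
        estimates = []
        for tau in (10.0, 25.0, 50.0, 80.0, 120.0):
            tt = dataclasses.replace(nk.TIBIA_PRE, stand_thb_tau=tau)
            truth = nk.SimulationTruth(tissues={"tibia": tt}, noise=QUIET)
            fit = fit_stand_tau(unfiltered_segmented(truth), "tHb")["exponential"]
            estimates.append(fit.tau)
        assert all(a < b for a, b in zip(estimates, estimates[1:]))

    def test_short_stand_segment_rejected(self):
        protocol = nk.ProtocolDefinition(segments=(
            ("supine_baseline", 300.0), ("walk", 600.0),
            ("stand", 30.0), ("supine_end", 300.0),
        ))
        truth = nk.SimulationTruth(protocol=protocol, noise=QUIET)
        seg = unfiltered_segmented(truth)
        with pytest.raises(ValueError, match="120"):
            fit_stand_tau(seg, "tHb")

    def test_wrong_direction_fit_flagged(self):
        # walk plateau == stand plateau for tHb, but O2Hb falls: the rising
        # "recovery" reading is undefined for a falling trace unless the fit
        # direction matches; a falling exponential still yields a tau
        tt = dataclasses.replace(nk.TIBIA_PRE, stand_d_o2hb=-6.0, stand_d_hhb=0.0)
        truth = nk.SimulationTruth(tissues={"tibia": tt}, noise=QUIET)
        fit = fit_stand_tau(unfiltered_segmented(truth), "O2Hb")["exponential"]
        assert fit.tau is not None and not fit.flags  # direction-consistent


class TestPlateaus:
    def test_constant_input_all_deltas_zero(self):
        fs = 50.0
        n = int(1500 * fs)
        series = nk.ChromophoreSeries(
            tissue="tibia", time=np.arange(n) / fs, o2hb=np.full(n, 2.0),
            hhb=np.full(n, 1.0), tsi=np.full(n, 60.0), sample_rate_hz=fs,
        )
        res = plateau_deltas(segment(series, nk.DEFAULT_PROTOCOL))
        assert all(d.delta == pytest.approx(0.0, abs=1e-12) for d in res.deltas)

    def test_normalized_means_subtract_baseline(self, segmented_pre):
        res = plateau_deltas(segmented_pre["tibia"])
        assert res.normalized_means["TSI"]["supine_baseline"] == pytest.approx(0.0)
        assert res.normalized_means["TSI"]["walk"] == pytest.approx(
            res.delta("supine_baseline", "walk", "TSI")
        )

    def test_divide_normalization_option(self, segmented_pre):
        res = plateau_deltas(segmented_pre["tibia"], normalize="divide")
        assert res.normalized_means["TSI"]["supine_baseline"] == pytest.approx(1.0)

    def test_window_longer_than_segment_rejected(self, segmented_pre):
        with pytest.raises(ValueError, match="window"):
            plateau_deltas(segmented_pre["tibia"], window_s=400.0)


class TestWalkingSpeed:
    def test_single_lap(self):
        assert walking_speed([30.0]) == pytest.approx(38.0 / 30.0)

    def test_equal_laps_invariant(self):
        assert walking_speed([30.0, 30.0]) == pytest.approx(walking_speed([30.0]))

    def test_default_study_lap_times_give_reported_speed(self):
        from nirskinetics.synthetic import DEFAULT_LAP_TIMES_S
        assert walking_speed(DEFAULT_LAP_TIMES_S) == pytest.approx(1.27, abs=0.005)

    @pytest.mark.parametrize("laps", [[], [0.0], [-3.0, 10.0]])
    def test_invalid_lap_times_rejected(self, laps):
        with pytest.raises(ValueError):
            walking_speed(laps)
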