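"""Generator: transition shapes, conservation, noise, export round trips."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import signal as sps_signal

import nirskinetics as nk
from nirskinetics.io import DataError, read_export, write_export
from nirskinetics.synthetic import QUIET, DEFAULT_LAP_TIMES_S


def zero_amplitude_truth():
    tt = dataclasses.replace(
        nk.TIBIA_PRE,
        walk_d_o2hb=0, walk_d_hhb=0, walk_d_tsi=0,
        stand_d_o2hb=0, stand_d_hhb=0, stand_d_tsi=0,
        end_d_o2hb=0, end_d_hhb=0, end_d_tsi=0,
    )
    return nk.SimulationTruth(tissues={"tibia": tt}, noise=QUIET)


def test_zero_amplitudes_give_constant_baselines():
    conc = nk.simulate_concentrations(zero_amplitude_truth(), "tibia")
    assert np.allclose(conc.o2hb, nk.TIBIA_PRE.baseline_o2hb, atol=1e-12)
    assert np.allclose(conc.hhb, nk.TIBIA_PRE.baseline_hhb, atol=1e-12)
    assert np.allclose(conc.tsi, nk.TIBIA_PRE.baseline_tsi, atol=1e-12)


def test_exponential_identity_at_one_tau(quiet_truth, tibia_conc):
    """value(t0 + tau) - start == (1 - 1/e) * amplitude, to machine precision."""
    tt = quiet_truth.tissues["tibia"]
    t = tibia_conc.time
    # walk starts at 300 s from a settled baseline
    for channel, start, amp, tau in [
        ("TSI", tt.baseline_tsi, tt.walk_d_tsi, tt.walk_desaturation_tau),
        ("HHb", tt.baseline_hhb, tt.walk_d_hhb, tt.walk_desaturation_tau),
    ]:
        i = np.argmin(np.abs(t - (300.0 + tau)))
        expected = start + amp * (1 - math.exp(-(t[i] - 300.0) / tau))
        assert tibia_conc.channel(channel)[i] == pytest.approx(expected, abs=1e-12)


def test_thb_is_exact_sum_everywhere(tibia_conc):
    # tHb is derived, never stored: the identity is structural, including in
    # the stand segment where O2Hb and tHb are the exponential primitives
    assert np.array_equal(tibia_conc.thb, tibia_conc.o2hb + tibia_conc.hhb)


def test_stand_thb_follows_its_own_time_constant(quiet_truth, tibia_conc):
    """tHb in stand is mono-exponential with stand_thb_tau although O2Hb and
    HHb individually follow different kinetics."""
    tt = quiet_truth.tissues["tibia"]
    t = tibia_conc.time
    m = (t >= 900.0) & (t < 1200.0)
    thb = tibia_conc.thb[m]
    trel = t[m] - 900.0
    start, target = thb[0], thb[0] + (tt.stand_d_o2hb + tt.stand_d_hhb)
    # start is the settled walk plateau (walk lasted >14 tau)
    expected = target - (target - start) * np.exp(-trel / tt.stand_thb_tau)
    assert np.allclose(thb, expected, atol=1e-6)


def test_unknown_tissue_error_names_valid_ids(quiet_truth):
    with pytest.raises(KeyError, match="gastrocnemius"):
        nk.simulate_concentrations(quiet_truth, "femur")


def test_forward_model_zero_delta_gives_zero_attenuation_change(quiet_truth):
    conc = nk.simulate_concentrations(zero_amplitude_truth(), "tibia")
    raw = nk.forward_model(conc, nk.TIBIA_DEVICE)
    assert np.allclose(raw.delta_attenuation(), 0.0, atol=1e-12)


def test_mbll_component_scales_with_dpf_and_rho(quiet_truth):
    """With HHb frozen, the Tx2 attenuation change is the hand-computed MBLL
    product and scales linearly in DPF (slope component cancels at Tx2)."""
    conc = nk.simulate_concentrations(quiet_truth, "tibia")
    conc.hhb = np.full_like(conc.hhb, conc.hhb[0])  # freeze HHb
    ext = nk.ExtinctionTable.default()
    for dpf_scale in (1.0, 2.0):
        dev = dataclasses.replace(nk.TIBIA_DEVICE, dpf=nk.TIBIA_DEVICE.dpf * dpf_scale)
        raw = nk.forward_model(conc, dev)
        i = 30000  # a mid-walk sample
        d_o2 = conc.o2hb[i] - conc.o2hb[0]
        for j, wl in enumerate(dev.wavelengths_nm):
            eps_o2, _ = ext.epsilon(wl)
            expected = eps_o2 * 1e-4 * d_o2 * dev.dpf * dev.separations_mm[1]
            assert raw.delta_attenuation()[i, j, 1] == pytest.approx(expected, rel=1e-12)


def test_noise_deterministic_under_seed(quiet_truth):
    conc = nk.simulate_concentrations(quiet_truth, "tibia")
    raw = nk.forward_model(conc, nk.TIBIA_DEVICE)
    noise = nk.NoiseModel(rng_seed=42, clock_offset=1.5)
    a = nk.add_noise_and_clock(raw, noise, quiet_truth.protocol)
    b = nk.add_noise_and_clock(raw, noise, quiet_truth.protocol)
    assert np.array_equal(a.attenuation, b.attenuation)
    assert np.array_equal(a.time, b.time)
    assert a.events == b.events


def test_zero_noise_zero_offset_is_identity_plus_events(quiet_truth, tibia_raw):
    conc = nk.simulate_concentrations(quiet_truth, "tibia")
    raw = nk.forward_model(conc, nk.TIBIA_DEVICE)
    out = nk.add_noise_and_clock(raw, QUIET, quiet_truth.protocol)
    assert np.array_equal(out.attenuation, raw.attenuation)
    assert np.array_equal(out.time, raw.time)
    assert len(out.events) == 6


def test_cadence_artifact_peaks_at_cadence_freq_in_walk_only(quiet_truth):
    conc = nk.simulate_concentrations(quiet_truth, "tibia")
    raw = nk.forward_model(conc, nk.TIBIA_DEVICE)
    noise = nk.NoiseModel(white_noise_sd=0.05, cadence_freq=0.9, cadence_amp=2.0,
                          drift_slope=0.0, rng_seed=3)
    noisy = nk.add_noise_and_clock(raw, noise, quiet_truth.protocol)
    fs = 50.0
    t = noisy.time

    def band_power(mask):
        f, p = sps_signal.periodogram(noisy.attenuation[mask, 0, 1], fs=fs)
        at_cad = p[np.abs(f - 0.9) < 0.05].max()
        away = p[(f > 1.5) & (f < 2.5)].max()
        return at_cad, away

    walk_cad, walk_away = band_power((t >= 300) & (t < 900))
    stand_cad, _ = band_power((t >= 900) & (t < 1200))
    assert walk_cad > 100 * walk_away    # sharp peak during walking
    assert walk_cad > 100 * stand_cad    # absent while standing


def test_cadence_frequency_must_clear_filter_cutoff():
    with pytest.raises(ValueError, match="0.05"):
        nk.NoiseModel(cadence_freq=0.2, cadence_amp=1.0)


def test_export_round_trip_with_events(tmp_path, quiet_truth):
    conc = nk.simulate_concentrations(quiet_truth, "tibia")
    raw = nk.forward_model(conc, nk.TIBIA_DEVICE)
    raw = nk.add_noise_and_clock(raw, nk.NoiseModel(rng_seed=1, clock_offset=3.7),
                                 quiet_truth.protocol)
    # 10 s slice keeps the test fast; carry the six events along
    n = 500
    short = nk.RawRecording(
        device=raw.device, time=raw.time[:n], attenuation=raw.attenuation[:n],
        tsi=raw.tsi[:n],
        events=[(i + 1, float(raw.time[j])) for i, j in enumerate(range(0, 300, 50))],
    )
    path = write_export(short, tmp_path / "tibia.tsv")
    back = read_export(path)
    assert back.device == short.device
    assert np.allclose(back.time, short.time, atol=1e-4)
    assert np.allclose(back.attenuation, short.attenuation, atol=1e-9)
    assert np.allclose(back.tsi, short.tsi, atol=1e-5)
    assert [i for i, _ in back.events] == [1, 2, 3, 4, 5, 6]
    assert len(back.events) == 6


def test_export_is_byte_deterministic(tmp_path, tibia_raw):
    p1 = write_export(tibia_raw, tmp_path / "a.tsv")
    p2 = write_export(tibia_raw, tmp_path / "b.tsv")
    assert p1.read_bytes() == p2.read_bytes()


def test_empty_recording_rejected():
    with pytest.raises(ValueError, match="empty"):
        nk.RawRecording(
            device=nk.TIBIA_DEVICE, time=np.array([]),
            attenuation=np.empty((0, 2, 3)), tsi=np.array([]),
        )


def test_simulation_truth_serialization_round_trip(quiet_truth):
    d = quiet_truth.to_dict()
    back = nk.SimulationTruth.from_dict(d)
    assert back == quiet_truth
    assert back.lap_times == DEFAULT_LAP_TIMES_S
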