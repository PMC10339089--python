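"""Forward simulator: ground-truth hemodynamics → raw two-wavelength NIRS.

The generator produces what the two acquisition laptops would have recorded
during the four-posture test: per-tissue chromophore dynamics with known
transition amplitudes and time constants, rendered to three-distance,
two-wavelength attenuation signals, with measurement noise, a cadence
artifact during walking, slow drift, independent device clocks and six
shared synchronization events.  Because every parameter is known, each
pipeline stage can be verified by parameter recovery.

Transition model
----------------
Within each posture segment every channel relaxes mono-exponentially from
its value at the segment boundary toward ``previous plateau + amplitude``
with that segment's time constant — the simplest shape consistent with the
reported estimands (a 1-1/e time constant and a time-to-95%-of-nadir, the
latter implying ``t95 = tau * ln 20`` for an exponential approach to nadir).
During standing, O2Hb and tHb are the exponential primitives (they carry
separately reported time constants) and HHb is derived as ``tHb - O2Hb``;
everywhere else O2Hb and HHb are primitives.  Total hemoglobin is never an
independent channel.

The supine-recovery segment's plateau is specified as an offset from the
*baseline* plateau (the start-to-end contrast), not from the stand plateau;
the two parameterizations cannot both be honored because reported adjacent
deltas need not telescope across a cohort.

Default parameter sets (`TRUTHS`) encode the pre- and post-bed-rest group
means: e.g. tibia PRE — walk TSI delta -7.4 %, desaturation time constant
125.4/ln(20) s (so t95 = 125.4 s), stand tHb tau 37.5 s, stand O2Hb tau
44.8 s; gastrocnemius PRE — t95 55.0 s, stand tHb tau 51.6 s.  Between-
subject standard deviations (`POPULATION_SD`) allow sampling synthetic
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .protocol import DEFAULT_PROTOCOL, ProtocolDefinition
from .spectroscopy import _EPS_UM_MM, LN10, ExtinctionTable, default_extinction
from .types import (
    DEFAULT_DEVICES,
    GASTRO_DEVICE,
    TIBIA_DEVICE,
    ChromophoreSeries,
    DeviceConfig,
    RawRecording,
)

LN20 = math.log(20.0)

#: default corridor walking: 38 m laps at the reported 1.27 m/s group mean
DEFAULT_LAP_LENGTH_M = 38.0
DEFAULT_LAP_TIMES_S = tuple([round(38.0 / 1.27, 2)] * 20)


@dataclass(frozen=True)
class TissueTruth:
    """Ground-truth kinetics of one tissue over the four-posture protocol.

    Amplitudes are plateau-to-plateau deltas in channel units (µM for
    hemoglobin, % for TSI).  ``walk_*`` and ``stand_*`` deltas are relative
    to the preceding plateau; ``end_*`` deltas are relative to the baseline
    plateau.  tHb has no amplitude of its own: its stand-transition
    primitive uses ``stand_d_o2hb + stand_d_hhb``.
    """

    tissue: str
    baseline_o2hb: float  # µM, simulator-internal absolute
    baseline_hhb: float   # µM
    baseline_tsi: float   # %
    walk_d_o2hb: float
    walk_d_hhb: float
    walk_d_tsi: float
    stand_d_o2hb: float
    stand_d_hhb: float
    stand_d_tsi: float
    end_d_o2hb: float
    end_d_hhb: float
    end_d_tsi: float
    walk_desaturation_tau: float  # s; t95 of the walk nadir = tau * ln 20
    stand_thb_tau: float          # s
    stand_o2hb_tau: float         # s (also drives stand TSI recovery)
    supine_recovery_tau: float    # s

    def __post_init__(self) -> None:
        for name in ("walk_desaturation_tau", "stand_thb_tau",
                     "stand_o2hb_tau", "supine_recovery_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_o2hb <= 0 or self.baseline_hhb <= 0:
            raise ValueError("baseline concentrations must be positive")
        if not (0 < self.baseline_tsi < 100):
            raise ValueError("baseline TSI must be in (0, 100)")


# Group-mean parameter sets.  Kinetics: t95 tibia 125.4 s PRE / 135.1 s POST,
# gastrocnemius 55.0 / 36.4 s; stand tHb tau 37.5/51.6 s PRE, 36.9/45.7 s
# POST; stand O2Hb tau 44.8/50.4 s PRE, 42.9/44.7 s POST (tibia/gastroc).
# Plateau deltas from the pre-bed-rest adjacent-transition table; post-bed-
# rest deltas reuse the PRE values except where a POST group mean was
# reported (tibia stand O2Hb +6.4, tHb +6.2; tibia start-to-end TSI +1.6).
# Absolute baselines are not observable by CW-NIRS; plausible resting values
# are used (muscle TSI ~70 %, marrow-containing tibia lower).
TIBIA_PRE = TissueTruth(
    tissue="tibia", baseline_o2hb=39.0, baseline_hhb=21.0, baseline_tsi=65.0,
    walk_d_o2hb=-0.22, walk_d_hhb=3.8, walk_d_tsi=-7.4,
    stand_d_o2hb=9.2, stand_d_hhb=0.6, stand_d_tsi=9.1,
    end_d_o2hb=2.8, end_d_hhb=-1.5, end_d_tsi=4.6,
    walk_desaturation_tau=125.4 / LN20, stand_thb_tau=37.5,
    stand_o2hb_tau=44.8, supine_recovery_tau=30.0,
)
GASTRO_PRE = TissueTruth(
    tissue="gastrocnemius", baseline_o2hb=42.0, baseline_hhb=18.0, baseline_tsi=70.0,
    walk_d_o2hb=1.6, walk_d_hhb=3.0, walk_d_tsi=-2.2,
    stand_d_o2hb=9.0, stand_d_hhb=6.0, stand_d_tsi=0.6,
    end_d_o2hb=3.4, end_d_hhb=-0.7, end_d_tsi=2.9,
    walk_desaturation_tau=55.0 / LN20, stand_thb_tau=51.6,
    stand_o2hb_tau=50.4, supine_recovery_tau=30.0,
)
TIBIA_POST = replace(
    TIBIA_PRE,
    stand_d_o2hb=6.4, stand_d_hhb=-0.2, end_d_tsi=1.6,
    walk_desaturation_tau=135.1 / LN20, stand_thb_tau=36.9, stand_o2hb_tau=42.9,
)
GASTRO_POST = replace(
    GASTRO_PRE,
    walk_desaturation_tau=36.4 / LN20, stand_thb_tau=45.7, stand_o2hb_tau=44.7,
)

TRUTHS: dict[tuple[str, str], TissueTruth] = {
    ("tibia", "PRE"): TIBIA_PRE,
    ("gastrocnemius", "PRE"): GASTRO_PRE,
    ("tibia", "POST"): TIBIA_POST,
    ("gastrocnemius", "POST"): GASTRO_POST,
}

# Between-subject standard deviations for cohort sampling, from the reported
# group mean ± SD values; SDs never reported (baselines, recovery tau, some
# POST deltas) get plausible values.  t95 SDs are converted to tau scale.
_COMMON_SD = dict(
    baseline_o2hb=5.0, baseline_hhb=3.0, baseline_tsi=5.0, supine_recovery_tau=8.0,
)
POPULATION_SD: dict[tuple[str, str], dict[str, float]] = {
    ("tibia", "PRE"): dict(
        walk_d_tsi=6.7, walk_d_o2hb=5.5, walk_d_hhb=3.1,
        stand_d_tsi=7.5, stand_d_o2hb=3.3, stand_d_hhb=3.5,
        end_d_tsi=2.9, end_d_o2hb=2.5, end_d_hhb=1.5,
        walk_desaturation_tau=56.8 / LN20, stand_thb_tau=7.1, stand_o2hb_tau=8.5,
        **_COMMON_SD,
    ),
    ("gastrocnemius", "PRE"): dict(
        walk_d_tsi=2.1, walk_d_o2hb=2.0, walk_d_hhb=2.1,
        stand_d_tsi=1.9, stand_d_o2hb=3.8, stand_d_hhb=3.5,
        end_d_tsi=1.2, end_d_o2hb=2.6, end_d_hhb=1.5,
        walk_desaturation_tau=30.1 / LN20, stand_thb_tau=6.7, stand_o2hb_tau=8.6,
        **_COMMON_SD,
    ),
}
POPULATION_SD[("tibia", "POST")] = dict(
    POPULATION_SD[("tibia", "PRE")],
    stand_d_o2hb=3.0, end_d_tsi=1.3,
    walk_desaturation_tau=93.8 / LN20, stand_thb_tau=4.0, stand_o2hb_tau=6.8,
)
POPULATION_SD[("gastrocnemius", "POST")] = dict(
    POPULATION_SD[("gastrocnemius", "PRE")],
    walk_desaturation_tau=13.9 / LN20, stand_thb_tau=5.9, stand_o2hb_tau=6.7,
)

_MIN_TAU_S = 5.0  # truncation when sampling subjects: taus stay physiological


def sample_subject_truth(
    rng: np.random.Generator, tissue: str, timepoint: str = "PRE"
) -> TissueTruth:
    """Draw one subject's TissueTruth from the population means and SDs."""
    base = TRUTHS[(tissue, timepoint)]
    sds = POPULATION_SD[(tissue, timepoint)]
    values = asdict(base)
    for name, sd in sds.items():
        values[name] = float(rng.normal(values[name], sd))
    for name in ("walk_desaturation_tau", "stand_thb_tau",
                 "stand_o2hb_tau", "supine_recovery_tau"):
        values[name] = max(values[name], _MIN_TAU_S)
    values["baseline_o2hb"] = max(values["baseline_o2hb"], 5.0)
    values["baseline_hhb"] = max(values["baseline_hhb"], 2.0)
    values["baseline_tsi"] = float(np.clip(values["baseline_tsi"], 20.0, 95.0))
    return TissueTruth(**values)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections added to the rendered attenuation signals.

    Amplitudes are µM-equivalents: they are converted to OD per channel
    through the MBLL factor of an equal O2Hb/HHb mixture, so one number sets
    a comparable disturbance at every wavelength/separation.  The cadence
    sinusoid (step-frequency artifact of walking, ~0.9 Hz at 1.27 m/s with a
    ~1.4 m stride) is applied during the walk segment only and must sit well
    above the 0.05 Hz analysis low-pass.  The paper does not report the
    artifact's observed frequency or amplitude; these defaults are
    placeholders at a realistic scale.
    """

    white_noise_sd: float = 0.1    # µM-equivalent per 50 Hz sample
    cadence_freq: float = 0.9      # Hz
    cadence_amp: float = 2.0       # µM-equivalent
    drift_slope: float = 0.01      # µM/min
    clock_offset: float = 0.0      # s, added to this device's clock
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence_amp != 0 and self.cadence_freq < 10 * 0.05:
            raise ValueError(
                f"cadence_freq {self.cadence_freq} Hz must exceed the 0.05 Hz "
                "analysis cutoff by at least 10x"
            )


QUIET = NoiseModel(white_noise_sd=0.0, cadence_amp=0.0, drift_slope=0.0)


@dataclass
class SimulationTruth:
    """Everything the generator needs, and hence the recovery oracle."""

    protocol: ProtocolDefinition = field(default_factory=lambda: DEFAULT_PROTOCOL)
    tissues: dict[str, TissueTruth] = field(
        default_factory=lambda: {"tibia": TIBIA_PRE, "gastrocnemius": GASTRO_PRE}
    )
    devices: dict[str, DeviceConfig] = field(
        default_factory=lambda: dict(DEFAULT_DEVICES)
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    lap_times: tuple[float, ...] = DEFAULT_LAP_TIMES_S
    lap_length_m: float = DEFAULT_LAP_LENGTH_M

    def to_dict(self) -> dict:
        return {
            "protocol": {"segments": [[n, d] for n, d in self.protocol.segments]},
            "tissues": {k: asdict(v) for k, v in self.tissues.items()},
            "devices": {k: asdict(v) for k, v in self.devices.items()},
            "noise": asdict(self.noise),
            "lap_times": list(self.lap_times),
            "lap_length_m": self.lap_length_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        def _tuplify_device(v: dict) -> DeviceConfig:
            v = dict(v)
            v["wavelengths_nm"] = tuple(v["wavelengths_nm"])
            v["separations_mm"] = tuple(v["separations_mm"])
            return DeviceConfig(**v)

        return cls(
            protocol=ProtocolDefinition(
                segments=tuple((n, float(d_)) for n, d_ in d["protocol"]["segments"])
            ),
            tissues={k: TissueTruth(**v) for k, v in d["tissues"].items()},
            devices={k: _tuplify_device(v) for k, v in d["devices"].items()},
            noise=NoiseModel(**d["noise"]),
            lap_times=tuple(float(t) for t in d["lap_times"]),
            lap_length_m=float(d["lap_length_m"]),
        )


def _relax(t: np.ndarray, t0: float, start: float, target: float, tau: float) -> np.ndarray:
    return target - (target - start) * np.exp(-(t - t0) / tau)


def simulate_concentrations(truth: SimulationTruth, tissue: str) -> ChromophoreSeries:
    """Noiseless absolute chromophore + TSI dynamics for one tissue at 50 Hz.

    Piecewise mono-exponential relaxation per segment; tHb is derived as
    O2Hb + HHb at every sample.
    """
    if tissue not in truth.tissues:
        raise KeyError(
            f"unknown tissue {tissue!r}; valid ids: {sorted(truth.tissues)}"
        )
    tt = truth.tissues[tissue]
    device = truth.devices.get(tissue)
    fs = device.sample_rate_hz if device is not None else 50.0
    protocol = truth.protocol

    n = int(round(protocol.total_duration * fs))
    t = np.arange(n) / fs
    o2hb = np.empty(n)
    hhb = np.empty(n)
    tsi = np.empty(n)

    base = {"O2Hb": tt.baseline_o2hb, "HHb": tt.baseline_hhb, "TSI": tt.baseline_tsi}
    walk_target = {
        "O2Hb": base["O2Hb"] + tt.walk_d_o2hb,
        "HHb": base["HHb"] + tt.walk_d_hhb,
        "TSI": base["TSI"] + tt.walk_d_tsi,
    }
    stand_target = {
        "O2Hb": walk_target["O2Hb"] + tt.stand_d_o2hb,
        "tHb": walk_target["O2Hb"] + walk_target["HHb"] + tt.stand_d_o2hb + tt.stand_d_hhb,
        "TSI": walk_target["TSI"] + tt.stand_d_tsi,
    }
    end_target = {
        "O2Hb": base["O2Hb"] + tt.end_d_o2hb,
        "HHb": base["HHb"] + tt.end_d_hhb,
        "TSI": base["TSI"] + tt.end_d_tsi,
    }

    cur = dict(base)  # running value at the segment boundary
    for name, (t0, t1) in protocol.boundaries().items():
        m = (t >= t0) & (t < t1)
        tm = t[m]
        if name == "supine_baseline":
            o2hb[m], hhb[m], tsi[m] = cur["O2Hb"], cur["HHb"], cur["TSI"]
            # boundary values unchanged
        elif name == "walk":
            tau = tt.walk_desaturation_tau
            o2hb[m] = _relax(tm, t0, cur["O2Hb"], walk_target["O2Hb"], tau)
            hhb[m] = _relax(tm, t0, cur["HHb"], walk_target["HHb"], tau)
            tsi[m] = _relax(tm, t0, cur["TSI"], walk_target["TSI"], tau)
            for ch, tgt in walk_target.items():
                cur[ch] = float(_relax(np.array([t1]), t0, cur[ch], tgt, tau)[0])
        elif name == "stand":
            thb_start = cur["O2Hb"] + cur["HHb"]
            o2 = _relax(tm, t0, cur["O2Hb"], stand_target["O2Hb"], tt.stand_o2hb_tau)
            th = _relax(tm, t0, thb_start, stand_target["tHb"], tt.stand_thb_tau)
            o2hb[m] = o2
            hhb[m] = th - o2
            tsi[m] = _relax(tm, t0, cur["TSI"], stand_target["TSI"], tt.stand_o2hb_tau)
            end_o2 = float(_relax(np.array([t1]), t0, cur["O2Hb"],
                                  stand_target["O2Hb"], tt.stand_o2hb_tau)[0])
            end_th = float(_relax(np.array([t1]), t0, thb_start,
                                  stand_target["tHb"], tt.stand_thb_tau)[0])
            cur["TSI"] = float(_relax(np.array([t1]), t0, cur["TSI"],
                                      stand_target["TSI"], tt.stand_o2hb_tau)[0])
            cur["O2Hb"], cur["HHb"] = end_o2, end_th - end_o2
        elif name == "supine_end":
            tau = tt.supine_recovery_tau
            o2hb[m] = _relax(tm, t0, cur["O2Hb"], end_target["O2Hb"], tau)
            hhb[m] = _relax(tm, t0, cur["HHb"], end_target["HHb"], tau)
            tsi[m] = _relax(tm, t0, cur["TSI"], end_target["TSI"], tau)
            for ch, tgt in end_target.items():
                cur[ch] = float(_relax(np.array([t1]), t0, cur[ch], tgt, tau)[0])
        else:
            raise ValueError(f"unknown protocol segment {name!r}")

    return ChromophoreSeries(
        tissue=tissue, time=t, o2hb=o2hb, hhb=hhb, tsi=tsi,
        sample_rate_hz=fs, absolute=True,
    )


def forward_model(
    conc: ChromophoreSeries,
    device: DeviceConfig,
    extinction: ExtinctionTable | None = None,
) -> RawRecording:
    """Render chromophore dynamics to three-distance attenuation signals.

    The attenuation at wavelength lambda and separation rho is the MBLL
    component ``DPF * rho * sum_c eps_c * dC_c`` plus a spatial-slope
    component carrying the SRS information: the slope of A vs rho is set so
    the diffusion-approximation estimator returns exactly the absorption
    implied by the simulated TSI and total hemoglobin.  The slope component
    is zero-mean in rho, so when the middle separation equals the mean
    separation (the default 30/35/40 mm geometry) it cancels at Tx2 and the
    MBLL inversion there is exact as well.
    """
    ext = extinction or default_extinction()
    if not conc.absolute:
        raise ValueError("forward model needs absolute concentrations (simulator output)")
    E = ext.matrix(device.wavelengths_nm)  # (2, 2)
    seps = np.asarray(device.separations_mm, dtype=float)
    rho_bar = seps.mean()

    d_conc = np.stack([conc.o2hb - conc.o2hb[0], conc.hhb - conc.hhb[0]], axis=1)
    M = _EPS_UM_MM * d_conc @ E.T  # (n, 2 wavelengths), OD per mm

    # absolute absorption implied by the simulated TSI channel and total Hb
    thb = conc.thb
    srs_conc = np.stack([thb * conc.tsi / 100.0, thb * (1.0 - conc.tsi / 100.0)], axis=1)
    mua = LN10 * _EPS_UM_MM * srs_conc @ E.T  # (n, 2), mm^-1
    if np.any(mua <= 0):
        raise ValueError("non-positive absorption: check baselines and TSI range")
    mus = np.array([device.mu_s_prime(w) for w in device.wavelengths_nm])
    slope_target = (np.sqrt(3.0 * mus * mua) + 2.0 / rho_bar) / LN10  # (n, 2)

    A = (
        device.dpf * M[:, :, None] * seps[None, None, :]
        + (slope_target - device.dpf * M)[:, :, None] * (seps - rho_bar)[None, None, :]
    )
    return RawRecording(
        device=device,
        time=conc.time.copy(),
        attenuation=A,
        tsi=conc.tsi.copy(),
        events=[],
    )


def add_noise_and_clock(
    raw: RawRecording,
    noise: NoiseModel,
    protocol: ProtocolDefinition,
    extinction: ExtinctionTable | None = None,
) -> RawRecording:
    """Add white noise, walking-cadence artifact, drift, a clock offset and
    the six shared synchronization events.  Deterministic given ``rng_seed``.

    Noise amplitudes are µM-equivalents converted to OD through the MBLL
    factor of a 50:50 O2Hb/HHb mixture; the device TSI channel is left
    untouched (the pipeline re-derives TSI from the noisy attenuations).
    """
    ext = extinction or default_extinction()
    device = raw.device
    rng = np.random.default_rng(noise.rng_seed)
    E = ext.matrix(device.wavelengths_nm)
    seps = np.asarray(device.separations_mm, dtype=float)
    # OD per µM-equivalent, per (wavelength, separation)
    od_scale = _EPS_UM_MM * E.mean(axis=1)[:, None] * device.dpf * seps[None, :]

    t = raw.time
    A = raw.attenuation.copy()
    if noise.white_noise_sd > 0:
        A += noise.white_noise_sd * rng.standard_normal(A.shape) * od_scale[None, :, :]
    if noise.drift_slope != 0:
        A += (noise.drift_slope * (t - t[0]) / 60.0)[:, None, None] * od_scale[None, :, :]
    if noise.cadence_amp != 0:
        w0, w1 = protocol.boundaries()["walk"]
        in_walk = (t >= w0) & (t < w1)
        cad = noise.cadence_amp * np.sin(2 * np.pi * noise.cadence_freq * (t - w0))
        cad[~in_walk] = 0.0
        A += cad[:, None, None] * od_scale[None, :, :]

    # events at shared true instants, snapped to this device's sample grid
    shifted_t = t + noise.clock_offset
    events = []
    for idx, true_time in enumerate(protocol.sync_event_times(), start=1):
        i = int(np.argmin(np.abs(t - true_time)))
        events.append((idx, float(shifted_t[i])))

    return RawRecording(
        device=device, time=shifted_t, attenuation=A,
        tsi=raw.tsi.copy(), events=events,
    )


def simulate_device_recording(
    truth: SimulationTruth, tissue: str, clock_offset: float | None = None
) -> RawRecording:
    """simulate → forward-model → noise/clock for one device.

    Each device draws from its own noise stream (seed offset by its position
    in the tissue list) so the two recordings are not noise-correlated.
    """
    conc = simulate_concentrations(truth, tissue)
    device = truth.devices[tissue]
    raw = forward_model(conc, device)
    idx = sorted(truth.tissues).index(tissue)
    noise = replace(truth.noise, rng_seed=(truth.noise.rng_seed + 7919 * idx) % 2**31)
    if clock_offset is not None:
        noise = replace(noise, clock_offset=clock_offset)
    return add_noise_and_clock(raw, noise, truth.protocol)
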