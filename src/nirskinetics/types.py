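"""Core containers shared across the pipeline.

Conventions
-----------
* time: seconds; every series carries its own clock until synchronization.
* attenuation: decadic optical density (OD), shape ``(n_samples, n_wavelengths,
  n_separations)``.
* concentrations: micromolar (µM).  Continuous-wave NIRS only resolves
  *changes*, so pipeline outputs are deltas from the first valid sample;
  the simulator works with absolute values internally (``absolute=True``).
* TSI: percent oxygenated of total hemoglobin, in ``[0, 100]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class DeviceConfig:
    """Optode geometry and conversion constants of one NIRS device.

    ``k`` and ``h`` parameterize the reduced scattering coefficient used by
    spatially resolved spectroscopy, ``mu_s'(lambda) = k * (1 - h * lambda)``
    with lambda in nm and mu_s' in mm^-1.  ``dpf`` is the differential
    pathlength factor of the modified Beer-Lambert law.
    """

    tissue: str
    wavelengths_nm: tuple[float, float]
    separations_mm: tuple[float, float, float] = (30.0, 35.0, 40.0)
    dpf: float = 6.0
    k: float = 1.5
    h: float = 5e-4
    sample_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        if len(self.wavelengths_nm) != 2:
            raise ValueError("exactly two wavelengths required")
        seps = self.separations_mm
        if not all(b > a for a, b in zip(seps, seps[1:])):
            raise ValueError(f"separations must be strictly increasing, got {seps}")
        if self.dpf <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("dpf and sample_rate_hz must be positive")

    def mu_s_prime(self, wavelength_nm: float) -> float:
        """Reduced scattering coefficient (mm^-1) at a wavelength."""
        mus = self.k * (1.0 - self.h * wavelength_nm)
        if mus <= 0:
            raise ValueError(
                f"non-physical mu_s' = {mus:.3g} mm^-1 at {wavelength_nm} nm "
                f"(k={self.k}, h={self.h})"
            )
        return mus


# Device parameter sets used in the study: a tibial probe over the
# anteromedial tibia and a muscle probe over the lateral gastrocnemius.
TIBIA_DEVICE = DeviceConfig(
    tissue="tibia", wavelengths_nm=(853.0, 762.0), dpf=7.0, k=1.5, h=5e-4
)
GASTRO_DEVICE = DeviceConfig(
    tissue="gastrocnemius", wavelengths_nm=(845.0, 759.0), dpf=5.24, k=1.63, h=5.5e-4
)
DEFAULT_DEVICES = {"tibia": TIBIA_DEVICE, "gastrocnemius": GASTRO_DEVICE}


@dataclass
class RawRecording:
    """One device's raw multi-distance attenuation record with event markers.

    ``attenuation[i, j, m]`` is the OD at sample ``i``, wavelength ``j``
    (order of ``device.wavelengths_nm``) and transmitter ``m`` (order of
    ``device.separations_mm``).  ``tsi`` is the device-computed saturation
    channel as exported by the acquisition software.  ``events`` are
    ``(index, device_clock_time_s)`` pairs, 1-based and time-ordered.
    """

    device: DeviceConfig
    time: np.ndarray
    attenuation: np.ndarray
    tsi: np.ndarray
    events: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        self.tsi = np.asarray(self.tsi, dtype=float)
        n = self.time.shape[0]
        if n == 0:
            raise ValueError("empty recording")
        if self.attenuation.shape != (n, 2, len(self.device.separations_mm)):
            raise ValueError(
                f"attenuation shape {self.attenuation.shape} does not match "
                f"{n} samples x 2 wavelengths x {len(self.device.separations_mm)} separations"
            )
        if self.tsi.shape != (n,):
            raise ValueError("tsi channel length mismatch")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.time.shape[0])

    def delta_attenuation(self) -> np.ndarray:
        """Attenuation change from the first sample (the CW-NIRS observable)."""
        return self.attenuation - self.attenuation[0]

    def shifted(self, dt: float) -> "RawRecording":
        """Copy with the device clock shifted by ``dt`` seconds."""
        return RawRecording(
            device=self.device,
            time=self.time + dt,
            attenuation=self.attenuation.copy(),
            tsi=self.tsi.copy(),
            events=[(i, t + dt) for i, t in self.events],
        )


@dataclass
class ChromophoreSeries:
    """Per-tissue hemoglobin series: O2Hb, HHb (µM) and TSI (%).

    Total hemoglobin is never stored: ``thb`` is always the sample-wise sum
    ``o2hb + hhb`` so the conservation identity holds by construction.
    """

    tissue: str
    time: np.ndarray
    o2hb: np.ndarray
    hhb: np.ndarray
    tsi: np.ndarray
    sample_rate_hz: float
    absolute: bool = False  # simulator-internal absolute concentrations

    CHANNELS = ("O2Hb", "HHb", "tHb", "TSI")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.shape[0]
        for name in ("o2hb", "hhb", "tsi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"channel {name} length mismatch")
            setattr(self, name, arr)

    @property
    def thb(self) -> np.ndarray:
        return self.o2hb + self.hhb

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"O2Hb": self.o2hb, "HHb": self.hhb,
                    "tHb": self.thb, "TSI": self.tsi}[name]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}; expected one of {self.CHANNELS}")

    def map(self, fn) -> "ChromophoreSeries":
        """Apply ``fn`` to each stored channel (O2Hb, HHb, TSI)."""
        return ChromophoreSeries(
            tissue=self.tissue,
            time=self.time.copy(),
            o2hb=fn(self.o2hb),
            hhb=fn(self.hhb),
            tsi=fn(self.tsi),
            sample_rate_hz=self.sample_rate_hz,
            absolute=self.absolute,
        )

    def as_deltas(self) -> "ChromophoreSeries":
        """Concentrations re-referenced to the first sample (TSI untouched)."""
        out = self.map(lambda x: x)
        out.o2hb = self.o2hb - self.o2hb[0]
        out.hhb = self.hhb - self.hhb[0]
        out.absolute = False
        return out


@dataclass
class SegmentedSeries:
    """A ChromophoreSeries with per-sample posture labels and segment windows."""

    series: ChromophoreSeries
    labels: np.ndarray  # per-sample segment name ('' outside the protocol)
    boundaries: dict[str, tuple[float, float]]

    def segment_mask(self, name: str) -> np.ndarray:
        if name not in self.boundaries:
            raise KeyError(f"unknown segment {name!r}; have {list(self.boundaries)}")
        return self.labels == name

    def segment_time_and_values(self, name: str, channel: str):
        mask = self.segment_mask(name)
        return self.series.time[mask], self.series.channel(channel)[mask]

    def last_window_mean(self, name: str, channel: str, window_s: float = 60.0) -> float:
        """Mean of the final ``window_s`` seconds of a segment."""
        t0, t1 = self.boundaries[name]
        if window_s > (t1 - t0) + 1e-9:
            raise ValueError(
                f"window {window_s} s exceeds segment {name!r} duration {t1 - t0} s"
            )
        t, v = self.segment_time_and_values(name, channel)
        if t.size == 0:
            raise ValueError(f"segment {name!r} contains no samples")
        mask = t >= t1 - window_s
        return float(np.nanmean(v[mask]))


__all__ = [
    "DeviceConfig",
    "RawRecording",
    "ChromophoreSeries",
    "SegmentedSeries",
    "TIBIA_DEVICE",
    "GASTRO_DEVICE",
    "DEFAULT_DEVICES",
    "replace",
]
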