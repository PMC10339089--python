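"""Raw optical signal → chromophore concentrations and tissue saturation.

Two standard continuous-wave NIRS conversions:

* **Modified Beer–Lambert law (MBLL).**  The attenuation change at wavelength
  lambda and source–detector separation rho is

  .. math::

     \\Delta A(\\lambda, \\rho, t)
        = \\big( \\varepsilon_{O2Hb}(\\lambda)\\,\\Delta[O_2Hb](t)
        + \\varepsilon_{HHb}(\\lambda)\\,\\Delta[HHb](t) \\big)\\,DPF\\,\\rho .

  With two wavelengths this is a 2x2 linear system per sample for the two
  concentration changes.  By convention the middle transmitter (Tx2) is used,
  whose penetration depth (half the separation, 17.5 mm at 35 mm) spans the
  anterior tibial cortex and medulla.

* **Spatially resolved spectroscopy (SRS).**  The spatial slope of
  attenuation across the three separations yields the absolute absorption
  coefficient through the diffusion approximation,

  .. math::

     \\mu_a(\\lambda) = \\frac{1}{3 \\mu_s'(\\lambda)}
        \\left( \\ln 10 \\, \\frac{\\partial A}{\\partial \\rho}
        - \\frac{2}{\\bar\\rho} \\right)^2 ,

  with reduced scattering modeled as ``mu_s'(lambda) = k (1 - h lambda)``
  (device constants, mm^-1) and ``rho_bar`` the mean separation.  Converting
  the two absorption values to relative chromophore concentrations gives the
  tissue saturation index ``TSI = 100 * O2Hb / (O2Hb + HHb)``, which is
  independent of the overall concentration scale.

Units: epsilon in mM^-1 cm^-1, concentrations in µM, separations in mm;
``_EPS_UM_MM = 1e-4`` converts epsilon to µM^-1 mm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .types import ChromophoreSeries, DeviceConfig, RawRecording

#: mM^-1 cm^-1  ->  µM^-1 mm^-1
_EPS_UM_MM = 1e-4
LN10 = float(np.log(10.0))

#: above this condition number the two wavelengths no longer separate the
#: chromophores; far beyond any physical NIR pair
CONDITION_LIMIT = 1e6


@dataclass(frozen=True)
class ExtinctionTable:
    """Decadic molar extinction of O2Hb / HHb vs wavelength (mM^-1 cm^-1)."""

    wavelengths_nm: np.ndarray
    eps_o2hb: np.ndarray
    eps_hhb: np.ndarray

    @classmethod
    def from_file(cls, path) -> "ExtinctionTable":
        data = np.loadtxt(path, comments="#")
        return cls(data[:, 0], data[:, 1], data[:, 2])

    @classmethod
    def default(cls) -> "ExtinctionTable":
        ref = resources.files("nirskinetics").joinpath("data/extinction_hemoglobin.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def epsilon(self, wavelength_nm: float) -> tuple[float, float]:
        """(eps_O2Hb, eps_HHb) at a wavelength, linear interpolation."""
        w = self.wavelengths_nm
        if not (w[0] <= wavelength_nm <= w[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside extinction table "
                f"range [{w[0]}, {w[-1]}] nm"
            )
        return (
            float(np.interp(wavelength_nm, w, self.eps_o2hb)),
            float(np.interp(wavelength_nm, w, self.eps_hhb)),
        )

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 extinction matrix E[i, :] = (eps_O2Hb, eps_HHb) at wavelength i."""
        E = np.array([self.epsilon(w) for w in wavelengths])
        cond = np.linalg.cond(E)
        if cond > CONDITION_LIMIT:
            raise ValueError(
                f"extinction matrix ill-conditioned (cond={cond:.3g}) for "
                f"wavelengths {wavelengths}: cannot separate O2Hb from HHb"
            )
        return E


_DEFAULT_TABLE: ExtinctionTable | None = None


def default_extinction() -> ExtinctionTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ExtinctionTable.default()
    return _DEFAULT_TABLE


def invert_mbll(
    raw: RawRecording,
    rho_index: int = 2,
    extinction: ExtinctionTable | None = None,
) -> ChromophoreSeries:
    """Concentration changes (µM) from two-wavelength attenuation at one Tx.

    ``rho_index`` is 1-based (1..3); the default Tx2 matches the analysis
    convention for the tibial probe.  Output O2Hb/HHb are changes from the
    first sample; the TSI channel is left as the device's own (use
    :func:`estimate_tsi` for the SRS estimate).
    """
    ext = extinction or default_extinction()
    device = raw.device
    if rho_index not in (1, 2, 3):
        raise ValueError(f"rho_index must be 1, 2 or 3, got {rho_index}")
    rho = device.separations_mm[rho_index - 1]
    E = ext.matrix(device.wavelengths_nm)  # (2 wavelengths, 2 chromophores)

    dA = raw.delta_attenuation()[:, :, rho_index - 1]  # (n, 2)
    # dA = E @ c * (eps scale) * DPF * rho  ->  c = E^-1 dA / (scale DPF rho)
    conc = np.linalg.solve(E, dA.T).T / (_EPS_UM_MM * device.dpf * rho)
    return ChromophoreSeries(
        tissue=device.tissue,
        time=raw.time.copy(),
        o2hb=conc[:, 0],
        hhb=conc[:, 1],
        tsi=raw.tsi.copy(),
        sample_rate_hz=device.sample_rate_hz,
        absolute=False,
    )


def _spatial_slope(attenuation: np.ndarray, separations: np.ndarray) -> np.ndarray:
    """Least-squares slope of A vs rho, per sample and wavelength."""
    rho = separations - separations.mean()
    return np.einsum("ijm,m->ij", attenuation, rho) / np.dot(rho, rho)


def estimate_tsi(
    raw: RawRecording,
    extinction: ExtinctionTable | None = None,
    monotone_tol: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Tissue saturation index (%) by spatially resolved spectroscopy.

    Returns ``(tsi, valid)``.  Samples where the attenuation-vs-distance
    slope is too shallow for the diffusion relation (``ln10 * slope <=
    2/rho_bar``), decreases with distance beyond ``monotone_tol`` OD, or
    yields non-positive total hemoglobin are flagged invalid and set to NaN
    rather than silently dropped.
    """
    ext = extinction or default_extinction()
    device = raw.device
    seps = np.asarray(device.separations_mm, dtype=float)
    if seps.size < 3:
        raise ValueError("SRS needs at least three source-detector separations")
    rho_bar = seps.mean()

    slope = _spatial_slope(raw.attenuation, seps)  # (n, 2)
    span = raw.attenuation[:, :, -1] - raw.attenuation[:, :, 0]
    valid = np.all(span >= -monotone_tol, axis=1)

    core = LN10 * slope - 2.0 / rho_bar
    valid &= np.all(core > 0, axis=1)

    mus = np.array([device.mu_s_prime(w) for w in device.wavelengths_nm])
    mua = core**2 / (3.0 * mus)  # (n, 2), mm^-1

    # mu_a = ln10 * eps_scale * E @ [O2Hb, HHb]  (absolute, µM)
    E = ext.matrix(device.wavelengths_nm)
    conc = np.linalg.solve(E, mua.T).T / (LN10 * _EPS_UM_MM)
    total = conc.sum(axis=1)
    valid &= total > 0

    tsi = np.full(raw.n_samples, np.nan)
    tsi[valid] = 100.0 * conc[valid, 0] / total[valid]
    valid &= (tsi >= 0) & (tsi <= 100) | ~valid
    tsi[~valid] = np.nan
    return tsi, valid


def to_chromophores(
    raw: RawRecording,
    rho_index: int = 2,
    extinction: ExtinctionTable | None = None,
    use_srs_tsi: bool = True,
) -> ChromophoreSeries:
    """Full conversion: MBLL concentrations at Tx``rho_index`` + SRS TSI.

    Invalid SRS samples (NaN) are linearly interpolated so downstream
    filtering stays well-defined; the fraction interpolated is available to
    callers via :func:`estimate_tsi`.
    """
    series = invert_mbll(raw, rho_index=rho_index, extinction=extinction)
    if use_srs_tsi:
        tsi, valid = estimate_tsi(raw, extinction=extinction)
        if not valid.any():
            raise ValueError("no valid SRS samples: attenuation-vs-distance slope degenerate")
        if not valid.all():
            idx = np.arange(tsi.size)
            tsi = np.interp(idx, idx[valid], tsi[valid])
        series.tsi = tsi
    return series
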