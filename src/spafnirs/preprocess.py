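"""Raw-intensity preprocessing for continuous-wave fNIRS.

Implements the standard conversion chain: raw two-wavelength intensities ->
optical density (natural log, relative to the channel's mean intensity) ->
scalp-coupling-index quality screening -> modified Beer-Lambert inversion to
oxy-/deoxy-hemoglobin concentration changes (micromolar) -> anti-aliased
resampling to the GLM working rate, plus z-scoring / low-pass conditioning of
auxiliary systemic-physiology sensors onto the fNIRS timebase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "EXTINCTION_CM_PER_M",
    "OpticalDensitySeries",
    "HemoglobinSeries",
    "ChannelQuality",
    "intensity_to_od",
    "scalp_coupling_index",
    "prune_channels",
    "beer_lambert",
    "resample_series",
    "condition_physiology",
    "extinction_matrix",
]

# Molar extinction coefficients (cm^-1 / M), standard compiled hemoglobin
# spectra values at the two acquisition wavelengths. Columns: (HbO, HbR).
EXTINCTION_CM_PER_M = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}

CARDIAC_BAND_HZ = (0.7, 1.5)


def extinction_matrix(wavelengths=(760.0, 850.0)) -> np.ndarray:
    """2x2 extinction matrix E[lambda, chromophore] in cm^-1/M."""
    try:
        rows = [EXTINCTION_CM_PER_M[float(w)] for w in wavelengths]
    except KeyError as exc:  # pragma: no cover - guard
        raise KeyError(f"no extinction coefficients for wavelength {exc}") from exc
    E = np.array(rows, dtype=float)
    if abs(np.linalg.det(E)) < 1e-6:
        raise ValueError("singular extinction matrix")
    return E


@dataclass
class OpticalDensitySeries:
    od: np.ndarray  # (n_channels, n_wavelengths, n_times), unitless
    fs_hz: float
    channel_names: list[str]
    wavelengths: tuple[float, float] = (760.0, 850.0)


@dataclass
class HemoglobinSeries:
    hb: np.ndarray  # (n_channels, 2, n_times), micromolar; axis 1 = (HbO, HbR)
    fs_hz: float
    channel_names: list[str]
    chromophores: tuple[str, str] = ("HbO", "HbR")

    def channel(self, name: str, chromophore: str = "HbO") -> np.ndarray:
        return self.hb[self.channel_names.index(name), self.chromophores.index(chromophore)]


@dataclass
class ChannelQuality:
    """Per-channel scalp coupling index and retention flags."""

    sci: dict[str, float]
    retained: dict[str, bool] = field(default_factory=dict)
    threshold: float | None = None


def intensity_to_od(recording) -> OpticalDensitySeries:
    """Convert raw intensities to optical density: od = -ln(I / mean_t I).

    The temporal mean serves as the per-channel baseline, so any positive
    rescaling of the intensities leaves the OD unchanged.
    """
    I = np.asarray(recording.intensities, dtype=float)
    if np.any(I <= 0):
        raise ValueError("intensities must be strictly positive")
    baseline = I.mean(axis=-1, keepdims=True)
    od = -np.log(I / baseline)
    return OpticalDensitySeries(
        od, recording.fs_hz, list(recording.channel_names), tuple(recording.wavelengths)
    )


def scalp_coupling_index(od: OpticalDensitySeries, fs_hz: float | None = None) -> ChannelQuality:
    """Cardiac-band (0.7-1.5 Hz) zero-lag correlation between the two
    wavelengths of each channel.

    A channel coupled to the scalp carries the cardiac pulsation coherently
    at both wavelengths; a decoupled channel shows independent noise.
    Channels whose filtered signal has (numerically) zero variance get an
    undefined SCI (NaN) and are flagged as not retained.
    """
    fs = fs_hz if fs_hz is not None else od.fs_hz
    x = od.od
    if x.shape[-1] / fs < 10.0:
        raise ValueError("recording too short for SCI (need >= 10 s)")
    lo, hi = CARDIAC_BAND_HZ
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError("sampling rate too low to contain the cardiac band")
    sos = signal.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")
    filt = signal.sosfiltfilt(sos, x, axis=-1)
    filt = filt - filt.mean(axis=-1, keepdims=True)
    sd = filt.std(axis=-1)
    sci: dict[str, float] = {}
    for i, name in enumerate(od.channel_names):
        s0, s1 = sd[i]
        if s0 < 1e-300 or s1 < 1e-300:
            sci[name] = float("nan")
            continue
        r = float(np.dot(filt[i, 0], filt[i, 1]) / (x.shape[-1] * s0 * s1))
        sci[name] = float(np.clip(r, -1.0, 1.0))
    return ChannelQuality(sci=sci)


def prune_channels(quality: ChannelQuality, threshold: float = 0.7) -> ChannelQuality:
    """Retain channels with SCI >= threshold; undefined SCI is never retained."""
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("SCI threshold must lie in [-1, 1]")
    retained = {
        name: bool(np.isfinite(v) and v >= threshold) for name, v in quality.sci.items()
    }
    return ChannelQuality(sci=dict(quality.sci), retained=retained, threshold=threshold)


def beer_lambert(
    od: OpticalDensitySeries,
    montage,
    dpf: float | tuple[float, float] = 6.0,
) -> HemoglobinSeries:
    """Modified Beer-Lambert inversion to chromophore concentration changes.

    Solves, per channel, the 2x2 system
    ``dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d * DPF(lambda)``
    for (dHbO, dHbR) in micromolar, with d the source-detector separation and
    DPF the differential pathlength factor.
    """
    E = extinction_matrix(od.wavelengths)
    dpf_arr = np.broadcast_to(np.asarray(dpf, dtype=float), (2,))
    sep = {c.name: c.separation_mm for c in montage.channels}
    try:
        d_cm = np.array([sep[name] for name in od.channel_names]) / 10.0
    except KeyError as exc:
        raise KeyError(f"missing separation for channel {exc}") from exc
    invE = np.linalg.inv(E)
    # scale OD by per-wavelength pathlength, then invert the extinction matrix
    scaled = od.od / (dpf_arr[None, :, None] * d_cm[:, None, None])
    hb_molar = np.einsum("kl,clt->ckt", invE, scaled)
    return HemoglobinSeries(hb_molar * 1e6, od.fs_hz, list(od.channel_names))


def resample_series(x: np.ndarray, fs_hz: float, target_fs: float = 0.6):
    """Anti-aliased polyphase resampling along the last axis.

    Returns ``(y, new_fs)``. The rate ratio is expressed as a small rational
    (e.g. 0.6/5.1 = 2/17) so the output rate is exact.
    """
    if target_fs >= fs_hz:
        raise ValueError("target_fs must be below the source sampling rate")
    frac = Fraction(target_fs / fs_hz).limit_denominator(1000)
    y = signal.resample_poly(
        np.asarray(x, dtype=float), frac.numerator, frac.denominator,
        axis=-1, padtype="mean",
    )
    return y, fs_hz * frac.numerator / frac.denominator


def condition_physiology(
    aux: dict,
    fnirs_fs_hz: float,
    n_times: int,
    lowpass_hz: float | None = 0.5,
):
    """Condition auxiliary physiology onto the fNIRS sample grid.

    Each signal is z-scored (mean 0, sd 1), low-pass filtered at
    ``lowpass_hz`` (skipped when the signal's own Nyquist is below the
    cutoff), and linearly interpolated onto the fNIRS timebase.

    Returns ``(conditioned, excluded)`` where ``conditioned`` maps signal
    name -> array of length ``n_times`` and ``excluded`` lists constant
    (zero-variance) signals that cannot participate in denoising.
    """
    t_fnirs = np.arange(n_times) / fnirs_fs_hz
    out: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, series in aux.items():
        v = np.asarray(series.values, dtype=float)
        fs = series.fs_hz
        if (len(v) - 1) / fs < t_fnirs[-1] - 1e-9:
            raise ValueError(f"aux signal {name!r} does not cover the fNIRS time span")
        sd = v.std()
        if sd == 0:
            excluded.append(name)
            continue
        z = (v - v.mean()) / sd
        if lowpass_hz is not None and fs / 2.0 > lowpass_hz:
            sos = signal.butter(4, lowpass_hz / (fs / 2.0), btype="low", output="sos")
            z = signal.sosfiltfilt(sos, z)
        t_own = np.arange(len(z)) / fs
        out[name] = np.interp(t_fnirs, t_own, z)
    return out, excluded
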