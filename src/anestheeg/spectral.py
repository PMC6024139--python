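"""Multitaper spectral estimation and band-power extraction.

Power spectral densities are estimated by averaging periodograms computed with
orthonormal DPSS (Slepian) tapers, the standard variance-reduction technique
for EEG. All powers are one-sided densities in µV²/Hz, reported in dB as
10·log10(density), with no reference normalization.

Two parameter regimes are used downstream: short 2-s windows (nw=3, k=5) for
time-resolved spectrograms, and the full 120-s analysis epoch (nw=6, k=11) for
per-subject spectra, where the long window makes the 0.1–1 Hz slow band
resolvable (half-bandwidth nw/T = 0.05 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import detrend as _detrend
from scipy.signal.windows import dpss as _dpss

from .records import EEGRecord

#: Linear-density floor applied before taking logs, µV²/Hz.
POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


#: The study's canonical bands.
BANDS: dict[str, BandDefinition] = {
    "slow": BandDefinition("slow", 0.1, 1.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "slow_delta": BandDefinition("slow_delta", 0.1, 4.0),
    "total": BandDefinition("total", 0.1, 40.0),
}


@dataclass
class TaperParams:
    """Multitaper settings: time-halfbandwidth product, taper count, window/step (s)."""

    nw: float
    k: int
    window: float | None = None
    step: float | None = None


@dataclass
class SpectralEstimate:
    """A spectrum (power shape (n_freq,)) or spectrogram (shape (n_times, n_freq)).

    ``power_db`` is 10·log10 of one-sided density in µV²/Hz; ``times`` holds
    window centers in seconds for time-resolved estimates, else None.
    """

    freqs: np.ndarray
    power_db: np.ndarray
    taper_params: TaperParams
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.isfinite(self.power_db).all():
            raise ValueError("non-finite power")

    @property
    def power_linear(self) -> np.ndarray:
        return 10.0 ** (self.power_db / 10.0)


def dpss_tapers(n_samples: int, nw: float, k: int) -> np.ndarray:
    """Orthonormal DPSS tapers, shape (k, n_samples), by decreasing concentration.

    Requires k ≤ 2·nw − 1 (tapers beyond that have poor in-band energy
    concentration) and n_samples > k.
    """
    if k < 1 or k > 2 * nw - 1:
        raise ValueError(f"taper count k={k} must satisfy 1 <= k <= 2*nw-1 (nw={nw})")
    if n_samples <= k:
        raise ValueError("need more samples than tapers")
    return _cached_dpss(int(n_samples), float(nw), int(k))


@lru_cache(maxsize=32)
def _cached_dpss(n: int, nw: float, k: int) -> np.ndarray:
    # unit-energy normalization (norm=2 when Kmax given); the symmetric
    # eigenvector solution keeps the family exactly orthonormal
    return _dpss(n, nw, Kmax=k)


def multitaper_spectrum(
    segment: np.ndarray,
    fs: float,
    nw: float = 6.0,
    k: int = 11,
    tapers: np.ndarray | None = None,
    detrend: bool = True,
) -> SpectralEstimate:
    """Multitaper PSD of one channel segment.

    The segment is linearly detrended (constant + slope) before tapering so
    band powers are invariant to offsets. Passing an explicit ``tapers`` matrix
    (rows unit-energy) overrides the DPSS family — with a single rectangular
    taper 1/sqrt(n) the estimate is exactly the periodogram.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("segment must be a nonempty 1-D array")
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples in segment")
    if x.size < 2 * fs:
        raise ValueError("segment must be at least 2 s long")
    if detrend:
        x = _detrend(x, type="linear")
    if tapers is None:
        tapers = dpss_tapers(x.size, nw, k)
    else:
        tapers = np.atleast_2d(np.asarray(tapers, dtype=float))
        if tapers.shape[1] != x.size:
            raise ValueError("taper length mismatch")
        k = tapers.shape[0]
    psd = _taper_psd(x, tapers, fs)
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    power_db = 10.0 * np.log10(np.maximum(psd, POWER_FLOOR))
    return SpectralEstimate(freqs, power_db, TaperParams(nw=nw, k=k))


def _taper_psd(x: np.ndarray, tapers: np.ndarray, fs: float) -> np.ndarray:
    """One-sided PSD averaged over unit-energy tapers (µV²/Hz)."""
    n = x.size
    spec = np.fft.rfft(tapers * x[None, :], axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs
    # one-sided scaling: double all bins except DC and (for even n) Nyquist
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    return psd


def multitaper_spectrogram(
    record: EEGRecord,
    window: float = 2.0,
    step: float = 0.1,
    nw: float = 3.0,
    k: int = 5,
    channel: int | None = None,
) -> SpectralEstimate:
    """Sliding-window multitaper spectrogram.

    Returns one spectrum per window position with times at window centers.
    ``channel=None`` averages the four channels in linear power; an integer
    selects a single channel.
    """
    if window > record.duration:
        raise ValueError("window longer than record")
    nwin = int(round(window * record.fs))
    nstep = int(round(step * record.fs))
    if nstep < 1:
        raise ValueError("step too small")
    tapers = dpss_tapers(nwin, nw, k)
    freqs = np.fft.rfftfreq(nwin, 1.0 / record.fs)
    data = record.samples if channel is None else record.samples[channel:channel + 1]
    starts = np.arange(0, data.shape[1] - nwin + 1, nstep)
    power = np.empty((starts.size, freqs.size))
    for i, s in enumerate(starts):
        seg = _detrend(data[:, s:s + nwin], type="linear", axis=1)
        psd = np.mean(
            [_taper_psd(ch, tapers, record.fs) for ch in seg], axis=0
        )
        power[i] = 10.0 * np.log10(np.maximum(psd, POWER_FLOOR))
    times = (starts + nwin / 2.0) / record.fs
    return SpectralEstimate(
        freqs, power, TaperParams(nw=nw, k=k, window=window, step=step), times=times
    )


def average_channels(per_channel: list[SpectralEstimate]) -> SpectralEstimate:
    """Average spectra across channels in linear power, then convert back to dB.

    All inputs must share one frequency grid (and time grid, if resolved).
    """
    if not per_channel:
        raise ValueError("no spectra to average")
    ref = per_channel[0]
    for est in per_channel[1:]:
        if est.freqs.shape != ref.freqs.shape or not np.allclose(est.freqs, ref.freqs):
            raise ValueError("frequency grid mismatch")
    lin = np.mean([est.power_linear for est in per_channel], axis=0)
    return SpectralEstimate(
        ref.freqs.copy(),
        10.0 * np.log10(np.maximum(lin, POWER_FLOOR)),
        ref.taper_params,
        times=None if ref.times is None else ref.times.copy(),
    )


def epoch_spectrum(
    record: EEGRecord, nw: float = 6.0, k: int = 11
) -> SpectralEstimate:
    """Channel-averaged multitaper spectrum of a full (typically 120-s) epoch."""
    per_ch = [
        multitaper_spectrum(ch, record.fs, nw=nw, k=k) for ch in record.samples
    ]
    return average_channels(per_ch)


def band_power(spectrum: SpectralEstimate, band: BandDefinition | str) -> float:
    """Mean linear power density over the band's bins, in dB.

    Bins are included on the half-open interval [lo, hi). For time-resolved
    estimates the mean is over the band and all windows.
    """
    if isinstance(band, str):
        band = BANDS[band]
    mask = (spectrum.freqs >= band.lo) & (spectrum.freqs < band.hi)
    if not mask.any():
        raise ValueError(
            f"band [{band.lo}, {band.hi}) not resolved by frequency grid "
            f"(df={np.median(np.diff(spectrum.freqs)):.4g} Hz)"
        )
    lin = spectrum.power_linear[..., mask]
    return float(10.0 * np.log10(max(lin.mean(), POWER_FLOOR)))
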