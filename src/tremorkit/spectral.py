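"""Tremor power-spectrum analysis.

The pipeline mirrors a standard accelerometer/EMG tremor workflow: remove
any DC offset, resample so that FFT bins land on round frequencies, average
Hanning-windowed FFT segments into a one-sided power spectrum (V^2 per bin),
sum power over named frequency bands, and render sonograms.

Scaling convention
------------------
Spectra are Parseval-normalized: the sum of the one-sided bin powers equals
the mean-square of the (offset-removed) signal, with Hanning-window
compensation. A unit-amplitude sinusoid therefore integrates to 0.5 V^2.
Absolute V^2 values from uncalibrated accelerometers are only meaningful as
relative quantities; every comparison in this package is a within-pipeline
ratio.

Band definitions follow the tremor literature convention used throughout
the package: alpha+beta = 8 to 19.5 Hz (covering the harmaline tremor peak)
and gamma = 20 to 30 Hz, both closed intervals. The DC bin is excluded from
band sums since the offset is removed upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy import signal as sps

from .core import SignalTrace

__all__ = [
    "PowerSpectrum",
    "BandPower",
    "Sonogram",
    "ALPHA_BETA_BAND",
    "GAMMA_BAND",
    "remove_offset",
    "align_bins",
    "power_spectrum",
    "band_power",
    "peak_frequency",
    "normalize_to_peak",
    "sonogram",
]

#: Alpha + beta band (Hz), sized to capture the entire harmaline tremor peak.
ALPHA_BETA_BAND = (8.0, 19.5)
#: Gamma band (Hz), reflecting movement-related frequencies away from the peak.
GAMMA_BAND = (20.0, 30.0)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum: power per frequency bin in V^2."""

    freqs_hz: np.ndarray
    power_v2: np.ndarray
    resolution_hz: float
    window: str
    nfft: int

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs_hz, dtype=np.float64)
        power = np.asarray(self.power_v2, dtype=np.float64)
        if freqs.shape != power.shape:
            raise ValueError("freqs_hz and power_v2 must have equal length")
        if np.any(freqs < 0):
            raise ValueError("frequencies must be non-negative")
        if np.any(power < -1e-15):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "freqs_hz", freqs)
        object.__setattr__(self, "power_v2", np.maximum(power, 0.0))

    @property
    def total_power_v2(self) -> float:
        return float(self.power_v2.sum())


@dataclass(frozen=True)
class BandPower:
    """Summed bin power over a closed frequency band."""

    lo_hz: float
    hi_hz: float
    power_v2: float

    def __post_init__(self) -> None:
        if not (self.lo_hz < self.hi_hz):
            raise ValueError("band requires lo_hz < hi_hz")
        if self.power_v2 < 0:
            raise ValueError("band power must be non-negative")


@dataclass(frozen=True)
class Sonogram:
    """Short-time power spectrum in dB re 1 V^2 (time x frequency)."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power_db: np.ndarray
    window: str

    def __post_init__(self) -> None:
        if self.power_db.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValueError("power_db must be (n_freqs, n_times)")


def remove_offset(trace: SignalTrace) -> SignalTrace:
    """Subtract the sample mean so the waveform is centred on 0 V."""
    return SignalTrace(trace.samples - trace.samples.mean(), trace.fs_hz, trace.t0_s)


def align_bins(trace: SignalTrace, target_res_hz: float = 0.25) -> SignalTrace:
    """Resample so FFT bins align exactly to multiples of ``target_res_hz``.

    The returned sampling rate is the largest rate not exceeding the
    original for which ``fs / nfft == target_res_hz`` with ``nfft`` a power
    of two (e.g. 5000 Hz with a 0.25 Hz target resamples to 4096 Hz, nfft
    16384). Samples are linearly interpolated onto the new grid. The
    companion transform size is stored in ``meta`` via :func:`aligned_nfft`.

    Raises
    ------
    ValueError
        If ``target_res_hz`` does not divide 1 Hz, or the trace is shorter
        than one analysis window (``1 / target_res_hz`` seconds).
    """
    if target_res_hz <= 0 or abs(round(1.0 / target_res_hz) - 1.0 / target_res_hz) > 1e-9:
        raise ValueError("target_res_hz must divide 1 Hz (e.g. 0.25 or 0.5)")
    if trace.duration_s < 1.0 / target_res_hz:
        raise ValueError(
            f"trace of {trace.duration_s:.3f} s cannot support a "
            f"{target_res_hz} Hz resolution (needs >= {1.0 / target_res_hz:.1f} s)"
        )
    nfft = aligned_nfft(trace.fs_hz, target_res_hz)
    new_fs = nfft * target_res_hz
    if new_fs == trace.fs_hz:
        return trace
    new_n = int(np.floor(trace.duration_s * new_fs))
    new_times = np.arange(new_n) / new_fs
    old_times = np.arange(len(trace)) / trace.fs_hz
    resampled = np.interp(new_times, old_times, trace.samples)
    return SignalTrace(resampled, new_fs, trace.t0_s)


def aligned_nfft(fs_hz: float, target_res_hz: float) -> int:
    """Power-of-two transform size paired with :func:`align_bins`."""
    n = int(2 ** np.floor(np.log2(fs_hz / target_res_hz)))
    if n < 2:
        raise ValueError("sampling rate too low for requested resolution")
    return n


def power_spectrum(
    trace: SignalTrace, nfft: int, window: str = "hann"
) -> PowerSpectrum:
    """Welch-style averaged one-sided power spectrum (V^2 per bin).

    Non-overlapping ``nfft``-sample segments are windowed (Hanning by
    default), transformed, and averaged; the scaling is chosen so the sum
    over all bins equals the mean-square of the signal (window compensated).
    """
    if len(trace) < nfft:
        raise ValueError(f"trace ({len(trace)} samples) shorter than nfft={nfft}")
    freqs, psd = sps.welch(
        trace.samples,
        fs=trace.fs_hz,
        window=window,
        nperseg=nfft,
        noverlap=0,
        detrend=False,
        scaling="density",
        return_onesided=True,
    )
    df = trace.fs_hz / nfft
    return PowerSpectrum(freqs, psd * df, resolution_hz=df, window=window, nfft=nfft)


def _band_mask(
    freqs: np.ndarray, lo_hz: float, hi_hz: float, include_dc: bool = False
) -> np.ndarray:
    eps = 1e-9
    mask = (freqs >= lo_hz - eps) & (freqs <= hi_hz + eps)
    if not include_dc:
        mask &= freqs > eps
    return mask


def band_power(
    ps: PowerSpectrum, lo_hz: float, hi_hz: float, include_dc: bool = False
) -> BandPower:
    """Sum bin power over the closed band ``[lo_hz, hi_hz]``.

    The DC bin is excluded by default because the offset is removed
    upstream of spectral analysis.
    """
    if lo_hz >= hi_hz:
        raise ValueError("band requires lo_hz < hi_hz")
    if hi_hz > ps.freqs_hz[-1] + 1e-9 or lo_hz < -1e-9:
        raise ValueError("band lies outside the spectrum range")
    mask = _band_mask(ps.freqs_hz, lo_hz, hi_hz, include_dc)
    return BandPower(lo_hz, hi_hz, float(ps.power_v2[mask].sum()))


def peak_frequency(ps: PowerSpectrum, lo_hz: float, hi_hz: float) -> float:
    """Frequency of the maximum-power bin within ``[lo_hz, hi_hz]``.

    Ties break toward the lower frequency.
    """
    mask = _band_mask(ps.freqs_hz, lo_hz, hi_hz)
    if not np.any(mask):
        raise ValueError("band contains no spectrum bins")
    freqs = ps.freqs_hz[mask]
    power = ps.power_v2[mask]
    return float(freqs[int(np.argmax(power))])


def normalize_to_peak(values: Sequence) -> np.ndarray:
    """Divide each value by the maximum across conditions (max maps to 1).

    Accepts plain numbers or :class:`BandPower` objects, matching the
    convention of normalizing each individual's band powers to their
    overall maximum across pre/during/post (or baseline/tremor/DBS)
    periods.
    """
    arr = np.asarray(
        [v.power_v2 if isinstance(v, BandPower) else float(v) for v in values],
        dtype=np.float64,
    )
    if arr.size == 0:
        raise ValueError("no values supplied")
    if np.any(arr < 0):
        raise ValueError("band powers must be non-negative")
    peak = arr.max()
    if peak <= 0:
        raise ValueError("cannot normalize: all values are zero")
    return arr / peak


def sonogram(trace: SignalTrace, nfft: int, hop: int, window: str = "hann") -> Sonogram:
    """Short-time FFT power in dB re 1 V^2, with columns every ``hop`` samples.

    A stationary sinusoid produces a single horizontal ridge at its
    frequency; harmaline onset appears as a ridge near the tremor peak
    emerging partway through the recording.
    """
    if hop <= 0:
        raise ValueError("hop must be positive")
    if len(trace) < nfft:
        raise ValueError("trace shorter than one FFT window")
    freqs, times, psd = sps.spectrogram(
        trace.samples,
        fs=trace.fs_hz,
        window=window,
        nperseg=nfft,
        noverlap=nfft - hop,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    power = psd * (trace.fs_hz / nfft)
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    return Sonogram(times + trace.t0_s, freqs, power_db, window)
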