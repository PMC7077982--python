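"""Seeded generators for every input the analysis pipeline consumes.

These stand in for the study's recordings: accelerometer traces for
baseline physiological tremor (broadband 1/f-like noise with a weak ~11 Hz
peak), harmaline tremor (a strong narrowband ~12.5 Hz peak riding on the
baseline), optogenetically entrained tremor at a commanded frequency,
Purkinje-style spike trains (tonic gamma-renewal simple spikes with sparse
complex spikes, or harmaline-mode bursting led by a complex spike and
preceded by a pause), EMG as a rate-modulated motor-unit impulse train
convolved with a biphasic action-potential kernel, a controllable tremor
"plant" whose oscillation amplitude responds to stimulation (the closed-loop
test harness standing in for the mouse), and images of roughly circular
puncta with recorded ground truth.

Every generator is driven by one explicit integer seed per call; identical
configuration and seed produce byte-identical output. No global random
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import COMPLEX, SIMPLE, SignalTrace, SpikeTrain

__all__ = [
    "TremorSynthConfig",
    "SpikeSynthConfig",
    "PlantConfig",
    "PunctaSynthConfig",
    "PunctaGroundTruth",
    "TremorPlant",
    "baseline_config",
    "harmaline_config",
    "entrained_config",
    "gen_tremor_signal",
    "gen_spike_train",
    "gen_emg_signal",
    "run_plant",
    "gen_puncta_image",
]

MODES = ("baseline", "harmaline", "entrained")

# Default tremor-monitor sampling rate. The closed-loop detector spec
# (8192-point FFT spanning 1.6384 s) implies exactly 8192/1.6384 = 5000 Hz.
DEFAULT_FS_HZ = 5000.0

# Tremor peaks: baseline physiological peak ~11 Hz; harmaline tremor peak
# 12.5 Hz (control + harmaline condition).
BASELINE_PEAK_HZ = 11.0
HARMALINE_PEAK_HZ = 12.5

# Purkinje-cell control-baseline firing statistics used as tonic defaults:
# simple-spike rate 77.63 Hz with CV 0.4902 (gamma shape = CV^-2), complex
# spikes as a gamma(2) renewal process at 1.289 Hz.
DEFAULT_SS_RATE_HZ = 77.63
DEFAULT_SS_CV = 0.4902
DEFAULT_CS_RATE_HZ = 1.289

# Bursting-mode defaults drawn from the harmaline condition: burst (complex
# spike) rate 2.876 Hz with a 0.04651 s pre-complex-spike pause.
DEFAULT_BURST_RATE_HZ = 2.876
DEFAULT_PRE_CS_PAUSE_S = 0.04651


@dataclass(frozen=True)
class TremorSynthConfig:
    """Parameters of a synthetic tremor-monitor trace.

    The signal is 1/f-shaped Gaussian noise (physiological tremor spectra
    decay with frequency) plus an amplitude-modulated sinusoid at
    ``peak_freq_hz``; the mode selects which condition the defaults
    emulate.
    """

    duration_s: float
    fs_hz: float = DEFAULT_FS_HZ
    peak_freq_hz: float = HARMALINE_PEAK_HZ
    peak_amp_v: float = 0.1
    am_depth: float = 0.3
    am_rate_hz: float = 1.0
    noise_floor_v: float = 0.02
    mode: str = "harmaline"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.fs_hz <= 2 * self.peak_freq_hz:
            raise ValueError("fs_hz must exceed twice peak_freq_hz (Nyquist)")
        if not (0.0 <= self.am_depth <= 1.0):
            raise ValueError("am_depth must lie in [0, 1]")
        if self.peak_amp_v < 0 or self.noise_floor_v < 0:
            raise ValueError("amplitudes must be non-negative")


def baseline_config(duration_s: float = 120.0, seed: int = 0, **kw) -> TremorSynthConfig:
    """Baseline physiological tremor: weak ~11 Hz peak over 1/f noise."""
    defaults = dict(
        peak_freq_hz=BASELINE_PEAK_HZ, peak_amp_v=0.01, noise_floor_v=0.02,
        mode="baseline",
    )
    defaults.update(kw)
    return TremorSynthConfig(duration_s=duration_s, seed=seed, **defaults)


def harmaline_config(duration_s: float = 120.0, seed: int = 0, **kw) -> TremorSynthConfig:
    """Harmaline tremor: strong narrowband 12.5 Hz peak over the baseline."""
    defaults = dict(
        peak_freq_hz=HARMALINE_PEAK_HZ, peak_amp_v=0.1, noise_floor_v=0.02,
        mode="harmaline",
    )
    defaults.update(kw)
    return TremorSynthConfig(duration_s=duration_s, seed=seed, **defaults)


def entrained_config(
    freq_hz: float, duration_s: float = 120.0, seed: int = 0, **kw
) -> TremorSynthConfig:
    """Optogenetically entrained tremor at the commanded frequency."""
    defaults = dict(peak_freq_hz=freq_hz, peak_amp_v=0.1, noise_floor_v=0.02,
                    mode="entrained")
    defaults.update(kw)
    return TremorSynthConfig(duration_s=duration_s, seed=seed, **defaults)


def _pink_noise(rng: np.random.Generator, n: int, fs_hz: float) -> np.ndarray:
    """Unit-variance 1/f-power-shaped Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 -> power ~ 1/f
    pink = np.fft.irfft(spec * shaping, n)
    std = pink.std()
    return pink / std if std > 0 else pink


def _tremor_components(config: TremorSynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """(noise, oscillation) parts of a tremor trace, drawn from one seed."""
    n = int(round(config.duration_s * config.fs_hz))
    t = np.arange(n) / config.fs_hz
    rng = np.random.default_rng(config.seed)
    carrier_phase = rng.uniform(0.0, 2.0 * np.pi)
    am_phase = rng.uniform(0.0, 2.0 * np.pi)
    envelope = config.peak_amp_v * (
        1.0 + config.am_depth * np.sin(2.0 * np.pi * config.am_rate_hz * t + am_phase)
    )
    osc = envelope * np.sin(2.0 * np.pi * config.peak_freq_hz * t + carrier_phase)
    if config.noise_floor_v > 0:
        noise = config.noise_floor_v * _pink_noise(rng, n, config.fs_hz)
    else:
        noise = np.zeros(n)
    return noise, osc


def gen_tremor_signal(config: TremorSynthConfig) -> SignalTrace:
    """Synthetic accelerometer trace for the configured tremor condition."""
    noise, osc = _tremor_components(config)
    return SignalTrace(noise + osc, config.fs_hz)


@dataclass(frozen=True)
class SpikeSynthConfig:
    """Parameters of a synthetic Purkinje-style spike train.

    Tonic mode draws simple-spike ISIs from a gamma renewal process
    (CV = gamma_shape^-1/2) with complex spikes as an independent slow
    gamma renewal process. Bursting mode emulates the harmaline response:
    each burst period opens with a complex spike followed by a
    variable-size burst of simple spikes (Poisson around
    ``spikes_per_burst``) at irregular intervals; the last simple spike of
    each burst is pinned exactly ``pre_cs_pause_s`` before the next
    complex spike, so every burst is led by a complex spike and preceded
    by a pause. The irregular intra-burst intervals and varying burst
    sizes elevate the simple-spike CV above the tonic value, as bursting
    does in recordings.
    """

    duration_s: float
    ss_rate_hz: float = DEFAULT_SS_RATE_HZ
    gamma_shape: float = 1.0 / DEFAULT_SS_CV**2
    cs_rate_hz: float = DEFAULT_CS_RATE_HZ
    cs_gamma_shape: float = 2.0
    mode: str = "tonic"
    burst_rate_hz: float = DEFAULT_BURST_RATE_HZ
    spikes_per_burst: int = 17
    pre_cs_pause_s: float = DEFAULT_PRE_CS_PAUSE_S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.mode not in ("tonic", "bursting"):
            raise ValueError(f"mode must be 'tonic' or 'bursting', got {self.mode!r}")
        for name in ("ss_rate_hz", "cs_rate_hz", "burst_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gamma_shape <= 0 or self.cs_gamma_shape <= 0:
            raise ValueError("gamma shapes must be positive")
        if self.mode == "bursting":
            if self.spikes_per_burst < 1:
                raise ValueError("bursting mode needs spikes_per_burst >= 1")
            if self.burst_rate_hz <= 0:
                raise ValueError("bursting mode needs a positive burst rate")
            if not (0 < self.pre_cs_pause_s < 1.0 / self.burst_rate_hz):
                raise ValueError(
                    "pre_cs_pause_s must be positive and shorter than the burst period"
                )


def _gamma_renewal_times(
    rng: np.random.Generator, rate_hz: float, shape: float, duration_s: float
) -> np.ndarray:
    """Event times of a gamma renewal process truncated to the duration."""
    if rate_hz <= 0:
        return np.empty(0)
    scale = 1.0 / (shape * rate_hz)
    times: list[np.ndarray] = []
    t_end = 0.0
    # draw in blocks sized from the expected count until the span is covered
    block = max(16, int(duration_s * rate_hz * 1.2) + 16)
    while t_end < duration_s:
        isis = rng.gamma(shape, scale, size=block)
        chunk = t_end + np.cumsum(isis)
        times.append(chunk)
        t_end = chunk[-1]
    all_times = np.concatenate(times)
    return all_times[all_times < duration_s]


def gen_spike_train(config: SpikeSynthConfig) -> SpikeTrain:
    """Synthetic spike train for the configured firing mode."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "tonic":
        ss = _gamma_renewal_times(rng, config.ss_rate_hz, config.gamma_shape,
                                  config.duration_s)
        cs = _gamma_renewal_times(rng, config.cs_rate_hz, config.cs_gamma_shape,
                                  config.duration_s)
        times = np.concatenate([ss, cs])
        labels = np.concatenate(
            [np.full(ss.size, SIMPLE, "U1"), np.full(cs.size, COMPLEX, "U1")]
        )
        order = np.argsort(times, kind="stable")
        times, labels = times[order], labels[order]
        # continuous draws never tie in practice; guard against it anyway
        keep = np.concatenate([[True], np.diff(times) > 0])
        times, labels = times[keep], labels[keep]
    else:
        period = 1.0 / config.burst_rate_hz
        span = period - config.pre_cs_pause_s  # burst occupies the rest
        times_list: list[float] = []
        labels_list: list[str] = []
        t0 = 0.0
        while t0 < config.duration_s:
            times_list.append(t0)
            labels_list.append(COMPLEX)
            n_k = max(1, int(rng.poisson(config.spikes_per_burst)))
            interior = np.sort(rng.uniform(0.0, span, size=n_k - 1))
            # last simple spike pinned so the pre-complex-spike pause is exact
            for ss_t in np.append(t0 + interior, t0 + span):
                if ss_t < config.duration_s:
                    times_list.append(ss_t)
                    labels_list.append(SIMPLE)
            t0 += period
        times = np.asarray(times_list)
        labels = np.asarray(labels_list, dtype="U1")
        keep = np.concatenate([[True], np.diff(times) > 0])
        times, labels = times[keep], labels[keep]
    return SpikeTrain(times, labels, duration_s=config.duration_s)


def gen_emg_signal(
    tremor_freq_hz: float,
    duration_s: float,
    fs_hz: float = DEFAULT_FS_HZ,
    seed: int = 0,
    *,
    base_rate_hz: float = 100.0,
    mod_depth: float = 0.8,
    kernel_amp_v: float = 1.0,
    kernel_width_s: float = 0.002,
) -> SignalTrace:
    """EMG trace: rate-modulated motor-unit impulses through a biphasic kernel.

    Motor-unit firing is an inhomogeneous Poisson process whose rate is
    sinusoidally modulated at the tremor frequency; each impulse is
    convolved with a biphasic (Gaussian-derivative) motor-unit action
    potential. The power spectrum peaks at ``tremor_freq_hz``, and band
    power scales with the square of ``kernel_amp_v``.
    """
    if fs_hz < 1000:
        raise ValueError("EMG synthesis requires fs_hz >= 1000")
    if tremor_freq_hz >= fs_hz / 2:
        raise ValueError("tremor frequency must be below Nyquist")
    if not (0.0 <= mod_depth <= 1.0):
        raise ValueError("mod_depth must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    rate = base_rate_hz * (1.0 + mod_depth * np.sin(2.0 * np.pi * tremor_freq_hz * t))
    p = np.clip(rate / fs_hz, 0.0, 1.0)
    impulses = (rng.random(n) < p).astype(np.float64)
    half = int(round(3 * kernel_width_s * fs_hz))
    tk = np.arange(-half, half + 1) / fs_hz
    kernel = -tk / kernel_width_s * np.exp(-(tk**2) / (2.0 * kernel_width_s**2))
    kernel *= kernel_amp_v / np.abs(kernel).max()
    emg = np.convolve(impulses, kernel, mode="same")
    return SignalTrace(emg, fs_hz)


@dataclass(frozen=True)
class PlantConfig:
    """Controllable tremor plant for closed-loop testing.

    The plant's oscillation amplitude relaxes exponentially toward
    ``floor_fraction`` of its nominal value with time constant
    ``suppression_tau_s`` while stimulation is ON, and back toward nominal
    with ``recovery_tau_s`` while OFF. This is test scaffolding standing in
    for the animal: in the original protocol the mouse itself closes the
    loop.
    """

    tremor: TremorSynthConfig
    suppression_tau_s: float = 0.2
    recovery_tau_s: float = 1.0
    floor_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.suppression_tau_s <= 0 or self.recovery_tau_s <= 0:
            raise ValueError("time constants must be positive")
        if not (0.0 <= self.floor_fraction <= 1.0):
            raise ValueError("floor_fraction must lie in [0, 1]")


class TremorPlant:
    """Streaming interface to a :class:`PlantConfig` tremor source.

    Samples are consumed with :meth:`step`, which applies the amplitude
    dynamics for the current stimulation state. With stimulation always
    OFF the output equals :func:`gen_tremor_signal` of the underlying
    tremor configuration exactly.
    """

    def __init__(self, config: PlantConfig):
        self.config = config
        noise, osc = _tremor_components(config.tremor)
        self._noise = noise
        self._osc = osc
        self._gain = 1.0
        self._pos = 0

    @property
    def fs_hz(self) -> float:
        return self.config.tremor.fs_hz

    @property
    def n_samples(self) -> int:
        return self._noise.size

    @property
    def remaining(self) -> int:
        return self.n_samples - self._pos

    def step(self, n: int, stim_on: bool) -> np.ndarray:
        """Emit the next ``n`` samples under the given stimulation state."""
        if n < 0 or n > self.remaining:
            raise ValueError("requested samples exceed the plant horizon")
        cfg = self.config
        target = cfg.floor_fraction if stim_on else 1.0
        tau = cfg.suppression_tau_s if stim_on else cfg.recovery_tau_s
        dt = 1.0 / self.fs_hz
        if self._gain == target:
            gains = np.full(n, target)
        else:
            decay = np.exp(-dt * np.arange(1, n + 1) / tau)
            gains = target + (self._gain - target) * decay
        sl = slice(self._pos, self._pos + n)
        out = self._noise[sl] + gains * self._osc[sl]
        if n:
            self._gain = float(gains[-1])
        self._pos += n
        return out


def run_plant(plant: PlantConfig, stim_state: np.ndarray) -> SignalTrace:
    """Run the plant over a precomputed on/off schedule.

    ``stim_state`` is a boolean array sampled at the plant's rate; its
    length must match the tremor configuration's sample count.
    """
    stim = np.asarray(stim_state, dtype=bool)
    sim = TremorPlant(plant)
    if stim.size != sim.n_samples:
        raise ValueError(
            f"stim_state length {stim.size} does not match plant length {sim.n_samples}"
        )
    out = np.empty(stim.size)
    # emit in runs of constant state so the exponential update is exact
    pos = 0
    while pos < stim.size:
        state = stim[pos]
        end = pos + 1
        while end < stim.size and stim[end] == state:
            end += 1
        out[pos:end] = sim.step(end - pos, bool(state))
        pos = end
    return SignalTrace(out, sim.fs_hz)


@dataclass(frozen=True)
class PunctaSynthConfig:
    """Parameters of a synthetic puncta image."""

    size_px: int = 256
    pixel_size_um: float = 0.5
    n_puncta: int = 50
    radius_px: float = 4.0
    radius_jitter: float = 0.15
    intensity: float = 200.0
    noise_sigma: float = 5.0
    clump_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 8:
            raise ValueError("image must be at least 8 px")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be non-negative")
        if self.radius_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("radius and pixel size must be positive")
        if not (0.0 <= self.clump_fraction <= 1.0):
            raise ValueError("clump_fraction must lie in [0, 1]")
        if not (0.0 <= self.radius_jitter < 1.0):
            raise ValueError("radius_jitter must lie in [0, 1)")


@dataclass(frozen=True)
class PunctaGroundTruth:
    """Recorded truth for a generated puncta image."""

    centers_px: np.ndarray  # (n, 2) as (row, col)
    radii_px: np.ndarray
    areas_px: np.ndarray  # rasterized pixel count per punctum
    touching_pairs: tuple = field(default_factory=tuple)
    foreground_fraction: float = 0.0

    @property
    def count(self) -> int:
        return int(self.radii_px.size)


def _disk_mask(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def gen_puncta_image(
    config: PunctaSynthConfig,
) -> tuple[np.ndarray, PunctaGroundTruth]:
    """Grayscale image of disks plus Gaussian background noise, with truth.

    A ``clump_fraction`` of the puncta are placed in overlapping pairs
    (centres ~1.5 radii apart) so watershed splitting can be exercised;
    the remainder are kept well separated.
    """
    rng = np.random.default_rng(config.seed)
    size = config.size_px
    n = config.n_puncta
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    touching: list[tuple[int, int]] = []

    def draw_radius() -> float:
        r = config.radius_px * (1.0 + config.radius_jitter * rng.uniform(-1, 1))
        return max(r, 1.0)

    def fits(cy: float, cx: float, r: float, min_gap: float) -> bool:
        margin = r + 1.0
        if not (margin <= cy <= size - margin and margin <= cx <= size - margin):
            return False
        for (oy, ox), orad in zip(centers, radii):
            if np.hypot(cy - oy, cx - ox) < r + orad + min_gap:
                return False
        return True

    n_pairs = int(round(config.clump_fraction * n / 2.0))
    gap = max(3.0, config.radius_px)
    max_tries = 20000
    placed_pairs = 0
    while len(centers) < n:
        r = draw_radius()
        make_pair = placed_pairs < n_pairs and len(centers) + 2 <= n
        for _ in range(max_tries):
            cy, cx = rng.uniform(0, size, size=2)
            if not make_pair:
                if fits(cy, cx, r, gap):
                    centers.append((cy, cx))
                    radii.append(r)
                    break
            else:
                r2 = draw_radius()
                theta = rng.uniform(0, 2 * np.pi)
                d = 0.75 * (r + r2)  # overlapping pair for watershed tests
                cy2, cx2 = cy + d * np.sin(theta), cx + d * np.cos(theta)
                # the pair must fit while staying clear of everyone else
                if fits(cy, cx, r, gap) and fits(cy2, cx2, r2, -d):
                    ok = True
                    m2 = r2 + 1.0
                    if not (m2 <= cy2 <= size - m2 and m2 <= cx2 <= size - m2):
                        ok = False
                    for (oy, ox), orad in zip(centers, radii):
                        if np.hypot(cy2 - oy, cx2 - ox) < r2 + orad + gap:
                            ok = False
                            break
                    if ok:
                        i = len(centers)
                        centers.extend([(cy, cx), (cy2, cx2)])
                        radii.extend([r, r2])
                        touching.append((i, i + 1))
                        placed_pairs += 1
                        break
        else:
            raise ValueError(
                f"could not place {n} puncta of radius ~{config.radius_px} px "
                f"in a {size} px image"
            )

    image = config.noise_sigma * rng.standard_normal((size, size))
    union = np.zeros((size, size), dtype=bool)
    areas = np.zeros(len(centers))
    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        mask = _disk_mask(size, cy, cx, r)
        areas[i] = int(mask.sum())
        union |= mask
    image[union] += config.intensity
    truth = PunctaGroundTruth(
        centers_px=np.asarray(centers).reshape(-1, 2),
        radii_px=np.asarray(radii),
        areas_px=areas,
        touching_pairs=tuple(touching),
        foreground_fraction=float(union.mean()),
    )
    return image, truth
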