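"""Seeded synthetic wrist-pulse waveform simulator with exact phase truth.

Each beat is a three-Gaussian mixture: main (systolic) wave, dicrotic
prewave / tidal wave, and dicrotic wave.  The dicrotic notch — the
systole/diastole boundary — is the minimum of the continuous mixture
between the tidal and dicrotic centers, so ground truth is analytic up to
grid resolution.  Seven morphological presets cover the classical TCM
pulse categories: the three-peak normal pulse; bimodal "slippery" variants
with a clear notch; and "flat top" string-like/fine variants whose tidal
wave has merged with the main wave and whose dicrotic wave is weak.

Records are built by concatenating beats with heart-period jitter, then
contaminated with white noise, 50 Hz powerline interference, and a
sub-0.4 Hz sinusoidal respiratory baseline drift — all added *after* the
truth indices are fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .sequences import DIASTOLE, SYSTOLE, LabelSequence

PULSE_TYPES = (
    "normal",
    "slippery",
    "fine_slippery",
    "string_slippery",
    "string",
    "fine",
    "fine_string",
)

#: Flat-top morphologies: tidal wave merged into the main wave, weak notch.
FLAT_TOP_TYPES = ("string", "fine", "fine_string")

#: Per-type record counts of the reference 1400-case composition.
DEFAULT_COUNTS: dict[str, int] = {
    "normal": 120,
    "slippery": 100,
    "fine_slippery": 360,
    "string_slippery": 100,
    "string": 100,
    "fine": 100,
    "fine_string": 520,
}

DEFAULT_FS = 720.0
DEFAULT_N_SAMPLES = 2160


@dataclass(frozen=True)
class BeatParams:
    """Three-Gaussian beat model parameters.

    Amplitudes are in arbitrary units; centers and widths are fractions of
    the beat period.  Component order: main wave, tidal wave (dicrotic
    prewave), dicrotic wave.
    """

    period_s: float
    amps: tuple[float, float, float]
    centers: tuple[float, float, float]
    widths: tuple[float, float, float]

    def __post_init__(self) -> None:
        a, c, w = self.amps, self.centers, self.widths
        vals = (self.period_s, *a, *c, *w)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("beat parameters must be finite")
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if min(a) < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (a[0] > a[1] and a[0] > a[2]):
            raise ValueError("main-wave amplitude must dominate")
        if a[2] < 0.05 * a[0]:
            raise ValueError("dicrotic amplitude below 0.05×main: no notch minimum")
        if not (0 < c[0] < c[1] < c[2] < 1):
            raise ValueError("centers must be increasing fractions in (0, 1)")
        if min(w) <= 0:
            raise ValueError("widths must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Additive contamination levels, as fractions of main-wave amplitude."""

    white_sigma: float = 0.05
    powerline_amp: float = 0.05
    powerline_freq: float = 50.0
    drift_amp: float = 0.3
    drift_freq: float = 0.25
    drift_phase: float = 0.0

    def __post_init__(self) -> None:
        if min(self.white_sigma, self.powerline_amp, self.drift_amp) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not 0.0 < self.drift_freq < 0.4:
            raise ValueError("drift frequency must lie below the 0.4 Hz respiration bound")

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(white_sigma=0.0, powerline_amp=0.0, drift_amp=0.0)


@dataclass
class PulseRecord:
    """A sampled single-channel pulse waveform."""

    samples: np.ndarray
    fs: float = DEFAULT_FS
    pulse_type: str = "normal"
    record_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class BeatTruth:
    """Ground-truth phase boundaries of one complete beat (sample indices)."""

    onset: int
    notch: int
    next_onset: int

    def __post_init__(self) -> None:
        if not self.onset < self.notch < self.next_onset:
            raise ValueError("require onset < notch < next_onset")


# Morphological presets.  Amplitude scale < 1 encodes the low-amplitude
# "fine" character; tidal proximity/height encodes the flat top; the
# dicrotic amplitude encodes notch clarity.  The dicrotic component is
# deliberately broad and late: it doubles as the diastolic runoff, keeping
# late diastole above the notch level so the notch is the unique interior
# minimum of the central beat.
_PRESETS: dict[str, BeatParams] = {
    "normal": BeatParams(0.8, (1.0, 0.40, 0.32), (0.15, 0.32, 0.68), (0.050, 0.060, 0.145)),
    "slippery": BeatParams(0.8, (1.0, 0.45, 0.33), (0.16, 0.24, 0.67), (0.060, 0.070, 0.130)),
    "fine_slippery": BeatParams(0.8, (0.5, 0.225, 0.165), (0.16, 0.24, 0.67), (0.060, 0.070, 0.130)),
    "string_slippery": BeatParams(0.8, (1.0, 0.60, 0.30), (0.17, 0.25, 0.66), (0.065, 0.075, 0.130)),
    "string": BeatParams(0.8, (1.0, 0.90, 0.14), (0.16, 0.24, 0.70), (0.065, 0.070, 0.130)),
    "fine": BeatParams(0.8, (0.50, 0.44, 0.070), (0.16, 0.24, 0.70), (0.062, 0.070, 0.130)),
    "fine_string": BeatParams(0.8, (0.60, 0.54, 0.084), (0.16, 0.24, 0.70), (0.065, 0.070, 0.130)),
}


def type_preset(pulse_type: str, period_s: float | None = None) -> BeatParams:
    """Return the beat-parameter preset for one of the seven pulse types."""
    if pulse_type not in _PRESETS:
        raise ValueError(f"unknown pulse type {pulse_type!r}; expected one of {PULSE_TYPES}")
    params = _PRESETS[pulse_type]
    if period_s is not None:
        params = replace(params, period_s=period_s)
    return params


def _mixture(t: np.ndarray, params: BeatParams) -> np.ndarray:
    """Evaluate the continuous three-Gaussian beat model at times t (seconds)."""
    out = np.zeros_like(t)
    for a, c, w in zip(params.amps, params.centers, params.widths):
        mu, sigma = c * params.period_s, w * params.period_s
        out += a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))
    return out


def make_beat(params: BeatParams, fs: float = DEFAULT_FS) -> tuple[np.ndarray, int]:
    """Sample one beat and locate its dicrotic notch.

    Returns the waveform over one period and the notch offset in samples.
    The notch is the argmin of the *continuous* mixture between the tidal
    and dicrotic centers, found on a grid 10× denser than the sampling
    rate and snapped to the nearest output sample.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    n = int(round(params.period_s * fs))
    t = np.arange(n) / fs
    waveform = _mixture(t, params)

    t_lo = params.centers[1] * params.period_s
    t_hi = params.centers[2] * params.period_s
    dense = np.linspace(t_lo, t_hi, max(int(round((t_hi - t_lo) * fs * 10)), 2))
    notch_t = dense[int(np.argmin(_mixture(dense, params)))]
    notch_offset = int(np.clip(round(notch_t * fs), 1, n - 2))
    # the nearest sample to the continuous argmin can sit one sample off
    # the discrete minimum; snap so the sampled waveform attains its local
    # minimum exactly at the reported index
    notch_offset += int(np.argmin(waveform[notch_offset - 1 : notch_offset + 2])) - 1
    return waveform, notch_offset


def notch_prominence(params: BeatParams, fs: float = DEFAULT_FS) -> float:
    """Depth of the dicrotic-notch valley, in main-wave amplitude units.

    Measured as the smaller of the two climbs out of the valley (toward the
    preceding shoulder and toward the dicrotic peak), i.e. the topographic
    prominence of the dip.  Flat-top morphologies have weak prominence.
    """
    waveform, notch = make_beat(params, fs)
    lo = int(params.centers[1] * params.period_s * fs)
    before = waveform[lo : notch + 1].max() if notch > lo else waveform[notch]
    after = waveform[notch:].max()
    return float(min(before, after) - waveform[notch]) / params.amps[0]


def _jitter_preset(params: BeatParams, rng: np.random.Generator, frac: float = 0.04) -> BeatParams:
    """Mild per-record morphological variation that preserves the invariants."""
    a = np.array(params.amps) * (1.0 + frac * rng.standard_normal(3))
    c = np.array(params.centers) * (1.0 + 0.5 * frac * rng.standard_normal(3))
    w = np.array(params.widths) * (1.0 + frac * rng.standard_normal(3))
    # clip back into the invariant region relative to the main wave
    a = np.clip(a, 1e-3, None)
    a[1] = min(a[1], 0.95 * a[0])
    a[2] = float(np.clip(a[2], 0.051 * a[0], 0.95 * a[0]))
    # keep the flat-top character (weak dicrotic wave) of flat-top presets
    if params.amps[2] <= 0.15 * params.amps[0]:
        a[2] = min(a[2], 0.145 * a[0])
    c = np.sort(np.clip(c, 0.02, 0.95))
    c[1] = max(c[1], c[0] + 0.01)
    c[2] = max(c[2], c[1] + 0.05)
    w = np.clip(w, 0.02, 0.25)
    return BeatParams(params.period_s, tuple(a), tuple(np.clip(c, 0.02, 0.98)), tuple(w))


def generate_record(
    pulse_type: str,
    n_samples: int = DEFAULT_N_SAMPLES,
    fs: float = DEFAULT_FS,
    hr_bpm: float = 75.0,
    hr_jitter: float = 0.03,
    noise: NoiseParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    record_id: str | None = None,
) -> tuple[PulseRecord, list[BeatTruth], LabelSequence]:
    """Generate one record with per-beat truth and per-sample labels.

    Beats are concatenated with per-beat periods drawn from the mean heart
    rate with multiplicative Gaussian jitter.  Samples before the first
    onset and after the last complete beat carry the background class.
    Identical seeds give byte-identical output.
    """
    noise = NoiseParams() if noise is None else noise
    mean_period = 60.0 / hr_bpm
    if n_samples < mean_period * fs:
        raise ValueError("n_samples must cover at least one full beat")
    rng = np.random.default_rng(seed)
    base = _jitter_preset(type_preset(pulse_type), rng)

    samples = np.zeros(n_samples)
    truths: list[BeatTruth] = []
    labels = np.zeros(n_samples, dtype=np.int8)

    start = int(rng.uniform(0.05, 0.2) * fs)
    while True:
        period = mean_period * (1.0 + hr_jitter * float(np.clip(rng.standard_normal(), -3, 3)))
        period = max(period, 0.4)
        params = replace(base, period_s=period)
        beat, notch_off = make_beat(params, fs)
        end = start + beat.size
        if end > n_samples:
            # truncated final partial beat: waveform kept, labels stay background
            samples[start:] = beat[: n_samples - start]
            break
        samples[start:end] = beat
        truths.append(BeatTruth(start, start + notch_off, end))
        labels[start : start + notch_off] = SYSTOLE
        labels[start + notch_off : end] = DIASTOLE
        start = end

    a_main = base.amps[0]
    t = np.arange(n_samples) / fs
    if noise.white_sigma > 0:
        samples = samples + noise.white_sigma * a_main * rng.standard_normal(n_samples)
    if noise.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        samples = samples + noise.powerline_amp * a_main * np.sin(
            2 * np.pi * noise.powerline_freq * t + phase
        )
    if noise.drift_amp > 0:
        samples = samples + noise.drift_amp * a_main * np.sin(
            2 * np.pi * noise.drift_freq * t + noise.drift_phase
        )

    record = PulseRecord(
        samples,
        fs=fs,
        pulse_type=pulse_type,
        record_id=record_id or f"{pulse_type}-0",
        meta={"hr_bpm": hr_bpm, "noise": noise},
    )
    return record, truths, LabelSequence(labels, fs=fs)


def scaled_counts(scale: float, counts: Mapping[str, int] | None = None) -> dict[str, int]:
    """Scale a per-type composition by a factor, rounding to integers."""
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    return {k: int(round(v * scale)) for k, v in counts.items()}


def generate_dataset(
    counts_by_type: Mapping[str, int] | None = None,
    seed: int = 0,
    **record_kwargs,
) -> list[tuple[PulseRecord, list[BeatTruth], LabelSequence]]:
    """Generate a dataset with the requested per-type record counts.

    Defaults to the full 1400-record composition (see DEFAULT_COUNTS).
    Every record gets a seed derived from (seed, running index), so any
    subset is reproducible from the master seed alone.
    """
    counts = dict(DEFAULT_COUNTS if counts_by_type is None else counts_by_type)
    unknown = set(counts) - set(PULSE_TYPES)
    if unknown:
        raise ValueError(f"unknown pulse types in counts: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")

    dataset = []
    index = 0
    for pulse_type in PULSE_TYPES:
        for j in range(counts.get(pulse_type, 0)):
            child = np.random.SeedSequence(entropy=(int(seed), index))
            dataset.append(
                generate_record(
                    pulse_type,
                    seed=child,
                    record_id=f"{pulse_type}-{j:04d}",
                    **record_kwargs,
                )
            )
            index += 1
    return dataset


def write_signal(path: str | Path, record: PulseRecord) -> None:
    """Write a waveform as plain text, one amplitude per line."""
    np.savetxt(path, record.samples, fmt="%.9g")


def read_signal(path: str | Path, fs: float = DEFAULT_FS, **kwargs) -> PulseRecord:
    samples = np.loadtxt(path)
    return PulseRecord(np.atleast_1d(samples), fs=fs, record_id=Path(path).stem, **kwargs)
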