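"""Slope-sum-function (SSF) phase segmentation — the non-learned baseline.

The SSF transform accumulates the positive first differences of the
signal over a sliding window, turning each systolic upstroke into a sharp
hump.  Beat onsets are found by adaptive thresholding of the SSF: a
crossing of the threshold (a fraction of the recent SSF peak level)
triggers a backward search for the foot of the upstroke.  Within each
beat the dicrotic notch is located as the local minimum after the
systolic peak; "flat top" beats without an interior minimum fall back to
the point of flattest slope (inflection surrogate), and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .sequences import DIASTOLE, SYSTOLE
from .segmenter import SegmentationResult
from .synthgen import PulseRecord


@dataclass(frozen=True)
class SSFConfig:
    """Parameters of the SSF onset detector and notch rule."""

    window_s: float = 0.13  # SSF accumulation window, seconds
    threshold_frac: float = 0.6  # fraction of the recent SSF peak level
    refractory_s: float = 0.3  # minimum onset-to-onset distance, seconds
    notch_search: tuple[float, float] = (0.15, 0.6)  # beat fraction after systolic peak
    foot_frac: float = 0.01  # backward search stops below this fraction of the peak
    peak_history: int = 5  # onsets kept for the running threshold median

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.refractory_s <= 0:
            raise ValueError("window and refractory period must be positive")
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold fraction must be in (0, 1)")

    def window_samples(self, fs: float) -> int:
        return max(int(round(self.window_s * fs)), 1)


def ssf_transform(samples: np.ndarray, window_w: int) -> np.ndarray:
    """Windowed sum of positive first differences.

    ssf[k] = sum_{i=k-w+1..k} max(x[i] - x[i-1], 0), with the difference at
    i=0 taken as 0; the first w samples use the available prefix.  Output
    has the input's length and is non-negative.
    """
    x = np.asarray(samples, dtype=np.float64)
    if window_w < 1:
        raise ValueError("window must be at least 1 sample")
    if window_w >= x.size:
        raise ValueError("window must be shorter than the record")
    d = np.empty_like(x)
    d[0] = 0.0
    np.clip(np.diff(x), 0.0, None, out=d[1:])
    csum = np.concatenate(([0.0], np.cumsum(d)))
    w = np.minimum(np.arange(1, x.size + 1), window_w)
    return csum[1:] - csum[np.arange(1, x.size + 1) - w]


def detect_onsets(ssf: np.ndarray, cfg: SSFConfig, fs: float) -> list[int]:
    """Adaptive-threshold onset detection on an SSF signal.

    The threshold is `threshold_frac` times the running median of the last
    few SSF peak heights, initialized from the global 90th percentile.  A
    crossing triggers a backward search for the nearest sample where the
    SSF falls below `foot_frac` of the local peak — that sample is the
    onset.  Crossings within the refractory period are suppressed.
    """
    ssf = np.asarray(ssf, dtype=np.float64)
    n = ssf.size
    refractory = int(round(cfg.refractory_s * fs))
    lookahead = int(round(0.25 * fs))

    base = float(np.percentile(ssf, 90))
    if base <= 0:
        return []
    peaks: list[float] = []
    threshold = cfg.threshold_frac * base

    onsets: list[int] = []
    i = 1
    while i < n:
        if ssf[i - 1] < threshold <= ssf[i]:
            peak_idx = i + int(np.argmax(ssf[i : min(n, i + lookahead)]))
            peak = ssf[peak_idx]
            k = i
            while k > 0 and ssf[k] > cfg.foot_frac * peak:
                k -= 1
            if not onsets or k - onsets[-1] >= refractory:
                onsets.append(k)
                peaks.append(peak)
                threshold = cfg.threshold_frac * float(
                    np.median(peaks[-cfg.peak_history :])
                )
            i = max(peak_idx, i) + 1
        else:
            i += 1
    return onsets


def detect_notch(
    samples: np.ndarray, onset_pair: tuple[int, int], cfg: SSFConfig, fs: float
) -> tuple[int | None, bool]:
    """Locate the dicrotic notch within one beat.

    Searches a window placed `notch_search` beat-fractions after the
    systolic peak for a local minimum of the signal.  Beats without an
    interior local minimum (flat tops) fall back to the sample of smallest
    first-derivative magnitude in the window.  Returns (index, fallback
    flag); (None, True) when the window is degenerate.
    """
    onset, next_onset = onset_pair
    beat_len = next_onset - onset
    if beat_len < int(0.3 * fs):
        return None, True
    beat = np.asarray(samples[onset:next_onset], dtype=np.float64)
    sys_peak = int(np.argmax(beat))
    lo = sys_peak + int(cfg.notch_search[0] * beat_len)
    hi = min(sys_peak + int(cfg.notch_search[1] * beat_len), beat_len - 1)
    if hi - lo < 3:
        return None, True
    window = beat[lo : hi + 1]
    rel = int(np.argmin(window))
    if 0 < rel < window.size - 1:
        return onset + lo + rel, False
    # flat-top beat: no interior minimum — take the flattest point instead
    slope = np.abs(np.gradient(window))
    rel = 1 + int(np.argmin(slope[1:-1]))
    return onset + lo + rel, True


def ssf_segment(
    record: PulseRecord, cfg: SSFConfig | None = None
) -> SegmentationResult:
    """Full SSF pipeline: onsets -> beats -> notches -> phase labels.

    Beats whose notch is undefined are labeled entirely systolic and
    counted in the result flags.
    """
    cfg = cfg or SSFConfig()
    x = record.samples
    ssf = ssf_transform(x, cfg.window_samples(record.fs))
    onsets = detect_onsets(ssf, cfg, record.fs)

    classes = np.zeros(x.size, dtype=np.int8)
    fallbacks = undefined = 0
    for onset, next_onset in zip(onsets, onsets[1:]):
        notch, fell_back = detect_notch(x, (onset, next_onset), cfg, record.fs)
        if notch is None:
            classes[onset:next_onset] = SYSTOLE
            undefined += 1
            continue
        fallbacks += int(fell_back)
        classes[onset:notch] = SYSTOLE
        classes[notch:next_onset] = DIASTOLE

    probs = np.zeros((x.size, 3))
    probs[np.arange(x.size), classes] = 1.0
    return SegmentationResult(
        classes=classes,
        probs=probs,
        flags={
            "onsets": onsets,
            "notch_fallbacks": fallbacks,
            "undefined_notches": undefined,
        },
    )
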