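"""Boundary-tolerance evaluation of phase segmentations.

The primary metric matches predicted phase segments to ground-truth
periods: a truth systole (onset → notch) counts as correct when some
predicted systolic segment has *both* boundaries within ±tolerance
(default 50 ms) of the true ones; likewise for diastole (notch → next
onset); a whole period is correct only if both phases are.  Accuracies
are pooled over periods, overall and per pulse type — the standard
report shape: three rows (systolic, diastolic, whole period), one column
block per method.

A per-sample accuracy restricted to the labeled region (truth ≠
background) is provided as a secondary diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .sequences import BACKGROUND, DIASTOLE, SYSTOLE
from .synthgen import BeatTruth


@dataclass
class PeriodVerdict:
    """Correctness of one ground-truth period."""

    systole_ok: bool
    diastole_ok: bool

    @property
    def period_ok(self) -> bool:
        return self.systole_ok and self.diastole_ok


@dataclass
class SegReport:
    """Systolic / diastolic / whole-period accuracies, overall and per type."""

    systolic_acc: float
    diastolic_acc: float
    whole_period_acc: float
    per_type: dict[str, dict[str, float]] = field(default_factory=dict)
    n_periods: int = 0
    tolerance_s: float = 0.05

    def __post_init__(self) -> None:
        for v in (self.systolic_acc, self.diastolic_acc, self.whole_period_acc):
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError("accuracies must lie in [0, 1]")
        if self.whole_period_acc > min(self.systolic_acc, self.diastolic_acc) + 1e-12:
            raise ValueError("whole-period accuracy cannot exceed either phase accuracy")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def table(self) -> str:
        """Format as the conventional three-row text table."""
        lines = [
            f"{'Segmentation accuracy':<28}{'overall':>10}",
            f"{'Systolic phase':<28}{self.systolic_acc:>10.3f}",
            f"{'Diastolic phase':<28}{self.diastolic_acc:>10.3f}",
            f"{'Whole period':<28}{self.whole_period_acc:>10.3f}",
            "",
            f"{'Pulse type':<20}{'systole':>9}{'diastole':>9}{'whole':>9}",
        ]
        for name, row in self.per_type.items():
            lines.append(
                f"{name:<20}{row['systolic_acc']:>9.3f}"
                f"{row['diastolic_acc']:>9.3f}{row['whole_period_acc']:>9.3f}"
            )
        return "\n".join(lines)


def match_periods(
    segments: Sequence[tuple[int, int, int]],
    truths: Sequence[BeatTruth],
    tolerance_s: float = 0.05,
    fs: float = 720.0,
) -> list[PeriodVerdict]:
    """Match predicted segments against truth periods at a boundary tolerance.

    Assignment is greedy by nearest onset: truths are processed in time
    order and each claims the unused predicted segment of the right phase
    whose start is closest to the true boundary (ties to the earlier
    segment).  Each predicted segment can satisfy at most one period.
    """
    if tolerance_s <= 0:
        raise ValueError("tolerance must be positive")
    for a, b in zip(truths, truths[1:]):
        if b.onset < a.next_onset:
            raise ValueError("overlapping truth periods")
    tol = tolerance_s * fs

    sys_segs = [(s, e) for s, e, cls in segments if cls == SYSTOLE]
    dia_segs = [(s, e) for s, e, cls in segments if cls == DIASTOLE]
    used_sys: set[int] = set()
    used_dia: set[int] = set()

    def claim(pool, used, target_start, target_end):
        best, best_d = None, None
        for idx, (s, e) in enumerate(pool):
            if idx in used:
                continue
            d = abs(s - target_start)
            if best_d is None or d < best_d:
                best, best_d = idx, d
        if best is None:
            return False
        used.add(best)
        s, e = pool[best]
        return abs(s - target_start) <= tol and abs(e - target_end) <= tol

    verdicts = []
    for t in truths:
        sys_ok = claim(sys_segs, used_sys, t.onset, t.notch)
        dia_ok = claim(dia_segs, used_dia, t.notch, t.next_onset)
        verdicts.append(PeriodVerdict(sys_ok, dia_ok))
    return verdicts


def score(
    per_record: Sequence[tuple[str, Sequence[PeriodVerdict]]],
    tolerance_s: float = 0.05,
) -> SegReport:
    """Pool period verdicts into a report, overall and per pulse type.

    `per_record` holds (pulse_type, verdicts) pairs.  Accuracies are
    correct/total pooled over periods; a type with zero periods is
    reported as NaN rather than 0.
    """
    if not per_record:
        raise ValueError("nothing to score")

    def pool(verdicts: list[PeriodVerdict]):
        n = len(verdicts)
        if n == 0:
            return float("nan"), float("nan"), float("nan"), 0
        sys = sum(v.systole_ok for v in verdicts) / n
        dia = sum(v.diastole_ok for v in verdicts) / n
        whole = sum(v.period_ok for v in verdicts) / n
        return sys, dia, whole, n

    all_verdicts = [v for _, vs in per_record for v in vs]
    sys, dia, whole, n = pool(all_verdicts)

    per_type = {}
    for ptype in sorted({pt for pt, _ in per_record}):
        vs = [v for pt, verdicts in per_record if pt == ptype for v in verdicts]
        tsys, tdia, twhole, tn = pool(vs)
        per_type[ptype] = {
            "systolic_acc": tsys,
            "diastolic_acc": tdia,
            "whole_period_acc": twhole,
            "n_periods": tn,
        }
    return SegReport(
        systolic_acc=sys,
        diastolic_acc=dia,
        whole_period_acc=whole,
        per_type=per_type,
        n_periods=n,
        tolerance_s=tolerance_s,
    )


def truths_from_labels(labels) -> list[BeatTruth]:
    """Recover (onset, notch, next_onset) triples from a truth label sequence.

    Each systolic run immediately followed by a diastolic run forms one
    complete period.
    """
    segs = [r for r in labels.runs() if r[2] != BACKGROUND]
    truths = []
    for (s1, e1, c1), (s2, e2, c2) in zip(segs, segs[1:]):
        if c1 == SYSTOLE and c2 == DIASTOLE and e1 == s2:
            truths.append(BeatTruth(onset=s1, notch=e1, next_onset=e2))
    return truths


def per_sample_accuracy(pred: np.ndarray, truth: np.ndarray) -> float | None:
    """Fraction of matching samples over the labeled region (truth != 0).

    Returns None when the truth is entirely background (undefined).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    mask = truth != BACKGROUND
    if not mask.any():
        return None
    return float((pred[mask] == truth[mask]).mean())
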