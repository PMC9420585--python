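"""Per-sample phase label sequences and run-length / interval-file helpers.

The label alphabet is shared across the whole package: 0 = background
(samples outside any complete beat), 1 = systole (onset up to the dicrotic
notch), 2 = diastole (notch up to the next onset).  All intervals are
0-based and half-open, so the boundary sample always belongs to the later
phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BACKGROUND, SYSTOLE, DIASTOLE = 0, 1, 2

PHASE_NAMES = {BACKGROUND: "background", SYSTOLE: "systole", DIASTOLE: "diastole"}
PHASE_CODES = {v: k for k, v in PHASE_NAMES.items()}


def runs_from_classes(classes: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a class sequence into (start, end, cls) half-open runs.

    The runs partition [0, len(classes)) exactly.
    """
    classes = np.asarray(classes)
    if classes.size == 0:
        return []
    change = np.flatnonzero(np.diff(classes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [classes.size]))
    return [(int(s), int(e), int(classes[s])) for s, e in zip(starts, ends)]


def classes_from_runs(runs: Iterable[tuple[int, int, int]], length: int) -> np.ndarray:
    classes = np.zeros(length, dtype=np.int8)
    for start, end, cls in runs:
        classes[start:end] = cls
    return classes


@dataclass
class LabelSequence:
    """Per-sample phase classes aligned to one pulse record."""

    classes: np.ndarray
    fs: float = 720.0

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int8)
        if self.classes.ndim != 1:
            raise ValueError("classes must be one-dimensional")
        if not np.isin(self.classes, (BACKGROUND, SYSTOLE, DIASTOLE)).all():
            raise ValueError("classes must take values in {0, 1, 2}")

    def __len__(self) -> int:
        return int(self.classes.size)

    def runs(self) -> list[tuple[int, int, int]]:
        return runs_from_classes(self.classes)

    def segments(self) -> list[tuple[int, int, int]]:
        """Non-background runs only."""
        return [r for r in self.runs() if r[2] != BACKGROUND]

    def validate_alternation(self) -> None:
        """Require systolic and diastolic runs to strictly alternate in time."""
        phases = [cls for _, _, cls in self.segments()]
        for a, b in zip(phases, phases[1:]):
            if a == b:
                raise ValueError(
                    f"phase runs do not alternate: consecutive runs of class {a}"
                )


def write_intervals(path: str | Path, entries: Sequence[tuple[str, LabelSequence]]) -> None:
    """Write label sequences as a tab-separated interval file.

    Columns: record_id, start, end, phase (0-based half-open, phase names).
    Background runs are written too, so a file round-trips exactly.
    """
    lines = ["record_id\tstart\tend\tphase"]
    for record_id, labels in entries:
        for start, end, cls in labels.runs():
            lines.append(f"{record_id}\t{start}\t{end}\t{PHASE_NAMES[cls]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_intervals(path: str | Path, fs: float = 720.0) -> dict[str, LabelSequence]:
    """Read an interval TSV back into per-record label sequences."""
    per_record: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record_id"):
            raise ValueError(f"{path}: missing interval header")
        for line in fh:
            if not line.strip():
                continue
            record_id, start, end, phase = line.rstrip("\n").split("\t")
            per_record.setdefault(record_id, []).append(
                (int(start), int(end), PHASE_CODES[phase])
            )
    out = {}
    for record_id, runs in per_record.items():
        length = max(end for _, end, _ in runs)
        out[record_id] = LabelSequence(classes_from_runs(runs, length), fs=fs)
    return out
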