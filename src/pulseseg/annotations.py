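"""LabelMe-dialect annotations: parsing, pixel-to-sample mapping, splits.

Annotators mark systolic and diastolic spans as rectangles over a rendered
waveform image (default resolution 2264×1296 for a 2160-sample signal).
Only the horizontal extent of a shape is meaningful.  A marked pixel
position P maps to the sample index

    S = round(P / W × L)

where W is the image width and L the signal length.  Endpoints are
interval bounds: spans become 0-based half-open sample intervals, so a
boundary sample always belongs to the later phase.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequences import BACKGROUND, DIASTOLE, PHASE_NAMES, SYSTOLE, LabelSequence

_LABEL_CODES = {"systole": SYSTOLE, "diastole": DIASTOLE}


@dataclass(frozen=True)
class PixelMapping:
    """Geometry linking a waveform image to the underlying signal."""

    width: int = 2264  # image width, px
    height: int = 1296  # image height, px (informational only)
    length: int = 2160  # signal length, samples

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("image width and signal length must be positive")


@dataclass(frozen=True)
class Span:
    """One labeled horizontal extent, in pixels."""

    label: str  # "systole" or "diastole"
    start_px: float
    end_px: float


@dataclass
class AnnotationSet:
    """Labeled pixel spans for one record, with the mapping geometry."""

    spans: list[Span]
    mapping: PixelMapping = field(default_factory=PixelMapping)
    record_id: str = ""

    def __post_init__(self) -> None:
        self.spans = sorted(self.spans, key=lambda s: s.start_px)
        w = self.mapping.width
        prev = None
        for s in self.spans:
            if s.label not in _LABEL_CODES:
                raise ValueError(f"unknown phase label {s.label!r}")
            if not s.start_px < s.end_px:
                raise ValueError(f"span {s} has non-positive width")
            if s.start_px < 0 or s.end_px > w:
                raise ValueError(f"span {s} outside image width [0, {w}]")
            if prev is not None:
                if prev.label == s.label and s.start_px < prev.end_px:
                    raise ValueError(
                        f"overlapping {s.label} spans at {prev.end_px}/{s.start_px} px"
                    )
                if prev.label == s.label:
                    raise ValueError(
                        f"consecutive {s.label} spans do not alternate with the other phase"
                    )
            prev = s


def px_to_sample(p: float, mapping: PixelMapping) -> int:
    """Map an image pixel position to a signal sample index.

    Rounds half away from zero and clamps to [0, L]; the result is an
    interval endpoint, monotone non-decreasing in P.
    """
    if not 0 <= p <= mapping.width:
        raise ValueError(f"pixel position {p} outside [0, {mapping.width}]")
    s = math.floor(p / mapping.width * mapping.length + 0.5)
    return int(min(max(s, 0), mapping.length))


def sample_to_px(s: int, mapping: PixelMapping) -> float:
    """Inverse mapping used by the annotation writer (exact, unrounded)."""
    if not 0 <= s <= mapping.length:
        raise ValueError(f"sample index {s} outside [0, {mapping.length}]")
    return s / mapping.length * mapping.width


def load_labelme(path: str | Path, mapping: PixelMapping | None = None) -> AnnotationSet:
    """Parse a LabelMe-dialect JSON file into an AnnotationSet.

    Shapes must be labeled "systole" or "diastole" (case-insensitive).
    Rectangles use their two x-coordinates; any polygon falls back to the
    min/max of its x-coordinates.  Image geometry is read from the file's
    imageWidth/imageHeight when present, else from `mapping`.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    defaults = mapping or PixelMapping()
    geo = PixelMapping(
        width=int(doc.get("imageWidth", defaults.width)),
        height=int(doc.get("imageHeight", defaults.height)),
        length=int(doc.get("signalLength", defaults.length)),
    )
    spans = []
    for shape in doc.get("shapes", []):
        label = str(shape.get("label", "")).strip().lower()
        if label not in _LABEL_CODES:
            raise ValueError(f"{path.name}: unknown shape label {shape.get('label')!r}")
        xs = [float(pt[0]) for pt in shape["points"]]
        if len(xs) < 2:
            raise ValueError(f"{path.name}: shape with fewer than two points")
        spans.append(Span(label, min(xs), max(xs)))
    record_id = str(doc.get("imagePath", path.stem)).rsplit(".", 1)[0]
    return AnnotationSet(spans, mapping=geo, record_id=record_id)


def write_labelme(path: str | Path, ann: AnnotationSet) -> None:
    """Write an AnnotationSet in the LabelMe JSON dialect (rectangle shapes)."""
    m = ann.mapping
    shapes = [
        {
            "label": s.label,
            "points": [[s.start_px, 0.0], [s.end_px, float(m.height)]],
            "shape_type": "rectangle",
            "flags": {},
        }
        for s in ann.spans
    ]
    doc = {
        "version": "5.0.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": f"{ann.record_id}.png",
        "imageData": None,
        "imageHeight": m.height,
        "imageWidth": m.width,
        "signalLength": m.length,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def labels_to_annotation(
    labels: LabelSequence, mapping: PixelMapping | None = None, record_id: str = ""
) -> AnnotationSet:
    """Convert a per-sample label sequence into pixel spans (fixture writer)."""
    mapping = mapping or PixelMapping(length=len(labels))
    spans = [
        Span(PHASE_NAMES[cls], sample_to_px(start, mapping), sample_to_px(end, mapping))
        for start, end, cls in labels.runs()
        if cls != BACKGROUND
    ]
    return AnnotationSet(spans, mapping=mapping, record_id=record_id)


def annotation_to_labels(ann: AnnotationSet, fs: float = 720.0) -> LabelSequence:
    """Rasterize pixel spans into a per-sample class sequence of length L."""
    classes = np.zeros(ann.mapping.length, dtype=np.int8)
    for span in ann.spans:
        s0 = px_to_sample(span.start_px, ann.mapping)
        s1 = px_to_sample(span.end_px, ann.mapping)
        if s0 >= s1:
            raise ValueError(f"span {span} collapses after rounding ({s0} >= {s1})")
        classes[s0:s1] = _LABEL_CODES[span.label]
    return LabelSequence(classes, fs=fs)


def split_dataset(
    records: Sequence,
    ratios: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
    stratify_by_type: bool = True,
    key=None,
) -> tuple[list, list, list]:
    """Shuffle and split records into train/validation/test parts.

    Sizes follow the ratio by largest-remainder apportionment (8:1:1 on
    1400 records gives exactly 1120/140/140), with every part guaranteed
    at least one record.  With stratification the ratio is applied within
    each pulse type, preserving per-type proportions.  Deterministic for a
    given seed.
    """
    if min(ratios) <= 0:
        raise ValueError("ratios must be positive")
    if len(records) < 3:
        raise ValueError(f"cannot split {len(records)} records into three parts")
    key = key or (lambda item: (item[0] if isinstance(item, tuple) else item).pulse_type)

    rng = np.random.default_rng(seed)
    if stratify_by_type:
        groups: dict[str, list] = {}
        for item in records:
            groups.setdefault(key(item), []).append(item)
        train, val, test = [], [], []
        for name in sorted(groups):
            parts = _split_once(groups[name], ratios, rng)
            for dst, part in zip((train, val, test), parts):
                dst.extend(part)
        return train, val, test
    return _split_once(list(records), ratios, rng)


def _split_once(items: list, ratios: tuple[int, int, int], rng: np.random.Generator):
    order = rng.permutation(len(items))
    shuffled = [items[i] for i in order]
    n, total = len(items), sum(ratios)
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    remainders = sorted(range(3), key=lambda i: quotas[i] - sizes[i], reverse=True)
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1
    if n >= 3:
        # every part gets at least one item; steal from the largest part
        for i in range(3):
            while sizes[i] == 0:
                j = int(np.argmax(sizes))
                sizes[j] -= 1
                sizes[i] += 1
    bounds = np.cumsum([0] + sizes)
    return tuple(shuffled[bounds[k] : bounds[k + 1]] for k in range(3))
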