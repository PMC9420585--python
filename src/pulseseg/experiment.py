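"""End-to-end experiment: simulate, split, preprocess, train, compare.

One call (or `pulseseg run-all`) reproduces the whole study design on
synthetic data: generate a seven-type pulse dataset, split it 8:1:1
(stratified by pulse type), preprocess every record, train the BiLSTM
segmenter, and evaluate both the segmenter and the SSF baseline on the
identical held-out test split with boundary-tolerance accuracy reports.

Every stage draws its randomness from seeds derived from the single
experiment seed, so a config reproduces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .annotations import split_dataset
from .metrics import SegReport, match_periods, per_sample_accuracy, score
from .preprocess import PreprocessConfig, preprocess
from .segmenter import BiLSTMSegmenter, ModelConfig, train
from .sequences import write_intervals
from .ssf import SSFConfig, ssf_segment
from .synthgen import NoiseParams, generate_dataset, scaled_counts

log = logging.getLogger("pulseseg")


@dataclass
class ExperimentConfig:
    """All knobs of a full run, serializable to/from YAML or JSON."""

    scale: float = 0.1  # fraction of the 1400-record reference composition
    counts_by_type: dict[str, int] | None = None  # overrides scale when given
    hr_bpm: float = 75.0
    hr_jitter: float = 0.03
    noise: NoiseParams = field(default_factory=NoiseParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        batch_size=8, max_epochs=30, early_stop_patience=10))
    ssf: SSFConfig = field(default_factory=SSFConfig)
    tolerance_s: float = 0.05
    seed: int = 0
    out_dir: str = "runs/experiment"

    def counts(self) -> dict[str, int]:
        if self.counts_by_type is not None:
            return dict(self.counts_by_type)
        return scaled_counts(self.scale)

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "ExperimentConfig":
        doc = dict(doc)
        for key, sub in (("noise", NoiseParams), ("preprocess", PreprocessConfig),
                         ("model", ModelConfig), ("ssf", SSFConfig)):
            if key in doc and isinstance(doc[key], Mapping):
                sub_doc = dict(doc[key])
                if "notch_search" in sub_doc:
                    sub_doc["notch_search"] = tuple(sub_doc["notch_search"])
                doc[key] = sub(**sub_doc)
        return cls(**doc)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        return cls.from_mapping(doc)

    def to_dict(self) -> dict:
        return asdict(self)


def run_experiment(cfg: ExperimentConfig) -> tuple[SegReport, SegReport]:
    """Run the full pipeline; returns (segmenter report, SSF report).

    Artifacts written under cfg.out_dir: both reports (JSON + text table),
    predicted and truth interval files for the test split, the trained
    checkpoint, and a manifest with the config, derived seeds, and split
    membership.  Output depends only on (config, seed).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = cfg.counts()
    if sum(counts.values()) == 0:
        raise RuntimeError("stage synthgen: empty dataset requested")

    log.info("generating %d records", sum(counts.values()))
    dataset = generate_dataset(
        counts, seed=cfg.seed, hr_bpm=cfg.hr_bpm, hr_jitter=cfg.hr_jitter,
        noise=cfg.noise,
    )

    train_set, val_set, test_set = split_dataset(
        dataset, seed=cfg.seed + 1, stratify_by_type=True
    )
    log.info("split %d/%d/%d", len(train_set), len(val_set), len(test_set))

    def prep(items):
        done = []
        for record, truths, labels in items:
            try:
                done.append((preprocess(record, cfg.preprocess), truths, labels))
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"stage preprocess: record {record.record_id!r}: {exc}"
                ) from exc
        return done

    train_pp, val_pp, test_pp = prep(train_set), prep(val_set), prep(test_set)

    model_cfg = dataclasses.replace(cfg.model, seed=cfg.seed + 2)
    model = BiLSTMSegmenter(model_cfg)
    log.info("training up to %d epochs", model_cfg.max_epochs)
    model, history = train(model, train_pp, val_pp, model_cfg)
    checkpoint = out / "segmenter.npz"
    model.save(checkpoint)

    lstm_rows, ssf_rows = [], []
    lstm_sample_accs, ssf_sample_accs = [], []
    pred_intervals, truth_intervals = [], []
    for record, truths, labels in test_pp:
        res_lstm = model.predict(record)
        res_ssf = ssf_segment(record, cfg.ssf)
        lstm_rows.append((record.pulse_type, match_periods(
            res_lstm.segments, truths, cfg.tolerance_s, record.fs)))
        ssf_rows.append((record.pulse_type, match_periods(
            res_ssf.segments, truths, cfg.tolerance_s, record.fs)))
        a = per_sample_accuracy(res_lstm.classes, labels.classes)
        if a is not None:
            lstm_sample_accs.append(a)
        a = per_sample_accuracy(res_ssf.classes, labels.classes)
        if a is not None:
            ssf_sample_accs.append(a)
        pred_intervals.append((record.record_id, res_lstm.labels(record.fs)))
        truth_intervals.append((record.record_id, labels))

    report_lstm = score(lstm_rows, cfg.tolerance_s)
    report_ssf = score(ssf_rows, cfg.tolerance_s)

    (out / "report_lstm.json").write_text(report_lstm.to_json())
    (out / "report_ssf.json").write_text(report_ssf.to_json())
    (out / "report.txt").write_text(
        "Segmenter (BiLSTM)\n" + report_lstm.table()
        + "\n\nSSF baseline\n" + report_ssf.table() + "\n"
    )
    write_intervals(out / "test_pred_lstm.tsv", pred_intervals)
    write_intervals(out / "test_truth.tsv", truth_intervals)

    from . import __version__ as version

    manifest = {
        "version": version,
        "config": cfg.to_dict(),
        "counts": counts,
        "derived_seeds": {"dataset": cfg.seed, "split": cfg.seed + 1,
                          "model": cfg.seed + 2},
        "split_ids": {
            "train": [r.record_id for r, _, _ in train_set],
            "val": [r.record_id for r, _, _ in val_set],
            "test": [r.record_id for r, _, _ in test_set],
        },
        "history": history,
        "mean_sample_accuracy": {
            "lstm": sum(lstm_sample_accs) / max(len(lstm_sample_accs), 1),
            "ssf": sum(ssf_sample_accs) / max(len(ssf_sample_accs), 1),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("reports written to %s", out)
    return report_lstm, report_ssf


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
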