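"""End-to-end pipeline: data -> split -> (optional segmentation) ->
preprocess -> one-cycle training -> evaluation.

Every run writes its artifacts (split manifest, learning-rate/loss history,
checkpoint, evaluation report, log) into a config-hash-named directory, so a
rerun with the same configuration lands in the same place and reproduces the
same manifests and metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import hsv_segmentation, io_preprocess, metrics_eval, onecycle_training
from .cells import CLASS_NAMES, CellClass
from .dense_model import DenseNetConfig, build_model, save_checkpoint
from .synthetic_smear import generate_dataset

logger = logging.getLogger("leukoscope.pipeline")

_KNOWN_SECTIONS = {"data", "preprocess", "segmentation", "model", "training", "output"}
_KNOWN_KEYS = {
    "data": {"source", "root", "manifest", "n_per_class", "image_side", "seed",
             "train_fraction"},
    "preprocess": {"target_side", "normalize_train_only", "channel_means",
                   "channel_stds"},
    "segmentation": {"enabled", "lower_hue", "upper_hue", "saturation_min", "radius"},
    "model": {"initial_channels", "growth_rate", "block_layout",
              "transition_compression", "n_classes", "input_side", "seed"},
    "training": {"min_lr", "max_lr", "epochs", "batch_size", "seed",
                 "final_fraction", "momentum", "weight_decay"},
}


@dataclass(frozen=True)
class PipelineConfig:
    data: dict = field(default_factory=lambda: {
        "source": "synthetic", "n_per_class": 50, "image_side": 64, "seed": 0,
        "train_fraction": 0.8})
    preprocess: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=lambda: {"enabled": False, "radius": 2})
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=lambda: {
        "min_lr": 0.003, "max_lr": 0.045, "epochs": 10, "batch_size": 16,
        "seed": 0, "final_fraction": 0.1})
    output: str = "runs"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        for section, keys in _KNOWN_KEYS.items():
            bad = set(raw.get(section, {})) - keys
            if bad:
                raise ValueError(
                    f"unknown key(s) in config section {section!r}: {sorted(bad)}")
        defaults = cls()
        merged = {s: {**getattr(defaults, s), **raw.get(s, {})}
                  for s in ("data", "preprocess", "segmentation", "model", "training")}
        return cls(**merged, output=raw.get("output", defaults.output))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _gather_samples(cfg: PipelineConfig):
    data = cfg.data
    if data.get("source", "synthetic") == "synthetic":
        samples = generate_dataset(int(data.get("n_per_class", 50)),
                                   int(data.get("image_side", 64)),
                                   int(data.get("seed", 0)))
        return [(s.image, s.label) for s in samples]
    items = io_preprocess.load_labeled_images(data["root"], data.get("manifest"))
    return [(io_preprocess.load_image(it.path), it.label) for it in items]


def run_pipeline(config: PipelineConfig, output_root: str | Path | None = None) -> Path:
    """Execute all stages and return the run directory."""
    run_dir = Path(output_root or config.output) / f"run-{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, run_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, run_dir: Path) -> Path:
    (run_dir / "config.json").write_text(json.dumps(asdict(config), indent=2, default=str))

    logger.info("stage 1/4: data + split")
    pairs = _gather_samples(config)
    seed = int(config.data.get("seed", 0))
    fraction = float(config.data.get("train_fraction", 0.8))
    by_class: dict[CellClass, list] = {c: [] for c in CellClass.all()}
    for img, lab in pairs:
        by_class[lab].append((img, lab))
    rng = np.random.default_rng(seed)
    train_pairs, val_pairs = [], []
    manifest_rows = []
    for cls in CellClass.all():
        members = by_class[cls]
        if not members:
            raise ValueError(f"class {cls.name!r} has 0 items")
        order = rng.permutation(len(members))
        n_val = int(round((1.0 - fraction) * len(members)))
        n_val = min(max(n_val, 0), len(members) - 1)
        shuffled = [members[i] for i in order]
        val_pairs.extend(shuffled[:n_val])
        train_pairs.extend(shuffled[n_val:])
        for rank, i in enumerate(order):
            subset = "validation" if rank < n_val else "train"
            manifest_rows.append((f"{cls.name}/{i}", cls.name, subset))
    import pandas as pd

    pd.DataFrame(manifest_rows, columns=["filename", "label", "subset"]).to_csv(
        run_dir / "split_manifest.csv", index=False)

    seg_cfg = config.segmentation
    if seg_cfg.get("enabled", False):
        logger.info("stage 2/4: HSV segmentation (on)")
        t = hsv_segmentation.HsvThresholds(
            float(seg_cfg.get("lower_hue", 0.0)),
            float(seg_cfg.get("upper_hue", 1.0)),
            float(seg_cfg.get("saturation_min", 0.45)))
        radius = int(seg_cfg.get("radius", 2))
        train_pairs = [(hsv_segmentation.segment(img, t, radius).segmented, lab)
                       for img, lab in train_pairs]
        val_pairs = [(hsv_segmentation.segment(img, t, radius).segmented, lab)
                     for img, lab in val_pairs]
    else:
        logger.info("stage 2/4: segmentation: off (raw images flow to training)")

    logger.info("stage 3/4: preprocess + one-cycle training")
    model_kwargs = dict(config.model)
    if "block_layout" in model_kwargs:
        model_kwargs["block_layout"] = tuple(model_kwargs["block_layout"])
    model_cfg = DenseNetConfig(**model_kwargs) if model_kwargs else DenseNetConfig()
    side = int(config.preprocess.get("target_side", model_cfg.input_side))
    if side != model_cfg.input_side:
        raise ValueError(
            f"preprocess.target_side ({side}) must match model.input_side "
            f"({model_cfg.input_side})")
    pp = io_preprocess.PreprocessConfig(
        target_side=side,
        normalize_train_only=bool(config.preprocess.get("normalize_train_only", True)),
        channel_means=tuple(config.preprocess.get("channel_means", (0.0, 0.0, 0.0))),
        channel_stds=tuple(config.preprocess.get("channel_stds", (1.0, 1.0, 1.0))))

    def prep(pairs, is_train: bool):
        out = []
        for img, lab in pairs:
            img = io_preprocess.resize_image(np.asarray(img, dtype=float), side)
            if is_train or not pp.normalize_train_only:
                img = io_preprocess.normalize_image(img, pp)
            out.append((img, lab))
        return out

    train_items = prep(train_pairs, True)
    val_items = prep(val_pairs, False)

    tr = config.training
    epochs = int(tr.get("epochs", 10))
    batch = int(tr.get("batch_size", 16))
    total = epochs * onecycle_training.iterations_per_epoch(len(train_items), batch)
    schedule = onecycle_training.build_schedule(
        float(tr.get("min_lr", 0.003)), float(tr.get("max_lr", 0.045)), total,
        float(tr.get("final_fraction", 0.1)))
    model = build_model(model_cfg)
    model, history = onecycle_training.train(
        model, train_items, val_items, schedule, epochs, batch,
        int(tr.get("seed", 0)),
        momentum=float(tr.get("momentum", 0.9)),
        weight_decay=float(tr.get("weight_decay", 1e-4)))
    history.iterations_frame().to_csv(run_dir / "history_iterations.csv", index=False)
    history.epochs_frame().to_csv(run_dir / "history_epochs.csv", index=False)
    save_checkpoint(model, run_dir / "checkpoint.npz")
    for e, (ta, va) in enumerate(zip(history.epoch_train_acc, history.epoch_val_acc)):
        logger.info("epoch %d: train_acc=%.3f val_acc=%.3f", e, ta, va)

    logger.info("stage 4/4: evaluation")
    report = metrics_eval.evaluate(model, val_items, preprocess=pp)
    payload = report.to_dict()
    payload["segmentation"] = "on" if seg_cfg.get("enabled", False) else "off"
    (run_dir / "report.json").write_text(json.dumps(payload, indent=2))
    report.table_frame().to_csv(run_dir / "report_table.csv", index=False)
    report.confusion.to_frame().to_csv(run_dir / "confusion_matrix.csv")
    logger.info("validation accuracy: %.4f", report.accuracy)
    return run_dir
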