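"""End-to-end screening pipeline: generate -> segment -> crop -> classify.

Stages run in order with per-stage seeds derived from one master seed, and
every artifact (masks, crops, metrics, traces, resolved parameters) is
written under the run directory so any reported number can be traced to a
parameter set.  Glaucoma is the positive class for every derived metric.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from .capsnet import CapsNetClassifier
from .gwo import GWOConfig, write_trace_csv
from .synthetic import FundusParams, generate_dataset, save_dataset, split_dataset
from .unetpp import (SegSearchSpace, UnetPlusPlusSegmenter, dice,
                     gwo_tune_segmenter, iou)

__all__ = [
    "ConfusionCounts",
    "ScreeningResult",
    "crop_disc_region",
    "compute_metrics",
    "validate_config",
    "default_config",
    "run_pipeline",
]

logger = logging.getLogger("gwoscreen.pipeline")


@dataclass
class ConfusionCounts:
    """Binary confusion counts; glaucoma is the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive: str = "glaucoma"
                    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        t = y_true == positive
        p = y_pred == positive
        return cls(tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
                   tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)))


@dataclass
class ScreeningResult:
    per_image: pd.DataFrame
    counts: ConfusionCounts
    metrics: dict
    segmentation: dict = field(default_factory=dict)


def crop_disc_region(image: np.ndarray, disc_mask: np.ndarray,
                     target_side: int = 64, normalize: bool = True) -> np.ndarray:
    """Square crop centered on the disc-mask centroid, resized bilinearly.

    Crop side is twice the disc bounding box's larger dimension (clamped to
    the image); an empty mask falls back to a centered crop with a warning.
    With ``normalize`` (default) the crop is contrast-stretched to span
    [0, 1], which removes per-image brightness jitter before
    classification.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    mask = np.asarray(disc_mask).astype(bool)
    if mask.any():
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        side = 2 * max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    else:
        warnings.warn("empty disc mask: falling back to center crop",
                      RuntimeWarning)
        logger.warning("empty disc mask: falling back to center crop")
        cy, cx = h / 2.0, w / 2.0
        side = min(h, w) // 2
    side = int(min(max(side, 8), min(h, w)))
    top = int(round(cy - side / 2))
    left = int(round(cx - side / 2))
    top = min(max(top, 0), h - side)
    left = min(max(left, 0), w - side)
    crop = image[top:top + side, left:left + side]
    out = resize(crop, (target_side, target_side) + crop.shape[2:],
                 order=1, anti_aliasing=True, preserve_range=True)
    out = np.clip(out, 0.0, 1.0)
    if normalize:
        lo, hi = out.min(), out.max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
    return out.astype(np.float32)


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy/precision/recall/specificity/sensitivity as percentages.

    A ratio with a zero denominator is reported as NaN with a warning
    (never silently as 0); recall and sensitivity are the same quantity
    reported under both names.
    """
    if counts.total == 0:
        raise ValueError("no evaluated samples (total = 0)")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning)
            return float("nan")
        return 100.0 * num / den

    accuracy = 100.0 * (counts.tp + counts.tn) / counts.total
    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "specificity": specificity, "sensitivity": recall}


# ---------------------------------------------------------------------------
# configuration


def default_config() -> dict:
    """Full-scale defaults (Adam 1e-4, batch 32, 100 epochs, early stop);
    the shipped example config overrides the budgets to desk scale."""
    return {
        "seed": 0,
        "data": {
            "image_side": 64,
            "n_per_class": 40,
            "train_fraction": 0.8,
            "disc_radius_range": [0.18, 0.28],
        },
        "gwo": {
            "enabled": False,
            "n_wolves": 5,
            "max_iters": 5,
            "budget_epochs_per_eval": 3,
            "variant": "standard",
        },
        "segmenter": {
            "depth": 2,
            "base_filters": 8,
            "dropout_rate": 0.0,
            "learning_rate": 1e-3,
            "binarize_threshold": 0.5,
            "epochs": 100,
            "batch_size": 32,
            "patience": 10,
        },
        "capsnet": {
            "conv_filters": 32,
            "primary_caps_types": 4,
            "routing_iters": 3,
            "epochs": 100,
            "batch_size": 32,
            "learning_rate": 1e-4,
            "patience": 10,
        },
        "eval": {"positive_class": "glaucoma"},
    }


_SCHEMA = {
    "seed": (int, None),
    "data.image_side": (int, lambda v: v > 0 and v % 4 == 0),
    "data.n_per_class": (int, lambda v: v >= 2),
    "data.train_fraction": (float, lambda v: 0.0 < v < 1.0),
    "gwo.enabled": (bool, None),
    "gwo.n_wolves": (int, lambda v: v >= 3),
    "gwo.max_iters": (int, lambda v: v >= 0),
    "gwo.budget_epochs_per_eval": (int, lambda v: v >= 1),
    "segmenter.depth": (int, lambda v: v >= 1),
    "segmenter.base_filters": (int, lambda v: v >= 1),
    "segmenter.dropout_rate": (float, lambda v: 0.0 <= v < 1.0),
    "segmenter.learning_rate": (float, lambda v: v > 0),
    "segmenter.binarize_threshold": (float, lambda v: 0.0 < v < 1.0),
    "segmenter.epochs": (int, lambda v: v >= 1),
    "capsnet.epochs": (int, lambda v: v >= 0),
    "capsnet.learning_rate": (float, lambda v: v > 0),
    "capsnet.batch_size": (int, lambda v: v >= 1),
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge over defaults and check types/ranges; lists every offending key."""
    merged = default_config()
    known_sections = set(merged) | {"out_dir"}
    bad: list[str] = []
    for key, val in (config or {}).items():
        if key not in known_sections:
            bad.append(f"unknown key: {key}")
            continue
        if isinstance(val, dict):
            for k2, v2 in val.items():
                if k2 not in merged[key]:
                    bad.append(f"unknown key: {key}.{k2}")
                else:
                    merged[key][k2] = v2
        else:
            merged[key] = val
    for dotted, (typ, check) in _SCHEMA.items():
        parts = dotted.split(".")
        v = merged
        for p in parts:
            v = v[p]
        if typ is float and isinstance(v, int) and not isinstance(v, bool):
            v = float(v)
        if not isinstance(v, typ) or (typ is int and isinstance(v, bool)):
            bad.append(f"wrong type for {dotted}: expected {typ.__name__}, "
                       f"got {type(v).__name__}")
        elif check is not None and not check(v):
            bad.append(f"value out of range for {dotted}: {v}")
    if bad:
        raise ConfigError("invalid configuration: " + "; ".join(bad))
    return merged


# ---------------------------------------------------------------------------
# the run


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: dict | str | Path, out_dir=None,
                 dry_run: bool = False) -> ScreeningResult | None:
    """Execute the full screening pipeline.

    config may be a dict or a path to a YAML file.  With ``dry_run`` the
    resolved stage plan is logged and nothing executes.
    """
    if isinstance(config, (str, Path)):
        import yaml
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = validate_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "run_out"))
    stages = ["generate", "tune-seg" if cfg["gwo"]["enabled"] else None,
              "train-seg", "segment", "crop", "train-caps", "evaluate"]
    stages = [s for s in stages if s]
    if dry_run:
        for s in stages:
            logger.info("planned stage: %s", s)
        print("stage plan: " + " -> ".join(stages))
        return None
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    with open(out / "resolved_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2)

    # --- generate ---------------------------------------------------------
    s0 = _stage_seed(seed, 0)
    logger.info("stage=generate seed=%d", s0)
    params = FundusParams(image_side=cfg["data"]["image_side"],
                          disc_radius_range=tuple(cfg["data"]["disc_radius_range"]),
                          seed=s0)
    samples, manifest = generate_dataset(params, cfg["data"]["n_per_class"])
    manifest = save_dataset(samples, manifest, out / "data")
    train_m, test_m = split_dataset(manifest, cfg["data"]["train_fraction"],
                                    stratify=True, seed=s0)
    train_m.to_csv(out / "train_manifest.csv", index=False)
    test_m.to_csv(out / "test_manifest.csv", index=False)
    by_id = {row["sample_id"]: samples[i] for i, (_, row) in enumerate(manifest.iterrows())}
    tr_samples = [by_id[sid] for sid in train_m["sample_id"]]
    te_samples = [by_id[sid] for sid in test_m["sample_id"]]
    xtr = np.stack([s.image for s in tr_samples])
    ytr = np.stack([np.stack([s.disc_mask, s.cup_mask], axis=-1)
                    for s in tr_samples]).astype(np.float32)

    seg_kw = cfg["segmenter"]

    # --- optional GWO tuning ---------------------------------------------
    tuned = None
    if cfg["gwo"]["enabled"]:
        s1 = _stage_seed(seed, 1)
        logger.info("stage=tune-seg seed=%d", s1)
        gwo_cfg = GWOConfig(
            n_wolves=cfg["gwo"]["n_wolves"], dim=4,
            max_iters=cfg["gwo"]["max_iters"],
            lower_bounds=np.zeros(4), upper_bounds=np.ones(4),
            variant=cfg["gwo"]["variant"], seed=s1)
        tuned, trace = gwo_tune_segmenter(
            xtr, ytr, SegSearchSpace(), gwo_cfg,
            budget_epochs_per_eval=cfg["gwo"]["budget_epochs_per_eval"],
            depth=seg_kw["depth"], train_seed=s1)
        write_trace_csv(trace, out / "gwo_trace.csv")

    # --- train segmenter --------------------------------------------------
    s2 = _stage_seed(seed, 2)
    logger.info("stage=train-seg seed=%d", s2)
    seg = UnetPlusPlusSegmenter(
        depth=seg_kw["depth"],
        base_filters=tuned.base_filters if tuned else seg_kw["base_filters"],
        dropout_rate=tuned.dropout_rate if tuned else seg_kw["dropout_rate"],
        learning_rate=tuned.learning_rate if tuned else seg_kw["learning_rate"],
        binarize_threshold=(tuned.binarize_threshold if tuned
                            else seg_kw["binarize_threshold"]),
        epochs=seg_kw["epochs"], batch_size=seg_kw["batch_size"],
        patience=seg_kw["patience"], seed=s2)
    seg.fit(xtr, ytr)
    pd.DataFrame(seg.history_).to_csv(out / "seg_history.csv", index=False)

    # --- segment + crop ---------------------------------------------------
    logger.info("stage=segment+crop")
    import imageio.v3 as iio
    (out / "masks").mkdir(exist_ok=True)
    (out / "crops").mkdir(exist_ok=True)

    def crops_for(sample_list, manifest_part):
        crops, seg_dice_d, seg_dice_c = [], [], []
        pred = seg.predict(np.stack([s.image for s in sample_list]))
        for i, s in enumerate(sample_list):
            sid = manifest_part["sample_id"].iloc[i]
            disc, cup = pred[i, :, :, 0], pred[i, :, :, 1]
            iio.imwrite(out / "masks" / f"{sid}_disc_pred.png",
                        (disc * 255).astype(np.uint8))
            iio.imwrite(out / "masks" / f"{sid}_cup_pred.png",
                        (cup * 255).astype(np.uint8))
            seg_dice_d.append(dice(disc, s.disc_mask))
            seg_dice_c.append(dice(cup, s.cup_mask))
            crop = crop_disc_region(s.image, disc, target_side=64)
            iio.imwrite(out / "crops" / f"{sid}.png",
                        (crop * 255).astype(np.uint8))
            crops.append(crop)
        return np.stack(crops), seg_dice_d, seg_dice_c

    ctr, dtr_d, dtr_c = crops_for(tr_samples, train_m)
    cte, dte_d, dte_c = crops_for(te_samples, test_m)

    # --- train capsnet ----------------------------------------------------
    s3 = _stage_seed(seed, 3)
    logger.info("stage=train-caps seed=%d", s3)
    cap_kw = cfg["capsnet"]
    clf = CapsNetClassifier(
        conv_filters=cap_kw["conv_filters"],
        primary_caps_types=cap_kw["primary_caps_types"],
        routing_iters=cap_kw["routing_iters"], epochs=cap_kw["epochs"],
        batch_size=cap_kw["batch_size"],
        learning_rate=cap_kw["learning_rate"], patience=cap_kw["patience"],
        seed=s3)
    clf.fit(ctr, train_m["label"].to_numpy())
    pd.DataFrame(clf.history_).to_csv(out / "caps_history.csv", index=False)

    # --- evaluate ---------------------------------------------------------
    logger.info("stage=evaluate")
    proba = clf.predict_proba(cte)
    pred_labels = clf.predict(cte)
    cls = list(clf.classes_)
    gi = cls.index("glaucoma") if "glaucoma" in cls else 0
    per_image = pd.DataFrame({
        "image_id": test_m["sample_id"].to_numpy(),
        "p_glaucoma": proba[:, gi],
        "p_normal": proba[:, 1 - gi],
        "predicted_label": pred_labels,
        "true_label": test_m["label"].to_numpy(),
        "dice_disc": dte_d,
        "dice_cup": dte_c,
    })
    per_image.to_csv(out / "predictions.csv", index=False)
    counts = ConfusionCounts.from_labels(test_m["label"], pred_labels,
                                         positive=cfg["eval"]["positive_class"])
    metrics = compute_metrics(counts)
    segmentation = {
        "train_dice_disc": float(np.mean(dtr_d)),
        "train_dice_cup": float(np.mean(dtr_c)),
        "test_dice_disc": float(np.mean(dte_d)),
        "test_dice_cup": float(np.mean(dte_c)),
    }
    rows = ([{"block": "classification", "metric": k, "value": v}
             for k, v in metrics.items()]
            + [{"block": "segmentation", "metric": k, "value": v}
               for k, v in segmentation.items()])
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    logger.info("done: accuracy=%.2f%%", metrics["accuracy"])
    return ScreeningResult(per_image=per_image, counts=counts,
                           metrics=metrics, segmentation=segmentation)
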