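"""End-to-end pipeline orchestration: data → preprocess → CNN → head → scores.

``run_pipeline`` executes the full chain from a single declarative config
(nested dict, typically loaded from YAML): optional synthetic-data
generation, preprocessing and splitting, CNN training, calibration to a
feature extractor, hybrid-head fitting, test-set evaluation, and RPE
differentiation scoring. Every artifact it writes records the config hash
and seed that produced it, and the structured log carries per-stage sample
counts so the 4x/5x augmentation arithmetic is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import diffscore, hybrid, model as mstmodel, preprocess, synthetic
from .types import CLASS_ORDER, CellClass

__all__ = ["default_config", "run_pipeline"]

log = logging.getLogger("mstcell.pipeline")


def default_config() -> dict:
    """Pipeline defaults mirroring the published hyperparameters."""
    return {
        "seed": 0,
        "data": {
            "dir": None,               # existing dataset; None -> generate
            "generate": {"counts": {"IPSC": 40, "MSC": 40, "RGC": 40, "RPE": 40},
                         "canvas_side": 128, "scale_bar_frac": 0.0},
        },
        "preprocess": {"crop_margin": 0.0, "divide_expand": False,
                       "train_frac": 0.75, "val_frac": 0.20},
        "model": {"kind": "multi", "canvas_side": 128,
                  "branch_filters": [8, 16, 32], "merge_filters": 32,
                  "dense_width": 32, "epochs": 19, "batch_size": 8,
                  "scale_mode": "sym_one", "learning_rate": 1e-3},
        "head": {"k": 512, "projector": "pca", "kernel": "rbf", "C": 1.0},
        "score": {"ref": "IPSC", "target": "RPE"},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def _validate(cfg: dict) -> None:
    pp = cfg["preprocess"]
    if not (0.0 < pp["train_frac"] < 1.0):
        raise ValueError(f"preprocess.train_frac must lie in (0, 1), "
                         f"got {pp['train_frac']}")
    if not (0.0 <= pp["val_frac"] < 1.0):
        raise ValueError("preprocess.val_frac must lie in [0, 1)")
    if cfg["model"]["kind"] not in ("multi", "single"):
        raise ValueError("model.kind must be 'multi' or 'single'")


def run_pipeline(config: dict | str | Path, out_dir, seed: int | None = None,
                 verbose: bool = False) -> dict:
    """Run every stage; returns the artifact dict (report, scores, paths).

    ``config`` may be a dict or a path to a YAML file; missing keys take
    the defaults. All randomness derives from ``seed`` (falling back to the
    config's). Stage failures surface with the stage name attached.
    """
    if not isinstance(config, dict):
        import yaml
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = _merge(default_config(), config)
    _validate(cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    stage = "init"
    counts: dict = {}
    try:
        # -- data ------------------------------------------------------------
        stage = "gen-data"
        if cfg["data"]["dir"] is not None:
            images = preprocess.read_manifest(cfg["data"]["dir"])
        else:
            g = cfg["data"]["generate"]
            images = synthetic.generate_dataset(
                g["counts"], seed=seed, canvas_side=g["canvas_side"],
                scale_bar_frac=g.get("scale_bar_frac", 0.0))
        counts["source_images"] = len(images)
        log.info("stage=%s n=%d", stage, len(images))

        # -- preprocess / split ----------------------------------------------
        stage = "prep"
        pp = cfg["preprocess"]
        if pp["crop_margin"] > 0:
            images = [preprocess.crop_scale_bar(im, pp["crop_margin"])
                      for im in images]
        split = preprocess.split_dataset(images, pp["train_frac"],
                                         pp["val_frac"], seed=seed)
        if pp["divide_expand"]:
            side = cfg["model"]["canvas_side"]
            split.train = preprocess.divide_expand(split.train, side=side)
        counts.update(split.counts())
        split.membership_frame().to_csv(out / "split.csv", index=False)
        log.info("stage=%s counts=%s", stage, split.counts())

        # -- train -----------------------------------------------------------
        stage = "train"
        m = cfg["model"]
        mcfg = mstmodel.ModelConfig(
            canvas_side=m["canvas_side"],
            branch_filters=tuple(m["branch_filters"]),
            merge_filters=m["merge_filters"], dense_width=m["dense_width"],
            epochs=m["epochs"], batch_size=m["batch_size"],
            scale_mode=m["scale_mode"], learning_rate=m["learning_rate"],
            seed=seed)
        net = (mstmodel.build_multi_slice(mcfg) if m["kind"] == "multi"
               else mstmodel.build_single_tensor(mcfg))
        net, history = mstmodel.train(net, split, mcfg, verbose=verbose)
        history.to_frame().to_csv(out / "history.csv", index=False)
        net.save(out / "model.ckpt.npz")

        # -- calibrate + features --------------------------------------------
        stage = "calibrate"
        extractor = mstmodel.calibrate(net)
        extractor.save(out / "extractor.ckpt.npz")
        feats_train = extractor.transform_images(split.train)
        feats_test = extractor.transform_images(split.test)
        y_train = [im.label for im in split.train]
        y_test = [im.label for im in split.test]

        # -- hybrid head -----------------------------------------------------
        stage = "fit-head"
        h = cfg["head"]
        head = hybrid.fit_head(feats_train, y_train, k=h["k"],
                               projector=h["projector"], kernel=h["kernel"],
                               C=h["C"], seed=seed)
        head.save(out / "head.pkl")

        stage = "evaluate"
        preds = hybrid.classify(head, feats_test)
        report = hybrid.evaluate(preds, y_test)
        report.write(out / "confusion.csv", out / "report.txt")
        log.info("stage=%s accuracy=%.1f%%", stage, report.accuracy)

        # -- differentiation scoring -----------------------------------------
        stage = "score-rpe"
        sc = cfg["score"]
        Z_test = hybrid.project(head, feats_test)
        axis = diffscore.find_separating_axis(
            hybrid.project(head, feats_train), y_train,
            ref_class=sc["ref"], target_class=sc["target"])
        tgt = CellClass.parse(sc["target"])
        tgt_idx = [i for i, l in enumerate(y_test) if l == tgt]
        scores = diffscore.score_samples(
            axis, Z_test[tgt_idx],
            [split.test[i].source_id for i in tgt_idx])
        import pandas as pd
        pd.DataFrame([{"sample_id": s.sample_id, "axis": axis.axis_index,
                       "coordinate": s.coordinate, "rank": s.rank}
                      for s in scores]).to_csv(out / "scores.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r} "
                           f"(config {cfg_hash}): {exc}") from exc

    provenance = {"config_hash": cfg_hash, "seed": seed, "counts": counts,
                  "accuracy_pct": report.accuracy,
                  "separating_axis": axis.axis_index,
                  "sided_fraction": axis.sided_fraction}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {"config": cfg, "split": split, "model": net, "history": history,
            "extractor": extractor, "head": head, "report": report,
            "axis": axis, "scores": scores, "provenance": provenance,
            "out_dir": out}
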