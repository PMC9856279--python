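"""Shared fixtures: one end-to-end trained pipeline reused across tests.

The pipeline fixture trains the multi-slice CNN on a synthetic four-class
set at reduced scale (64-px canvas, 8/16/32 filters) — the same code paths
as the full-size architecture, sized to train on one CPU in well under a
minute — then calibrates it and fits the PCA+SVM head. Everything is
seeded, so fixture results are identical across runs.
"""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

import mstcell as M
from mstcell.model import ModelConfig, build_multi_slice, prepare_inputs, train


SMALL_NET = dict(branch_filters=(8, 16, 32), merge_filters=32, dense_width=32)


def small_config(canvas_side=64, **kw) -> ModelConfig:
    base = dict(canvas_side=canvas_side, epochs=10, batch_size=8,
                scale_mode="sym_one", seed=0, **SMALL_NET)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def trained_pipeline():
    """CNN + calibrated extractor + hybrid head, trained once per session."""
    imgs = M.generate_dataset({c: 100 for c in M.CLASS_ORDER}, seed=11,
                              canvas_side=64)
    cfg = small_config()
    split = M.split_dataset(imgs, train_frac=0.75, val_frac_of_augmented=0.0,
                            seed=0, augment=False)
    x_tr, y_tr = prepare_inputs(split.train, cfg)
    x_te, y_te = prepare_inputs(split.test, cfg)
    model = build_multi_slice(cfg)
    model, history = train(model, (x_tr, y_tr, x_te, y_te), cfg)

    extractor = M.calibrate(model)
    feats_train = extractor.transform_images(split.train)
    feats_test = extractor.transform_images(split.test)
    labels_train = [im.label for im in split.train]
    labels_test = [im.label for im in split.test]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # PCA rank cap
        head = M.fit_head(feats_train, labels_train, k=512)
    preds = M.classify(head, feats_test)
    report = M.evaluate(preds, labels_test)
    z_train = M.project(head, feats_train)
    axis = M.find_separating_axis(z_train, labels_train)
    return SimpleNamespace(
        cfg=cfg, split=split, model=model, history=history,
        extractor=extractor, feats_train=feats_train, feats_test=feats_test,
        labels_train=labels_train, labels_test=labels_test, head=head,
        preds=preds, report=report, z_train=z_train, axis=axis)


@pytest.fixture(scope="session")
def rpe_degree_series(trained_pipeline):
    """Held-out RPE images spanning degrees 0.1–0.9, with their projections."""
    degrees = np.tile([0.1, 0.3, 0.5, 0.7, 0.9], 8)
    imgs = [M.generate_image(M.PhenotypeSpec(
        M.CellClass.RPE, canvas_side=64, rpe_degree=float(d), seed=1000 + i))
        for i, d in enumerate(degrees)]
    feats = trained_pipeline.extractor.transform_images(imgs)
    z = M.project(trained_pipeline.head, feats)
    return SimpleNamespace(degrees=degrees, images=imgs, projections=z)
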