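"""The multi-slice tensor CNN: five weight-stacks over one image.

One 512x512x3 *macroscopic* tensor is average-pooled 2x2 at the front and
fed to the first branch; the four 256x256x3 quadrant (*microscopic*) tensors
feed the other four branches. Each branch is three rounds of
[3x3 conv, ReLU, 2x2 max pool] with 32/64/128 filters, taking 256x256x3 down
to 32x32x128. The five branch outputs are concatenated on channels to
32x32x640, merged by one 3x3x128 convolution, passed through 50% dropout and
a 2x2 average pool to 16x16x128, flattened to 32,768 features, and finished
by a 128-unit hidden layer and a 4-way softmax.

A *single-tensor* baseline keeps only the macro branch (merge conv applied
to its lone 32x32x128 output). *Calibrating* a trained model truncates it at
the flatten layer, turning it into a fixed 32,768-dim feature extractor for
the PCA/SVM head.

All shapes scale with ``canvas_side`` and the filter counts, so the same
code runs the published architecture and smaller variants; the published
defaults are what :class:`ModelConfig` ships with.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from .preprocess import SCALE_MODES, DatasetSplit, SliceBundle, prepare_bundle
from .types import CLASS_ORDER, CellClass, LabeledImage

__all__ = ["ModelConfig", "TrainHistory", "MultiSliceModel", "FeatureExtractor",
           "build_multi_slice", "build_single_tensor", "train", "calibrate",
           "predict", "prepare_inputs", "load_model", "load_extractor"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the published configuration: 512 canvas, 3x3 kernels,
    branch filters 32/64/128 with 2x2 max pools, merge conv 128, dropout
    0.5, 2x2 average pools front and post-merge, dense 128, 4 classes,
    19 epochs at batch size 8, seed 0. Optimizer (Adam, lr 1e-3) and ReLU
    activations are the package's own choices and are exposed here.
    """

    canvas_side: int = 512
    branch_filters: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 3
    merge_filters: int = 128
    dropout_rate: float = 0.5
    dense_width: int = 128
    n_classes: int = 4
    epochs: int = 19
    batch_size: int = 8
    scale_mode: str = "sym_one"
    seed: int = 0
    learning_rate: float = 1e-3
    tie_branch_weights: bool = False

    def __post_init__(self) -> None:
        if self.kernel != 3:
            raise ValueError("only 3x3 kernels are supported")
        if self.canvas_side % 32:
            raise ValueError("canvas_side must be divisible by 32")
        if len(self.branch_filters) != 3:
            raise ValueError("branch_filters must list three conv widths")
        if self.scale_mode not in SCALE_MODES:
            raise ValueError(f"scale_mode must be one of {SCALE_MODES}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.branch_input_side % 8:
            raise ValueError("branch input side must be divisible by 8")
        if self.branch_out_side % 2:
            raise ValueError("branch output side must be even")

    # -- derived shape ledger ------------------------------------------------
    @property
    def branch_input_side(self) -> int:
        return self.canvas_side // 2

    @property
    def branch_out_side(self) -> int:
        return self.branch_input_side // 8

    @property
    def concat_channels(self) -> int:
        return 5 * self.branch_filters[-1]

    @property
    def post_merge_side(self) -> int:
        return self.branch_out_side // 2

    @property
    def flatten_len(self) -> int:
        return self.post_merge_side ** 2 * self.merge_filters

    def shape_ledger(self, n_branches: int = 5) -> dict[str, tuple]:
        """Every intermediate shape the architecture promises."""
        s = self.branch_input_side
        o = self.branch_out_side
        return {
            "branch_input": (s, s, 3),
            "branch_output": (o, o, self.branch_filters[-1]),
            "concat": (o, o, n_branches * self.branch_filters[-1]),
            "post_merge_pool": (self.post_merge_side, self.post_merge_side,
                                self.merge_filters),
            "flatten": (self.post_merge_side ** 2 * self.merge_filters,),
        }


@dataclass
class TrainHistory:
    """Per-epoch curves, one record per completed epoch."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float | None] = field(default_factory=list)
    val_acc: list[float | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "train_loss": self.train_loss, "train_acc": self.train_acc,
            "val_loss": self.val_loss, "val_acc": self.val_acc,
        })

    def plot(self, out_path=None):
        """Accuracy and loss line charts, one panel each."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, (ax_a, ax_l) = plt.subplots(1, 2, figsize=(9, 3.5))
        epochs = np.arange(1, len(self) + 1)
        ax_a.plot(epochs, self.train_acc, label="train")
        if any(v is not None for v in self.val_acc):
            ax_a.plot(epochs, self.val_acc, label="validation")
        ax_a.set(xlabel="epoch", ylabel="accuracy", title="model accuracy")
        ax_a.legend()
        ax_l.plot(epochs, self.train_loss, label="train")
        if any(v is not None for v in self.val_loss):
            ax_l.plot(epochs, self.val_loss, label="validation")
        ax_l.set(xlabel="epoch", ylabel="loss", title="model loss")
        ax_l.legend()
        fig.tight_layout()
        if out_path is not None:
            fig.savefig(out_path, dpi=120)
            plt.close(fig)
        return fig


class _Branch:
    """Three [conv, ReLU, max-pool] rounds; optionally weight-tied."""

    def __init__(self, filters, rng, share_with: "_Branch | None" = None):
        self.layers = []
        c_in = 3
        for k, c_out in enumerate(filters):
            tied = share_with.layers[3 * k] if share_with is not None else None
            self.layers += [nn.Conv3x3(c_in, c_out, rng, share_with=tied),
                            nn.ReLU(), nn.MaxPool2()]
            c_in = c_out

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class MultiSliceModel:
    """The trainable network; ``n_branches=5`` (multi) or 1 (single-tensor)."""

    def __init__(self, cfg: ModelConfig, n_branches: int = 5):
        if n_branches not in (1, 5):
            raise ValueError("n_branches must be 1 (single tensor) or 5")
        self.cfg = cfg
        self.n_branches = n_branches
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))

        self.front_pool = nn.AvgPool2()
        self.branches: list[_Branch] = []
        for i in range(n_branches):
            share = self.branches[0] if (cfg.tie_branch_weights and i > 0) else None
            self.branches.append(_Branch(cfg.branch_filters, rng, share_with=share))

        c_cat = n_branches * cfg.branch_filters[-1]
        self.merge_conv = nn.Conv3x3(c_cat, cfg.merge_filters, rng)
        self.merge_relu = nn.ReLU()
        self.dropout = nn.Dropout(cfg.dropout_rate)
        self.post_pool = nn.AvgPool2()
        self.flatten = nn.Flatten()
        self.dense1 = nn.Dense(cfg.flatten_len, cfg.dense_width, rng)
        self.relu1 = nn.ReLU()
        self.dense2 = nn.Dense(cfg.dense_width, cfg.n_classes, rng)
        self._check_shapes()

    # -- plumbing ------------------------------------------------------------
    def _check_shapes(self) -> None:
        """Build-time shape ledger: forward one dummy input and compare."""
        ledger = self.cfg.shape_ledger(self.n_branches)
        s = self.cfg.canvas_side
        dummy = [np.zeros((1, s, s, 3), dtype=np.float32)]
        dummy += [np.zeros((1, s // 2, s // 2, 3), dtype=np.float32)
                  for _ in range(self.n_branches - 1)]
        report = {}
        x = self.front_pool.forward(dummy[0])
        report["branch_input"] = x.shape[1:]
        outs = [self.branches[0].forward(x)]
        for br, q in zip(self.branches[1:], dummy[1:]):
            outs.append(br.forward(q))
        report["branch_output"] = outs[0].shape[1:]
        cat = np.concatenate(outs, axis=3)
        report["concat"] = cat.shape[1:]
        y = self.post_pool.forward(self.merge_relu.forward(
            self.merge_conv.forward(cat)))
        report["post_merge_pool"] = y.shape[1:]
        report["flatten"] = self.flatten.forward(y).shape[1:]
        bad = {k: (v, report[k]) for k, v in ledger.items() if report[k] != v}
        if bad:
            raise ValueError(f"architecture shape ledger violated: {bad}")
        self.shape_report = report

    def params(self):
        out = []
        for br in self.branches:
            out += br.params()
        for layer in (self.merge_conv, self.dense1, self.dense2):
            out += layer.params()
        return nn.Adam.dedup(out)

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def _inputs_for(self, arrays: list[np.ndarray]) -> list[np.ndarray]:
        if len(arrays) != self.n_branches:
            raise ValueError(f"model expects {self.n_branches} input tensors, "
                             f"got {len(arrays)}")
        s = self.cfg.canvas_side
        if arrays[0].shape[1:] != (s, s, 3):
            raise ValueError(f"macro input must be Nx{s}x{s}x3, "
                             f"got {arrays[0].shape}")
        return arrays

    # -- forward / backward --------------------------------------------------
    def forward(self, arrays: list[np.ndarray], train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a batch; caches activations for :meth:`backward`."""
        arrays = self._inputs_for(arrays)
        x = self.front_pool.forward(arrays[0])
        outs = [self.branches[0].forward(x, train=train, rng=rng)]
        for br, q in zip(self.branches[1:], arrays[1:]):
            outs.append(br.forward(q, train=train, rng=rng))
        cat = np.concatenate(outs, axis=3)
        self._branch_outs = outs
        self._split_channels = [o.shape[3] for o in outs]
        a = self.merge_relu.forward(self.merge_conv.forward(cat))
        self._merge_act = a
        y = self.post_pool.forward(self.dropout.forward(a, train=train, rng=rng))
        self._flat = self.flatten.forward(y)
        h = self.relu1.forward(self.dense1.forward(self._flat,
                                                   train=train, rng=rng))
        return self.dense2.forward(h, train=train, rng=rng)

    def backward(self, dlogits: np.ndarray,
                 stop_at_merge: bool = False) -> np.ndarray | None:
        """Backprop; with ``stop_at_merge`` returns d(out)/d(merge activation)."""
        d = self.dense2.backward(dlogits)
        d = self.dense1.backward(self.relu1.backward(d))
        d = self.flatten.backward(d)
        d = self.dropout.backward(self.post_pool.backward(d))
        if stop_at_merge:
            return d
        d = self.merge_conv.backward(self.merge_relu.backward(d))
        splits = np.cumsum(self._split_channels)[:-1]
        chunks = np.split(d, splits, axis=3)
        d0 = self.branches[0].backward(chunks[0])
        self.front_pool.backward(d0)
        for br, dq in zip(self.branches[1:], chunks[1:]):
            br.backward(dq)
        return None

    # -- inference helpers ---------------------------------------------------
    def predict_proba(self, bundle_or_arrays) -> np.ndarray:
        arrays = _as_arrays(bundle_or_arrays, self.n_branches)
        return nn.softmax(self.forward(arrays, train=False))

    def features(self, bundle_or_arrays) -> np.ndarray:
        """Flatten-layer activations (dropout disabled): N x flatten_len."""
        arrays = _as_arrays(bundle_or_arrays, self.n_branches)
        self.forward(arrays, train=False)
        return self._flat.copy()

    def merge_activation_grad(self, bundle_or_arrays,
                              class_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """Merge-layer activations and d(class logit)/d(activation)."""
        arrays = _as_arrays(bundle_or_arrays, self.n_branches)
        logits = self.forward(arrays, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_idx] = 1.0
        for layer in (self.dense1, self.dense2):
            layer.zero_grad()
        grad = self.backward(dlogits, stop_at_merge=True)
        return self._merge_act.copy(), grad

    def branch_activation_grads(self, bundle_or_arrays, class_idx: int
                                ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-branch (activation, gradient) pairs at the merge conv input.

        The concatenation input is the last point where channels are still
        attributable to individual branches, hence to distinct image
        regions; class-activation mapping uses this to paint heat into the
        right geometry.
        """
        arrays = _as_arrays(bundle_or_arrays, self.n_branches)
        logits = self.forward(arrays, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_idx] = 1.0
        for layer in (self.dense1, self.dense2, self.merge_conv):
            layer.zero_grad()
        d = self.backward(dlogits, stop_at_merge=True)
        dcat = self.merge_conv.backward(self.merge_relu.backward(d))
        splits = np.cumsum(self._split_channels)[:-1]
        grads = np.split(dcat, splits, axis=3)
        return [(o.copy(), g) for o, g in zip(self._branch_outs, grads)]

    # -- persistence ---------------------------------------------------------
    def _weight_dict(self, truncated: bool = False) -> dict[str, np.ndarray]:
        out = {}
        for i, br in enumerate(self.branches):
            if self.cfg.tie_branch_weights and i > 0:
                continue
            for k in range(3):
                conv = br.layers[3 * k]
                out[f"branch{i}_conv{k}_W"] = conv.W
                out[f"branch{i}_conv{k}_b"] = conv.b
        out["merge_W"], out["merge_b"] = self.merge_conv.W, self.merge_conv.b
        if not truncated:
            out["dense1_W"], out["dense1_b"] = self.dense1.W, self.dense1.b
            out["dense2_W"], out["dense2_b"] = self.dense2.W, self.dense2.b
        return out

    def _load_weights(self, data, truncated: bool = False) -> None:
        for i, br in enumerate(self.branches):
            j = 0 if self.cfg.tie_branch_weights else i
            for k in range(3):
                conv = br.layers[3 * k]
                conv.W[...] = data[f"branch{j}_conv{k}_W"]
                conv.b[...] = data[f"branch{j}_conv{k}_b"]
        self.merge_conv.W[...] = data["merge_W"]
        self.merge_conv.b[...] = data["merge_b"]
        if not truncated:
            self.dense1.W[...] = data["dense1_W"]
            self.dense1.b[...] = data["dense1_b"]
            self.dense2.W[...] = data["dense2_W"]
            self.dense2.b[...] = data["dense2_b"]

    def save(self, path) -> None:
        """Single-file checkpoint: weights plus the exact config."""
        meta = json.dumps({"config": asdict(self.cfg),
                           "n_branches": self.n_branches,
                           "truncated": False})
        np.savez_compressed(path, __meta__=np.frombuffer(
            meta.encode(), dtype=np.uint8), **self._weight_dict())


def _as_arrays(x, n_branches: int) -> list[np.ndarray]:
    """Accept a SliceBundle, a list of bundles, or ready input arrays."""
    if isinstance(x, SliceBundle):
        x = [x]
    if isinstance(x, (list, tuple)) and x and isinstance(x[0], SliceBundle):
        macro = np.stack([b.macro for b in x]).astype(np.float32)
        if n_branches == 1:
            return [macro]
        quads = [np.stack([b.quadrants[i] for b in x]).astype(np.float32)
                 for i in range(4)]
        return [macro] + quads
    arrays = [np.asarray(a, dtype=np.float32) for a in x]
    return arrays


def prepare_inputs(imgs: list[LabeledImage], cfg: ModelConfig,
                   crop_margin: float = 0.0
                   ) -> tuple[list[np.ndarray], np.ndarray]:
    """Preprocess images into batched branch inputs plus integer labels."""
    bundles = [prepare_bundle(im, cfg.scale_mode, cfg.canvas_side, crop_margin)
               for im in imgs]
    labels = np.array([CLASS_ORDER.index(im.label) for im in imgs])
    return _as_arrays(bundles, 5), labels


def build_multi_slice(cfg: ModelConfig) -> MultiSliceModel:
    """The five-branch multi-slice tensor network."""
    return MultiSliceModel(cfg, n_branches=5)


def build_single_tensor(cfg: ModelConfig) -> MultiSliceModel:
    """Single-tensor baseline: macro branch only, identical head."""
    return MultiSliceModel(cfg, n_branches=1)


def _subset(arrays: list[np.ndarray], idx) -> list[np.ndarray]:
    return [a[idx] for a in arrays]


def _eval_on(model: MultiSliceModel, arrays, labels,
             batch: int = 32) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(labels), batch):
        sl = slice(i, i + batch)
        logits = model.forward(_subset(arrays, sl), train=False)
        loss, _ = nn.softmax_cross_entropy(logits, labels[sl])
        losses.append(loss * len(labels[sl]))
        correct += int((logits.argmax(axis=1) == labels[sl]).sum())
    return float(np.sum(losses) / len(labels)), correct / len(labels)


def train(model: MultiSliceModel, split, cfg: ModelConfig | None = None,
          crop_margin: float = 0.0, verbose: bool = False
          ) -> tuple[MultiSliceModel, TrainHistory]:
    """Train in place for ``cfg.epochs`` epochs of ``cfg.batch_size`` batches.

    ``split`` is either a :class:`DatasetSplit` of labelled images (which are
    preprocessed here with the model's scale mode) or a tuple
    ``(train_arrays, train_labels[, val_arrays, val_labels])`` of prepared
    inputs. Sample order is reshuffled every epoch, deterministically from
    ``cfg.seed``; loss is categorical cross-entropy under Adam.
    """
    cfg = cfg or model.cfg
    if isinstance(split, DatasetSplit):
        if not split.train:
            raise ValueError("empty training split")
        tr_arrays, tr_labels = prepare_inputs(split.train, cfg, crop_margin)
        val = prepare_inputs(split.val, cfg, crop_margin) if split.val else None
    else:
        parts = tuple(split)
        tr_arrays, tr_labels = parts[0], np.asarray(parts[1])
        val = (parts[2], np.asarray(parts[3])) if len(parts) == 4 else None
        if len(tr_labels) == 0:
            raise ValueError("empty training split")
    if model.n_branches == 1:
        tr_arrays = tr_arrays[:1]
        val = (val[0][:1], val[1]) if val else None

    n = len(tr_labels)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    history = TrainHistory()

    for epoch in range(cfg.epochs):
        order = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 31, epoch])).permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            batch = _subset(tr_arrays, idx)
            logits = model.forward(batch, train=True, rng=drop_rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, tr_labels[idx])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, step {i // cfg.batch_size}: "
                    f"{loss}; try a lower learning rate")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == tr_labels[idx]).sum())
        history.train_loss.append(float(np.sum(losses) / n))
        history.train_acc.append(correct / n)
        if val is not None and len(val[1]):
            vl, va = _eval_on(model, val[0], val[1])
        else:
            vl = va = None
        history.val_loss.append(vl)
        history.val_acc.append(va)
        if verbose:
            msg = (f"epoch {epoch + 1}/{cfg.epochs} "
                   f"loss {history.train_loss[-1]:.4f} "
                   f"acc {history.train_acc[-1]:.3f}")
            if va is not None:
                msg += f" val_loss {vl:.4f} val_acc {va:.3f}"
            print(msg)
    return model, history


class FeatureExtractor:
    """A trained model truncated at the flatten layer.

    Maps a :class:`SliceBundle` (or a list of them) to 32,768-dim feature
    vectors; the dense layers are discarded, so the serialized form is
    strictly smaller than the full checkpoint.
    """

    def __init__(self, model: MultiSliceModel):
        if not hasattr(model, "flatten"):
            raise ValueError("model has no flatten layer to calibrate at")
        self.model = model
        self.n_features = model.cfg.flatten_len

    def __call__(self, bundle_or_arrays) -> np.ndarray:
        feats = self.model.features(bundle_or_arrays)
        if not np.isfinite(feats).all():
            raise RuntimeError("non-finite feature activations")
        return feats

    def transform_images(self, imgs: list[LabeledImage],
                         crop_margin: float = 0.0,
                         batch: int = 16) -> np.ndarray:
        arrays, _ = prepare_inputs(imgs, self.model.cfg, crop_margin)
        if self.model.n_branches == 1:
            arrays = arrays[:1]
        out = [self(_subset(arrays, slice(i, i + batch)))
               for i in range(0, len(imgs), batch)]
        return np.concatenate(out, axis=0)

    def save(self, path) -> None:
        meta = json.dumps({"config": asdict(self.model.cfg),
                           "n_branches": self.model.n_branches,
                           "truncated": True})
        np.savez_compressed(path, __meta__=np.frombuffer(
            meta.encode(), dtype=np.uint8),
            **self.model._weight_dict(truncated=True))


def calibrate(model: MultiSliceModel) -> FeatureExtractor:
    """Truncate a trained model at the flatten layer (drop the dense head)."""
    return FeatureExtractor(model)


def predict(model: MultiSliceModel, bundle: SliceBundle) -> np.ndarray:
    """Class-probability 4-vector for one bundle, in the fixed class order."""
    if bundle.scale_mode != model.cfg.scale_mode:
        raise ValueError(
            f"bundle scale_mode {bundle.scale_mode!r} does not match the "
            f"model's {model.cfg.scale_mode!r}")
    return model.predict_proba(bundle)[0]


def _read_checkpoint(path):
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_d = meta["config"]
    cfg_d["branch_filters"] = tuple(cfg_d["branch_filters"])
    cfg = ModelConfig(**cfg_d)
    model = MultiSliceModel(cfg, n_branches=meta["n_branches"])
    model._load_weights(data, truncated=meta["truncated"])
    return model, meta


def load_model(path) -> MultiSliceModel:
    model, meta = _read_checkpoint(path)
    if meta["truncated"]:
        raise ValueError(f"{path} is a calibrated extractor, not a full model")
    return model


def load_extractor(path) -> FeatureExtractor:
    model, meta = _read_checkpoint(path)
    if not meta["truncated"]:
        return FeatureExtractor(model)
    return FeatureExtractor(model)
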