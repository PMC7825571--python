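"""The customized CNN family for 10-class insect classification.

The family has four convolutional layers, each followed by 2x2 stride-2
max pooling, then one hidden dense layer and a 10-way softmax output.
The two middle convolutions are fixed at 64 kernels of 3x3; the first
and last convolution's kernel size and depth, and the dense layer width,
are the searched hyperparameters:

    conv(depth_first, kernel_first) - pool
    conv(64, 3) - pool
    conv(64, 3) - pool
    conv(depth_last, kernel_last) - pool
    flatten (8*8*depth_last)
    dense(fc_size) - dropout(0.3)
    dense(10, softmax)

With a 128x128x3 input the four poolings leave an 8x8 map, so the
flatten width is 64*depth_last.  ``count_parameters`` gives the exact
learnable-parameter total of any member in closed form.

Detected insects are cropped from the frame with padding, expanded to a
square and resized to 128x128x3; training data is multiplied by
label-preserving augmentation (flips, rotation, zoom, illumination).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from mothtrap import nn
from mothtrap.segmentation import Detection

__all__ = [
    "SPECIES",
    "BACKGROUND",
    "CLASSES",
    "ArchitectureSpec",
    "TrainConfig",
    "LabeledCrop",
    "preprocess_crop",
    "augment",
    "build_model",
    "count_parameters",
    "enumerate_grid",
    "train",
    "predict",
    "save_model",
    "load_model",
]

#: The eight monitored noctuid taxa plus the wasp class.
SPECIES: Tuple[str, ...] = (
    "Agrotis puta",
    "Amphipyra pyramidea",
    "Autographa gamma",
    "Hoplodrina complex",
    "Mythimna pallens",
    "Noctua fimbriata",
    "Noctua pronuba",
    "Xestia c-nigrum",
    "Vespula vulgaris",
)
BACKGROUND = "background"
#: Closed label set of the classifier (9 insect classes + background).
CLASSES: Tuple[str, ...] = SPECIES + (BACKGROUND,)

_KERNEL_OPTIONS = (1, 3, 5)
_DEPTH_OPTIONS = (32, 64, 128)
_FC_OPTIONS = (256, 512)
_OPTIMIZERS = ("Adam", "SGD")

INPUT_SIZE = 128
_MIDDLE_DEPTH = 64
_MIDDLE_KERNEL = 3
_N_POOLS = 4
_FINAL_SPATIAL = INPUT_SIZE // 2 ** _N_POOLS  # 8


@dataclass(frozen=True)
class ArchitectureSpec:
    """One member of the customized CNN family."""

    kernel_first: int = 5
    kernel_last: int = 3
    depth_first: int = 32
    depth_last: int = 64
    fc_size: int = 512
    n_classes: int = 10
    input_size: int = INPUT_SIZE
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.kernel_first not in _KERNEL_OPTIONS or self.kernel_last not in _KERNEL_OPTIONS:
            raise ValueError(f"kernel sizes must be in {_KERNEL_OPTIONS}")
        if self.depth_first not in _DEPTH_OPTIONS or self.depth_last not in _DEPTH_OPTIONS:
            raise ValueError(f"convolutional depths must be in {_DEPTH_OPTIONS}")
        if self.fc_size not in _FC_OPTIONS:
            raise ValueError(f"fully connected size must be in {_FC_OPTIONS}")
        if self.input_size % 2 ** _N_POOLS:
            raise ValueError("input size must be divisible by 16")

    @property
    def flatten_width(self) -> int:
        side = self.input_size // 2 ** _N_POOLS
        return side * side * self.depth_last


@dataclass
class TrainConfig:
    """Training hyperparameters of the classifier."""

    optimizer: str = "Adam"
    learning_rate: Optional[float] = None  # None -> optimiser default
    batch_size: int = 32
    epochs: int = 3
    dropout: float = 0.3
    val_fraction: float = 0.2
    augmentation_factor: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {_OPTIMIZERS}")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.augmentation_factor < 1:
            raise ValueError("augmentation_factor must be >= 1")


@dataclass(frozen=True)
class LabeledCrop:
    """A 128x128x3 uint8 crop with its class label."""

    pixels: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        px = np.asarray(self.pixels)
        if px.shape != (INPUT_SIZE, INPUT_SIZE, 3):
            raise ValueError(f"crop must be {INPUT_SIZE}x{INPUT_SIZE}x3, got {px.shape}")


def preprocess_crop(
    image: np.ndarray,
    det: Detection,
    pad_fraction: float = 0.1,
    size: int = INPUT_SIZE,
) -> np.ndarray:
    """Crop a detection and resize to the classifier's fixed input window.

    The bounding box is padded by ``pad_fraction`` on every side, expanded
    to a square (so the aspect ratio survives the resize), clipped to the
    frame, and bilinearly resized to ``size`` x ``size`` x 3 uint8.
    """
    if pad_fraction < 0:
        raise ValueError("pad_fraction must be >= 0")
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    h, w = arr.shape[:2]
    x, y, bw, bh = det.bbox
    if bw <= 0 or bh <= 0:
        raise ValueError("degenerate bbox")
    px, py = bw * pad_fraction, bh * pad_fraction
    x0, x1 = x - px, x + bw + px
    y0, y1 = y - py, y + bh + py
    # square expansion around the padded box center
    side = max(x1 - x0, y1 - y0)
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    x0, x1 = cx - side / 2, cx + side / 2
    y0, y1 = cy - side / 2, cy + side / 2
    x0i, x1i = max(0, int(round(x0))), min(w, int(round(x1)))
    y0i, y1i = max(0, int(round(y0))), min(h, int(round(y1)))
    crop = arr[y0i:y1i, x0i:x1i, :3]
    if crop.shape[0] == size and crop.shape[1] == size:
        return np.ascontiguousarray(crop.astype(np.uint8))
    img = Image.fromarray(crop.astype(np.uint8))
    return np.asarray(img.resize((size, size), Image.BILINEAR))


def _augment_one(img: Image.Image, rng: np.random.Generator) -> Image.Image:
    """One random label-preserving transform chain: flips, rotation, zoom, illumination."""
    if rng.random() < 0.5:
        img = img.transpose(Image.FLIP_LEFT_RIGHT)
    if rng.random() < 0.5:
        img = img.transpose(Image.FLIP_TOP_BOTTOM)
    angle = float(rng.uniform(-30, 30))
    img = img.rotate(angle, resample=Image.BILINEAR)
    zoom = float(rng.uniform(1.0, 1.25))
    if zoom > 1.0:
        side = img.width
        zs = int(round(side * zoom))
        img = img.resize((zs, zs), Image.BILINEAR)
        off = (zs - side) // 2
        img = img.crop((off, off, off + side, off + side))
    gain = float(rng.uniform(0.7, 1.3))
    arr = np.asarray(img, dtype=np.float32) * gain
    return Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8))


def augment(crop: LabeledCrop, factor: int, rng: np.random.Generator | int | None = None) -> List[LabeledCrop]:
    """Exactly ``factor`` crops per input, the first being the untouched original."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = [crop]
    base = Image.fromarray(np.asarray(crop.pixels, dtype=np.uint8))
    for _ in range(factor - 1):
        out.append(LabeledCrop(np.asarray(_augment_one(base, rng)), crop.label))
    return out


def build_model(spec: ArchitectureSpec, dropout: float = 0.3,
                seed: int = 0) -> nn.Sequential:
    """Instantiate one family member as a trainable network."""
    rng = np.random.default_rng(seed)
    layers: List[nn.Layer] = []
    chans = [
        (spec.in_channels, spec.depth_first, spec.kernel_first),
        (spec.depth_first, _MIDDLE_DEPTH, _MIDDLE_KERNEL),
        (_MIDDLE_DEPTH, _MIDDLE_DEPTH, _MIDDLE_KERNEL),
        (_MIDDLE_DEPTH, spec.depth_last, spec.kernel_last),
    ]
    for i, (cin, cout, k) in enumerate(chans):
        layers += [nn.Conv2D(cin, cout, k, rng, first=(i == 0)), nn.ReLU(), nn.MaxPool2()]
    layers += [
        nn.Flatten(),
        nn.Dense(spec.flatten_width, spec.fc_size, rng),
        nn.ReLU(),
        nn.Dropout(dropout, rng),
        nn.Dense(spec.fc_size, spec.n_classes, rng),
    ]
    return nn.Sequential(layers)


def count_parameters(spec: ArchitectureSpec) -> int:
    """Exact learnable-parameter total (weights + biases), in closed form.

    Each convolution contributes (k^2 * c_in + 1) * c_out, each dense
    layer (n_in + 1) * n_out; pooling, dropout and activations have no
    parameters.  Independent of :func:`build_model`.
    """
    k1, kl = spec.kernel_first, spec.kernel_last
    d1, dl = spec.depth_first, spec.depth_last
    total = (k1 * k1 * spec.in_channels + 1) * d1
    total += (_MIDDLE_KERNEL ** 2 * d1 + 1) * _MIDDLE_DEPTH
    total += (_MIDDLE_KERNEL ** 2 * _MIDDLE_DEPTH + 1) * _MIDDLE_DEPTH
    total += (kl * kl * _MIDDLE_DEPTH + 1) * dl
    total += (spec.flatten_width + 1) * spec.fc_size
    total += (spec.fc_size + 1) * spec.n_classes
    return total


def enumerate_grid(
    kernel_first: Iterable[int] = _KERNEL_OPTIONS,
    kernel_last: Iterable[int] = _KERNEL_OPTIONS,
    depth_first: Iterable[int] = _DEPTH_OPTIONS,
    depth_last: Iterable[int] = _DEPTH_OPTIONS,
    fc_size: Iterable[int] = _FC_OPTIONS,
    optimizers: Iterable[str] = _OPTIMIZERS,
) -> List[Tuple[ArchitectureSpec, str]]:
    """Cartesian product of hyperparameter options, paired with optimisers."""
    out = []
    for k1, kl, d1, dl, fc, opt in product(kernel_first, kernel_last, depth_first,
                                           depth_last, fc_size, optimizers):
        out.append((ArchitectureSpec(k1, kl, d1, dl, fc), opt))
    if not out:
        raise ValueError("option sets must be nonempty")
    return out


def _make_optimizer(config: TrainConfig) -> nn.Optimizer:
    if config.optimizer == "Adam":
        return nn.Adam(lr=config.learning_rate or 1e-3)
    return nn.SGD(lr=config.learning_rate or 0.01)


def _encode(crops: Sequence[LabeledCrop]) -> Tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.asarray(c.pixels, dtype=np.float32) / 255.0 for c in crops])
    y = np.array([CLASSES.index(c.label) for c in crops], dtype=np.int64)
    return x, y


def _validation_report(y_true: np.ndarray, y_pred: np.ndarray,
                       class_names: Sequence[str]) -> Dict:
    n = len(class_names)
    cm = np.zeros((n, n), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    per_class = {}
    f1s = []
    for i, name in enumerate(class_names):
        tp = int(cm[i, i])
        fp = int(cm[:, i].sum() - tp)
        fn = int(cm[i, :].sum() - tp)
        prec = tp / (tp + fp) if tp + fp else None
        rec = tp / (tp + fn) if tp + fn else None
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
        per_class[name] = {"tp": tp, "fp": fp, "fn": fn,
                           "precision": prec, "recall": rec, "f1": f1}
        f1s.append(f1 if f1 is not None else 0.0)
    return {
        "confusion_matrix": cm.tolist(),
        "class_names": list(class_names),
        "per_class": per_class,
        "macro_f1": float(np.mean(f1s)),
        "accuracy": float((y_true == y_pred).mean()),
        "n_validation": int(len(y_true)),
    }


def train(
    model: nn.Sequential,
    crops: Sequence[LabeledCrop],
    config: TrainConfig,
    verbose: bool = False,
) -> Dict:
    """Train on a stratified split and report validation metrics.

    The crop set is split per class into (1 - val_fraction) training and
    val_fraction validation so every class is represented on both sides.
    Returns a report with per-class precision/recall/F1, the macro F1,
    and the validation confusion matrix (rows = true class).
    """
    labels = sorted({c.label for c in crops})
    if len(labels) < 2:
        raise ValueError("training requires at least two classes")
    rng = np.random.default_rng(config.seed)
    by_class: Dict[str, List[int]] = {}
    for i, c in enumerate(crops):
        by_class.setdefault(c.label, []).append(i)
    train_idx, val_idx = [], []
    for label in labels:
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        n_val = max(1, int(round(len(idx) * config.val_fraction)))
        if n_val >= len(idx):
            raise ValueError(f"class {label!r} has too few samples to split")
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    train_idx, val_idx = np.array(train_idx), np.array(val_idx)

    x_val, y_val = _encode([crops[i] for i in val_idx])
    optimizer = _make_optimizer(config)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [crops[i] for i in order[start:start + config.batch_size]]
            xb, yb = _encode(batch)
            losses.append(model.train_step(xb, yb, optimizer))
        history.append(float(np.mean(losses)))
        if verbose:  # pragma: no cover
            print(f"epoch {epoch + 1}/{config.epochs}: loss {history[-1]:.4f}")

    proba = model.predict_proba(x_val)
    report = _validation_report(y_val, proba.argmax(axis=1), CLASSES)
    report["train_loss"] = history
    report["n_train"] = int(len(train_idx))
    return report


def predict(model: nn.Sequential, crop: np.ndarray) -> Tuple[str, float]:
    """Classify one crop; returns (label, softmax confidence of the argmax)."""
    arr = np.asarray(crop)
    if arr.shape != (INPUT_SIZE, INPUT_SIZE, 3):
        raise ValueError(f"expected {INPUT_SIZE}x{INPUT_SIZE}x3 input, got {arr.shape}")
    x = arr.astype(np.float32)[None]
    if x.max() > 1.0:
        x = x / 255.0
    p = model.predict_proba(x)[0]
    k = int(p.argmax())
    return CLASSES[k], float(p[k])


def save_model(path, model: nn.Sequential, spec: ArchitectureSpec) -> None:
    """Persist weights and the architecture to one .npz file."""
    meta = np.array([spec.kernel_first, spec.kernel_last, spec.depth_first,
                     spec.depth_last, spec.fc_size], dtype=np.int64)
    np.savez(path, __spec__=meta, **model.state_dict())


def load_model(path) -> Tuple[nn.Sequential, ArchitectureSpec]:
    with np.load(path) as data:
        k1, kl, d1, dl, fc = (int(v) for v in data["__spec__"])
        spec = ArchitectureSpec(k1, kl, d1, dl, fc)
        model = build_model(spec)
        model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return model, spec
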