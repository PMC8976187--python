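"""Transfer-learning binary classifier head (healthy vs. ALL).

The classification stage reuses a frozen, pretrained convolutional backbone
as a feature extractor and trains only a minimal head on top of it:

    image -> resize 150x150, scale to (-1, 1) -> backbone features (depth d)
          -> global average pooling -> dense sigmoid unit -> probability

The head has exactly ``d + 1`` trainable parameters (2049 at the canonical
feature depth d = 2048).  A prediction strictly over 0.5 is labelled
*healthy*; 0.5 or below is labelled *ALL* (acute lymphoblastic leukemia).

The feature-extractor contract is "any callable image -> FeatureMap of fixed
depth".  A pretrained network (e.g. InceptionV3) is the intended extractor in
production; :func:`toy_feature_extractor` — a seeded random projection of the
downsampled image — fulfils the same contract deterministically so that the
head can be exercised end-to-end without model downloads.  Fine-tuning the
backbone itself is out of scope: only the head's d + 1 parameters train here.

Training is full-batch gradient descent on the binary cross-entropy (label
encoding healthy = 1, ALL = 0), which is convex in the head parameters, runs
for a fixed number of epochs (default 300) and is reproducible for a fixed
seed.  The final classifier is the epoch with the highest validation
accuracy, ties broken by the lowest validation loss, then the earliest epoch.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .errors import ParameterError, SemanticError
from .io_color import RasterImage

__all__ = [
    "FeatureMap",
    "HeadParameters",
    "TrainConfig",
    "LearningCurve",
    "preprocess_for_extractor",
    "toy_feature_extractor",
    "global_average_pool",
    "predict",
    "count_trainable_parameters",
    "train_head",
    "select_best_epoch",
    "augment",
    "save_head",
    "load_head",
    "save_features",
    "load_features",
]

LABELS = ("healthy", "ALL")
_LABEL_TO_INT = {"healthy": 1, "ALL": 0, 1: 1, 0: 0}


@dataclass
class FeatureMap:
    """A spatial ``h x w x d`` feature grid or a pre-pooled ``d``-vector."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim not in (1, 3):
            raise ParameterError(
                f"feature map must be a d-vector or an h x w x d grid, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ParameterError("feature map contains non-finite values")
        self.values = arr

    @property
    def depth(self) -> int:
        return self.values.shape[-1]

    @property
    def is_pooled(self) -> bool:
        return self.values.ndim == 1


@dataclass
class HeadParameters:
    """Weights and bias of the single sigmoid dense unit."""

    weights: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or w.size < 1:
            raise ParameterError("weights must be a nonempty 1-D vector")
        self.weights = w
        self.bias = float(self.bias)

    @property
    def depth(self) -> int:
        return self.weights.size


@dataclass
class TrainConfig:
    """Training hyper-parameters; defaults mirror the published protocol."""

    epochs: int = 300
    split: tuple[int, int, int] = (208, 26, 26)  # train / validation / test
    learning_rate: float = 0.05
    seed: int = 0
    augmentation: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if len(self.split) != 3 or any(s <= 0 for s in self.split):
            raise ParameterError("split must be three positive sizes")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        self.split = tuple(int(s) for s in self.split)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split"] = list(self.split)
        d["augmentation"] = list(self.augmentation)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "TrainConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown training config key(s): {sorted(unknown)}")
        data = dict(data)
        if "split" in data:
            data["split"] = tuple(data["split"])
        if "augmentation" in data:
            data["augmentation"] = tuple(data["augmentation"])
        return cls(**data)


@dataclass
class LearningCurve:
    """Per-epoch training/validation accuracy and loss."""

    train_accuracy: np.ndarray
    val_accuracy: np.ndarray
    train_loss: np.ndarray
    val_loss: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.train_accuracy)
        for name in ("val_accuracy", "train_loss", "val_loss"):
            if len(getattr(self, name)) != n:
                raise ParameterError("learning-curve series must have equal length")
        if n and (np.min(self.train_loss) < 0 or np.min(self.val_loss) < 0):
            raise ParameterError("losses must be nonnegative")

    def __len__(self) -> int:
        return len(self.train_accuracy)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_accuracy": self.train_accuracy,
                "val_accuracy": self.val_accuracy,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )


def preprocess_for_extractor(image: RasterImage) -> np.ndarray:
    """Resize to 150 x 150 (bilinear) and map intensities into (-1, 1).

    Returns a float ``150 x 150 x 3`` array with ``v -> v / 127.5 - 1``, the
    input convention of the pretrained backbone.
    """
    if image.channel_order != "RGB":
        raise SemanticError(
            f"preprocessing expects an RGB image, got {image.channel_order}"
        )
    resized = _sk_resize(
        image.pixels.astype(np.float64),
        (150, 150, 3),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    return resized / 127.5 - 1.0


def toy_feature_extractor(
    image: RasterImage, depth: int = 2048, seed: int = 0
) -> FeatureMap:
    """Deterministic lightweight feature extractor (seeded random projection).

    Mean-pools the preprocessed image to 15 x 15 x 3, flattens, and projects
    the 675 values through a fixed Gaussian random matrix to ``depth`` features.
    Satisfies the extractor contract (image -> fixed-depth FeatureMap) for
    tests and examples; swap in a pretrained CNN for real data.
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    x = preprocess_for_extractor(image)
    flat = x.reshape(15, 10, 15, 10, 3).mean(axis=(1, 3)).reshape(-1)  # 15*15*3 = 675
    rng = np.random.default_rng(seed)
    projection = rng.standard_normal((flat.size, depth)) / np.sqrt(flat.size)
    return FeatureMap(flat @ projection)


def global_average_pool(fm: FeatureMap) -> FeatureMap:
    """Per-channel spatial mean; pooled vectors pass through unchanged."""
    if fm.is_pooled:
        return fm
    return FeatureMap(fm.values.mean(axis=(0, 1)))


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


def predict(head: HeadParameters, fm: FeatureMap) -> dict:
    """Sigmoid probability and the 0.5-rule label.

    Probability strictly over 0.5 => "healthy"; otherwise (including exactly
    0.5) => "ALL".
    """
    x = global_average_pool(fm).values
    if x.size != head.depth:
        raise SemanticError(f"feature depth {x.size} != head depth {head.depth}")
    p = float(_sigmoid(head.weights @ x + head.bias))
    return {"probability": p, "label": "healthy" if p > 0.5 else "ALL"}


def count_trainable_parameters(head: HeadParameters) -> int:
    """d weights + 1 bias."""
    return head.depth + 1


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _accuracy(p: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((p > 0.5) == (y == 1)))


def _split_sizes(n: int, split: tuple[int, int, int]) -> tuple[int, int, int]:
    if sum(split) == n:
        return split
    total = sum(split)
    n_train = round(n * split[0] / total)
    n_val = round(n * split[1] / total)
    n_val = max(1, min(n_val, n - n_train - 1)) if n - n_train >= 2 else 0
    return n_train, n_val, n - n_train - n_val


def train_head(
    features: list[FeatureMap],
    labels: list[str],
    config: TrainConfig | None = None,
) -> tuple[HeadParameters, LearningCurve]:
    """Train the sigmoid head by full-batch gradient descent on BCE.

    The data are shuffled deterministically (``config.seed``) and split into
    train/validation/test portions per ``config.split`` (scaled
    proportionally when the sizes do not sum to ``len(features)``); the test
    portion is held out entirely.  Returns the final-epoch parameters and the
    full learning curve for best-epoch selection.
    """
    if config is None:
        config = TrainConfig()
    if len(features) == 0 or len(features) != len(labels):
        raise ParameterError("features and labels must be equal-length and nonempty")
    try:
        y_all = np.array([_LABEL_TO_INT[l] for l in labels], dtype=np.float64)
    except KeyError as exc:
        raise ParameterError(f"unknown label {exc.args[0]!r}; use 'healthy' or 'ALL'") from exc
    pooled = [global_average_pool(f).values for f in features]
    depths = {v.size for v in pooled}
    if len(depths) != 1:
        raise SemanticError(f"inconsistent feature depths in dataset: {sorted(depths)}")
    X_all = np.stack(pooled)
    n = len(X_all)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_train, n_val, _ = _split_sizes(n, config.split)
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    X_tr, y_tr = X_all[idx_train], y_all[idx_train]
    X_va, y_va = X_all[idx_val], y_all[idx_val]
    if len(np.unique(y_tr)) < 2:
        raise SemanticError("training split must contain both classes")
    d = X_tr.shape[1]
    w = np.zeros(d)
    b = 0.0
    tr_acc, va_acc, tr_loss, va_loss = [], [], [], []
    for _ in range(config.epochs):
        p = _sigmoid(X_tr @ w + b)
        err = p - y_tr
        w -= config.learning_rate * (X_tr.T @ err) / len(y_tr)
        b -= config.learning_rate * float(np.mean(err))
        p_tr = _sigmoid(X_tr @ w + b)
        tr_loss.append(_bce(p_tr, y_tr))
        tr_acc.append(_accuracy(p_tr, y_tr))
        if len(y_va):
            p_va = _sigmoid(X_va @ w + b)
            va_loss.append(_bce(p_va, y_va))
            va_acc.append(_accuracy(p_va, y_va))
        else:  # no validation portion: mirror training metrics
            va_loss.append(tr_loss[-1])
            va_acc.append(tr_acc[-1])
    curve = LearningCurve(
        np.array(tr_acc), np.array(va_acc), np.array(tr_loss), np.array(va_loss)
    )
    return HeadParameters(w, b), curve


def select_best_epoch(curve: LearningCurve) -> int:
    """1-based epoch with top validation accuracy; ties -> lowest validation
    loss, then earliest epoch."""
    if len(curve) == 0:
        raise ParameterError("learning curve is empty")
    acc = np.asarray(curve.val_accuracy, dtype=np.float64)
    loss = np.asarray(curve.val_loss, dtype=np.float64)
    best = np.flatnonzero(acc == acc.max())
    best = best[loss[best] == loss[best].min()]
    return int(best[0]) + 1


_TRANSFORMS = ("flip_h", "flip_v", "rotate90", "translate")


def augment(image: RasterImage, transform: str, seed: int = 0) -> RasterImage:
    """Deterministic augmentation transform (flip / rotate / translate).

    ``translate`` shifts by a seeded random offset up to 1/8 of each
    dimension, zero-filling the vacated border.  ``rotate90`` rotates a
    quarter turn (shape swaps for non-square images); flips and translation
    preserve shape.
    """
    if transform not in _TRANSFORMS:
        raise ParameterError(f"unknown transform {transform!r}; choose from {_TRANSFORMS}")
    px = image.pixels
    if transform == "flip_h":
        out = px[:, ::-1]
    elif transform == "flip_v":
        out = px[::-1]
    elif transform == "rotate90":
        out = np.rot90(px, k=1, axes=(0, 1))
    else:
        h, w = image.shape
        rng = np.random.default_rng(seed)
        dy = int(rng.integers(-(h // 8), h // 8 + 1))
        dx = int(rng.integers(-(w // 8), w // 8 + 1))
        out = np.zeros_like(px)
        src = px[
            max(0, -dy) : h - max(0, dy),
            max(0, -dx) : w - max(0, dx),
        ]
        out[
            max(0, dy) : max(0, dy) + src.shape[0],
            max(0, dx) : max(0, dx) + src.shape[1],
        ] = src
    return RasterImage(np.ascontiguousarray(out), image.channel_order)


# ---------------------------------------------------------------------------
# serialization

def save_head(head: HeadParameters, path: str | os.PathLike, config: TrainConfig | None = None) -> str:
    """Serialize a trained head (weights, bias, depth, config) as JSON."""
    payload = {
        "depth": head.depth,
        "weights": head.weights.tolist(),
        "bias": head.bias,
        "config": config.to_dict() if config is not None else None,
    }
    path = os.fspath(path)
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path


def load_head(path: str | os.PathLike) -> tuple[HeadParameters, TrainConfig | None]:
    with open(path) as fh:
        payload = json.load(fh)
    head = HeadParameters(np.array(payload["weights"], dtype=np.float64), payload["bias"])
    cfg = TrainConfig.from_dict(payload["config"]) if payload.get("config") else None
    return head, cfg


def save_features(
    features: np.ndarray, labels: list[str], prefix: str | os.PathLike
) -> tuple[str, str]:
    """Write a dense feature matrix CSV plus a sidecar label CSV.

    ``<prefix>_features.csv`` holds one row per sample (no header);
    ``<prefix>_labels.csv`` has columns ``filename,label`` (filename is the
    row index when no real files back the features).
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or len(X) != len(labels):
        raise ParameterError("features must be 2-D with one row per label")
    prefix = os.fspath(prefix)
    fpath, lpath = f"{prefix}_features.csv", f"{prefix}_labels.csv"
    np.savetxt(fpath, X, delimiter=",")
    pd.DataFrame({"filename": [f"row{i}" for i in range(len(labels))], "label": labels}).to_csv(
        lpath, index=False
    )
    return fpath, lpath


def load_features(features_path: str, labels_path: str) -> tuple[np.ndarray, list[str]]:
    """Read a feature matrix and its aligned sidecar labels."""
    X = np.loadtxt(features_path, delimiter=",", ndmin=2)
    table = pd.read_csv(labels_path)
    if "label" not in table.columns:
        raise ParameterError(f"label CSV {labels_path!r} needs a 'label' column")
    labels = table["label"].astype(str).tolist()
    if len(labels) != len(X):
        raise SemanticError(
            f"{len(X)} feature rows but {len(labels)} labels; inputs are misaligned"
        )
    return X, labels
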