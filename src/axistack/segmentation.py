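"""Per-slice semantic segmentation: preprocessing, segmenter implementations
and the training harness.

Every segmenter obeys one contract: ``predict(image, geometry, slice_index)``
returns a label map of the image's original shape whose values are valid
class ids.  Three implementations are provided:

* :class:`OracleSegmenter` — replays ground-truth labels, optionally with a
  controlled corruption rate; isolates downstream stages from segmentation
  error in pipeline tests.
* :class:`NearestMeanSegmenter` — per-pixel nearest class-mean intensity;
  exact on noise-free phantom renderings.
* :class:`TrainableSegmenter` — a lightweight trainable model: a per-pixel
  multilayer perceptron over multi-scale intensity features (raw intensity,
  Gaussian-smoothed intensity at three scales, normalized image coordinates)
  with manual backpropagation, minibatch Adam/SGD, categorical cross-entropy,
  affine data augmentation and patience-based early stopping.  It is a
  desk-scale stand-in wired so a heavier convolutional model can drop in
  behind the same contract.

Images are standardized onto a fixed 560×560 canvas before inference: the
longer side is scaled to 560 with aspect ratio preserved and the shorter
side centered between zero-padding bands; the placement record allows exact
inverse mapping of label maps back to the original shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .imaging_io import LabelClass, N_CLASSES, SeriesRecord, SliceGeometry, SliceRecord

CANVAS = 560


# ---------------------------------------------------------------------------
# canvas preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    """Where an image landed on the canvas; enables the exact inverse map."""

    orig_shape: tuple[int, int]
    scaled_shape: tuple[int, int]
    row_offset: int
    col_offset: int


def _nearest_resize(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize by symmetric center-of-pixel index mapping;
    exactly invertible for integer-ratio scales."""
    rows = np.floor((np.arange(shape[0]) + 0.5) * arr.shape[0] / shape[0]).astype(int)
    cols = np.floor((np.arange(shape[1]) + 0.5) * arr.shape[1] / shape[1]).astype(int)
    return arr[np.ix_(rows, cols)]


def preprocess(image: np.ndarray, *, is_labels: bool = False):
    """Resample onto the 560×560 canvas, zero-padded for non-square inputs.

    The longer side is scaled to 560 preserving aspect ratio; the shorter
    side is centered.  Label maps are resampled nearest-neighbor, images
    bilinearly.  Returns ``(canvas, placement)``.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("preprocess expects a non-empty 2D array")
    h, w = image.shape
    if h >= w:
        scaled = (CANVAS, int(round(w * CANVAS / h)))
    else:
        scaled = (int(round(h * CANVAS / w)), CANVAS)
    if is_labels:
        resized = _nearest_resize(image, scaled)
    else:
        resized = _sk_resize(
            image.astype(np.float32), scaled, order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    canvas = np.zeros((CANVAS, CANVAS), dtype=resized.dtype)
    r_off = (CANVAS - scaled[0]) // 2
    c_off = (CANVAS - scaled[1]) // 2
    canvas[r_off : r_off + scaled[0], c_off : c_off + scaled[1]] = resized
    return canvas, Placement((h, w), scaled, r_off, c_off)


def postprocess(canvas_labels: np.ndarray, placement: Placement) -> np.ndarray:
    """Invert :func:`preprocess` for a label map: strip the padding bands and
    resample nearest-neighbor back to the original shape."""
    canvas_labels = np.asarray(canvas_labels)
    if canvas_labels.shape != (CANVAS, CANVAS):
        raise ValueError(f"canvas must be {CANVAS}×{CANVAS}, got {canvas_labels.shape}")
    sh, sw = placement.scaled_shape
    cropped = canvas_labels[
        placement.row_offset : placement.row_offset + sh,
        placement.col_offset : placement.col_offset + sw,
    ]
    return _nearest_resize(cropped, placement.orig_shape)


# ---------------------------------------------------------------------------
# segmenter implementations
# ---------------------------------------------------------------------------

class Segmenter(Protocol):
    def predict(self, image: np.ndarray, geometry: SliceGeometry,
                slice_index: Optional[int] = None) -> np.ndarray: ...


class OracleSegmenter:
    """Replays ground-truth label maps with an optional corruption rate.

    Exactly ``floor(rate · n_pixels)`` pixels per slice are flipped to a
    uniformly random *other* class; the flip pattern is a deterministic
    function of (seed, slice_index).
    """

    def __init__(self, truth_labels: Sequence[np.ndarray], corruption_rate: float = 0.0,
                 seed: int = 0):
        if not 0.0 <= corruption_rate < 1.0:
            raise ValueError("corruption_rate must be in [0, 1)")
        self.truth_labels = [np.asarray(t) for t in truth_labels]
        self.corruption_rate = corruption_rate
        self.seed = seed

    @classmethod
    def from_series(cls, series: SeriesRecord, corruption_rate: float = 0.0, seed: int = 0):
        return cls([s.labels for s in series.slices], corruption_rate, seed)

    def predict(self, image, geometry, slice_index=None):
        if slice_index is None:
            raise ValueError("OracleSegmenter needs the slice index")
        labels = self.truth_labels[slice_index].copy()
        n_flip = int(np.floor(self.corruption_rate * labels.size))
        if n_flip:
            rng = np.random.default_rng((self.seed, slice_index))
            flat = labels.ravel()
            idx = rng.choice(labels.size, size=n_flip, replace=False)
            # uniform over the 8 classes other than the current one
            offsets = rng.integers(1, N_CLASSES, size=n_flip)
            flat[idx] = (flat[idx] + offsets) % N_CLASSES
        return labels


class NearestMeanSegmenter:
    """Assigns each pixel the class whose mean intensity is nearest
    (ties broken toward the lowest class id)."""

    def __init__(self, intensity_map: Dict[int, float]):
        missing = [int(c) for c in LabelClass if int(c) not in intensity_map]
        if missing:
            raise ValueError(f"intensity map missing classes {missing}")
        self.means = np.array([intensity_map[int(c)] for c in LabelClass], dtype=np.float64)

    def predict(self, image, geometry, slice_index=None):
        diffs = np.abs(image[None, :, :].astype(np.float64) - self.means[:, None, None])
        return np.argmin(diffs, axis=0).astype(np.uint8)


# ---------------------------------------------------------------------------
# trainable model
# ---------------------------------------------------------------------------

_FEATURE_SIGMAS = (2.0, 5.0, 10.0)
_INTENSITY_SCALE = 350.0  # brings phantom intensities to O(1)


def _features(canvas: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack on the canvas: normalized intensity, Gaussian
    pyramids, and normalized (row, col) coordinates.  Shape (H, W, F).

    The coarse scales are filtered on a 4×-decimated grid and bilinearly
    re-expanded — indistinguishable from full-resolution smoothing at these
    sigmas, at a fraction of the cost.
    """
    img = canvas.astype(np.float32) / _INTENSITY_SCALE
    chans = [img, ndimage.gaussian_filter(img, _FEATURE_SIGMAS[0])]
    h, w = canvas.shape
    small = img.reshape(h // 4, 4, w // 4, 4).mean(axis=(1, 3))
    for sigma in _FEATURE_SIGMAS[1:]:
        coarse = ndimage.gaussian_filter(small, sigma / 4.0)
        chans.append(ndimage.zoom(coarse, 4.0, order=1, mode="nearest",
                                  grid_mode=True).astype(np.float32))
    rr, cc = np.meshgrid(
        np.linspace(0.0, 1.0, canvas.shape[0], dtype=np.float32),
        np.linspace(0.0, 1.0, canvas.shape[1], dtype=np.float32),
        indexing="ij",
    )
    chans += [rr, cc]
    return np.stack(chans, axis=-1)


N_FEATURES = 3 + len(_FEATURE_SIGMAS)


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Loss is categorical cross-entropy over minibatches of ``batch_size``
    images; augmentation draws a random affine (rescale, rotate, shear,
    translate) per image per epoch; training stops when the validation loss
    has not reached a new minimum for ``patience`` consecutive epochs.
    """

    batch_size: int = 20
    learning_rate: float = 0.001
    patience: int = 5
    max_epochs: int = 40
    seed: int = 0
    optimizer: str = "adam"  # or "sgd"
    pixels_per_image: int = 1500
    pixel_batch: int = 512  # pixels per optimizer step within an image batch
    augment: bool = True
    rescale_range: tuple[float, float] = (0.9, 1.1)
    rotate_deg: float = 10.0
    shear_deg: float = 5.0
    translate_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class TrainableSegmenter:
    """Per-pixel MLP over multi-scale features; one hidden ReLU layer and a
    9-way softmax head, trained with manual backprop."""

    def __init__(self, hidden_units: int = 48, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden_units = hidden_units
        scale1 = np.sqrt(2.0 / N_FEATURES)
        scale2 = np.sqrt(2.0 / hidden_units)
        self.params = {
            "W1": rng.normal(0, scale1, size=(N_FEATURES, hidden_units)).astype(np.float64),
            "b1": np.zeros(hidden_units),
            "W2": rng.normal(0, scale2, size=(hidden_units, N_CLASSES)).astype(np.float64),
            "b2": np.zeros(N_CLASSES),
        }
        self._adam_state: Optional[dict] = None

    # -- forward/backward --------------------------------------------------

    def logits(self, X: np.ndarray) -> np.ndarray:
        h = np.maximum(X @ self.params["W1"] + self.params["b1"], 0.0)
        return h @ self.params["W2"] + self.params["b2"]

    def loss_and_grad(self, X: np.ndarray, y: np.ndarray):
        """Mean categorical cross-entropy and its parameter gradients."""
        W1, b1, W2, b2 = (self.params[k] for k in ("W1", "b1", "W2", "b2"))
        z1 = X @ W1 + b1
        h = np.maximum(z1, 0.0)
        logits = h @ W2 + b2
        logits = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        n = X.shape[0]
        loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {
            "W2": h.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dh = dlogits @ W2.T
        dh[z1 <= 0] = 0.0
        grads["W1"] = X.T @ dh
        grads["b1"] = dh.sum(axis=0)
        return loss, grads

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        logits = self.logits(X)
        logits = logits - logits.max(axis=1, keepdims=True)
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        return float(-logp[np.arange(X.shape[0]), y].mean())

    def step(self, grads: dict, learning_rate: float, optimizer: str = "adam") -> None:
        if optimizer == "sgd":
            for k in self.params:
                self.params[k] -= learning_rate * grads[k]
            return
        if optimizer != "adam":
            raise ValueError(f"unknown optimizer {optimizer!r}")
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": {k: np.zeros_like(v) for k, v in self.params.items()},
                "v": {k: np.zeros_like(v) for k, v in self.params.items()},
            }
        st = self._adam_state
        st["t"] += 1
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for k in self.params:
            st["m"][k] = beta1 * st["m"][k] + (1 - beta1) * grads[k]
            st["v"][k] = beta2 * st["v"][k] + (1 - beta2) * grads[k] ** 2
            mhat = st["m"][k] / (1 - beta1 ** st["t"])
            vhat = st["v"][k] / (1 - beta2 ** st["t"])
            self.params[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)

    # -- inference ----------------------------------------------------------

    def predict(self, image, geometry, slice_index=None):
        canvas, placement = preprocess(image)
        feats = _features(canvas).reshape(-1, N_FEATURES)
        pred = np.argmax(self.logits(feats), axis=1).astype(np.uint8)
        return postprocess(pred.reshape(CANVAS, CANVAS), placement)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Single-file container: weights plus config and the class list."""
        meta = {
            "hidden_units": self.hidden_units,
            "n_features": N_FEATURES,
            "feature_sigmas": list(_FEATURE_SIGMAS),
            "classes": [c.name for c in LabelClass],
        }
        np.savez(path, meta=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "TrainableSegmenter":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = cls(hidden_units=int(meta["hidden_units"]))
            for k in model.params:
                model.params[k] = data[k]
        return model


# ---------------------------------------------------------------------------
# training harness
# ---------------------------------------------------------------------------

def _random_affine(rng: np.random.Generator, cfg: TrainConfig, shape):
    s = rng.uniform(*cfg.rescale_range)
    theta = np.deg2rad(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg))
    shear = np.deg2rad(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
    ty = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * shape[0]
    tx = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * shape[1]
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shear_m = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    mat = s * rot @ shear_m
    center = np.array(shape) / 2.0
    offset = center - mat @ center + np.array([ty, tx])
    return mat, offset


def _augment_pair(image, labels, rng, cfg):
    mat, offset = _random_affine(rng, cfg, image.shape)
    img_aug = ndimage.affine_transform(image.astype(np.float32), mat, offset=offset,
                                       order=1, mode="constant", cval=0.0)
    lab_aug = ndimage.affine_transform(labels, mat, offset=offset, order=0,
                                       mode="constant", cval=0)
    return img_aug, lab_aug


def _sample_pixels(labels_flat: np.ndarray, n_pixels: int, rng) -> np.ndarray:
    """Class-balanced pixel sampling: up to n/k pixels from each of the k
    classes present (keeps minority structures visible in the loss)."""
    present = np.unique(labels_flat)
    per_class = max(1, n_pixels // len(present))
    chunks = []
    for c in present:
        idx = np.nonzero(labels_flat == c)[0]
        take = min(per_class, len(idx))
        chunks.append(rng.choice(idx, size=take, replace=False))
    return np.concatenate(chunks)


def _validate_labels(records: Sequence[SliceRecord], name: str) -> None:
    for i, r in enumerate(records):
        if r.labels is None:
            raise ValueError(f"{name} slice {i} has no labels")
        if r.labels.size and (r.labels.min() < 0 or r.labels.max() >= N_CLASSES):
            raise ValueError(f"{name} slice {i} contains an invalid class id")


def train(model: TrainableSegmenter, train_set: Sequence[SliceRecord],
          val_set: Sequence[SliceRecord], config: TrainConfig):
    """Train a segmenter, returning ``(model, history)``.

    The model is restored to the weights with the lowest validation loss.
    ``history`` maps ``train_loss`` / ``val_loss`` to per-epoch values.  The
    whole run is a deterministic function of ``config.seed``.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    _validate_labels(train_set, "train")
    _validate_labels(val_set, "val")

    rng = np.random.default_rng(config.seed)

    # fixed validation pixel sample, reused every epoch for comparability
    val_X, val_y = [], []
    for r in val_set:
        canvas, _ = preprocess(r.image)
        lab_canvas, _ = preprocess(r.labels, is_labels=True)
        feats = _features(canvas).reshape(-1, N_FEATURES)
        flat = lab_canvas.ravel()
        idx = _sample_pixels(flat, config.pixels_per_image, rng)
        val_X.append(feats[idx])
        val_y.append(flat[idx])
    val_X = np.concatenate(val_X)
    val_y = np.concatenate(val_y).astype(np.intp)

    history = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    epochs_since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            Xs, ys = [], []
            for j in batch:
                r = train_set[j]
                image, labels = r.image, r.labels
                if config.augment:
                    image, labels = _augment_pair(image, labels, rng, config)
                canvas, _ = preprocess(image)
                lab_canvas, _ = preprocess(labels, is_labels=True)
                feats = _features(canvas).reshape(-1, N_FEATURES)
                flat = lab_canvas.ravel()
                idx = _sample_pixels(flat, config.pixels_per_image, rng)
                Xs.append(feats[idx])
                ys.append(flat[idx])
            X = np.concatenate(Xs)
            y = np.concatenate(ys).astype(np.intp)
            # one image batch feeds several optimizer steps over pixel
            # sub-batches (the training example here is a pixel)
            order_px = rng.permutation(len(X))
            for s0 in range(0, len(order_px), config.pixel_batch):
                sub = order_px[s0 : s0 + config.pixel_batch]
                loss, grads = model.loss_and_grad(X[sub], y[sub])
                model.step(grads, config.learning_rate, config.optimizer)
                epoch_losses.append(loss)

        val_loss = model.loss(val_X, val_y)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(float(val_loss))

        if val_loss < best_loss:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break

    model.params = best_params
    return model, history


def segment_series(series: SeriesRecord, segmenter: Segmenter) -> SeriesRecord:
    """Predict a label map for every slice; images and geometry untouched."""
    new_slices = []
    for i, s in enumerate(series.slices):
        pred = segmenter.predict(s.image, s.geometry, i)
        pred = np.asarray(pred)
        if pred.shape != s.image.shape:
            raise ValueError("segmenter returned a label map of the wrong shape")
        new_slices.append(SliceRecord(image=s.image, geometry=s.geometry,
                                      labels=pred.astype(np.uint8)))
    return SeriesRecord(
        slices=new_slices,
        manufacturer=series.manufacturer,
        bsa=series.bsa,
        height_cm=series.height_cm,
        weight_kg=series.weight_kg,
    )
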