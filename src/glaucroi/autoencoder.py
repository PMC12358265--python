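"""Dense 5-layer autoencoders and reconstruction-error maps.

Two class-specific autoencoders are the heart of the method: one trained
exclusively on healthy texture enface maps (learning normal anatomy and
aging variation) and one trained exclusively on glaucomatous maps (learning
disease-specific damage).  At inference an eye's map is reconstructed by
both; the pair of per-pixel squared-residual maps is the evidence image for
ROI segmentation — a healthy eye reconstructs poorly under the glaucoma
model and well under the healthy model, and vice versa.

Architecture: flattened inputs, widths [D, n1, bottleneck, n1, D]
(default n1=256, bottleneck=64), tanh hidden activations with a linear
output, Glorot-uniform initialisation, Adam (lr 1e-3), MSE loss, batch 50,
150 epochs; the checkpoint with the lowest reconstruction MSE on a held-out
10% validation split (patient-disjoint when patient ids are supplied) is
returned.  Inputs are rescaled from [0, 1] to [-0.9, 0.9] to keep tanh
units out of saturation.  The implementation is plain NumPy (float32 GEMMs)
— the model is small enough that a tensor framework would add nothing.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

from ._rng import substream
from .types import ReconErrorFeature

__all__ = ["AEConfig", "AEModel", "train_autoencoder", "error_map", "dual_features"]


@dataclass
class AEConfig:
    input_size: tuple[int, int] = (128, 128)
    hidden: int = 256
    bottleneck: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 50
    epochs: int = 150
    val_fraction: float = 0.10
    smooth_error: bool = True  # 3x3 mean smoothing of the residual map
    scale_low: float = -0.9
    scale_high: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bottleneck >= self.input_size[0] * self.input_size[1]:
            raise ValueError("bottleneck must be smaller than the flattened input")
        if self.hidden < self.bottleneck:
            raise ValueError("hidden width must be >= bottleneck")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")

    @property
    def layer_widths(self) -> list[int]:
        d = self.input_size[0] * self.input_size[1]
        return [d, self.hidden, self.bottleneck, self.hidden, d]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


class AEModel:
    """A trained autoencoder: weights, config, training class, and the
    validation MSE of the selected checkpoint."""

    def __init__(
        self,
        weights: list[np.ndarray],
        biases: list[np.ndarray],
        cfg: AEConfig,
        train_class: str,
        selection_mse: float,
    ) -> None:
        self.weights = weights
        self.biases = biases
        self.cfg = cfg
        self.train_class = train_class
        self.selection_mse = float(selection_mse)

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        n = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < n - 1:
                h = np.tanh(h)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Reconstruct one scaled, flattened image (or a batch)."""
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 1
        out = self._forward(np.atleast_2d(x))
        return out[0] if single else out

    # -- persistence: single-file blob with embedded config -----------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        meta = json.dumps(
            {
                "format_version": 1,
                "cfg": asdict(self.cfg),
                "train_class": self.train_class,
                "selection_mse": self.selection_mse,
            }
        )
        buf = _io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
        path.write_bytes(buf.getvalue())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AEModel":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            n = sum(1 for k in data.files if k.startswith("w"))
            weights = [data[f"w{i}"] for i in range(n)]
            biases = [data[f"b{i}"] for i in range(n)]
        cfg_dict = meta["cfg"]
        cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
        cfg = AEConfig(**cfg_dict)
        return cls(weights, biases, cfg, meta["train_class"], meta["selection_mse"])


def _prepare(images: Sequence[np.ndarray], cfg: AEConfig, allow_resize: bool = True) -> np.ndarray:
    """Resize to ``cfg.input_size`` (bilinear), rescale [0,1] -> tanh range,
    flatten to a (n, D) float32 matrix."""
    out = []
    for img in images:
        arr = np.asarray(img, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("images must be 2D")
        if arr.shape != tuple(cfg.input_size):
            if not allow_resize:
                raise ValueError(f"image shape {arr.shape} != input_size {cfg.input_size}")
            arr = resize(arr, cfg.input_size, order=1, anti_aliasing=False, preserve_range=True)
        out.append(arr.ravel())
    x = np.asarray(out, dtype=np.float32)
    lo, hi = cfg.scale_low, cfg.scale_high
    return (x * (hi - lo) + lo).astype(np.float32)


def train_autoencoder(
    images: Sequence[np.ndarray],
    cfg: AEConfig,
    class_label: str,
    patient_ids: Optional[Sequence[str]] = None,
) -> AEModel:
    """Train one class-specific autoencoder.

    A 10% validation split (grouped by ``patient_ids`` when given, so the
    split is patient-disjoint) is held out of the gradient updates; after
    every epoch the validation MSE is evaluated and the best-epoch weights
    are kept.  Fully deterministic for fixed inputs, config and seed.
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"mixed image sizes in training set: {sorted(shapes)}")
    x = _prepare(images, cfg)
    n = x.shape[0]

    rng = substream(cfg.seed, "ae", class_label)
    if patient_ids is not None:
        if len(patient_ids) != n:
            raise ValueError("patient_ids must match images")
        groups = np.asarray([str(p) for p in patient_ids])
        uniq = np.array(sorted(set(groups)))
        n_val_g = max(1, int(round(cfg.val_fraction * len(uniq)))) if len(uniq) > 1 else 0
        val_groups = set(uniq[rng.permutation(len(uniq))[:n_val_g]])
        val_mask = np.isin(groups, list(val_groups))
    else:
        n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
        val_mask = np.zeros(n, dtype=bool)
        val_mask[rng.permutation(n)[:n_val]] = True
    x_train, x_val = x[~val_mask], x[val_mask]
    if x_train.shape[0] == 0:
        x_train = x
    if x_val.shape[0] == 0:
        x_val = x_train

    widths = cfg.layer_widths
    weights = [_glorot(rng, widths[i], widths[i + 1]) for i in range(len(widths) - 1)]
    biases = [np.zeros(widths[i + 1], dtype=np.float32) for i in range(len(widths) - 1)]

    params = weights + biases
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0

    def forward_cache(xb: np.ndarray):
        acts = [xb]
        h = xb
        n_layers = len(weights)
        for i in range(n_layers):
            pre = h @ weights[i] + biases[i]
            h = np.tanh(pre) if i < n_layers - 1 else pre
            acts.append(h)
        return acts

    def val_mse() -> float:
        recon = forward_cache(x_val)[-1]
        return float(np.mean((x_val - recon) ** 2))

    best = (np.inf, [w.copy() for w in weights], [b.copy() for b in biases])
    n_train = x_train.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, cfg.batch_size):
            xb = x_train[order[start : start + cfg.batch_size]]
            acts = forward_cache(xb)
            bsz = xb.shape[0]
            # d(MSE)/d(out); MSE averaged over batch and pixels
            delta = (2.0 / (bsz * xb.shape[1])) * (acts[-1] - xb)
            grads_w = [None] * len(weights)
            grads_b = [None] * len(weights)
            for i in range(len(weights) - 1, -1, -1):
                grads_w[i] = acts[i].T @ delta
                grads_b[i] = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ weights[i].T) * (1.0 - acts[i] ** 2)
            t_step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t_step) / (1 - beta1**t_step)
            for j, g in enumerate(grads_w + grads_b):
                m_adam[j] = beta1 * m_adam[j] + (1 - beta1) * g
                v_adam[j] = beta2 * v_adam[j] + (1 - beta2) * g * g
                params[j] -= (lr_t * m_adam[j] / (np.sqrt(v_adam[j]) + eps)).astype(np.float32)
        mse = val_mse()
        if mse < best[0]:
            best = (mse, [w.copy() for w in weights], [b.copy() for b in biases])

    return AEModel(best[1], best[2], cfg, class_label, best[0])


def error_map(model, x: np.ndarray, allow_resize: bool = True) -> np.ndarray:
    """Per-pixel squared reconstruction residual of map ``x`` (values in
    [0, 1]) on the model's input grid, optionally 3x3 mean-smoothed."""
    cfg = model.cfg
    flat = _prepare([x], cfg, allow_resize=allow_resize)[0]
    recon = np.asarray(model.reconstruct(flat), dtype=np.float64)
    err = (flat.astype(np.float64) - recon) ** 2
    err = err.reshape(cfg.input_size)
    if getattr(cfg, "smooth_error", False):
        from scipy.ndimage import uniform_filter

        err = uniform_filter(err, size=3, mode="reflect")
    return np.clip(err, 0.0, None)


def upsample_to(err: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsampling of an error map back to native shape."""
    if err.shape == tuple(shape):
        return err
    return resize(err, shape, order=0, anti_aliasing=False, preserve_range=True)


def dual_features(h_model, g_model, x: np.ndarray) -> ReconErrorFeature:
    """Present ``x`` to both class autoencoders and pair the error maps."""
    if tuple(h_model.cfg.input_size) != tuple(g_model.cfg.input_size):
        raise ValueError("models must share input size")
    return ReconErrorFeature(
        e_healthy=error_map(h_model, x),
        e_glaucoma=error_map(g_model, x),
    )
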