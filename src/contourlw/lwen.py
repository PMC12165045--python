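"""Liveweight regression directly from contour coordinates.

The network consumes N contour points per animal (ordered or unordered),
normalizes them jointly against the image (retaining absolute position and
apparent size) and against their own bounding box (a positional embedding
of the shape), projects the resulting N x 4 sequence to a hidden width,
mixes it with multi-head self-attention, mean-pools over the points and
regresses a single weight in kilograms through a two-layer head:

    LW = LeakyReLU(mean_N(MHSA(X_norm W_lp)) W_fc1) W_fc2

Mean pooling over points makes the prediction invariant to the input point
order, so unordered contour predictions are as valid an input as sampled
ground-truth outlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor
from .contour_core import box_normalize, sample_contour_points
from .nn_blocks import MhsaBlock, init_matrix

__all__ = [
    "LwenConfig",
    "LwenModel",
    "lwen_normalize",
    "lwen_loss",
    "train_lwen",
    "count_parameters",
    "format_parameter_count",
]


@dataclass
class LwenConfig:
    n_points: int = 128
    input_width: int = 4
    d_hide: int = 512
    mhsa_layers: int = 1
    heads: int = 8
    ffn_mult: int = 4
    d_fc: int = 128
    leaky_slope: float = 0.01
    img_norm: str = "corner"  # "corner": (x-W)/W in [-1,0]; "centered": (x-W/2)/(W/2)
    # training schedule
    epochs: int = 400
    lr: float = 1e-3
    weight_decay: float = 5e-4
    warmup_epochs: int = 10
    warmup_factor: float = 0.1
    milestones: tuple = (80, 160, 240, 320)
    lr_decay: float = 0.1
    batch_size: int = 32
    noise_sd: float = 0.5  # pixels, input-coordinate augmentation
    flip_augment: bool = True

    def __post_init__(self):
        if self.d_hide % self.heads:
            raise ValueError("d_hide must be divisible by the head count")

    @classmethod
    def wide(cls, **kw) -> "LwenConfig":
        return cls(d_hide=1024, **kw)

    @classmethod
    def deep(cls, **kw) -> "LwenConfig":
        return cls(mhsa_layers=6, **kw)

    @classmethod
    def desk(cls, **kw) -> "LwenConfig":
        """CPU-scale preset: narrower model, shorter schedule, fewer points."""
        kw.setdefault("d_hide", 64)
        kw.setdefault("n_points", 32)
        kw.setdefault("epochs", 60)
        kw.setdefault("warmup_epochs", 3)
        kw.setdefault("milestones", (30, 45))
        kw.setdefault("lr_decay", 0.3)
        kw.setdefault("batch_size", 64)
        return cls(**kw)


def lwen_normalize(points, image_size, mode: str = "corner") -> np.ndarray:
    """N x 4 normalized sequence: image-relative columns then box-relative.

    Image normalization anchors at the far corner: ((x - W)/W, (y - H)/H)
    maps the image to [-1, 0]^2; ``mode="centered"`` offers the symmetric
    (x - W/2)/(W/2) instead. Box normalization rescales the points to the
    unit square via their own bounding box and doubles as the positional
    embedding.
    """
    pts = np.asarray(points, dtype=np.float64)
    w, h = float(image_size[0]), float(image_size[1])
    if w <= 0 or h <= 0:
        raise ValueError("image dims must be positive")
    if mode == "corner":
        img = np.stack([(pts[:, 0] - w) / w, (pts[:, 1] - h) / h], axis=1)
    elif mode == "centered":
        img = np.stack([(pts[:, 0] - w / 2) / (w / 2), (pts[:, 1] - h / 2) / (h / 2)], axis=1)
    else:
        raise ValueError("unknown image normalization mode")
    return np.concatenate([img, box_normalize(pts)], axis=1)


class LwenModel:
    def __init__(self, config: LwenConfig | None = None, seed: int = 0):
        self.config = config or LwenConfig()
        rng = np.random.default_rng(seed)
        c = self.config
        self.w_lp = init_matrix(rng, c.input_width, c.d_hide)
        self.b_lp = Tensor(np.zeros(c.d_hide), requires_grad=True)
        self.blocks = [MhsaBlock(c.d_hide, c.heads, rng, c.ffn_mult) for _ in range(c.mhsa_layers)]
        self.w_fc1 = init_matrix(rng, c.d_hide, c.d_fc)
        self.b_fc1 = Tensor(np.zeros(c.d_fc), requires_grad=True)
        self.w_fc2 = init_matrix(rng, c.d_fc, 1)
        self.b_fc2 = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self):
        params = [self.w_lp, self.b_lp, self.w_fc1, self.b_fc1, self.w_fc2, self.b_fc2]
        for blk in self.blocks:
            params += blk.parameters()
        return params

    def forward(self, x_norm) -> Tensor:
        """Predict weights (kg) for a (B, N, 4) or (N, 4) normalized batch."""
        x = x_norm if isinstance(x_norm, Tensor) else Tensor(np.asarray(x_norm, float))
        squeeze = x.ndim == 2
        if squeeze:
            x = x.reshape(1, *x.shape)
        h = x @ self.w_lp + self.b_lp
        for blk in self.blocks:
            h = blk(h)
        pooled = h.mean(axis=1)  # (B, d_hide)
        out = (pooled @ self.w_fc1 + self.b_fc1).leaky_relu(self.config.leaky_slope)
        lw = (out @ self.w_fc2 + self.b_fc2).reshape(x.shape[0])
        return lw.reshape(()) if squeeze else lw

    __call__ = forward

    def predict(self, polygons, image_size) -> np.ndarray:
        """Weights for a list of pixel-space contours (resampled to N points
        when the vertex count differs)."""
        c = self.config
        batch = []
        for poly in polygons:
            poly = np.asarray(poly, float)
            if len(poly) != c.n_points:
                poly = sample_contour_points(poly, c.n_points)
            batch.append(lwen_normalize(poly, image_size, c.img_norm))
        return self.forward(np.stack(batch)).data


def lwen_loss(predicted: Tensor, truth: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) loss between predicted and true weights."""
    diff = predicted - Tensor(np.asarray(truth, float))
    quad = np.abs(diff.data) < beta
    sign = np.sign(diff.data)
    branch = diff * diff * Tensor(quad * 0.5 / beta) + diff * Tensor(~quad * sign) - Tensor(
        (~quad) * 0.5 * beta
    )
    return branch.mean()


def count_parameters(model) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def format_parameter_count(n: int) -> str:
    return f"{n / 1e6:.1f}M"


def _epoch_lr(cfg: LwenConfig, epoch: int) -> float:
    lr = cfg.lr
    if epoch < cfg.warmup_epochs:
        return lr * cfg.warmup_factor
    for m in cfg.milestones:
        if epoch >= m:
            lr *= cfg.lr_decay
    return lr


def train_lwen(dataset, config: LwenConfig | None = None, seed: int = 0, verbose: bool = False):
    """Train a weight regressor on (polygon, image dims, weight) triples.

    Per step, N points are drawn from a 4N-point uniform resampling of the
    ground-truth outline at a random phase, jittered with Gaussian pixel
    noise, optionally mirrored horizontally; supervision is smooth-L1 on
    kilograms with the warm-up + milestone learning-rate schedule.
    Returns ``(model, history)``.
    """
    cfg = config or LwenConfig()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    model = LwenModel(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    # pre-densify every outline to 4N points once
    dense = [
        (sample_contour_points(poly, 4 * cfg.n_points), dims, wt)
        for poly, dims, wt in dataset
    ]
    history = {"epoch_loss": [], "lr": []}
    n = len(dense)
    for epoch in range(cfg.epochs):
        opt.lr = _epoch_lr(cfg, epoch)
        order = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xs, ys = [], []
            for i in idx:
                poly4n, dims, wt = dense[i]
                start = rng.integers(0, 4)
                pts = poly4n[start::4][: cfg.n_points].copy()
                if cfg.noise_sd > 0:
                    pts += rng.normal(0.0, cfg.noise_sd, pts.shape)
                if cfg.flip_augment and rng.random() < 0.5:
                    pts[:, 0] = dims[0] - pts[:, 0]
                xs.append(lwen_normalize(pts, dims, cfg.img_norm))
                ys.append(wt)
            x = Tensor(np.stack(xs))
            pred = model.forward(x)
            loss = lwen_loss(pred, np.array(ys))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        history["epoch_loss"].append(total / n)
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs} loss {total / n:.3f}")
    return model, history
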