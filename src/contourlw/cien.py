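"""Contour-extraction network: multi-scale features, centre-heatmap contour
initialization, and self-attention contour evolution.

The detector is single-class and contour-native: a small convolutional
backbone produces feature maps at strides 4/8/16/32 which are fused by
iterative deep aggregation (IDA) into a stride-4 map F. Two heads on F
predict a sigmoid centre heatmap and, per location, the 2N offsets of an
initial N-vertex contour regressed straight from the object centre. Each
contour is then refined by contour self-attention (CSA) blocks: per-vertex
features sampled bilinearly from a refined map F' are concatenated with
the bounding-box-normalized vertex coordinates (the contour positional
embedding) and passed through multi-head self-attention; a linear head
turns each output row into a per-vertex offset.

Training supervises the heatmap with a penalty-reduced focal loss and the
contours at each stage with either the debiased Sinkhorn divergence
("SoftAssign") or a Kuhn-Munkres matched smooth-L1 ("HardAssign"):

    L = L_focal + 0.5 L_contour^init + 0.5 L_contour^CSA1 + L_contour^CSA2
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import ot_supervision as ots
from .autodiff import Adam, Tensor, concat, conv2d, grid_sample, upsample_nearest
from .contour_core import box_normalize, sample_contour_points
from .nn_blocks import MhsaBlock, init_matrix

__all__ = [
    "CienConfig",
    "CienModel",
    "focal_heatmap_loss",
    "splat_heatmap_target",
    "cien_total_loss",
    "train_cien",
]


@dataclass
class CienConfig:
    n_vertices: int = 128
    image_size: tuple = (768, 576)  # (W, H)
    csa_blocks: int = 2
    heads: int = 8
    feat_channels: int = 24
    fprime_channels: int = 254  # point-feature width; CSA dim = this + 2
    reg_head_width: int = 64
    backbone_widths: tuple = (16, 24, 32, 48, 64)  # stem, stride-4, 8, 16, 32
    heatmap_thresh: float = 0.3
    # OT cost units: "feature" = raw feature-map pixels (epsilon 0.05 is
    # sharp, a fraction of the inter-vertex spacing); "image" = coordinates
    # divided by the image extent so epsilon is a fraction of the scene
    ot_scale: str = "feature"
    # training schedule
    epochs: int = 300
    lr: float = 1e-4
    milestones: tuple = (50, 100, 150, 200, 250, 270)
    lr_decay: float = 0.5
    flip_augment: bool = True
    sinkhorn: ots.SinkhornConfig = field(
        default_factory=lambda: ots.SinkhornConfig(max_iters=30, tol=1e-4, fail_tol=1e9)
    )

    def __post_init__(self):
        if self.n_vertices < 3:
            raise ValueError("need at least 3 contour vertices")
        if (self.fprime_channels + 2) % self.heads:
            raise ValueError("fprime_channels + 2 must be divisible by the head count")

    @property
    def csa_dim(self) -> int:
        return self.fprime_channels + 2

    @classmethod
    def desk(cls, **kw) -> "CienConfig":
        """CPU-scale preset: 96 x 96 scenes, narrow backbone, short schedule."""
        kw.setdefault("image_size", (96, 96))
        kw.setdefault("n_vertices", 64)
        kw.setdefault("fprime_channels", 30)
        kw.setdefault("backbone_widths", (8, 12, 16, 24, 32))
        kw.setdefault("epochs", 15)
        kw.setdefault("lr", 1e-3)
        kw.setdefault("milestones", (8, 12))
        return cls(**kw)


def _conv_param(rng, cout, cin, k):
    std = 1.0 / np.sqrt(cin * k * k)
    w = Tensor(rng.normal(0.0, std, (cout, cin, k, k)), requires_grad=True)
    b = Tensor(np.zeros(cout), requires_grad=True)
    return w, b


class CienModel:
    def __init__(self, config: CienConfig | None = None, seed: int = 0):
        self.config = config or CienConfig.desk()
        c = self.config
        rng = np.random.default_rng(seed)
        w0, w1, w2, w3, w4 = c.backbone_widths
        fc = c.feat_channels
        self.convs = {}

        def add(name, cout, cin, k):
            self.convs[name] = _conv_param(rng, cout, cin, k)

        add("stem", w0, 3, 3)
        add("s4", w1, w0, 3)
        add("s8", w2, w1, 3)
        add("s16", w3, w2, 3)
        add("s32", w4, w3, 3)
        for i, w in enumerate((w1, w2, w3, w4)):
            add(f"proj{i}", fc, w, 1)  # project each scale to the fused width
        for i in range(3):
            add(f"ida{i}", fc, fc, 3)  # aggregation nodes
        add("ct0", fc, fc, 3)
        add("ct1", 1, fc, 1)
        self.convs["ct1"][1].data[:] = -2.19  # start the heatmap near 0.1
        add("reg0", c.reg_head_width, fc, 3)
        add("reg1", c.n_vertices * 2, c.reg_head_width, 1)
        add("fp0", c.fprime_channels, fc, 3)
        add("fp1", c.fprime_channels, c.fprime_channels, 3)
        self.csa = []
        for _ in range(c.csa_blocks):
            block = MhsaBlock(c.csa_dim, c.heads, rng)
            w_off = Tensor(np.zeros((c.csa_dim, 2)), requires_grad=True)  # identity at init
            self.csa.append((block, w_off))

    def parameters(self):
        params = []
        for w, b in self.convs.values():
            params += [w, b]
        for block, w_off in self.csa:
            params += block.parameters() + [w_off]
        return params

    # ------------------------------------------------------------- features
    def backbone(self, x: Tensor):
        def step(name, t, stride):
            w, b = self.convs[name]
            return conv2d(t, w, b, stride=stride, pad=1).relu()

        t = step("stem", x, 2)
        o1 = step("s4", t, 2)
        o2 = step("s8", o1, 2)
        o3 = step("s16", o2, 2)
        o4 = step("s32", o3, 2)
        return [o1, o2, o3, o4]

    def ida_aggregate(self, series) -> Tensor:
        """Recursive pairwise fusion T(o1..on) = T(N(o1, o2), o3, ..., on).

        Each aggregation node upsamples the deeper map to the running
        resolution, adds, and convolves; a length-1 series is returned
        as-is (projected to the fused width).
        """
        proj = [
            conv2d(o, *self.convs[f"proj{i}"], stride=1, pad=0)
            for i, o in enumerate(series)
        ]
        x = proj[0]
        for i, deeper in enumerate(proj[1:]):
            factor = x.shape[2] // deeper.shape[2]
            up = upsample_nearest(deeper, factor) if factor > 1 else deeper
            w, b = self.convs[f"ida{i}"]
            x = conv2d(x + up, w, b, stride=1, pad=1).relu()
        return x

    def heads_forward(self, f: Tensor):
        ct = conv2d(f, *self.convs["ct0"], stride=1, pad=1).relu()
        heatmap = conv2d(ct, *self.convs["ct1"], stride=1, pad=0).sigmoid()
        rg = conv2d(f, *self.convs["reg0"], stride=1, pad=1).relu()
        reg = conv2d(rg, *self.convs["reg1"], stride=1, pad=0)
        fp = conv2d(f, *self.convs["fp0"], stride=1, pad=1).relu()
        fprime = conv2d(fp, *self.convs["fp1"], stride=1, pad=1).relu()
        return heatmap, reg, fprime

    def features(self, image: np.ndarray):
        """image: (H, W, 3) uint8/float -> heatmap, regression map, F'."""
        x = np.asarray(image, dtype=np.float64) / 255.0 - 0.5
        t = Tensor(x.transpose(2, 0, 1)[None])
        f = self.ida_aggregate(self.backbone(t))
        return self.heads_forward(f)

    # -------------------------------------------------------------- contours
    def initialize_contour(self, reg: Tensor, center) -> Tensor:
        """Initial contour for one centre (feature-map units): centre + the
        N x 2 regression vector stored at that cell."""
        n = self.config.n_vertices
        cx, cy = center
        h, w = reg.shape[2], reg.shape[3]
        ix = int(np.clip(round(cx), 0, w - 1))
        iy = int(np.clip(round(cy), 0, h - 1))
        if ix != round(cx) or iy != round(cy):
            warnings.warn("centre outside feature grid; clamped")
        offs = reg[0, :, iy, ix].reshape(n, 2)
        return offs + Tensor(np.array([cx, cy], dtype=np.float64))

    def csa_refine(self, contour: Tensor, fprime: Tensor, block_idx: int) -> Tensor:
        """One CSA evolution step; returns the refined contour (N, 2)."""
        block, w_off = self.csa[block_idx]
        feats = grid_sample(fprime.reshape(fprime.shape[1:]) if fprime.ndim == 4 else fprime, contour)
        cpe = Tensor(box_normalize(contour.data))  # positional embedding
        p = concat([feats, cpe], axis=1)
        offsets = block(p) @ w_off
        return contour + offsets

    def contours_from_centers(self, reg: Tensor, fprime: Tensor, centers):
        """Initial + refined contour stack per centre (feature units)."""
        stages_all = []
        for center in centers:
            stages = [self.initialize_contour(reg, center)]
            for b in range(self.config.csa_blocks):
                stages.append(self.csa_refine(stages[-1], fprime, b))
            stages_all.append(stages)
        return stages_all

    # ------------------------------------------------------------- inference
    def infer(self, image: np.ndarray, threshold: float | None = None):
        """Detected contours in input-pixel units with their peak scores."""
        thr = self.config.heatmap_thresh if threshold is None else threshold
        heatmap, reg, fprime = self.features(image)
        hm = heatmap.data[0, 0]
        peaks = (hm == ndimage.maximum_filter(hm, size=3)) & (hm >= thr)
        ys, xs = np.nonzero(peaks)
        out = []
        for x, y in zip(xs, ys):
            stages = self.contours_from_centers(reg, fprime, [(float(x), float(y))])[0]
            out.append((stages[-1].data * 4.0, float(hm[y, x])))
        return out


# ------------------------------------------------------------------- losses
def splat_heatmap_target(centers, bbox_diags, shape) -> np.ndarray:
    """Gaussian centre splats on the feature grid; sigma scales with the
    object's bbox diagonal (feature units)."""
    h, w = shape
    target = np.zeros((h, w))
    ys, xs = np.mgrid[0:h, 0:w]
    for (cx, cy), diag in zip(centers, bbox_diags):
        sigma = max(1.0, diag / 6.0)
        g = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
        target = np.maximum(target, g)
        ix, iy = int(np.clip(round(cx), 0, w - 1)), int(np.clip(round(cy), 0, h - 1))
        target[iy, ix] = 1.0
    return target


def focal_heatmap_loss(pred: Tensor, target: np.ndarray, alpha: float = 2.0, beta: float = 4.0) -> Tensor:
    """Penalty-reduced pixel-wise focal loss, normalized by object count."""
    t = np.asarray(target, dtype=np.float64)
    pos = t >= 0.999
    n_obj = int(pos.sum())
    if n_obj == 0:
        warnings.warn("no objects in heatmap target")
        return Tensor(0.0)
    p = pred.reshape(t.shape) * (1.0 - 2e-7) + 1e-7  # keep logs finite
    pos_term = ((1.0 - p) ** alpha) * p.log() * Tensor(pos.astype(float))
    neg_w = ((1.0 - t) ** beta) * (~pos)
    neg_term = (p**alpha) * (1.0 - p).log() * Tensor(neg_w)
    return -(pos_term.sum() + neg_term.sum()) * (1.0 / n_obj)


def cien_total_loss(l_focal, l_init, l_csa1, l_csa2):
    """Weighted sum of the heatmap and per-stage contour losses."""
    return l_focal + 0.5 * l_init + 0.5 * l_csa1 + l_csa2


def _ot_loss_node(pts: Tensor, gt: np.ndarray, sinkhorn: ots.SinkhornConfig, scale: float, v_bb: float | None = None) -> Tensor:
    """Debiased Sinkhorn divergence between a predicted contour (autodiff
    node, feature units) and a fixed target; the closed-form gradient is
    injected into the graph. The target self-term ``v_bb`` is constant in
    the parameters and can be passed in pre-computed."""
    psi = pts.data / scale
    phi = np.asarray(gt, dtype=np.float64) / scale
    alpha = ots.uniform_measure(psi)
    beta = ots.uniform_measure(phi)
    v_ab, (_, g_ab) = ots.sinkhorn_ot(alpha, beta, sinkhorn)
    v_aa, f_aa = ots.sinkhorn_self(alpha, sinkhorn)
    if v_bb is None:
        v_bb, _ = ots.sinkhorn_self(beta, sinkhorn)
    loss = v_ab - 0.5 * v_aa - 0.5 * v_bb
    grad = ots.ot_gradient(alpha, beta, g_ab, f_aa, sinkhorn.epsilon_target) / scale

    out = Tensor(np.float64(loss))
    out.requires_grad = True
    out._prev = (pts,)
    out._backward = lambda g: pts._accum(g * grad)
    return out


def _km_loss_node(pts: Tensor, gt: np.ndarray, scale: float) -> Tensor:
    """Hungarian-matched smooth-L1 on unit-box-normalized coordinates."""
    perm, _ = ots.km_hard_assign(pts.data, gt)
    diff = pts * (1.0 / scale) - Tensor(np.asarray(gt, float)[perm] / scale)
    quad = np.abs(diff.data) < 1.0
    sign = np.sign(diff.data)
    return (
        diff * diff * Tensor(quad * 0.5) + diff * Tensor(~quad * sign) - Tensor((~quad) * 0.5)
    ).mean()


# ------------------------------------------------------------------ training
def _scene_instances(scene, cfg: CienConfig, rng, flip: bool):
    """Ground-truth contours (feature units) + centres + bbox diagonals."""
    w_img = scene.image.shape[1]
    gts, centers, diags = [], [], []
    for inst in scene.instances:
        poly = inst["polygon"]
        if flip:
            poly = poly.copy()
            poly[:, 0] = w_img - poly[:, 0]
        phase = rng.random()
        pts = sample_contour_points(poly, cfg.n_vertices, phase) / 4.0
        gts.append(pts)
        centers.append(tuple(pts.mean(axis=0)))
        ext = pts.max(axis=0) - pts.min(axis=0)
        diags.append(float(np.hypot(*ext)))
    return gts, centers, diags


def train_cien(scenes, config: CienConfig | None = None, seed: int = 0, supervision: str = "ot", verbose: bool = False):
    """Train on a list of SceneRecords; ``supervision`` picks the contour
    loss ("ot" = debiased Sinkhorn SoftAssign, "km" = Hungarian HardAssign).
    Centres come from the ground truth during training. Returns
    ``(model, history)`` with per-epoch loss components."""
    if len(scenes) == 0:
        raise ValueError("empty dataset")
    if supervision not in ("ot", "km"):
        raise ValueError("supervision must be 'ot' or 'km'")
    cfg = config or CienConfig.desk()
    model = CienModel(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.parameters(), lr=cfg.lr)
    scale = 1.0 if cfg.ot_scale == "feature" else max(cfg.image_size) / 4.0
    history = {"loss": [], "focal": [], "contour": []}
    for epoch in range(cfg.epochs):
        lr = cfg.lr
        for m in cfg.milestones:
            if epoch >= m:
                lr *= cfg.lr_decay
        opt.lr = lr
        tot = tot_f = tot_c = 0.0
        for si in rng.permutation(len(scenes)):
            scene = scenes[si]
            flip = cfg.flip_augment and rng.random() < 0.5
            image = scene.image[:, ::-1] if flip else scene.image
            gts, centers, diags = _scene_instances(scene, cfg, rng, flip)
            if not gts:
                continue
            heatmap, reg, fprime = model.features(image)
            target = splat_heatmap_target(centers, diags, heatmap.data.shape[2:])
            l_focal = focal_heatmap_loss(heatmap, target)
            n_stages = cfg.csa_blocks + 1
            stage_losses = [Tensor(0.0) for _ in range(n_stages)]
            stages_all = model.contours_from_centers(reg, fprime, centers)
            for gt, stages in zip(gts, stages_all):
                v_bb = None
                if supervision == "ot":
                    v_bb, _ = ots.sinkhorn_self(ots.uniform_measure(gt / scale), cfg.sinkhorn)
                for s, pts in enumerate(stages):
                    if supervision == "ot":
                        node = _ot_loss_node(pts, gt, cfg.sinkhorn, scale, v_bb=v_bb)
                    else:
                        node = _km_loss_node(pts, gt, scale)
                    stage_losses[s] = stage_losses[s] + node
            n_inst = len(gts)
            stage_losses = [s * (1.0 / n_inst) for s in stage_losses]
            if n_stages == 3:
                loss = cien_total_loss(l_focal, *stage_losses)
            else:  # intermediate stages at half weight, final stage at full
                loss = l_focal
                for s in stage_losses[:-1]:
                    loss = loss + 0.5 * s
                loss = loss + stage_losses[-1]
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += float(loss.data)
            tot_f += float(l_focal.data)
            tot_c += float(sum(s.data for s in stage_losses))
        n = len(scenes)
        history["loss"].append(tot / n)
        history["focal"].append(tot_f / n)
        history["contour"].append(tot_c / n)
        if verbose:
            print(
                f"epoch {epoch + 1}/{cfg.epochs} loss {tot / n:.4f} "
                f"(focal {tot_f / n:.4f}, contour {tot_c / n:.4f})"
            )
    return model, history
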