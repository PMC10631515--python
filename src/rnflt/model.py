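"""The artifact-correction network: a small encoder-decoder with skip
connections, trained with a three-term composite loss.

The model inpaints sub-floor artifact regions of an RNFLT map from the
surrounding anatomy. Training pairs come from pseudo-artifact
transplantation (:mod:`rnflt.pseudo`); the input has two channels, the
(scaled) corrupted thickness grid and the artifact mask. The network
predicts a residual added to the corrupted grid, so the identity mapping
off the artifact region is trivially available.

The training objective is::

    L_overall = L_correct + w_contrast * L_contrast
                          + w_consistency * L_consistency

* ``L_correct`` — global L1 reconstruction error plus a mask-weighted L1
  term emphasizing the artifact region (the region where the evaluation
  metric lives).
* ``L_contrast`` — a normalized-temperature cross-entropy (NT-Xent) over
  cosine similarities of bottleneck embeddings, pulling each map toward
  its rigidly perturbed (shifted/rotated) version and away from the rest
  of the batch, so the learned features are stable under acquisition
  jitter.
* ``L_consistency`` — first-two-moment matching: the corrected map must
  keep the mean and standard deviation of the original map over the
  clean (non-disc, non-artifact) region.

At inference, artifacts are detected with the floor rule and only the
detected region is replaced by (floor-clipped) network output, so
measured pixels are never altered; correction is therefore idempotent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import _nn
from .errors import DegenerateBatchError, ShapeError
from .maps import ArtifactMask, DiscMask, RNFLTMap, compute_artifact_mask
from .pseudo import TrainingPair

#: Thickness values are scaled by this constant (um) before entering the
#: network, putting typical maps in the order-one range.
THICKNESS_SCALE_UM = 100.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class LossConfig:
    """Weights and knobs of the composite training objective."""

    w_contrast: float = 0.1
    w_consistency: float = 0.1
    lambda_mask: float = 5.0        # weight of the artifact-region term
    mask_norm: str = "l2"           # "l1" or "l2" artifact-region penalty
    temperature: float = 0.5        # NT-Xent temperature
    max_shift_px: int = 6           # augmentation bounds for the contrastive pair
    max_rotation_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_contrast < 0 or self.w_consistency < 0:
            raise ValueError("loss weights must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class TrainConfig:
    epochs: int = 8
    batch_size: int = 8
    learning_rate: float = 2e-3    # peak Adam step size
    cosine_decay: bool = False     # optionally anneal lr to ~0 over the run
    grad_clip: float = 0.0         # global-norm gradient clip (0 disables)
    ema_decay: float = 0.0         # Polyak weight averaging (0 disables)
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)


@dataclass
class TrainingHistory:
    """Per-epoch averages of the four loss terms on the training set."""

    l_correct: list[float] = field(default_factory=list)
    l_contrast: list[float] = field(default_factory=list)
    l_consistency: list[float] = field(default_factory=list)
    l_overall: list[float] = field(default_factory=list)

    def append(self, lc: float, lk: float, ls: float, lo: float) -> None:
        self.l_correct.append(lc)
        self.l_contrast.append(lk)
        self.l_consistency.append(ls)
        self.l_overall.append(lo)

    @property
    def n_epochs(self) -> int:
        return len(self.l_overall)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_array(
    x: np.ndarray,
    shift_px: tuple[int, int],
    rotation_deg: float,
) -> np.ndarray:
    """Rigid shift (integer pixels) and rotation with reflected boundary.

    Channel-first stacks (C, H, W) are transformed with one common
    motion. Zero shift and zero rotation return the input unchanged.
    """
    y = np.asarray(x, dtype=float)
    single = y.ndim == 2
    if single:
        y = y[None]
    if rotation_deg != 0.0:
        y = np.stack(
            [ndimage.rotate(ch, rotation_deg, reshape=False, order=1, mode="reflect")
             for ch in y]
        )
    dr, dc = int(shift_px[0]), int(shift_px[1])
    if (dr, dc) != (0, 0):
        h, w = y.shape[-2:]
        pr, pc = abs(dr), abs(dc)
        pad_width = ((0, 0), (pr, pr), (pc, pc)) if pr or pc else None
        if pad_width:
            yp = np.pad(y, pad_width, mode="reflect")
            y = yp[:, pr - dr : pr - dr + h, pc - dc : pc - dc + w]
    return y[0] if single else y


def augment(rnflt_map: RNFLTMap, config: LossConfig, seed: int) -> RNFLTMap:
    """Seeded random rigid perturbation of a map (the contrastive 'view')."""
    rng = np.random.default_rng(seed)
    shift = tuple(int(s) for s in rng.integers(-config.max_shift_px,
                                               config.max_shift_px + 1, 2))
    rot = (float(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
           if config.max_rotation_deg > 0 else 0.0)
    values = np.clip(augment_array(rnflt_map.values, shift, rot), 0.0, 500.0)
    return rnflt_map.copy_with(values)


# ---------------------------------------------------------------------------
# loss terms (each optionally returns its gradient)
# ---------------------------------------------------------------------------

def correction_loss(
    pred: np.ndarray,
    target: np.ndarray,
    pseudo_mask: np.ndarray,
    lambda_mask: float = 5.0,
    mask_norm: str = "l2",
    return_grad: bool = False,
):
    """Global L1 plus a mask-weighted penalty over the artifact region.

    ``mean|pred - target| + lambda_mask * mean_mask(rho(pred - target))``
    where ``rho`` is ``|.|`` (``mask_norm='l1'``) or ``(.)**2``
    (``'l2'``, the default: the squared penalty keeps gradients on the
    rare large inpainting errors and avoids the shrinkage-toward-median
    bias of a pure L1 objective). The mask term is 0 for an empty mask.
    """
    if pred.shape != target.shape:
        raise ShapeError("pred and target shapes differ")
    if mask_norm not in ("l1", "l2"):
        raise ValueError("mask_norm must be 'l1' or 'l2'")
    d = pred - target
    n_all = d.size
    loss = float(np.abs(d).mean())
    m = np.broadcast_to(np.asarray(pseudo_mask, dtype=float), d.shape)
    n_mask = m.sum()
    if n_mask > 0:
        rho = np.abs(d) if mask_norm == "l1" else d**2
        loss += lambda_mask * float((rho * m).sum() / n_mask)
    if not return_grad:
        return loss
    grad = np.sign(d) / n_all
    if n_mask > 0:
        drho = np.sign(d) if mask_norm == "l1" else 2.0 * d
        grad = grad + lambda_mask * drho * m / n_mask
    return loss, grad


def consistency_loss(
    pred: np.ndarray,
    input_map: np.ndarray,
    region: np.ndarray,
    return_grad: bool = False,
):
    """First-two-moment matching over the clean region.

    ``|mean(pred) - mean(input)| + |sd(pred) - sd(input)|`` computed over
    ``region`` (non-disc, non-artifact pixels), per sample, averaged over
    the batch. Accepts (H, W) or batched (N, 1, H, W) arrays.
    """
    p = np.asarray(pred, dtype=float)
    x = np.asarray(input_map, dtype=float)
    r = np.broadcast_to(np.asarray(region, dtype=bool), p.shape)
    if p.shape != x.shape:
        raise ShapeError("pred and input shapes differ")
    batched = p.ndim == 4
    if not batched:
        p, x, r = p[None, None], x[None, None], r[None, None]
    n = p.shape[0]
    grad = np.zeros_like(p) if return_grad else None
    total = 0.0
    for i in range(n):
        sel = r[i, 0]
        k = sel.sum()
        if k == 0:
            continue
        pv, xv = p[i, 0][sel], x[i, 0][sel]
        mu_p, mu_x = pv.mean(), xv.mean()
        sd_p, sd_x = pv.std(), xv.std()
        total += abs(mu_p - mu_x) + abs(sd_p - sd_x)
        if return_grad:
            g = np.sign(mu_p - mu_x) / k
            if sd_p > 1e-12:
                g = g + np.sign(sd_p - sd_x) * (pv - mu_p) / (k * sd_p)
            grad[i, 0][sel] = g / n
    loss = total / n
    if not return_grad:
        return float(loss)
    return float(loss), grad


def contrastive_loss(
    z1: np.ndarray,
    z2: np.ndarray,
    temperature: float = 0.5,
    return_grad: bool = False,
):
    """NT-Xent over L2-normalized embeddings.

    ``z1[i]`` and ``z2[i]`` are embeddings of a map and its perturbed
    view (the positive pair); all other batch members are negatives.
    Requires at least 2 pairs so that negatives exist.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape or z1.ndim != 2:
        raise ShapeError("z1 and z2 must be (B, D) with equal shapes")
    b = z1.shape[0]
    if b < 2:
        raise DegenerateBatchError("contrastive loss needs >= 2 pairs in the batch")
    z = np.vstack([z1, z2])                      # (2B, D)
    s = z @ z.T / temperature
    np.fill_diagonal(s, -np.inf)
    pos = np.concatenate([np.arange(b, 2 * b), np.arange(0, b)])
    smax = s.max(axis=1, keepdims=True)
    exps = np.exp(s - smax)
    denom = exps.sum(axis=1, keepdims=True)
    logprob = (s - smax) - np.log(denom)
    loss = float(-logprob[np.arange(2 * b), pos].mean())
    if not return_grad:
        return loss
    q = exps / denom                             # softmax with diag excluded
    g = q.copy()
    g[np.arange(2 * b), pos] -= 1.0
    g /= 2 * b
    np.fill_diagonal(g, 0.0)
    dz = (g + g.T) @ z / temperature
    return loss, (dz[:b], dz[b:])


def total_loss(
    l_correct: float,
    l_contrast: float,
    l_consistency: float,
    config: LossConfig,
) -> float:
    """Weighted sum of the three terms."""
    for v in (l_correct, l_contrast, l_consistency):
        if not np.isfinite(v):
            raise ValueError("loss terms must be finite")
    return (
        l_correct
        + config.w_contrast * l_contrast
        + config.w_consistency * l_consistency
    )


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    resolution: int = 64        # input grid edge; must be divisible by 8
    in_channels: int = 2        # thickness + artifact-mask channel
    coord_channels: bool = True  # append polar coordinate channels (r, sin, cos)
    harmonic_prior: bool = True  # initialize the in-mask thickness channel
                                 # with a polar-harmonic field fitted to the
                                 # clean pixels; the network refines it
    base_channels: int = 8      # width at the top level; doubles per level
    convs_per_level: int = 1    # stacked 3x3 convs in each block
    global_channels: int = 16   # pooled-bottleneck vector injected into the
                                # decoder at every level (0 disables); carries
                                # global state (overall bundle loss) to pixels
                                # far from any clean context
    embed_dim: int = 32         # contrastive embedding size
    seed: int = 0               # parameter-initialization seed

    @property
    def total_in_channels(self) -> int:
        return self.in_channels + (3 if self.coord_channels else 0)

    def __post_init__(self) -> None:
        if self.resolution % 8 != 0:
            raise ValueError("resolution must be divisible by 8 (three poolings)")
        if self.convs_per_level < 1:
            raise ValueError("convs_per_level must be >= 1")


class CorrectionNet:
    """Four-level convolutional encoder-decoder with skip connections.

    Encoder levels at full, 1/2, 1/4 resolution plus a 1/8-resolution
    bottleneck; the decoder mirrors them, concatenating the encoder
    activation of each level (UNet-style skips). A dense head on the
    globally pooled bottleneck yields the contrastive embedding. The
    final 1x1 convolution predicts a residual added to the input
    thickness channel.
    """

    def __init__(self, config: Optional[ModelConfig] = None):
        self.config = config or ModelConfig()
        c = self.config.base_channels
        ci = self.config.total_in_channels
        rng = np.random.default_rng(self.config.seed)
        p: dict[str, np.ndarray] = {}

        def block(name: str, f: int, cin: int) -> None:
            for k in range(self.config.convs_per_level):
                fin = cin if k == 0 else f
                p[f"{name}{k}_w"] = _nn.he_init(rng, (f, fin, 3, 3), fin * 9)
                p[f"{name}{k}_b"] = np.zeros(f)

        g = self.config.global_channels
        block("enc1", c, ci)
        block("enc2", 2 * c, c)
        block("enc3", 4 * c, 2 * c)
        block("bott", 8 * c, 4 * c)
        block("dec3", 4 * c, 12 * c + g)   # up(8c) ++ skip(4c) ++ global
        block("dec2", 2 * c, 6 * c + g)    # up(4c) ++ skip(2c) ++ global
        block("dec1", c, 3 * c + g)        # up(2c) ++ skip(c) ++ global
        if g > 0:
            p["glob_w"] = _nn.he_init(rng, (g, 8 * c), 8 * c)
            p["glob_b"] = np.zeros(g)
        p["out_w"] = rng.normal(0.0, 0.01, size=(1, c))
        p["out_b"] = np.zeros(1)
        p["emb_w"] = _nn.he_init(rng, (self.config.embed_dim, 8 * c), 8 * c)
        p["emb_b"] = np.zeros(self.config.embed_dim)
        self.params = p
        self.grads = {k: np.zeros_like(v) for k, v in p.items()}

    # -- forward -----------------------------------------------------------

    def _conv_relu(self, x, name, cache):
        """A block of stacked conv3x3 + ReLU layers."""
        for k in range(self.config.convs_per_level):
            y, cc = _nn.conv3_forward(
                x, self.params[f"{name}{k}_w"], self.params[f"{name}{k}_b"]
            )
            x, rc = _nn.relu_forward(y)
            cache[f"{name}{k}"] = (cc, rc)
        return x

    def forward(self, x: np.ndarray, encoder_only: bool = False):
        """Run the network.

        Returns ``(pred, embedding, cache)``; ``pred`` is None when
        ``encoder_only`` is set (the contrastive pass).
        """
        if x.ndim != 4 or x.shape[1] != self.config.total_in_channels:
            raise ShapeError(
                f"expected (N, {self.config.total_in_channels}, H, W) input"
            )
        cache: dict = {}
        a1 = self._conv_relu(x, "enc1", cache)
        p1, cache["pool1"] = _nn.avgpool2_forward(a1)
        a2 = self._conv_relu(p1, "enc2", cache)
        p2, cache["pool2"] = _nn.avgpool2_forward(a2)
        a3 = self._conv_relu(p2, "enc3", cache)
        p3, cache["pool3"] = _nn.avgpool2_forward(a3)
        bott = self._conv_relu(p3, "bott", cache)

        gap = bott.mean(axis=(2, 3))
        cache["gap_shape"] = bott.shape
        e, cache["emb_dense"] = _nn.dense_forward(
            gap, self.params["emb_w"], self.params["emb_b"]
        )
        emb, cache["emb_norm"] = _nn.l2norm_forward(e)

        if encoder_only:
            return None, emb, cache

        g = self.config.global_channels
        if g > 0:
            gv_pre, cache["glob_dense"] = _nn.dense_forward(
                gap, self.params["glob_w"], self.params["glob_b"]
            )
            gvec, cache["glob_relu"] = _nn.relu_forward(gv_pre)
        else:
            gvec = None

        def tile(v, h, w):
            return np.broadcast_to(v[:, :, None, None], (*v.shape, h, w))

        u3, cache["up3"] = _nn.upsample2_forward(bott)
        parts3 = [u3, a3] + ([tile(gvec, *u3.shape[2:])] if g else [])
        c3 = np.concatenate(parts3, axis=1)
        cache["cat3"] = (u3.shape[1], a3.shape[1])
        d3 = self._conv_relu(c3, "dec3", cache)
        u2, cache["up2"] = _nn.upsample2_forward(d3)
        parts2 = [u2, a2] + ([tile(gvec, *u2.shape[2:])] if g else [])
        c2 = np.concatenate(parts2, axis=1)
        cache["cat2"] = (u2.shape[1], a2.shape[1])
        d2 = self._conv_relu(c2, "dec2", cache)
        u1, cache["up1"] = _nn.upsample2_forward(d2)
        parts1 = [u1, a1] + ([tile(gvec, *u1.shape[2:])] if g else [])
        c1 = np.concatenate(parts1, axis=1)
        cache["cat1"] = (u1.shape[1], a1.shape[1])
        d1 = self._conv_relu(c1, "dec1", cache)
        raw, cache["out"] = _nn.conv1_forward(
            d1, self.params["out_w"], self.params["out_b"]
        )
        # blend through the mask channel: exact identity off the artifact,
        # a learned residual on the thickness channel (which holds the
        # harmonic-prior fill in-mask) on the artifact itself
        thick, mask_ch = x[:, :1], x[:, 1:2]
        pred = thick + raw * mask_ch
        cache["blend_mask"] = mask_ch
        return pred, emb, cache

    # -- backward ----------------------------------------------------------

    def zero_grads(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def _back_conv_relu(self, da, name, cache):
        for k in reversed(range(self.config.convs_per_level)):
            cc, rc = cache[f"{name}{k}"]
            dy = _nn.relu_backward(da, rc)
            da, dw, db = _nn.conv3_backward(dy, cc)
            self.grads[f"{name}{k}_w"] += dw
            self.grads[f"{name}{k}_b"] += db
        return da

    def backward(
        self,
        cache: dict,
        d_pred: Optional[np.ndarray] = None,
        d_emb: Optional[np.ndarray] = None,
    ) -> None:
        """Accumulate parameter gradients for one forward pass.

        ``d_pred`` feeds the decoder head (None for encoder-only passes);
        ``d_emb`` feeds the embedding head. Both may be given at once.
        """
        g = self.config.global_channels
        d_bott = 0.0
        d_gvec = 0.0
        if d_pred is not None:
            d_pred = d_pred * cache["blend_mask"]   # only in-mask output trains
            dx1, dw, db = _nn.conv1_backward(d_pred, cache["out"])
            self.grads["out_w"] += dw
            self.grads["out_b"] += db

            def split(dc, key):
                ku, ks = cache[key]
                du, ds = dc[:, :ku], dc[:, ku : ku + ks]
                dg = dc[:, ku + ks :].sum(axis=(2, 3)) if g else 0.0
                return du, ds, dg

            dc1 = self._back_conv_relu(dx1, "dec1", cache)
            du1, da1_skip, dg1 = split(dc1, "cat1")
            dd2 = _nn.upsample2_backward(du1, cache["up1"])
            dc2 = self._back_conv_relu(dd2, "dec2", cache)
            du2, da2_skip, dg2 = split(dc2, "cat2")
            dd3 = _nn.upsample2_backward(du2, cache["up2"])
            dc3 = self._back_conv_relu(dd3, "dec3", cache)
            du3, da3_skip, dg3 = split(dc3, "cat3")
            d_bott = _nn.upsample2_backward(du3, cache["up3"])
            d_gvec = dg1 + dg2 + dg3
        else:
            da1_skip = da2_skip = da3_skip = 0.0

        n, cch, h, w = cache["gap_shape"]
        if d_pred is not None and g > 0:
            dgv_pre = _nn.relu_backward(d_gvec, cache["glob_relu"])
            dgap_g, dw, db = _nn.dense_backward(dgv_pre, cache["glob_dense"])
            self.grads["glob_w"] += dw
            self.grads["glob_b"] += db
            d_bott = d_bott + dgap_g[:, :, None, None] / (h * w)

        if d_emb is not None:
            de = _nn.l2norm_backward(d_emb, cache["emb_norm"])
            dgap, dw, db = _nn.dense_backward(de, cache["emb_dense"])
            self.grads["emb_w"] += dw
            self.grads["emb_b"] += db
            d_bott = d_bott + dgap[:, :, None, None] / (h * w)

        dp3 = self._back_conv_relu(d_bott, "bott", cache)
        da3 = _nn.avgpool2_backward(dp3, cache["pool3"]) + da3_skip
        dp2 = self._back_conv_relu(da3, "enc3", cache)
        da2 = _nn.avgpool2_backward(dp2, cache["pool2"]) + da2_skip
        dp1 = self._back_conv_relu(da2, "enc2", cache)
        da1 = _nn.avgpool2_backward(dp1, cache["pool1"]) + da1_skip
        self._back_conv_relu(da1, "enc1", cache)
        # gradient w.r.t. the input itself is discarded (the residual path
        # contributes d_pred directly to the thickness channel, unused here)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: parameter arrays (.npz) + JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.params)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "CorrectionNet":
        path = Path(path)
        config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        net = cls(config)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            for k in net.params:
                net.params[k] = data[k]
        net.grads = {k: np.zeros_like(v) for k, v in net.params.items()}
        return net


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def polar_harmonic_fit(
    values: np.ndarray,
    clean: np.ndarray,
    pixel_pitch: float,
    center: Optional[tuple[float, float]] = None,
    n_harmonics: int = 4,
    n_radial: int = 6,
    ridge: float = 1e-3,
    fill_max_um: float = 300.0,
) -> np.ndarray:
    """Smooth normative-field fit: angular harmonics x radial bumps.

    Peripapillary thickness is, to first order, a smooth function of
    polar position around the disc (the classic double-hump pattern),
    so a low-order angular Fourier basis (harmonics 0..n) crossed with
    Gaussian radial bumps, fitted to the clean pixels by least squares,
    gives a strong model-based estimate of the field under an artifact.
    The correction network uses this fit as the in-mask initialization
    of its thickness channel and learns residual structure on top.

    The fit is ridge-regularized toward the clean-pixel mean
    (``ridge`` scales with the clean-pixel count): large artifact
    masks can leave basis directions nearly unconstrained, and an
    unregularized fit then extrapolates wildly. The returned field is
    additionally clipped to the physiological range
    ``[0, fill_max_um]``.

    Returns the fitted field over the whole grid.
    """
    h, w = values.shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    x_mm = (cc - center[1]) * pixel_pitch
    y_mm = (center[0] - rr) * pixel_pitch
    r = np.hypot(x_mm, y_mm)
    theta = np.arctan2(y_mm, x_mm)

    centers = np.linspace(0.4, 3.0, n_radial)
    sigma = centers[1] - centers[0]
    radial = [np.exp(-0.5 * ((r - c) / sigma) ** 2) for c in centers]
    radial.append(np.ones_like(r))                     # global offset basis
    angular = [np.ones_like(theta)]
    for k in range(1, n_harmonics + 1):
        angular.append(np.cos(k * theta))
        angular.append(np.sin(k * theta))
    design = np.stack(
        [(rb * ab).ravel() for rb in radial for ab in angular], axis=1
    )
    sel = np.asarray(clean, dtype=bool).ravel()
    if sel.sum() < design.shape[1]:
        # nearly fully masked map: fall back to the clean-pixel mean
        fill = float(values.ravel()[sel].mean()) if sel.any() else 0.0
        return np.full_like(values, fill)
    x_sel = design[sel]
    y_sel = values.ravel()[sel]
    y_mean = y_sel.mean()
    lam = ridge * sel.sum()
    gram = x_sel.T @ x_sel + lam * np.eye(design.shape[1])
    coef = np.linalg.solve(gram, x_sel.T @ (y_sel - y_mean))
    field = y_mean + (design @ coef).reshape(h, w)
    return np.clip(field, 0.0, fill_max_um)


def polar_coord_channels(
    shape: tuple[int, int],
    pixel_pitch: float,
    center: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Fixed conditioning channels: (r_mm/3, sin theta, cos theta).

    Peripapillary anatomy is organized in polar coordinates around the
    disc (radial ridge profile, angular bundle humps), so handing the
    network its polar position makes that structure directly learnable
    instead of having to be inferred from padding artifacts.
    """
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    x_mm = (cc - center[1]) * pixel_pitch
    y_mm = (center[0] - rr) * pixel_pitch
    r = np.hypot(x_mm, y_mm)
    theta = np.arctan2(y_mm, x_mm)
    return np.stack([r / 3.0, np.sin(theta), np.cos(theta)])


def _pair_tensors(pair: TrainingPair, config: "ModelConfig"):
    vals = pair.input_map.values
    mask = pair.pseudo_mask.mask
    region = ~pair.disc.mask & ~mask
    center = pair.disc.centroid()
    if config.harmonic_prior and mask.any():
        fit = polar_harmonic_fit(vals, region, pair.input_map.pixel_pitch, center)
        vals = vals.copy()
        vals[mask] = fit[mask]
    x = vals / THICKNESS_SCALE_UM
    t = pair.target_map.values / THICKNESS_SCALE_UM
    m = mask.astype(float)
    coords = (
        polar_coord_channels(pair.input_map.shape, pair.input_map.pixel_pitch,
                             center)
        if config.coord_channels
        else None
    )
    return x, t, m, region, coords


def train(
    model: CorrectionNet,
    pairs: Sequence[TrainingPair],
    config: Optional[TrainConfig] = None,
) -> tuple[CorrectionNet, TrainingHistory]:
    """Train the correction network on pseudo-artifact pairs.

    Mini-batch Adam on the composite loss; the contrastive term uses a
    perturbed copy of each batch member passed through the encoder only.
    Fully deterministic given the config seeds. Aborts with a diagnostic
    if any loss term becomes non-finite.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    config = config or TrainConfig()
    lc = config.loss
    res = model.config.resolution
    for p in pairs:
        if p.input_map.shape != (res, res):
            raise ShapeError(
                f"pair shape {p.input_map.shape} != model resolution {res}"
            )

    data = [_pair_tensors(p, model.config) for p in pairs]
    rng = np.random.default_rng(config.seed)
    aug_rng = np.random.default_rng(lc.seed + 1)
    opt = _nn.Adam(model.params, lr=config.learning_rate)
    history = TrainingHistory()
    steps_per_epoch = int(np.ceil(len(data) / config.batch_size))
    total_steps = max(1, config.epochs * steps_per_epoch)
    step = 0
    ema = (
        {k: v.copy() for k, v in model.params.items()}
        if config.ema_decay > 0
        else None
    )

    for _epoch in range(config.epochs):
        order = rng.permutation(len(data))
        sums = np.zeros(4)
        n_seen = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            nb = len(idx)
            xs = np.stack([data[i][0] for i in idx])
            ts = np.stack([data[i][1] for i in idx])[:, None]
            ms = np.stack([data[i][2] for i in idx])[:, None]
            rs = np.stack([data[i][3] for i in idx])[:, None]
            chans = [xs[:, None], ms]
            if model.config.coord_channels:
                chans.append(np.stack([data[i][4] for i in idx]))
            xb = np.concatenate(chans, axis=1)           # (N, C_in, H, W)

            pred, emb1, cache1 = model.forward(xb)
            l_corr, g_corr = correction_loss(
                pred, ts, ms, lc.lambda_mask, lc.mask_norm, return_grad=True
            )
            l_cons, g_cons = consistency_loss(pred, xs[:, None], rs, return_grad=True)

            if nb >= 2 and lc.w_contrast > 0:
                # perturb the map/mask channels; coordinate channels are a
                # fixed frame and stay put
                xa = xb.copy()
                for i in range(nb):
                    xa[i, :2] = augment_array(
                        xb[i, :2],
                        tuple(int(s) for s in aug_rng.integers(
                            -lc.max_shift_px, lc.max_shift_px + 1, 2)),
                        float(aug_rng.uniform(-lc.max_rotation_deg,
                                              lc.max_rotation_deg)),
                    )
                _, emb2, cache2 = model.forward(xa, encoder_only=True)
                l_contr, (dz1, dz2) = contrastive_loss(
                    emb1, emb2, lc.temperature, return_grad=True
                )
            else:
                l_contr, dz1, dz2, cache2 = 0.0, None, None, None

            l_total = total_loss(l_corr, l_contr, l_cons, lc)
            if not np.isfinite(l_total):
                raise RuntimeError(
                    f"training aborted: non-finite loss at epoch {_epoch} "
                    f"(correct={l_corr}, contrast={l_contr}, consistency={l_cons})"
                )

            d_pred = g_corr + lc.w_consistency * g_cons
            model.zero_grads()
            model.backward(
                cache1, d_pred,
                lc.w_contrast * dz1 if dz1 is not None else None,
            )
            if cache2 is not None:
                model.backward(cache2, None, lc.w_contrast * dz2)
            if config.grad_clip > 0:
                gnorm = np.sqrt(
                    sum(float((g**2).sum()) for g in model.grads.values())
                )
                if gnorm > config.grad_clip:
                    scale = config.grad_clip / gnorm
                    for g in model.grads.values():
                        g *= scale
            if config.cosine_decay:
                opt.lr = config.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * step / total_steps)
                )
            step += 1
            opt.step(model.grads)
            if ema is not None:
                d = config.ema_decay
                for k, v in model.params.items():
                    ema[k] = d * ema[k] + (1.0 - d) * v

            sums += nb * np.array([l_corr, l_contr, l_cons, l_total])
            n_seen += nb
        history.append(*(sums / n_seen))
    if ema is not None:
        model.params.update(ema)
    return model, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _resample(values: np.ndarray, out_shape: tuple[int, int], order: int) -> np.ndarray:
    zoom = (out_shape[0] / values.shape[0], out_shape[1] / values.shape[1])
    return ndimage.zoom(values, zoom, order=order, mode="nearest", grid_mode=True)


def correct(
    model: CorrectionNet,
    rnflt_map: RNFLTMap,
    disc: Optional[DiscMask] = None,
    floor_um: float = 50.0,
    blend: bool = True,
    tta: bool = True,
) -> tuple[RNFLTMap, ArtifactMask]:
    """Detect and inpaint floor-rule artifacts in a map.

    The detected artifact mask (sub-floor, non-disc pixels) is replaced
    by network output clipped to ``[floor_um, 500]``; all other pixels
    keep their measured values (set ``blend=False`` to return the full
    network regeneration instead). Maps whose grid differs from the
    model resolution are bilinearly resampled through the network and
    back. With no sub-floor pixels the map is returned unchanged.

    With ``tta`` (test-time augmentation), predictions are averaged over
    the identity and the two mirror flips of the input, exploiting the
    superior/inferior and nasal/temporal symmetry of peripapillary
    anatomy to reduce prediction variance.
    """
    if disc is None:
        disc = DiscMask.empty(rnflt_map.shape)
    detected = compute_artifact_mask(rnflt_map, disc, floor_um)
    if blend and not detected.mask.any():
        return rnflt_map.copy_with(rnflt_map.values), detected

    res = model.config.resolution
    vals = rnflt_map.values
    if model.config.harmonic_prior and detected.mask.any():
        clean = ~disc.mask & ~detected.mask
        fit = polar_harmonic_fit(vals, clean, rnflt_map.pixel_pitch,
                                 disc.centroid())
        vals = vals.copy()
        vals[detected.mask] = fit[detected.mask]
    x = vals / THICKNESS_SCALE_UM
    m = detected.mask.astype(float)
    native = rnflt_map.shape == (res, res)
    h, w = rnflt_map.shape
    if not native:
        x = _resample(x, (res, res), order=1)
        m = (_resample(m, (res, res), order=1) > 0.25).astype(float)
    chans = [x, m]
    if model.config.coord_channels:
        center = disc.centroid()
        pitch = rnflt_map.pixel_pitch
        if not native:
            center = (center[0] * res / h, center[1] * res / w)
            pitch = pitch * h / res
        chans.extend(polar_coord_channels((res, res), pitch, center))
    x_in = np.stack(chans)[None]
    flips: list[tuple[bool, bool]] = [(False, False)]
    if tta:
        flips += [(True, False), (False, True), (True, True)]
    preds = []
    for fud, flr in flips:
        xt = x_in
        if fud:
            xt = xt[:, :, ::-1, :]
        if flr:
            xt = xt[:, :, :, ::-1]
        p, _, _ = model.forward(np.ascontiguousarray(xt))
        if flr:
            p = p[:, :, :, ::-1]
        if fud:
            p = p[:, :, ::-1, :]
        preds.append(p)
    pred = np.mean(preds, axis=0)
    pred_um = pred[0, 0] * THICKNESS_SCALE_UM
    if not native:
        pred_um = _resample(pred_um, rnflt_map.shape, order=1)
    pred_um = np.clip(pred_um, floor_um, 500.0)

    if blend:
        out = rnflt_map.values.copy()
        out[detected.mask] = pred_um[detected.mask]
    else:
        out = pred_um
    return rnflt_map.copy_with(out), detected
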