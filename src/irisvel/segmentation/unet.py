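"""U-Net iris segmentation implemented directly in NumPy.

The encoder-decoder follows the classic U-Net layout: a contracting path
of repeated [3x3 conv -> batch norm -> ReLU] x 2 blocks with 2x2
max-pooling, an expanding path of nearest-neighbour upsampling (scale 2)
with skip-connection concatenation, and a final 1x1 convolution onto two
class maps (iris / non-iris).  Training minimizes pixel-wise cross entropy
of the class probabilities with the Adam optimizer (learning rate 1e-4,
first/second moment decay 0.55 / 0.99, batch size 8).

Everything — forward pass, backpropagation, the optimizer — is explicit
NumPy, in float64: runs are bit-reproducible given a seed, gradients are
unit-testable against finite differences, and the model stays small enough
to train smoke-scale instances on a laptop CPU.  The default width/depth
(4 stages, 64 base channels) matches the classic architecture; tests use
much smaller instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize


@dataclass
class UNetConfig:
    input_size: int = 224
    in_channels: int = 3
    out_classes: int = 2
    depth: int = 4
    base_channels: int = 64
    lr: float = 1e-4
    beta1: float = 0.55
    beta2: float = 0.99
    eps: float = 1e-8
    batch_size: int = 8
    epochs: int = 40
    augment_flip: bool = True

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2**self.depth}"
            )
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")


# ----------------------------------------------------------------------
# layers: each returns (output, cache); backward takes (grad_out, cache)

def _conv3x3(x, w, b):
    # x: (N, C, H, W); w: (K, C, 3, 3); same padding
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    out = np.einsum("nchwij,kcij->nkhw", win, w, optimize=True) + b[None, :, None, None]
    return out, (win, w, x.shape)


def _conv3x3_backward(g, cache):
    win, w, xshape = cache
    dw = np.einsum("nkhw,nchwij->kcij", g, win, optimize=True)
    db = g.sum(axis=(0, 2, 3))
    gp = np.pad(g, ((0, 0), (0, 0), (1, 1), (1, 1)))
    gwin = sliding_window_view(gp, (3, 3), axis=(2, 3))  # (N, K, H, W, 3, 3)
    wflip = w[:, :, ::-1, ::-1]
    dx = np.einsum("nkhwij,kcij->nchw", gwin, wflip, optimize=True)
    return dx, dw, db


def _conv1x1(x, w, b):
    out = np.einsum("nchw,kc->nkhw", x, w, optimize=True) + b[None, :, None, None]
    return out, (x, w)


def _conv1x1_backward(g, cache):
    x, w = cache
    dw = np.einsum("nkhw,nchw->kc", g, x, optimize=True)
    db = g.sum(axis=(0, 2, 3))
    dx = np.einsum("nkhw,kc->nchw", g, w, optimize=True)
    return dx, dw, db


def _batchnorm(x, gamma, beta, running, momentum=0.1, train=True, eps=1e-5):
    if train:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running[0] = (1 - momentum) * running[0] + momentum * mu
        running[1] = (1 - momentum) * running[1] + momentum * var
    else:
        mu, var = running
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out, (xhat, inv, gamma)


def _batchnorm_backward(g, cache):
    xhat, inv, gamma = cache
    n = g.shape[0] * g.shape[2] * g.shape[3]
    dgamma = (g * xhat).sum(axis=(0, 2, 3))
    dbeta = g.sum(axis=(0, 2, 3))
    gx = g * gamma[None, :, None, None]
    dx = (
        inv[None, :, None, None]
        / n
        * (
            n * gx
            - gx.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
    )
    return dx, dgamma, dbeta


def _relu(x):
    out = np.maximum(x, 0.0)
    return out, (x > 0)


def _maxpool2(x):
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _maxpool2_backward(g, cache):
    idx, xshape = cache
    n, c, h, w = xshape
    flat = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(flat, idx[..., None], g[..., None], axis=-1)
    dx = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(xshape)
    return dx


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(g):
    n, c, h, w = g.shape
    return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _softmax_ce(logits, labels):
    # logits: (N, K, H, W); labels: (N, H, W) int
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n, k, h, w = logits.shape
    onehot = np.eye(k)[labels].transpose(0, 3, 1, 2)
    eps = 1e-12
    loss = -(onehot * np.log(p + eps)).sum() / (n * h * w)
    grad = (p - onehot) / (n * h * w)
    return loss, grad


# ----------------------------------------------------------------------
class _ConvBlock:
    """[conv3x3 -> BN -> ReLU] x 2."""

    def __init__(self, c_in, c_out, rng):
        self.params = {}
        for i, (ci, co) in enumerate([(c_in, c_out), (c_out, c_out)]):
            std = np.sqrt(2.0 / (ci * 9))
            self.params[f"w{i}"] = rng.normal(0, std, (co, ci, 3, 3))
            self.params[f"b{i}"] = np.zeros(co)
            self.params[f"g{i}"] = np.ones(co)
            self.params[f"beta{i}"] = np.zeros(co)
        self.running = [
            [np.zeros(c_out), np.ones(c_out)],
            [np.zeros(c_out), np.ones(c_out)],
        ]

    def forward(self, x, train=True):
        caches = []
        for i in range(2):
            x, c1 = _conv3x3(x, self.params[f"w{i}"], self.params[f"b{i}"])
            x, c2 = _batchnorm(
                x, self.params[f"g{i}"], self.params[f"beta{i}"], self.running[i], train=train
            )
            x, c3 = _relu(x)
            caches.append((c1, c2, c3))
        return x, caches

    def backward(self, g, caches, grads):
        for i in (1, 0):
            c1, c2, c3 = caches[i]
            g = g * c3
            g, dgamma, dbeta = _batchnorm_backward(g, c2)
            grads[f"g{i}"] = dgamma
            grads[f"beta{i}"] = dbeta
            g, dw, db = _conv3x3_backward(g, c1)
            grads[f"w{i}"] = dw
            grads[f"b{i}"] = db
        return g


class UNetSegmenter:
    """Trained U-Net predictor (see module docstring for the architecture)."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, base = config.depth, config.base_channels
        self.enc = []
        c_in = config.in_channels
        for i in range(d):
            self.enc.append(_ConvBlock(c_in, base * 2**i, rng))
            c_in = base * 2**i
        self.bottleneck = _ConvBlock(c_in, base * 2**d, rng)
        self.dec = []
        for i in reversed(range(d)):
            c_up = base * 2 ** (i + 1)
            self.dec.append(_ConvBlock(c_up + base * 2**i, base * 2**i, rng))
        std = np.sqrt(2.0 / base)
        self.head_w = rng.normal(0, std, (config.out_classes, base))
        self.head_b = np.zeros(config.out_classes)
        self._fitted = False

    # -- parameter plumbing -------------------------------------------
    def _blocks(self):
        return self.enc + [self.bottleneck] + self.dec

    def parameters(self):
        out = {}
        for bi, blk in enumerate(self._blocks()):
            for k, v in blk.params.items():
                out[f"blk{bi}.{k}"] = v
        out["head.w"] = self.head_w
        out["head.b"] = self.head_b
        return out

    # -- forward / backward -------------------------------------------
    def forward(self, x, train=True):
        caches = {"enc": [], "dec": []}
        skips = []
        for blk in self.enc:
            x, c = blk.forward(x, train)
            skips.append(x)
            x, cp = _maxpool2(x)
            caches["enc"].append((c, cp))
        x, cb = self.bottleneck.forward(x, train)
        caches["bottleneck"] = cb
        for blk, skip in zip(self.dec, reversed(skips)):
            x = _upsample2(x)
            x = np.concatenate([x, skip], axis=1)
            caches["dec"].append(x.shape[1] - skip.shape[1])
            x, c = blk.forward(x, train)
            caches["dec"][-1] = (caches["dec"][-1], c)
        logits, ch = _conv1x1(x, self.head_w, self.head_b)
        caches["head"] = ch
        return logits, caches

    def backward(self, grad_logits, caches):
        grads = {}
        g, dw, db = _conv1x1_backward(grad_logits, caches["head"])
        grads["head.w"] = dw
        grads["head.b"] = db
        n_blocks = self._blocks()
        skip_grads = []
        for di, blk in reversed(list(enumerate(self.dec))):
            c_up, c = caches["dec"][di]
            bg = {}
            g = blk.backward(g, c, bg)
            bi = len(self.enc) + 1 + di
            for k, v in bg.items():
                grads[f"blk{bi}.{k}"] = v
            g_up, g_skip = g[:, :c_up], g[:, c_up:]
            skip_grads.append(g_skip)
            g = _upsample2_backward(g_up)
        bg = {}
        g = self.bottleneck.backward(g, caches["bottleneck"], bg)
        for k, v in bg.items():
            grads[f"blk{len(self.enc)}.{k}"] = v
        for ei, blk in reversed(list(enumerate(self.enc))):
            c, cp = caches["enc"][ei]
            g = _maxpool2_backward(g, cp)
            g = g + skip_grads[ei]
            bg = {}
            g = blk.backward(g, c, bg)
            for k, v in bg.items():
                grads[f"blk{ei}.{k}"] = v
        return grads

    # -- inference -----------------------------------------------------
    def predict_mask(self, frame: np.ndarray) -> np.ndarray:
        """Binary iris mask for one image, any resolution.

        The image is resized to the network input size, classified, and the
        argmax map resized back (nearest neighbour) to the frame resolution.
        """
        if not self._fitted:
            raise RuntimeError("model is untrained; call train_unet first")
        x = _prep_images(np.asarray(frame)[None], self.config)
        logits, _ = self.forward(x, train=False)
        mask_small = logits.argmax(axis=1)[0].astype(bool)
        return (
            resize(mask_small.astype(float), frame.shape[:2], order=0, anti_aliasing=False)
            > 0.5
        )


# ----------------------------------------------------------------------
def _prep_images(images: np.ndarray, config: UNetConfig) -> np.ndarray:
    """To (N, C, S, S) float64 in [0, 1] at the network input size."""
    imgs = np.asarray(images)
    out = np.empty(
        (len(imgs), config.in_channels, config.input_size, config.input_size)
    )
    for i, im in enumerate(imgs):
        im = np.asarray(im)
        if im.dtype == np.uint8:
            im = im.astype(np.float64) / 255.0
        if im.ndim == 2:
            im = np.repeat(im[..., None], config.in_channels, axis=-1)
        if im.shape[:2] != (config.input_size, config.input_size):
            im = resize(im, (config.input_size, config.input_size), anti_aliasing=True)
        out[i] = im.transpose(2, 0, 1)
    return out


def _prep_masks(masks: np.ndarray, config: UNetConfig) -> np.ndarray:
    out = np.empty((len(masks), config.input_size, config.input_size), dtype=int)
    for i, m in enumerate(masks):
        m = np.asarray(m).astype(float)
        if m.shape != (config.input_size, config.input_size):
            m = resize(m, (config.input_size, config.input_size), order=0, anti_aliasing=False)
        out[i] = (m > 0.5).astype(int)
    return out


def train_unet(
    images: np.ndarray,
    masks: np.ndarray,
    config: UNetConfig | None = None,
    seed: int = 0,
) -> tuple[UNetSegmenter, list[float]]:
    """Train the segmenter; returns the model and the per-epoch mean loss.

    ``images``: (N, H, W[, C]) uint8 or float; ``masks``: (N, H, W) binary.
    Horizontal-flip augmentation doubles the training set when enabled.
    Deterministic given ``seed`` (weight init, shuffling).
    """
    config = config or UNetConfig()
    images = np.asarray(images)
    masks = np.asarray(masks)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(masks):
        raise ValueError("images and masks must have equal length")
    for im, m in zip(images, masks):
        if np.asarray(im).shape[:2] != np.asarray(m).shape[:2]:
            raise ValueError("image/mask spatial shape mismatch")

    x = _prep_images(images, config)
    y = _prep_masks(masks, config)
    if config.augment_flip:
        x = np.concatenate([x, x[:, :, :, ::-1]])
        y = np.concatenate([y, y[:, :, ::-1]])

    model = UNetSegmenter(config, seed=seed)
    params = model.parameters()
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    rng = np.random.default_rng(seed + 1)
    step = 0
    losses: list[float] = []
    n = len(x)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits, caches = model.forward(x[idx], train=True)
            loss, grad = _softmax_ce(logits, y[idx])
            grads = model.backward(grad, caches)
            step += 1
            for k, p in params.items():
                g = grads[k]
                m_state[k] = config.beta1 * m_state[k] + (1 - config.beta1) * g
                v_state[k] = config.beta2 * v_state[k] + (1 - config.beta2) * g * g
                mhat = m_state[k] / (1 - config.beta1**step)
                vhat = v_state[k] / (1 - config.beta2**step)
                p -= config.lr * mhat / (np.sqrt(vhat) + config.eps)
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
    model._fitted = True
    return model, losses
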