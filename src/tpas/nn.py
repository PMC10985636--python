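"""Miniature convolutional networks for the two-stage detection workflow.

The study-scale backbone this emulates is a self-configuring 3D U-Net; here
the backbone is deliberately a small two-level 2D U-Net because the object
under test is the *training strategy*, not the architecture. The interface
(multi-channel voxel grid in, same-shape voxel map out) is preserved.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, avgpool2, concat, conv2d, upsample2

__all__ = ["UNet2D", "Adam", "softmax_ce", "soft_dice_multiclass",
           "bce_logits", "soft_dice_binary", "seg_loss"]


def _he_init(rng: np.random.Generator, f: int, c: int, k: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (c * k * k)), size=(f, c, k, k))


@dataclass
class UNetConfig:
    in_channels: int = 1
    out_channels: int = 1
    width: int = 8
    kernel: int = 3
    seed: int = 0


class UNet2D:
    """Two-level encoder/decoder with a skip connection.

    enc(w) -> pool -> bottleneck(2w) -> up -> cat -> dec(w) -> 1x1 head.
    Output is a logit map with the same spatial shape as the input.
    """

    def __init__(self, in_channels: int, out_channels: int, width: int = 8,
                 kernel: int = 3, seed: int = 0):
        self.config = UNetConfig(in_channels, out_channels, width, kernel, seed)
        rng = np.random.default_rng(seed)
        w, k = width, kernel
        self.params: dict[str, Tensor] = {}

        def add_conv(name: str, f: int, c: int, ksz: int) -> None:
            self.params[name + ".w"] = Tensor(_he_init(rng, f, c, ksz),
                                              requires_grad=True)
            self.params[name + ".b"] = Tensor(np.zeros(f), requires_grad=True)

        add_conv("enc1", w, in_channels, k)
        add_conv("enc2", w, w, k)
        add_conv("bot1", 2 * w, w, k)
        add_conv("bot2", 2 * w, 2 * w, k)
        add_conv("dec1", w, 3 * w, k)
        add_conv("dec2", w, w, k)
        add_conv("head", out_channels, w, 1)

    def _conv(self, name: str, x: Tensor) -> Tensor:
        return conv2d(x, self.params[name + ".w"], self.params[name + ".b"])

    def forward(self, x: Tensor) -> Tensor:
        e = self._conv("enc1", x).relu()
        e = self._conv("enc2", e).relu()
        b = avgpool2(e)
        b = self._conv("bot1", b).relu()
        b = self._conv("bot2", b).relu()
        u = concat([upsample2(b), e], axis=1)
        d = self._conv("dec1", u).relu()
        d = self._conv("dec2", d).relu()
        return self._conv("head", d)

    __call__ = forward

    # ----------------------------------------------------------- persistence
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            a = np.asarray(arrays[k], dtype=np.float64)
            if a.shape != t.data.shape:
                raise ValueError(f"state shape mismatch for {k}")
            t.data = a.copy()

    def config_json(self) -> str:
        return json.dumps(asdict(self.config), sort_keys=True)

    @classmethod
    def from_config_json(cls, s: str) -> "UNet2D":
        cfg = json.loads(s)
        return cls(cfg["in_channels"], cfg["out_channels"], cfg["width"],
                   cfg["kernel"], cfg["seed"])

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()


class Adam:
    """Adam with fixed hyper-parameters; fully deterministic."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------- losses
def softmax_ce(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean voxel-wise cross-entropy. ``logits`` (N,K,H,W), integer target
    (N,H,W)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    n, k, h, w = z.shape
    idx = (np.arange(n)[:, None, None], target,
           np.arange(h)[None, :, None], np.arange(w)[None, None, :])
    picked = z[np.arange(n)[:, None, None], target,
               np.arange(h)[None, :, None], np.arange(w)[None, None, :]]
    loss_val = float((lse[:, 0] - picked).mean())
    out = Tensor(loss_val, logits.requires_grad)
    out._parents = (logits,)
    softmax = np.exp(z - lse)

    def _bwd():
        if logits.requires_grad:
            g = softmax.copy()
            onehot = np.zeros_like(g)
            onehot[np.arange(n)[:, None, None], target,
                   np.arange(h)[None, :, None], np.arange(w)[None, None, :]] = 1
            logits._accumulate(out.grad * (g - onehot) / (n * h * w))
    out._backward = _bwd
    return out


def _softmax_tensor(logits: Tensor) -> Tensor:
    zmax = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    e = (logits - zmax).exp()
    return e / e.sum(axis=1, keepdims=True)


def soft_dice_multiclass(logits: Tensor, target: np.ndarray,
                         smooth: float = 1.0) -> Tensor:
    """1 - mean soft Dice over foreground classes (softmax probabilities)."""
    k = logits.shape[1]
    probs = _softmax_tensor(logits)
    terms = []
    for cls in range(1, k):
        t = (target == cls).astype(np.float64)
        # select the class channel via mask multiply (keeps the graph simple)
        mask = np.zeros((1, k, 1, 1))
        mask[0, cls, 0, 0] = 1.0
        pc = (probs * Tensor(mask)).sum(axis=1)          # (N,H,W)
        inter = (pc * Tensor(t)).sum()
        denom = pc.sum() + float(t.sum())
        terms.append(1.0 - (2.0 * inter + smooth) / (denom + smooth))
    total = terms[0]
    for t_ in terms[1:]:
        total = total + t_
    return total * (1.0 / len(terms))


def bce_logits(logits: Tensor, target: np.ndarray,
               pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy with logits; numerically stable.

    ``pos_weight`` rescales the positive-voxel terms — the usual remedy for
    the extreme foreground/background imbalance of lesion maps.
    """
    z = logits.data
    t = np.asarray(target, dtype=np.float64)
    w = 1.0 + (pos_weight - 1.0) * t
    elem = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    val = float((w * elem).mean())
    out = Tensor(val, logits.requires_grad)
    out._parents = (logits,)
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def _bwd():
        if logits.requires_grad:
            logits._accumulate(out.grad * w * (sig - t) / z.size)
    out._backward = _bwd
    return out


def soft_dice_binary(logits: Tensor, target: np.ndarray,
                     smooth: float = 1.0) -> Tensor:
    p = logits.sigmoid()
    t = np.asarray(target, dtype=np.float64)
    inter = (p * Tensor(t)).sum()
    denom = p.sum() + float(t.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def seg_loss(logits: Tensor, target: np.ndarray, *, binary: bool,
             w_overlap: float = 1.0, w_ce: float = 1.0,
             pos_weight: float = 1.0) -> Tensor:
    """Weighted overlap + cross-entropy compound loss used by both stages."""
    if binary:
        loss = w_ce * bce_logits(logits, target, pos_weight)
        if w_overlap > 0:
            loss = loss + w_overlap * soft_dice_binary(logits, target)
    else:
        loss = w_ce * softmax_ce(logits, target)
        if w_overlap > 0:
            loss = loss + w_overlap * soft_dice_multiclass(logits, target)
    return loss
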