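"""Rectal-artifact-pattern adversarial noise.

The attack jointly optimizes three terms over a bounded per-channel noise
field delta added to the T2W/ADC/DWI planes of a case:

* a *style* term — squared distance between Gram (channel-correlation)
  matrices of a frozen feature extractor, pulling the perturbed image's
  texture statistics towards a severe-artifact exemplar;
* a *content* term — deep-feature consistency with the original image, so
  lesion structure is preserved;
* an *adversarial* term — the task model's own training loss, ascended so
  the noise degrades the prediction.

The composite objective  J(delta) = ls*style + lc*content - la*task  is
minimized by signed-gradient steps with per-step projection onto
|delta| <= eps (fraction of the channel intensity range) and composition
clipping to the original image's per-channel min/max. The returned noise is
the best-objective iterate whose style distance does not exceed the
zero-noise baseline, so the perturbation never moves *away* from the
artifact style; delta = 0 is always admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .autodiff import Tensor, avgpool2, concat, conv2d
from .model import TaskModel, cspca_target, normalize_channel
from .nn import _he_init, seg_loss
from .phantom import CHANNELS, MultiModalVolume, PhantomCase, body_mask

__all__ = ["FeatureExtractor", "StyleSample", "NoiseConfig",
           "AdversarialSample", "style_distance", "content_distance",
           "adversarial_task_loss", "generate_noise", "clip_to_bounds",
           "attack_cohort", "style_sample_from_case", "gram_matrix"]

# extractor/image plane order (the three image contrasts, no zone masks)
IMG_PLANES = ("t2w", "adc", "dwi")


class FeatureExtractor:
    """Frozen convolutional feature stack with designated style layers
    (intermediate blocks, texture statistics) and content layers (deepest
    block, semantic structure).

    Weights are deterministic given ``seed`` and are never trained; random
    shallow convolutional features are a standard basis for Gram-matrix
    texture statistics at this scale, and the extractor is pluggable.
    """

    STYLE_LAYERS = ("block1", "block2")
    CONTENT_LAYERS = ("block3",)

    def __init__(self, in_channels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.weights = {
            "conv1": Tensor(_he_init(rng, 8, in_channels, 3)),
            "conv2": Tensor(_he_init(rng, 16, 8, 3)),
            "conv3a": Tensor(_he_init(rng, 16, 16, 3)),
            "conv3b": Tensor(_he_init(rng, 16, 16, 3)),
        }
        assert not set(self.STYLE_LAYERS) & set(self.CONTENT_LAYERS)

    def features(self, x: Tensor) -> dict[str, Tensor]:
        """``x``: (N, 3, H, W) normalized image planes -> named activations."""
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"extractor expects {self.in_channels} channels, "
                f"got {x.shape[1]}")
        b1 = conv2d(x, self.weights["conv1"]).relu()
        b2 = conv2d(avgpool2(b1), self.weights["conv2"]).relu()
        h = conv2d(avgpool2(b2), self.weights["conv3a"]).relu()
        b3 = conv2d(h, self.weights["conv3b"]).relu()
        return {"block1": b1, "block2": b2, "block3": b3}


@dataclass
class StyleSample:
    """Severe-artifact exemplar: normalized image planes (N, 3, H, W)."""
    planes: np.ndarray
    provenance: str

    def validate(self) -> None:
        if self.planes.size == 0:
            raise ValueError("empty style sample")
        if self.planes.ndim != 4 or self.planes.shape[1] != len(IMG_PLANES):
            raise ValueError("style sample must be (N, 3, H, W)")


def style_sample_from_case(case: PhantomCase) -> StyleSample:
    """Build a style exemplar from a (typically grade-4) artifact case."""
    planes = np.stack(
        [normalize_channel(case.volume.channel(n), case.volume.ranges[n])
         for n in IMG_PLANES], axis=1)
    return StyleSample(planes, provenance=case.case_id)


@dataclass
class NoiseConfig:
    epsilon: float = 0.02        # per-channel bound, fraction of range
    iters: int = 20
    step: float = 0.004          # signed-gradient step size, same units
    lambda_style: float = 200.0
    lambda_content: float = 100.0
    lambda_adv: float = 1.0
    restrict_to_body: bool = True
    w_overlap: float = 1.0       # task-loss weights (match training)
    w_ce: float = 1.0
    pos_weight: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.iters < 1:
            raise ValueError("iters must be >= 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if min(self.lambda_style, self.lambda_content, self.lambda_adv) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class AdversarialSample:
    """A bounded artifact-styled perturbation of one case."""
    case: PhantomCase
    noise: dict[str, np.ndarray]         # raw intensity units, per channel
    trajectory: pd.DataFrame             # per-iteration loss components
    epsilon: float

    def attacked_case(self, case_id: str | None = None) -> PhantomCase:
        """Compose base + noise with clipping to the base per-channel
        min/max; the result is a PhantomCase whose metadata mirrors the
        base (the perturbation is invisible by design, grade stays 1)."""
        chans = {}
        for name in CHANNELS:
            base = self.case.volume.channel(name)
            chans[name] = clip_to_bounds(base, base + self.noise[name])
        vol = MultiModalVolume(chans["t2w"], chans["dwi"], chans["adc"],
                               self.case.volume.spacing,
                               dict(self.case.volume.ranges))
        return replace(self.case, volume=vol,
                       case_id=case_id or self.case.case_id + "*")

    def validate(self) -> None:
        for name in CHANNELS:
            lo, hi = self.case.volume.ranges[name]
            if np.abs(self.noise[name]).max() > self.epsilon * (hi - lo) + 1e-9:
                raise ValueError(f"noise bound violated on {name}")
        atk = self.attacked_case()
        for name in CHANNELS:
            base = self.case.volume.channel(name)
            a = atk.volume.channel(name)
            if a.min() < base.min() - 1e-12 or a.max() > base.max() + 1e-12:
                raise ValueError(f"composition bound violated on {name}")


# ------------------------------------------------------------------- losses
def gram_matrix(feat: Tensor) -> Tensor:
    """Normalized channel-correlation matrix, averaged over the batch.

    ``feat``: (N, C, H, W) -> (C, C); G = F F^T / (H*W), mean over N.
    Position information is discarded — this is the texture statistic.
    """
    n, c, h, w = feat.shape
    f = feat.reshape(n, c, h * w)
    g = f @ f.transpose((0, 2, 1))              # (N, C, C)
    return g.sum(axis=0) * (1.0 / (n * h * w))


def style_distance(x_adv: Tensor | np.ndarray, style_sample: StyleSample,
                   extractor: FeatureExtractor) -> Tensor:
    """Sum over style layers of squared Gram-matrix distance."""
    if not extractor.STYLE_LAYERS:
        raise ValueError("extractor has no style layers")
    xa = x_adv if isinstance(x_adv, Tensor) else Tensor(x_adv)
    fa = extractor.features(xa)
    fs = extractor.features(Tensor(style_sample.planes))
    total = None
    for layer in extractor.STYLE_LAYERS:
        d = gram_matrix(fa[layer]) - gram_matrix(fs[layer]).detach()
        term = (d * d).sum()
        total = term if total is None else total + term
    return total


def content_distance(x_adv: Tensor | np.ndarray, x_orig: np.ndarray,
                     extractor: FeatureExtractor) -> Tensor:
    """Sum over content layers of mean squared feature difference."""
    if not extractor.CONTENT_LAYERS:
        raise ValueError("extractor has no content layers")
    xa = x_adv if isinstance(x_adv, Tensor) else Tensor(x_adv)
    if tuple(xa.shape) != tuple(np.asarray(x_orig).shape):
        raise ValueError("content_distance requires matching shapes")
    fa = extractor.features(xa)
    fo = extractor.features(Tensor(x_orig))
    total = None
    for layer in extractor.CONTENT_LAYERS:
        d = fa[layer] - fo[layer].detach()
        term = (d * d).mean()
        total = term if total is None else total + term
    return total


def adversarial_task_loss(model: TaskModel, x5: Tensor | np.ndarray,
                          target: np.ndarray, w_overlap: float = 1.0,
                          w_ce: float = 1.0,
                          pos_weight: float = 1.0) -> Tensor:
    """The task model's own training loss at (x, truth) — the quantity the
    attack ascends."""
    x = x5 if isinstance(x5, Tensor) else Tensor(x5)
    if x.shape[1] != 5:
        raise ValueError("detector input must have 5 channels")
    return seg_loss(model.net(x), target, binary=True,
                    w_overlap=w_overlap, w_ce=w_ce, pos_weight=pos_weight)


def clip_to_bounds(x_orig: np.ndarray, x_plus_delta: np.ndarray) -> np.ndarray:
    """Clamp the composed image to the original's min/max; idempotent."""
    return np.clip(x_plus_delta, x_orig.min(), x_orig.max())


# -------------------------------------------------------------------- attack
def _zone_masks_from_norm_t2w(gland: TaskModel, t2w_norm: np.ndarray):
    logits = gland._forward_batch(t2w_norm[:, None])
    lab = logits.argmax(axis=1)
    return lab == 1, lab == 2


def generate_noise(case: PhantomCase, model: TaskModel,
                   extractor: FeatureExtractor, style_sample: StyleSample,
                   config: NoiseConfig) -> AdversarialSample:
    """Optimize a bounded artifact-styled perturbation against ``model``.

    Signed-gradient descent on the composite objective with per-step
    projection; fully deterministic. The zone masks feeding the detector are
    re-predicted from the perturbed T2W each iteration (no gradient is taken
    through the discrete mask).
    """
    config.validate()
    style_sample.validate()
    if model.kind != "detector":
        raise ValueError("generate_noise expects a lesion-detector model")
    ranges = case.volume.ranges
    x0 = {n: normalize_channel(case.volume.channel(n), ranges[n])
          for n in IMG_PLANES}
    bounds = {n: (x0[n].min(), x0[n].max()) for n in IMG_PLANES}
    support = body_mask(case).astype(np.float64) if config.restrict_to_body \
        else np.ones(case.volume.shape)
    target = cspca_target(case)[:, None]
    x_img0 = np.stack([x0[n] for n in IMG_PLANES], axis=1)   # (nz,3,H,W)
    eps, alpha = config.epsilon, config.step
    delta = {n: np.zeros_like(x0[n]) for n in IMG_PLANES}

    rows = []
    best = {"J": np.inf, "delta": None}
    style0 = None
    for it in range(config.iters + 1):           # iterate 0 is delta = 0
        dts = {n: Tensor(delta[n], requires_grad=True) for n in IMG_PLANES}
        comp = {n: (Tensor(x0[n]) + dts[n] * Tensor(support))
                .clip(*bounds[n]) for n in IMG_PLANES}
        # zone masks from the perturbed T2W, held fixed within the iteration
        pz, tz = _zone_masks_from_norm_t2w(model.gland,
                                           np.clip(x0["t2w"] + delta["t2w"]
                                                   * support, *bounds["t2w"]))
        planes = [comp["t2w"].reshape(comp["t2w"].shape[0], 1,
                                      *comp["t2w"].shape[1:]),
                  comp["adc"].reshape(comp["adc"].shape[0], 1,
                                      *comp["adc"].shape[1:]),
                  comp["dwi"].reshape(comp["dwi"].shape[0], 1,
                                      *comp["dwi"].shape[1:]),
                  Tensor(tz.astype(np.float64)[:, None]),
                  Tensor(pz.astype(np.float64)[:, None])]
        x5 = concat(planes, axis=1)
        x_img = concat(planes[:3], axis=1)
        s = style_distance(x_img, style_sample, extractor)
        c = content_distance(x_img, x_img0, extractor)
        t = adversarial_task_loss(model, x5, target, config.w_overlap,
                                  config.w_ce, config.pos_weight)
        J = config.lambda_style * s + config.lambda_content * c \
            - config.lambda_adv * t
        rows.append({"iteration": it, "style": s.item(), "content": c.item(),
                     "task": t.item(), "composite": J.item()})
        if style0 is None:
            style0 = s.item()
        if s.item() <= style0 + 1e-12 and J.item() < best["J"]:
            best = {"J": J.item(),
                    "delta": {n: delta[n].copy() for n in IMG_PLANES}}
        if it == config.iters:
            break
        J.backward()
        for n in IMG_PLANES:
            g = dts[n].grad
            if g is None or not np.all(np.isfinite(g)):
                raise RuntimeError(
                    f"non-finite gradient for {n} at iteration {it}")
            delta[n] = np.clip(delta[n] - alpha * np.sign(g), -eps, eps) \
                * support

    noise_raw = {}
    for n in IMG_PLANES:
        lo, hi = ranges[n]
        noise_raw[n] = best["delta"][n] * (hi - lo)
    sample = AdversarialSample(case, noise_raw, pd.DataFrame(rows), eps)
    sample.validate()
    return sample


def attack_cohort(cases: list[PhantomCase], model: TaskModel,
                  extractor: FeatureExtractor, style_sample: StyleSample,
                  config: NoiseConfig
                  ) -> tuple[list[AdversarialSample], pd.DataFrame, list]:
    """Attack every case; per-case failures are logged, not fatal.

    Returns (samples, manifest, errors); the manifest links each clean id to
    its attacked counterpart — the synthetic analogue of turning a clean
    external testing set into its imperceptibly perturbed twin.
    """
    samples, rows, errors = [], [], []
    for case in cases:
        try:
            s = generate_noise(case, model, extractor, style_sample, config)
        except Exception as e:   # noqa: BLE001 - cohort robustness contract
            errors.append((case.case_id, repr(e)))
            continue
        samples.append(s)
        rows.append({"case_id": case.case_id,
                     "attacked_id": case.case_id + "*",
                     "attacked": True})
    return samples, pd.DataFrame(rows), errors
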