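"""Targeted adversarial training with proprietary adversarial samples.

The defended detector is trained on the clean stream plus artifact-styled
adversarial samples generated *against the current model*; sample
generation and parameter optimization alternate: after a warmup, the
adversarial pool is regenerated at the end of every complete refresh block
and appended to each subsequent epoch's training stream at a fixed mixing
fraction. The matched control is the identical pipeline with the mixing
fraction at zero — by construction it consumes the same clean stream under
the same seed, so the two training runs differ only in the adversarial
additions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .advnoise import (FeatureExtractor, NoiseConfig, StyleSample,
                       generate_noise)
from .autodiff import Tensor
from .model import (DETECTOR_IN_CHANNELS, TaskModel, TrainConfig,
                    _detector_sample)
from .nn import Adam, UNet2D, seg_loss
from .phantom import PhantomCase

__all__ = ["TpasSchedule", "tpas_train", "control_train"]


@dataclass
class TpasSchedule:
    refresh_interval: int = 4        # epochs between pool regenerations
    mix_fraction: float = 0.5        # adversarial share of the clean stream
    warmup: int = 4                  # epochs before the first regeneration
    noise: NoiseConfig | None = None

    def validate(self) -> None:
        if not 0.0 <= self.mix_fraction <= 1.0:
            raise ValueError("mix_fraction must be in [0, 1]")
        if self.refresh_interval < 1:
            raise ValueError("refresh_interval must be >= 1")
        if self.warmup < 0:
            raise ValueError("warmup must be >= 0")
        if self.mix_fraction > 0 and self.noise is None:
            raise ValueError("mix_fraction > 0 requires a noise config")


def _stream_hash(order: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(order, dtype=np.int64)
                        .tobytes()).hexdigest()[:16]


def _regen_epochs(epochs: int, warmup: int, r: int) -> set[int]:
    """Pool regenerations happen at the end of each complete refresh block
    after warmup: epochs warmup+r-1, warmup+2r-1, ... — exactly
    floor((epochs - warmup) / r) events."""
    return {warmup + m * r - 1 for m in range(1, (epochs - warmup) // r + 1)}


def tpas_train(cases: list[PhantomCase], config: TrainConfig,
               schedule: TpasSchedule, gland_model: TaskModel,
               extractor: FeatureExtractor | None = None,
               style_sample: StyleSample | None = None
               ) -> tuple[TaskModel, pd.DataFrame]:
    """Train the defended lesion detector.

    ``extractor`` and ``style_sample`` are required whenever
    ``schedule.mix_fraction > 0``. Deterministic under ``config.seed``: the
    clean-stream shuffling, the adversarial-subset selection and the noise
    optimization all derive from it through separate generators, so the
    clean stream is identical between the control and defended runs.
    """
    config.validate()
    schedule.validate()
    if not cases:
        raise ValueError("empty training set")
    use_adv = schedule.mix_fraction > 0
    if use_adv and (extractor is None or style_sample is None):
        raise ValueError("adversarial training requires an extractor "
                         "and a style sample")
    labels = {c.patient_label for c in cases}
    if use_adv and len(labels) < 2:
        raise ValueError("training set must contain csPCa and non-csPCa cases")

    ranges = dict(cases[0].volume.ranges)
    clean = [_detector_sample(c, ranges, gland_model,
                              config.use_oracle_masks) for c in cases]
    net = UNet2D(DETECTOR_IN_CHANNELS, 1, width=config.width,
                 seed=config.seed + 1)
    opt = Adam(net.params, lr=config.lr)
    rng_data = np.random.default_rng(config.seed)
    rng_select = np.random.default_rng(config.seed + 7919)
    n = len(cases)
    n_adv_target = int(round(schedule.mix_fraction * n))
    regen_at = _regen_epochs(config.epochs, schedule.warmup,
                             schedule.refresh_interval) if use_adv else set()
    adv_pool: list[tuple[np.ndarray, np.ndarray]] = []
    rows = []
    for epoch in range(config.epochs):
        order = rng_data.permutation(n)
        stream = [clean[i] for i in order] + adv_pool
        losses = []
        for start in range(0, len(stream), config.batch_size):
            batch = stream[start:start + config.batch_size]
            x = np.concatenate([s[0] for s in batch], axis=0)
            t = np.concatenate([s[1] for s in batch], axis=0)
            net.zero_grad()
            loss = seg_loss(net(Tensor(x)), t, binary=True,
                            w_overlap=config.w_overlap, w_ce=config.w_ce,
                            pos_weight=config.pos_weight)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        regenerated = epoch in regen_at and n_adv_target > 0
        if regenerated:
            current = TaskModel("detector", net, ranges, config.seed,
                                config.use_oracle_masks, gland=gland_model)
            picks = rng_select.choice(n, size=n_adv_target, replace=False)
            adv_pool = []
            for i in sorted(picks):
                s = generate_noise(cases[i], current, extractor,
                                   style_sample, schedule.noise)
                atk = s.attacked_case()
                adv_pool.append(_detector_sample(
                    atk, ranges, gland_model, config.use_oracle_masks))
        rows.append({"epoch": epoch, "loss": float(np.mean(losses)),
                     "n_adv": len(adv_pool), "regenerated": bool(regenerated),
                     "clean_stream_hash": _stream_hash(order)})
    model = TaskModel("detector", net, ranges, config.seed,
                      config.use_oracle_masks, gland=gland_model)
    return model, pd.DataFrame(rows)


def control_train(cases: list[PhantomCase], config: TrainConfig,
                  gland_model: TaskModel) -> tuple[TaskModel, pd.DataFrame]:
    """Matched undefended training: the degenerate schedule with no
    adversarial additions; bit-identical to ``tpas_train`` at
    ``mix_fraction = 0`` under the same seed."""
    schedule = TpasSchedule(mix_fraction=0.0, noise=None)
    return tpas_train(cases, config, schedule, gland_model)
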