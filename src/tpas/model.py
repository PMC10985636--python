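"""Two-stage csPCa detection workflow at desk scale.

Stage 1 segments the prostate zones (background / peripheral / transition)
from the T2-weighted channel. Stage 2 consumes five aligned input planes —
T2W, ADC, DWI and the two *predicted* zone masks — and emits a voxel-wise
lesion confidence map in [0, 1], from which lesion candidates and the
patient-level csPCa score are derived downstream.

Models are small 2D U-Nets applied slice-wise along z; training is plain
mini-batch Adam on a compound overlap + cross-entropy loss and is bit-
deterministic under the training seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .nn import Adam, UNet2D, seg_loss
from .phantom import CHANNELS, PhantomCase

__all__ = ["TrainConfig", "TaskModel", "train_gland_segmenter",
           "train_lesion_detector", "predict_confidence", "crossval_select",
           "predict_zone_masks", "detector_input", "normalize_channel"]

DETECTOR_IN_CHANNELS = 5


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    lr: float = 2e-3
    w_overlap: float = 1.0          # soft-Dice term weight
    w_ce: float = 1.0               # cross-entropy term weight
    folds: int = 5
    seed: int = 0
    width: int = 8
    pos_weight: float = 10.0        # positive-voxel BCE weight (stage 2)
    use_oracle_masks: bool = False  # feed ground-truth zones to stage 2

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.w_overlap < 0 or self.w_ce < 0:
            raise ValueError("loss weights must be >= 0")


def normalize_channel(arr: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
    lo, hi = rng
    return (np.asarray(arr, dtype=np.float64) - lo) / (hi - lo)


@dataclass
class TaskModel:
    """A trained predictor plus everything needed to reproduce and rerun it.

    ``kind`` is "gland" (T2W -> 3-class zone map) or "detector" (5 input
    planes -> csPCa confidence). A detector embeds its upstream gland model
    so the whole pipeline serializes as a single file.
    """

    kind: str
    net: UNet2D
    ranges: dict[str, tuple[float, float]]
    train_seed: int
    use_oracle_masks: bool = False
    gland: "TaskModel | None" = None

    # ------------------------------------------------------------ inference
    def _forward_batch(self, x: np.ndarray) -> np.ndarray:
        return self.net(Tensor(x)).data

    def save(self, path) -> None:
        arrays = {f"net/{k}": v for k, v in self.net.state_arrays().items()}
        meta = {"kind": self.kind, "ranges": self.ranges,
                "train_seed": self.train_seed,
                "use_oracle_masks": self.use_oracle_masks,
                "net_config": json.loads(self.net.config_json())}
        if self.gland is not None:
            arrays.update({f"gland/{k}": v
                           for k, v in self.gland.net.state_arrays().items()})
            meta["gland"] = {"kind": self.gland.kind,
                             "ranges": self.gland.ranges,
                             "train_seed": self.gland.train_seed,
                             "net_config":
                                 json.loads(self.gland.net.config_json())}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TaskModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
        def build(prefix: str, m: dict) -> "TaskModel":
            net = UNet2D.from_config_json(json.dumps(m["net_config"]))
            net.load_state({k[len(prefix):]: v for k, v in arrays.items()
                            if k.startswith(prefix)})
            return cls(m["kind"], net,
                       {k: tuple(v) for k, v in m["ranges"].items()},
                       m["train_seed"],
                       m.get("use_oracle_masks", False))
        model = build("net/", meta)
        if "gland" in meta:
            model.gland = build("gland/", meta["gland"])
        return model


# ------------------------------------------------------------- sample makers
def _gland_sample(case: PhantomCase,
                  ranges: dict) -> tuple[np.ndarray, np.ndarray]:
    x = normalize_channel(case.volume.t2w, ranges["t2w"])[:, None]  # (nz,1,H,W)
    tgt = np.zeros(case.volume.shape, dtype=np.int64)
    tgt[case.masks.pz] = 1
    tgt[case.masks.tz] = 2
    return x, tgt


def predict_zone_masks(gland_model: TaskModel,
                       t2w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted (PZ, TZ) binary masks from a raw-intensity T2W volume."""
    x = normalize_channel(t2w, gland_model.ranges["t2w"])[:, None]
    logits = gland_model._forward_batch(x)           # (nz,3,H,W)
    lab = logits.argmax(axis=1)
    return lab == 1, lab == 2


def detector_input(volume_channels: dict[str, np.ndarray],
                   pz_mask: np.ndarray, tz_mask: np.ndarray,
                   ranges: dict) -> np.ndarray:
    """Stack the five detector input planes: T2W, ADC, DWI, TZ, PZ.

    ``volume_channels`` holds raw-intensity grids of shape (nz, H, W).
    Returns (nz, 5, H, W) in normalized units.
    """
    planes = [normalize_channel(volume_channels["t2w"], ranges["t2w"]),
              normalize_channel(volume_channels["adc"], ranges["adc"]),
              normalize_channel(volume_channels["dwi"], ranges["dwi"]),
              tz_mask.astype(np.float64), pz_mask.astype(np.float64)]
    x = np.stack(planes, axis=1)
    if x.shape[1] != DETECTOR_IN_CHANNELS:
        raise ValueError(f"detector expects {DETECTOR_IN_CHANNELS} channels")
    return x


def cspca_target(case: PhantomCase) -> np.ndarray:
    ids = [i for i, l in case.masks.lesion_labels.items() if l == "csPCa"]
    return np.isin(case.masks.lesions, ids).astype(np.float64)


def _detector_sample(case: PhantomCase, model_ranges: dict,
                     gland_model: TaskModel | None,
                     use_oracle_masks: bool) -> tuple[np.ndarray, np.ndarray]:
    if use_oracle_masks or gland_model is None:
        pz, tz = case.masks.pz, case.masks.tz
    else:
        pz, tz = predict_zone_masks(gland_model, case.volume.t2w)
    chans = {n: case.volume.channel(n) for n in CHANNELS}
    x = detector_input(chans, pz, tz, model_ranges)
    tgt = cspca_target(case)[:, None]                 # (nz,1,H,W)
    return x, tgt


# ----------------------------------------------------------------- training
def _train(samples: list[tuple[np.ndarray, np.ndarray]], net: UNet2D,
           config: TrainConfig, *, binary: bool) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params, lr=config.lr)
    rows = []
    idx = np.arange(len(samples))
    for epoch in range(config.epochs):
        rng.shuffle(idx)
        losses = []
        for start in range(0, len(idx), config.batch_size):
            batch = idx[start:start + config.batch_size]
            x = np.concatenate([samples[i][0] for i in batch], axis=0)
            t = np.concatenate([samples[i][1] for i in batch], axis=0)
            net.zero_grad()
            loss = seg_loss(net(Tensor(x)), t, binary=binary,
                            w_overlap=config.w_overlap, w_ce=config.w_ce,
                            pos_weight=config.pos_weight if binary else 1.0)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        rows.append({"epoch": epoch, "loss": float(np.mean(losses))})
    return pd.DataFrame(rows)


def train_gland_segmenter(cases: list[PhantomCase], config: TrainConfig
                          ) -> tuple[TaskModel, pd.DataFrame]:
    """Stage 1: T2W -> {background, PZ, TZ} voxel map."""
    config.validate()
    if not cases:
        raise ValueError("empty training set")
    ranges = dict(cases[0].volume.ranges)
    samples = [_gland_sample(c, ranges) for c in cases]
    if all((s[1] == 0).all() for s in samples):
        raise ValueError("all-background zone labels")
    net = UNet2D(1, 3, width=config.width, seed=config.seed)
    history = _train(samples, net, config, binary=False)
    return TaskModel("gland", net, ranges, config.seed), history


def train_lesion_detector(cases: list[PhantomCase], gland_model: TaskModel,
                          config: TrainConfig
                          ) -> tuple[TaskModel, pd.DataFrame]:
    """Stage 2: five input planes -> voxel-wise csPCa confidence."""
    config.validate()
    if not cases:
        raise ValueError("empty training set")
    ranges = dict(cases[0].volume.ranges)
    samples = [_detector_sample(c, ranges, gland_model,
                                config.use_oracle_masks) for c in cases]
    net = UNet2D(DETECTOR_IN_CHANNELS, 1, width=config.width,
                 seed=config.seed + 1)
    history = _train(samples, net, config, binary=True)
    model = TaskModel("detector", net, ranges, config.seed,
                      config.use_oracle_masks, gland=gland_model)
    return model, history


def predict_confidence(model: TaskModel, case: PhantomCase) -> np.ndarray:
    """Voxel-wise confidence map in [0, 1], same shape as the case volume.

    Pure function of (model parameters, case volume): for a detector the
    zone masks are re-predicted from the (possibly perturbed) T2W channel
    unless the model was trained with oracle masks.
    """
    if model.kind == "gland":
        x = normalize_channel(case.volume.t2w, model.ranges["t2w"])[:, None]
        logits = model._forward_batch(x)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        out = 1.0 - probs[:, 0]                       # P(gland tissue)
    elif model.kind == "detector":
        x, _ = _detector_sample(case, model.ranges, model.gland,
                                model.use_oracle_masks)
        z = model._forward_batch(x)[:, 0]
        out = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    if out.shape != case.volume.shape:
        raise ValueError("confidence map shape mismatch")
    return np.clip(out, 0.0, 1.0)


# ----------------------------------------------------------- model selection
def crossval_select(cases: list[PhantomCase], k: int, config: TrainConfig,
                    trainer, scorer, seed: int | None = None):
    """k-fold cross-validation with best-fold selection.

    ``trainer(train_cases, config) -> model`` and
    ``scorer(model, val_cases) -> float`` (higher is better; the default
    protocol scores validation patient-level AUC). Folds partition the cases;
    returns ``(best_model, fold_table, assignment)`` where ``assignment``
    maps case_id -> fold for audit.
    """
    n = len(cases)
    if k > n:
        raise ValueError(f"k={k} exceeds number of cases n={n}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    order = rng.permutation(n)
    folds = [sorted(order[i::k].tolist()) for i in range(k)]
    assignment = {cases[i].case_id: f for f, idxs in enumerate(folds)
                  for i in idxs}
    rows, models = [], []
    for f, val_idx in enumerate(folds):
        val = [cases[i] for i in val_idx]
        train = [cases[i] for i in range(n) if i not in set(val_idx)]
        model = trainer(train, config)
        score = scorer(model, val)
        models.append(model)
        rows.append({"fold": f, "n_train": len(train), "n_val": len(val),
                     "val_score": float(score)})
    table = pd.DataFrame(rows)
    best = int(table["val_score"].idxmax())
    return models[best], table, assignment
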