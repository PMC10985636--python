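"""One-command benchmark: the whole defended-vs-control experiment.

Stages: phantom cohort generation (a mixed-severity training cohort and an
artifact-free testing cohort) -> shared gland segmenter -> control and
defended detector training -> adversarial perturbation of the clean testing
cohort against the control model (the invisible-noise twin set) -> paired
evaluation. All numeric outputs are byte-identical across reruns of the
same config; a file manifest with content hashes is written alongside.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from .advnoise import FeatureExtractor, NoiseConfig, attack_cohort, \
    style_sample_from_case
from .advtrain import TpasSchedule, control_train, tpas_train
from .config import RunConfig, derive_seed
from .evalstats import EvalReport, compare_models
from .model import TrainConfig, train_gland_segmenter
from .phantom import GenerationConfig, generate_case, generate_cohort

__all__ = ["run_benchmark", "BenchmarkError"]

log = logging.getLogger("tpas.benchmark")


class BenchmarkError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"benchmark stage '{stage}' failed: {cause!r}")


def _train_config(cfg: RunConfig, seed: int, epochs: int | None = None
                  ) -> TrainConfig:
    m = cfg.model
    return TrainConfig(epochs=epochs or m.epochs, batch_size=m.batch_size,
                       lr=m.lr, w_overlap=m.w_overlap, w_ce=m.w_ce,
                       folds=m.folds, seed=seed, width=m.width,
                       pos_weight=m.pos_weight)


def _noise_config(cfg: RunConfig, seed: int) -> NoiseConfig:
    n = cfg.noise
    return NoiseConfig(epsilon=n.epsilon, iters=n.iters, step=n.step,
                       lambda_style=n.lambda_style,
                       lambda_content=n.lambda_content,
                       lambda_adv=n.lambda_adv,
                       restrict_to_body=n.restrict_to_body,
                       w_overlap=cfg.model.w_overlap, w_ce=cfg.model.w_ce,
                       pos_weight=cfg.model.pos_weight, seed=seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_benchmark(config: RunConfig, out_dir) -> tuple[EvalReport, dict]:
    """Execute the full experiment; returns the report and artifact paths.

    Any stage failure raises :class:`BenchmarkError` naming the stage;
    artifacts produced by completed stages are left in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    artifacts: dict[str, Path] = {"config": out / "config.yaml"}
    stage = "setup"
    t_start = time.time()
    try:
        # ------------------------------------------------------ cohorts
        stage = "phantom"
        t0 = time.time()
        gen_train = GenerationConfig(
            shape=config.phantom.shape,
            cspca_prevalence=config.phantom.cspca_prevalence,
            grade_probs=config.phantom.train_grade_probs,
            contrast_margin_sigmas=config.phantom.contrast_margin_sigmas)
        train_cases, train_manifest = generate_cohort(
            config.phantom.n_train, gen_train,
            derive_seed(config.seed, "phantom.train"), id_prefix="train")
        gen_test = GenerationConfig(
            shape=config.phantom.shape,
            cspca_prevalence=config.phantom.cspca_prevalence,
            grade_probs=(1.0, 0.0, 0.0, 0.0),
            contrast_margin_sigmas=config.phantom.contrast_margin_sigmas)
        test_cases, test_manifest = generate_cohort(
            config.phantom.n_test, gen_test,
            derive_seed(config.seed, "phantom.test"), id_prefix="test")
        train_manifest.to_csv(out / "train_manifest.csv", index=False)
        test_manifest.to_csv(out / "test_manifest.csv", index=False)
        artifacts["train_manifest"] = out / "train_manifest.csv"
        artifacts["test_manifest"] = out / "test_manifest.csv"
        log.info("phantom: %d train / %d test cases (%.1fs)",
                 len(train_cases), len(test_cases), time.time() - t0)

        # ------------------------------------------------------- models
        stage = "gland"
        t0 = time.time()
        gland, gland_hist = train_gland_segmenter(
            train_cases, _train_config(config,
                                       derive_seed(config.seed, "gland"),
                                       epochs=config.model.gland_epochs))
        gland_hist.to_csv(out / "gland_history.csv", index=False)
        log.info("gland segmenter trained (%.1fs)", time.time() - t0)

        stage = "control_train"
        t0 = time.time()
        seed_train = derive_seed(config.seed, "detector")
        control, control_hist = control_train(
            train_cases, _train_config(config, seed_train), gland)
        control_hist.to_csv(out / "control_history.csv", index=False)
        control.save(out / "control.npz")
        artifacts["control_ckpt"] = out / "control.npz"
        log.info("control detector trained (%.1fs)", time.time() - t0)

        stage = "tpas_train"
        t0 = time.time()
        extractor = FeatureExtractor(
            seed=derive_seed(config.seed, "extractor"))
        grade4 = [c for c in train_cases if c.artifact.grade == 4]
        style_case = grade4[0] if grade4 else generate_case(
            GenerationConfig(shape=config.phantom.shape,
                             grade_probs=(0.0, 0.0, 0.0, 1.0)),
            derive_seed(config.seed, "style"))
        style = style_sample_from_case(style_case)
        schedule = TpasSchedule(
            refresh_interval=config.schedule.refresh_interval,
            mix_fraction=config.schedule.mix_fraction,
            warmup=config.schedule.warmup,
            noise=_noise_config(config, derive_seed(config.seed, "noise")))
        tpas, tpas_hist = tpas_train(train_cases,
                                     _train_config(config, seed_train),
                                     schedule, gland, extractor, style)
        tpas_hist.to_csv(out / "tpas_history.csv", index=False)
        tpas.save(out / "tpas.npz")
        artifacts["tpas_ckpt"] = out / "tpas.npz"
        log.info("defended detector trained (%.1fs)", time.time() - t0)

        # ------------------------------------------------------- attack
        # per-model resilience protocol: each detector is evaluated on
        # noise optimized against it (the invisible-noise twin cohorts)
        stage = "attack"
        t0 = time.time()
        attacked = {}
        for mname, target in (("control", control), ("tpas", tpas)):
            samples, attack_manifest, errors = attack_cohort(
                test_cases, target, extractor, style,
                _noise_config(config, derive_seed(config.seed, "attack")))
            if errors:
                log.warning("attack errors (%s) on %d cases: %s",
                            mname, len(errors), errors)
            if len(samples) != len(test_cases):
                raise RuntimeError(
                    f"attack vs {mname} failed on {len(errors)} cases")
            attacked[mname] = [s.attacked_case() for s in samples]
            attack_manifest.to_csv(out / f"attack_manifest_{mname}.csv",
                                   index=False)
        log.info("attacked %d cases per model (%.1fs)",
                 len(test_cases), time.time() - t0)

        # ----------------------------------------------------- evaluate
        stage = "evaluate"
        t0 = time.time()
        report = compare_models(
            control, tpas, test_cases, attacked["control"],
            attacked_cases_tpas=attacked["tpas"],
            threshold=config.evaluation.threshold,
            min_overlap=config.evaluation.min_overlap,
            min_size=config.evaluation.min_size,
            bootstrap_b=config.evaluation.bootstrap_b,
            seed=derive_seed(config.seed, "bootstrap"))
        for p in report.write(out):
            artifacts[p.name] = p
        log.info("evaluation done (%.1fs)", time.time() - t0)
    except Exception as e:
        raise BenchmarkError(stage, e) from e

    # -------------------------------------------------------- manifest
    hashed = {}
    for p in sorted(out.iterdir()):
        if p.name in ("files.json", "run.log") or p.is_dir():
            continue
        hashed[p.name] = _sha256(p)
    (out / "files.json").write_text(json.dumps(hashed, indent=1,
                                               sort_keys=True))
    artifacts["files"] = out / "files.json"
    log.info("benchmark complete in %.1fs", time.time() - t_start)
    return report, artifacts
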