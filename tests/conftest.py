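"""Shared fixtures.

Small phantoms (1x48x48) keep unit tests fast; the session-scoped benchmark
fixture runs the full pinned experiment once and is shared by the
acceptance checks that need trained models or the headline report.
"""

from __future__ import annotations

import pytest

from tpas.phantom import GenerationConfig, generate_cohort

SMALL_SHAPE = (1, 48, 48)


def small_config(**kw) -> GenerationConfig:
    kw.setdefault("shape", SMALL_SHAPE)
    return GenerationConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    """12 mixed-severity cases at 48x48 for training-path tests."""
    cases, manifest = generate_cohort(12, small_config(), seed=11)
    return cases, manifest


@pytest.fixture(scope="session")
def clean_cohort():
    """8 artifact-free cases at 48x48."""
    cases, _ = generate_cohort(8, small_config(grade_probs=(1, 0, 0, 0)),
                               seed=23)
    return cases


@pytest.fixture(scope="session")
def trained_small(small_cohort):
    """A small trained two-stage pipeline shared across tests."""
    from tpas.model import (TrainConfig, train_gland_segmenter,
                            train_lesion_detector)
    cases, _ = small_cohort
    tc = TrainConfig(epochs=12, batch_size=6, lr=5e-3, seed=3)
    gland, gland_hist = train_gland_segmenter(cases, tc)
    det, det_hist = train_lesion_detector(cases, gland, tc)
    return {"cases": cases, "gland": gland, "detector": det,
            "gland_hist": gland_hist, "det_hist": det_hist, "config": tc}


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory):
    """One full run of the pinned benchmark (shipped config, seed 1)."""
    from pathlib import Path
    from tpas.benchmark import run_benchmark
    from tpas.config import validate_config
    cfg = validate_config(Path(__file__).resolve().parents[1]
                          / "configs" / "benchmark.yaml")
    out = tmp_path_factory.mktemp("bench")
    report, artifacts = run_benchmark(cfg, out)
    return {"config": cfg, "report": report, "artifacts": artifacts,
            "out": out}
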