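"""Adversarial-noise core: loss definitions, gradient correctness,
PGD invariants, bound preservation."""

import numpy as np
import pytest

from tpas.advnoise import (FeatureExtractor, NoiseConfig,
                           adversarial_task_loss, attack_cohort,
                           clip_to_bounds, content_distance, generate_noise,
                           gram_matrix, style_distance, style_sample_from_case,
                           StyleSample)
from tpas.autodiff import Tensor
from tpas.phantom import CHANNELS, generate_case

from conftest import small_config


class IdentityExtractor:
    """Single 1-channel layer whose features are the raw input — lets the
    Gram arithmetic be checked by hand."""

    STYLE_LAYERS = ("raw",)
    CONTENT_LAYERS = ("raw2",)
    in_channels = 1

    def features(self, x):
        return {"raw": x, "raw2": x}


def const_image(value, n=6):
    return np.full((1, 1, n, n), float(value))


def test_style_distance_identity_and_hand_example():
    ex = IdentityExtractor()
    s = StyleSample(const_image(2.0), "toy")
    # identical input -> 0
    assert style_distance(const_image(2.0), s, ex).item() == pytest.approx(0)
    # constant features 1 vs 2 over N positions with 1/N normalization:
    # Gram values 1 and 4 -> squared distance (1-4)^2 = 9
    assert style_distance(const_image(1.0), s, ex).item() == pytest.approx(9.0)


def test_style_distance_invariant_to_spatial_permutation():
    rng = np.random.default_rng(0)
    ex = IdentityExtractor()
    img = rng.normal(size=(1, 1, 4, 4))
    perm = img.reshape(1, 1, -1)[:, :, rng.permutation(16)].reshape(img.shape)
    s = StyleSample(rng.normal(size=(1, 1, 4, 4)), "toy")
    assert style_distance(img, s, ex).item() == pytest.approx(
        style_distance(perm, s, ex).item())


def test_gram_matrix_formula():
    rng = np.random.default_rng(1)
    f = rng.normal(size=(1, 3, 4, 5))
    g = gram_matrix(Tensor(f)).data
    flat = f[0].reshape(3, -1)
    assert np.allclose(g, flat @ flat.T / 20)


def test_content_distance_properties():
    ex = IdentityExtractor()
    rng = np.random.default_rng(2)
    x = rng.normal(size=(1, 1, 6, 6))
    assert content_distance(x, x, ex).item() == pytest.approx(0.0)
    d1 = content_distance(x + 0.01, x, ex).item()
    d2 = content_distance(x + 0.02, x, ex).item()
    assert 0.0 < d1 < d2            # monotone in the identity extractor
    with pytest.raises(ValueError):
        content_distance(np.zeros((1, 1, 4, 4)), x, ex)


def test_loss_gradients_match_finite_differences(trained_small):
    """Analytic input-gradients of the three objective terms agree with
    central differences on tiny inputs."""
    det = trained_small["detector"]
    ex = FeatureExtractor(seed=1)
    rng = np.random.default_rng(3)
    x3 = rng.random(size=(1, 3, 8, 8))
    sty = StyleSample(rng.random(size=(1, 3, 8, 8)), "toy")
    x5 = rng.random(size=(1, 5, 8, 8))
    tgt = rng.integers(0, 2, size=(1, 1, 8, 8)).astype(float)

    def numgrad(f, arr, eps=1e-6):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            arr[i] += eps
            fp = f()
            arr[i] -= 2 * eps
            fm = f()
            arr[i] += eps
            g[i] = (fp - fm) / (2 * eps)
        return g

    t = Tensor(x3, requires_grad=True)
    style_distance(t, sty, ex).backward()
    assert np.abs(t.grad - numgrad(
        lambda: style_distance(x3, sty, ex).item(), x3)).max() < 1e-6

    t = Tensor(x3, requires_grad=True)
    content_distance(t, x3.copy(), ex).backward()
    ref = x3.copy()
    assert np.abs(t.grad - numgrad(
        lambda: content_distance(x3, ref, ex).item(), x3)).max() < 1e-6

    t = Tensor(x5, requires_grad=True)
    adversarial_task_loss(det, t, tgt).backward()
    assert np.abs(t.grad - numgrad(
        lambda: adversarial_task_loss(det, x5, tgt).item(), x5)).max() < 1e-6


def test_clip_to_bounds_examples_and_idempotence():
    orig = np.array([0.0, 50.0, 100.0])
    assert clip_to_bounds(orig, np.array([103.0]))[0] == 100.0
    assert clip_to_bounds(orig, np.array([-2.0]))[0] == 0.0
    x = np.array([-5.0, 42.0, 250.0])
    once = clip_to_bounds(orig, x)
    assert np.array_equal(clip_to_bounds(orig, once), once)


@pytest.fixture(scope="module")
def attack_setup(trained_small):
    g4 = generate_case(small_config(grade_probs=(0, 0, 0, 1.0)), 77)
    return {
        "det": trained_small["detector"],
        "style": style_sample_from_case(g4),
        "ex": FeatureExtractor(seed=2),
        "case": trained_small["cases"][0],
    }


def test_generate_noise_bounds_and_determinism(attack_setup):
    nc = NoiseConfig(iters=6)
    s1 = generate_noise(attack_setup["case"], attack_setup["det"],
                        attack_setup["ex"], attack_setup["style"], nc)
    s2 = generate_noise(attack_setup["case"], attack_setup["det"],
                        attack_setup["ex"], attack_setup["style"], nc)
    for name in CHANNELS:
        lo, hi = s1.case.volume.ranges[name]
        assert np.abs(s1.noise[name]).max() <= nc.epsilon * (hi - lo) + 1e-9
        assert np.array_equal(s1.noise[name], s2.noise[name])
    atk = s1.attacked_case()
    for name in CHANNELS:
        base = s1.case.volume.channel(name)
        a = atk.volume.channel(name)
        assert a.min() >= base.min() and a.max() <= base.max()
    s1.validate()   # internal invariant checks agree


def test_composite_objective_never_worse_than_zero_noise(attack_setup):
    """The returned perturbation's composite objective is <= the value at
    delta = 0, and its style distance does not exceed the baseline."""
    nc = NoiseConfig(iters=8)
    s = generate_noise(attack_setup["case"], attack_setup["det"],
                       attack_setup["ex"], attack_setup["style"], nc)
    tr = s.trajectory
    j0, style0 = tr["composite"].iloc[0], tr["style"].iloc[0]
    # recompute at the returned iterate via the recorded best row
    best_rows = tr[(tr["style"] <= style0 + 1e-12)]
    assert best_rows["composite"].min() <= j0 + 1e-12
    assert tr["composite"].iloc[-1] <= j0 + 1e-9 or \
        best_rows["composite"].min() <= j0 + 1e-12


def test_zero_adv_weight_and_self_style_keeps_zero_noise(attack_setup):
    """With lambda_adv = 0 and the case itself as the style exemplar,
    delta = 0 minimizes the objective, so the returned noise is zero."""
    case = attack_setup["case"]
    self_style = style_sample_from_case(case)
    nc = NoiseConfig(iters=5, lambda_adv=0.0)
    s = generate_noise(case, attack_setup["det"], attack_setup["ex"],
                       self_style, nc)
    for name in CHANNELS:
        assert np.allclose(s.noise[name], 0.0)
    assert s.trajectory["composite"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_noise_config_validation():
    for bad in (dict(epsilon=0), dict(iters=0), dict(step=0),
                dict(lambda_style=-1)):
        with pytest.raises(ValueError):
            NoiseConfig(**bad).validate()


def test_attack_cohort_preserves_ids_and_bounds(attack_setup, trained_small):
    cases = trained_small["cases"][:4]
    nc = NoiseConfig(iters=4)
    samples, manifest, errors = attack_cohort(
        cases, attack_setup["det"], attack_setup["ex"],
        attack_setup["style"], nc)
    assert not errors
    assert len(samples) == len(cases)
    assert list(manifest["case_id"]) == [c.case_id for c in cases]
    assert all(a.endswith("*") for a in manifest["attacked_id"])
    for s in samples:
        s.validate()
        for name in CHANNELS:
            lo, hi = s.case.volume.ranges[name]
            assert np.abs(s.noise[name]).mean() <= nc.epsilon * (hi - lo)
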