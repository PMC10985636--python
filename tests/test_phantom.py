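"""Phantom generator: invariants, grading, determinism, I/O."""


import numpy as np
import pytest
from scipy import stats

from tpas.phantom import (ArtifactSpec, apply_visible_artifact,
                          cases_equal, generate_case, generate_cohort,
                          grade_artifact, read_case, write_case,
                          _sample_artifact_spec, clean_subset, CHANNELS)

from conftest import small_config


def test_generation_is_deterministic():
    cfg = small_config()
    a = generate_case(cfg, 7)
    b = generate_case(cfg, 7)
    assert cases_equal(a, b)
    c = generate_case(cfg, 8)
    assert not np.array_equal(a.volume.t2w, c.volume.t2w)


def test_anatomy_invariants_hold_across_cases():
    cfg = small_config()
    for seed in range(20):
        case = generate_case(cfg, 100 + seed)
        m = case.masks
        assert not np.any(m.pz & m.tz)
        assert np.array_equal(m.pz | m.tz, m.gland)
        assert not np.any((m.lesions > 0) & ~m.gland)
        assert not np.any(m.rectum & m.gland)
        assert m.pz.sum() > 0 and m.tz.sum() > 0 and m.rectum.sum() > 0
        for name in CHANNELS:
            lo, hi = case.volume.ranges[name]
            ch = case.volume.channel(name)
            assert np.all(np.isfinite(ch))
            assert ch.min() >= lo and ch.max() <= hi
        assert case.patient_label == any(
            v == "csPCa" for v in m.lesion_labels.values())


def test_zero_prevalence_forces_negative_patients():
    cfg = small_config(cspca_prevalence=0.0)
    for seed in range(10):
        case = generate_case(cfg, seed)
        assert not case.patient_label
        assert "csPCa" not in case.masks.lesion_labels.values()


def test_prevalence_within_binomial_bounds():
    """At prevalence 0.5 and n=200 the positive count must lie inside the
    central 99% binomial interval [73, 127]."""
    lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.5)
    cases, manifest = generate_cohort(200, small_config(), seed=1)
    k = int(manifest["label"].sum())
    assert lo <= k <= hi


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        generate_case(small_config(shape=(0, 48, 48)), 1)
    with pytest.raises(ValueError):
        # lesion radius beyond the gland semi-axis
        generate_case(small_config(lesion_radius_mm=(9.0, 12.0)), 1)


# ------------------------------------------------------------------ artifact
def _clean_case(seed=5):
    return generate_case(small_config(grade_probs=(1, 0, 0, 0)), seed)


def test_grade1_artifact_is_identity():
    case = _clean_case()
    spec = ArtifactSpec(1, 0.0, False, 0.2, 5.0, 3)
    out = apply_visible_artifact(case, spec)
    for name in CHANNELS:
        assert np.array_equal(out.volume.channel(name),
                              case.volume.channel(name))
    assert not out.artifact_mask.any()
    assert grade_artifact(out) == 1


def test_zero_amplitude_leaves_voxels_unchanged():
    case = _clean_case()
    spec = ArtifactSpec(3, 0.7, False, 0.0, 5.0, 3)
    out = apply_visible_artifact(case, spec)
    for name in CHANNELS:
        assert np.array_equal(out.volume.channel(name),
                              case.volume.channel(name))
    assert out.artifact_mask.any()          # support recorded regardless


def test_grade4_involves_transition_zone():
    case = _clean_case()
    spec = ArtifactSpec(4, 0.6, True, 0.15, 5.0, 3)
    out = apply_visible_artifact(case, spec)
    assert np.any(out.artifact_mask & out.masks.tz)
    assert grade_artifact(out) == 4


def test_grading_rules_on_constructed_masks():
    """The 4-point scale: PZ fraction 0 -> 1, <0.5 -> 2, >=0.5 -> 3, any
    TZ involvement -> 4."""
    case = _clean_case()
    npz = int(case.masks.pz.sum())
    pz_flat = np.flatnonzero(case.masks.pz.ravel())

    def with_mask(k_pz, tz=False):
        mask = np.zeros(case.volume.shape, dtype=bool)
        mask.ravel()[pz_flat[:k_pz]] = True
        if tz:
            tz_flat = np.flatnonzero(case.masks.tz.ravel())
            mask.ravel()[tz_flat[:1]] = True
        grade = 4 if tz else (1 if k_pz == 0 else
                              (2 if k_pz / npz < 0.5 else 3))
        from dataclasses import replace
        f = 0.0 if grade == 1 else min(k_pz / npz, 1.0)
        f = {1: 0.0, 2: f, 3: max(f, 0.5), 4: f}[grade]
        spec = ArtifactSpec(grade, f, tz, 0.1, 5.0, 0)
        return replace(case, artifact=spec, artifact_mask=mask)

    assert grade_artifact(with_mask(0)) == 1
    assert grade_artifact(with_mask(int(0.3 * npz))) == 2
    assert grade_artifact(with_mask(int(0.7 * npz))) == 3
    assert grade_artifact(with_mask(int(0.2 * npz), tz=True)) == 4


def test_artifact_respects_intensity_ranges_and_spec_validation():
    case = _clean_case()
    out = apply_visible_artifact(case, ArtifactSpec(3, 0.9, False, 0.5, 4.0, 1))
    for name in CHANNELS:
        lo, hi = out.volume.ranges[name]
        ch = out.volume.channel(name)
        assert ch.min() >= lo and ch.max() <= hi
    with pytest.raises(ValueError):
        ArtifactSpec(5, 0.5, False, 0.1, 5.0, 1).validate()
    with pytest.raises(ValueError):
        apply_visible_artifact(case, ArtifactSpec(2, 0.7, False, 0.1, 5.0, 1))


# -------------------------------------------------------------------- cohort
def test_cohort_manifest_and_clean_filter():
    cases, manifest = generate_cohort(10, small_config(grade_probs=(1, 0, 0, 0)),
                                      seed=2)
    assert list(manifest.columns) == ["case_id", "label", "grade", "site"]
    assert (manifest["grade"] == 1).all()
    assert len(clean_subset(cases)) == 10
    _, manifest2 = generate_cohort(10, small_config(grade_probs=(1, 0, 0, 0)),
                                   seed=2)
    assert manifest.equals(manifest2)
    with pytest.raises(ValueError):
        generate_cohort(0, small_config(), seed=1)


def test_grade_distribution_within_multinomial_bounds():
    """Per-grade counts at n=1000 under probs (.7,.1,.1,.1) stay inside the
    Bonferroni-adjusted 99% binomial envelopes."""
    n = 1000
    probs = (0.7, 0.1, 0.1, 0.1)
    _, manifest = generate_cohort(n, small_config(grade_probs=probs), seed=9)
    counts = manifest["grade"].value_counts()
    for g, p in zip((1, 2, 3, 4), probs):
        lo, hi = stats.binom.ppf([0.00125, 0.99875], n, p)
        assert lo <= counts.get(g, 0) <= hi, f"grade {g}: {counts.get(g, 0)}"


def test_generator_grader_consistency_sample():
    rng = np.random.default_rng(4)
    base = _clean_case(31)
    sampler_cfg = small_config(grade_probs=(0.0, 1 / 3, 1 / 3, 1 / 3))
    for _ in range(25):
        spec = _sample_artifact_spec(sampler_cfg, rng)
        assert grade_artifact(apply_visible_artifact(base, spec)) == spec.grade


# ------------------------------------------------------------------------ io
def test_nifti_roundtrip_exact(tmp_path):
    case = generate_case(small_config(), 17)
    write_case(case, tmp_path)
    back = read_case(tmp_path, case.case_id)
    assert cases_equal(case, back)
    # masks stored as unsigned ints, channels as floats
    import nibabel as nib
    m = nib.load(tmp_path / f"{case.case_id}_mask_gland.nii.gz")
    c = nib.load(tmp_path / f"{case.case_id}_t2w.nii.gz")
    assert np.issubdtype(m.get_data_dtype(), np.unsignedinteger)
    assert np.issubdtype(c.get_data_dtype(), np.floating)


def test_corrupt_sidecar_raises_parse_error(tmp_path):
    case = generate_case(small_config(), 18)
    write_case(case, tmp_path)
    (tmp_path / f"{case.case_id}.json").write_text("{not json")
    with pytest.raises(ValueError, match="corrupt sidecar"):
        read_case(tmp_path, case.case_id)
    with pytest.raises(FileNotFoundError):
        read_case(tmp_path, "missing_case")
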