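"""Synthetic biparametric-MRI phantom cohorts with graded rectal artifacts.

Each phantom patient is a small aligned multi-channel volume (T2-weighted,
high-b-value DWI, ADC) with voxel-level anatomy: an ellipsoidal prostate
gland split into transition zone (TZ, inner) and peripheral zone
(PZ = gland minus TZ), a posterior rectum, and zero or more lesion instances
labelled clinically-significant (csPCa) or not. csPCa lesions carry the
canonical contrast pattern — hypointense on T2W and ADC, hyperintense on
DWI — at a configurable margin above the background noise.

Rectal susceptibility artifacts are simulated as an additive banded
perturbation emanating from the rectum into the gland, with severity graded
on the clinical 4-point scale:

1. no artifact;
2. mild — less than 50% of the PZ involved;
3. moderate — 50-100% of the PZ involved, TZ spared;
4. severe — the artifact extends into the TZ.

Coordinate convention: arrays are indexed ``(z, y, x)``, 0-based; ``y``
increases towards posterior (the rectum side). Masks are boolean arrays of
the volume shape. Everything is deterministic under ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GenerationConfig", "MultiModalVolume", "AnatomyMasks", "ArtifactSpec",
    "PhantomCase", "generate_case", "apply_visible_artifact", "grade_artifact",
    "generate_cohort", "write_case", "read_case", "cases_equal", "body_mask",
    "CHANNELS",
]

CHANNELS = ("t2w", "dwi", "adc")


# ----------------------------------------------------------------- containers
@dataclass
class GenerationConfig:
    """Study-condition knobs for the phantom generator.

    Intensity units are arbitrary but fixed per channel; contrast margins are
    expressed in multiples of the channel noise sigma so the lesion/zone
    separation is controlled explicitly (default 3 sigma: learnable by a
    small model, not trivially separable voxel-wise).
    """

    shape: tuple[int, int, int] = (1, 64, 64)          # (z, y, x)
    spacing: tuple[float, float, float] = (3.0, 0.5, 0.5)  # mm
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "t2w": (0.0, 1000.0), "dwi": (0.0, 800.0), "adc": (0.0, 3000.0)})
    noise_sigma: dict[str, float] = field(default_factory=lambda: {
        "t2w": 40.0, "dwi": 32.0, "adc": 120.0})
    contrast_margin_sigmas: float = 3.0
    lesion_radius_mm: tuple[float, float] = (1.5, 3.0)
    lesion_count_probs: tuple[float, ...] = (0.25, 0.5, 0.25)  # P(0,1,2 lesions)
    cspca_prevalence: float = 0.5
    extra_cspca_prob: float = 0.3      # extra lesions of a positive patient
    grade_probs: tuple[float, float, float, float] = (0.55, 0.15, 0.15, 0.15)
    artifact_amplitude: tuple[float, float] = (0.10, 0.22)  # fraction of range
    band_period_mm: tuple[float, float] = (3.0, 7.0)
    site_tag: str = "synthetic"

    def validate(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("volume shape must be positive")
        if not np.isclose(sum(self.lesion_count_probs), 1.0):
            raise ValueError("lesion_count_probs must sum to 1")
        if not np.isclose(sum(self.grade_probs), 1.0):
            raise ValueError("grade_probs must sum to 1")
        if not 0.0 <= self.cspca_prevalence <= 1.0:
            raise ValueError("cspca_prevalence must be in [0, 1]")
        # gland semi-axis along y is ~0.20 * ny voxels (see _geometry)
        max_lesion_vox = self.lesion_radius_mm[1] / min(self.spacing[1:])
        if max_lesion_vox >= 0.20 * self.shape[1]:
            raise ValueError("lesion radius exceeds gland radius")


@dataclass
class MultiModalVolume:
    t2w: np.ndarray
    dwi: np.ndarray
    adc: np.ndarray
    spacing: tuple[float, float, float]
    ranges: dict[str, tuple[float, float]]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t2w.shape

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def validate(self) -> None:
        for name in CHANNELS:
            a = self.channel(name)
            if a.shape != self.shape:
                raise ValueError("channel shapes differ")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite values in {name}")
            lo, hi = self.ranges[name]
            if a.min() < lo or a.max() > hi:
                raise ValueError(f"{name} outside configured range")


@dataclass
class AnatomyMasks:
    gland: np.ndarray
    pz: np.ndarray
    tz: np.ndarray
    rectum: np.ndarray
    lesions: np.ndarray                 # int instance labels, 0 = background
    lesion_labels: dict[int, str]       # id -> "csPCa" | "non-csPCa"

    def validate(self) -> None:
        if np.any(self.pz & self.tz):
            raise ValueError("PZ and TZ overlap")
        if not np.array_equal(self.pz | self.tz, self.gland):
            raise ValueError("PZ + TZ must partition the gland")
        if np.any((self.lesions > 0) & ~self.gland):
            raise ValueError("lesion voxels outside the gland")
        if np.any(self.rectum & self.gland):
            raise ValueError("rectum overlaps the gland")
        ids = set(np.unique(self.lesions)) - {0}
        if ids != set(self.lesion_labels):
            raise ValueError("lesion ids and labels inconsistent")


@dataclass
class ArtifactSpec:
    grade: int
    pz_affected_fraction: float
    tz_involved: bool
    amplitude: float                    # fraction of channel intensity range
    band_period: float                  # mm
    seed: int

    def validate(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise ValueError(f"artifact grade must be 1-4, got {self.grade}")
        f, tz = self.pz_affected_fraction, self.tz_involved
        ok = {1: f == 0.0 and not tz,
              2: 0.0 < f < 0.5 and not tz,
              3: 0.5 <= f <= 1.0 and not tz,
              4: tz}[self.grade]
        if not ok:
            raise ValueError(
                f"inconsistent artifact spec: grade={self.grade}, "
                f"pz_affected_fraction={f}, tz_involved={tz}")


@dataclass
class PhantomCase:
    case_id: str
    volume: MultiModalVolume
    masks: AnatomyMasks
    artifact: ArtifactSpec
    artifact_mask: np.ndarray
    patient_label: bool
    site_tag: str = "synthetic"

    def validate(self) -> None:
        self.volume.validate()
        self.masks.validate()
        self.artifact.validate()
        has_cspca = any(v == "csPCa" for v in self.masks.lesion_labels.values())
        if self.patient_label != has_cspca:
            raise ValueError("patient_label inconsistent with lesion labels")
        if (self.artifact.grade == 1) != (not self.artifact_mask.any()):
            raise ValueError("artifact_mask must be empty iff grade 1")


# ------------------------------------------------------------------- geometry
def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / max(r, 1e-9)) ** 2
    return acc <= 1.0


def _geometry(cfg: GenerationConfig, rng: np.random.Generator) -> AnatomyMasks:
    nz, ny, nx = cfg.shape
    cz = (nz - 1) / 2.0
    cy = 0.40 * ny + rng.uniform(-1.5, 1.5)
    cx = 0.50 * nx + rng.uniform(-1.5, 1.5)
    ry = 0.20 * ny * rng.uniform(0.9, 1.1)
    rx = 0.27 * nx * rng.uniform(0.9, 1.1)
    rz = max(0.6, 0.4 * nz)
    gland = _ellipsoid(cfg.shape, (cz, cy, cx), (rz, ry, rx))
    tz = gland & _ellipsoid(cfg.shape, (cz, cy - 0.25 * ry, cx),
                            (rz, 0.55 * ry, 0.60 * rx))
    pz = gland & ~tz
    # posterior rectum: tube just behind the gland
    gap = 2.0
    rr = 0.09 * ny
    rect_cy = cy + ry + gap + rr
    rectum = _ellipsoid(cfg.shape, (cz, rect_cy, cx), (max(rz, nz), rr, 1.3 * rr))
    rectum &= ~gland
    lesions = np.zeros(cfg.shape, dtype=np.int32)
    return AnatomyMasks(gland, pz, tz, rectum, lesions, {})


def _place_lesions(masks: AnatomyMasks, cfg: GenerationConfig,
                   rng: np.random.Generator) -> None:
    n = int(rng.choice(len(cfg.lesion_count_probs), p=cfg.lesion_count_probs))
    positive = rng.random() < cfg.cspca_prevalence
    if positive and n == 0:
        n = 1
    if n == 0:
        return
    host = np.argwhere(masks.pz)
    spacing = np.array(cfg.spacing)
    next_id = 1
    for i in range(n):
        for _ in range(30):                      # rejection sampling
            center = host[rng.integers(len(host))]
            r_mm = rng.uniform(*cfg.lesion_radius_mm)
            radii = np.maximum(r_mm / spacing, 0.5)
            les = _ellipsoid(masks.gland.shape, center, radii) & masks.gland
            if les.any() and not np.any(les & (masks.lesions > 0)):
                masks.lesions[les] = next_id
                if positive and (i == 0 or rng.random() < cfg.extra_cspca_prob):
                    masks.lesion_labels[next_id] = "csPCa"
                else:
                    masks.lesion_labels[next_id] = "non-csPCa"
                next_id += 1
                break


# base tissue means as fractions of the channel range, per compartment
_TISSUE = {
    #            air    body   pz     tz     rectum
    "t2w": (0.05, 0.30, 0.65, 0.45, 0.15),
    "dwi": (0.03, 0.12, 0.18, 0.14, 0.08),
    "adc": (0.08, 0.50, 0.62, 0.55, 0.30),
}
# csPCa contrast direction per channel
_LESION_SIGN = {"t2w": -1.0, "dwi": +1.0, "adc": -1.0}


def _render(masks: AnatomyMasks, cfg: GenerationConfig,
            rng: np.random.Generator) -> MultiModalVolume:
    channels = {}
    cspca = np.isin(masks.lesions,
                    [i for i, l in masks.lesion_labels.items() if l == "csPCa"])
    benign = (masks.lesions > 0) & ~cspca
    body = body_region(masks)
    for name in CHANNELS:
        lo, hi = cfg.ranges[name]
        span = hi - lo
        air, tissue, pzv, tzv, rectv = (_TISSUE[name][i] for i in range(5))
        img = np.full(cfg.shape, lo + air * span)
        img[body] = lo + tissue * span
        img[masks.pz] = lo + pzv * span
        img[masks.tz] = lo + tzv * span
        img[masks.rectum] = lo + rectv * span
        sigma = cfg.noise_sigma[name]
        margin = cfg.contrast_margin_sigmas * sigma
        img[cspca] += _LESION_SIGN[name] * margin
        img[benign] += _LESION_SIGN[name] * 0.5 * margin
        img = img + rng.normal(0.0, sigma, size=cfg.shape)
        channels[name] = np.clip(img, lo, hi)
    return MultiModalVolume(channels["t2w"], channels["dwi"], channels["adc"],
                            cfg.spacing, dict(cfg.ranges))


def body_region(masks: AnatomyMasks) -> np.ndarray:
    """Soft-tissue support: gland and rectum plus a surrounding margin."""
    seed = masks.gland | masks.rectum
    struct = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_dilation(seed, structure=struct, iterations=8)


def body_mask(case: "PhantomCase") -> np.ndarray:
    return body_region(case.masks)


# ----------------------------------------------------------------- operations
def _sample_artifact_spec(cfg: GenerationConfig,
                          rng: np.random.Generator) -> ArtifactSpec:
    grade = int(rng.choice(4, p=cfg.grade_probs)) + 1
    amp = float(rng.uniform(*cfg.artifact_amplitude))
    period = float(rng.uniform(*cfg.band_period_mm))
    seed = int(rng.integers(0, 2 ** 31 - 1))
    if grade == 1:
        return ArtifactSpec(1, 0.0, False, amp, period, seed)
    if grade == 2:
        return ArtifactSpec(2, float(rng.uniform(0.05, 0.45)), False,
                            amp, period, seed)
    if grade == 3:
        return ArtifactSpec(3, float(rng.uniform(0.5, 1.0)), False,
                            amp, period, seed)
    return ArtifactSpec(4, float(rng.uniform(0.3, 1.0)), True, amp, period, seed)


def generate_case(config: GenerationConfig, seed: int,
                  case_id: str | None = None) -> PhantomCase:
    """Generate one phantom patient; bit-identical under (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    masks = _geometry(config, rng)
    _place_lesions(masks, config, rng)
    volume = _render(masks, config, rng)
    spec = _sample_artifact_spec(config, rng)
    case = PhantomCase(
        case_id=case_id or f"case_{seed:08d}",
        volume=volume,
        masks=masks,
        artifact=ArtifactSpec(1, 0.0, False, spec.amplitude,
                              spec.band_period, spec.seed),
        artifact_mask=np.zeros(config.shape, dtype=bool),
        patient_label=any(v == "csPCa" for v in masks.lesion_labels.values()),
        site_tag=config.site_tag,
    )
    if spec.grade > 1:
        case = apply_visible_artifact(case, spec)
    case.validate()
    return case


def _affected_voxels(masks: AnatomyMasks, spec: ArtifactSpec,
                     dist: np.ndarray) -> np.ndarray:
    """Select the artifact support: PZ voxels nearest the rectum at the
    requested fraction; for grade 4 also the nearest slice of the TZ."""
    affected = np.zeros(masks.gland.shape, dtype=bool)
    pz_idx = np.flatnonzero(masks.pz.ravel())
    order = pz_idx[np.argsort(dist.ravel()[pz_idx], kind="stable")]
    npz = len(pz_idx)
    k = int(round(spec.pz_affected_fraction * npz))
    if spec.grade == 2:
        k = int(np.clip(k, 1, int(np.ceil(0.5 * npz)) - 1))
    elif spec.grade == 3:
        k = int(np.clip(k, int(np.ceil(0.5 * npz)), npz))
    else:  # grade 4: any PZ share, at least one voxel
        k = int(np.clip(k, 1, npz))
    affected.ravel()[order[:k]] = True
    if spec.grade == 4:
        tz_idx = np.flatnonzero(masks.tz.ravel())
        torder = tz_idx[np.argsort(dist.ravel()[tz_idx], kind="stable")]
        kt = max(1, int(0.2 * len(tz_idx)))
        affected.ravel()[torder[:kt]] = True
    return affected


def apply_visible_artifact(case: PhantomCase, spec: ArtifactSpec) -> PhantomCase:
    """Superimpose a graded rectal artifact; returns a new case.

    The perturbation is an alternating band pattern in distance-from-rectum,
    attenuated away from the rectum, plus smooth random signal pile-up, and is
    confined to the selected gland voxels. Channel intensities stay inside
    their configured ranges (clipping).
    """
    spec.validate()
    vol, masks = case.volume, case.masks
    if spec.grade == 1:
        out = replace(case, artifact=spec,
                      artifact_mask=np.zeros(vol.shape, dtype=bool))
        out.validate()
        return out
    dist = ndimage.distance_transform_edt(~masks.rectum, sampling=vol.spacing)
    affected = _affected_voxels(masks, spec, dist)
    rng = np.random.default_rng(spec.seed)
    band = np.sin(2.0 * np.pi * dist / spec.band_period)
    envelope = np.exp(-dist / 12.0)
    blob = ndimage.gaussian_filter(rng.normal(size=vol.shape), sigma=(0, 2, 2))
    blob = blob / max(np.abs(blob).max(), 1e-12)
    pattern = 0.7 * band * envelope + 0.3 * blob
    weights = {"t2w": 0.6, "dwi": 1.0, "adc": 0.8}
    new_channels = {}
    for name in CHANNELS:
        lo, hi = vol.ranges[name]
        img = vol.channel(name).copy()
        img[affected] += spec.amplitude * (hi - lo) * weights[name] \
            * pattern[affected]
        new_channels[name] = np.clip(img, lo, hi)
    out_vol = MultiModalVolume(new_channels["t2w"], new_channels["dwi"],
                               new_channels["adc"], vol.spacing,
                               dict(vol.ranges))
    out = replace(case, volume=out_vol, artifact=spec, artifact_mask=affected)
    out.validate()
    return out


def grade_artifact(case: PhantomCase) -> int:
    """Automated reading of the 4-point rectal-artifact scale from the
    artifact support mask and the zone masks."""
    npz = int(case.masks.pz.sum())
    if npz == 0:
        raise ValueError("empty PZ mask: cannot grade artifact")
    mask = case.artifact_mask
    if not mask.any():
        return 1
    if np.any(mask & case.masks.tz):
        return 4
    f = float((mask & case.masks.pz).sum()) / npz
    return 2 if f < 0.5 else 3


def generate_cohort(n: int, config: GenerationConfig, seed: int,
                    id_prefix: str = "case"
                    ) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate ``n`` cases and the accompanying manifest.

    The manifest has one row per case: ``case_id, label, grade, site``.
    Filtering it to ``grade == 1`` reproduces a clean, artifact-free testing
    set.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    root = np.random.SeedSequence([int(seed), 0x7A5])
    case_seeds = [int(s) for s in
                  root.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF]
    cases, rows = [], []
    for i, cs in enumerate(case_seeds):
        case = generate_case(config, cs, case_id=f"{id_prefix}_{i:04d}")
        cases.append(case)
        rows.append({"case_id": case.case_id,
                     "label": int(case.patient_label),
                     "grade": case.artifact.grade,
                     "site": case.site_tag})
    return cases, pd.DataFrame(rows)


def clean_subset(cases: list[PhantomCase]) -> list[PhantomCase]:
    """The artifact-free (grade 1) subset — the clean-testing-set analogue."""
    return [c for c in cases if c.artifact.grade == 1]


# ------------------------------------------------------------------------ I/O
def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # arrays are (z, y, x); NIfTI axes are (x, y, z)
    sz, sy, sx = spacing
    return np.diag([sx, sy, sz, 1.0])


def _save_grid(path, arr: np.ndarray, spacing, dtype) -> None:
    data = np.ascontiguousarray(arr.transpose(2, 1, 0).astype(dtype))
    nib.save(nib.Nifti1Image(data, _affine(spacing)), str(path))


def _load_grid(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    sx, sy, sz = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj).transpose(2, 1, 0), (float(sz), float(sy),
                                                        float(sx))

_MASKS = ("gland", "pz", "tz", "rectum")


def write_case(case: PhantomCase, directory) -> None:
    """Serialize a case: one NIfTI per channel (float) and per mask
    (unsigned int), plus a JSON sidecar with all metadata."""
    from pathlib import Path
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cid, sp = case.case_id, case.volume.spacing
    for name in CHANNELS:
        _save_grid(d / f"{cid}_{name}.nii.gz", case.volume.channel(name),
                   sp, np.float64)
    for name in _MASKS:
        _save_grid(d / f"{cid}_mask_{name}.nii.gz",
                   getattr(case.masks, name), sp, np.uint16)
    _save_grid(d / f"{cid}_mask_lesions.nii.gz", case.masks.lesions,
               sp, np.uint16)
    _save_grid(d / f"{cid}_mask_artifact.nii.gz", case.artifact_mask,
               sp, np.uint16)
    meta = {
        "case_id": cid,
        "spacing": list(sp),
        "ranges": {k: list(v) for k, v in case.volume.ranges.items()},
        "lesion_labels": {str(k): v for k, v in
                          case.masks.lesion_labels.items()},
        "artifact": {
            "grade": case.artifact.grade,
            "pz_affected_fraction": case.artifact.pz_affected_fraction,
            "tz_involved": case.artifact.tz_involved,
            "amplitude": case.artifact.amplitude,
            "band_period": case.artifact.band_period,
            "seed": case.artifact.seed,
        },
        "patient_label": bool(case.patient_label),
        "site_tag": case.site_tag,
    }
    (d / f"{cid}.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_case(directory, case_id: str) -> PhantomCase:
    """Inverse of :func:`write_case`; exact round-trip."""
    from pathlib import Path
    d = Path(directory)
    sidecar = d / f"{case_id}.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupt sidecar {sidecar}: {e}") from e
    grids, spacings = {}, []
    for name in CHANNELS:
        grids[name], sp = _load_grid(d / f"{case_id}_{name}.nii.gz")
        spacings.append(sp)
    for name in _MASKS + ("lesions", "artifact"):
        grids[name], sp = _load_grid(d / f"{case_id}_mask_{name}.nii.gz")
        spacings.append(sp)
    shapes = {g.shape for g in grids.values()}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among grids of {case_id}: {shapes}")
    spacing = tuple(meta["spacing"])
    vol = MultiModalVolume(
        grids["t2w"].astype(np.float64), grids["dwi"].astype(np.float64),
        grids["adc"].astype(np.float64), spacing,
        {k: tuple(v) for k, v in meta["ranges"].items()})
    masks = AnatomyMasks(
        grids["gland"].astype(bool), grids["pz"].astype(bool),
        grids["tz"].astype(bool), grids["rectum"].astype(bool),
        grids["lesions"].astype(np.int32),
        {int(k): v for k, v in meta["lesion_labels"].items()})
    a = meta["artifact"]
    spec = ArtifactSpec(a["grade"], a["pz_affected_fraction"],
                        a["tz_involved"], a["amplitude"], a["band_period"],
                        a["seed"])
    case = PhantomCase(case_id, vol, masks, spec,
                       grids["artifact"].astype(bool),
                       bool(meta["patient_label"]), meta["site_tag"])
    case.validate()
    return case


def cases_equal(a: PhantomCase, b: PhantomCase) -> bool:
    if a.case_id != b.case_id or a.patient_label != b.patient_label \
            or a.site_tag != b.site_tag or a.artifact != b.artifact \
            or a.masks.lesion_labels != b.masks.lesion_labels:
        return False
    for name in CHANNELS:
        if not np.array_equal(a.volume.channel(name), b.volume.channel(name)):
            return False
    for name in _MASKS + ("lesions",):
        if not np.array_equal(getattr(a.masks, name), getattr(b.masks, name)):
            return False
    return np.array_equal(a.artifact_mask, b.artifact_mask)
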