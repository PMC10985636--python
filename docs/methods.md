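# Methods

This note documents the models, algorithms and numerical choices behind
`tpas`: a desk-scale, fully reproducible implementation of targeted
adversarial training against rectal-artifact-patterned noise in
biparametric prostate MRI (bpMRI) lesion detection, together with the
synthetic cohorts and the statistical machinery used to evaluate it.

## The problem being modelled

Rectal susceptibility artifacts — signal distortions caused by gas/stool
near the prostate — degrade the peripheral zone (PZ) on T2-weighted and
diffusion-weighted images and can mislead deep-learning detectors of
clinically significant prostate cancer (csPCa). Worse, *imperceptible*
perturbations with the same texture statistics can do the same. The
defense studied here generates bounded, artifact-styled adversarial noise
against the current detector and mixes the perturbed cases into training,
alternating noise generation with parameter updates.

Everything runs on synthetic phantoms: no clinical data, no pretrained
weights, no GPU. The package therefore demonstrates the *mechanics and
direction* of the method, not clinical performance numbers.

## Synthetic phantoms (`tpas.phantom`)

A phantom patient is a small aligned multi-channel volume (default
1×64×64 voxels at 3.0×0.5×0.5 mm; arrays indexed `(z, y, x)` with `y`
increasing towards posterior):

* **Anatomy** — axis-aligned ellipsoidal gland; inner ellipsoid =
  transition zone (TZ), remainder = peripheral zone (PZ); a posterior
  rectal tube separated from the gland by a ~2-voxel gap. PZ ∪ TZ
  partitions the gland exactly; rectum and gland are disjoint.
* **Channels** — T2W, high-b DWI and ADC rendered from per-compartment
  mean intensities plus i.i.d. Gaussian noise (σ = 40/32/120 intensity
  units on ranges 0–1000 / 0–800 / 0–3000), clipped to the channel range.
* **Lesions** — 0–2 ellipsoidal PZ-seeded lesions of radius 1.5–3 mm.
  A patient is csPCa-positive with probability `cspca_prevalence`
  (default 0.5, a case-control style prevalence); positive patients carry
  ≥ 1 csPCa lesion. csPCa lesions show the canonical contrast pattern
  (T2W↓, DWI↑, ADC↓) at a margin of 3 noise σ per channel — large enough
  for a small model to learn, small enough not to be voxel-wise trivial.
  Benign lesions show the same pattern at half margin and act as
  distractors (they are labelled background for the detector).
* **Artifacts** — severity follows the clinical 4-point scale:
  1 none; 2 mild (< 50 % of PZ); 3 moderate (50–100 % of PZ, TZ spared);
  4 severe (extends into TZ). The forward model is a stand-in (no
  quantitative artifact morphology is published for this grading): an
  alternating band pattern in distance-from-rectum (period 3–7 mm,
  exponential envelope, 12 mm decay) plus smooth random signal pile-up,
  applied to the k PZ voxels nearest the rectum where k realizes the
  requested PZ fraction (plus the nearest 20 % of TZ voxels for grade 4),
  scaled per channel (DWI 1.0, ADC 0.8, T2W 0.6 of the amplitude) and
  clipped to the channel range. The automated grader recomputes the grade
  from the artifact support and the zone masks, and agrees with the
  generator by construction — including at the 50 % boundary, where the
  affected-voxel count is clamped away from the wrong side.

Everything is bit-deterministic under `(config, seed)`; cohort case seeds
derive from a `SeedSequence` of the cohort seed. Cases serialize to
NIfTI (float channels, unsigned-integer masks, affine from the voxel
spacing) plus a JSON sidecar, with exact round-trip.

What the phantoms deliberately do **not** model: MR physics (no Bloch or
k-space simulation), inter-sequence misregistration, anatomical
variability beyond ellipsoid jitter, scanner/site effects (the `site`
tag exists for the reporting machinery but all synthetic cases share one
site). Passing results show the training strategy behaves as described
on separable data; they say nothing about clinical accuracy.

## The two-stage detector (`tpas.nn`, `tpas.model`)

The study-scale backbone this emulates is a self-configuring 3D U-Net;
here it is a two-level 2D U-Net (width 8, ~9k parameters) applied
slice-wise, because the object under test is the *training strategy*.
Networks, losses and input-gradients run on a small reverse-mode
autodiff engine over numpy (`tpas.autodiff`); convolution gradients are
verified against central finite differences in the test suite.

* **Stage 1 (zone segmentation)** — T2W → 3-class voxel map
  (background/PZ/TZ); loss = cross-entropy + mean foreground soft-Dice.
* **Stage 2 (lesion detection)** — five input planes (T2W, ADC, DWI and
  the *predicted* TZ and PZ masks, binarized by arg-max) → sigmoid csPCa
  confidence in [0, 1]; supervision = union of csPCa lesion voxels;
  loss = soft-Dice + BCE with a positive-voxel weight (`pos_weight`,
  default 10). The weight is essential at this scale: lesions occupy
  ~1 % of the grid and the unweighted loss has a strong all-background
  basin (loss ≈ 1, empty predictions).
* **Training** — mini-batch Adam (lr 2·10⁻³, batch 8), shuffled by a
  dedicated generator; bit-deterministic under the seed. Checkpoints are
  single `.npz` files embedding the config, the seed, and the upstream
  zone model, with exact round-trip.
* **Model selection** — generic k-fold cross-validation
  (`crossval_select`, default k = 5) with selection by highest
  validation patient-level AUC (the selection metric was an open choice;
  patient-level AUC matches the reporting focus).

Patient-level post-processing (`tpas.postproc`): candidates are
face-connected components of {confidence ≥ 0.45} (the working point) of
size ≥ 2; candidate probability = max confidence over the component;
patient score = max candidate probability (0 if none). A candidate is a
true positive when its overlap with a csPCa ground-truth lesion reaches
0.10, with overlap pinned to IoU (intersection-over-ground-truth is
available by flag); matching is greedy in descending candidate
probability, each lesion matched at most once.

## Artifact-styled adversarial noise (`tpas.advnoise`)

Per case, a per-channel noise field δ (T2W/ADC/DWI, in normalized units)
is optimized under the composite objective

    J(δ) = λ_style · style + λ_content · content − λ_adv · task

* **style** — Σ over style layers of squared distance between Gram
  matrices G = F·Fᵀ/(H·W) of a frozen extractor's features, between the
  perturbed image and a severe-artifact exemplar;
* **content** — Σ over content layers of mean squared feature
  difference from the original image;
* **task** — the detector's own training loss (Dice + weighted BCE) at
  the perturbed input; zone masks are re-predicted from the perturbed
  T2W each iteration (no gradient through the discrete arg-max).

Optimization is signed-gradient descent (PGD-style): T = 10 steps of
size α = 0.004, each followed by projection onto |δ| ≤ ε (ε = 0.02 of
the channel range — the "invisible" regime) and restriction to the body
support; the composed image is clipped to the original's per-channel
min/max, so the attacked image's bounds never exceed the original's
(assertable exactly). The returned δ is the best-objective iterate whose
style distance does not exceed the δ = 0 baseline; δ = 0 is always
admissible, so the returned noise never moves away from the artifact
style and never has a worse objective than no noise.

The extractor is a small frozen convolutional stack (3→8→16→16→16
channels; style layers = the two shallow blocks, content layer = the
deepest block) with deterministic seeded weights. Random shallow
convolutional features are an adequate basis for Gram texture statistics
at this scale, and the extractor is pluggable. The loss weights default
to λ_style = 200, λ_content = 100, λ_adv = 1 — chosen by magnitude
matching (Gram distances are O(10⁻³) and content distances O(10⁻⁵) on
these images, against a task loss of O(1)), the same reasoning that
leads classical neural style transfer to large style weights. With small
style weights the style term is numerically inert.

## Alternating adversarial training (`tpas.advtrain`)

The defended detector trains on the clean stream plus an adversarial
pool. After a warmup (4 epochs), the pool is regenerated against the
*current* model at the end of every complete refresh block (every 4
epochs), giving exactly ⌊(epochs − warmup)/R⌋ regenerations; between
regenerations the pool is reused. Each epoch the pool (a `mix_fraction`
= 0.5 share of the cohort, re-sampled per regeneration from a dedicated
generator) is appended to the shuffled clean stream. The control is the
identical pipeline at `mix_fraction` = 0 — same initialization, same
clean stream under the same seed (verified by stream hashing), so the
runs differ only in the adversarial additions. Adversarial samples are
only ever generated from training cases.

## Evaluation (`tpas.evalstats`)

* **Patient level** — Mann–Whitney AUC (exact midrank arithmetic; equal
  to rational pair counting bit-for-bit). Correlated AUCs are compared
  with DeLong's structural-components test (two-sided normal
  approximation; degenerate variance with equal scores reports p = 1,
  otherwise NaN). Variance is validated against a jackknife oracle and
  the p-value against a paired permutation oracle; type-I error is
  calibrated in simulation.
* **Lesion level** — candidates pooled over the cohort, sorted by
  probability (stable tie-break on case and candidate id); AUPRC =
  average precision with step interpolation, recall denominator = all
  ground-truth csPCa lesions; missed lesions enter only through that
  denominator. Between-model AUPRC differences use a paired
  patient-level bootstrap (patients resampled with replacement, both
  models evaluated on the same resample; percentile CI; two-sided p from
  the bootstrap distribution; B = 500 in the benchmark config).
* **Segmentation** — Dice of {confidence ≥ 0.45} against the csPCa
  ground truth, reported mean ± SD over csPCa-positive cases; the
  both-empty convention is 1.0 and is flagged where it can occur.
* **Reader agreement** — Cohen weighted κ with linear weights by default
  (quadratic by flag; the weighting scheme is not fixed by convention in
  the 4-point-scale literature).
* **Subgroups** — per-grade and per-site AUC/AUPRC tables; single-class
  strata are reported as NA, never dropped.

## The benchmark protocol (`tpas.benchmark`)

The pinned experiment (shipped config, global seed 1): 60 mixed-severity
training phantoms, 80 artifact-free testing phantoms; one shared zone
segmenter; control and defended detectors trained on the identical clean
stream; the testing cohort perturbed with imperceptible artifact-styled
noise; paired evaluation with DeLong and bootstrap contrasts. Two runs
of the same config are byte-identical (hash-manifested outputs; every
stage seed derives from the global seed and the operation path).

**Attack target.** Each detector is evaluated on noise optimized against
*it* (per-model white-box attacks). A single shared attacked cohort
(crafted against the control) is supported — `compare_models` takes one
attacked cohort by default — but is not used for the headline benchmark:
because the two detectors share initialization and clean stream by
design, noise crafted on one transfers essentially undiminished to its
twin, and the shared-cohort protocol then measures transfer between
near-identical models rather than each model's resilience to worst-case
artifact-styled interference, which is the question the experiment asks.

Problem sizes (60/80 cases, 20 epochs, T = 10 attack iterations,
B = 500 bootstrap resamples) are the package's desk-scale operating
point: large enough for the effect direction to be stable at the pinned
seed, small enough that the whole experiment runs in minutes on one CPU.

## Known limitations

* The artifact forward model and the severity-conditional geometry are
  stand-ins; no claim of radiological realism is made.
* Desk-scale training of ~10⁴-parameter networks is basin-sensitive:
  the defended-vs-control ordering is verified at the pinned benchmark
  and is noisy across other seeds and scales; an over-trained zone
  segmenter can push a subsequent detector run into the all-background
  basin. The `pos_weight` term mitigates but does not remove this.
* The 2D slice mode is the default and the only extensively exercised
  path; multi-slice volumes are supported by slice-wise application.
* Reported numbers are synthetic-benchmark quantities; they are not
  comparable to clinical AUC/AUPRC values.
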