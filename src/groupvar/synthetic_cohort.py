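"""Synthetic cohorts of pre-segmented brain-like tissue phantoms.

Real morphometry cohorts cannot ship with the package, so experiments run
on phantoms that reproduce the *statistical structure* the sensitivity
analysis needs: each subject is a set of GM/WM/CSF concentration maps with

* a shared gross anatomy — a central CSF "ventricle", a WM body and an
  outer cortical GM ribbon;
* subject-unique cortical folding, realised as seeded sinusoidal
  perturbations of the ribbon boundary (each subject's gyral pattern is
  unique, which is precisely the feature group templates wash out);
* age-dependent morphology — the ribbon thins linearly with age and the
  ventricle dilates, emulating cortical atrophy over ~10-29 years;
* an optional diagnosis effect — localized additive GM concentration
  deltas at fixed loci (with small per-subject positional jitter) for the
  case group;
* a small random affine jitter and a mild partial-volume blur so maps have
  soft edges rather than binary masks.

Everything is deterministic given ``(age, diagnosis, seed, params)``; the
cohort generator derives per-subject seeds from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    CardinalityError,
    DegenerateGeometryError,
    Diagnosis,
    ParameterError,
    SubjectRecord,
    TissueMapSet,
)

__all__ = ["CohortParams", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class CohortParams:
    """Configuration of the phantom generator and cohort layout.

    Length-like quantities are in voxels, ages in years.  The default
    magnitudes of the age and diagnosis effects are calibrated once so that
    variability summaries from the resampling experiments land in the
    0.01-0.05 concentration range typical of template-driven pipelines;
    they are configuration values, not constants.
    """

    grid_shape: tuple[int, ...] = (96, 96)
    spacing: tuple[float, ...] = (1.0, 1.0)

    # cohort layout
    n_tdc: int = 24
    n_asd: int = 24
    n_extension: int = 33  # older TDCs enabling the sliding-age protocol
    age_min: float = 10.5
    age_max: float = 14.8
    extension_age_min: float = 11.0
    extension_age_max: float = 29.0
    asd_age_jitter: float = 0.3  # |ASD age - matched TDC age| bound, years

    # base geometry (voxels, at the reference age ``age_min``)
    brain_radius_frac: float = 0.38  # of the smallest grid axis
    base_ribbon_thickness: float = 7.0
    base_ventricle_radius: float = 5.0

    # age effects (voxels / year)
    age_atrophy_rate: float = 0.12
    ventricle_growth_rate: float = 0.18

    # subject-unique folding of the ribbon boundary
    folding_amplitude: tuple[float, float] = (1.5, 3.0)
    folding_frequency: tuple[int, int] = (5, 9)

    # diagnosis effect: additive GM deltas at fixed mid-ribbon loci
    diagnosis_effect_size: float = 0.15
    diagnosis_loci_deg: tuple[float, ...] = (40.0, 220.0)
    diagnosis_locus_sigma: float = 1.5
    diagnosis_locus_jitter: float = 1.0  # voxels, per-subject positional

    # whole-phantom affine jitter
    affine_rotation_deg: float = 2.0
    affine_translation_vox: float = 1.0
    affine_scale_frac: float = 0.02

    pv_blur_sigma: float = 0.8  # partial-volume edge blur, voxels

    master_seed: int = 0

    def overall_age_range(self) -> tuple[float, float]:
        return (min(self.age_min, self.extension_age_min),
                max(self.age_max, self.extension_age_max))


def _radial_coords(shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Radius and in-plane angle of every voxel about the grid centre.

    For 3-D grids the angle is taken in the first two axes; the radius is
    the full Euclidean distance, so the phantom is a folded spheroid.
    """
    center = [(n - 1) / 2.0 for n in shape]
    axes = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    deltas = [ax - c for ax, c in zip(axes, center)]
    r = np.sqrt(sum(d * d for d in deltas))
    theta = np.arctan2(deltas[1], deltas[0])
    return r, theta


def _affine_jitter_matrix(ndim: int, rng: np.random.Generator,
                          params: CohortParams) -> tuple[np.ndarray, np.ndarray]:
    """Small random rotation+scale matrix and translation (voxel units)."""
    angle = np.deg2rad(rng.uniform(-params.affine_rotation_deg,
                                   params.affine_rotation_deg))
    scale = 1.0 + rng.uniform(-params.affine_scale_frac, params.affine_scale_frac)
    mat = np.eye(ndim)
    c, s = np.cos(angle), np.sin(angle)
    mat[0, 0], mat[0, 1] = c, -s
    mat[1, 0], mat[1, 1] = s, c
    mat *= scale
    shift = rng.uniform(-params.affine_translation_vox,
                        params.affine_translation_vox, size=ndim)
    return mat, shift


def _apply_affine(arr: np.ndarray, mat: np.ndarray, shift: np.ndarray) -> np.ndarray:
    center = (np.asarray(arr.shape, dtype=float) - 1) / 2.0
    offset = center - mat @ center + shift
    return ndimage.affine_transform(arr, mat, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def generate_subject(age: float, diagnosis: Diagnosis | str, seed: int,
                     params: CohortParams | None = None) -> SubjectRecord:
    """Generate one phantom subject.

    Deterministic given ``(age, diagnosis, seed, params)``.  Independent
    random substreams are used for folding, affine jitter and the diagnosis
    loci so that a TDC/ASD pair sharing a seed differs *only* by the
    diagnosis effect.
    """
    params = params or CohortParams()
    diagnosis = Diagnosis(diagnosis)
    lo, hi = params.overall_age_range()
    if not (lo <= age <= hi):
        raise ParameterError(f"age {age} outside generator range [{lo}, {hi}]")
    if seed < 0:
        raise ParameterError("seed must be non-negative")

    thickness = params.base_ribbon_thickness - params.age_atrophy_rate * (age - params.age_min)
    if thickness <= 0:
        raise DegenerateGeometryError("ribbon thickness <= 0 at this age")
    vent_r = params.base_ventricle_radius + params.ventricle_growth_rate * (age - params.age_min)

    shape = params.grid_shape
    ndim = len(shape)
    rng_fold = np.random.default_rng([seed, 0])
    rng_affine = np.random.default_rng([seed, 1])
    rng_diag = np.random.default_rng([seed, 2])

    r, theta = _radial_coords(shape)
    base_r = params.brain_radius_frac * min(shape)

    amp = rng_fold.uniform(*params.folding_amplitude)
    freq = int(rng_fold.integers(params.folding_frequency[0],
                                 params.folding_frequency[1] + 1))
    phase = rng_fold.uniform(0, 2 * np.pi)
    freq2 = int(rng_fold.integers(params.folding_frequency[0],
                                  params.folding_frequency[1] + 1))
    phase2 = rng_fold.uniform(0, 2 * np.pi)
    fold = amp * np.sin(freq * theta + phase) + 0.5 * amp * np.sin(freq2 * theta + phase2)

    outer_r = base_r + fold
    inner_r = outer_r - thickness
    if np.any(inner_r <= vent_r):
        raise DegenerateGeometryError("GM ribbon overlaps the ventricle")

    gm = ((r >= inner_r) & (r < outer_r)).astype(float)
    wm = ((r >= vent_r) & (r < inner_r)).astype(float)
    csf = (r < vent_r).astype(float)

    # Diagnosis effect: additive GM deltas at fixed mid-ribbon loci with
    # small positional jitter.  The jitter stream is consumed regardless of
    # diagnosis so TDC/ASD phantoms with equal seed stay voxel-aligned.
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    for k, ang_deg in enumerate(params.diagnosis_loci_deg):
        jit = rng_diag.uniform(-params.diagnosis_locus_jitter,
                               params.diagnosis_locus_jitter, size=ndim)
        if diagnosis is not Diagnosis.ASD or params.diagnosis_effect_size == 0:
            continue
        ang = np.deg2rad(ang_deg)
        # Loci sit on the inner GM/WM interface: concentration differences
        # at tissue boundaries are what boundary-driven registration (and
        # hence the downstream experiments) can actually respond to; a
        # delta in the flat ribbon interior is invisible to any
        # gradient-based matching term.
        edge_r = base_r - thickness
        locus = center.copy()
        locus[0] += edge_r * np.cos(ang)
        locus[1] += edge_r * np.sin(ang)
        locus += jit
        axes = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        d2 = sum((ax - c) ** 2 for ax, c in zip(axes, locus))
        sigma2 = params.diagnosis_locus_sigma ** 2
        # Truncated at 3 sigma so the effect stays focal.  Deltas are
        # negative (localized GM reduction in the case group): positive
        # deltas inside the near-saturated ribbon would be clipped away.
        blob = np.where(d2 <= 9 * sigma2, np.exp(-d2 / (2 * sigma2)), 0.0)
        gm = gm - params.diagnosis_effect_size * blob

    mat, shift = _affine_jitter_matrix(ndim, rng_affine, params)
    gm = _apply_affine(gm, mat, shift)
    wm = _apply_affine(wm, mat, shift)
    csf = _apply_affine(csf, mat, shift)

    sig = params.pv_blur_sigma
    if sig > 0:
        gm = ndimage.gaussian_filter(gm, sig)
        wm = ndimage.gaussian_filter(wm, sig)
        csf = ndimage.gaussian_filter(csf, sig)

    gm = np.clip(gm, 0.0, 1.0)
    wm = np.clip(wm, 0.0, 1.0)
    csf = np.clip(csf, 0.0, 1.0)
    total = gm + wm + csf
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-12), 1.0)
    gm, wm, csf = gm * scale, wm * scale, csf * scale

    maps = TissueMapSet(gm=gm, wm=wm, csf=csf, spacing=params.spacing)
    maps.validate()
    sid = f"{'ASD' if diagnosis is Diagnosis.ASD else 'TDC'}-a{age:05.2f}-s{seed}"
    return SubjectRecord(subject_id=sid, age=float(age), diagnosis=diagnosis,
                         seed=int(seed), maps=maps)


def _subject_seed(master_seed: int, index: int) -> int:
    """Stable per-subject seed below 2**31 derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2 ** 31))


@dataclass
class Cohort:
    """A generated cohort plus its age-matched TDC/ASD pairing."""

    subjects: list[SubjectRecord] = field(default_factory=list)
    params: CohortParams = field(default_factory=CohortParams)

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def by_id(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def group(self, diagnosis: Diagnosis | str) -> list[SubjectRecord]:
        diagnosis = Diagnosis(diagnosis)
        return [s for s in self.subjects if s.diagnosis is diagnosis]


def generate_cohort(params: CohortParams | None = None) -> Cohort:
    """Generate the full study cohort from a single master seed.

    The default configuration produces 24 TDC and 24 ASD subjects in the
    core 10.5-14.8 year band (ASD ages jittered off their matched TDC's by
    at most ``asd_age_jitter`` years, so nearest-age pairing recovers the
    match), plus an extension pool of older TDCs up to
    ``extension_age_max`` years for the sliding-age protocol.
    """
    params = params or CohortParams()
    n_total = params.n_tdc + params.n_asd + params.n_extension
    if n_total < 1:
        raise CardinalityError("cohort must contain at least one subject")

    rng = np.random.default_rng(params.master_seed)
    tdc_ages = np.sort(rng.uniform(params.age_min, params.age_max, size=params.n_tdc))
    if params.n_asd:
        base = tdc_ages[: params.n_asd]
        if params.n_asd > params.n_tdc:
            extra = rng.uniform(params.age_min, params.age_max,
                                size=params.n_asd - params.n_tdc)
            base = np.concatenate([base, extra])
        asd_ages = np.clip(
            base + rng.uniform(-params.asd_age_jitter, params.asd_age_jitter,
                               size=params.n_asd),
            params.age_min, params.age_max)
    else:
        asd_ages = np.array([])
    ext_ages = np.sort(rng.uniform(params.extension_age_min, params.extension_age_max,
                                   size=params.n_extension)) if params.n_extension else np.array([])

    subjects: list[SubjectRecord] = []
    idx = 0

    def _make(age: float, diagnosis: Diagnosis, label: str) -> SubjectRecord:
        nonlocal idx
        seed = _subject_seed(params.master_seed, idx)
        rec = generate_subject(age, diagnosis, seed, params)
        rec = SubjectRecord(subject_id=label, age=rec.age, diagnosis=rec.diagnosis,
                            seed=rec.seed, maps=rec.maps)
        idx += 1
        return rec

    for i, age in enumerate(tdc_ages):
        subjects.append(_make(float(age), Diagnosis.TDC, f"TDC{i + 1:02d}"))
    for i, age in enumerate(asd_ages):
        subjects.append(_make(float(age), Diagnosis.ASD, f"ASD{i + 1:02d}"))
    for i, age in enumerate(ext_ages):
        subjects.append(_make(float(age), Diagnosis.TDC, f"TDCX{i + 1:02d}"))

    return Cohort(subjects=subjects, params=params)
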