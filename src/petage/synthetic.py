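"""Seeded synthetic FDG-PET-like cohorts with the statistical structure the
analysis assumes.

The generator emulates what the pipeline needs from a real resting-state
FDG-PET study: a common voxel grid, an integer parcellation, a designated set
of "aging" regions whose intensity declines linearly with age, a reference
region that is metabolically flat across age, an optional disease group with
additional regional hypometabolism scaled by a per-subject severity, additive
Gaussian voxel noise (optionally spatially smoothed), and clinical scores tied
to the disease severity. It does NOT simulate PET physics (attenuation,
scatter, reconstruction) or anatomy; regions are rectangular parcels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .volumes import (
    Cohort,
    LabelAtlas,
    Mask,
    RegionInfo,
    SubjectRecord,
    Volume,
    VolumeGrid,
    gaussian_smooth,
    region_mask,
)

__all__ = [
    "RegionBox",
    "ClinicalLink",
    "GeneratorSpec",
    "CohortTruth",
    "default_region_boxes",
    "make_atlas",
    "make_cohort",
    "make_ic_voxelvalue_map",
    "make_sweep_phantom",
    "DEFAULT_AGING_IDS",
    "DEFAULT_REFERENCE_IDS",
    "DEFAULT_AD_IDS",
]

#: AAL-style ids used by the default block atlas. The aging set mirrors the
#: parcels where metabolic decline with age is typically reported (inferior
#: orbital frontal, medial frontal, insula, cingulate, superior temporal
#: poles); 69/70 is the paracentral lobule used as the SUVR reference.
DEFAULT_AGING_IDS = frozenset({15, 16, 23, 25, 30, 31, 33, 83, 84})
DEFAULT_REFERENCE_IDS = frozenset({69, 70})
DEFAULT_AD_IDS = frozenset({31, 83, 84, 89, 90})

#: Decade counts of the 255-subject healthy discovery cohort (ages 20-80)
#: used by the "decades" age-sampling mode.
DECADE_BINS = ((20, 30), (31, 40), (41, 50), (51, 60), (61, 70), (71, 80))
DECADE_COUNTS = (44, 44, 42, 45, 50, 30)


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned voxel box [lo, hi) carrying one atlas region."""

    region_id: int
    name: str
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    is_reference_candidate: bool = False


def default_region_boxes(grid: VolumeGrid) -> list[RegionBox]:
    """Block parcellation: the grid is split into a 4 x 5 x 4 cell lattice and
    named regions occupy single cells (left/right pairs mirrored in x)."""
    nx, ny, nz = grid.shape
    cx, cy, cz = nx // 4, ny // 5, nz // 4
    if min(cx, cy, cz) < 2:
        raise ValueError(f"grid {grid.shape} too small for the default atlas")

    def cell(i: int, j: int, k: int) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        return (i * cx, j * cy, k * cz), ((i + 1) * cx, (j + 1) * cy, (k + 1) * cz)

    layout = [
        # aging set (metabolic decline with age)
        (15, "Frontal_Inf_Orb_L", (1, 4, 1), False),
        (16, "Frontal_Inf_Orb_R", (2, 4, 1), False),
        (23, "Frontal_Sup_Medial_L", (1, 4, 3), False),
        (25, "Frontal_Med_Orb_L", (1, 4, 2), False),
        (30, "Insula_R", (2, 2, 1), False),
        (31, "Cingulum_Ant_L", (1, 3, 2), False),
        (33, "Cingulum_Mid_L", (1, 2, 2), False),
        (83, "Temporal_Pole_Sup_L", (0, 3, 1), False),
        (84, "Temporal_Pole_Sup_R", (3, 3, 1), False),
        # reference candidates
        (69, "Paracentral_Lobule_L", (1, 1, 3), True),
        (70, "Paracentral_Lobule_R", (2, 1, 3), True),
        (91, "Cerebelum_Crus1_L", (0, 1, 0), True),
        (92, "Cerebelum_Crus1_R", (3, 1, 0), True),
        (105, "Cerebellar_Tonsil_L", (1, 0, 0), True),
        (106, "Cerebellar_Tonsil_R", (2, 0, 0), True),
        # age-flat filler parcels
        (43, "Calcarine_L", (1, 0, 1), False),
        (44, "Calcarine_R", (2, 0, 1), False),
        (57, "Postcentral_L", (1, 2, 3), False),
        (58, "Postcentral_R", (2, 2, 3), False),
        (89, "Temporal_Inf_L", (0, 2, 1), False),
        (90, "Temporal_Inf_R", (3, 2, 1), False),
    ]
    boxes = []
    for rid, name, (i, j, k), ref in layout:
        lo, hi = cell(i, j, k)
        boxes.append(RegionBox(rid, name, lo, hi, ref))
    return boxes


@dataclass(frozen=True)
class ClinicalLink:
    """Linear links from per-subject disease severity s (HC: s=0, AD: s~N(1, sd))
    to clinical scores, calibrated so HC/AD marginal means echo typical values
    (MMSE 29.0 vs 23.2; CDRSB 0.0 vs 4.1; meta-ROI FDG 1.3 vs 1.1)."""

    mmse_intercept: float = 29.0
    mmse_slope: float = 5.8
    mmse_sd: float = 1.0
    cdrsb_slope: float = 4.1
    cdrsb_sd: float = 0.6
    fdg_intercept: float = 1.3
    fdg_slope: float = 0.2
    fdg_sd: float = 0.05
    severity_sd: float = 0.25


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic cohort generator.

    Defaults are the discovery-cohort conditions: 255 healthy subjects, ages
    20-80, a linear decline of -0.004 intensity units per year in the aging
    regions, additive voxel noise of sd 0.05 (intensity units; baseline 1.0),
    and an age-flat reference region.
    """

    n_subjects: int = 255
    age_range: tuple[float, float] = (20.0, 80.0)
    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid((32, 40, 32), (4.0, 4.0, 4.0)))
    region_boxes: tuple[RegionBox, ...] | None = None  # None -> default atlas
    aging_region_ids: frozenset[int] = DEFAULT_AGING_IDS
    reference_region_ids: frozenset[int] = DEFAULT_REFERENCE_IDS
    ad_region_ids: frozenset[int] = DEFAULT_AD_IDS
    decline_per_year: float = -0.004
    baseline: float = 1.0
    ad_fraction: float = 0.0
    ad_deficit: float = 0.08
    noise_sd: float = 0.05
    regional_noise_sd: float = 0.0
    smooth_fwhm_mm: float = 0.0
    global_scale_sd: float = 0.0
    age_sampling: str = "uniform"  # or "decades"
    with_clinical: bool = True
    clinical_link: ClinicalLink = field(default_factory=ClinicalLink)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.ad_fraction <= 1.0:
            raise ValueError("ad_fraction must be in [0, 1]")
        if set(self.aging_region_ids) & set(self.reference_region_ids):
            raise ValueError("aging and reference region sets must be disjoint")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (lo, hi) with lo <= hi")
        if self.age_sampling not in ("uniform", "decades"):
            raise ValueError(f"unknown age_sampling mode {self.age_sampling!r}")
        object.__setattr__(self, "aging_region_ids", frozenset(int(i) for i in self.aging_region_ids))
        object.__setattr__(self, "reference_region_ids",
                           frozenset(int(i) for i in self.reference_region_ids))
        object.__setattr__(self, "ad_region_ids", frozenset(int(i) for i in self.ad_region_ids))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {"shape": list(self.grid.shape), "spacing_mm": list(self.grid.spacing_mm)}
        for key in ("aging_region_ids", "reference_region_ids", "ad_region_ids"):
            d[key] = sorted(d[key])
        if self.region_boxes is not None:
            d["region_boxes"] = [dataclasses.asdict(b) for b in self.region_boxes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = VolumeGrid(tuple(d["grid"]["shape"]), tuple(d["grid"]["spacing_mm"]))
        for key in ("aging_region_ids", "reference_region_ids", "ad_region_ids"):
            if key in d:
                d[key] = frozenset(d[key])
        if d.get("region_boxes") is not None:
            d["region_boxes"] = tuple(
                RegionBox(b["region_id"], b["name"], tuple(b["lo"]), tuple(b["hi"]),
                          bool(b.get("is_reference_candidate", False)))
                for b in d["region_boxes"]
            )
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "clinical_link" in d and isinstance(d["clinical_link"], dict):
            d["clinical_link"] = ClinicalLink(**d["clinical_link"])
        return cls(**d)


@dataclass
class CohortTruth:
    """Generator ground truth kept alongside a cohort for validation."""

    atlas: LabelAtlas
    aging_mask: Mask
    reference_mask: Mask
    ad_mask: Mask
    severity: np.ndarray  # per subject, 0 for HC


def make_atlas(spec: GeneratorSpec) -> LabelAtlas:
    """Deterministic block-parcellation atlas for the spec's grid."""
    boxes = list(spec.region_boxes) if spec.region_boxes is not None \
        else default_region_boxes(spec.grid)
    labels = np.zeros(spec.grid.shape, dtype=np.int32)
    for b in boxes:
        lo, hi = b.lo, b.hi
        if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, spec.grid.shape)) \
                or any(h <= l for l, h in zip(lo, hi)):
            raise ValueError(f"region {b.region_id} extent {lo}..{hi} does not fit grid")
        block = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if np.any(block != 0):
            raise ValueError(f"region {b.region_id} overlaps a previously placed region")
        block[...] = b.region_id
    regions = [RegionInfo(b.region_id, b.name, b.is_reference_candidate) for b in boxes]
    return LabelAtlas(spec.grid, labels, regions)


def _sample_ages(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.age_range
    if spec.age_sampling == "uniform":
        return rng.uniform(lo, hi, size=spec.n_subjects)
    # decade quotas, rescaled to n_subjects and clipped to age_range
    counts = np.array(DECADE_COUNTS, dtype=float)
    quota = np.floor(counts / counts.sum() * spec.n_subjects).astype(int)
    while quota.sum() < spec.n_subjects:  # distribute the remainder
        quota[int(np.argmax(counts / counts.sum() * spec.n_subjects - quota))] += 1
    ages = []
    for (b_lo, b_hi), q in zip(DECADE_BINS, quota):
        ages.append(rng.uniform(max(b_lo, lo), min(b_hi, hi), size=q))
    ages = np.concatenate(ages)
    return rng.permutation(ages)


_EDU = {"HC": (16.3, 2.7), "AD": (15.1, 3.0)}
_APOE4_P = {"HC": (0.72, 0.26, 0.02), "AD": (0.25, 0.50, 0.25)}


def make_cohort(spec: GeneratorSpec, return_truth: bool = False):
    """Generate a seeded cohort (subject table + image stack).

    Image model per subject i with age a_i (intensity units, baseline 1.0):

    * background voxels 0, brain voxels ``baseline``
    * aging regions: + decline_per_year * a_i
    * AD subjects: - ad_deficit * severity_i in ad regions
    * i.i.d. N(0, noise_sd) noise everywhere, optionally smoothed
    * optional per-subject, per-region N(0, regional_noise_sd) offsets
      (biological between-subject variability that does not average out
      over voxels, unlike the i.i.d. term)
    * optional per-subject global scale factor (multiplicative)
    """
    if spec.n_subjects < 3:
        raise ValueError("need at least 3 subjects (correlation undefined below that)")
    rng = np.random.default_rng(spec.seed)
    atlas = make_atlas(spec)
    aging = region_mask(atlas, spec.aging_region_ids)
    ref = region_mask(atlas, spec.reference_region_ids)
    admask = region_mask(atlas, spec.ad_region_ids) if spec.ad_region_ids \
        else Mask(spec.grid, np.zeros(spec.grid.shape, dtype=bool))
    brain = atlas.brain_mask()

    n = spec.n_subjects
    ages = _sample_ages(spec, rng)
    n_ad = int(round(spec.ad_fraction * n))
    is_ad = np.zeros(n, dtype=bool)
    is_ad[rng.permutation(n)[:n_ad]] = True
    sex = np.where(rng.random(n) < 0.5, "M", "F")

    link = spec.clinical_link
    severity = np.zeros(n)
    if n_ad:
        severity[is_ad] = np.clip(rng.normal(1.0, link.severity_sd, size=n_ad), 0.2, None)

    stack = np.zeros((n, *spec.grid.shape))
    base = np.where(brain.indicator, spec.baseline, 0.0)
    for i in range(n):
        img = base.copy()
        img[aging.indicator] += spec.decline_per_year * ages[i]
        if is_ad[i]:
            img[admask.indicator] -= spec.ad_deficit * severity[i]
        stack[i] = img
    noise = rng.normal(0.0, spec.noise_sd, size=stack.shape) if spec.noise_sd > 0 else 0.0
    stack = stack + noise
    if spec.regional_noise_sd > 0:
        labels = atlas.labels.ravel()
        uniq = np.unique(labels)
        region_index = np.searchsorted(uniq, labels)  # 0 = background
        offsets = rng.normal(0.0, spec.regional_noise_sd, size=(n, len(uniq)))
        offsets[:, 0] = 0.0
        # reference regions are metabolically stable by construction -- that
        # stability is the premise of using them as the SUVR denominator
        offsets[:, np.isin(uniq, sorted(spec.reference_region_ids))] = 0.0
        stack = (stack.reshape(n, -1) + offsets[:, region_index]).reshape(stack.shape)
    if spec.smooth_fwhm_mm > 0:
        for i in range(n):
            stack[i] = gaussian_smooth(Volume(spec.grid, stack[i]), spec.smooth_fwhm_mm).values
    if spec.global_scale_sd > 0:
        scales = np.clip(rng.normal(1.0, spec.global_scale_sd, size=n), 0.5, None)
        stack *= scales[:, None, None, None]

    subjects = []
    for i in range(n):
        group = "AD" if is_ad[i] else "HC"
        if spec.with_clinical:
            mu_e, sd_e = _EDU[group]
            edu = float(np.clip(rng.normal(mu_e, sd_e), 6.0, 24.0))
            apoe4 = float(rng.choice(3, p=_APOE4_P[group]))
            mmse = float(np.clip(
                link.mmse_intercept - link.mmse_slope * severity[i] + rng.normal(0, link.mmse_sd),
                0.0, 30.0))
            cdrsb = float(np.clip(
                link.cdrsb_slope * severity[i] + rng.normal(0, link.cdrsb_sd), 0.0, 18.0))
            fdg = float(link.fdg_intercept - link.fdg_slope * severity[i]
                        + rng.normal(0, link.fdg_sd))
        else:
            edu = apoe4 = mmse = cdrsb = fdg = np.nan
        subjects.append(SubjectRecord(
            id=f"sub-{i:04d}", age=float(ages[i]), sex=str(sex[i]), group=group,
            edu=edu, apoe4=apoe4, mmse=mmse, cdrsb=cdrsb, fdg=fdg))

    cohort = Cohort(subjects, spec.grid, stack)
    if return_truth:
        return cohort, CohortTruth(atlas, aging, ref, admask, severity)
    return cohort


def make_ic_voxelvalue_map(strength: Volume, v_max: int = 38) -> Volume:
    """Discretize a non-negative relevance map to integers 1..v_max on its
    support (0 outside), monotone in the input: vv = ceil(v_max * s / s_max).

    The integer "voxel value" attached to a component map by the upstream
    decomposition toolkit is not published in a reproducible form; this
    monotone rescaling is a documented stand-in with the same contract.
    """
    s = strength.values
    if np.any(s < 0):
        raise ValueError("strength map must be non-negative")
    s_max = s.max()
    if s_max <= 0:
        raise ValueError("strength map is all zero; no support to discretize")
    if v_max < 1:
        raise ValueError("v_max must be >= 1")
    vv = np.zeros(strength.grid.shape)
    support = s > 0
    vv[support] = np.ceil(v_max * s[support] / s_max)
    return Volume(strength.grid, vv)


# ---------------------------------------------------------------------------
# Sweep phantom

#: Voxel-count profile of the phantom's voxel-value histogram:
#: count(v) = round(220 * exp(-v / 6)) + 10, v = 1..38. Low values dominate
#: (mirroring the empirical cumulative distribution of component voxel values,
#: where the bottom quarter of values covers more than half the region) while
#: the top values keep a small tail of O(10) voxels.
_PHANTOM_AMPLITUDE = 220.0
_PHANTOM_TAU = 6.0
_PHANTOM_FLOOR = 10


def phantom_counts(v_max: int = 38) -> np.ndarray:
    v = np.arange(1, v_max + 1)
    return (np.round(_PHANTOM_AMPLITUDE * np.exp(-v / _PHANTOM_TAU)) + _PHANTOM_FLOOR).astype(int)


def make_sweep_phantom(spec: GeneratorSpec, sigma_true: int, v_max: int = 38,
                       return_truth: bool = False):
    """Cohort + integer voxel-value map where the age signal lives only in
    voxels with value >= ``sigma_true`` (flat elsewhere).

    Voxels carrying values are placed deterministically inside the aging
    regions; counts per value follow :func:`phantom_counts`. Returns
    ``(cohort, vv_volume, atlas)`` (plus the signal mask if requested).
    """
    if not 1 <= sigma_true <= v_max:
        raise ValueError(f"sigma_true must be in [1, {v_max}]")
    rng = np.random.default_rng(spec.seed)
    atlas = make_atlas(spec)
    aging = region_mask(atlas, spec.aging_region_ids)
    ref = region_mask(atlas, spec.reference_region_ids)
    brain = atlas.brain_mask()

    counts = phantom_counts(v_max)
    total = int(counts.sum())
    aging_idx = np.flatnonzero(aging.indicator.ravel())
    if total > aging_idx.size:
        raise ValueError(f"phantom needs {total} voxels but aging regions hold {aging_idx.size}")
    chosen = rng.choice(aging_idx, size=total, replace=False)
    vv_flat = np.zeros(spec.grid.n_voxels)
    values = np.repeat(np.arange(1, v_max + 1), counts)
    vv_flat[chosen] = values
    vv = Volume(spec.grid, vv_flat.reshape(spec.grid.shape))

    signal = Mask(spec.grid, (vv.values >= sigma_true))
    n = spec.n_subjects
    if n < 3:
        raise ValueError("need at least 3 subjects")
    ages = _sample_ages(spec, rng)
    stack = np.zeros((n, *spec.grid.shape))
    base = np.where(brain.indicator, spec.baseline, 0.0)
    for i in range(n):
        img = base.copy()
        img[signal.indicator] += spec.decline_per_year * ages[i]
        stack[i] = img
    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)

    subjects = [SubjectRecord(id=f"sub-{i:04d}", age=float(ages[i]),
                              sex="M" if i % 2 else "F") for i in range(n)]
    cohort = Cohort(subjects, spec.grid, stack)
    if return_truth:
        return cohort, vv, atlas, signal
    return cohort, vv, atlas
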