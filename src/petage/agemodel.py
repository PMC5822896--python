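"""Estimation of the SUVR decline slope beta_C and the linear age correction.

The model assumes the SUVR mean of the age-related region declines linearly
over adulthood,

    SUVR_mean = beta_C * age + p2,

estimates beta_C as the average least-squares slope over repeated random
subsamples of the discovery (healthy) cohort, and corrects any target index by
subtracting the age-attributable offset Delta = beta_C * age:

    Index_cor = Index_tar - Delta.

The intercept p2 is stored for reporting but plays no role in the correction.
A voxel-level variant fits one slope per voxel inside the final mask and
applies the same subtraction voxelwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .sweep import SweepResult, _draw_subsamples, suvr_table
from .volumes import Cohort, Mask, Volume, VolumeGrid

__all__ = [
    "AgeModel",
    "VoxelAgeModel",
    "AgeCorrector",
    "VoxelAgeCorrector",
    "fit_age_model",
    "age_delta",
    "correct_index",
    "correct_cohort_suvr",
    "fit_voxel_model",
    "correct_volume",
    "save_age_model",
    "load_age_model",
]


class AgeCorrector(BaseEstimator):
    """Linear age-effect corrector for a scalar index (sklearn-style).

    fit(age, index) estimates ``beta_c_`` as the mean OLS slope of index on
    age over ``n_rep`` subsamples of size ``n_draw`` (None -> full sample) and
    ``intercept_`` from the full-sample fit. transform subtracts
    beta_c_ * age from the index.
    """

    def __init__(self, n_draw: int | None = 250, n_rep: int = 3000,
                 random_state: int | None = None):
        self.n_draw = n_draw
        self.n_rep = n_rep
        self.random_state = random_state

    def fit(self, age: np.ndarray, index: np.ndarray) -> "AgeCorrector":
        age = np.asarray(age, dtype=float)
        index = np.asarray(index, dtype=float)
        n = len(age)
        if n < 3:
            raise ValueError("need at least 3 subjects to fit the age model")
        if len(index) != n:
            raise ValueError("age and index must be aligned")
        if np.ptp(age) == 0:
            raise ValueError("ages are constant; slope undefined")
        n_draw = n if self.n_draw is None else min(int(self.n_draw), n)
        rng = np.random.default_rng(self.random_state)
        idx = _draw_subsamples(rng, n, n_draw, self.n_rep)
        a = age[idx]
        v = index[idx]
        am = a - a.mean(axis=1, keepdims=True)
        vm = v - v.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", am, am)
        good = sxx > 0
        if not np.any(good):
            raise ValueError("all subsamples had constant age")
        slopes = np.einsum("ij,ij->i", am, vm)[good] / sxx[good]
        self.beta_c_ = float(slopes.mean())
        self.beta_c_sd_ = float(slopes.std(ddof=0))
        # intercept from the full-sample fit (reported, not used to correct)
        full_slope, full_intercept = np.polyfit(age, index, 1)
        self.intercept_ = float(full_intercept)
        self.full_sample_slope_ = float(full_slope)
        self.n_subjects_ = n
        return self

    def age_delta(self, age) -> np.ndarray | float:
        """Age-attributable offset Delta = beta_c * age (age in years >= 0)."""
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be non-negative")
        out = self.beta_c_ * age
        return float(out) if out.ndim == 0 else out

    def transform(self, index, age):
        """Corrected index = index - beta_c * age."""
        index = np.asarray(index, dtype=float)
        out = index - self.age_delta(age)
        return float(out) if out.ndim == 0 else out


@dataclass
class AgeModel:
    """The fitted correction: slope, intercept, chosen sigma, final mask and
    reference region, plus resampling provenance."""

    beta_c: float
    intercept_p2: float
    sigma_star: int
    final_mask: Mask
    ref_mask: Mask
    ref_region_ids: tuple[int, ...]
    n_draw: int
    n_rep: int
    seed: int | None
    beta_c_sd: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta_c):
            raise ValueError("beta_c must be finite")
        if self.final_mask.voxel_count == 0:
            raise ValueError("final mask must be non-empty")


def fit_age_model(cohort: Cohort, sweep: SweepResult, n_draw: int = 250,
                  n_rep: int = 3000, seed: int | None = None,
                  ref_region_ids: tuple[int, ...] = ()) -> AgeModel:
    """Fit beta_C on the discovery cohort's SUVR means over the sweep's final
    mask (thin wrapper over :class:`AgeCorrector`)."""
    suvr = suvr_table(cohort, sweep.final_mask, sweep.ref_mask)
    est = AgeCorrector(n_draw=min(n_draw, len(cohort)), n_rep=n_rep, random_state=seed)
    est.fit(cohort.ages, suvr)
    return AgeModel(
        beta_c=est.beta_c_, intercept_p2=est.intercept_, sigma_star=sweep.sigma_star,
        final_mask=sweep.final_mask, ref_mask=sweep.ref_mask,
        ref_region_ids=tuple(int(i) for i in ref_region_ids),
        n_draw=min(n_draw, len(cohort)), n_rep=n_rep, seed=seed,
        beta_c_sd=est.beta_c_sd_,
    )


def age_delta(model: AgeModel, age) -> float | np.ndarray:
    """Delta = beta_C * age."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    out = model.beta_c * age
    return float(out) if out.ndim == 0 else out


def correct_index(model: AgeModel, value, age) -> float | np.ndarray:
    """Index_cor = Index_tar - beta_C * age."""
    value = np.asarray(value, dtype=float)
    out = value - age_delta(model, age)
    return float(out) if out.ndim == 0 else out


def correct_cohort_suvr(model: AgeModel, cohort: Cohort,
                        refit: bool = False) -> np.ndarray:
    """SUVR means of a cohort over the model's mask, age-corrected.

    By default the discovery-cohort beta_C is transferred to the new cohort;
    ``refit=True`` re-estimates the slope on this cohort instead.
    """
    suvr = suvr_table(cohort, model.final_mask, model.ref_mask)
    if refit:
        est = AgeCorrector(n_draw=min(model.n_draw, len(cohort)), n_rep=model.n_rep,
                           random_state=model.seed).fit(cohort.ages, suvr)
        return est.transform(suvr, cohort.ages)
    return correct_index(model, suvr, cohort.ages)


# ---------------------------------------------------------------------------
# Voxel-level model


@dataclass
class VoxelAgeModel:
    """Per-voxel decline slopes over the final mask support."""

    mask: Mask
    beta_map: Volume  # slopes inside mask, 0 outside

    def __post_init__(self) -> None:
        outside = ~self.mask.indicator
        if np.any(self.beta_map.values[outside] != 0):
            raise ValueError("beta_map support must equal the mask")


class VoxelAgeCorrector(BaseEstimator):
    """Voxelwise linear age-effect corrector within a mask."""

    def __init__(self, mask: Mask):
        self.mask = mask

    def fit(self, stack: np.ndarray, ages: np.ndarray) -> "VoxelAgeCorrector":
        ages = np.asarray(ages, dtype=float)
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 4 or stack.shape[1:] != self.mask.grid.shape:
            raise ValueError("stack must be (subjects, *grid.shape)")
        if len(ages) != stack.shape[0]:
            raise ValueError("ages must align with the stack")
        if np.ptp(ages) == 0:
            raise ValueError("ages are constant; voxel slopes undefined")
        if self.mask.voxel_count == 0:
            raise ValueError("mask is empty")
        flat = stack.reshape(stack.shape[0], -1)[:, self.mask.indicator.ravel()]
        am = ages - ages.mean()
        slopes = am @ (flat - flat.mean(axis=0)) / (am @ am)
        beta = np.zeros(self.mask.grid.shape)
        beta[self.mask.indicator] = slopes
        self.beta_map_ = Volume(self.mask.grid, beta)
        return self

    def transform(self, img_values: np.ndarray, age: float) -> np.ndarray:
        if age < 0:
            raise ValueError("age must be non-negative")
        out = np.array(img_values, dtype=float, copy=True)
        ind = self.mask.indicator
        out[ind] = out[ind] - self.beta_map_.values[ind] * age
        return out


def fit_voxel_model(cohort: Cohort, mask: Mask) -> VoxelAgeModel:
    """Per-voxel OLS slope of intensity on age within the mask."""
    est = VoxelAgeCorrector(mask).fit(cohort.stack, cohort.ages)
    return VoxelAgeModel(mask, est.beta_map_)


def correct_volume(vmodel: VoxelAgeModel, img: Volume, age: float) -> Volume:
    """Subtract slope*age voxelwise inside the mask; untouched outside."""
    if img.grid != vmodel.mask.grid:
        raise ValueError("image grid does not match the voxel model grid")
    if age < 0:
        raise ValueError("age must be non-negative")
    out = img.values.copy()
    ind = vmodel.mask.indicator
    out[ind] = out[ind] - vmodel.beta_map.values[ind] * age
    return Volume(img.grid, out)


def correct_stack(vmodel: VoxelAgeModel, stack: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Voxel-level correction of a whole (subjects, *grid) stack."""
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    out = np.array(stack, dtype=float, copy=True)
    ind = vmodel.mask.indicator
    beta = vmodel.beta_map.values[ind]
    out[:, ind] = out[:, ind] - ages[:, None] * beta[None, :]
    return out


# ---------------------------------------------------------------------------
# Serialization


def save_age_model(model: AgeModel, path: str | Path) -> None:
    """JSON round-trip with beta_c at full precision; the mask is stored as
    flat voxel indices on the model grid."""
    grid = model.final_mask.grid
    payload = {
        "beta_c": model.beta_c,
        "beta_c_sd": model.beta_c_sd,
        "intercept_p2": model.intercept_p2,
        "sigma_star": model.sigma_star,
        "ref_region_ids": list(model.ref_region_ids),
        "n_draw": model.n_draw,
        "n_rep": model.n_rep,
        "seed": model.seed,
        "grid": {"shape": list(grid.shape), "spacing_mm": list(grid.spacing_mm)},
        "mask_indices": np.flatnonzero(model.final_mask.indicator.ravel()).tolist(),
        "ref_mask_indices": np.flatnonzero(model.ref_mask.indicator.ravel()).tolist(),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_age_model(path: str | Path) -> AgeModel:
    payload = json.loads(Path(path).read_text())
    grid = VolumeGrid(tuple(payload["grid"]["shape"]), tuple(payload["grid"]["spacing_mm"]))
    def mask_from(key: str) -> Mask:
        ind = np.zeros(grid.n_voxels, dtype=bool)
        ind[np.asarray(payload[key], dtype=int)] = True
        return Mask(grid, ind.reshape(grid.shape))

    return AgeModel(
        beta_c=float(payload["beta_c"]), intercept_p2=float(payload["intercept_p2"]),
        sigma_star=int(payload["sigma_star"]), final_mask=mask_from("mask_indices"),
        ref_mask=mask_from("ref_mask_indices"),
        ref_region_ids=tuple(payload["ref_region_ids"]),
        n_draw=int(payload["n_draw"]), n_rep=int(payload["n_rep"]),
        seed=payload["seed"], beta_c_sd=float(payload["beta_c_sd"]),
    )
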