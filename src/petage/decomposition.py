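"""Spatial ICA of the subject x voxel stack and component-age screening.

The decomposition is a single-modality stand-in for linked multimodal ICA:
fixed-point negentropy-maximising ICA (FastICA) on the whitened, per-voxel
demeaned data, treating spatial maps as the independent non-Gaussian sources
and per-subject loadings as the mixing weights.

Scale convention: each spatial map has unit L2 norm and positive skewness;
loading columns have unit variance; a per-component scale vector carries the
reconstruction magnitude, so that

    stack  ~=  mean + loadings @ diag(scales) @ maps
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .synthetic import make_ic_voxelvalue_map
from .volumes import Cohort, Volume, VolumeGrid

__all__ = [
    "FitStats",
    "AssociationResult",
    "ComponentSet",
    "SpatialICA",
    "NoAgingComponentError",
    "decompose",
    "screen_components",
    "grouped_association",
    "select_aging_component",
    "polynomial_age_fit",
]


class NoAgingComponentError(RuntimeError):
    """No screened component qualifies as the aging component."""


@dataclass(frozen=True)
class FitStats:
    """Least-squares polynomial fit of a loading on age."""

    degree: int
    r_squared: float
    p_value: float
    coeffs: tuple[float, ...]  # highest degree first (numpy polyfit order)


def polynomial_age_fit(loading: np.ndarray, ages: np.ndarray, degree: int) -> FitStats:
    """OLS polynomial fit with R^2 and the overall F-test p-value.

    F = (R^2 / k) / ((1 - R^2) / (n - k - 1)) with k = degree regressors.
    """
    loading = np.asarray(loading, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if n != len(loading):
        raise ValueError("loading and ages must be aligned")
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} subjects for a degree-{degree} fit")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; association with age undefined")
    coeffs = np.polyfit(ages, loading, degree)
    resid = loading - np.polyval(coeffs, ages)
    ss_tot = float(np.sum((loading - loading.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0:
        return FitStats(degree, 0.0, 1.0, tuple(coeffs))
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    k = degree
    df_res = n - k - 1
    if r2 >= 1.0 or ss_res == 0:
        return FitStats(degree, 1.0, 0.0, tuple(coeffs))
    f = (r2 / k) / ((1.0 - r2) / df_res)
    p = float(stats.f.sf(f, k, df_res))
    return FitStats(degree, float(r2), p, tuple(coeffs))


@dataclass(frozen=True)
class AssociationResult:
    """Linear + quadratic association of one component's loading with age.

    ``r_squared``/``p_value`` are the headline (quadratic) statistics;
    ``monotone`` is true when the quadratic vertex falls outside the observed
    age range (the fitted curve does not turn within the data), and
    ``direction`` is the sign of the linear trend.
    """

    component_index: int
    linear: FitStats
    quadratic: FitStats
    monotone: bool
    direction: int

    @property
    def fit_kind(self) -> str:
        return "quadratic"

    @property
    def r_squared(self) -> float:
        return self.quadratic.r_squared

    @property
    def p_value(self) -> float:
        return self.quadratic.p_value


@dataclass
class ComponentSet:
    """ICA output: per-subject loadings, spatial maps, integer voxel-value maps."""

    grid: VolumeGrid
    loadings: np.ndarray          # (M, N), columns unit variance
    maps: np.ndarray              # (N, V) flattened, rows unit norm, skew-positive
    scales: np.ndarray            # (N,), reconstruction magnitude per component
    mean: np.ndarray              # (V,) per-voxel mean removed before ICA
    subject_offsets: np.ndarray | None = None  # (M,) per-subject spatial mean term
    converged: bool = True
    v_max: int = 38

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.loadings.shape[0]

    def map_volume(self, index: int) -> Volume:
        return Volume(self.grid, self.maps[index].reshape(self.grid.shape))

    def voxel_value_volume(self, index: int, support_z: float = 2.5) -> Volume:
        """Integer relevance map of a component: voxels whose map magnitude
        exceeds ``support_z`` robust standard deviations (1.4826 * MAD of the
        signed map) form the support; surviving magnitudes are discretized to
        1..v_max."""
        signed = self.maps[index]
        center = np.median(signed)  # baseline of a mostly-inactive map
        sigma = 1.4826 * np.median(np.abs(signed - center))
        m = np.abs(signed - center)
        thresh = support_z * sigma
        strength = np.where(m > thresh, m, 0.0)
        if not np.any(strength > 0):  # degenerate flat map: keep the max voxel
            strength = np.where(m == m.max(), m, 0.0)
        return make_ic_voxelvalue_map(Volume(self.grid, strength.reshape(self.grid.shape)),
                                      self.v_max)

    @property
    def voxel_values(self) -> list[Volume]:
        return [self.voxel_value_volume(i) for i in range(self.n_components)]

    def oriented(self, index: int, ages: np.ndarray) -> "ComponentSet":
        """Return a copy where component ``index`` is sign-flipped (map and
        loading together) if needed so its loading-age linear trend is negative."""
        slope = np.polyfit(np.asarray(ages, float), self.loadings[:, index], 1)[0]
        if slope <= 0:
            return self
        loadings = self.loadings.copy()
        maps = self.maps.copy()
        loadings[:, index] *= -1.0
        maps[index] *= -1.0
        return ComponentSet(self.grid, loadings, maps, self.scales.copy(), self.mean,
                            self.subject_offsets, self.converged, self.v_max)

    def reconstruct(self) -> np.ndarray:
        """(M, V) reconstruction: voxel mean + per-subject offset +
        loadings @ diag(scales) @ maps."""
        out = self.loadings @ (self.scales[:, None] * self.maps) + self.mean
        if self.subject_offsets is not None:
            out = out + self.subject_offsets[:, None]
        return out


class SpatialICA(BaseEstimator):
    """Spatial ICA estimator over a (subjects, voxels) matrix.

    Parameters
    ----------
    n_components : int or None
        Number of components; None selects the smallest number of principal
        components retaining ``pca_var`` of the variance.
    pca_var : float
        Variance fraction for automatic model-order selection.
    max_iter, tol : fixed-point iteration controls.
    n_restarts : additional seeds tried when FastICA does not converge.
    random_state : seed; the decomposition is deterministic given it.
    """

    def __init__(self, n_components: int | None = None, pca_var: float = 0.90,
                 max_iter: int = 500, tol: float = 1e-6, n_restarts: int = 3,
                 v_max: int = 38, random_state: int | None = None):
        self.n_components = n_components
        self.pca_var = pca_var
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.v_max = v_max
        self.random_state = random_state

    def _pick_order(self, X: np.ndarray) -> int:
        # eigenvalues of the subject-space Gram matrix = PCA spectrum
        Xc = X - X.mean(axis=0)
        ev = np.linalg.eigvalsh(Xc @ Xc.T)[::-1]
        ev = np.clip(ev, 0, None)
        frac = np.cumsum(ev) / ev.sum()
        return int(np.searchsorted(frac, self.pca_var) + 1)

    def fit(self, X: np.ndarray, y=None) -> "SpatialICA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a (subjects, voxels) matrix")
        m, v = X.shape
        if self.n_components is not None:
            k = int(self.n_components)
            if k > min(m, v):
                raise ValueError(f"n_components={k} exceeds min(subjects, voxels)={min(m, v)}")
        else:
            # demeaning across voxels leaves at most m-1 informative directions
            k = min(self._pick_order(X), m - 1) if m > 1 else 1
        mean = X.mean(axis=0)
        Xc = X - mean

        rank = np.linalg.matrix_rank(Xc @ Xc.T)
        if rank < k:
            raise ValueError(
                f"stack is rank deficient (rank {rank} < {k} components); "
                "duplicated or constant subjects?")

        seed = self.random_state if self.random_state is not None else 0
        converged = False
        sources = mixing = None
        for attempt in range(self.n_restarts + 1):
            ica = FastICA(n_components=k, algorithm="parallel", fun="logcosh",
                          whiten="unit-variance", max_iter=self.max_iter, tol=self.tol,
                          random_state=seed + attempt)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                sources = ica.fit_transform(Xc.T)  # (V, k) spatial sources
            mixing = ica.mixing_                   # (M, k) subject weights
            subject_offsets = ica.mean_.copy()     # per-subject spatial mean
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
            if converged:
                break
        if not converged:
            warnings.warn("FastICA did not converge after restarts; results flagged",
                          RuntimeWarning, stacklevel=2)

        maps = sources.T          # (k, V)
        loadings = mixing.copy()  # (k columns)
        # unit-norm maps, positive skewness, unit-variance loadings
        norms = np.linalg.norm(maps, axis=1)
        norms[norms == 0] = 1.0
        maps /= norms[:, None]
        loadings *= norms[None, :]
        skews = stats.skew(maps, axis=1)
        flip = np.where(skews < 0, -1.0, 1.0)
        maps *= flip[:, None]
        loadings *= flip[None, :]
        scales = loadings.std(axis=0, ddof=0)
        scales[scales == 0] = 1.0
        loadings = loadings / scales[None, :]
        order = np.argsort(scales)[::-1]  # explained energy, descending

        self.n_components_ = k
        self.loadings_ = loadings[:, order]
        self.maps_ = maps[order]
        self.scales_ = scales[order]
        self.mean_ = mean
        self.subject_offsets_ = subject_offsets
        self.converged_ = converged
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project (subjects, voxels) data onto the fitted spatial maps,
        returning loadings on the fitted scale convention."""
        X = np.asarray(X, dtype=float) - self.mean_
        raw = X @ self.maps_.T  # maps are unit-norm rows
        return raw / self.scales_[None, :]

    def component_set(self, grid: VolumeGrid) -> ComponentSet:
        return ComponentSet(grid, self.loadings_, self.maps_, self.scales_,
                            self.mean_, self.subject_offsets_, self.converged_, self.v_max)


def decompose(cohort: Cohort, n_components: int | None = None,
              seed: int | None = None, **kwargs) -> ComponentSet:
    """Spatial ICA of a cohort's image stack (thin wrapper over SpatialICA)."""
    X = cohort.stack.reshape(len(cohort), -1)
    est = SpatialICA(n_components=n_components, random_state=seed, **kwargs)
    est.fit(X)
    return est.component_set(cohort.grid)


def screen_components(cs: ComponentSet | np.ndarray, ages: np.ndarray) -> list[AssociationResult]:
    """Linear and quadratic fits of every component loading on age.

    A component is flagged monotone when the quadratic fit's turning point lies
    outside the observed age range (or the curvature is numerically zero).
    """
    loadings = cs.loadings if isinstance(cs, ComponentSet) else np.asarray(cs, float)
    ages = np.asarray(ages, dtype=float)
    if loadings.shape[0] != len(ages):
        raise ValueError("ages must align with loadings rows")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; screening undefined")
    results = []
    lo, hi = ages.min(), ages.max()
    for j in range(loadings.shape[1]):
        y = loadings[:, j]
        lin = polynomial_age_fit(y, ages, 1)
        quad = polynomial_age_fit(y, ages, 2)
        a2, a1, _ = quad.coeffs
        scale = max(abs(a1) / (hi - lo), np.finfo(float).tiny)
        if abs(a2) < 1e-12 * scale:
            monotone = True
        else:
            vertex = -a1 / (2.0 * a2)
            monotone = not (lo <= vertex <= hi)
        direction = int(np.sign(lin.coeffs[0])) if lin.coeffs[0] != 0 else 0
        results.append(AssociationResult(j, lin, quad, monotone, direction))
    return results


def grouped_association(loading: np.ndarray, ages: np.ndarray,
                        group_breaks: list[float]) -> dict[str, pd.DataFrame]:
    """Quadratic loading-age fits per age bin and per cumulative prefix of bins.

    ``group_breaks`` are bin edges (e.g. [20, 30, 40, ...]); bin i covers
    [breaks[i], breaks[i+1]), the last bin closed. Bins with fewer than 3
    subjects are skipped with a warning (per-group table only; cumulative
    prefixes always use every subject seen so far).
    """
    loading = np.asarray(loading, dtype=float)
    ages = np.asarray(ages, dtype=float)
    breaks = list(group_breaks)
    if len(breaks) < 2:
        raise ValueError("need at least two break points")
    per_rows, cum_rows = [], []
    for i in range(len(breaks) - 1):
        lo, hi = breaks[i], breaks[i + 1]
        last = i == len(breaks) - 2
        in_bin = (ages >= lo) & ((ages <= hi) if last else (ages < hi))
        in_cum = (ages >= breaks[0]) & ((ages <= hi) if last else (ages < hi))
        label = f"{lo:g}-{hi:g}"
        if in_bin.sum() < 3:
            warnings.warn(f"age group {label} has {int(in_bin.sum())} (<3) subjects; skipped",
                          UserWarning, stacklevel=2)
        else:
            fit = polynomial_age_fit(loading[in_bin], ages[in_bin], 2)
            per_rows.append({"group": label, "n": int(in_bin.sum()),
                             "p": fit.p_value, "R": np.sqrt(fit.r_squared)})
        if in_cum.sum() >= 3:
            fit = polynomial_age_fit(loading[in_cum], ages[in_cum], 2)
            cum_rows.append({"group": f"{breaks[0]:g}-{hi:g}", "n": int(in_cum.sum()),
                             "p": fit.p_value, "R": np.sqrt(fit.r_squared)})
    return {"per_group": pd.DataFrame(per_rows), "cumulative": pd.DataFrame(cum_rows)}


def select_aging_component(results: list[AssociationResult], alpha: float = 0.05) -> int:
    """Index of the monotone, negatively age-trending component with maximal
    R^2 among those significant at ``alpha`` (ties -> lowest index)."""
    candidates = [r for r in results
                  if r.monotone and r.direction < 0 and r.p_value < alpha]
    if not candidates:
        raise NoAgingComponentError(
            f"no monotone negatively-trending component with p < {alpha}")
    best = max(candidates, key=lambda r: (r.r_squared, -r.component_index))
    return best.component_index
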