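"""Evaluation of the age-corrected index on healthy and disease cohorts.

Five checks mirror how an age-correction model is validated in practice:

1. Pearson correlation between SUVR mean and age on an independent healthy
   cohort, before and after correction (the corrected slope should be flat).
2. A qualitative case study: voxel-level correction of one healthy and one
   diseased subject.
3. Independent (Welch) t-test of HC vs AD SUVR means before/after correction.
4. Partial correlation of SUVR with clinical indices (MMSE, CDRSB, meta-ROI
   FDG) in the disease group, controlling education, sex and ApoE4 count.
5. PCA + linear-SVM leave-one-out classification of HC vs AD on the image
   stacks before/after correction, reported as accuracy and AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .agemodel import AgeModel, VoxelAgeModel, correct_index, correct_stack, fit_voxel_model
from .sweep import suvr_table
from .volumes import Cohort, Mask, Volume, mean_in_mask

__all__ = [
    "PartialCorrelation",
    "partial_correlation",
    "group_ttest",
    "ClassificationResult",
    "ClassificationReport",
    "classify_loocv",
    "loocv_pca_svm",
    "case_study",
    "CaseStudyResult",
    "EvaluationReport",
    "evaluate_cohort",
    "merge_thin_bins",
]


class PartialCorrelation(NamedTuple):
    r: float
    p: float
    n: int


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(x, y, covariates=None) -> PartialCorrelation:
    """Pearson correlation of x and y after removing covariates by OLS
    residualization (with intercept); p via the t transform with n-k-2 df.

    ``covariates`` may be None, a (n, k) array, or a DataFrame. Rows with any
    missing value are dropped (the count is reflected in the returned n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
        names = []
    elif isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        names = [f"covariate_{i}" for i in range(cov.shape[1])]
    if len(y) != len(x) or len(cov) != len(x):
        raise ValueError("x, y and covariates must be aligned")

    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} row(s) with missing values dropped", UserWarning,
                      stacklevel=2)
    x, y, cov = x[keep], y[keep], cov[keep]
    n, k = len(x), cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k+2 observations (n={n}, k={k})")

    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # identify an offending column for the error message
        for j in range(cov.shape[1]):
            sub = np.column_stack([np.ones(n), cov[:, : j + 1]])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise ValueError(f"covariate {names[j]!r} is collinear with the others")
        raise ValueError("covariate design matrix is rank deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return PartialCorrelation(r, 0.0, n)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelation(r, p, n)


def group_ttest(values_a, values_b, equal_var: bool = False) -> tuple[float, float]:
    """Independent-samples t-test (Welch by default).

    Two zero-variance groups with equal means return (0, 1) by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# PCA + linear SVM leave-one-out classification


@dataclass
class ClassificationResult:
    accuracy: float
    auc: float
    predictions: np.ndarray      # per-fold predicted labels (0/1)
    decision_values: np.ndarray  # per-fold SVM decision values


@dataclass
class ClassificationReport:
    before: ClassificationResult
    after: ClassificationResult


def loocv_pca_svm(X: np.ndarray, y: np.ndarray, pca_var: float = 0.95,
                  seed: int | None = None) -> ClassificationResult:
    """Leave-one-out: per fold, PCA (retaining ``pca_var`` variance) and a
    linear-kernel SVM are fit on the training folds only; the held-out subject
    is predicted from its decision value. AUC is computed from the decision
    values, not the hard labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 6:
        raise ValueError("need at least 6 subjects for LOOCV classification")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    y01 = (y == classes[1]).astype(int)
    decisions = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if len(np.unique(y01[tr])) < 2:
            raise ValueError("a training fold contains a single class")
        pca = PCA(n_components=pca_var, svd_solver="full", random_state=seed)
        Z = pca.fit_transform(X[tr])
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Z, y01[tr])
        z0 = pca.transform(X[i][None, :])
        decisions[i] = float(clf.decision_function(z0)[0])
        preds[i] = int(clf.predict(z0)[0])
    accuracy = float((preds == y01).mean())
    auc = float(roc_auc_score(y01, decisions))
    return ClassificationResult(accuracy, auc, preds, decisions)


def classify_loocv(stack_before: np.ndarray, stack_after: np.ndarray, labels,
                   pca_var: float = 0.95, seed: int | None = None,
                   feature_mask: Mask | None = None) -> ClassificationReport:
    """HC/AD LOOCV classification on image stacks before and after correction.

    ``feature_mask`` restricts the feature vector to (e.g. brain) voxels.
    """
    def flatten(stack: np.ndarray) -> np.ndarray:
        flat = np.asarray(stack, dtype=float).reshape(stack.shape[0], -1)
        if feature_mask is not None:
            flat = flat[:, feature_mask.indicator.ravel()]
        return flat

    labels = np.asarray(labels)
    return ClassificationReport(
        before=loocv_pca_svm(flatten(stack_before), labels, pca_var, seed),
        after=loocv_pca_svm(flatten(stack_after), labels, pca_var, seed),
    )


# ---------------------------------------------------------------------------
# Case study


@dataclass
class CaseStudyResult:
    hc_before: float
    hc_after: float
    ad_before: float
    ad_after: float


def case_study(vmodel: VoxelAgeModel, img_hc: Volume, age_hc: float,
               img_ad: Volume, age_ad: float, mask: Mask | None = None) -> CaseStudyResult:
    """Voxel-level correction of one healthy and one diseased subject; returns
    the mask-mean intensity before and after for each."""
    from .agemodel import correct_volume

    mask = vmodel.mask if mask is None else mask
    cor_hc = correct_volume(vmodel, img_hc, age_hc)
    cor_ad = correct_volume(vmodel, img_ad, age_ad)
    return CaseStudyResult(
        hc_before=mean_in_mask(img_hc, mask), hc_after=mean_in_mask(cor_hc, mask),
        ad_before=mean_in_mask(img_ad, mask), ad_after=mean_in_mask(cor_ad, mask),
    )


# ---------------------------------------------------------------------------
# Whole-cohort evaluation


def merge_thin_bins(ages: np.ndarray, breaks: list[float], min_n: int = 5) -> list[float]:
    """Merge age bins holding fewer than ``min_n`` subjects into their nearest
    neighbour bin, returning the reduced break list."""
    breaks = sorted(breaks)
    while len(breaks) > 2:
        counts = []
        for i in range(len(breaks) - 1):
            last = i == len(breaks) - 2
            hi_ok = (ages <= breaks[i + 1]) if last else (ages < breaks[i + 1])
            counts.append(int(((ages >= breaks[i]) & hi_ok).sum()))
        thin = [i for i, c in enumerate(counts) if c < min_n]
        if not thin:
            break
        i = thin[0]
        # drop the interior break shared with the smaller neighbour
        if i == 0:
            del breaks[1]
        elif i == len(counts) - 1:
            del breaks[-2]
        elif counts[i - 1] <= counts[i + 1]:
            del breaks[i]
        else:
            del breaks[i + 1]
    return breaks


@dataclass
class EvaluationReport:
    pearson_before: tuple[float, float]
    pearson_after: tuple[float, float]
    partial: dict[str, dict[str, PartialCorrelation]]  # index -> before/after
    ttest_before: tuple[float, float]
    ttest_after: tuple[float, float]
    classification: ClassificationReport | None
    case: CaseStudyResult | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "pearson_before": {"r": self.pearson_before[0], "p": self.pearson_before[1]},
            "pearson_after": {"r": self.pearson_after[0], "p": self.pearson_after[1]},
            "ttest_before": {"t": self.ttest_before[0], "p": self.ttest_before[1]},
            "ttest_after": {"t": self.ttest_after[0], "p": self.ttest_after[1]},
            "partial": {
                idx: {when: {"r": pc.r, "p": pc.p, "n": pc.n} for when, pc in d2.items()}
                for idx, d2 in self.partial.items()
            },
        }
        if self.classification is not None:
            d["classification"] = {
                "before": {"accuracy": self.classification.before.accuracy,
                           "auc": self.classification.before.auc},
                "after": {"accuracy": self.classification.after.accuracy,
                          "auc": self.classification.after.auc},
            }
        if self.case is not None:
            d["case_study"] = {
                "hc_before": self.case.hc_before, "hc_after": self.case.hc_after,
                "ad_before": self.case.ad_before, "ad_after": self.case.ad_after,
            }
        d.update(self.extras)
        return d


_CLINICAL_INDICES = ("mmse", "cdrsb", "fdg")
_DEFAULT_COVARIATES = ("edu", "sex", "apoe4")


def evaluate_cohort(model: AgeModel, cohort: Cohort, pca_var: float = 0.95,
                    covariates: tuple[str, ...] = _DEFAULT_COVARIATES,
                    classify: bool = True, n_class_per_group: int | None = None,
                    feature_mask: Mask | None = None,
                    seed: int | None = None) -> EvaluationReport:
    """Run the full before/after evaluation battery on an HC(+AD) cohort.

    The ROI-level correction transfers the discovery beta_C; the voxel-level
    correction used for classification and the case study refits per-voxel
    slopes on this cohort's healthy subjects within the model mask.
    """
    ages = cohort.ages
    groups = cohort.groups
    hc = groups == "HC"
    ad = groups == "AD"
    suvr = suvr_table(cohort, model.final_mask, model.ref_mask)
    suvr_cor = correct_index(model, suvr, ages)

    r_b, p_b = stats.pearsonr(ages[hc], suvr[hc])
    r_a, p_a = stats.pearsonr(ages[hc], suvr_cor[hc])

    partial: dict[str, dict[str, PartialCorrelation]] = {}
    tab = cohort.table()
    has_clinical = bool(np.isfinite(tab.loc[ad, "mmse"].to_numpy(dtype=float)).any()) \
        if ad.any() else False
    if ad.sum() >= len(covariates) + 4 and has_clinical:
        cov_df = tab.loc[ad, list(covariates)].copy()
        if "sex" in cov_df:
            cov_df["sex"] = (tab.loc[ad, "sex"] == "M").astype(float)
        for idx_name in _CLINICAL_INDICES:
            vals = tab.loc[ad, idx_name].to_numpy(dtype=float)
            partial[idx_name] = {
                "before": partial_correlation(suvr[ad], vals, cov_df),
                "after": partial_correlation(suvr_cor[ad], vals, cov_df),
            }

    if ad.sum() >= 2 and hc.sum() >= 2:
        tt_b = group_ttest(suvr[hc], suvr[ad])
        tt_a = group_ttest(suvr_cor[hc], suvr_cor[ad])
    else:
        tt_b = tt_a = (float("nan"), float("nan"))

    classification = None
    case = None
    if classify and ad.sum() >= 3 and hc.sum() >= 3:
        vmodel = fit_voxel_model(cohort.subset(hc), model.final_mask)
        corrected = correct_stack(vmodel, cohort.stack, ages)
        n_per = n_class_per_group or int(ad.sum())
        hc_idx = np.flatnonzero(hc)
        ad_idx = np.flatnonzero(ad)
        # age-matched healthy subset of the same size as the disease group
        hc_pick = hc_idx[np.argsort(np.abs(ages[hc_idx] - ages[ad_idx].mean()))[:n_per]]
        ad_pick = ad_idx[:n_per] if len(ad_idx) >= n_per else ad_idx
        sel = np.sort(np.concatenate([hc_pick, ad_pick]))
        labels = (groups[sel] == "AD").astype(int)
        classification = classify_loocv(cohort.stack[sel], corrected[sel], labels,
                                        pca_var=pca_var, seed=seed,
                                        feature_mask=feature_mask)
        # typical subjects: oldest healthy and youngest diseased
        i_hc = int(hc_idx[np.argmax(ages[hc_idx])])
        i_ad = int(ad_idx[np.argmin(ages[ad_idx])])
        case = case_study(vmodel, Volume(cohort.grid, cohort.stack[i_hc]), ages[i_hc],
                          Volume(cohort.grid, cohort.stack[i_ad]), ages[i_ad])

    return EvaluationReport(
        pearson_before=(float(r_b), float(p_b)), pearson_after=(float(r_a), float(p_a)),
        partial=partial, ttest_before=tt_b, ttest_after=tt_a,
        classification=classification, case=case,
    )
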