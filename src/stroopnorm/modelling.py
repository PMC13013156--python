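"""Transformed-covariate model space, OLS fitting, and BIC selection.

For each performance index the normative analysis enumerates every linear
model built from subsets of {sex, age, education}, with age and education
each entering under one of six transformations (none, square root, quadratic,
cubic, natural log, reciprocal) and optionally ln(100 - age) for age.
Continuous covariates are centred at their cohort mean after transformation.
With the six-transform set this yields 98 candidate models per score
(1 null + 1 sex + 6 age + 6 education + 6 sex*age + 6 sex*education +
36 age*education + 36 sex*age*education); allowing ln(100 - age) gives 112.

Each candidate is fitted by OLS and scored with the Gaussian BIC
(-2 max log L + k ln n, k counting intercept, slopes and residual variance).
Selection uses a parsimony rule: the minimum-BIC model wins unless another
model lies within 2 BIC points with strictly fewer parameters, in which case
the fewest-parameter model among those within 2 points is preferred (ties
broken by lower BIC, then canonical enumeration order).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from ._transforms import (AGE_TRANSFORMS, EDUCATION_TRANSFORMS,
                          apply_transform, transform_label)
from .correction import CorrectionModel, CorrectionTerm

__all__ = [
    "CandidateModel",
    "FitResult",
    "enumerate_models",
    "fit_model",
    "bic",
    "select_best",
    "covariate_significance",
    "NormativeModelSearch",
]

_PREDICTOR_ORDER = ("sex", "age", "education")


@dataclass(frozen=True)
class CandidateModel:
    """One point in the model space.

    ``predictors`` is a subset of (sex, age, education) in canonical order;
    a transform is present exactly when the corresponding predictor is.
    """

    predictors: tuple[str, ...]
    age_transform: str | None = None
    education_transform: str | None = None

    def __post_init__(self):
        if tuple(p for p in _PREDICTOR_ORDER if p in self.predictors) != self.predictors:
            raise ValueError("predictors must be in canonical (sex, age, education) order")
        if ("age" in self.predictors) != (self.age_transform is not None):
            raise ValueError("age transform present iff age is a predictor")
        if ("education" in self.predictors) != (self.education_transform is not None):
            raise ValueError("education transform present iff education is a predictor")
        if self.age_transform is not None and self.age_transform not in AGE_TRANSFORMS:
            raise ValueError(f"illegal age transform {self.age_transform!r}")
        if (self.education_transform is not None
                and self.education_transform not in EDUCATION_TRANSFORMS):
            raise ValueError(f"illegal education transform {self.education_transform!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        out = []
        for p in self.predictors:
            if p == "sex":
                out.append("sex[male]")
            elif p == "age":
                out.append(transform_label(self.age_transform, "age"))
            else:
                out.append(transform_label(self.education_transform, "education"))
        return tuple(out)

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"y ~ 1 + {rhs}" if self.terms else "y ~ 1"


def enumerate_models(include_ln100: bool = False) -> list[CandidateModel]:
    """Enumerate the full model space in deterministic canonical order.

    Ordered by predictor subset (null, sex, age, education, sex+age,
    sex+education, age+education, all three), then by age transform, then by
    education transform.  Duplicate-free by construction.
    """
    age_set = AGE_TRANSFORMS if include_ln100 else EDUCATION_TRANSFORMS
    subsets = [()]
    for r in (1, 2, 3):
        subsets.extend(itertools.combinations(_PREDICTOR_ORDER, r))
    models = []
    for subset in subsets:
        age_opts = age_set if "age" in subset else (None,)
        edu_opts = EDUCATION_TRANSFORMS if "education" in subset else (None,)
        for at in age_opts:
            for et in edu_opts:
                models.append(CandidateModel(subset, age_transform=at,
                                             education_transform=et))
    return models


@dataclass(frozen=True)
class FitResult:
    """Fitted summary of one candidate model on one score."""

    model: CandidateModel
    response: str
    intercept: float
    coefficients: dict[str, float]
    centrings: dict[str, float]
    residual_variance: float      # MLE, RSS / n
    rss: float
    n: int
    k: int                        # intercept + slopes + residual variance
    bic: float
    r_squared: float
    p_values: dict[str, float]

    def to_correction_model(self, score_name: str | None = None) -> CorrectionModel:
        terms = []
        for p in self.model.predictors:
            if p == "sex":
                terms.append(CorrectionTerm("sex", "identity",
                                            self.coefficients["sex[male]"],
                                            self.centrings["sex[male]"]))
            elif p == "age":
                lbl = transform_label(self.model.age_transform, "age")
                terms.append(CorrectionTerm("age", self.model.age_transform,
                                            self.coefficients[lbl],
                                            self.centrings[lbl]))
            else:
                lbl = transform_label(self.model.education_transform, "education")
                terms.append(CorrectionTerm("education",
                                            self.model.education_transform,
                                            self.coefficients[lbl],
                                            self.centrings[lbl]))
        return CorrectionModel(score_name or self.response, tuple(terms))


def _gaussian_bic(rss: float, n: int, k: int) -> float:
    if rss <= 0:
        return -math.inf
    loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
    return -2.0 * loglik + k * math.log(n)


def bic(fit: FitResult) -> float:
    """Gaussian BIC = -2 max log L + k ln n, k including the variance."""
    if fit.n <= fit.k:
        raise ValueError(f"BIC undefined for n={fit.n} <= k={fit.k}")
    return _gaussian_bic(fit.rss, fit.n, fit.k)


def fit_model(model: CandidateModel, cohort: pd.DataFrame,
              response: str) -> FitResult:
    """Fit one candidate by OLS on the rows with complete data.

    Continuous covariates are transformed then centred at the cohort mean of
    the transformed covariate; sex is a male/female contrast centred at the
    male proportion (female = reference).  Raises on rank-deficient designs
    and transform-domain violations.
    """
    cols = [response] + [c for c in ("sex", "age", "education")
                         if c in model.predictors]
    data = cohort.dropna(subset=cols)
    y = data[response].to_numpy(dtype=float)
    n = len(y)

    columns, names, centrings = [], [], {}
    for p in model.predictors:
        if p == "sex":
            x = (data["sex"].to_numpy() == "male").astype(float)
            name = "sex[male]"
        elif p == "age":
            x = apply_transform(model.age_transform,
                                data["age"].to_numpy(dtype=float), "age")
            name = transform_label(model.age_transform, "age")
        else:
            x = apply_transform(model.education_transform,
                                data["education"].to_numpy(dtype=float),
                                "education")
            name = transform_label(model.education_transform, "education")
        c = float(np.mean(x))
        columns.append(x - c)
        names.append(name)
        centrings[name] = c

    X = np.column_stack([np.ones(n)] + columns)
    k = X.shape[1] + 1  # + residual variance
    if n <= k:
        raise ValueError(f"cannot fit {model.formula}: n={n} <= k={k}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {model.formula}; collinear terms "
            f"among {['intercept'] + names}")

    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if (tss == 0 or not model.predictors) \
        else float(np.clip(1.0 - rss / tss, 0.0, 1.0))
    return FitResult(
        model=model,
        response=response,
        intercept=float(res.params[0]),
        coefficients={nm: float(b) for nm, b in zip(names, res.params[1:])},
        centrings=centrings,
        residual_variance=rss / n,
        rss=rss,
        n=n,
        k=k,
        bic=_gaussian_bic(rss, n, k),
        r_squared=r2,
        p_values={nm: float(p) for nm, p in zip(names, res.pvalues[1:])},
    )


def select_best(fits: list[FitResult], window: float = 2.0) -> FitResult:
    """Apply the BIC-with-parsimony selection rule.

    Candidate set = all fits within ``window`` BIC points of the minimum;
    winner = fewest parameters, ties broken by lower BIC, then by position in
    the input (canonical enumeration) order.
    """
    if not fits:
        raise ValueError("select_best needs a non-empty list of fits")
    min_bic = min(f.bic for f in fits)
    candidates = [(f.k, f.bic, i) for i, f in enumerate(fits)
                  if f.bic - min_bic <= window]
    _, _, best = min(candidates)
    return fits[best]


def covariate_significance(fit: FitResult, family_size: int) -> dict[str, bool]:
    """Bonferroni-corrected significance flags per term.

    A term is significant iff p * family_size <= 0.05 (boundary inclusive).
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return {term: p * family_size <= 0.05 for term, p in fit.p_values.items()}


class NormativeModelSearch(BaseEstimator):
    """sklearn-style estimator running the model-space search per score.

    Parameters
    ----------
    scores : list of response column names, or None to use every canonical
        score column present in the fitted DataFrame.
    include_ln100 : enumerate the 112-model space (seven age transforms)
        instead of the 98-model space.
    bic_window : parsimony window in BIC points.
    bonferroni_family : family size for term significance; None = number of
        terms in the selected model.

    Attributes (after ``fit``)
    --------------------------
    models_ : the enumerated candidate list (shared across scores).
    fits_ : dict score -> list of FitResult in enumeration order.
    selected_ : dict score -> winning FitResult.
    correction_models_ : dict canonical score name -> CorrectionModel.
    significant_ : dict score -> {term: bool}.
    report_ : tidy DataFrame (score, formula, k, bic, r_squared, selected).
    """

    def __init__(self, scores=None, include_ln100: bool = False,
                 bic_window: float = 2.0, bonferroni_family: int | None = None):
        self.scores = scores
        self.include_ln100 = include_ln100
        self.bic_window = bic_window
        self.bonferroni_family = bonferroni_family

    def fit(self, X: pd.DataFrame, y=None):
        from .scoring import COLUMN_TO_SCORE
        scores = self.scores
        if scores is None:
            scores = [c for c in COLUMN_TO_SCORE if c in X.columns]
        if not scores:
            raise ValueError("no score columns to fit")
        self.models_ = enumerate_models(self.include_ln100)
        self.fits_, self.selected_ = {}, {}
        self.correction_models_, self.significant_ = {}, {}
        rows = []
        for score in scores:
            fits = []
            for m in self.models_:
                try:
                    fits.append(fit_model(m, X, score))
                except ValueError:
                    continue  # e.g. ln(education) with 0 years present
            if not fits:
                raise ValueError(f"no candidate model could be fitted for {score!r}")
            best = select_best(fits, self.bic_window)
            self.fits_[score] = fits
            self.selected_[score] = best
            family = self.bonferroni_family or max(1, len(best.p_values))
            self.significant_[score] = covariate_significance(best, family)
            canonical = COLUMN_TO_SCORE.get(score, score)
            self.correction_models_[canonical] = best.to_correction_model(canonical)
            for f in fits:
                rows.append({"score": score, "formula": f.model.formula,
                             "k": f.k, "bic": f.bic, "r_squared": f.r_squared,
                             "selected": f is best})
        self.report_ = pd.DataFrame(rows)
        return self
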