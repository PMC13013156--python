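"""Demographic correction of raw Stroop scores.

A fitted normative model for a score is reduced to a :class:`CorrectionModel`:
a list of ``(covariate, transform, coefficient, centring)`` terms.  The
additive correction for a subject is

    correction = -(sum_j  coef_j * (transform_j(covariate_j) - centring_j))

and ``corrected = raw + correction``: a subject whose demographics predict
worse-than-reference performance receives a favourable (negative for times at
high education / low age... sign follows the model) adjustment toward the
centred reference subject.

The published formulas for all twelve scores ship with the package as a
frozen, versioned norm set.  For four scores the published exact formula does
not regenerate the published band-midpoint correction grid (the table
clinicians actually use); those models are flagged ``consistent=False`` and a
grid-lookup mode evaluates the printed grid directly with nearest-band
assignment instead of silently resolving the discrepancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._transforms import AGE_TRANSFORMS, apply_transform, transform_label

__all__ = [
    "CorrectionTerm",
    "CorrectionModel",
    "NormGrid",
    "correction_term",
    "build_norm_grid",
    "apply_correction",
    "load_published_norms",
    "load_published_grids",
    "grid_correction",
    "DemographicCorrector",
    "DEFAULT_AGE_BANDS",
    "DEFAULT_EDUCATION_BANDS",
]

DEFAULT_AGE_BANDS = [(20, 24), (25, 29), (30, 34), (35, 39), (40, 44),
                     (45, 49), (50, 54), (55, 59), (60, 64), (65, 69),
                     (70, 74), (75, 79), (80, 84), (85, 90)]
DEFAULT_EDUCATION_BANDS = [(0, 4), (5, 8), (9, 13), (14, 19)]


@dataclass(frozen=True)
class CorrectionTerm:
    covariate: str           # 'age' | 'education' | 'sex'
    transform: str
    coefficient: float
    centring: float

    def __post_init__(self):
        if self.transform not in AGE_TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if not (np.isfinite(self.coefficient) and np.isfinite(self.centring)):
            raise ValueError("coefficient and centring must be finite")

    @property
    def label(self) -> str:
        return transform_label(self.transform, self.covariate)


@dataclass(frozen=True)
class CorrectionModel:
    """Selected transforms, coefficients, and centring constants for a score."""

    score_name: str
    terms: tuple[CorrectionTerm, ...]
    consistent: bool = True
    note: str = ""


def _term_value(term: CorrectionTerm, age: float, education: float,
                sex: str | None) -> float:
    if term.covariate == "age":
        return apply_transform(term.transform, age, "age")
    if term.covariate == "education":
        return apply_transform(term.transform, education, "education")
    if term.covariate == "sex":
        if sex is None:
            raise ValueError(f"model {term.label!r} needs the subject's sex")
        return 1.0 if sex == "male" else 0.0
    raise ValueError(f"unknown covariate {term.covariate!r}")


def correction_term(model: CorrectionModel, age: float, education: float,
                    sex: str | None = None) -> float:
    """Additive demographic correction for one subject.

    Raises on domain violations (e.g. ln(education) at education 0, or
    ln(100-age) at age >= 100), naming the offending transform.
    """
    s = 0.0
    for term in model.terms:
        try:
            value = _term_value(term, age, education, sex)
        except ValueError as exc:
            raise ValueError(f"{model.score_name}: {term.label}: {exc}") from None
        s += term.coefficient * (value - term.centring)
    return -s


def apply_correction(raw: float, model: CorrectionModel, record,
                     floor: float | None = None) -> float:
    """Adjusted score = raw + correction; optional floor (for error scores).

    ``record`` may be a ParticipantRecord or anything with age / education /
    sex attributes.
    """
    adj = raw + correction_term(model, record.age, record.education,
                                getattr(record, "sex", None))
    if floor is not None:
        adj = max(floor, adj)
    return adj


def _round_half_away(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class NormGrid:
    """Band-midpoint correction table for one score.

    ``cells[i][j]`` is the full-precision correction for education band i and
    age band j (a single row when the model has no education term);
    :meth:`rounded` applies the display convention (2 d.p., ties away from
    zero).
    """

    score_name: str
    age_bands: tuple
    education_bands: tuple | None
    cells: tuple

    def rounded(self, decimals: int = 2):
        return [[_round_half_away(c, decimals) for c in row]
                for row in self.cells]

    def to_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        rows = self.rounded(decimals) if decimals is not None else self.cells
        index = (["-"] if self.education_bands is None
                 else [f"{lo}-{hi}" for lo, hi in self.education_bands])
        cols = [f"{lo}-{hi}" for lo, hi in self.age_bands]
        return pd.DataFrame(rows, index=pd.Index(index, name="education"),
                            columns=cols)


def _midpoint(band) -> float:
    lo, hi = band
    return (lo + hi) / 2.0


def build_norm_grid(model: CorrectionModel, age_bands=None,
                    education_bands=None) -> NormGrid:
    """Evaluate the correction at every band-midpoint combination.

    ``education_bands`` may be None for age-only models.  Bands must be
    ordered and non-overlapping.
    """
    age_bands = list(age_bands or DEFAULT_AGE_BANDS)
    uses_edu = any(t.covariate == "education" for t in model.terms)
    if uses_edu and education_bands is None:
        education_bands = DEFAULT_EDUCATION_BANDS
    for bands in (age_bands, education_bands or []):
        pairs = list(bands)
        for (l1, h1), (l2, h2) in zip(pairs, pairs[1:]):
            if l2 <= h1:
                raise ValueError("bands must be ordered and non-overlapping")
    edu_mids = ([None] if not uses_edu or education_bands is None
                else [_midpoint(b) for b in education_bands])
    cells = tuple(
        tuple(correction_term(model, _midpoint(ab), em if em is not None else 10.0)
              for ab in age_bands)
        for em in edu_mids
    )
    return NormGrid(
        score_name=model.score_name,
        age_bands=tuple(tuple(b) for b in age_bands),
        education_bands=(None if edu_mids == [None]
                         else tuple(tuple(b) for b in education_bands)),
        cells=cells,
    )


def _load_data(name: str) -> dict:
    with resources.files("stroopnorm.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_published_norms() -> dict[str, CorrectionModel]:
    """The twelve published correction formulas, transcribed digit-for-digit.

    Models whose published formula conflicts with the published correction
    grid carry ``consistent=False`` plus an explanatory note.
    """
    raw = _load_data("published_norms.json")["norms"]
    return {
        name: CorrectionModel(
            score_name=name,
            terms=tuple(CorrectionTerm(**t) for t in entry["terms"]),
            consistent=entry["consistent"],
            note=entry.get("note", ""),
        )
        for name, entry in raw.items()
    }


def load_published_grids() -> dict[str, NormGrid]:
    """The published band-midpoint correction grids (2 d.p., as printed)."""
    raw = _load_data("published_grids.json")
    age_bands = tuple(tuple(b) for b in raw["age_bands"])
    edu_bands = tuple(tuple(b) for b in raw["education_bands"])
    grids = {}
    for name, rows in raw["grids"].items():
        grids[name] = NormGrid(
            score_name=name,
            age_bands=age_bands,
            education_bands=edu_bands if len(rows) > 1 else None,
            cells=tuple(tuple(r) for r in rows),
        )
    return grids


def _band_index(bands, value: float) -> int:
    """Nearest-band assignment: containing band, else closest by distance."""
    for i, (lo, hi) in enumerate(bands):
        if lo <= value <= hi:
            return i
    dists = [min(abs(value - lo), abs(value - hi)) for lo, hi in bands]
    return int(np.argmin(dists))


def grid_correction(grid: NormGrid, age: float, education: float | None = None) -> float:
    """Correction looked up from a printed grid with nearest-band assignment."""
    j = _band_index(grid.age_bands, age)
    if grid.education_bands is None:
        return grid.cells[0][j]
    if education is None:
        raise ValueError(f"{grid.score_name}: grid lookup needs education")
    i = _band_index(grid.education_bands, education)
    return grid.cells[i][j]


class DemographicCorrector(TransformerMixin, BaseEstimator):
    """sklearn transformer: raw scores -> demographically adjusted scores.

    Parameters
    ----------
    norms : 'published' or a mapping score-name -> CorrectionModel
        With 'published' the frozen published formulas are used.
    inconsistent_mode : {'formula', 'grid'}
        For published models flagged inconsistent, either apply the
        as-published formula anyway ('formula') or look the correction up in
        the printed grid ('grid', the clinical behaviour).
    floor_errors : bool
        Floor adjusted error scores at 0.
    """

    def __init__(self, norms="published", inconsistent_mode: str = "grid",
                 floor_errors: bool = False):
        self.norms = norms
        self.inconsistent_mode = inconsistent_mode
        self.floor_errors = floor_errors

    def fit(self, X=None, y=None):
        if self.inconsistent_mode not in ("formula", "grid"):
            raise ValueError("inconsistent_mode must be 'formula' or 'grid'")
        if self.norms == "published":
            self.models_ = load_published_norms()
            self.grids_ = load_published_grids()
        else:
            self.models_ = dict(self.norms)
            self.grids_ = {name: build_norm_grid(m)
                           for name, m in self.models_.items()}
        return self

    def correction(self, score_name: str, age: float, education: float,
                   sex: str | None = None) -> float:
        model = self.models_[score_name]
        if not model.consistent and self.inconsistent_mode == "grid":
            return grid_correction(self.grids_[score_name], age, education)
        return correction_term(model, age, education, sex)

    def transform(self, X: pd.DataFrame, score_columns: dict | None = None
                  ) -> pd.DataFrame:
        """Append ``adj_<column>`` columns for every scored column present.

        ``score_columns`` maps DataFrame column -> norm score name; defaults
        to the canonical lowercase mapping (t4 -> T4, t4_t3 -> T4-T3, ...).
        """
        from .scoring import COLUMN_TO_SCORE  # local import avoids cycle
        if not hasattr(self, "models_"):
            self.fit()
        mapping = score_columns or {
            col: name for col, name in COLUMN_TO_SCORE.items()
            if col in X.columns and name in self.models_
        }
        out = X.copy()
        for col, name in mapping.items():
            adj = []
            for _, row in X.iterrows():
                raw = row[col]
                if pd.isna(raw):
                    adj.append(np.nan)
                    continue
                a = raw + self.correction(name, row["age"], row["education"],
                                          row.get("sex"))
                if self.floor_errors and col.startswith("e"):
                    a = max(0.0, a)
                adj.append(a)
            out[f"adj_{col}"] = adj
        return out

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X, y).transform(X, **kwargs)
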