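"""Covariate transformations used throughout the norming pipeline.

The model space applies one of a small set of monotone (or polynomial)
transformations to age and education before centring.  Domains are enforced
here so that every caller (model search, correction formulas, the synthetic
cohort generator) rejects e.g. ``ln(education)`` at education 0 with the same
diagnostic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EDUCATION_TRANSFORMS",
    "AGE_TRANSFORMS",
    "apply_transform",
    "transform_label",
]

#: transforms legal for education (and, minus the last entry, for age too)
EDUCATION_TRANSFORMS = ("identity", "sqrt", "square", "cube", "ln", "reciprocal")

#: transforms legal for age; ``ln_100_minus_age`` only makes sense for age
AGE_TRANSFORMS = EDUCATION_TRANSFORMS + ("ln_100_minus_age",)


def apply_transform(name: str, values, covariate: str = "covariate"):
    """Apply the named transform elementwise, validating its domain.

    Parameters
    ----------
    name : transform identifier from :data:`AGE_TRANSFORMS`.
    values : scalar or array-like of covariate values.
    covariate : name used in error messages.
    """
    x = np.asarray(values, dtype=float)
    if name == "identity":
        out = x
    elif name == "sqrt":
        if np.any(x < 0):
            raise ValueError(f"sqrt({covariate}) undefined for negative values")
        out = np.sqrt(x)
    elif name == "square":
        out = x**2
    elif name == "cube":
        out = x**3
    elif name == "ln":
        if np.any(x <= 0):
            raise ValueError(f"ln({covariate}) undefined for {covariate} <= 0")
        out = np.log(x)
    elif name == "reciprocal":
        if np.any(x == 0):
            raise ValueError(f"1/{covariate} undefined for {covariate} = 0")
        out = 1.0 / x
    elif name == "ln_100_minus_age":
        if np.any(x >= 100):
            raise ValueError("ln(100 - age) undefined for age >= 100")
        out = np.log(100.0 - x)
    else:
        raise ValueError(f"unknown transform {name!r}")
    if np.ndim(values) == 0:
        return float(out)
    return out


def transform_label(name: str, covariate: str) -> str:
    """Human-readable term label, e.g. ``('cube', 'age') -> 'age^3'``."""
    labels = {
        "identity": covariate,
        "sqrt": f"sqrt({covariate})",
        "square": f"{covariate}^2",
        "cube": f"{covariate}^3",
        "ln": f"ln({covariate})",
        "reciprocal": f"1/{covariate}",
        "ln_100_minus_age": "ln(100-age)",
    }
    try:
        return labels[name]
    except KeyError:
        raise ValueError(f"unknown transform {name!r}") from None
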