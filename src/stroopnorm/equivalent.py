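"""Non-parametric tolerance limits and Equivalent-Score cut-offs.

Adjusted scores are standardised on the Italian five-level Equivalent-Score
(ES) scale using distribution-free one-sided tolerance limits:

* the **outer tolerance limit** (OTL) is the order statistic guaranteeing,
  with the stated confidence (default 95%), that no more than 5% of the
  reference population performs worse than it;
* the **inner tolerance limit** (ITL) symmetrically guarantees that no less
  than 5% performs worse; it is reported but plays no role in ES assignment.

Scores worse than the OTL are ES = 0 (defective); scores better than the
sample median are ES = 4 (normal).  The ranks strictly between the OTL rank
and the median are subdivided into three contiguous blocks of equal count
(+-1) whose boundaries are the ES 1/2/3 cut-offs, so the three intermediate
classes have equal density in the calibration sample.

Internally every score is put on a worst-to-best ordering (times and error
counts sort descending), so a single code path serves both polarities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ToleranceBands",
    "tolerance_order_index",
    "compute_bands",
    "assign_es",
    "load_published_bands",
    "EquivalentScoreScaler",
]


@dataclass(frozen=True)
class ToleranceBands:
    """OTL/ITL and ES cut-offs for one score, on the adjusted-score scale.

    For ``higher_is_worse``: ES 0 iff adjusted > ``otl``; ES k (k = 1..3) iff
    adjusted lies in (next cut-off, previous cut-off]; ES 4 iff adjusted <=
    ``cutoff_es3`` (the median).  Mirrored with < / >= for
    ``lower_is_worse``.  Adjacent equal cut-offs (legal, occurs in published
    norms) collapse the class between them to empty.
    """

    score_name: str
    direction: str                # 'higher_is_worse' | 'lower_is_worse'
    otl: float
    itl: float
    cutoff_es1: float
    cutoff_es2: float
    cutoff_es3: float             # the sample median
    coverage: float = 0.95
    confidence: float = 0.95
    degenerate: bool = False

    def __post_init__(self):
        if self.direction not in ("higher_is_worse", "lower_is_worse"):
            raise ValueError(f"unknown direction {self.direction!r}")


def tolerance_order_index(n: int, coverage: float = 0.95,
                          confidence: float = 0.95, side: str = "outer") -> int:
    """Order-statistic rank (1-based, worst-to-best) of a tolerance limit.

    With ``q = 1 - coverage`` the population fraction allowed beyond the
    limit, and B ~ Binomial(n, q) the number of sample values falling in the
    population's worst-q tail:

    * outer: the largest rank r with P(B >= r) >= confidence — the least
      conservative order statistic still guaranteeing that at most a
      fraction q of the population is worse than it;
    * inner: the smallest rank r with P(B <= r - 1) >= confidence — the
      companion bound from the other side.

    Raises when no rank satisfies the guarantee (n too small; at the 95/95
    defaults the outer limit first exists at n = 59).
    """
    if side not in ("outer", "inner"):
        raise ValueError("side must be 'outer' or 'inner'")
    if not (0 < coverage < 1 and 0 < confidence < 1):
        raise ValueError("coverage and confidence must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    q = 1.0 - coverage
    if side == "outer":
        # P(B >= r) = sf(r - 1); decreasing in r
        if stats.binom.sf(0, n, q) < confidence:
            raise ValueError(
                f"insufficient n: no outer tolerance limit exists for n={n} "
                f"at coverage {coverage}, confidence {confidence}")
        r = 1
        while r < n and stats.binom.sf(r, n, q) >= confidence:
            r += 1
        return r
    # inner: P(B <= r - 1) = cdf(r - 1); increasing in r
    r = int(stats.binom.ppf(confidence, n, q)) + 1
    while stats.binom.cdf(r - 1, n, q) < confidence:
        r += 1
    if r > n:
        raise ValueError(
            f"insufficient n: no inner tolerance limit exists for n={n} "
            f"at coverage {coverage}, confidence {confidence}")
    return r


def _equal_blocks(m: int) -> tuple[int, int, int]:
    """Split m ranks into three contiguous blocks with counts differing <= 1.

    Remainders go to the worse (OTL-adjacent) end first: deterministic.
    """
    base, rem = divmod(m, 3)
    return tuple(base + (1 if i < rem else 0) for i in range(3))


def compute_bands(adjusted_scores, direction: str = "higher_is_worse",
                  coverage: float = 0.95, confidence: float = 0.95,
                  score_name: str = "") -> ToleranceBands:
    """Tolerance limits and ES cut-offs from a calibration sample.

    Missing values are dropped.  An all-equal sample yields degenerate bands
    (all cut-offs equal) with the ``degenerate`` flag set.
    """
    x = np.asarray(adjusted_scores, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    sign = 1.0 if direction == "higher_is_worse" else -1.0
    w = np.sort(sign * x)[::-1]          # worst first

    if n and np.all(w == w[0]):
        v = float(sign * w[0])
        return ToleranceBands(score_name, direction, v, v, v, v, v,
                              coverage, confidence, degenerate=True)

    r_otl = tolerance_order_index(n, coverage, confidence, "outer")
    r_itl = tolerance_order_index(n, coverage, confidence, "inner")
    otl = float(w[r_otl - 1])
    itl = float(w[r_itl - 1])
    median = float(np.median(w))

    upper = n // 2                        # last rank on the worse side of the median
    m = max(0, upper - r_otl)             # ranks strictly between OTL and median
    b1, b2, _ = _equal_blocks(m)
    c1 = float(w[r_otl + b1 - 1]) if m else otl
    c2 = float(w[r_otl + b1 + b2 - 1]) if m else median

    return ToleranceBands(
        score_name=score_name, direction=direction,
        otl=sign * otl, itl=sign * itl,
        cutoff_es1=sign * c1, cutoff_es2=sign * c2, cutoff_es3=sign * median,
        coverage=coverage, confidence=confidence,
    )


def assign_es(adjusted: float, bands: ToleranceBands) -> int:
    """Map an adjusted score to its Equivalent Score (0-4).

    The five classes partition the real line; ties at a cut-off fall in the
    better class (the published tables use "<=" on the ES 4 side).
    """
    sign = 1.0 if bands.direction == "higher_is_worse" else -1.0
    v = sign * adjusted
    cuts = (sign * bands.otl, sign * bands.cutoff_es1,
            sign * bands.cutoff_es2, sign * bands.cutoff_es3)
    for es, cut in enumerate(cuts):
        if v > cut:
            return es
    return 4


def load_published_bands() -> dict[str, ToleranceBands]:
    """The published ITL and ES cut-offs (higher is worse for every score)."""
    with resources.files("stroopnorm.data").joinpath("published_bands.json").open() as fh:
        raw = json.load(fh)["bands"]
    return {
        name: ToleranceBands(
            score_name=name, direction="higher_is_worse",
            otl=b["es0"], itl=b["itl"],
            cutoff_es1=b["es1"], cutoff_es2=b["es2"], cutoff_es3=b["es3"],
        )
        for name, b in raw.items()
    }


class EquivalentScoreScaler(TransformerMixin, BaseEstimator):
    """sklearn transformer: adjusted scores -> Equivalent Scores.

    ``fit`` calibrates one :class:`ToleranceBands` per column of the adjusted
    healthy-score DataFrame (or uses the frozen published cut-offs when
    ``bands='published'``); ``transform`` maps adjusted scores to ES 0-4.
    """

    def __init__(self, bands="fit", direction: str = "higher_is_worse",
                 coverage: float = 0.95, confidence: float = 0.95):
        self.bands = bands
        self.direction = direction
        self.coverage = coverage
        self.confidence = confidence

    def fit(self, X, y=None):
        import pandas as pd
        if isinstance(self.bands, str) and self.bands == "published":
            self.bands_ = load_published_bands()
        elif isinstance(self.bands, dict):
            self.bands_ = dict(self.bands)
        else:
            X = pd.DataFrame(X)
            self.bands_ = {
                col: compute_bands(X[col], self.direction, self.coverage,
                                   self.confidence, score_name=str(col))
                for col in X.columns
            }
        return self

    def transform(self, X):
        import pandas as pd
        X = pd.DataFrame(X)
        out = {}
        for col in X.columns:
            key = col if col in self.bands_ else None
            if key is None:
                continue
            b = self.bands_[key]
            out[col] = [np.nan if pd.isna(v) else assign_es(float(v), b)
                        for v in X[col]]
        return pd.DataFrame(out, index=X.index)
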