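"""ICC(2,1) reliability of derived neural indices.

The intraclass correlation used here is the two-way random-effects,
absolute-agreement, single-measure form: subjects are rows (targets),
repeated determinations of the same index (e.g. day x resolution-parameter
combinations) are columns. Values >= 0.40 are flagged "fair to good".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, InvalidParameterError

FAIR_TO_GOOD_THRESHOLD = 0.40


@dataclass(frozen=True)
class IccResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    fair_to_good: bool


def icc_2_1(table) -> IccResult:
    """ICC(2,1) from the two-way ANOVA decomposition of an n x k table.

    With MSR/MSC/MSE the between-target, between-measurement and residual
    mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Systematic column offsets lower the ICC (absolute agreement, not mere
    consistency). Negative estimates are reported as-is.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise InvalidParameterError("ratings must form a 2-D targets x measurements table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InvalidParameterError("need at least 2 targets and 2 measurements")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("ratings contain missing or non-finite values")
    grand = x.mean()
    sst = float(((x - grand) ** 2).sum())
    if sst == 0.0:
        raise DegenerateDataError("degenerate ratings: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return IccResult(
        icc=float(icc), ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse),
        fair_to_good=bool(icc >= FAIR_TO_GOOD_THRESHOLD),
    )


def residualize_motion(values, motion) -> np.ndarray:
    """Residualize a per-subject index on (intercept, mean displacement).

    A constant motion vector carries no information; the centered values
    are returned with a warning in that case.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(motion, dtype=float)
    if v.shape != m.shape or v.ndim != 1:
        raise InvalidParameterError("values and motion must be equal-length vectors")
    if np.ptp(m) == 0.0:
        warnings.warn("motion vector is constant; returning centered values", stacklevel=2)
        return v - v.mean()
    X = np.column_stack([np.ones_like(m), m])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta
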