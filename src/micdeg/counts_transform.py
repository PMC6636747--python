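"""Continuous-to-count transformation for count-based downstream tools.

Count-model methods (e.g. negative-binomial RNA-seq tools) need nonnegative
integers, but simulated expression values are continuous and may be
negative; naive rounding also destroys low-intensity information.  The
transformation here:

  1. (Cauchy data only) winsorizes extreme low outliers — values below
     -2*sigma, sigma the population standard deviation of the whole matrix
     — to the -2*sigma boundary, then multiplies the remaining values by 10
     so that sub-unit expression differences survive integer rounding;
  2. if any value is still negative, shifts the whole matrix by |min| + 2
     (the +2 keeps zeros rare);
  3. rounds half away from zero.

Scaling and translation do not deform a density curve, so the transform
does not change which genes look differentially expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["TransformReport", "to_counts"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransformReport:
    n_outliers_handled: int
    shift_applied: float
    scaled_by_10: bool
    sigma: float


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def to_counts(matrix, cauchy_flag: bool = False,
              outlier_mode: str = "clamp") -> tuple[np.ndarray, TransformReport]:
    """Transform continuous expression values into nonnegative integer counts.

    ``outlier_mode`` is "clamp" (winsorize; keeps the matrix rectangular) or
    "drop" (delete outlier entries; only valid for 1-D input).  Returns the
    integer array and a report of what was done.
    """
    d = np.asarray(matrix, dtype=float).copy()
    if d.size == 0:
        raise ValueError("matrix must be nonempty")
    if outlier_mode not in ("clamp", "drop"):
        raise ValueError("outlier_mode must be 'clamp' or 'drop'")
    if outlier_mode == "drop" and d.ndim != 1:
        raise ValueError("outlier_mode='drop' requires a 1-D vector")

    n_outliers = 0
    scaled = False
    sigma = float(d.std(ddof=0))
    if cauchy_flag and sigma == 0.0:
        log.warning("constant input: sigma is 0, transform degenerates to "
                    "shift + round")
    elif cauchy_flag:
        scaled = True
        bound = -2.0 * sigma
        out = d < bound
        n_outliers = int(out.sum())
        if outlier_mode == "drop":
            d = d[~out]
            d *= 10.0
        else:
            d[~out] *= 10.0
            d[out] = bound
    if d.size == 0:
        raise ValueError("every entry was dropped as an outlier")
    mn = d.min()
    shift = 0.0
    if mn < 0:
        shift = abs(mn) + 2.0
        d = d + shift
    counts = _round_half_away(d)
    return counts, TransformReport(n_outliers_handled=n_outliers,
                                   shift_applied=shift,
                                   scaled_by_10=scaled,
                                   sigma=sigma)
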