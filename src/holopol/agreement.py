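"""Bland-Altman agreement between estimated and reference measurements.

The classic form: for paired values, the differences d_i = estimate_i -
reference_i are summarized by their mean (bias) and sample standard
deviation; the 95% limits of agreement are bias +/- 1.96 * SD.  The
per-pair table lists ((estimate + reference)/2, difference) for the
standard plot.  No proportional-bias regression or repeated-measures
variant is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ShapeError

__all__ = ["BlandAltmanResult", "bland_altman"]

#: Normal 97.5% quantile used for the 95% limits of agreement.
LOA_QUANTILE = 1.96


@dataclass
class BlandAltmanResult:
    n: int
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    table: pd.DataFrame  # columns: mean, difference
    fraction_inside: float

    def summary(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd": self.sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "fraction_inside": self.fraction_inside,
        }


def bland_altman(estimates, references) -> BlandAltmanResult:
    """Bland-Altman statistics for paired estimate/reference values.

    SD uses the sample divisor (n - 1).  ``fraction_inside`` is the
    share of pairs whose difference lies within [loa_low, loa_high];
    for normally distributed differences it approaches 0.95.
    """
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(references, dtype=float)
    if e.shape != r.shape or e.ndim != 1:
        raise ShapeError("estimates and references must be 1-D of equal length")
    n = len(e)
    if n < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    d = e - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - LOA_QUANTILE * sd, bias + LOA_QUANTILE * sd
    inside = float(np.mean((d >= lo) & (d <= hi)))
    table = pd.DataFrame({"mean": (e + r) / 2.0, "difference": d})
    return BlandAltmanResult(n, bias, sd, lo, hi, table, inside)
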