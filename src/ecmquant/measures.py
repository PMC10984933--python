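"""Distribution comparison and assay arithmetic.

ECDF and the two-sample Kolmogorov–Smirnov test operate on the pooled
relative aggregate sizes produced by the classification chain; the
carbohydrate formula converts an Anthrone-assay glucose-equivalent
reading into µg carbohydrate per mg dry weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["EcdfCurve", "ecdf", "KsResult", "ks_two_sample", "carbohydrate_content"]


@dataclass(frozen=True)
class EcdfCurve:
    """Right-continuous empirical CDF: F(q) = #{x_i <= q} / n."""

    x: np.ndarray  # sorted sample values
    heights: np.ndarray  # i/n at each sorted value

    def __call__(self, q) -> np.ndarray | float:
        q = np.asarray(q, dtype=float)
        out = np.searchsorted(self.x, q, side="right") / self.x.size
        return float(out) if out.ndim == 0 else out


def ecdf(values) -> EcdfCurve:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ecdf needs at least one value")
    if not np.all(np.isfinite(values)):
        raise ValueError("ecdf requires finite values")
    x = np.sort(values)
    n = x.size
    return EcdfCurve(x=x, heights=np.arange(1, n + 1) / n)


@dataclass(frozen=True)
class KsResult:
    """Two-sample KS comparison.

    ``d_stat`` is the two-sided sup |F1 - F2| over the pooled sample
    points; ``d_plus``/``d_minus`` are the one-sided statistics
    sup(F1 - F2) and sup(F2 - F1) with their one-sided asymptotic
    p-values, reported because some study designs use one-sided tests
    without fixing the direction. ``p_value`` belongs to ``d_stat``.
    """

    d_stat: float
    p_value: float
    d_plus: float
    d_minus: float
    p_plus: float
    p_minus: float
    n1: int
    n2: int
    method: str


def ks_two_sample(a, b, method: str = "auto") -> KsResult:
    """Two-sample Kolmogorov–Smirnov test.

    ``method``: 'asymptotic' uses the Kolmogorov distribution with
    effective n = n1*n2/(n1+n2); 'exact' uses the exact two-sided null
    distribution (delegated to scipy) and is the 'auto' choice when
    n1*n2 <= 10_000.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    pooled = np.concatenate((a_sorted, b_sorted))
    f1 = np.searchsorted(a_sorted, pooled, side="right") / n1
    f2 = np.searchsorted(b_sorted, pooled, side="right") / n2
    d_plus = float(np.max(f1 - f2))
    d_minus = float(np.max(f2 - f1))
    d = max(d_plus, d_minus, 0.0)
    en = n1 * n2 / (n1 + n2)
    if method == "auto":
        method = "exact" if n1 * n2 <= 10_000 else "asymptotic"
    if method == "exact":
        p = float(stats.ks_2samp(a, b, method="exact").pvalue)
    elif method == "asymptotic":
        p = float(special.kolmogorov(np.sqrt(en) * d))
    else:
        raise ValueError(f"unknown method {method!r}")
    p_plus = float(np.clip(np.exp(-2.0 * en * d_plus**2), 0.0, 1.0))
    p_minus = float(np.clip(np.exp(-2.0 * en * d_minus**2), 0.0, 1.0))
    return KsResult(
        d_stat=d,
        p_value=min(p, 1.0),
        d_plus=d_plus,
        d_minus=d_minus,
        p_plus=p_plus,
        p_minus=p_minus,
        n1=n1,
        n2=n2,
        method=method,
    )


def carbohydrate_content(
    glc_eq_ug: float, dwc_mg_per_ml: float, cm: float, ce: float
) -> float:
    """µg carbohydrate per mg dry weight from an Anthrone assay.

    result = Glc.eq / (DWC * (CM / CE)) where Glc.eq (µg) is the
    glucose weight matching the OD620 reading, DWC the dry weight per
    mL of sample, CM the concentration of the re-suspended sample used
    for the measurement, and CE the dry weight of extracted EPS per mL.
    """
    for name, val in (
        ("glc_eq_ug", glc_eq_ug),
        ("dwc_mg_per_ml", dwc_mg_per_ml),
        ("cm", cm),
        ("ce", ce),
    ):
        if not np.isfinite(val) or val <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {val}")
    return float(glc_eq_ug / (dwc_mg_per_ml * (cm / ce)))
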