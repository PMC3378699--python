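"""Method-comparison and disease-normalization statistics.

Covers the agreement analyses used to compare acquisition variants
(ordinary least-squares regression with a t-test of slope = 1,
Bland-Altman bias with +-2 SD limits of agreement), the percent
normalization of diseased-heart velocities to controls, and the
24-sector correlation map that flags asynchronous or artifact-corrupted
wall regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class AgreementReport:
    """Regression + Bland-Altman agreement summary for paired series."""

    slope: float
    intercept: float
    pearson_r: float
    p_slope_vs_1: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("agreement analysis needs >= 3 pairs")


def pair_series(a, b):
    """Match two series frame by frame, truncating to the shorter one
    (acquisition variants may differ by a couple of frames)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n = min(len(a), len(b))
    return a[:n], b[:n]


def ir_normalize(v_ir, v_control):
    """Percent difference of a diseased-heart velocity vs control:
    100 * (v_ir - v_control) / v_control.

    Normalizing to the signed control value makes a reduced magnitude
    read negative for both positive (systolic contraction) and negative
    (diastolic relaxation, longitudinal) components.  A zero control
    value is undefined and reported as NaN.
    """
    v_ir = np.asarray(v_ir, dtype=float)
    v_control = np.asarray(v_control, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * (v_ir - v_control) / v_control
    out = np.where(v_control == 0, np.nan, out)
    return float(out) if out.ndim == 0 else out


def bland_altman(a, b):
    """Bland-Altman statistics of paired measurements.

    Differences d = a - b; bias = mean(d); sd_diff = sample SD(d);
    limits of agreement = bias +- 2 SD.
    Returns ``(bias, sd_diff, loa_low, loa_high)``.  The sample SD is
    defined from two pairs on; the combined :func:`agreement_report`
    requires at least three.
    """
    a, b = pair_series(a, b)
    if len(a) < 2:
        raise ValueError("Bland-Altman analysis needs >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 2 * sd, bias + 2 * sd


def regression_slope_test(x, y, null_slope: float = 1.0):
    """OLS regression of y on x with a t-test of slope == ``null_slope``.

    Returns ``(slope, intercept, r, p)`` with the two-sided p-value of
    t = (slope - null) / SE(slope) on n - 2 degrees of freedom.  A
    perfect fit (SE = 0) cannot reject: p = 1 when the slope equals the
    null value, else p = 0.
    """
    x, y = pair_series(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("regression needs >= 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("regression needs variance in x")
    res = sps.linregress(x, y)
    se = res.stderr
    if se == 0 or not np.isfinite(se):
        p = 1.0 if np.isclose(res.slope, null_slope) else 0.0
    else:
        t = (res.slope - null_slope) / se
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(p)


def agreement_report(a, b, null_slope: float = 1.0) -> AgreementReport:
    """Full agreement analysis of method a vs method b (paired)."""
    a, b = pair_series(a, b)
    slope, intercept, r, p = regression_slope_test(b, a, null_slope)
    bias, sd, lo, hi = bland_altman(a, b)
    return AgreementReport(slope=slope, intercept=intercept, pearson_r=r,
                           p_slope_vs_1=p, bias=bias, sd_diff=sd,
                           loa_low=lo, loa_high=hi, n_points=len(a))


def correlation_map(segment_series: np.ndarray, global_series: np.ndarray
                    ) -> np.ndarray:
    """Pearson correlation of each angular sector's mean radial velocity
    series with the global time course.

    ``segment_series`` has shape (n_segments, n_frames); sectors with a
    constant series have undefined correlation and yield NaN.  For a
    synchronously contracting ventricle all coefficients approach 1.
    """
    seg = np.atleast_2d(np.asarray(segment_series, dtype=float))
    g = np.asarray(global_series, dtype=float)
    if seg.shape[1] != len(g) or len(g) < 3:
        raise ValueError("need same-length series of length >= 3")
    g0 = g - g.mean()
    g_norm = np.sqrt((g0 ** 2).sum())
    out = np.full(seg.shape[0], np.nan)
    for i, s in enumerate(seg):
        s0 = s - np.nanmean(s)
        # a constant series (up to rounding) has no defined correlation
        if np.nanstd(s) < 1e-12 * (np.nanmax(np.abs(s)) + 1.0):
            continue
        denom = g_norm * np.sqrt(np.nansum(s0 ** 2))
        if denom == 0 or not np.isfinite(denom):
            continue
        out[i] = np.nansum(s0 * g0) / denom
    return out
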