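"""Bespoke statistics for the measurement tables: 2^ΔCt expression and
modified Thompson Tau outlier rejection.

Standard hypothesis tests (ANOVA, Tukey HSD, Kolmogorov–Smirnov, Wilcoxon,
Mann–Whitney) are deliberately thin pass-throughs to scipy and are not
re-derived here.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

__all__ = [
    "relative_expression",
    "thompson_tau_filter",
    "thompson_tau",
    "anova",
    "tukey_hsd",
    "ks_test",
    "wilcoxon",
    "mann_whitney",
]


def relative_expression(ct_control: float, ct_target: float) -> float:
    """Relative expression R = 2^(Ct_control − Ct_target).

    Cycle-threshold differences against a reference gene (e.g. Gapdh) map to
    fold changes on the doubling scale; equal Ct gives R = 1.
    """
    ct_control = float(ct_control)
    ct_target = float(ct_target)
    if not (np.isfinite(ct_control) and np.isfinite(ct_target)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (ct_control - ct_target))


def thompson_tau(n: int, alpha: float = 0.05) -> float:
    """Modified Thompson rejection multiple τ for sample size n.

    τ = t · (n − 1) / (√n · √(n − 2 + t²)) with t the two-sided Student
    quantile t_(α/2, n−2); the most extreme point is an outlier when its
    absolute deviation from the mean exceeds τ·SD.
    """
    if n < 3:
        raise ValueError("Thompson Tau requires n >= 3")
    t = _st.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t * (n - 1) / (np.sqrt(n) * np.sqrt(n - 2 + t**2)))


def thompson_tau_filter(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative Thompson Tau outlier exclusion.

    At each step the most extreme point (largest |x − mean|) is tested
    against τ·SD and removed if it exceeds it; the procedure repeats on the
    reduced sample until no removal occurs or fewer than three points remain.
    Returns (retained, excluded) in input order.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1D")
    if len(x) < 3:
        raise ValueError("Thompson Tau filtering requires n >= 3")
    keep = np.ones(len(x), dtype=bool)
    while keep.sum() >= 3:
        sample = x[keep]
        sd = sample.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sample - sample.mean())
        worst = int(np.argmax(dev))
        if dev[worst] > thompson_tau(len(sample), alpha) * sd:
            keep[np.flatnonzero(keep)[worst]] = False
        else:
            break
    return x[keep], x[~keep]


# -- thin pass-throughs ------------------------------------------------------

def anova(*groups):
    """One-way ANOVA (scipy.stats.f_oneway)."""
    return _st.f_oneway(*groups)


def tukey_hsd(*groups):
    """Tukey-Kramer honest significant difference (scipy.stats.tukey_hsd)."""
    return _st.tukey_hsd(*groups)


def ks_test(a, b):
    """Two-sample Kolmogorov–Smirnov test."""
    return _st.ks_2samp(a, b)


def wilcoxon(a, b=None, **kw):
    """Wilcoxon signed-rank test."""
    return _st.wilcoxon(a, b, **kw)


def mann_whitney(a, b, **kw):
    """Mann–Whitney U test."""
    return _st.mannwhitneyu(a, b, **kw)
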