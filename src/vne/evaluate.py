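"""Method-agreement statistics for paired measurements.

Covers the comparisons used to validate virtual native enhancement against
conventional LGE: ordinary least squares / Pearson correlation, intraclass
correlation ICC(2,1) (two-way random effects, absolute agreement, single
rater), Bland–Altman bias and limits of agreement (parametric and
percentile, since real-data intervals are often asymmetric), and the
Wilcoxon signed-rank test for paired scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "linear_fit",
    "icc_agreement",
    "bland_altman",
    "wilcoxon_paired",
    "agreement_report",
]


@dataclass
class PairedMeasurements:
    """Two methods' measurements on the same subjects."""

    subjects: list
    method_a: np.ndarray
    method_b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        n = len(self.subjects)
        if not (len(self.method_a) == len(self.method_b) == n):
            raise ValueError("subjects, method_a and method_b must have equal length")
        if n < 2:
            raise ValueError("at least two paired measurements are required")
        if not (np.all(np.isfinite(self.method_a)) and np.all(np.isfinite(self.method_b))):
            raise ValueError("measurements must be finite")

    @property
    def n(self) -> int:
        return len(self.subjects)


@dataclass
class AgreementReport:
    """Correlation, reliability and Bland–Altman summary for one comparison."""

    label: str
    n: int
    r: float
    slope: float
    intercept: float
    icc: float
    icc_ci95: tuple[float, float]
    icc_degenerate: bool
    bias: float
    loa_parametric: tuple[float, float]
    loa_percentile: tuple[float, float]
    bias_ci95: tuple[float, float]
    loa_lower_ci95: tuple[float, float]
    loa_upper_ci95: tuple[float, float]


def linear_fit(pm: PairedMeasurements) -> tuple[float, float, float]:
    """OLS of method_b on method_a: (slope, intercept, Pearson R)."""
    if pm.n < 3:
        raise ValueError("linear fit requires n >= 3")
    if np.var(pm.method_a) == 0:
        raise ValueError("degenerate input: method_a has zero variance")
    res = stats.linregress(pm.method_a, pm.method_b)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def icc_agreement(pm: PairedMeasurements) -> tuple[float, tuple[float, float], bool]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Returns (estimate, 95% CI, degenerate_flag).  When the between-subject
    variance is degenerate (all measurements identical) the boundary value is
    returned with the flag set and a warning issued.
    """
    if pm.n < 3:
        raise ValueError("ICC requires n >= 3")
    both = np.concatenate([pm.method_a, pm.method_b])
    if np.allclose(both, both[0]):
        warnings.warn("degenerate variance: all measurements identical; ICC set to 1.0")
        return 1.0, (1.0, 1.0), True
    df = pd.DataFrame(
        {
            "subject": list(pm.subjects) * 2,
            "rater": ["a"] * pm.n + ["b"] * pm.n,
            "score": both,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score", nan_policy="raise")
    table = table.set_index("Type")
    # absolute-agreement single-rater row; label varies across pingouin versions
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[key]
    est = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in row.index else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    if not np.isfinite(est):
        warnings.warn("degenerate variance in ICC computation")
        return 0.0, (0.0, 0.0), True
    return est, (lo, hi), False


def bland_altman(pm: PairedMeasurements) -> dict:
    """Bland–Altman bias and limits of agreement for a − b.

    Parametric limits are bias ± 1.96·SD with standard large-sample CIs;
    percentile limits are the 2.5th/97.5th empirical percentiles of the
    differences, reported alongside because real differences are often
    skewed.
    """
    if pm.n < 3:
        raise ValueError("Bland-Altman requires n >= 3")
    d = pm.method_a - pm.method_b
    n = pm.n
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo = bias - 1.96 * sd
    hi = bias + 1.96 * sd
    p_lo, p_hi = (float(v) for v in np.percentile(d, [2.5, 97.5]))
    t = stats.t.ppf(0.975, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return {
        "bias": bias,
        "sd": sd,
        "loa_parametric": (lo, hi),
        "loa_percentile": (p_lo, p_hi),
        "bias_ci95": (bias - t * se_bias, bias + t * se_bias),
        "loa_lower_ci95": (lo - t * se_loa, lo + t * se_loa),
        "loa_upper_ci95": (hi - t * se_loa, hi + t * se_loa),
    }


_EXACT_LIMIT = 25  # exact signed-rank null by DP up to this many non-zero pairs


def _signed_rank_exact_sf(ranks2: np.ndarray) -> np.ndarray:
    """Null PMF of 2·W+ for given doubled (midrank-safe) ranks, by DP."""
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt
    return pmf / pmf.sum()


def wilcoxon_paired(pm: PairedMeasurements) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired scores (two-sided).

    Zero differences are dropped (Wilcoxon's convention) and ties are
    mid-ranked.  The null distribution is enumerated exactly (dynamic
    programming over sign patterns) for up to 25 non-zero pairs; beyond
    that the normal approximation with tie and continuity corrections is
    used.  Returns (statistic = min(W+, W−), p-value).
    """
    d = pm.method_a - pm.method_b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no signal: all paired differences are zero")
    if n < 5:
        raise ValueError("at least 5 non-zero differences are required")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= _EXACT_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(int)
        pmf = _signed_rank_exact_sf(ranks2)
        w2 = int(round(2 * w_plus))
        p_lo = pmf[: w2 + 1].sum()
        p_hi = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    else:
        mean = n * (n + 1) / 4.0
        # variance with midrank tie correction
        var = ranks.astype(float) ** 2 / 4.0
        var = var.sum()
        z = (statistic - mean + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.cdf(z))
    return statistic, float(p)


def agreement_report(pm: PairedMeasurements) -> AgreementReport:
    """Full agreement summary (correlation, ICC, Bland–Altman) for one pair set."""
    slope, intercept, r = linear_fit(pm)
    icc, icc_ci, degenerate = icc_agreement(pm)
    ba = bland_altman(pm)
    return AgreementReport(
        label=pm.label,
        n=pm.n,
        r=r,
        slope=slope,
        intercept=intercept,
        icc=icc,
        icc_ci95=icc_ci,
        icc_degenerate=degenerate,
        bias=ba["bias"],
        loa_parametric=ba["loa_parametric"],
        loa_percentile=ba["loa_percentile"],
        bias_ci95=ba["bias_ci95"],
        loa_lower_ci95=ba["loa_lower_ci95"],
        loa_upper_ci95=ba["loa_upper_ci95"],
    )
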