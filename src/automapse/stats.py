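"""Method-comparison statistics for paired MAPSE measurements.

Implements the agreement protocol used to compare an automatic method with a
manual reference: Bland–Altman bias with 95% limits of agreement, the two-way
mixed-model intraclass correlation for consistency (ICC(3,1), optionally
average-measures) with its F-based confidence interval, Pearson correlation
with a Fisher-z confidence interval, Fisher-z comparison of two correlation
coefficients, Fisher's exact test on feasibility counts, and the cohort
feasibility tally (per wall, >=1 wall, >=2 walls, >=1 complete view, all four
walls).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BlandAltman", "IccResult", "PearsonResult",
    "complete_pairs", "bland_altman", "icc_consistency", "pearson_ci",
    "compare_correlations", "compare_correlations_dependent",
    "fisher_exact_2x2", "feasibility_table", "VIEW_WALLS", "WALLS",
]

# anatomical walls per mid-oesophageal view (left/right landmark in each)
VIEW_WALLS = {
    "me4ch": ("inferoseptal", "anterolateral"),
    "me2ch": ("inferior", "anterior"),
}
WALLS = VIEW_WALLS["me4ch"] + VIEW_WALLS["me2ch"]


@dataclass(frozen=True)
class BlandAltman:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    diagnostic: str | None = None


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


def complete_pairs(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Listwise-complete view of two paired measurement vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


def bland_altman(a, b) -> BlandAltman:
    """Bias = mean(a - b) and 95% limits of agreement bias +- 1.96 sd(a - b).

    The standard deviation uses the n-1 (sample) denominator.
    """
    a, b = complete_pairs(a, b)
    if len(a) < 2:
        raise ValueError("need at least 2 complete pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(n=len(a), bias=bias, sd_diff=sd,
                       loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def icc_consistency(a, b, alpha: float = 0.05,
                    average: bool = False) -> IccResult:
    """Two-way mixed-model intraclass correlation for consistency.

    Single-measure ICC(3,1) by default, average-measures ICC(3,k) with
    ``average=True``; k = 2 raters.  The confidence interval follows the
    F-based interval on MS_rows / MS_error.  Consistency ICC ignores a fixed
    offset between raters (b = a + c gives ICC = 1).
    """
    a, b = complete_pairs(a, b)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    x = np.column_stack([a, b])
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    # rounding floor: an exactly consistent table has ss_err == 0
    if ss_total > 0 and ss_err < 1e-12 * ss_total:
        ss_err = 0.0
    df_rows, df_err = n - 1, (n - 1) * (k - 1)
    msr = ss_rows / df_rows
    mse = ss_err / df_err

    if msr <= 0.0 and mse <= 0.0:
        return IccResult(icc=float("nan"), ci_low=float("nan"),
                         ci_high=float("nan"), n=n,
                         diagnostic="zero variance across subjects")
    if mse == 0.0:
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, n=n,
                         diagnostic="zero residual variance")

    f_obs = msr / mse
    fq = sps.f.ppf(1 - alpha / 2, df_rows, df_err)
    fq_rev = sps.f.ppf(1 - alpha / 2, df_err, df_rows)
    fl = f_obs / fq
    fu = f_obs * fq_rev
    if average:
        icc = (msr - mse) / msr
        lo, hi = 1.0 - 1.0 / fl, 1.0 - 1.0 / fu
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse)
        lo = (fl - 1.0) / (fl + k - 1.0)
        hi = (fu - 1.0) / (fu + k - 1.0)
    return IccResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi), n=n)


def pearson_ci(a, b, alpha: float = 0.05) -> PearsonResult:
    """Pearson r with the Fisher-z confidence interval tanh(z ± z_q/√(n-3))."""
    a, b = complete_pairs(a, b)
    n = len(a)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(sps.pearsonr(a, b).statistic)
    if abs(r) >= 1.0 - 1e-12:
        warnings.warn("|r| = 1: Fisher-z interval degenerates to a point")
        return PearsonResult(r=r, ci_low=r, ci_high=r, n=n)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zq = sps.norm.ppf(1 - alpha / 2)
    return PearsonResult(r=r, ci_low=math.tanh(z - zq * se),
                         ci_high=math.tanh(z + zq * se), n=n)


def compare_correlations(r1: float, n1: int, r2: float,
                         n2: int) -> tuple[float, float]:
    """Fisher-z comparison of two correlations from independent samples.

    Returns ``(z, p)`` with a two-sided normal p-value.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ValueError("|r| = 1 cannot be compared on the z scale")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return float(z), p


def compare_correlations_dependent(r12: float, r13: float, r23: float,
                                   n: int) -> tuple[float, float]:
    """Steiger's z for two correlations sharing one variable (same sample).

    Compares r12 with r13 where variable 1 is common and r23 is the
    correlation between the two non-shared variables.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r12, r13):
        if abs(r) >= 1.0:
            raise ValueError("|r| = 1 cannot be compared on the z scale")
    z12, z13 = math.atanh(r12), math.atanh(r13)
    rbar2 = ((r12 + r13) / 2.0) ** 2
    cov = (r23 * (1 - 2 * rbar2) - 0.5 * rbar2
           * (1 - 2 * rbar2 - r23 ** 2)) / (1 - rbar2) ** 2
    z = (z12 - z13) * math.sqrt((n - 3) / (2.0 * (1 - cov)))
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return float(z), p


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p on a 2x2 count table.

    Two-sidedness follows the standard convention of summing the
    probabilities of all tables no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = np.round(t).astype(int)
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def feasibility_table(feasible: pd.DataFrame) -> pd.DataFrame:
    """Cohort feasibility tally across two views (four walls) per recording.

    ``feasible`` is long format with columns ``id``, ``method``, ``wall``
    (one of ``WALLS``) and boolean ``feasible``.  Returns counts and
    percentages per method for: overall (4 walls pooled), each wall,
    >= 1 wall, >= 2 walls, >= 1 view with both walls, and all four walls.
    """
    required = {"id", "method", "wall", "feasible"}
    if not required.issubset(feasible.columns):
        raise ValueError(f"feasibility table needs columns {sorted(required)}")
    unknown = set(feasible["wall"]) - set(WALLS)
    if unknown:
        raise ValueError(f"unknown wall labels: {sorted(unknown)}")

    rows = []
    for method, grp in feasible.groupby("method", sort=False):
        wide = grp.pivot_table(index="id", columns="wall", values="feasible",
                               aggfunc="first").reindex(columns=WALLS)
        wide = wide.fillna(False).astype(bool)
        n_rec = len(wide)
        per_rec = wide.sum(axis=1)
        view_ok = {v: wide[list(ws)].all(axis=1)
                   for v, ws in VIEW_WALLS.items()}
        any_view = np.logical_or(view_ok["me4ch"], view_ok["me2ch"])

        def add(label, count, total):
            rows.append({"method": method, "analysis": label,
                         "n": int(count), "total": int(total),
                         "pct": 100.0 * count / total if total else np.nan})

        add("overall_4_walls", wide.values.sum(), n_rec * 4)
        for wall in WALLS:
            add(wall, wide[wall].sum(), n_rec)
        add("ge1_wall", (per_rec >= 1).sum(), n_rec)
        add("ge2_walls", (per_rec >= 2).sum(), n_rec)
        add("ge1_view_both_walls", any_view.sum(), n_rec)
        add("all_4_walls", (per_rec == 4).sum(), n_rec)
    return pd.DataFrame(rows)
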