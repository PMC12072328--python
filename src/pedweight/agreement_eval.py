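"""Agreement statistics between estimated and actual weights.

Implements the full method-comparison battery for a weight estimator
evaluated against measured weights:

* per-subject percentage errors e_i = 100·(pred_i − actual_i)/actual_i;
* MPE (bias), MAPE and RMSPE (precision), RMSE in kg;
* Bland–Altman mean difference and 95% limits of agreement
  (mean ± 1.96·SD of the kg differences, predicted − actual);
* PW10/PW20 accuracy: the share of subjects within 10%/20% of actual;
* intraclass correlation, two-way random-effects, absolute agreement,
  single measures — ICC(A,1) — with an F-based 95% CI and the conventional
  banding poor (<0.25) / low (0.25–0.49) / moderate (0.50–0.69) /
  good (0.70–0.89) / excellent (≥0.90);
* age-subgroup stratification (1–12 months, 13–71 months, 72–155 months;
  13–23-month-olds are placed in the middle group so the partition is
  exhaustive), cohort summary tables, and the two-proportion sample-size
  formula.

The SD in the limits of agreement uses the population convention
(divide by n) by default, under which the algebraic identity
rmse² = mean_diff² + var(diff) is exact — the engine behind reconstructing
an RMSE from printed limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

__all__ = [
    "AgreementReport",
    "IccResult",
    "AGE_SUBGROUPS",
    "percentage_errors",
    "summarize",
    "rmse_from_loa",
    "icc",
    "icc_band",
    "subgroup_reports",
    "cohort_summary",
    "percentage",
    "sample_size_two_proportions",
    "bland_altman_plot",
]

#: Age subgroup bounds in months (inclusive), labels as reported clinically.
AGE_SUBGROUPS = (
    ("1-12 months", 1, 12),
    ("2-5 years", 13, 71),
    ("6-12 years", 72, 155),
)

ICC_BANDS = (
    (0.25, "poor"),
    (0.50, "low"),
    (0.70, "moderate"),
    (0.90, "good"),
    (float("inf"), "excellent"),
)


@dataclass
class AgreementReport:
    n: int
    mpe: float
    mape: float
    rmspe: float
    rmse: float
    mean_diff: float
    loa_lower: float
    loa_upper: float
    pw10: float
    pw20: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IccResult:
    icc: float
    ci_lower: float
    ci_upper: float
    p_value: float
    band: str

    def to_dict(self) -> dict:
        return asdict(self)


def percentage_errors(actual: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """100·(pred − actual)/actual per subject."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have matching shapes")
    if np.any(actual <= 0):
        raise ValueError("actual weights must be strictly positive")
    if not np.all(np.isfinite(predicted)):
        raise ValueError("non-finite predictions")
    return 100.0 * (predicted - actual) / actual


def summarize(
    actual: np.ndarray,
    predicted: np.ndarray,
    sd_convention: str = "population",
    pw_thresholds: tuple[float, float] = (10.0, 20.0),
    z: float = 1.96,
) -> AgreementReport:
    """All scalar agreement metrics for one method on one (sub)cohort."""
    if sd_convention not in ("population", "sample"):
        raise ValueError("sd_convention must be 'population' or 'sample'")
    e = percentage_errors(actual, predicted)
    n = len(e)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    diff = np.asarray(predicted, dtype=float) - np.asarray(actual, dtype=float)
    ddof = 0 if sd_convention == "population" else 1
    sd = float(diff.std(ddof=ddof))
    mean_diff = float(diff.mean())
    t10, t20 = pw_thresholds
    return AgreementReport(
        n=n,
        mpe=float(e.mean()),
        mape=float(np.abs(e).mean()),
        rmspe=float(np.sqrt(np.mean(e**2))),
        rmse=float(np.sqrt(np.mean(diff**2))),
        mean_diff=mean_diff,
        loa_lower=mean_diff - z * sd,
        loa_upper=mean_diff + z * sd,
        pw10=100.0 * float(np.mean(np.abs(e) <= t10)),
        pw20=100.0 * float(np.mean(np.abs(e) <= t20)),
    )


def rmse_from_loa(lower: float, upper: float, z: float = 1.96) -> float:
    """Reconstruct an RMSE from printed 95% limits of agreement.

    With mean = (U+L)/2 and sd = (U−L)/(2z), rmse = √(mean² + sd²) — exact
    under the population-SD convention for the limits.
    """
    if upper < lower:
        raise ValueError("upper limit below lower limit")
    mean = (upper + lower) / 2.0
    sd = (upper - lower) / (2.0 * z)
    return math.sqrt(mean * mean + sd * sd)


# ---------------------------------------------------------------------------
# Intraclass correlation: ICC(A,1), two-way random, absolute agreement
# ---------------------------------------------------------------------------

def icc_band(value: float) -> str:
    for upper, label in ICC_BANDS:
        if value < upper:
            return label
    return "excellent"


def icc(actual: np.ndarray, predicted: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(A,1) on the n×2 (actual, predicted) matrix, CI by the F method.

    Mean squares come from the two-way subjects × methods ANOVA; the
    confidence interval uses the Satterthwaite-degrees-of-freedom F bounds
    and the p-value tests ICC = 0 via F = MS_rows/MS_error.
    """
    y = np.column_stack([np.asarray(actual, float), np.asarray(predicted, float)])
    n, k = y.shape
    if n < 5:
        raise ValueError("need at least 5 subjects for ICC")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("ICC undefined: no between-subject variance")

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    value = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # McGraw & Wong CI for ICC(A,1)
    a = (k * value) / (n * (1.0 - value)) if value < 1.0 else np.inf
    b = 1.0 + (k * value * (n - 1)) / (n * (1.0 - value)) if value < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        denom_const = k * msc + (k * n - k - n) * mse
        lower = n * (msr - f_l * mse) / (f_l * denom_const + n * msr)
        upper = n * (f_u * msr - mse) / (denom_const + n * f_u * msr)
    else:
        lower = upper = 1.0

    with np.errstate(divide="ignore"):  # mse == 0 under perfect agreement
        f_stat = msr / mse if mse > 0 else np.inf
    p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    value = float(value)
    return IccResult(
        icc=value,
        ci_lower=float(min(lower, value)),
        ci_upper=float(max(upper, value)),
        p_value=p,
        band=icc_band(value),
    )


# ---------------------------------------------------------------------------
# Stratification and cohort description
# ---------------------------------------------------------------------------

def assign_subgroup(age_months: float) -> str:
    for label, lo, hi in AGE_SUBGROUPS:
        if lo <= age_months <= hi:
            return label
    raise ValueError(f"age {age_months} months outside [1, 155]")


def subgroup_reports(
    pairs: pd.DataFrame, sd_convention: str = "population"
) -> dict[str, dict]:
    """Per-age-subgroup and overall agreement + ICC.

    ``pairs`` needs columns actual_kg, predicted_kg, age_months.
    """
    groups: dict[str, dict] = {}
    labels = pairs["age_months"].map(assign_subgroup)
    for label, _, _ in AGE_SUBGROUPS:
        sub = pairs[labels == label]
        if len(sub) == 0:
            continue
        groups[label] = _report_pair(sub, sd_convention)
    groups["overall"] = _report_pair(pairs, sd_convention)
    return groups


def _report_pair(sub: pd.DataFrame, sd_convention: str) -> dict:
    a = sub["actual_kg"].to_numpy()
    p = sub["predicted_kg"].to_numpy()
    out = {"agreement": summarize(a, p, sd_convention=sd_convention)}
    try:
        out["icc"] = icc(a, p)
    except ValueError:
        out["icc"] = None
    return out


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Count percentage at fixed precision (round-half-to-even)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def _median_iqr(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear-interpolation quantiles
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def cohort_summary(subjects: pd.DataFrame) -> dict:
    """Descriptive table: median [IQR] for continuous, n (%) for categorical.

    ``subjects`` needs columns age_months, sex, body_type, height_cm,
    weight_kg.  BMI is derived.  Statistics are reported overall and per age
    subgroup; category percentages are rounded to 1 decimal place.
    """
    if len(subjects) < 1:
        raise ValueError("empty cohort")
    df = subjects.copy()
    df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    df["age_years"] = df["age_months"] / 12.0
    df["subgroup"] = df["age_months"].map(assign_subgroup)

    def describe(sub: pd.DataFrame) -> dict:
        n = len(sub)
        out: dict = {"n": n}
        for col in ("age_years", "weight_kg", "height_cm", "bmi"):
            out[col] = _median_iqr(sub[col].to_numpy())
        out["sex"] = {
            level: {"n": int((sub["sex"] == level).sum()),
                    "pct": percentage(int((sub["sex"] == level).sum()), n)}
            for level in ("male", "female")
        }
        out["body_type"] = {
            level: {"n": int((sub["body_type"] == level).sum()),
                    "pct": percentage(int((sub["body_type"] == level).sum()), n)}
            for level in ("thin", "normal", "overweight")
        }
        return out

    summary = {"overall": describe(df)}
    for label, _, _ in AGE_SUBGROUPS:
        sub = df[df["subgroup"] == label]
        if len(sub):
            summary[label] = describe(sub)
    return summary


# ---------------------------------------------------------------------------
# Design: sample size for comparing two proportions
# ---------------------------------------------------------------------------

def sample_size_two_proportions(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Per-group n for the two-sided two-proportion z-test (normal approx.).

    n = (z_{α/2}·√(2·p̄·q̄) + z_β·√(p1·q1 + p2·q2))² / (p2 − p1)², ceiled.
    """
    for name, v in (("p1", p1), ("p2", p2), ("alpha", alpha), ("power", power)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 must differ from p2 (required n is infinite)")
    z_a = ndtri(1.0 - alpha / 2.0)
    z_b = ndtri(power)
    pbar = (p1 + p2) / 2.0
    qbar = 1.0 - pbar
    num = z_a * math.sqrt(2.0 * pbar * qbar) + z_b * math.sqrt(
        p1 * (1 - p1) + p2 * (1 - p2)
    )
    return int(math.ceil((num / (p2 - p1)) ** 2))


# ---------------------------------------------------------------------------
# Bland–Altman plot
# ---------------------------------------------------------------------------

def bland_altman_plot(
    actual: np.ndarray,
    predicted: np.ndarray,
    path,
    title: str = "Bland-Altman",
    sd_convention: str = "population",
) -> None:
    """Difference-vs-mean scatter with mean-difference and LOA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = summarize(actual, predicted, sd_convention=sd_convention)
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    mean = (actual + predicted) / 2.0
    diff = predicted - actual

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=10, alpha=0.5)
    ax.axhline(rep.mean_diff, color="k", lw=1)
    for y in (rep.loa_lower, rep.loa_upper):
        ax.axhline(y, color="r", lw=1, ls="--")
    ax.set_xlabel("Mean of actual and predicted weight (kg)")
    ax.set_ylabel("Predicted - actual (kg)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
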