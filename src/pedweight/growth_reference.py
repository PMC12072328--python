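"""Growth reference: percentile lookup, body-type bands, height↔age bridging.

A growth reference is a sex- and age-indexed table of height and weight
distribution parameters for a reference pediatric population.  Here each
(sex, age-in-months) cell carries a median and a coefficient of variation
and the within-cell distribution is log-normal, i.e. the p-quantile of
weight at a cell is

    q(p) = median * exp(z_p * sigma),   sigma = sqrt(ln(1 + cv^2))

with ``z_p`` the standard-normal quantile.  This is the LMS growth-curve
family in its L→0 limit: strictly positive, right-skewed, and with
percentile curves that never cross as long as the median curve is monotone.

The module ships a synthetic reference built from smooth parametric median
curves (fast infant growth saturating into a linear childhood phase) so the
whole pipeline is testable without external chart tables; a real reference
with the same CSV schema can be dropped in unchanged.

Body habitus is anchored to the weight-for-age distribution: *thin* below
the 25th percentile, *overweight* above the 75th, *normal* in between
(boundaries inclusive to normal).  A habitus band is converted back to a
single displayed weight via a representative percentile per band
(defaults 12.5 / 50 / 87.5, the band midpoints).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "Sex",
    "BodyType",
    "GrowthChart",
    "AgeRangeError",
    "HeightRangeError",
    "synthetic_growth_chart",
    "percentile_weight",
    "percentile_height",
    "classify_body_type",
    "derive_weight",
    "height_to_age_equivalent",
    "DEFAULT_BAND_PERCENTILES",
]

AGE_MIN_MONTHS = 1
AGE_MAX_MONTHS = 155  # 1 month through 12 years inclusive

#: Representative percentile used to collapse a habitus band to one weight.
DEFAULT_BAND_PERCENTILES = {"thin": 0.125, "normal": 0.50, "overweight": 0.875}

THIN_CUTOFF = 0.25
OVERWEIGHT_CUTOFF = 0.75


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class BodyType(str, enum.Enum):
    thin = "thin"
    normal = "normal"
    overweight = "overweight"


class AgeRangeError(ValueError):
    """Queried age falls outside the chart's age grid."""


class HeightRangeError(ValueError):
    """Queried height falls outside the chart's median-height range."""


def _as_sex(sex: Sex | str) -> str:
    return Sex(sex).value


def _as_body_type(body_type: BodyType | str) -> str:
    return BodyType(body_type).value


@dataclass
class GrowthChart:
    """Sex × age-month grid of height/weight log-normal parameters.

    ``table`` columns: sex, age_months, height_median_cm, height_cv,
    weight_median_kg, weight_cv.  Medians must increase strictly with age
    within each sex and CVs must lie in (0, 0.5); both are validated on
    construction.
    """

    table: pd.DataFrame
    _by_sex: dict = field(init=False, repr=False)

    REQUIRED_COLUMNS = (
        "sex",
        "age_months",
        "height_median_cm",
        "height_cv",
        "weight_median_kg",
        "weight_cv",
    )

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"growth chart missing columns: {sorted(missing)}")
        self._by_sex = {}
        for sex in ("male", "female"):
            sub = (
                self.table[self.table["sex"] == sex]
                .sort_values("age_months")
                .reset_index(drop=True)
            )
            if sub.empty:
                raise ValueError(f"growth chart has no rows for sex={sex!r}")
            ages = sub["age_months"].to_numpy()
            if not np.array_equal(ages, np.unique(ages)):
                raise ValueError(f"duplicate ages for sex={sex!r}")
            for col in ("height_median_cm", "weight_median_kg"):
                if not np.all(np.diff(sub[col].to_numpy()) > 0):
                    raise ValueError(f"{col} not strictly increasing with age ({sex})")
            for col in ("height_cv", "weight_cv"):
                cv = sub[col].to_numpy()
                if np.any(cv <= 0) or np.any(cv >= 0.5):
                    raise ValueError(f"{col} outside (0, 0.5) ({sex})")
            self._by_sex[sex] = sub

    # -- grid access ---------------------------------------------------

    @property
    def age_min(self) -> int:
        return int(min(s["age_months"].iloc[0] for s in self._by_sex.values()))

    @property
    def age_max(self) -> int:
        return int(max(s["age_months"].iloc[-1] for s in self._by_sex.values()))

    def ages(self, sex: Sex | str) -> np.ndarray:
        return self._by_sex[_as_sex(sex)]["age_months"].to_numpy()

    def params(self, sex: Sex | str, age_months: float) -> dict[str, float]:
        """Chart parameters at an (interpolated, possibly fractional) age."""
        sub = self._by_sex[_as_sex(sex)]
        ages = sub["age_months"].to_numpy(dtype=float)
        if not (ages[0] <= age_months <= ages[-1]):
            raise AgeRangeError(
                f"age {age_months} months outside chart grid [{ages[0]}, {ages[-1]}]"
            )
        out = {}
        for col in ("height_median_cm", "height_cv", "weight_median_kg", "weight_cv"):
            out[col] = float(np.interp(age_months, ages, sub[col].to_numpy(dtype=float)))
        return out

    # -- serialization -------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "GrowthChart":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic reference curves
#
# Median stature follows a saturating-exponential infant phase plus a linear
# childhood phase:
#     h(a) = h0 + G * (1 - exp(-a / tau)) + s * a          [cm, a in months]
# with h0 = 49 cm, G = 28.3 cm, tau = 10 months, s = 0.519 cm/month, which
# lands at ~75 cm at 12 months, ~108 cm at 5 years and ~152 cm at 12 years.
# Median weight couples allometrically to stature, w(a) = w1 * (h(a)/h(1))^2.1
# with w1 = 4.3 kg, giving ~8.6 kg at 9 months, ~15 kg at 3 years and
# ~40 kg at 12 years — the regime of the cohort this package emulates.
# Weight dispersion widens with age as in real references (habitus diverges
# through childhood): CV rises linearly from 0.11 at 1 month to 0.20 at 12
# years, slowly enough that weight quantiles stay monotone in age for every
# percentile the pipeline queries.  Height CV is ~constant at 0.035.
# ---------------------------------------------------------------------------

_H0, _GAIN, _TAU, _SLOPE = 49.0, 28.3, 10.0, 0.519
_W1, _ALLOMETRIC_EXP = 4.3, 2.1
_SEX_HEIGHT_FACTOR = {"male": 1.005, "female": 0.995}
_HEIGHT_CV = 0.035
_WEIGHT_CV_INFANT, _WEIGHT_CV_CHILD = 0.11, 0.20


def _median_height_cm(age_months: np.ndarray, sex: str) -> np.ndarray:
    a = np.asarray(age_months, dtype=float)
    base = _H0 + _GAIN * (1.0 - np.exp(-a / _TAU)) + _SLOPE * a
    return base * _SEX_HEIGHT_FACTOR[sex]


def synthetic_growth_chart(
    age_min: int = AGE_MIN_MONTHS, age_max: int = AGE_MAX_MONTHS
) -> GrowthChart:
    """Build the package's synthetic growth reference on an integer month grid."""
    rows = []
    ages = np.arange(age_min, age_max + 1)
    t = (ages - AGE_MIN_MONTHS) / (AGE_MAX_MONTHS - AGE_MIN_MONTHS)
    weight_cv = _WEIGHT_CV_INFANT + t * (_WEIGHT_CV_CHILD - _WEIGHT_CV_INFANT)
    for sex in ("male", "female"):
        h = _median_height_cm(ages, sex)
        h1 = _median_height_cm(np.array([1.0]), sex)[0]
        w = _W1 * (h / h1) ** _ALLOMETRIC_EXP
        rows.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age_months": ages,
                    "height_median_cm": h,
                    "height_cv": _HEIGHT_CV,
                    "weight_median_kg": w,
                    "weight_cv": weight_cv,
                }
            )
        )
    return GrowthChart(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Quantile operations
# ---------------------------------------------------------------------------

def _lognormal_quantile(median: float, cv: float, p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValueError(f"percentile p={p} outside (0, 1)")
    sigma = math.sqrt(math.log1p(cv * cv))
    return median * math.exp(ndtri(p) * sigma)


def percentile_weight(
    chart: GrowthChart, sex: Sex | str, age_months: float, p: float
) -> float:
    """p-quantile of the weight-for-age distribution at (sex, age), in kg."""
    prm = chart.params(sex, age_months)
    return _lognormal_quantile(prm["weight_median_kg"], prm["weight_cv"], p)


def percentile_height(
    chart: GrowthChart, sex: Sex | str, age_months: float, p: float
) -> float:
    """p-quantile of the height-for-age distribution at (sex, age), in cm."""
    prm = chart.params(sex, age_months)
    return _lognormal_quantile(prm["height_median_cm"], prm["height_cv"], p)


def classify_body_type(
    chart: GrowthChart, sex: Sex | str, age_months: float, weight_kg: float
) -> BodyType:
    """Habitus band of a weight: thin < P25 ≤ normal ≤ P75 < overweight."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    lo = percentile_weight(chart, sex, age_months, THIN_CUTOFF)
    hi = percentile_weight(chart, sex, age_months, OVERWEIGHT_CUTOFF)
    if weight_kg < lo:
        return BodyType.thin
    if weight_kg > hi:
        return BodyType.overweight
    return BodyType.normal


def derive_weight(
    chart: GrowthChart,
    sex: Sex | str,
    age_months: float,
    body_type: BodyType | str,
    band_percentiles: dict[str, float] = DEFAULT_BAND_PERCENTILES,
) -> float:
    """Weight displayed for a habitus band: the band's representative quantile."""
    p = band_percentiles[_as_body_type(body_type)]
    return percentile_weight(chart, sex, age_months, p)


def height_to_age_equivalent(
    chart: GrowthChart, sex: Sex | str, height_cm: float
) -> float:
    """Fractional age (months) whose median height equals ``height_cm``.

    Bridges the regressor's height output to age-indexed weight lookup by
    inverting the (strictly increasing) median-height curve with linear
    interpolation between grid months.
    """
    sub = chart._by_sex[_as_sex(sex)]
    ages = sub["age_months"].to_numpy(dtype=float)
    medians = sub["height_median_cm"].to_numpy(dtype=float)
    if not (medians[0] <= height_cm <= medians[-1]):
        raise HeightRangeError(
            f"height {height_cm:.2f} cm outside median range "
            f"[{medians[0]:.2f}, {medians[-1]:.2f}] for sex={_as_sex(sex)}"
        )
    return float(np.interp(height_cm, medians, ages))
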