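"""Normative age-trend modeling and per-feature age estimation.

Session-median features are screened against age at testing with Spearman's
rank correlation (two-sided p below 0.05 marks a feature a significant
predictor of age).  For each significant feature a normative trend — a
linear or quadratic least-squares polynomial of feature versus age, with
goodness of fit R^2 = 1 - SS_res / SS_tot — is fitted over the term-infant
sessions.  Inverting a trend curve at an observed feature value yields a
per-feature estimate of developmental age; a median estimate below the
infant's actual age flags a potential delay for that feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from kicksense.features import FEATURE_NAMES


@dataclass
class ScreenResult:
    """Spearman screen outcome for one feature."""

    feature: str
    r_s: float
    p: float
    significant: bool
    n: int
    screenable: bool = True


@dataclass
class TrendModel:
    """Normative feature-versus-age curve.

    ``coefficients`` are polynomial coefficients in ascending order
    (c0 + c1*age [+ c2*age^2]); ``age_range`` is the training range in weeks.
    """

    feature: str
    form: str  # "linear" | "quadratic"
    coefficients: tuple
    r_squared: float
    age_range: tuple
    n: int

    def __post_init__(self) -> None:
        want = {"linear": 2, "quadratic": 3}.get(self.form)
        if want is None:
            raise ValueError(f"unknown form {self.form!r}")
        if len(self.coefficients) != want:
            raise ValueError(f"{self.form} model needs {want} coefficients")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")

    def predict(self, age) -> np.ndarray:
        """Feature value at the given age(s)."""
        return np.polynomial.polynomial.polyval(np.asarray(age, dtype=float),
                                                self.coefficients)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature, "form": self.form,
            "coefficients": [float(c) for c in self.coefficients],
            "r_squared": float(self.r_squared),
            "age_range": [float(a) for a in self.age_range],
            "n": int(self.n),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrendModel":
        return cls(feature=d["feature"], form=d["form"],
                   coefficients=tuple(d["coefficients"]),
                   r_squared=d["r_squared"],
                   age_range=tuple(d["age_range"]), n=d["n"])


@dataclass
class AgeEstimate:
    """Per-feature developmental-age estimate and delay flag."""

    feature: str
    predicted_age: float  # weeks
    actual_age: float  # weeks
    delayed: bool

    def __post_init__(self) -> None:
        if self.delayed != (self.predicted_age < self.actual_age):
            raise ValueError("delayed flag inconsistent with ages")


def spearman(x, y) -> tuple:
    """Spearman's rho on average ranks with a two-sided t-approximation p.

    Requires n >= 4 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman's rho undefined for a constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def screen_features(summaries, alpha: float = 0.05,
                    features=FEATURE_NAMES) -> list:
    """Screen each feature's session medians against age at testing.

    Sessions where a feature is undefined are dropped pairwise for that
    feature; features with fewer than 4 defined sessions, or constant
    values, are marked not screenable.
    """
    ages = np.array([s.age_at_test for s in summaries], dtype=float)
    results = []
    for name in features:
        vals = np.array([s.features.get(name, float("nan")) for s in summaries],
                        dtype=float)
        ok = ~np.isnan(vals)
        n = int(ok.sum())
        if n < 4 or np.ptp(vals[ok]) == 0 or np.ptp(ages[ok]) == 0:
            results.append(ScreenResult(feature=name, r_s=float("nan"),
                                        p=float("nan"), significant=False,
                                        n=n, screenable=False))
            continue
        r, p = spearman(ages[ok], vals[ok])
        results.append(ScreenResult(feature=name, r_s=r, p=p,
                                    significant=p < alpha, n=n))
    return results


def fit_trend(ages, values, feature: str = "",
              quad_delta_r2: float = 0.05) -> TrendModel:
    """Least-squares linear or quadratic feature-versus-age fit.

    The quadratic form is selected only when it improves R^2 by more than
    ``quad_delta_r2`` over the linear fit, guarding against overfitting; an
    (numerically) exact quadratic fit is always preferred, since noise
    cannot produce one.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~(np.isnan(ages) | np.isnan(values))
    ages, values = ages[ok], values[ok]
    if len(ages) < 4:
        raise ValueError("need at least 4 sessions to fit a trend")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate design: all ages equal")

    def fit(deg):
        coeffs = np.polynomial.polynomial.polyfit(ages, values, deg)
        pred = np.polynomial.polynomial.polyval(ages, coeffs)
        ss_res = float(np.sum((values - pred) ** 2))
        ss_tot = float(np.sum((values - values.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 and ss_res < 1e-12 else 1.0 - ss_res / ss_tot
        return tuple(float(c) for c in coeffs), r2

    lin_c, lin_r2 = fit(1)
    quad_ok = len(np.unique(ages)) >= 3
    if quad_ok:
        quad_c, quad_r2 = fit(2)
    if quad_ok and (quad_r2 - lin_r2 > quad_delta_r2
                    or (quad_r2 > 1 - 1e-9 and lin_r2 < 1 - 1e-9)):
        form, coeffs, r2 = "quadratic", quad_c, quad_r2
    else:
        form, coeffs, r2 = "linear", lin_c, lin_r2
    return TrendModel(feature=feature, form=form, coefficients=coeffs,
                      r_squared=min(r2, 1.0),
                      age_range=(float(ages.min()), float(ages.max())),
                      n=len(ages))


def predict_age(model: TrendModel, value: float,
                grid_step: float = 0.1) -> float:
    """Invert the trend curve: age minimizing |f(age) - value| on a grid.

    The grid covers the training age range at ``grid_step`` weeks, so
    observed values outside the model's range map to the nearest endpoint.
    Exact ties (non-monotone quadratics) resolve to the mean of tied ages.
    """
    lo, hi = model.age_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    diffs = np.abs(model.predict(grid) - value)
    best = diffs.min()
    tied = grid[diffs <= best + 1e-12]
    return float(tied.mean())


def flag_delay(predicted: dict, actual_age: float) -> list:
    """Per-feature delay flags: delayed iff median predicted age < actual."""
    return [
        AgeEstimate(feature=name, predicted_age=float(p),
                    actual_age=float(actual_age), delayed=bool(p < actual_age))
        for name, p in predicted.items()
    ]


def save_models(models, path) -> None:
    with open(path, "w") as fh:
        json.dump({"models": [m.to_dict() for m in models]}, fh, indent=1)


def load_models(path) -> list:
    with open(path) as fh:
        d = json.load(fh)
    return [TrendModel.from_dict(m) for m in d["models"]]
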