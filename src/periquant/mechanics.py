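"""Cortical tension, cell-number staging, and cohort success statistics.

* Micropipette aspiration: at the critical pressure P_c the aspirated
  cortex matches the pipette radius R_p, and Young-Laplace gives the
  cortical tension γ = P_c / (2 (1/R_p − 1/R_c)) for a cell of radius R_c.
* Staging: total cell number grows exponentially with developmental time,
  y = a·e^{b·x} with x in hours past E4.5; fitting is ordinary least
  squares on the log scale and inverting the fit stages an embryo from its
  cell count (embryonic day = 4.5 + x/24).
* Threshold optimization: sweeping an initial-cell-count threshold,
  "above" meaning count >= threshold, and scoring each by confusion-matrix
  accuracy (TP+TN)/(TP+FP+TN+FN) against egg-cylinder formation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import Cohort

log = logging.getLogger(__name__)

#: Default threshold grid (cells): 0..230 step 10.
DEFAULT_THRESHOLDS = tuple(range(0, 231, 10))


@dataclass
class AspirationMeasurement:
    """Critical pressure P_c (Pa), pipette radius R_p (m), cell radius R_c (m)."""

    p_c: float
    r_p: float
    r_c: float

    def __post_init__(self) -> None:
        if not self.p_c > 0:
            raise ValidationError(f"p_c must be > 0, got {self.p_c}")
        if not 0 < self.r_p < self.r_c:
            raise ValidationError(
                f"need 0 < r_p < r_c, got r_p={self.r_p}, r_c={self.r_c}"
            )


@dataclass
class GrowthRegression:
    """Exponential growth fit y = a·e^{b·x}; R² on the log-linear scale;
    x measured in hours from E4.5."""

    a: float
    b: float
    r_squared: float
    time_origin: str = "E4.5"

    def predict(self, hours) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(hours, dtype=float))


@dataclass
class ThresholdScan:
    table: pd.DataFrame  # threshold, tp, fp, tn, fn, accuracy
    optimum: int


def cortical_tension(m: AspirationMeasurement) -> float:
    """γ = P_c / (2 (1/R_p − 1/R_c)) in N/m."""
    return m.p_c / (2.0 * (1.0 / m.r_p - 1.0 / m.r_c))


def fit_exponential_growth(hours: Sequence[float], counts: Sequence[float]) -> GrowthRegression:
    """OLS of ln(count) on hours; a = exp(intercept), b = slope.

    Constant counts give b = 0 with R² = 1 (zero residuals)."""
    x = np.asarray(hours, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError(f"need >= 3 matched points, got {x.size}")
    if np.any(y <= 0):
        raise ValidationError("counts must be strictly positive for a log fit")
    logy = np.log(y)
    if np.ptp(logy) == 0.0:
        return GrowthRegression(a=float(y[0]), b=0.0, r_squared=1.0)
    res = stats.linregress(x, logy)
    return GrowthRegression(
        a=float(np.exp(res.intercept)),
        b=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


def stage_from_count(total_count: float, reg: GrowthRegression) -> float:
    """Invert the growth fit: embryonic day = 4.5 + ln(count/a)/(24 b)."""
    if not total_count >= 1:
        raise ValidationError(f"total_count must be >= 1, got {total_count}")
    if reg.b == 0:
        raise ValidationError("cannot stage from a flat regression (b = 0)")
    hours = math.log(total_count / reg.a) / reg.b
    return 4.5 + hours / 24.0


def threshold_scan(
    cohort: Cohort, thresholds: Sequence[int] = DEFAULT_THRESHOLDS
) -> ThresholdScan:
    """Confusion-matrix sweep over initial-cell-count thresholds.

    At each threshold t, embryos with count >= t are "above". TP = above
    and formed an egg cylinder, FP = above and did not, TN = below and did
    not, FN = below and did. The optimum is the smallest threshold
    attaining maximal accuracy.
    """
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    counts = cohort.counts()
    success = cohort.outcomes()
    rows = []
    for t in thresholds:
        above = counts >= t
        tp = int(np.sum(above & success))
        fp = int(np.sum(above & ~success))
        tn = int(np.sum(~above & ~success))
        fn = int(np.sum(~above & success))
        rows.append(
            {
                "threshold": int(t),
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                "accuracy": (tp + tn) / len(cohort),
            }
        )
    table = pd.DataFrame(rows)
    best = table["accuracy"].max()
    optimum = int(table.loc[table["accuracy"] == best, "threshold"].min())
    return ThresholdScan(table=table, optimum=optimum)


def success_rates(
    n_total: int,
    n_cylinders: int,
    n_evaluated: Optional[int] = None,
    n_asymmetric: Optional[int] = None,
) -> dict:
    """Culture success rates from outcome counts.

    egg_cylinder_rate = cylinders/total; ave_rate_given_cylinder =
    asymmetric/evaluated (None when nothing was evaluated); overall_rate =
    the product of the two. Rates are fractions in [0, 1].
    """
    if n_total <= 0 or n_cylinders < 0 or n_cylinders > n_total:
        raise ValidationError(
            f"invalid counts: total={n_total}, cylinders={n_cylinders}"
        )
    egg = n_cylinders / n_total
    if not n_evaluated:
        return {
            "egg_cylinder_rate": egg,
            "ave_rate_given_cylinder": None,
            "overall_rate": None,
        }
    if n_asymmetric is None or not 0 <= n_asymmetric <= n_evaluated:
        raise ValidationError(
            f"invalid AVE counts: evaluated={n_evaluated}, asymmetric={n_asymmetric}"
        )
    ave = n_asymmetric / n_evaluated
    return {
        "egg_cylinder_rate": egg,
        "ave_rate_given_cylinder": ave,
        "overall_rate": egg * ave,
    }


def cohort_rates(cohort: Cohort) -> dict:
    """Success rates of a cohort: egg-cylinder formation, AVE asymmetry
    among evaluated cylinders, and their product (overall success)."""
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    n_cyl = int(np.sum(cohort.outcomes()))
    evaluated = [r for r in cohort.records if r.ave_asymmetric is not None]
    n_asym = sum(bool(r.ave_asymmetric) for r in evaluated)
    return success_rates(len(cohort), n_cyl, len(evaluated), n_asym)


def temporal_delay(in_utero_hours: float, culture_hours: float) -> float:
    """Fractional temporal delay of cultured development:
    1 − in_utero_hours/culture_hours (the in-utero-equivalent time achieved
    per hour of culture, as a shortfall)."""
    if not (in_utero_hours > 0 and culture_hours > 0):
        raise ValidationError("durations must be > 0")
    if in_utero_hours > culture_hours:
        log.warning(
            "in_utero_hours %g > culture_hours %g: negative delay (culture "
            "ran ahead of in utero development)", in_utero_hours, culture_hours,
        )
    return 1.0 - in_utero_hours / culture_hours
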