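"""Synthetic dietary survey generation.

No public accession exists for the 2009 Cameroon micronutrient survey, so the
pipeline runs on synthetic surveys with the same statistical structure: one
24-h vitamin A recall per child, a second recall for a subsample, habitual
fortification-vehicle consumption (oil g/day, bouillon g/day, maize kcal/day),
a VAS-receipt indicator, and macroregion stratification.

Generating model per child i in a region:

    usual intake   U_i  ~ lognormal(median, between_cv)
    recall day j   Y_ij = U_i * exp(e_ij),  e_ij ~ N(0, s_w) (within_cv)
    vehicle v      consumer with prob p_v; amount ~ lognormal(median_v, cv_v)
    VAS receipt    Bernoulli(vas_reach)

After drawing, a calibration loop rescales the usual intakes (a location shift
on the log scale) until the generator-known prevalence of U_i < EAR matches
the profile's baseline prevalence to within +/-0.01.

Column dictionary of the returned dataframe (CSV-ready):

    child_id          integer, unique within the dataset
    region            NORTH | SOUTH | CITIES
    age_months        6-59
    sex               F | M
    day1_intake       ug RAE/day, first 24-h recall
    day2_intake       ug RAE/day, second recall; NaN outside the repeat subsample
    oil_g_day         fortifiable oil, g/day (0 for non-consumers)
    bouillon_g_day    bouillon cube, g/day (0 for non-consumers)
    maize_kcal_day    maize energy, kcal/day (0 for non-consumers)
    vas_received      0/1, received a VA supplement in the last 6 months
    weight            survey weight (1.0 by default)
    usual_intake_true generator-known usual intake (for recovery testing)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intake import EarTable
from .regions import RegionProfile, project_child_population  # noqa: F401 (re-export)

__all__ = ["generate_survey", "project_child_population", "CalibrationError",
           "SURVEY_COLUMNS"]

SURVEY_COLUMNS = [
    "child_id", "region", "age_months", "sex", "day1_intake", "day2_intake",
    "oil_g_day", "bouillon_g_day", "maize_kcal_day", "vas_received", "weight",
    "usual_intake_true",
]


class CalibrationError(RuntimeError):
    """Prevalence calibration failed to reach the target within tolerance."""

    def __init__(self, target: float, achieved: float):
        self.target, self.achieved = target, achieved
        super().__init__(
            f"could not calibrate simulated prevalence to {target:.3f} "
            f"(achieved {achieved:.3f})"
        )


def _lognormal(rng: np.random.Generator, median: float, cv: float, size: int) -> np.ndarray:
    sigma = np.sqrt(np.log1p(cv * cv))
    return median * np.exp(rng.normal(0.0, sigma, size))


def _consumer_mask(rng, frac, n, base_normal=None, sel_corr=0.0):
    """Consumption indicator; ``sel_corr`` couples the propensity with the
    usual-intake driver (negative = consumers concentrate among low-intake
    children)."""
    from scipy.stats import norm
    if frac <= 0.0:
        return np.zeros(n, bool)
    if frac >= 1.0:
        return np.ones(n, bool)
    eps = rng.normal(0.0, 1.0, n)
    if sel_corr != 0.0 and base_normal is not None:
        propensity = -sel_corr * base_normal + np.sqrt(1.0 - sel_corr ** 2) * eps
    else:
        propensity = eps
    return propensity < norm.ppf(frac)


def _amounts(rng, dist, n, base_normal=None, amount_corr=0.0, amount_max=np.inf):
    """Lognormal amounts among consumers, optionally correlated with the
    intake driver and clipped at a physiological ceiling."""
    median, cv = dist
    sigma = np.sqrt(np.log1p(cv * cv))
    z = rng.normal(0.0, 1.0, n)
    if amount_corr != 0.0 and base_normal is not None:
        z = amount_corr * base_normal + np.sqrt(1.0 - amount_corr ** 2) * z
    return np.minimum(median * np.exp(sigma * z), amount_max)


def _vehicle(rng, frac, dist, n, base_normal=None, amount_corr=0.0, sel_corr=0.0,
             amount_max=np.inf, consumer=None):
    """Amounts for one vehicle: consumption indicator x lognormal amount."""
    if consumer is None:
        consumer = _consumer_mask(rng, frac, n, base_normal, sel_corr)
    else:
        rng.normal(0.0, 1.0, n)  # keep the stream layout stable
    amounts = _amounts(rng, dist, n, base_normal, amount_corr, amount_max)
    return np.where(consumer, amounts, 0.0), consumer


def _calibrate_scale(usual: np.ndarray, ears: np.ndarray, target: float,
                     tol: float = 0.01, max_iter: int = 200) -> float:
    """Multiplicative scale s such that mean(usual * s < ear) ~ target.

    Monotone bisection on log(s); prevalence is a step function with steps of
    1/n, so with n >= 50 the nearest achievable value is within the tolerance.
    """
    def prev(log_s):
        return float(np.mean(usual * np.exp(log_s) < ears))

    lo, hi = -8.0, 8.0  # prev() is nonincreasing in log_s: prev(lo) ~ 1, prev(hi) ~ 0
    if prev(lo) < target or prev(hi) > target:  # pragma: no cover - degenerate
        raise CalibrationError(target, prev(0.0))
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            hi = mid
        else:
            lo = mid
    # pick the better of the bracketing endpoints
    best = min((abs(prev(x) - target), x) for x in (lo, hi, 0.5 * (lo + hi)))[1]
    if abs(prev(best) - target) > tol:
        raise CalibrationError(target, prev(best))
    return float(np.exp(best))


def generate_survey(profile: RegionProfile, n_children: int, repeat_frac: float,
                    seed: int, ear_table: EarTable, calibrate: bool = True) -> pd.DataFrame:
    """Generate one region's synthetic survey dataset.

    Identical ``seed`` (with identical arguments) reproduces the dataset
    bit-for-bit.  See the module docstring for the column dictionary.
    """
    if n_children < 50:
        raise ValueError("n_children must be >= 50")
    if not 0.0 < repeat_frac <= 1.0:
        raise ValueError("repeat_frac must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    n = int(n_children)

    age = rng.integers(6, 60, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    sigma_b = np.sqrt(np.log1p(profile.between_cv ** 2))
    z_b = rng.normal(0.0, 1.0, n)
    usual = profile.intake_median * np.exp(sigma_b * z_b)

    ears = np.array([ear_table.lookup(int(a), s) for a, s in zip(age, sex)])
    if calibrate:
        scale = _calibrate_scale(usual, ears, profile.baseline_inadequate_prev)
        usual = usual * scale

    sigma_w = np.sqrt(np.log1p(profile.within_cv ** 2))
    day1 = usual * np.exp(rng.normal(0.0, sigma_w, n))
    repeat = rng.random(n) < repeat_frac
    day2 = np.where(repeat, usual * np.exp(rng.normal(0.0, sigma_w, n)), np.nan)

    global_corr = profile.vehicle_intake_correlation
    amount_corrs = [c if c != 0.0 else global_corr for c in profile.amount_corr]
    sel_corrs = profile.selection_corr
    oil, _ = _vehicle(rng, profile.oil_consumer_frac, profile.oil_g_day_dist, n, z_b,
                      amount_corrs[0], sel_corrs[0], profile.amount_max[0])
    bouillon, bou_cons = _vehicle(rng, profile.bouillon_consumer_frac,
                                  profile.bouillon_g_day_dist, n, z_b,
                                  amount_corrs[1], sel_corrs[1], np.inf)
    q_mix, token_ratio = profile.bouillon_mix
    substantial = rng.random(n) < q_mix
    if q_mix < 1.0:
        bouillon = np.where(substantial, bouillon, bouillon * token_ratio)
    bouillon = np.minimum(bouillon, profile.amount_max[1])
    if profile.maize_nested_in_bouillon and profile.bouillon_consumer_frac > 0:
        # maize consumers are a subset of bouillon consumers, drawn from the
        # substantial-use class first
        share = profile.maize_consumer_frac / profile.bouillon_consumer_frac
        r_hi = min(1.0, share / q_mix) if q_mix > 0 else 0.0
        r_lo = max(0.0, share - q_mix) / (1.0 - q_mix) if q_mix < 1.0 else 0.0
        u = rng.random(n)
        maize_cons = bou_cons & np.where(substantial, u < r_hi, u < r_lo)
    else:
        maize_cons = None
    maize, _ = _vehicle(rng, profile.maize_consumer_frac, profile.maize_kcal_day_dist,
                        n, z_b, amount_corrs[2], sel_corrs[2], profile.amount_max[2],
                        consumer=maize_cons)
    vc = profile.vas_intake_corr
    eps_vas = rng.normal(0.0, 1.0, n)
    vas_prop = -vc * z_b + np.sqrt(1.0 - vc * vc) * eps_vas if vc != 0.0 else eps_vas
    from scipy.stats import norm
    vas = (vas_prop < norm.ppf(profile.vas_reach)).astype(int) if profile.vas_reach < 1.0 \
        else np.ones(n, int)

    return pd.DataFrame({
        "child_id": np.arange(n),
        "region": profile.region.value,
        "age_months": age,
        "sex": sex,
        "day1_intake": day1,
        "day2_intake": day2,
        "oil_g_day": oil,
        "bouillon_g_day": bouillon,
        "maize_kcal_day": maize,
        "vas_received": vas,
        "weight": np.ones(n),
        "usual_intake_true": usual,
    })
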