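"""Quantile limits, standard-style tables, and cross-study comparison.

The safety limit for a body location and condition is a quantile of the
fitted threshold distribution,

    y_q = exp(beta0 + x_G * beta1 + alpha * z_q),

with z_q the standardized kernel quantile (logit(q) for the default
log-logistic family).  The published tables use q = 0.75 and a worker
mix of 70% males (x_G = 0.7) wherever the gender effect is relevant.
Confidence intervals come from the delta method on the linear predictor.

For standard-style presentation, limits are rounded to the nearest 10
and the untestable neck muscle is filled in as 1.2x the temple limits.
Two comparison statistics are provided: the impact/pinching quantile
ratio w_q per location (with its mean over the measured locations), and
the relative deviation eps = 1 - reference/own against the printed 90th
percentiles of earlier studies, together with the force-pressure
Pearson correlation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .errors import InvalidArgumentError
from .model import AFTFit, standard_quantile

DEFAULT_Q = 0.75
DEFAULT_XG = 0.7
NECK_SCALE = 1.2


def fit_from_params(beta0: float, beta1: float, alpha: float,
                    family: str = "log-logistic") -> AFTFit:
    """Wrap published parameters as a fit with no stored uncertainty."""
    k = 3
    return AFTFit(family=family, beta0=beta0, beta1=beta1, alpha=alpha,
                  covariance=np.zeros((k, k)), log_likelihood=math.nan,
                  n_used=0, constrained=False)


def reference_fits() -> dict:
    """The bundled fitted parameters as ``{(row, load, contact): AFTFit}``."""
    return {
        key: fit_from_params(p.beta0, p.beta1, p.alpha)
        for key, p in reference.THRESHOLD_PARAMS.items()
    }


def quantile_limit(fit: AFTFit, q: float = DEFAULT_Q,
                   x_g: float = DEFAULT_XG) -> float:
    """Quantile of the expanded threshold distribution (N or N/cm^2)."""
    if not 0.0 < q < 1.0:
        raise InvalidArgumentError("q must lie strictly in (0, 1)")
    if not 0.0 <= x_g <= 1.0:
        raise InvalidArgumentError("male fraction must lie in [0, 1]")
    z = float(standard_quantile(q, fit.family))
    return math.exp(fit.beta0 + x_g * fit.beta1 + fit.alpha * z)


def quantile_ci(fit: AFTFit, q: float = DEFAULT_Q, x_g: float = DEFAULT_XG,
                level: float = 0.95):
    """Delta-method confidence interval for the quantile limit.

    The linear predictor ``eta = beta0 + x_G*beta1 + alpha*z_q`` is
    normal to first order with variance ``g' Sigma g`` for gradient
    ``g = (1, x_G, z_q)`` (``(1, z_q)`` for constrained fits); the
    interval is ``exp(eta +/- z_crit * se)``.
    """
    if not 0.0 < level < 1.0:
        raise InvalidArgumentError("confidence level must lie in (0, 1)")
    cov = np.asarray(fit.covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1] or not np.all(np.isfinite(cov)):
        raise InvalidArgumentError("fit has no valid covariance")
    z_q = float(standard_quantile(q, fit.family))
    eta = fit.beta0 + x_g * fit.beta1 + fit.alpha * z_q
    if fit.constrained or cov.shape[0] == 2:
        grad = np.array([1.0, z_q])
        cov = cov[:2, :2] if cov.shape[0] == 2 else cov
    else:
        grad = np.array([1.0, x_g, z_q])
    var = float(grad @ cov @ grad)
    se = math.sqrt(max(var, 0.0))
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(eta - z_crit * se), math.exp(eta + z_crit * se)


@dataclass(frozen=True)
class LimitEntry:
    """One limit-table row: point limit with confidence bounds."""

    body_location: str
    load_type: str
    contact_type: str
    q: float
    x_g: float
    y_b: float
    y_l: float
    y_u: float
    units: str
    gender_relevant: bool


def build_limit_table(fits: dict, q: float = DEFAULT_Q, x_g: float = DEFAULT_XG,
                      relevance: dict | None = None,
                      level: float = 0.95) -> pd.DataFrame:
    """Limit table over all fitted (location, load, contact) cells.

    ``fits`` maps ``(row, load_type, contact_type)`` to fits; the gender
    mix ``x_g`` is applied only where the location's gender effect is
    relevant (``relevance`` maps rows to booleans; by default the
    bundled relevance flags).  Missing cells are reported as gaps
    (NaN rows), not failures.
    """
    if relevance is None:
        relevance = {row: row in reference.GENDER_RELEVANT_ROWS
                     for row in reference.MEASURED_ROWS}
    entries = []
    for row in reference.MEASURED_ROWS:
        rel = bool(relevance.get(row, False))
        for load, contact in reference.CONDITIONS:
            fit = fits.get((row, load, contact))
            units = reference.units_for(contact)
            if fit is None:
                entries.append(LimitEntry(row, load, contact, q, x_g,
                                          math.nan, math.nan, math.nan,
                                          units, rel))
                continue
            xg_eff = x_g if rel else 0.0
            y_b = quantile_limit(fit, q, xg_eff)
            try:
                y_l, y_u = quantile_ci(fit, q, xg_eff, level)
            except InvalidArgumentError:
                y_l = y_u = math.nan
            entries.append(LimitEntry(row, load, contact, q, xg_eff,
                                      y_b, y_l, y_u, units, rel))
    return pd.DataFrame([asdict(e) for e in entries])


def round_to_ten(value: float) -> float:
    """Round to the nearest 10, halves away from zero."""
    return 10.0 * math.floor(abs(value) / 10.0 + 0.5) * (1 if value >= 0 else -1)


def round_for_standard(table: pd.DataFrame) -> pd.DataFrame:
    """Standard-style limit table: values rounded to the nearest 10.

    Adds the neck-muscle row, estimated as 1.2x the temple's rounded
    limits (the two locations have similarly distributed thresholds but
    the neck could not be tested), rounded to the nearest 10 again.
    """
    temple = table[table["body_location"] == "2"]
    if temple.empty or temple["y_b"].isna().all():
        raise InvalidArgumentError("table lacks temple entries for the neck estimate")
    out = table.copy()
    out["limit"] = out["y_b"].map(
        lambda v: round_to_ten(v) if np.isfinite(v) else v
    )
    neck_rows = []
    for _, r in temple.iterrows():
        neck_rows.append({
            "body_location": str(reference.EXCLUDED_LOCATION),
            "load_type": r["load_type"],
            "contact_type": r["contact_type"],
            "q": r["q"], "x_g": r["x_g"],
            "y_b": math.nan, "y_l": math.nan, "y_u": math.nan,
            "units": r["units"], "gender_relevant": False,
            "limit": round_to_ten(NECK_SCALE * round_to_ten(r["y_b"])),
        })
    out = pd.concat([out, pd.DataFrame(neck_rows)], ignore_index=True)
    order = {row: i for i, row in enumerate(
        ["1", "2", "3", str(reference.EXCLUDED_LOCATION)]
        + [r for r in reference.MEASURED_ROWS if r not in ("1", "2", "3")]
    )}
    out["_ord"] = out["body_location"].map(order)
    return out.sort_values(["_ord", "load_type", "contact_type"]) \
              .drop(columns="_ord").reset_index(drop=True)


def relative_difference(fits: dict, contact_type: str, q: float = DEFAULT_Q,
                        x_g: float = DEFAULT_XG,
                        relevance: dict | None = None):
    """Impact/pinching quantile ratio w_q per location and its mean.

    Only locations with both load-type fits for the contact type enter;
    the mean is the arithmetic mean over those locations.  Returns
    ``(per_location, mean)``.
    """
    if relevance is None:
        relevance = {row: row in reference.GENDER_RELEVANT_ROWS
                     for row in reference.MEASURED_ROWS}
    ratios = {}
    for row in reference.MEASURED_ROWS:
        f_imp = fits.get((row, "impact", contact_type))
        f_pin = fits.get((row, "pinching", contact_type))
        if f_imp is None or f_pin is None:
            continue
        xg_eff = x_g if relevance.get(row, False) else 0.0
        ratios[row] = (quantile_limit(f_imp, q, xg_eff)
                       / quantile_limit(f_pin, q, xg_eff))
    if not ratios:
        raise InvalidArgumentError("no location has both load-type fits")
    return ratios, float(np.mean(list(ratios.values())))


def relative_deviation(reference_value: float, own_value: float) -> float:
    """Relative deviation eps = 1 - reference/own of two quantile values."""
    if own_value <= 0:
        raise InvalidArgumentError("own value must be positive")
    return 1.0 - reference_value / own_value


def pearson_k(forces, pressures) -> float:
    """Pearson correlation between maximum forces and peak pressures."""
    forces = np.asarray(forces, dtype=float)
    pressures = np.asarray(pressures, dtype=float)
    if forces.size != pressures.size or forces.size < 3:
        raise InvalidArgumentError("need equal-length lists with at least 3 pairs")
    if np.std(forces) == 0 or np.std(pressures) == 0:
        raise InvalidArgumentError("correlation undefined for constant input")
    return float(stats.pearsonr(forces, pressures)[0])


def study_comparison_table(comparison: dict | None = None) -> pd.DataFrame:
    """Relative deviations against the printed cross-study P90 columns.

    Applies ``eps = 1 - reference/own`` to each printed pair (reference
    study vs. control group, per gender mix) and summarizes mean, min
    and max of the deviations.
    """
    comparison = reference.STUDY_COMPARISON if comparison is None else comparison
    rows = []
    for row, c in comparison.items():
        eps1 = relative_deviation(c.s1, c.g5_57)
        eps2 = relative_deviation(c.s2, c.g5_100) if c.s2 is not None else math.nan
        rows.append({"body_location": row, "s1": c.s1, "g5_57": c.g5_57,
                     "eps1": eps1, "s2": c.s2, "g5_100": c.g5_100,
                     "eps2": eps2, "k": c.k})
    return pd.DataFrame(rows)


def write_limit_table(table: pd.DataFrame, path) -> None:
    """Write a limit table as CSV (UTF-8, '.' decimal, inf spelled out)."""
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6g")


def write_fits_json(fits: dict, path) -> None:
    """Write fitted parameters as JSON keyed by location|load|contact."""
    payload = {}
    for (row, load, contact), fit in fits.items():
        payload["|".join((row, load, contact))] = {
            "family": fit.family,
            "beta0": fit.beta0,
            "beta1": fit.beta1,
            "alpha": fit.alpha,
            "log_likelihood": fit.log_likelihood,
            "n_used": fit.n_used,
            "constrained": fit.constrained,
            "p_beta1": fit.p_beta1,
            "r_squared": fit.r_squared,
        }
    Path(path).write_text(json.dumps(payload, indent=2))
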