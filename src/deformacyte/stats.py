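"""Population statistics, modality correlation and Hill dose-response fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "DoseResponseFit",
    "LinearFit",
    "normal_fit",
    "linear_fit",
    "hill_curve",
    "fit_hill",
    "welch_t_test",
    "group_summary",
]


@dataclass
class DoseResponseFit:
    """Three-parameter Hill fit result.

    ``y_max`` is the zero-dose plateau, ``y_min`` the saturating floor (close
    to 1 for fully crosslinked, bead-like cells), ``ec50`` the half-maximal
    concentration in the units of the supplied concentrations (% v/v for
    glutaraldehyde).
    """

    y_max: float
    y_min: float
    ec50: float
    residual_sse: float
    converged: bool
    ci_ec50: tuple[float, float] | None = None
    message: str = ""


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float


def normal_fit(values) -> tuple[float, float]:
    """Sample mean and SD (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("normal_fit needs at least two values")
    return float(v.mean()), float(v.std(ddof=1))


def linear_fit(x, y, through_origin: bool = False) -> LinearFit:
    """Least-squares line; R^2 is measured against the mean model."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("linear_fit needs at least three points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values identical")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        slope, intercept = (float(c) for c in np.polyfit(x, y, 1))
    resid = y - (slope * x + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return LinearFit(slope=slope, intercept=intercept, r2=r2)


def hill_curve(c, y_max: float, y_min: float, ec50: float):
    """Three-parameter Hill dose-response with unit slope.

    y(c) = y_max + (y_min - y_max) * c / (ec50 + c); y(0) = y_max,
    y(ec50) = (y_max + y_min) / 2, y(inf) = y_min.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    out = y_max + (y_min - y_max) * c / (ec50 + c)
    return float(out) if out.ndim == 0 else out


def _hill_least_squares(c: np.ndarray, r: np.ndarray, log_ec50_0: float,
                        y_max0: float, y_min0: float):
    def resid(p):
        y_max, y_min, log_e = p
        e = 10.0 ** log_e
        frac = np.divide(c, e + c, out=np.zeros_like(c), where=(e + c) > 0)
        return y_max + (y_min - y_max) * frac - r

    return optimize.least_squares(
        resid, x0=[y_max0, y_min0, log_ec50_0],
        method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)


def fit_hill(concentrations, responses, n_boot: int = 0,
             seed: int | None = None) -> DoseResponseFit:
    """Fit the three-parameter Hill curve by multi-start least squares.

    ``concentrations`` may repeat (replicates).  Zero concentration is the
    exact zero-dose anchor (the model evaluates to ``y_max`` there; no log
    transform is applied to the data).  Initial EC50 values are scanned over
    a log grid spanning the positive concentrations plus one decade on each
    side.  The bootstrap CI resamples replicates within each concentration
    level.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and responses must align")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(r <= 0):
        raise ValueError("responses must be positive")
    levels = np.unique(c)
    if levels.size < 4:
        raise ValueError("need at least four concentration levels")

    if np.ptp(r) < 1e-10 * max(1.0, float(np.abs(r).max())):
        return DoseResponseFit(
            y_max=float(r.mean()), y_min=float(r.mean()), ec50=float("nan"),
            residual_sse=0.0, converged=False,
            message="responses are constant; EC50 is unidentifiable")

    pos = levels[levels > 0]
    # power-of-two anchor keeps the fit scale-equivariant to solver precision
    scale = 2.0 ** round(np.log2(np.median(pos)))
    cs = c / scale

    y_max0 = float(r[c == c.min()].mean())
    y_min0 = float(r[c == c.max()].mean())
    lo = np.log10(pos.min() / scale) - 1.0
    hi = np.log10(pos.max() / scale) + 1.0
    best = None
    for log_e0 in np.linspace(lo, hi, 9):
        try:
            res = _hill_least_squares(cs, r, log_e0, y_max0, y_min0)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return DoseResponseFit(float("nan"), float("nan"), float("nan"),
                               float("nan"), False, message="solver failure")

    y_max, y_min, log_e = best.x
    ec50 = float(10.0 ** log_e * scale)
    sse = float(2 * best.cost)
    converged = bool(best.success) and bool(abs(y_max - y_min) > 1e-8)
    # an EC50 pushed far outside the sampled range is not identified
    if not (pos.min() / 1e3 <= ec50 <= pos.max() * 1e3):
        converged = False
    converged = bool(converged)
    msg = "" if converged else "EC50 outside identifiable range"

    ci = None
    if n_boot > 0 and converged:
        rng = np.random.default_rng(seed)
        idx_by_level = [np.nonzero(c == lv)[0] for lv in levels]
        boots = []
        for _ in range(n_boot):
            take = np.concatenate([
                rng.choice(ix, size=ix.size, replace=True)
                for ix in idx_by_level])
            sub = fit_hill(c[take], r[take], n_boot=0)
            if sub.converged:
                boots.append(sub.ec50)
        if len(boots) >= max(10, n_boot // 2):
            ci = (float(np.percentile(boots, 2.5)),
                  float(np.percentile(boots, 97.5)))

    return DoseResponseFit(y_max=float(y_max), y_min=float(y_min), ec50=ec50,
                           residual_sse=sse, converged=converged,
                           ci_ec50=ci, message=msg)


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch two-sample t statistic, Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            raise ValueError("zero variance in both groups with equal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def group_summary(df: pd.DataFrame, by: str = "group",
                  value_cols: tuple[str, ...] = ("ed", "od")) -> pd.DataFrame:
    """n, mean, SD and SEM per group for each value column."""
    rows = []
    for group, sub in df.groupby(by, sort=True):
        row: dict = {by: group, "n": len(sub)}
        for col in value_cols:
            v = sub[col].dropna().to_numpy(dtype=float)
            row[f"{col}_mean"] = v.mean() if v.size else float("nan")
            row[f"{col}_sd"] = v.std(ddof=1) if v.size > 1 else float("nan")
            row[f"{col}_sem"] = (v.std(ddof=1) / np.sqrt(v.size)
                                 if v.size > 1 else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
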