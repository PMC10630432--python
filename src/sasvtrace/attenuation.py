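"""Power-law depth-attenuation fits of shared-fraction profiles.

The model is the Martin-curve form S_Z = S_ref (Z/Z_ref)^b: a straight line in
log-log space, fit here as an *unweighted nonlinear least squares on the
linear scale* with both S_ref and b free (ordinary log-log regression supplies
the starting point). R^2 is computed on the linear scale, the p-value is a
two-sided t test of b = 0 using the standard error from the NLS parameter
covariance with n - 2 degrees of freedom, and the 95% confidence interval on b
is b ± 2·SE (two-sigma). Depths outside the requested window are excluded —
upper-ocean fits start at the export reference depth (75 m by default), the
deep increasing fit at 250 m.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sasv import DepthProfileStat

logger = logging.getLogger("sasvtrace")

P_VALUE_METHOD = "two-sided t test of b=0 from NLS covariance, df = n - 2"


@dataclass(frozen=True)
class PowerLawFit:
    """One fitted power law S_Z = s_ref (Z/z_ref)^b.

    ``r2`` is ``None`` when the profile has zero variance (R^2 undefined for a
    flat profile). ``s_scale`` records whether ``s_ref`` is a fraction or a
    percent; the model is scale-equivariant so b, R^2 and p do not depend on
    it.
    """

    z_ref: float
    s_ref: float
    b: float
    r2: float | None
    p_value: float
    se_b: float
    ci_b: tuple[float, float]
    n_points: int
    depth_window: tuple[float, float]
    s_scale: str = "fraction"

    def predict(self, depth_m) -> np.ndarray:
        z = np.asarray(depth_m, dtype=float)
        return self.s_ref * (z / self.z_ref) ** self.b

    def to_dict(self) -> dict:
        return {
            "z_ref": self.z_ref,
            "s_ref": self.s_ref,
            "s_ref_percent": (self.s_ref * 100.0
                              if self.s_scale == "fraction" else self.s_ref),
            "b": self.b,
            "r2": self.r2,
            "p_value": self.p_value,
            "se_b": self.se_b,
            "ci_b": list(self.ci_b),
            "n_points": self.n_points,
            "depth_window": list(self.depth_window),
            "s_scale": self.s_scale,
            "p_value_method": P_VALUE_METHOD,
        }


@dataclass
class BTimeSeries:
    """Per-trap-interval power-law fits (the b-coefficient time series)."""

    entries: list[tuple[str, PowerLawFit]]

    def __post_init__(self) -> None:
        for _, fit in self.entries:
            if fit.n_points < 2:
                raise ValueError("every per-interval fit needs >= 2 depths")

    @property
    def b_values(self) -> pd.Series:
        return pd.Series({iid: f.b for iid, f in self.entries}, name="b")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iid, f in self.entries:
            rows.append({
                "interval_id": iid, "b": f.b, "s_ref": f.s_ref,
                "r2": np.nan if f.r2 is None else f.r2,
                "p_value": f.p_value, "ci_low": f.ci_b[0],
                "ci_high": f.ci_b[1], "n_points": f.n_points,
            })
        return pd.DataFrame(rows)


def _extract_profile(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, DepthProfileStat):
        return profile.depths, profile.means
    if isinstance(profile, pd.DataFrame):
        col = "mean" if "mean" in profile.columns else "value"
        return (profile["depth_m"].to_numpy(dtype=float),
                profile[col].to_numpy(dtype=float))
    depths, values = profile
    return np.asarray(depths, dtype=float), np.asarray(values, dtype=float)


def fit_power_law(
    profile,
    z_ref: float,
    depth_window: tuple[float, float],
    s_scale: str = "fraction",
) -> PowerLawFit:
    """Fit S_Z = s_ref (Z/z_ref)^b to a depth profile of means.

    ``profile`` may be a :class:`~sasvtrace.sasv.DepthProfileStat`, a
    DataFrame with ``depth_m``/``mean`` columns, or a ``(depths, values)``
    pair. Depths outside ``depth_window`` (inclusive) are excluded; at least
    two strictly positive points must remain. A flat profile returns b = 0
    with undefined R^2 and p = 1; a two-point profile is solved in closed form
    (exact fit, no uncertainty estimate).
    """
    depths, values = _extract_profile(profile)
    lo, hi = depth_window
    mask = (depths >= lo) & (depths <= hi)
    z, y = depths[mask], values[mask]
    order = np.argsort(z)
    z, y = z[order], y[order]
    if len(z) < 2:
        raise ValueError(
            f"need >= 2 depths inside window [{lo}, {hi}] m, got {len(z)}")
    nonpos = z[y <= 0]
    if len(nonpos):
        raise ValueError(
            f"nonpositive profile value inside the fit window at depth(s) "
            f"{nonpos.tolist()} m (power law requires positive values)")
    if not (z_ref > 0):
        raise ValueError("z_ref must be positive")
    if not (z.min() <= z_ref <= z.max()):
        logger.warning(
            "z_ref = %g m lies outside the fitted depth span [%g, %g] m; "
            "s_ref is an extrapolation", z_ref, z.min(), z.max())

    n = len(z)
    window = (float(lo), float(hi))

    if np.ptp(y) == 0:  # flat profile: b = 0 exactly, R^2 undefined
        return PowerLawFit(
            z_ref=float(z_ref), s_ref=float(y[0]), b=0.0, r2=None,
            p_value=1.0, se_b=0.0, ci_b=(0.0, 0.0), n_points=n,
            depth_window=window, s_scale=s_scale)

    if n == 2:
        b = math.log(y[1] / y[0]) / math.log(z[1] / z[0])
        s_ref = y[0] / (z[0] / z_ref) ** b
        return PowerLawFit(
            z_ref=float(z_ref), s_ref=float(s_ref), b=float(b), r2=1.0,
            p_value=1.0, se_b=float("inf"), ci_b=(-math.inf, math.inf),
            n_points=2, depth_window=window, s_scale=s_scale)

    # log-log OLS initialization (exact for noiseless power-law data)
    slope, intercept = np.polyfit(np.log(z / z_ref), np.log(y), 1)
    p0 = (math.exp(intercept), slope)

    def model(zz, s, b):
        return s * (zz / z_ref) ** b

    popt, pcov = optimize.curve_fit(model, z, y, p0=p0, maxfev=20000)
    s_ref, b = float(popt[0]), float(popt[1])
    resid = y - model(z, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot

    var_b = float(pcov[1, 1])
    se_b = math.sqrt(var_b) if np.isfinite(var_b) and var_b >= 0 else float("inf")
    df = n - 2
    if se_b == 0.0:
        p = float(np.finfo(float).tiny)  # perfect fit with nonzero slope
    elif not np.isfinite(se_b):
        p = 1.0
    else:
        t = b / se_b
        p = float(2.0 * stats.t.sf(abs(t), df))
        p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    ci = (b - 2.0 * se_b, b + 2.0 * se_b)
    return PowerLawFit(
        z_ref=float(z_ref), s_ref=s_ref, b=b, r2=r2, p_value=p, se_b=se_b,
        ci_b=ci, n_points=n, depth_window=window, s_scale=s_scale)


def refit_reference(
    profile,
    new_z_ref: float,
    z_max: float | None = None,
    s_scale: str = "fraction",
) -> PowerLawFit:
    """Refit with a new reference depth, window starting at the new z_ref.

    Used for reference-depth sensitivity: on exact power-law data the exponent
    is reference-invariant while s_ref rescales; on noisy data both b and R^2
    may change because shallow points leave the window.
    """
    depths, _ = _extract_profile(profile)
    hi = float(z_max) if z_max is not None else float(np.max(depths))
    return fit_power_law(profile, new_z_ref, (float(new_z_ref), hi),
                         s_scale=s_scale)


def fit_per_interval(
    fractions: pd.DataFrame,
    z_ref: float,
    depth_window: tuple[float, float],
    value: str = "water_fraction",
) -> BTimeSeries:
    """One power-law fit per trap interval from a tidy fraction table.

    Intervals with fewer than two usable depths (or nonpositive values inside
    the window) are skipped with a warning; zero fittable intervals is an
    error.
    """
    entries: list[tuple[str, PowerLawFit]] = []
    for iid, g in fractions.groupby("interval_id", sort=True):
        prof = (g["depth_m"].to_numpy(dtype=float),
                g[value].to_numpy(dtype=float))
        try:
            entries.append((str(iid), fit_power_law(prof, z_ref, depth_window)))
        except ValueError as exc:
            logger.warning("skipping interval %s: %s", iid, exc)
    if not entries:
        raise ValueError("no interval had a fittable profile")
    return BTimeSeries(entries)


def correlate_b_covariates(
    b_series: BTimeSeries,
    covariates: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate per-interval b coefficients with environmental covariates.

    ``covariates`` is indexed by interval id (or carries an ``interval_id``
    column). Spearman rank correlation by default (``method="pearson"``
    available); pairwise-complete observations; two-sided p. A constant
    covariate or fewer than three pairs yields an undefined (NaN) coefficient
    flagged in the ``note`` column rather than an error.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    cov = covariates.copy()
    if "interval_id" in cov.columns:
        cov = cov.set_index("interval_id")
    b = b_series.b_values
    rows = []
    for name in cov.columns:
        paired = pd.concat([b, cov[name]], axis=1, join="inner").dropna()
        note = ""
        coef = p = float("nan")
        if len(paired) < 3:
            note = "fewer than 3 paired observations"
        elif paired[name].nunique() == 1:
            note = "constant covariate; correlation undefined"
        else:
            x, yv = paired["b"].to_numpy(), paired[name].to_numpy(dtype=float)
            if method == "spearman":
                res = stats.spearmanr(x, yv)
            else:
                res = stats.pearsonr(x, yv)
            coef, p = float(res.statistic), float(res.pvalue)
        rows.append({"covariate": name, "method": method, "coefficient": coef,
                     "p_value": p, "n": len(paired), "note": note})
    return pd.DataFrame(rows)
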