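"""Calibration of the force laws from summarised cutting trials.

Two fits are performed.  The normal-force power law Fz = C·V^α is fitted on
log–log scale by ordinary least squares (multiplicative-error model; a direct
nonlinear fit on the original scale is available as an option).  The
orientation sinusoid f_p(θ) = C1 + C2·sin(C3·θ + θ0) is fitted by constrained
least squares over the replicate ploughing coefficients, with C2 ≥ 0 and the
phase restricted to the first branch 0 < C3·θ_max ≤ π — the sparse 3-angle
design aliases the phase rate, so higher branches reproduce the same three
fitted values and are reported rather than searched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .core import (
    AnisotropyModel,
    NormalForceModel,
    ToolGeometry,
    indentation_volume,
    tangential_force,
)
from .preprocessing import TrialSummary

__all__ = [
    "PowerLawFit",
    "AnisotropyFit",
    "InfeasibleBranchError",
    "fit_power_law",
    "fit_anisotropy",
    "solve_three_angle",
    "regression_diagnostics",
    "error_rate_table",
    "ErrorRateTable",
]


class InfeasibleBranchError(ValueError):
    """No first-branch sinusoid phase is consistent with the data."""


@dataclass
class PowerLawFit:
    """Fitted normal-force power law with regression bookkeeping.

    ``observed``/``predicted`` are on the fitting scale (log scale for the
    default mode), so the stored diagnostics are recomputable from them.
    ``relative_errors`` are per-point 100·|pred − obs|/obs on the original
    (newton) scale.
    """

    model: NormalForceModel
    mode: str
    n_points: int
    r_squared: float
    ss_res: float
    ss_tot: float
    df_model: int
    df_resid: int
    f_statistic: float
    f_pvalue: float
    observed: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray
    relative_errors: np.ndarray
    n_params: int = 2

    @property
    def C(self) -> float:
        return self.model.C

    @property
    def alpha(self) -> float:
        return self.model.alpha


@dataclass
class AnisotropyFit:
    """Fitted orientation sinusoid with branch/identifiability report."""

    model: AnisotropyModel
    n_points: int
    angle_means: dict[float, float]
    r_squared: float
    observed: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray
    branch_report: dict[str, Any] = field(default_factory=dict)
    n_params: int = 3

    @property
    def C1(self) -> float:
        return self.model.C1

    @property
    def C2(self) -> float:
        return self.model.C2

    @property
    def C3(self) -> float:
        return self.model.C3


def fit_power_law(
    V: Sequence[float],
    Fz: Sequence[float],
    mode: str = "log",
) -> PowerLawFit:
    """Fit Fz = C·V^α by least squares.

    mode="log" (default): OLS of log Fz on log V — the multiplicative-error
    reading, unbiased when noise is log-normal.  mode="direct": nonlinear
    least squares on the newton scale, seeded from the log fit.

    Requires at least two points with distinct positive volumes and positive
    forces; two points give the exact interpolating law (residual degrees of
    freedom zero, F statistic undefined).
    """
    v = np.asarray(V, dtype=float)
    f = np.asarray(Fz, dtype=float)
    if v.size != f.size:
        raise ValueError("V and Fz must have equal length")
    if v.size < 2:
        raise ValueError("need at least 2 points to fit a power law")
    if np.any(v <= 0) or np.any(f <= 0):
        raise ValueError("all volumes and forces must be strictly positive")
    if np.ptp(v) == 0:
        raise ValueError("singular design: all volumes are equal")
    if mode not in ("log", "direct"):
        raise ValueError(f"unknown fit mode {mode!r}")

    x = np.log(v)
    y = np.log(f)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    C = float(np.exp(ols.params[0]))
    alpha = float(ols.params[1])

    if mode == "direct":
        popt, _ = scipy.optimize.curve_fit(
            lambda vv, c, a: c * vv**a, v, f, p0=[C, alpha], maxfev=10000
        )
        C, alpha = float(popt[0]), float(popt[1])
        obs, pred = f, C * v**alpha
    else:
        obs, pred = y, ols.params[0] + alpha * x

    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n = v.size
    df_model, df_resid = 1, n - 2
    if df_resid > 0 and ss_res > 0:
        fstat = (ss_tot - ss_res) / df_model / (ss_res / df_resid)
        fpval = float(scipy.stats.f.sf(fstat, df_model, df_resid))
    else:
        fstat, fpval = math.inf if df_resid > 0 else math.nan, math.nan
    fhat = C * v**alpha
    rel = 100.0 * np.abs(fhat - f) / f
    model = NormalForceModel(
        C=C,
        alpha=alpha,
        r_squared=min(max(r2, 0.0), 1.0),
        fit_metadata={
            "mode": mode,
            "n": n,
            "ss_res": ss_res,
            "f_statistic": fstat,
            "confidence_level": 0.95,
        },
    )
    return PowerLawFit(
        model=model,
        mode=mode,
        n_points=n,
        r_squared=r2,
        ss_res=ss_res,
        ss_tot=ss_tot,
        df_model=df_model,
        df_resid=df_resid,
        f_statistic=float(fstat),
        f_pvalue=fpval,
        observed=obs,
        predicted=pred,
        residuals=resid,
        relative_errors=rel,
    )


def solve_three_angle(
    m0: float, m45: float, m90: float
) -> tuple[float, float, float]:
    """Exact sinusoid through mean ploughing coefficients at 0°, 45°, 90°.

    With θ0 = 0 the three-mean system C1 + C2·sin(C3·θ) gives
    C1 = m0, cos(x) = (m90 − m0) / (2·(m45 − m0)) with x = C3·45° in radians,
    and C2 = (m45 − m0)/sin(x).  Returns ``(C1, C2, C3)`` with C3 in radians
    of phase per degree of cutting angle, first branch x ∈ (0, π).

    Degenerate isotropic input (m45 = m90 = m0) returns C2 = 0 with the
    conventional x = π/2.
    """
    if math.isclose(m45, m0, abs_tol=1e-15) and math.isclose(m90, m0, abs_tol=1e-15):
        return float(m0), 0.0, math.pi / 2.0 / 45.0
    if m45 <= m0:
        raise InfeasibleBranchError(
            "three-mean solver requires m45 > m0 (sinusoid rising at 45°)"
        )
    cos_x = (m90 - m0) / (2.0 * (m45 - m0))
    if abs(cos_x) > 1.0:
        raise InfeasibleBranchError(
            f"no real phase: |cos x| = {abs(cos_x):.4f} > 1 for the given means"
        )
    x = math.acos(cos_x)  # in (0, pi)
    C2 = (m45 - m0) / math.sin(x)
    return float(m0), float(C2), x / 45.0


def _sinusoid(theta: np.ndarray, c1: float, c2: float, c3: float, t0_deg: float) -> np.ndarray:
    return c1 + c2 * np.sin(c3 * theta + math.radians(t0_deg))


def fit_anisotropy(
    theta: Sequence[float],
    fp: Sequence[float],
    theta0: float = 0.0,
    fit_theta0: bool = False,
) -> AnisotropyFit:
    """Constrained least-squares fit of f_p(θ) = C1 + C2·sin(C3·θ + θ0).

    θ in degrees, C3 in radians of phase per degree.  Constraints: C2 ≥ 0 and
    the first-branch phase window 0 < C3·θ_max ≤ π.  θ0 is held fixed
    (default 0°) unless ``fit_theta0=True``.

    For the canonical 3-angle design {0°, 45°, 90°} the least-squares optimum
    interpolates the per-angle means, so the fit is taken from the closed-form
    three-mean solver; denser angle designs are fitted numerically
    (variable-projection grid start + bounded least squares).
    """
    th = np.asarray(theta, dtype=float)
    f = np.asarray(fp, dtype=float)
    if th.size != f.size:
        raise ValueError("theta and fp must have equal length")
    if np.any(f <= 0):
        raise ValueError("all ploughing coefficients must be positive")
    angles = np.unique(th)
    if angles.size < 3:
        raise ValueError(f"need >= 3 distinct angles, got {angles.size}")
    theta_max = float(np.max(np.abs(th)))
    if theta_max == 0:
        raise ValueError("angle design has no spread")
    means = {float(a): float(f[th == a].mean()) for a in angles}

    branch: dict[str, Any] = {
        "phase_constraint": f"0 < C3*{theta_max:g} deg <= pi (radians)",
        "theta0_fixed": not fit_theta0,
    }
    closed_form = None
    if not fit_theta0 and set(means) == {0.0, 45.0, 90.0}:
        try:
            closed_form = solve_three_angle(means[0.0], means[45.0], means[90.0])
        except InfeasibleBranchError as exc:
            branch["closed_form"] = f"infeasible: {exc}"

    if closed_form is not None:
        c1, c2, c3 = closed_form
        t0 = theta0
        branch["closed_form"] = "three-mean interpolation (exact LS optimum)"
    else:
        # variable projection: for fixed C3 (and theta0) the model is linear
        # in (C1, C2); scan the first branch, then polish within bounds
        grid = np.linspace(1e-3, math.pi, 400) / theta_max
        best = (np.inf, None)
        t0 = theta0
        for c3g in grid:
            design = np.column_stack([np.ones_like(th), np.sin(c3g * th + math.radians(t0))])
            coef, *_ = np.linalg.lstsq(design, f, rcond=None)
            if coef[1] < 0:
                continue
            sse = float(np.sum((design @ coef - f) ** 2))
            if sse < best[0]:
                best = (sse, (float(coef[0]), float(coef[1]), float(c3g)))
        if best[1] is None:
            raise InfeasibleBranchError(
                "no feasible first-branch solution with C2 >= 0; "
                "inspect the per-angle means"
            )
        c1, c2, c3 = best[1]
        if fit_theta0:
            x0 = [c1, c2, c3, t0]
            lo = [-np.inf, 0.0, 1e-9, -180.0]
            hi = [np.inf, np.inf, math.pi / theta_max, 180.0]
            res = scipy.optimize.least_squares(
                lambda p: _sinusoid(th, p[0], p[1], p[2], p[3]) - f, x0,
                bounds=(lo, hi),
            )
            c1, c2, c3, t0 = map(float, res.x)
        else:
            res = scipy.optimize.least_squares(
                lambda p: _sinusoid(th, p[0], p[1], p[2], t0) - f,
                [c1, c2, c3],
                bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, math.pi / theta_max]),
            )
            c1, c2, c3 = map(float, res.x)
        branch["closed_form"] = branch.get("closed_form", "not applicable (numeric fit)")

    x_rad = c3 * 45.0
    branch["x_rad_at_45deg"] = x_rad
    branch["C3_first_branch"] = c3
    # phase-rate aliases: adding full turns over the 45 deg spacing leaves the
    # fitted values at {0, 45, 90} unchanged
    branch["C3_aliases"] = [c3 + k * 2.0 * math.pi / 45.0 for k in (1, 2, 3)]

    pred = _sinusoid(th, c1, c2, c3, t0)
    resid = f - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fp0 = c1 + c2 * math.sin(c3 * 0.0 + math.radians(t0))
    model = AnisotropyModel(
        fp0=float(fp0), C1=float(c1), C2=float(c2), C3=float(c3),
        theta0=float(t0), convention="canonical",
    )
    return AnisotropyFit(
        model=model,
        n_points=int(th.size),
        angle_means=means,
        r_squared=min(max(r2, 0.0), 1.0),
        observed=f,
        predicted=pred,
        residuals=resid,
        branch_report=branch,
        n_params=4 if fit_theta0 else 3,
    )


def regression_diagnostics(fit: PowerLawFit | AnisotropyFit) -> dict[str, Any]:
    """Standard regression diagnostics from a completed fit.

    Returns R², the regression F statistic with its degrees of freedom and
    p-value, raw residuals, per-point relative error rates (percent), and a
    residual-range summary.  Computed on the fit's own fitting scale.
    """
    obs = np.asarray(fit.observed, dtype=float)
    pred = np.asarray(fit.predicted, dtype=float)
    n = obs.size
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance response: diagnostics undefined")
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    df_model = fit.n_params - 1
    df_resid = n - fit.n_params
    if df_resid > 0 and ss_res > 0:
        fstat = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid)
        fpval = float(scipy.stats.f.sf(fstat, df_model, df_resid))
    else:
        fstat, fpval = math.nan, math.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * np.abs(resid) / np.abs(obs)
    return {
        "r_squared": 1.0 - ss_res / ss_tot,
        "f_statistic": float(fstat),
        "f_pvalue": fpval,
        "df_model": df_model,
        "df_resid": df_resid,
        "ss_res": ss_res,
        "ss_tot": ss_tot,
        "residuals": resid,
        "relative_errors_pct": rel,
        "residual_range": (float(resid.min()), float(resid.max())),
    }


@dataclass
class ErrorRateTable:
    """Per-trial and per-condition relative errors of the tangential model."""

    per_trial: pd.DataFrame
    by_condition: pd.DataFrame


def error_rate_table(
    summaries: Iterable[TrialSummary],
    nmodel: NormalForceModel,
    amodel: AnisotropyModel,
    tool: ToolGeometry = ToolGeometry(),
) -> ErrorRateTable:
    """Relative error of predicted tangential force against trial summaries.

    For each trial the tangential force is predicted at the trial's indented
    volume V(h) and cutting angle θ from the calibrated models, and compared
    with the observed steady-state mean as 100·|pred − obs|/obs.  Aggregates
    min/max/mean per (h, θ) condition.
    """
    if nmodel is None or amodel is None:
        raise ValueError("both calibrated models are required")
    rows = []
    for s in summaries:
        V = indentation_volume(s.h, tool)
        pred = tangential_force(V, s.theta, nmodel, amodel)
        rows.append(
            {
                "trial_id": s.trial_id,
                "h_mm": s.h,
                "theta_deg": s.theta,
                "replicate": s.replicate,
                "fp_obs_n": s.Fp_mean,
                "fp_pred_n": pred.Fp,
                "error_rate_pct": 100.0 * abs(pred.Fp - s.Fp_mean) / s.Fp_mean,
            }
        )
    if not rows:
        raise ValueError("no trial summaries supplied")
    per_trial = pd.DataFrame(rows)
    by_condition = (
        per_trial.groupby(["h_mm", "theta_deg"])["error_rate_pct"]
        .agg(["min", "max", "mean"])
        .reset_index()
    )
    return ErrorRateTable(per_trial=per_trial, by_condition=by_condition)
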