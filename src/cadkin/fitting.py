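"""Phase-wise Gauss-Newton least squares for the two-phase uptake model.

Fits the uptake curve to colony observations of one phase, either with a
single (kA, kE) pair for all colonies ("pooled") or with habitat-indexed
pairs estimated in one joint regression ("by_habitat") so that residual
sums of squares, AIC and the extra-sum-of-squares F-test are comparable
between the two models.

The optimizer is a plain Gauss-Newton iteration with step-halving, a
relative-RSS convergence tolerance of 1e-10, at most 200 iterations and
a {0.1, 1, 5}^2 multi-start grid when the caller supplies no start.
Parameters are unconstrained; non-positive estimates are flagged, never
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ExposureSchedule,
    KineticParams,
    concentration_at_switch,
)

__all__ = [
    "CONTAMINATION",
    "DECONTAMINATION",
    "FitConvergenceError",
    "FitResult",
    "ModelComparison",
    "schedule_from_data",
    "phase_subset",
    "fit_phase",
    "asymptotic_ci",
    "adjusted_r2",
    "aic",
    "compare_nested",
]

CONTAMINATION = "contamination"
DECONTAMINATION = "decontamination"

_DEFAULT_STARTS = tuple(
    (a, b) for a in (0.1, 1.0, 5.0) for b in (0.1, 1.0, 5.0)
)
_GN_TOL = 1e-10
_GN_MAX_ITER = 200


class FitConvergenceError(RuntimeError):
    pass


@dataclass
class FitResult:
    """One fitted phase model with its inference statistics."""

    phase: str
    grouping: str  # "pooled" | "by_habitat"
    estimates: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    n_obs: int
    n_params: int
    adjusted_r2: float
    aic: float
    converged: bool
    n_iterations: int
    schedule: ExposureSchedule
    ci_level: float = 0.95
    ci_quantile: str = "t"
    anchor: str | None = None  # decontamination only: how C_ItC was set
    c_switch: float | Mapping[str, float] | None = None
    warnings: list[str] = field(default_factory=list)
    start_log: list[dict] = field(default_factory=list)
    # internals for CI recomputation and nested-comparison validation
    _jtj: np.ndarray | None = None
    _param_names: tuple[str, ...] = ()
    _data_key: np.ndarray | None = None

    def params(self, habitat: str | None = None) -> KineticParams:
        """Return the fitted (kA, kE) pair, per habitat if grouped."""
        suffix = "1" if self.phase == CONTAMINATION else "2"
        tag = f"_{habitat}" if habitat is not None else ""
        return KineticParams(
            kA=self.estimates[f"kA{suffix}{tag}"],
            kE=self.estimates[f"kE{suffix}{tag}"],
        )

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "grouping": self.grouping,
            "estimates": self.estimates,
            "se": self.se,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "adjusted_r2": self.adjusted_r2,
            "aic": self.aic,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "ci_level": self.ci_level,
            "ci_quantile": self.ci_quantile,
            "anchor": self.anchor,
            "c_switch": self.c_switch,
            "warnings": list(self.warnings),
            "schedule": {
                "C_I0": self.schedule.C_I0,
                "C_Eu": self.schedule.C_Eu,
                "C_Ed": self.schedule.C_Ed,
                "t_C": self.schedule.t_C,
            },
        }


@dataclass(frozen=True)
class ModelComparison:
    """Nested pooled-vs-habitat comparison for one phase."""

    phase: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    aic_null: float
    aic_alt: float
    preferred: str  # "by_habitat" iff its AIC is lower, else "pooled"

    @property
    def delta_aic(self) -> float:
        return self.aic_alt - self.aic_null

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "f_stat": self.f_stat,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "aic_null": self.aic_null,
            "aic_alt": self.aic_alt,
            "delta_aic": self.delta_aic,
            "preferred": self.preferred,
        }


def schedule_from_data(
    data: pd.DataFrame,
    C_Eu: float = 100.0,
    C_Ed: float = 1.0,
    t_C: float = 21.0,
) -> ExposureSchedule:
    """Build the exposure schedule, taking C_I0 as the mean day-0 concentration."""
    day0 = data.loc[data["time_days"] == 0, "concentration"]
    if day0.empty:
        raise ValueError("no day-0 observations to estimate C_I0 from")
    return ExposureSchedule(
        C_I0=float(day0.mean()), C_Eu=C_Eu, C_Ed=C_Ed, t_C=t_C
    )


def phase_subset(
    data: pd.DataFrame, phase: str, schedule: ExposureSchedule
) -> pd.DataFrame:
    """Observations belonging to one phase.

    Contamination: 0 < t <= t_C (day 0 is excluded because C_I0 enters the
    model as a fixed constant, not as a data point). Decontamination: t > t_C.
    """
    t = data["time_days"]
    if phase == CONTAMINATION:
        mask = (t > 0) & (t <= schedule.t_C)
    elif phase == DECONTAMINATION:
        mask = t > schedule.t_C
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return data.loc[mask]


def _curve_and_jac(theta: np.ndarray, tau: np.ndarray, c0: float, c_e: float):
    """Uptake curve value and its Jacobian w.r.t. (kA, kE)."""
    kA, kE = theta
    if kE == 0 or not np.all(np.isfinite(theta)):
        raise FloatingPointError("degenerate iterate")
    with np.errstate(over="ignore", invalid="ignore"):
        decay = np.exp(-kE * tau)
        grow = 1.0 - decay
        f = c0 * decay + c_e * (kA / kE) * grow
        d_kA = (c_e / kE) * grow
        d_kE = -c0 * tau * decay + c_e * kA * (tau * decay / kE - grow / kE**2)
    return f, np.column_stack([d_kA, d_kE])


def _gauss_newton(residual_jac, theta0, tol=_GN_TOL, max_iter=_GN_MAX_ITER):
    """Minimise ||r(theta)||^2 by Gauss-Newton with step-halving.

    Returns (theta, rss, n_iter, converged, jtj_at_optimum).
    """
    theta = np.asarray(theta0, dtype=float)
    try:
        r, jac = residual_jac(theta)
    except FloatingPointError:
        return theta, np.inf, 0, False, None
    with np.errstate(over="ignore", invalid="ignore"):
        rss = float(r @ r)
    if not np.isfinite(rss):
        return theta, np.inf, 0, False, None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        jtj = jac.T @ jac
        try:
            delta = -np.linalg.solve(jtj, jac.T @ r)
        except np.linalg.LinAlgError:
            delta = -np.linalg.lstsq(jac, r, rcond=None)[0]
        if not np.all(np.isfinite(delta)):
            break
        # step-halving line search
        step = 1.0
        improved = False
        for _ in range(40):
            cand = theta + step * delta
            try:
                r_new, jac_new = residual_jac(cand)
            except FloatingPointError:
                step *= 0.5
                continue
            with np.errstate(over="ignore", invalid="ignore"):
                rss_new = float(r_new @ r_new)
            if np.isfinite(rss_new) and rss_new < rss:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True  # no descent direction left: at a minimum
            break
        theta, r, jac = cand, r_new, jac_new
        if rss - rss_new <= tol * max(rss, 1e-300):
            rss = rss_new
            converged = True
            break
        rss = rss_new
    return theta, rss, n_iter, converged, jac.T @ jac


def _data_key(sub: pd.DataFrame) -> np.ndarray:
    """Order-independent fingerprint of the phase observations."""
    levels = sorted(sub["habitat"].astype(str).unique())
    codes = sub["habitat"].astype(str).map({h: i for i, h in enumerate(levels)})
    arr = np.column_stack(
        [
            sub["time_days"].to_numpy(float),
            sub["concentration"].to_numpy(float),
            codes.to_numpy(dtype=float),
        ]
    )
    return arr[np.lexsort(arr.T[::-1])]


def _resolve_c_switch(
    data: pd.DataFrame,
    schedule: ExposureSchedule,
    anchor: str,
    start,
) -> float | dict[str, float]:
    """Phase-1 prediction at t_C used to anchor the depuration branch."""
    if anchor == "pooled":
        fit1 = fit_phase(data, CONTAMINATION, schedule, "pooled", start=start)
        return concentration_at_switch(fit1.params(), schedule)
    if anchor == "by_habitat":
        fit1 = fit_phase(data, CONTAMINATION, schedule, "by_habitat", start=start)
        return {
            h: concentration_at_switch(fit1.params(h), schedule)
            for h in sorted(data["habitat"].unique())
        }
    raise ValueError(f"unknown anchor {anchor!r}")


def fit_phase(
    data: pd.DataFrame,
    phase: str,
    schedule: ExposureSchedule,
    grouping: str = "pooled",
    start: KineticParams | None = None,
    anchor: str = "pooled",
    c_switch: float | Mapping[str, float] | None = None,
) -> FitResult:
    """Fit one phase of the uptake model by Gauss-Newton least squares.

    Parameters
    ----------
    data
        Full observation table (canonical columns); the relevant phase
        subset is selected internally.
    phase
        ``"contamination"`` or ``"decontamination"``.
    grouping
        ``"pooled"`` estimates one (kA, kE); ``"by_habitat"`` estimates a
        pair per habitat in a single joint regression.
    start
        Optional starting pair; otherwise a multi-start grid is used.
    anchor
        For the decontamination phase only: how the switch concentration
        C_ItC is obtained (``"pooled"`` phase-1 fit by default;
        ``"by_habitat"`` for a sensitivity analysis).
    c_switch
        Pre-computed switch concentration(s); overrides ``anchor``.
    """
    if grouping not in ("pooled", "by_habitat"):
        raise ValueError(f"unknown grouping {grouping!r}")
    sub = phase_subset(data, phase, schedule)
    if sub["time_days"].nunique() < 3:
        raise ValueError(
            f"{phase} phase has {sub['time_days'].nunique()} distinct time "
            "points; need at least 3"
        )

    anchor_used: str | None = None
    if phase == DECONTAMINATION:
        if c_switch is None:
            c_switch = _resolve_c_switch(data, schedule, anchor, start)
            anchor_used = anchor
        else:
            anchor_used = "supplied"
        tau_offset = schedule.t_C
        c_e = schedule.C_Ed
        suffix = "2"
    else:
        tau_offset = 0.0
        c_e = schedule.C_Eu
        suffix = "1"

    tau = sub["time_days"].to_numpy(float) - tau_offset
    y = sub["concentration"].to_numpy(float)
    n = len(y)

    if grouping == "pooled":
        groups = [(None, np.ones(n, dtype=bool))]
    else:
        habitats = sorted(sub["habitat"].unique())
        if len(habitats) < 2:
            raise ValueError(
                "by_habitat grouping needs both habitat levels; found "
                f"{habitats}"
            )
        groups = [(h, (sub["habitat"] == h).to_numpy()) for h in habitats]

    p = 2 * len(groups)
    if n <= p:
        raise ValueError(f"{n} observations cannot identify {p} parameters")

    def c0_for(habitat):
        if phase == CONTAMINATION:
            return schedule.C_I0
        if isinstance(c_switch, Mapping):
            return c_switch[habitat] if habitat is not None else None
        return float(c_switch)

    def residual_jac(theta):
        r = np.empty(n)
        jac = np.zeros((n, p))
        for i, (hab, mask) in enumerate(groups):
            f, j = _curve_and_jac(theta[2 * i : 2 * i + 2], tau[mask], c0_for(hab), c_e)
            r[mask] = y[mask] - f
            jac[mask, 2 * i : 2 * i + 2] = -j
        return r, jac

    if start is not None:
        starts: Sequence[tuple[float, float]] = [(start.kA, start.kE)]
    else:
        starts = _DEFAULT_STARTS

    best = None
    start_log = []
    for s in starts:
        theta0 = np.tile(s, len(groups))
        theta, rss, n_iter, ok, jtj = _gauss_newton(residual_jac, theta0)
        start_log.append(
            {"start": list(s), "rss": rss, "converged": ok, "n_iterations": n_iter}
        )
        if ok and np.isfinite(rss) and (best is None or rss < best[1]):
            best = (theta, rss, n_iter, jtj)
    if best is None:
        raise FitConvergenceError(
            f"Gauss-Newton failed to converge from any start in {list(starts)}"
        )
    theta, rss, n_iter, jtj = best

    names = []
    for hab, _ in groups:
        tag = f"_{hab}" if hab is not None else ""
        names += [f"kA{suffix}{tag}", f"kE{suffix}{tag}"]
    estimates = dict(zip(names, (float(v) for v in theta)))

    warnings = [
        f"non-positive estimate {k} = {v:.4g}" for k, v in estimates.items() if v <= 0
    ]

    tss = float(np.sum((y - y.mean()) ** 2))
    adj_r2 = 1.0 - (rss / (n - p)) / (tss / (n - 1))
    if rss > 0:
        aic_val = _aic_value(rss, n, p)
    else:  # perfect fit: degenerate Gaussian likelihood
        aic_val = -np.inf
        warnings.append("rss = 0: AIC degenerate (-inf)")

    fit = FitResult(
        phase=phase,
        grouping=grouping,
        estimates=estimates,
        se={},
        ci95={},
        rss=rss,
        n_obs=n,
        n_params=p,
        adjusted_r2=adj_r2,
        aic=aic_val,
        converged=True,
        n_iterations=n_iter,
        schedule=schedule,
        anchor=anchor_used,
        c_switch=dict(c_switch) if isinstance(c_switch, Mapping) else c_switch,
        warnings=warnings,
        start_log=start_log,
        _jtj=jtj,
        _param_names=tuple(names),
        _data_key=_data_key(sub),
    )
    try:
        return asymptotic_ci(fit)
    except np.linalg.LinAlgError as exc:
        # ridge in the likelihood (e.g. kE unbounded once the curve is a
        # step): keep the point fit, flag the missing intervals
        fit.warnings.append(f"no asymptotic intervals: {exc}")
        return fit


def _aic_value(rss: float, n: int, p: int) -> float:
    if rss <= 0:
        raise ValueError("AIC undefined for rss = 0 (degenerate likelihood)")
    # Gaussian likelihood at the MLE variance rss/n; the variance counts
    # as an extra estimated parameter.
    return n * np.log(2 * np.pi * rss / n) + n + 2 * (p + 1)


def aic(fit: FitResult) -> float:
    """Gaussian-likelihood AIC with the residual variance as a parameter."""
    if not fit.converged:
        raise ValueError("AIC requires a converged fit")
    return _aic_value(fit.rss, fit.n_obs, fit.n_params)


def asymptotic_ci(
    fit: FitResult, level: float = 0.95, quantile: str = "t"
) -> FitResult:
    """Wald-type confidence intervals from the Gauss-Newton normal matrix.

    ``se = sqrt(s^2 * diag((J'J)^-1))`` with ``s^2 = rss / (n - p)``;
    intervals use Student-t quantiles by default (``quantile="z"`` for
    normal quantiles).
    """
    if fit._jtj is None:
        raise ValueError("fit carries no normal matrix; refit first")
    n, p = fit.n_obs, fit.n_params
    jtj = fit._jtj
    cond = np.linalg.cond(jtj)
    if not np.isfinite(cond) or cond > 1e15:
        eigval, eigvec = np.linalg.eigh(jtj)
        worst = fit._param_names[int(np.argmax(np.abs(eigvec[:, 0])))]
        raise np.linalg.LinAlgError(
            f"singular normal matrix: parameter {worst!r} is not identifiable"
        )
    cov = np.linalg.inv(jtj) * (fit.rss / (n - p))
    se = np.sqrt(np.diag(cov))
    alpha = 1.0 - level
    if quantile == "t":
        q = stats.t.ppf(1 - alpha / 2, n - p)
    elif quantile == "z":
        q = stats.norm.ppf(1 - alpha / 2)
    else:
        raise ValueError(f"unknown quantile type {quantile!r}")
    se_map = dict(zip(fit._param_names, (float(v) for v in se)))
    ci_map = {
        name: (fit.estimates[name] - q * se_map[name], fit.estimates[name] + q * se_map[name])
        for name in fit._param_names
    }
    return replace(fit, se=se_map, ci95=ci_map, ci_level=level, ci_quantile=quantile)


def adjusted_r2(fit: FitResult, data: pd.DataFrame) -> float:
    """Coefficient of determination penalised for degrees of freedom."""
    sub = phase_subset(data, fit.phase, fit.schedule)
    y = sub["concentration"].to_numpy(float)
    n, p = len(y), fit.n_params
    if n <= p:
        raise ValueError(f"n = {n} <= p = {p}")
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - (fit.rss / (n - p)) / (tss / (n - 1))


def compare_nested(null_fit: FitResult, alt_fit: FitResult) -> ModelComparison:
    """Extra-sum-of-squares F-test plus AIC preference for nested fits.

    The model with the lower AIC is ``preferred``; the F-test p-value is
    reported alongside regardless (two-step logic: AIC screen first,
    significance from the F-test).
    """
    if null_fit.phase != alt_fit.phase:
        raise ValueError(
            f"fits are for different phases: {null_fit.phase} vs {alt_fit.phase}"
        )
    if null_fit._data_key is None or alt_fit._data_key is None or not (
        null_fit._data_key.shape == alt_fit._data_key.shape
        and np.allclose(null_fit._data_key, alt_fit._data_key)
    ):
        raise ValueError("fits were produced from different observations")
    if alt_fit.n_params <= null_fit.n_params:
        raise ValueError("alternative model must have more parameters than null")
    df_num = alt_fit.n_params - null_fit.n_params
    df_den = alt_fit.n_obs - alt_fit.n_params
    f_stat = max(
        0.0,
        ((null_fit.rss - alt_fit.rss) / df_num) / (alt_fit.rss / df_den),
    )
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    preferred = "by_habitat" if alt_fit.aic < null_fit.aic else "pooled"
    return ModelComparison(
        phase=null_fit.phase,
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
        aic_null=null_fit.aic,
        aic_alt=alt_fit.aic,
        preferred=preferred,
    )
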