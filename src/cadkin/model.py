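"""Two-phase one-compartment dietary uptake/elimination model.

The internal concentration ``C_I(t)`` of a colony feeding on food with
concentration ``C_E`` follows first-order kinetics with an assimilation
rate constant ``kA`` and an elimination rate constant ``kE``::

    C_I(t) = C_0 * exp(-kE * t) + C_E * (kA / kE) * (1 - exp(-kE * t))

The experiment has two phases: an uptake phase on contaminated food
(``t <= t_C``, food concentration ``C_Eu``) and a depuration phase on
clean food (``t > t_C``, food concentration ``C_Ed``).  The depuration
branch starts from the concentration predicted by the uptake branch at
the switch day ``t_C``, so the full trajectory is continuous there by
construction.

All functions here are pure and accept scalar or array time arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateParameterError",
    "ExposureSchedule",
    "KineticParams",
    "TwoPhaseModel",
    "predict_contamination",
    "concentration_at_switch",
    "predict_decontamination",
    "predict_trajectory",
    "steady_state",
]


class DegenerateParameterError(ValueError):
    """Raised when kinetic parameters make the exponential model undefined."""


@dataclass(frozen=True)
class ExposureSchedule:
    """Fixed experimental constants.

    Parameters
    ----------
    C_I0 : float
        Internal concentration at the start of the uptake phase
        (mg·kg⁻¹ dry tissue), typically the mean of the initial colonies.
    C_Eu : float
        Food concentration during the contamination phase (mg·kg⁻¹).
    C_Ed : float
        Food concentration during the decontamination phase (mg·kg⁻¹).
    t_C : float
        Day on which the food is switched from contaminated to clean.
    """

    C_I0: float
    C_Eu: float = 100.0
    C_Ed: float = 1.0
    t_C: float = 21.0

    def __post_init__(self) -> None:
        for name in ("C_I0", "C_Eu", "C_Ed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.t_C <= 0:
            raise ValueError(f"t_C must be > 0, got {self.t_C}")


@dataclass(frozen=True)
class KineticParams:
    """An (assimilation, elimination) rate-constant pair, in day⁻¹."""

    kA: float
    kE: float

    @property
    def warning(self) -> bool:
        """True when either rate constant is non-positive (suspect fit)."""
        return self.kA <= 0 or self.kE <= 0

    def _require_nondegenerate(self) -> None:
        if self.kE == 0:
            raise DegenerateParameterError(
                "kE = 0 makes the exponential solution undefined; the "
                "degenerate limit is linear accumulation "
                "C_0 + C_E * kA * t, which this model deliberately does "
                "not apply."
            )


@dataclass(frozen=True)
class TwoPhaseModel:
    """Kinetic parameters for both phases plus the exposure schedule."""

    contamination: KineticParams
    decontamination: KineticParams
    schedule: ExposureSchedule


def _uptake_curve(tau, c0: float, c_e: float, params: KineticParams):
    """One-compartment solution from initial value ``c0`` at ``tau = 0``."""
    params._require_nondegenerate()
    tau = np.asarray(tau, dtype=float)
    decay = np.exp(-params.kE * tau)
    out = c0 * decay + c_e * (params.kA / params.kE) * (1.0 - decay)
    return out if out.ndim else float(out)


def predict_contamination(params: KineticParams, schedule: ExposureSchedule, t):
    """Internal concentration during the uptake phase (``t <= t_C``).

    ``t`` may be a scalar or array of days; must be >= 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return _uptake_curve(t, schedule.C_I0, schedule.C_Eu, params)


def concentration_at_switch(
    params_contamination: KineticParams, schedule: ExposureSchedule
) -> float:
    """Uptake-branch prediction at the switch day ``t_C``.

    This anchors the depuration branch so the two-phase trajectory is
    continuous at the food switch.
    """
    return float(
        predict_contamination(params_contamination, schedule, schedule.t_C)
    )


def predict_decontamination(model: TwoPhaseModel, t):
    """Internal concentration during the depuration phase (``t > t_C``)."""
    sched = model.schedule
    t = np.asarray(t, dtype=float)
    if np.any(t < sched.t_C):
        raise ValueError(f"decontamination branch requires t >= t_C = {sched.t_C}")
    c_switch = concentration_at_switch(model.contamination, sched)
    return _uptake_curve(t - sched.t_C, c_switch, sched.C_Ed, model.decontamination)


def predict_trajectory(model: TwoPhaseModel, times):
    """Piecewise two-phase prediction over arbitrary non-negative days.

    Days up to and including ``t_C`` use the uptake branch; later days
    use the depuration branch anchored at the switch concentration.
    """
    times = np.asarray(times, dtype=float)
    scalar = times.ndim == 0
    times = np.atleast_1d(times)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    out = np.empty_like(times)
    up = times <= model.schedule.t_C
    if np.any(up):
        out[up] = predict_contamination(
            model.contamination, model.schedule, times[up]
        )
    if np.any(~up):
        out[~up] = predict_decontamination(model, times[~up])
    return float(out[0]) if scalar else out


def steady_state(params: KineticParams, C_E: float) -> float:
    """Plateau concentration ``C_E * kA / kE`` reached as ``t -> inf``.

    Only defined for ``kE > 0``; otherwise the trajectory diverges.
    """
    if params.kE <= 0:
        raise DegenerateParameterError(
            f"no steady state for kE = {params.kE} (requires kE > 0)"
        )
    return C_E * params.kA / params.kE
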