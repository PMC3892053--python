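"""Indirect-response (turnover) pharmacodynamic models.

The response R is produced at a zero-order rate ``kin`` and lost at a
first-order rate ``kout``; drug concentration acts through a sigmoid Hill
function on one of the two:

* ``stimulate_kout`` — dR/dt = kin - kout * (1 + H(C)) * R, with
  H(C) = Emax * C^n / (C50^n + C^n).  Antipyresis: the drug speeds loss,
  lowering body temperature toward kin / (kout * (1 + Emax)).
* ``inhibit_kout``  — dR/dt = kin - kout * (1 - H(C)) * R, H capped by
  Imax <= 1.  Locomotor endpoints (creeping speed, vertical force): the
  drug removes the pain "brake", raising the response.
* ``inhibit_kin``   — dR/dt = kin * (1 - C^n / (C50^n + C^n)) - kout * R.
  Lameness score: full inhibition is structural (the cap is fixed at 1,
  not estimated).

Fitting is sequential: the concentration input is the subject's fitted
oral PK curve, and PD residuals are unweighted on the raw endpoint scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .effect_metrics import EffectTimeCourse
from .exceptions import InputError, IntegrationError
from .pharmacokinetics import FitDiagnostics, _wald_cis

__all__ = [
    "IndirectResponseModelKind",
    "IndirectResponseParameters",
    "SimulatedResponse",
    "ENDPOINT_MODEL_KIND",
    "hill_fraction",
    "simulate_turnover",
    "fit_turnover",
]


class IndirectResponseModelKind(str, Enum):
    STIMULATE_KOUT = "stimulate_kout"
    INHIBIT_KOUT = "inhibit_kout"
    INHIBIT_KIN = "inhibit_kin"


#: fixed endpoint -> model mapping
ENDPOINT_MODEL_KIND = {
    "body_temperature": IndirectResponseModelKind.STIMULATE_KOUT,
    "creeping_speed": IndirectResponseModelKind.INHIBIT_KOUT,
    "vertical_force": IndirectResponseModelKind.INHIBIT_KOUT,
    "lameness_score": IndirectResponseModelKind.INHIBIT_KIN,
}

HILL_N_MAX = 10.0


@dataclass(frozen=True)
class IndirectResponseParameters:
    """Turnover parameters; ``effect_cap`` is Emax or Imax by model kind."""

    kin: float  # response units / h
    kout: float  # 1/h
    effect_cap: float  # Emax (>0) or Imax in (0, 1]
    c50: float  # ug/L (== ng/mL)
    n: float  # Hill coefficient

    def __post_init__(self) -> None:
        if self.kin <= 0 or self.kout <= 0 or self.c50 <= 0:
            raise InputError("kin, kout and c50 must be positive")
        if not 0 < self.n <= HILL_N_MAX:
            raise InputError(f"Hill coefficient must be in (0, {HILL_N_MAX}]")
        if self.effect_cap <= 0:
            raise InputError("effect_cap must be positive")

    @property
    def baseline(self) -> float:
        """Steady-state response kin/kout in the absence of drug."""
        return self.kin / self.kout


@dataclass(frozen=True)
class SimulatedResponse:
    times: tuple[float, ...]
    response: tuple[float, ...]
    concentration_input: tuple[float, ...]


def hill_fraction(c, effect_cap: float, c50: float, n: float):
    """Sigmoid drug effect ``effect_cap * c^n / (c50^n + c^n)``.

    Strictly increasing in c, 0 at c = 0, effect_cap/2 at c = c50,
    approaching effect_cap as c grows.  Accepts scalars or arrays.
    """
    if c50 <= 0:
        raise InputError("c50 must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise InputError("concentration must be non-negative")
    # ratio form avoids overflow of c**n for large c
    with np.errstate(over="ignore"):
        r = (c / c50) ** n
    frac = effect_cap * np.where(np.isinf(r), 1.0, r / (1.0 + r))
    return float(frac) if frac.ndim == 0 else frac


def _rhs(kind, p: IndirectResponseParameters):
    if kind is IndirectResponseModelKind.STIMULATE_KOUT:
        return lambda h, r: p.kin - p.kout * (1.0 + h) * r
    if kind is IndirectResponseModelKind.INHIBIT_KOUT:
        return lambda h, r: p.kin - p.kout * (1.0 - h) * r
    return lambda h, r: p.kin * (1.0 - h) - p.kout * r


def simulate_turnover(
    kind: IndirectResponseModelKind,
    params: IndirectResponseParameters,
    conc_fn: Callable[[float], float],
    times: Sequence[float],
    rtol: float = 1e-9,
) -> SimulatedResponse:
    """Integrate the chosen turnover ODE from R(0) = kin/kout.

    The initial condition is the inflamed steady state at treatment time.
    For ``inhibit_kout`` the hill cap is Imax; for ``inhibit_kin`` the cap
    is structurally 1 regardless of ``params.effect_cap``.
    """
    kind = IndirectResponseModelKind(kind)
    t = np.asarray(times, dtype=float)
    if t.size == 0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise InputError("times must be a non-empty increasing sequence")
    if np.any(t < 0):
        raise InputError("times must be non-negative (treatment at t = 0)")
    if kind is IndirectResponseModelKind.INHIBIT_KOUT and params.effect_cap > 1.0:
        raise InputError("Imax must be <= 1 for inhibit_kout")

    cap = 1.0 if kind is IndirectResponseModelKind.INHIBIT_KIN else params.effect_cap
    rhs = _rhs(kind, params)

    def ode(tt, r):
        h = hill_fraction(max(conc_fn(tt), 0.0), cap, params.c50, params.n)
        return [rhs(h, r[0])]

    # integration always starts at treatment time with the inflamed steady state
    r0 = params.baseline
    sol = solve_ivp(
        ode,
        (0.0, t[-1] if t[-1] > 0 else 1e-9),
        [r0],
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=rtol * max(r0, 1e-3),
        max_step=1.0,
    )
    if not sol.success:
        raise IntegrationError(
            f"turnover ODE integration failed: {sol.message}",
            details={"kind": kind.value, "status": sol.status},
        )
    conc = np.array([max(conc_fn(tt), 0.0) for tt in t])
    # R >= 0 is structural for every model form; clip solver undershoot
    response = np.maximum(sol.y[0], 0.0)
    return SimulatedResponse(
        times=tuple(t), response=tuple(response), concentration_input=tuple(conc)
    )


# ---------------------------------------------------------------------------
# estimation


def _pd_initial_guess(
    kind: IndirectResponseModelKind, t: np.ndarray, y: np.ndarray, conc: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    r0 = max(float(y[0]), 1e-6)
    kout0 = 1.0
    cpos = conc[conc > 0]
    c50_0 = float(np.median(cpos)) if cpos.size else 100.0
    n0 = 2.0
    if kind is IndirectResponseModelKind.STIMULATE_KOUT:
        drop = max((r0 - float(np.min(y))) / max(float(np.min(y)), 1e-6), 0.01)
        cap0, cap_lo, cap_hi = min(drop, 5.0), 1e-6, 100.0
    elif kind is IndirectResponseModelKind.INHIBIT_KOUT:
        rise = 1.0 - r0 / max(float(np.max(y)), 1e-6)
        cap0, cap_lo, cap_hi = min(max(rise, 0.05), 0.95), 1e-6, 1.0
    else:  # inhibit_kin: cap fixed at 1, not a free parameter
        cap0 = cap_lo = cap_hi = 1.0
    theta0 = np.array([kout0 * r0, kout0, cap0, c50_0, n0])
    lo = np.array([1e-9, 1e-9, cap_lo, 1e-6, 0.05])
    hi = np.array([np.inf, np.inf, cap_hi, np.inf, HILL_N_MAX])
    names = ["kin", "kout", "effect_cap", "c50", "n"]
    return theta0, lo, hi, names


def fit_turnover(
    course: EffectTimeCourse,
    conc_fn: Callable[[float], float],
    kind: IndirectResponseModelKind | str,
) -> tuple[IndirectResponseParameters, FitDiagnostics]:
    """Per-subject least-squares estimation of the turnover parameters.

    Residuals are unweighted on the raw endpoint scale.  Bounds:
    n in (0, 10], Imax in (0, 1]; for the lameness model the drug-effect
    cap is fixed at 1 and carries no confidence interval.  The endpoint
    must match the model kind of :data:`ENDPOINT_MODEL_KIND`.
    """
    kind = IndirectResponseModelKind(kind)
    expected = ENDPOINT_MODEL_KIND.get(course.endpoint)
    if expected is None or expected is not kind:
        raise InputError(
            f"endpoint {course.endpoint!r} is not modeled by {kind.value!r}"
        )
    t = np.asarray(course.times, dtype=float)
    y = np.asarray(course.values, dtype=float)
    if len(t) < 6:
        raise InputError(f"need >= 6 observations, got {len(t)}")

    conc = np.array([max(conc_fn(tt), 0.0) for tt in t])
    theta0, lo, hi, names = _pd_initial_guess(kind, t, y, conc)
    fixed_cap = kind is IndirectResponseModelKind.INHIBIT_KIN
    free = np.array([True, True, not fixed_cap, True, True])

    def unpack(x: np.ndarray) -> IndirectResponseParameters:
        full = theta0.copy()
        full[free] = x
        return IndirectResponseParameters(
            kin=full[0], kout=full[1], effect_cap=full[2], c50=full[3], n=full[4]
        )

    def resid(x: np.ndarray) -> np.ndarray:
        try:
            sim = simulate_turnover(kind, unpack(x), conc_fn, t, rtol=1e-8)
        except (IntegrationError, InputError):
            return np.full_like(y, 1e6)
        return np.asarray(sim.response) - y

    res = optimize.least_squares(
        resid,
        theta0[free],
        bounds=(lo[free], hi[free]),
        method="trf",
        x_scale="jac",
        max_nfev=400,
    )
    params = unpack(res.x)
    fitted = np.asarray(simulate_turnover(kind, params, conc_fn, t).response)
    rss = float(np.sum((y - fitted) ** 2))

    cis = _wald_cis(res, [n for n, f in zip(names, free) if f], len(t))
    if fixed_cap:
        cis["effect_cap"] = (1.0, 1.0, 1.0)
    diag = FitDiagnostics(
        aic=len(t) * np.log(max(rss, 1e-300) / len(t)) + 2 * int(free.sum()),
        weighted_rss=rss,
        converged=bool(res.success),
        parameter_cis=cis,
        residuals=y - fitted,
        fitted=fitted,
        notes=(["effect cap fixed at 1 (full inhibition of kin)"] if fixed_cap else []),
    )
    if not res.success:
        diag.notes.append("optimizer did not converge; estimates are provisional")
    return params, diag
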