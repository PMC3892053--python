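"""One-compartment oral pharmacokinetics, polyexponential fitting and NCA.

The oral model is the Bateman function with a lag time: first-order
absorption (``k01``) into, and first-order elimination (``k10``) out of, a
single compartment of apparent volume ``V/F``.  Doses are supplied in mg/kg
and converted internally to ug/kg so that concentrations are ug/L
throughout.

Fitting uses least squares with 1/yhat^2 weights (iteratively reweighted
against the fitted values) and selects the number of exponential terms
(2 or 3) by AIC.  IV profiles are summarised by non-compartmental analysis
with a linear-up/log-down trapezoid and automatic terminal-point selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import DegenerateParameterError, EstimationError, InputError

__all__ = [
    "ConcentrationProfile",
    "OralPKParameters",
    "NCAResult",
    "FitDiagnostics",
    "oral_concentration",
    "fit_oral_pk",
    "nca_iv",
    "terminal_halflife_sparse",
]

#: mg/kg -> ug/kg
MG_TO_UG = 1000.0

#: default assay limit of quantification, ug/L (0.01 ug/mL)
DEFAULT_LOQ = 10.0


@dataclass(frozen=True)
class OralPKParameters:
    """Parameters of the lagged Bateman oral model.

    Attributes
    ----------
    v_over_f : float
        Apparent volume of distribution per bioavailability, L/kg.
    k01 : float
        First-order absorption rate constant, 1/h.
    k10 : float
        First-order elimination rate constant, 1/h.
    tlag : float
        Absorption lag time, h.
    """

    v_over_f: float
    k01: float
    k10: float
    tlag: float = 0.0

    def __post_init__(self) -> None:
        if self.v_over_f <= 0 or self.k01 <= 0 or self.k10 <= 0:
            raise InputError("v_over_f, k01 and k10 must all be positive")
        if self.tlag < 0:
            raise InputError("tlag must be non-negative")
        if self.k01 == self.k10:
            raise DegenerateParameterError(
                "k01 == k10: the Bateman form is degenerate (limiting form not supported)"
            )

    @property
    def terminal_halflife(self) -> float:
        """ln(2) over the slower of the two rate constants, h."""
        return float(np.log(2.0) / min(self.k01, self.k10))

    @property
    def tmax(self) -> float:
        """Time of peak concentration, h."""
        return float(self.tlag + np.log(self.k01 / self.k10) / (self.k01 - self.k10))

    def auc_0_inf(self, dose_mg_per_kg: float) -> float:
        """Closed-form AUC(0, inf) in h*ug/L for a dose in mg/kg."""
        return dose_mg_per_kg * MG_TO_UG / (self.v_over_f * self.k10)


@dataclass(frozen=True)
class ConcentrationProfile:
    """A single subject's concentration-time observations."""

    subject_id: str
    route: str  # "oral" | "iv"
    dose: float  # mg/kg
    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    bql_flags: tuple[bool, ...] = ()
    loq: float = DEFAULT_LOQ

    def __post_init__(self) -> None:
        if self.route not in ("oral", "iv"):
            raise InputError(f"route must be 'oral' or 'iv', got {self.route!r}")
        if self.dose <= 0:
            raise InputError("dose must be positive")
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size != c.size:
            raise InputError("times and concentrations must have equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise InputError("times must be strictly increasing and non-negative")
        if not self.bql_flags:
            object.__setattr__(self, "bql_flags", tuple(ci < self.loq for ci in c))
        elif len(self.bql_flags) != t.size:
            raise InputError("bql_flags length mismatch")
        bql = np.asarray(self.bql_flags, dtype=bool)
        if np.any(c[~bql] < 0):
            raise InputError("non-BQL concentrations must be non-negative")

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations of non-BQL observations."""
        bql = np.asarray(self.bql_flags, dtype=bool)
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        return t[~bql], c[~bql]


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental summary of an IV profile."""

    auc_0_inf: float  # h*ug/L
    auc_extrapolated_fraction: float
    lambda_z: float  # 1/h
    half_life: float  # h
    clearance: float  # L/h/kg
    v_z: float  # L/kg
    n_lambda_z_points: int
    extrapolation_warning: bool = False


@dataclass
class FitDiagnostics:
    """Diagnostics attached to every least-squares fit."""

    aic: float
    weighted_rss: float
    converged: bool
    parameter_cis: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    n_exponentials: int | None = None
    aic_by_candidate: dict[int, float] = field(default_factory=dict)
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None
    n_reweight_cycles: int = 0
    notes: list[str] = field(default_factory=list)


def oral_concentration(
    params: OralPKParameters, dose: float, times: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Concentration (ug/L) of the lagged Bateman model at ``times`` (h).

    ``dose`` is in mg/kg; zero is returned for t <= tlag.
    """
    if dose <= 0:
        raise InputError("dose must be positive")
    t = np.asarray(times, dtype=float)
    tau = t - params.tlag
    d_ug = dose * MG_TO_UG
    scale = d_ug * params.k01 / (params.v_over_f * (params.k01 - params.k10))
    with np.errstate(over="ignore"):
        c = scale * (np.exp(-params.k10 * tau) - np.exp(-params.k01 * tau))
    c = np.where(tau <= 0, 0.0, c)
    return np.maximum(c, 0.0)


# ---------------------------------------------------------------------------
# polyexponential oral fitting


def _bateman_predict(theta: np.ndarray, dose: float, t: np.ndarray) -> np.ndarray:
    v, k10, dk, tlag = theta
    p = OralPKParameters(v_over_f=v, k10=k10, k01=k10 + dk, tlag=tlag)
    return oral_concentration(p, dose, t)


def _triexp_predict(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    # A1 e^-l1 + A2 e^-l2 - (A1+A2) e^-ka, l1 < l2 < ka, shifted by tlag
    a1, a2, l1, dl2, dka, tlag = theta
    l2 = l1 + dl2
    ka = l2 + dka
    tau = t - tlag
    with np.errstate(over="ignore"):
        c = (
            a1 * np.exp(-l1 * tau)
            + a2 * np.exp(-l2 * tau)
            - (a1 + a2) * np.exp(-ka * tau)
        )
    return np.where(tau <= 0, 0.0, c)


def _irls(
    predict,
    theta0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    t: np.ndarray,
    y: np.ndarray,
    max_cycles: int = 10,
    rtol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, bool, int, optimize.OptimizeResult]:
    """Least squares with 1/yhat^2 weights, reweighted against fitted values."""
    weights = 1.0 / np.maximum(y, 1e-12) ** 2
    theta = theta0.copy()
    converged = False
    cycles = 0
    res = None
    for cycle in range(max_cycles):
        cycles = cycle + 1
        sw = np.sqrt(weights)

        def resid(th, _sw=sw):
            return (_sw * (predict(th, t) - y)).astype(float)

        res = optimize.least_squares(
            resid, theta, bounds=bounds, method="trf", x_scale="jac", max_nfev=2000
        )
        new_theta = res.x
        yhat = np.maximum(predict(new_theta, t), 1e-12)
        weights = 1.0 / yhat**2
        rel = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), 1e-12))
        theta = new_theta
        if rel < rtol:
            converged = res.success
            break
    return theta, weights, converged, cycles, res


def _aic(weighted_rss: float, n: int, p: int) -> float:
    return n * np.log(max(weighted_rss, 1e-300) / n) + 2 * p


def _wald_cis(
    res: optimize.OptimizeResult, names: Sequence[str], n: int, alpha: float = 0.05
) -> dict[str, tuple[float, float, float]]:
    """Approximate 95% Wald intervals from the least-squares Jacobian."""
    p = len(names)
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    return {
        name: (est - tcrit * s, est, est + tcrit * s)
        for name, est, s in zip(names, res.x, se)
    }


def _initial_bateman_guess(t: np.ndarray, y: np.ndarray, dose: float) -> np.ndarray:
    imax = int(np.argmax(y))
    tail_n = max(3, min(4, len(t) - imax - 1))
    tt, yy = t[-tail_n:], y[-tail_n:]
    if np.all(yy > 0) and len(tt) >= 2:
        slope = np.polyfit(tt, np.log(yy), 1)[0]
        k10 = max(-slope, 1e-3)
    else:
        k10 = 0.2
    k01 = max(5.0 * k10, k10 + 0.5)
    auc = np.trapezoid(y, t)
    v = dose * MG_TO_UG / max(auc * k10, 1e-9) if auc > 0 else 1.0
    return np.array([v, k10, k01 - k10, 0.0])


def fit_oral_pk(
    profile: ConcentrationProfile,
    candidate_n_exponentials: Sequence[int] = (2, 3),
) -> tuple[OralPKParameters, FitDiagnostics]:
    """Fit the oral profile by weighted least squares with AIC model selection.

    Candidates are the 2-exponential lagged Bateman model and a
    3-exponential extension sharing the absorption constraint C(tlag) = 0.
    Weights are 1/yhat^2, re-evaluated against the fitted curve until the
    parameters stabilise.  Whatever candidate wins, the returned
    :class:`OralPKParameters` describe the one-compartment reduction
    (terminal rate -> k10, fastest rate -> k01, V/F from the model AUC);
    the selected exponential count is recorded in the diagnostics.
    """
    if profile.route != "oral":
        raise InputError("fit_oral_pk requires an oral profile")
    t, y = profile.quantifiable()
    # pre-dose / onset exact zeros carry no information for the weighted fit
    keep = y > 0
    t, y = t[keep], y[keep]
    if len(t) < 6:
        raise InputError(f"need >= 6 quantifiable observations, got {len(t)}")

    candidates = sorted(set(candidate_n_exponentials))
    if any(c not in (2, 3) for c in candidates):
        raise InputError("candidate_n_exponentials must be a subset of {2, 3}")

    tlag_max = max(float(t[0]) - 1e-9, 0.0)
    fits: dict[int, dict] = {}
    skipped: list[str] = []

    for n_exp in candidates:
        if n_exp == 2:
            theta0 = _initial_bateman_guess(t, y, profile.dose)
            theta0[3] = min(theta0[3], tlag_max)
            lo = np.array([1e-9, 1e-9, 1e-9, 0.0])
            hi = np.array([np.inf, np.inf, np.inf, max(tlag_max, 1e-12)])
            predict = lambda th, tt: _bateman_predict(th, profile.dose, tt)  # noqa: E731
            names = ["v_over_f", "k10", "k01_minus_k10", "tlag"]
        else:
            g = _initial_bateman_guess(t, y, profile.dose)
            cmax = float(np.max(y))
            theta0 = np.array([cmax, cmax / 2, g[1], g[1], g[2], 0.0])
            lo = np.array([1e-9, 1e-9, 1e-9, 1e-9, 1e-9, 0.0])
            hi = np.array([np.inf] * 5 + [max(tlag_max, 1e-12)])
            predict = lambda th, tt: _triexp_predict(th, tt)  # noqa: E731
            names = ["a1", "a2", "lambda1", "dlambda2", "dka", "tlag"]
        if len(t) <= len(theta0):
            # candidate under-determined; drop it unless nothing else remains
            skipped.append(
                f"{n_exp}-exponential candidate skipped: {len(t)} points "
                f"cannot identify {len(theta0)} parameters"
            )
            continue
        theta, weights, converged, cycles, res = _irls(predict, theta0, (lo, hi), t, y)
        yhat = predict(theta, t)
        wrss = float(np.sum(weights * (y - yhat) ** 2))
        fits[n_exp] = {
            "theta": theta,
            "aic": _aic(wrss, len(t), len(theta)),
            "wrss": wrss,
            "converged": converged,
            "cycles": cycles,
            "res": res,
            "names": names,
            "yhat": yhat,
        }

    if not fits:
        raise InputError(
            f"{len(t)} points cannot identify any candidate model: "
            + "; ".join(skipped)
        )
    best_n = min(fits, key=lambda k: fits[k]["aic"])
    best = fits[best_n]
    theta = best["theta"]

    if best_n == 2:
        params = OralPKParameters(
            v_over_f=float(theta[0]),
            k10=float(theta[1]),
            k01=float(theta[1] + theta[2]),
            tlag=float(theta[3]),
        )
    else:
        a1, a2, l1, dl2, dka, tlag = theta
        l2, ka = l1 + dl2, l1 + dl2 + dka
        auc = a1 / l1 + a2 / l2 - (a1 + a2) / ka
        if auc <= 0:
            raise EstimationError("3-exponential fit yielded non-positive AUC")
        params = OralPKParameters(
            v_over_f=float(profile.dose * MG_TO_UG / (auc * l1)),
            k10=float(l1),
            k01=float(ka),
            tlag=float(tlag),
        )

    diag = FitDiagnostics(
        aic=float(best["aic"]),
        weighted_rss=best["wrss"],
        converged=bool(best["converged"]),
        parameter_cis=_wald_cis(best["res"], best["names"], len(t)),
        n_exponentials=best_n,
        aic_by_candidate={k: float(v["aic"]) for k, v in fits.items()},
        residuals=y - best["yhat"],
        fitted=best["yhat"],
        n_reweight_cycles=best["cycles"],
        notes=["constraint k01 > k10 enforced (terminal phase = elimination)"]
        + skipped,
    )
    if not best["converged"]:
        diag.notes.append("optimizer did not converge; estimates are provisional")
    return params, diag


# ---------------------------------------------------------------------------
# non-compartmental analysis


def _select_lambda_z(t: np.ndarray, c: np.ndarray) -> tuple[float, int, float]:
    """Terminal slope by log-linear regression on the last n >= 3 points.

    Returns (lambda_z, n_points, intercept).  The n maximising adjusted R^2
    is selected, ties broken toward more points.
    """
    imax = int(np.argmax(c))
    cand_t, cand_c = t[imax + 1 :], c[imax + 1 :]
    pos = cand_c > 0
    cand_t, cand_c = cand_t[pos], cand_c[pos]
    if len(cand_t) < 3:
        raise EstimationError("need >= 3 positive post-peak points for lambda_z")
    best = None
    logc = np.log(cand_c)
    for n in range(3, len(cand_t) + 1):
        tt, ll = cand_t[-n:], logc[-n:]
        slope, intercept = np.polyfit(tt, ll, 1)
        fitted = slope * tt + intercept
        ss_res = np.sum((ll - fitted) ** 2)
        ss_tot = np.sum((ll - ll.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj >= best[0] - 1e-10:
            best = (adj, slope, intercept, n)
    _, slope, intercept, n = best
    if slope >= 0:
        raise EstimationError("terminal phase is not decaying (lambda_z <= 0)")
    return -slope, n, intercept


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c2 > 0:
            auc += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return auc


def nca_iv(profile: ConcentrationProfile) -> NCAResult:
    """Non-compartmental analysis of an IV bolus profile.

    AUC uses the linear-up/log-down trapezoid to the last quantifiable
    observation plus a Clast/lambda_z tail; C0 is back-extrapolated
    log-linearly from the first two samples when the profile does not start
    at t = 0.  An extrapolated-AUC fraction above 20% raises a warning flag.
    """
    if profile.route != "iv":
        raise InputError("nca_iv requires an IV profile")
    t, c = profile.quantifiable()
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(t) < 3:
        raise InputError("need >= 3 positive observations for NCA")

    lambda_z, n_lz, _ = _select_lambda_z(t, c)

    if t[0] > 0 and len(t) >= 2:
        # log-linear back-extrapolation to t=0 (IV bolus convention)
        slope0 = (np.log(c[1]) - np.log(c[0])) / (t[1] - t[0])
        c0 = c[0] * np.exp(-slope0 * t[0]) if slope0 < 0 else c[0]
        t = np.insert(t, 0, 0.0)
        c = np.insert(c, 0, c0)

    auc_last = _auc_lin_up_log_down(t, c)
    tail = c[-1] / lambda_z
    auc_inf = auc_last + tail
    frac = tail / auc_inf
    dose_ug = profile.dose * MG_TO_UG
    cl = dose_ug / auc_inf
    return NCAResult(
        auc_0_inf=float(auc_inf),
        auc_extrapolated_fraction=float(frac),
        lambda_z=float(lambda_z),
        half_life=float(np.log(2.0) / lambda_z),
        clearance=float(cl),
        v_z=float(cl / lambda_z),
        n_lambda_z_points=int(n_lz),
        extrapolation_warning=bool(frac > 0.20),
    )


def terminal_halflife_sparse(
    times: Sequence[float], concentrations: Sequence[float]
) -> float:
    """Half-life from log-linear regression over post-peak points (h).

    Non-positive concentrations are excluded with a warning; at least two
    usable points after (and including) the peak are required and the slope
    must be negative.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size != c.size:
        raise InputError("times and concentrations must have equal length")
    bad = c <= 0
    if np.any(bad):
        warnings.warn(
            f"excluding {int(bad.sum())} non-positive concentration(s) from "
            "log-linear regression",
            UserWarning,
            stacklevel=2,
        )
        t, c = t[~bad], c[~bad]
    if len(c) < 2:
        raise EstimationError("fewer than 2 usable points")
    imax = int(np.argmax(c))
    t, c = t[imax:], c[imax:]
    if len(c) < 2:
        raise EstimationError("fewer than 2 post-peak points")
    slope = np.polyfit(t, np.log(c), 1)[0]
    if slope >= 0:
        raise EstimationError("no declining phase (slope >= 0)")
    return float(np.log(2.0) / (-slope))
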