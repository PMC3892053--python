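"""Virtual cohorts emulating the two study designs.

Study 1: 12 beagles in a 2x2 crossover, oral and IV 2 mg/kg, with a
bimodal metabolizer structure (extensive vs poor, clearance ~3-fold
apart).  Study 2: 4 breeds x 10 dogs, oral 2 mg/kg, sparse samples at
6, 8, 10 and 24 h.  Individual parameters are drawn log-normally around
class means; all randomness flows from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .effect_metrics import EffectTimeCourse
from .exceptions import InputError
from .indirect_response import (
    ENDPOINT_MODEL_KIND,
    IndirectResponseModelKind,
    IndirectResponseParameters,
    simulate_turnover,
)
from .pharmacokinetics import (
    DEFAULT_LOQ,
    MG_TO_UG,
    ConcentrationProfile,
    OralPKParameters,
    oral_concentration,
)

__all__ = [
    "SCHEDULES",
    "PKClassMeans",
    "CohortSpec",
    "VirtualDog",
    "generate_cohort",
    "generate_concentration_data",
    "generate_effect_data",
    "healthy_baseline",
]

#: named sampling designs (hours post-treatment)
SCHEDULES: dict[str, tuple[float, ...]] = {
    "oral_study1": (0.0, 0.5, 1.0, 1.5, 4.0, 6.0, 9.0, 15.0, 30.0, 48.0),
    "iv_study1": (2 / 60, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 9.0, 12.0, 24.0, 30.0, 48.0),
    "sparse_study2": (6.0, 8.0, 10.0, 24.0),
    "pd_study1": (2.0, 4.0, 9.0, 15.0, 22.0, 27.0),
    "pd_dense": (1.0, 2.0, 3.0, 4.0, 6.0, 9.0, 12.0, 15.0, 18.0, 22.0, 27.0, 36.0),
}


@dataclass(frozen=True)
class PKClassMeans:
    """Population means of the individual PK parameters for one class."""

    clearance: float  # L/h/kg
    volume: float  # L/kg
    k01: float = 1.5  # 1/h
    tlag: float = 0.25  # h

    @property
    def k10(self) -> float:
        return self.clearance / self.volume


# class means anchored to the printed IV summaries (EM / PM)
DEFAULT_PK_MEANS: dict[str, PKClassMeans] = {
    "EM": PKClassMeans(clearance=0.31, volume=1.12),
    "PM": PKClassMeans(clearance=0.11, volume=0.89),
}

# per-endpoint turnover means (EM / PM): kin, kout, effect_cap, c50, n
DEFAULT_PD_MEANS: dict[str, dict[str, IndirectResponseParameters]] = {
    "body_temperature": {
        "EM": IndirectResponseParameters(kin=41.30, kout=1.04, effect_cap=0.04, c50=193.2, n=5.09),
        "PM": IndirectResponseParameters(kin=45.84, kout=1.17, effect_cap=0.04, c50=473.4, n=6.99),
    },
    "creeping_speed": {
        "EM": IndirectResponseParameters(kin=0.90, kout=0.95, effect_cap=0.71, c50=239.4, n=4.74),
        "PM": IndirectResponseParameters(kin=0.76, kout=1.07, effect_cap=0.70, c50=344.5, n=3.68),
    },
    "lameness_score": {
        "EM": IndirectResponseParameters(kin=5.34, kout=1.08, effect_cap=1.0, c50=284.3, n=4.25),
        "PM": IndirectResponseParameters(kin=2.57, kout=0.509, effect_cap=1.0, c50=785.8, n=2.70),
    },
    "vertical_force": {
        "EM": IndirectResponseParameters(kin=0.09, kout=7.40, effect_cap=0.98, c50=160.8, n=6.13),
        "PM": IndirectResponseParameters(kin=0.09, kout=8.47, effect_cap=0.97, c50=325.1, n=5.67),
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a reproducible virtual cohort."""

    n_subjects: int = 12
    pm_fraction: float = 1.0 / 3.0
    pk_population_means: Mapping[str, PKClassMeans] = field(
        default_factory=lambda: dict(DEFAULT_PK_MEANS)
    )
    pd_population_means: Mapping[str, Mapping[str, IndirectResponseParameters]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PD_MEANS.items()}
    )
    between_subject_cv: float = 25.0  # %
    residual_cv_conc: float = 10.0  # %
    residual_sd_effect: float = 0.0  # endpoint units
    loq: float = DEFAULT_LOQ  # ug/L
    breeds: Mapping[str, float] | None = None  # breed -> mean terminal half-life (h)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pm_fraction <= 1:
            raise InputError("pm_fraction must lie in [0, 1]")
        if self.between_subject_cv < 0 or self.residual_cv_conc < 0:
            raise InputError("CVs must be non-negative")
        if self.residual_sd_effect < 0:
            raise InputError("residual_sd_effect must be non-negative")
        if self.n_subjects < 1:
            raise InputError("n_subjects must be >= 1")


@dataclass(frozen=True)
class VirtualDog:
    subject_id: str
    metabolizer: str  # "EM" | "PM"
    breed: str | None
    clearance: float  # L/h/kg
    volume: float  # L/kg
    k01: float  # 1/h
    tlag: float  # h
    pd_params: Mapping[str, IndirectResponseParameters]

    @property
    def k10(self) -> float:
        return self.clearance / self.volume

    @property
    def oral_params(self) -> OralPKParameters:
        return OralPKParameters(
            v_over_f=self.volume, k01=self.k01, k10=self.k10, tlag=self.tlag
        )


def _lognormal(rng: np.random.Generator, mean: float, cv_pct: float) -> float:
    """Draw with arithmetic mean ``mean`` and coefficient of variation ``cv_pct``."""
    if cv_pct == 0:
        return mean
    sigma2 = np.log1p((cv_pct / 100.0) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def generate_cohort(spec: CohortSpec) -> list[VirtualDog]:
    """Draw a cohort; identical specs produce identical cohorts."""
    rng = np.random.default_rng(spec.seed)
    breed_names = list(spec.breeds) if spec.breeds else [None]
    dogs = []
    for i in range(spec.n_subjects):
        label = "PM" if rng.random() < spec.pm_fraction else "EM"
        means = spec.pk_population_means[label]
        breed = breed_names[i % len(breed_names)]
        cl = _lognormal(rng, means.clearance, spec.between_subject_cv)
        v = _lognormal(rng, means.volume, spec.between_subject_cv)
        if breed is not None:
            # breed effect injected through the terminal rate at class volume
            hl = _lognormal(rng, spec.breeds[breed], spec.between_subject_cv)
            cl = np.log(2.0) / hl * v
        k01 = _lognormal(rng, means.k01, spec.between_subject_cv)
        tlag = means.tlag  # design constant, not a biological parameter
        pd_params = {}
        for endpoint, by_class in spec.pd_population_means.items():
            base = by_class[label]
            cap = (
                1.0
                if ENDPOINT_MODEL_KIND[endpoint] is IndirectResponseModelKind.INHIBIT_KIN
                else min(
                    _lognormal(rng, base.effect_cap, spec.between_subject_cv),
                    1.0 if base.effect_cap <= 1.0 else np.inf,
                )
            )
            pd_params[endpoint] = IndirectResponseParameters(
                kin=_lognormal(rng, base.kin, spec.between_subject_cv),
                kout=_lognormal(rng, base.kout, spec.between_subject_cv),
                effect_cap=cap,
                c50=_lognormal(rng, base.c50, spec.between_subject_cv),
                n=min(_lognormal(rng, base.n, spec.between_subject_cv), 10.0),
            )
        dogs.append(
            VirtualDog(
                subject_id=f"dog{i + 1:03d}",
                metabolizer=label,
                breed=breed,
                clearance=cl,
                volume=v,
                k01=k01,
                tlag=tlag,
                pd_params=pd_params,
            )
        )
    return dogs


def generate_concentration_data(
    cohort: Sequence[VirtualDog],
    schedule: str,
    dose: float = 2.0,
    residual_cv_conc: float = 10.0,
    loq: float = DEFAULT_LOQ,
    seed: int = 0,
) -> list[ConcentrationProfile]:
    """Concentration tables for a named design.

    Oral schedules use the lagged Bateman curve, IV schedules a
    monoexponential bolus decay C = (D/V) exp(-k10 t); proportional
    log-normal residual error is applied and values below ``loq`` flagged.
    """
    if not cohort:
        raise InputError("cohort must be non-empty")
    if schedule not in SCHEDULES:
        raise InputError(f"unknown schedule {schedule!r}; options: {sorted(SCHEDULES)}")
    times = np.asarray(SCHEDULES[schedule])
    route = "iv" if schedule.startswith("iv") else "oral"
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p((residual_cv_conc / 100.0) ** 2))
    profiles = []
    for dog in cohort:
        if route == "oral":
            mean_c = oral_concentration(dog.oral_params, dose, times)
        else:
            c0 = dose * MG_TO_UG / dog.volume
            mean_c = c0 * np.exp(-dog.k10 * times)
        if residual_cv_conc > 0:
            noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=times.shape))
            c = mean_c * noise
        else:
            c = mean_c.copy()
        profiles.append(
            ConcentrationProfile(
                subject_id=dog.subject_id,
                route=route,
                dose=dose,
                times=tuple(times),
                concentrations=tuple(c),
                bql_flags=tuple(ci < loq for ci in c),
                loq=loq,
            )
        )
    return profiles


def healthy_baseline(endpoint: str, params: IndirectResponseParameters) -> float:
    """Pre-inflammation baseline consistent with the turnover model.

    Full drug effect returns the endpoint to its healthy value, so the
    healthy baseline is the saturated steady state of the model (0 for the
    lameness score).
    """
    kind = ENDPOINT_MODEL_KIND[endpoint]
    if kind is IndirectResponseModelKind.STIMULATE_KOUT:
        return params.kin / (params.kout * (1.0 + params.effect_cap))
    if kind is IndirectResponseModelKind.INHIBIT_KOUT:
        return params.kin / (params.kout * (1.0 - min(params.effect_cap, 0.999)))
    return 0.0


def generate_effect_data(
    cohort: Sequence[VirtualDog],
    endpoint: str,
    conc_profiles: Mapping[str, ConcentrationProfile] | None = None,
    schedule: str = "pd_study1",
    dose: float = 2.0,
    residual_sd_effect: float = 0.0,
    seed: int = 0,
) -> list[EffectTimeCourse]:
    """Effect tables simulated from each dog's own turnover parameters.

    The concentration input is the dog's noise-free oral curve at the dose
    of its profile (or ``dose`` when no profiles are given).  Baselines are
    emitted consistently with the model: T+ at the inflamed steady state
    kin/kout, T- at the healthy (saturated-effect) value.  Lameness values
    are rounded to integer scores and clipped to [0, 5].
    """
    if endpoint not in ENDPOINT_MODEL_KIND:
        raise InputError(
            f"endpoint {endpoint!r} has no turnover model; options: "
            f"{sorted(ENDPOINT_MODEL_KIND)}"
        )
    if schedule not in SCHEDULES:
        raise InputError(f"unknown schedule {schedule!r}")
    times = np.asarray(SCHEDULES[schedule])
    rng = np.random.default_rng(seed)
    kind = ENDPOINT_MODEL_KIND[endpoint]
    courses = []
    for dog in cohort:
        if endpoint not in dog.pd_params:
            raise InputError(f"{dog.subject_id} has no PD parameters for {endpoint!r}")
        p = dog.pd_params[endpoint]
        d = conc_profiles[dog.subject_id].dose if conc_profiles else dose
        pk = dog.oral_params
        conc_fn = lambda t, _pk=pk, _d=d: float(oral_concentration(_pk, _d, [t])[0])
        sim = simulate_turnover(kind, p, conc_fn, times)
        values = np.asarray(sim.response)
        if residual_sd_effect > 0:
            values = values + rng.normal(0.0, residual_sd_effect, size=values.shape)
        if endpoint == "lameness_score":
            values = np.clip(np.round(values), 0, 5)
        courses.append(
            EffectTimeCourse(
                subject_id=dog.subject_id,
                endpoint=endpoint,
                times=tuple(times),
                values=tuple(values),
                t_minus=healthy_baseline(endpoint, p),
                t_plus=p.baseline,
            )
        )
    return courses
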