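"""CSV readers/writers for the tabular interchange formats.

Concentration tables:
    ``subject_id,route,dose_mg_per_kg,time_h,conc_ug_per_L,bql``
Effect tables:
    ``subject_id,endpoint,time_h,value,t_minus,t_plus``

All files are header-first UTF-8 CSV with dot decimals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .effect_metrics import EffectTimeCourse
from .exceptions import InputError
from .pharmacokinetics import DEFAULT_LOQ, ConcentrationProfile

CONC_COLUMNS = ["subject_id", "route", "dose_mg_per_kg", "time_h", "conc_ug_per_L", "bql"]
EFFECT_COLUMNS = ["subject_id", "endpoint", "time_h", "value", "t_minus", "t_plus"]


def read_concentration_csv(path: str | Path, loq: float = DEFAULT_LOQ) -> list[ConcentrationProfile]:
    df = pd.read_csv(path)
    missing = set(CONC_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"concentration CSV missing columns: {sorted(missing)}")
    profiles = []
    for (sid, route), g in df.groupby(["subject_id", "route"], sort=False):
        g = g.sort_values("time_h")
        dose = g["dose_mg_per_kg"].iloc[0]
        profiles.append(
            ConcentrationProfile(
                subject_id=str(sid),
                route=str(route),
                dose=float(dose),
                times=tuple(g["time_h"].astype(float)),
                concentrations=tuple(g["conc_ug_per_L"].astype(float)),
                bql_flags=tuple(g["bql"].astype(bool)),
                loq=loq,
            )
        )
    return profiles


def write_concentration_csv(profiles: Iterable[ConcentrationProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concentrations, p.bql_flags):
            rows.append((p.subject_id, p.route, p.dose, t, c, bool(b)))
    pd.DataFrame(rows, columns=CONC_COLUMNS).to_csv(path, index=False)


def read_effect_csv(path: str | Path) -> list[EffectTimeCourse]:
    df = pd.read_csv(path)
    missing = set(EFFECT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"effect CSV missing columns: {sorted(missing)}")
    courses = []
    for (sid, ep), g in df.groupby(["subject_id", "endpoint"], sort=False):
        g = g.sort_values("time_h")
        courses.append(
            EffectTimeCourse(
                subject_id=str(sid),
                endpoint=str(ep),
                times=tuple(g["time_h"].astype(float)),
                values=tuple(g["value"].astype(float)),
                t_minus=float(g["t_minus"].iloc[0]),
                t_plus=float(g["t_plus"].iloc[0]),
            )
        )
    return courses


def write_effect_csv(courses: Iterable[EffectTimeCourse], path: str | Path) -> None:
    rows = []
    for c in courses:
        for t, v in zip(c.times, c.values):
            rows.append((c.subject_id, c.endpoint, t, v, c.t_minus, c.t_plus))
    pd.DataFrame(rows, columns=EFFECT_COLUMNS).to_csv(path, index=False)
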