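"""End-to-end study-1 analysis pipeline.

Stages: per-subject oral PK fit -> metabolizer classification -> per-group
IV NCA summaries -> per-endpoint sequential PK/PD fits -> dose-grid
simulation with the extensive-metabolizer means.  Every stage writes
tidy CSVs into the output directory and appends to a JSON run log.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dose_simulation import DEFAULT_DOSE_GRID, select_dose, simulate_dose_grid
from .effect_metrics import EffectTimeCourse
from .exceptions import InputError, PkpdError
from .indirect_response import ENDPOINT_MODEL_KIND, IndirectResponseParameters, fit_turnover
from .io import read_concentration_csv, read_effect_csv
from .pharmacokinetics import OralPKParameters, fit_oral_pk, nca_iv, oral_concentration
from .population_stats import classify_metabolizers, compare_subgroups
from .units import DEFAULT_MOLAR_MASS

__all__ = ["RunConfig", "StageError", "run_study1_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    conc_csv: str
    effect_csv: str
    out_dir: str
    iv_conc_csv: str | None = None
    dose: float = 2.0
    molar_mass: float = DEFAULT_MOLAR_MASS
    plateau_tolerance: float = 10.0
    effect_threshold: float = 10.0
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    seed: int = 0
    endpoints: tuple[str, ...] = tuple(sorted(ENDPOINT_MODEL_KIND))

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise InputError("molar_mass must be positive")


class StageError(PkpdError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _ci_rows(subject_id: str, group: str, cis: dict) -> list[dict]:
    return [
        {"subject_id": subject_id, "group": group, "parameter": name,
         "estimate": est, "ci_lower": lo, "ci_upper": hi}
        for name, (lo, est, hi) in cis.items()
    ]


def run_study1_pipeline(config: RunConfig) -> dict:
    """Run the full study-1 analysis; returns a report dict (also on disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {k: v for k, v in vars(config).items()},
                 "version": __version__, "stages": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-tagged with the stage name
                raise StageError(name, str(exc)) from exc
            log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            return result
        return wrap

    # --- fit-pk -----------------------------------------------------------
    def _fit_pk():
        profiles = [p for p in read_concentration_csv(config.conc_csv) if p.route == "oral"]
        if not profiles:
            raise InputError(f"no oral profiles in {config.conc_csv}")
        fits, rows = {}, []
        for p in profiles:
            params, diag = fit_oral_pk(p)
            fits[p.subject_id] = (p, params, diag)
            rows.append({
                "subject_id": p.subject_id, "v_over_f": params.v_over_f,
                "k01": params.k01, "k10": params.k10, "tlag": params.tlag,
                "terminal_halflife_h": params.terminal_halflife,
                "aic": diag.aic, "converged": diag.converged,
                "n_exponentials": diag.n_exponentials,
            })
        pd.DataFrame(rows).to_csv(out / "oral_pk_parameters.csv", index=False)
        return fits

    pk_fits = stage("fit-pk")(_fit_pk)

    # --- classify-metabolizers -------------------------------------------
    def _classify():
        hl = {sid: params.terminal_halflife for sid, (_, params, _) in pk_fits.items()}
        result = classify_metabolizers(hl)
        pd.DataFrame(
            [{"subject_id": a.subject_id, "label": a.label,
              "halflife_h": a.basis_halflife} for a in result.assignments]
        ).to_csv(out / "metabolizer_labels.csv", index=False)
        return result

    classification = stage("classify-metabolizers")(_classify)
    labels = {a.subject_id: a.label for a in classification.assignments}

    # --- nca (optional IV arm) -------------------------------------------
    def _nca():
        if config.iv_conc_csv is None:
            return None
        iv = [p for p in read_concentration_csv(config.iv_conc_csv) if p.route == "iv"]
        rows = []
        for p in iv:
            r = nca_iv(p)
            rows.append({
                "subject_id": p.subject_id, "group": labels.get(p.subject_id, "NA"),
                "auc_0_inf": r.auc_0_inf, "half_life_h": r.half_life,
                "clearance_L_h_kg": r.clearance, "v_z_L_kg": r.v_z,
                "lambda_z": r.lambda_z,
                "extrapolated_fraction": r.auc_extrapolated_fraction,
                "extrapolation_warning": r.extrapolation_warning,
            })
        df = pd.DataFrame(rows)
        df.to_csv(out / "nca_iv.csv", index=False)
        comp_rows = []
        for param in ("half_life_h", "clearance_L_h_kg"):
            groups = {g: df.loc[df.group == g, param].to_list() for g in ("EM", "PM")}
            if all(len(v) >= 2 for v in groups.values()):
                c = compare_subgroups(groups, param)
                comp_rows.append({
                    "parameter": param, "EM_mean": c.group_means[0],
                    "PM_mean": c.group_means[1], "p_value": c.p_value,
                    "fold_ratio": c.fold_ratio, "significant": c.significant,
                })
        if comp_rows:
            pd.DataFrame(comp_rows).to_csv(out / "subgroup_comparison.csv", index=False)
        return df

    stage("nca")(_nca)

    # --- fit-pkpd ---------------------------------------------------------
    def _fit_pkpd():
        courses = read_effect_csv(config.effect_csv)
        by_key: dict[tuple[str, str], EffectTimeCourse] = {
            (c.subject_id, c.endpoint): c for c in courses
        }
        rows, ci_rows, fitted = [], [], {}
        for (sid, endpoint), course in by_key.items():
            if endpoint not in config.endpoints or sid not in pk_fits:
                continue
            profile, pk_params, _ = pk_fits[sid]
            conc_fn = lambda t, _p=pk_params, _d=profile.dose: float(
                oral_concentration(_p, _d, [t])[0]
            )
            params, diag = fit_turnover(course, conc_fn, ENDPOINT_MODEL_KIND[endpoint])
            fitted[(sid, endpoint)] = params
            rows.append({
                "subject_id": sid, "group": labels.get(sid, "NA"), "endpoint": endpoint,
                "kin": params.kin, "kout": params.kout, "effect_cap": params.effect_cap,
                "c50": params.c50, "n": params.n, "baseline": params.baseline,
                "converged": diag.converged,
            })
            for r in _ci_rows(sid, labels.get(sid, "NA"), diag.parameter_cis):
                ci_rows.append({**r, "endpoint": endpoint})
        if not rows:
            raise InputError("no endpoint series matched fitted PK subjects")
        pd.DataFrame(rows).to_csv(out / "pd_parameters.csv", index=False)
        pd.DataFrame(ci_rows).to_csv(out / "pd_parameter_cis.csv", index=False)
        return pd.DataFrame(rows), fitted

    pd_table, _ = stage("fit-pkpd")(_fit_pkpd)

    # --- simulate-dose (EM means) ----------------------------------------
    def _dose():
        em = pd_table[pd_table.group == "EM"]
        if em.empty:
            em = pd_table  # no subgroup structure detected: use everyone
        em_pk = [pk_fits[s][1] for s in em.subject_id.unique() if s in pk_fits]
        pk_mean = OralPKParameters(
            v_over_f=float(np.mean([p.v_over_f for p in em_pk])),
            k01=float(np.mean([p.k01 for p in em_pk])),
            k10=float(np.mean([p.k10 for p in em_pk])),
            tlag=float(np.mean([p.tlag for p in em_pk])),
        )
        results, rows = {}, []
        for endpoint in sorted(em.endpoint.unique()):
            g = em[em.endpoint == endpoint]
            mean_pd = IndirectResponseParameters(
                kin=float(g.kin.mean()), kout=float(g.kout.mean()),
                effect_cap=float(g.effect_cap.mean()), c50=float(g.c50.mean()),
                n=min(float(g.n.mean()), 10.0),
            )
            res = simulate_dose_grid(
                pk_mean, mean_pd, ENDPOINT_MODEL_KIND[endpoint],
                doses=config.dose_grid, endpoint=endpoint,
            )
            results[endpoint] = res
            for dose, peak, dur in zip(res.doses, res.max_effect,
                                       res.duration_above_threshold):
                rows.append({"endpoint": endpoint, "dose_mg_per_kg": dose,
                             "max_effect": peak, "duration_h": dur})
        pd.DataFrame(rows).to_csv(out / "dose_grid_summary.csv", index=False)
        if len(results) >= 2:
            sel = select_dose(results)
            log["selected_dose_mg_per_kg"] = sel.selected_dose
            log["dose_selection_attained"] = sel.attained
        return results

    stage("simulate-dose")(_dose)

    log["n_subjects"] = len(pk_fits)
    log["n_em"] = sum(1 for v in labels.values() if v == "EM")
    log["n_pm"] = sum(1 for v in labels.values() if v == "PM")
    log["bimodal"] = classification.bimodal
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log
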