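"""End-to-end regimen simulation: in-vivo dosing, blood draw, in-vitro assay.

Per patient: individualize the network and PK for genotype and
variability, integrate 20 days of once-daily dosing to steady state, draw
plasma at trough (immediately before the dose of the draw day), and hand
the state to the PT or aPTT assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .assays import AssayConfig, calibrate_standard, run_aptt, run_pt
from .drug_effects import DrugCoupling, VKORC1_VK_FACTOR, apply_vkorc1
from .errors import CoagSimError, ConfigError, SolverError, ValidationError
from .network import (
    DEFAULT_SOLVER,
    NetworkModel,
    PlasmaState,
    SolverConfig,
    simulate,
    steady_state_init,
)
from .pk import DoseRegimen, PKParameters, apply_cyp2c9, make_concentration_fn
from .population import PopulationSpec, VirtualPatient, build_population

log = logging.getLogger("coagsim")

DEFAULT_ENDPOINT = {"warfarin": "INR", "rivaroxaban": "aPTT"}


@dataclass(frozen=True)
class ScenarioResult:
    patient_id: int
    drug: str
    dose_mg: float
    cyp2c9: str
    vkorc1: str
    endpoint: str  # "INR" or "aPTT"
    value: float | None
    censored: bool = False
    failed: bool = False


def individualize(
    patient: VirtualPatient,
    base_network: NetworkModel,
    base_pk: PKParameters | None,
    drug: str,
) -> tuple[NetworkModel, PKParameters | None]:
    """Apply genotype transforms and variability multipliers.

    Production-rate multipliers shift both the production and the baseline
    concentration of a factor, so each patient starts at their personal
    steady state.  The VKORC1 vitamin-K limitation is applied only for
    vitamin-K antagonists: it has no pathway to act through for
    rivaroxaban, and leaving the state untouched keeps rivaroxaban results
    exactly genotype-invariant.
    """
    net = base_network.copy()
    for sid, m in patient.production_multipliers.items():
        sp = net.get(sid)
        sp.baseline_conc *= m
        if sp.production_rate is not None:
            sp.production_rate *= m
    if drug == "warfarin" and net.drug_params is not None:
        g = VKORC1_VK_FACTOR[patient.genotype.vkorc1]
        for sid in (net.drug_params.vk_species, net.drug_params.vko_species):
            if sid in net.index:
                net.get(sid).baseline_conc *= g
    pk = base_pk
    if pk is not None:
        pk = apply_cyp2c9(pk, patient.genotype.cyp2c9)
        changes = {f: getattr(pk, f) * m for f, m in patient.pk_multipliers.items()}
        pk = replace(pk, **changes)
    return net, pk


def simulate_patient(
    patient: VirtualPatient,
    regimen: DoseRegimen,
    network: NetworkModel,
    pk: PKParameters | None = None,
    draw_day: float = 20.0,
    solver: SolverConfig = DEFAULT_SOLVER,
) -> PlasmaState:
    """In-vivo multi-dose simulation; returns the trough plasma state.

    The draw is at ``draw_day * 24`` hours, immediately before that day's
    dose (first dose at t = 0).
    """
    if regimen.duration_days < draw_day:
        raise ValidationError("regimen duration must cover the draw day")
    if pk is None:
        pk = network.pk_defaults.get(regimen.drug)
        if pk is None and regimen.dose_mg > 0:
            raise ConfigError(f"no PK defaults for {regimen.drug!r} in table")
    net, pk = individualize(patient, network, pk, regimen.drug)
    state0 = steady_state_init(net)
    coupling = None
    conc_fn = None
    if regimen.dose_mg > 0 and pk is not None:
        conc_fn = make_concentration_fn(pk, regimen)
        coupling = DrugCoupling(
            drug=regimen.drug, params=net.drug_params, conc_fn=conc_fn
        )
    t_draw = draw_day * 24.0
    try:
        traj = simulate(net, state0, t_draw, "in_vivo",
                        coupling=coupling, solver=solver)
    except SolverError as exc:
        raise SolverError(
            f"patient {patient.patient_id}: {exc}", last_time=exc.last_time
        ) from exc
    y = traj.final_state()
    conc = {s.id: float(y[i]) for i, s in enumerate(net.species)}
    return PlasmaState(
        table_version=net.version,
        time_of_draw_h=t_draw,
        concentrations=conc,
        drug=regimen.drug if regimen.dose_mg > 0 else None,
        drug_conc_nM=float(conc_fn(t_draw)) if conc_fn else 0.0,
    )


def run_scenario(
    spec: PopulationSpec,
    regimen: DoseRegimen,
    assay: AssayConfig,
    network: NetworkModel,
    pk: PKParameters | None = None,
    endpoint: str | None = None,
    draw_day: float = 20.0,
    progress: bool = False,
) -> list[ScenarioResult]:
    """Simulate one (drug, dose) scenario for a whole virtual population.

    Per-patient solver failures are flagged, not fatal.  Deterministic
    under a fixed spec seed.
    """
    endpoint = endpoint or DEFAULT_ENDPOINT[regimen.drug]
    if endpoint not in ("INR", "aPTT"):
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    if assay.pt_standard_s is None or assay.aptt_standard_s is None:
        calibrate_standard(network, assay)
    patients = build_population(spec, network, pk)
    iterator = patients
    if progress:
        from tqdm import tqdm

        iterator = tqdm(patients, desc=f"{regimen.drug} {regimen.dose_mg} mg")
    results: list[ScenarioResult] = []
    for patient in iterator:
        base = dict(
            patient_id=patient.patient_id,
            drug=regimen.drug,
            dose_mg=regimen.dose_mg,
            cyp2c9=patient.genotype.cyp2c9,
            vkorc1=patient.genotype.vkorc1,
            endpoint=endpoint,
        )
        try:
            plasma = simulate_patient(
                patient, regimen, network, pk=pk, draw_day=draw_day,
                solver=assay.solver,
            )
            if endpoint == "INR":
                res = run_pt(plasma, network, assay)
                value = res.inr
            else:
                res = run_aptt(plasma, network, assay)
                value = res.clot_time_s
            results.append(
                ScenarioResult(**base, value=value, censored=res.censored)
            )
        except CoagSimError as exc:
            log.warning("patient %s failed: %s", patient.patient_id, exc)
            results.append(
                ScenarioResult(**base, value=None, censored=True, failed=True)
            )
    return results


def results_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "drug": r.drug,
                "dose_mg": r.dose_mg,
                "cyp2c9": r.cyp2c9,
                "vkorc1": r.vkorc1,
                "endpoint": r.endpoint,
                "value": r.value,
                "censored": r.censored,
                "failed": r.failed,
            }
            for r in results
        ]
    )


def genotype_stratified_summary(results) -> pd.DataFrame:
    """Median and quartiles per (dose, CYP2C9, VKORC1) stratum.

    Accepts a list of ScenarioResult or an equivalent DataFrame; censored
    and failed rows are excluded.  Empty strata are omitted with a warning.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if df.empty:
        raise ValidationError("no results to summarize")
    ok = df[~df["censored"] & df["value"].notna()]
    dropped = len(df) - len(ok)
    if dropped:
        log.warning("summary omits %d censored/failed results", dropped)
    if ok.empty:
        raise ValidationError("all results censored or failed")
    g = ok.groupby(["drug", "dose_mg", "endpoint", "cyp2c9", "vkorc1"])["value"]
    out = g.agg(
        n="count",
        median="median",
        q1=lambda v: float(np.percentile(v, 25)),
        q3=lambda v: float(np.percentile(v, 75)),
    ).reset_index()
    return out
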