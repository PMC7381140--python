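"""In-silico PT/INR and aPTT clotting assays.

A plasma state drawn from the in-vivo simulation is challenged in a closed
test tube (in-vitro mode): PT adds tissue factor, aPTT starts from the
contact-activated XIa/XI split.  Clot time is the earliest time at which
the area under the fibrin concentration-time curve reaches the configured
threshold (default 1500 nM*s, equivalent to roughly a 30% fibrinogen
reduction in normal plasma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .drug_effects import DrugCoupling
from .errors import ConfigError, SchemaError, ValidationError
from .network import (
    DEFAULT_SOLVER,
    NetworkModel,
    PlasmaState,
    SolverConfig,
    simulate,
    steady_state_init,
)


@dataclass
class AssayConfig:
    """Settings of the in-vitro tests.

    ``pt_standard_s`` / ``aptt_standard_s`` are the clot times of normal
    standard plasma; they are computed once per parameter table by
    :func:`calibrate_standard` (or lazily on first use) and cached here.
    """

    tf_trigger: float = 300.0  # nM TF added for PT
    ca_trigger: float = 300.0  # nM contact activator for aPTT preincubation
    preincubation_s: float = 180.0
    clot_auc_threshold: float = 1500.0  # nM*s
    isi: float = 1.0
    pt_standard_s: float | None = None
    aptt_standard_s: float | None = None
    max_assay_s: float = 300.0
    xia_fraction: float = 0.148  # XIa(0) = fraction * XI(0)
    xi_fraction: float = 0.339  # XI(0)  = fraction * XI(0)
    solver: SolverConfig = DEFAULT_SOLVER

    def __post_init__(self):
        for name in ("tf_trigger", "ca_trigger", "preincubation_s",
                     "clot_auc_threshold", "isi", "max_assay_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"assay config: {name} must be > 0")


@dataclass(frozen=True)
class AssayResult:
    assay: str  # "PT" or "aPTT"
    clot_time_s: float | None
    censored: bool = False
    inr: float | None = None

    def __post_init__(self):
        if not self.censored and (self.clot_time_s is None or self.clot_time_s <= 0):
            raise ValidationError("uncensored result requires clot_time_s > 0")
        if self.censored and self.inr is not None:
            raise ValidationError("censored results carry no INR")
        if self.assay != "PT" and self.inr is not None:
            raise ValidationError("INR is defined for PT only")


def compute_inr(pt_test_s: float, pt_standard_s: float, isi: float = 1.0) -> float:
    """INR = (PT_test / PT_standard) ** ISI."""
    if pt_test_s <= 0 or pt_standard_s <= 0:
        raise ValidationError("clot times must be > 0")
    return (pt_test_s / pt_standard_s) ** isi


def detect_clot_time(
    fibrin,
    threshold: float,
    max_assay_s: float,
    grid_dt: float = 0.02,
    time_tol: float = 1e-3,
) -> float | None:
    """Earliest t with integral_0^t fibrin(u) du >= threshold, or None.

    ``fibrin`` is a vectorized callable time(s) -> concentration(nM).  The
    crossing is bracketed on a fine trapezoid grid and then located by
    bisection to ``time_tol`` seconds.  Returns None when the threshold is
    never reached before ``max_assay_s`` (censored).
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    t = np.arange(0.0, max_assay_s + grid_dt, grid_dt)
    t[-1] = min(t[-1], max_assay_s)
    f = np.asarray(fibrin(t), dtype=float)
    if f.min() < -1e-6:
        raise ValidationError(
            f"fibrin trajectory goes negative ({f.min():.3g} nM); cumulative "
            "integral would be non-monotone"
        )
    f = np.maximum(f, 0.0)
    seg = 0.5 * (f[1:] + f[:-1]) * np.diff(t)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    hits = np.nonzero(cum >= threshold)[0]
    if len(hits) == 0:
        return None
    i = hits[0]
    lo, hi = t[i - 1], t[i]
    base = cum[i - 1]

    def auc_from_lo(tt: float) -> float:
        tg = np.linspace(lo, tt, 33)
        fg = np.maximum(np.asarray(fibrin(tg), dtype=float), 0.0)
        return float(np.trapezoid(fg, tg))

    while hi - lo > time_tol:
        mid = 0.5 * (lo + hi)
        if base + auc_from_lo(mid) >= threshold:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _riva_coupling(plasma: PlasmaState, network: NetworkModel) -> DrugCoupling | None:
    if plasma.drug == "rivaroxaban" and plasma.drug_conc_nM > 0:
        if network.drug_params is None:
            raise ConfigError("rivaroxaban assay requires drug params in table")
        return DrugCoupling(
            drug="rivaroxaban", params=network.drug_params,
            conc_nM=plasma.drug_conc_nM,
        )
    return None


def _fibrin_id(network: NetworkModel) -> str:
    fid = network.drug_params.fibrin_species if network.drug_params else "Fbn"
    if fid not in network.index:
        raise SchemaError(f"fibrin species {fid!r} not in network")
    return fid


def run_pt(
    plasma: PlasmaState, network: NetworkModel, config: AssayConfig
) -> AssayResult:
    """Prothrombin-time test: add TF, simulate the closed tube, detect clot.

    Needs ``config.pt_standard_s``; when missing it is computed from the
    given network's normal plasma and cached on the config (pass the
    unmodified base network in that case, or call
    :func:`calibrate_standard` up front).
    """
    if config.pt_standard_s is None:
        calibrate_standard(network, config)
    y0 = plasma.vector(network)
    y0[network.index["TF"]] = config.tf_trigger
    traj = simulate(
        network, y0, config.max_assay_s, "in_vitro",
        coupling=_riva_coupling(plasma, network), solver=config.solver,
    )
    ct = detect_clot_time(
        traj.series(_fibrin_id(network)), config.clot_auc_threshold,
        config.max_assay_s,
    )
    if ct is None:
        return AssayResult(assay="PT", clot_time_s=None, censored=True)
    return AssayResult(
        assay="PT", clot_time_s=ct,
        inr=compute_inr(ct, config.pt_standard_s, config.isi),
    )


def aptt_shortcut_state(
    plasma: PlasmaState, network: NetworkModel, config: AssayConfig
) -> np.ndarray:
    """Initial assay state for the shortcut aPTT: the precomputed
    contact-activation split XIa <- 0.148*XI(0), XI <- 0.339*XI(0); all
    other drawn concentrations unchanged."""
    for sid in ("XI", "XIa"):
        if sid not in network.index:
            raise SchemaError(f"aPTT requires species {sid!r} in the network")
    y0 = plasma.vector(network)
    idx = network.index
    xi0 = y0[idx["XI"]]
    y0[idx["XIa"]] = config.xia_fraction * xi0
    y0[idx["XI"]] = config.xi_fraction * xi0
    return y0


def run_aptt(
    plasma: PlasmaState,
    network: NetworkModel,
    config: AssayConfig,
    mode: str = "shortcut",
) -> AssayResult:
    """aPTT test on a plasma sample.

    ``shortcut`` (default) applies the precomputed contact-activation
    split via :func:`aptt_shortcut_state` and simulates the tube;
    ``full_preincubation`` instead adds contact activator, simulates the
    3-minute preincubation, and clocks the clot from its end (validation
    aid only).
    """
    idx = network.index
    coupling = _riva_coupling(plasma, network)
    if mode == "shortcut":
        y0 = aptt_shortcut_state(plasma, network, config)
    elif mode == "full_preincubation":
        y0 = plasma.vector(network)
        if "CA" not in idx:
            raise SchemaError("full_preincubation requires species 'CA'")
        y0[idx["CA"]] = config.ca_trigger
        pre = simulate(
            network, y0, config.preincubation_s, "in_vitro",
            coupling=coupling, solver=config.solver,
        )
        y0 = pre.final_state()
    else:
        raise ValidationError(f"unknown aPTT mode {mode!r}")
    traj = simulate(
        network, y0, config.max_assay_s, "in_vitro",
        coupling=coupling, solver=config.solver,
    )
    ct = detect_clot_time(
        traj.series(_fibrin_id(network)), config.clot_auc_threshold,
        config.max_assay_s,
    )
    if ct is None:
        return AssayResult(assay="aPTT", clot_time_s=None, censored=True)
    return AssayResult(assay="aPTT", clot_time_s=ct)


def calibrate_standard(network: NetworkModel, config: AssayConfig) -> AssayConfig:
    """Compute and cache normal-plasma PT and aPTT for this table.

    Mutates ``config`` in place (fills ``pt_standard_s``,
    ``aptt_standard_s``) and returns it.  Raises ConfigError when normal
    plasma does not clot — the shipped table must clot.
    """
    standard = steady_state_init(network.copy())
    probe = replace_config(config, pt_standard_s=1.0)  # break recursion
    pt = run_pt(standard, network, probe)
    if pt.censored:
        raise ConfigError(
            "normal standard plasma does not clot in the PT assay; the "
            "parameter table is miscalibrated"
        )
    aptt = run_aptt(standard, network, probe)
    if aptt.censored:
        raise ConfigError(
            "normal standard plasma does not clot in the aPTT assay; the "
            "parameter table is miscalibrated"
        )
    config.pt_standard_s = pt.clot_time_s
    config.aptt_standard_s = aptt.clot_time_s
    return config


def replace_config(config: AssayConfig, **changes) -> AssayConfig:
    return replace(config, **changes)
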