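"""Drug pharmacokinetics: one-compartment oral dosing with superposition.

Warfarin clearance is genotype-adjustable (CYP2C9); phenprocoumon is
handled by linear dose conversion to warfarin equivalents.  Rivaroxaban PK
is genotype-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

DRUGS = ("warfarin", "rivaroxaban")

#: multiplicative clearance factors: *2 = 30% reduction, *3 = 80% reduction
CYP2C9_CL_FACTOR = {"*1": 1.0, "*2": 0.70, "*3": 0.20}

#: 3 mg phenprocoumon is equivalent to 5 mg warfarin
PHENPROCOUMON_TO_WARFARIN = 5.0 / 3.0


@dataclass(frozen=True)
class PKParameters:
    """One-compartment disposition constants for a drug."""

    drug: str
    cl: float  # clearance, L/h
    v: float  # volume of distribution, L
    f: float  # oral bioavailability (0-1]
    ka: float  # first-order absorption constant, 1/h
    mw: float  # molecular weight, g/mol

    def __post_init__(self):
        if self.drug not in DRUGS:
            raise ValidationError(f"unknown drug {self.drug!r}")
        if self.cl <= 0 or self.v <= 0 or self.ka <= 0 or self.mw <= 0:
            raise ValidationError("cl, v, ka, mw must be > 0")
        if not 0 < self.f <= 1:
            raise ValidationError("bioavailability f must be in (0, 1]")

    @property
    def ke(self) -> float:
        """Elimination rate constant, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseRegimen:
    """A fixed oral multi-dose schedule."""

    drug: str
    dose_mg: float
    interval_h: float = 24.0
    duration_days: float = 20.0
    route: str = "oral"

    def __post_init__(self):
        if self.dose_mg < 0:
            raise ValidationError("dose_mg must be >= 0")
        if self.interval_h <= 0:
            raise ValidationError("interval_h must be > 0")
        if self.duration_days <= 0:
            raise ValidationError("duration_days must be > 0")

    def dose_times_h(self) -> np.ndarray:
        """Administration times in hours, first dose at t = 0."""
        end = self.duration_days * 24.0
        n = int(np.ceil(end / self.interval_h))
        times = np.arange(n) * self.interval_h
        return times[times < end]


def apply_cyp2c9(pk: PKParameters, allele: str) -> PKParameters:
    """Adjust warfarin clearance for a CYP2C9 allele.

    *1 leaves clearance unchanged, *2 reduces it by 30%, *3 by 80%.
    Rivaroxaban is not metabolised by CYP2C9: identity transform.
    """
    if allele not in CYP2C9_CL_FACTOR:
        raise ValidationError(f"unknown CYP2C9 allele {allele!r}")
    if pk.drug != "warfarin":
        return pk
    return replace(pk, cl=pk.cl * CYP2C9_CL_FACTOR[allele])


def phenprocoumon_to_warfarin(dose_mg: float) -> float:
    """Warfarin-equivalent dose for a phenprocoumon dose (linear, 5/3)."""
    if dose_mg < 0:
        raise ValidationError("dose_mg must be >= 0")
    return dose_mg * PHENPROCOUMON_TO_WARFARIN


def mg_to_nmol(dose_mg: float, mw: float) -> float:
    return dose_mg * 1e6 / mw  # mg -> ug -> nmol via g/mol


def concentration_profile(
    pk: PKParameters, regimen: DoseRegimen, t
) -> np.ndarray | float:
    """Plasma concentration (nM) at time(s) ``t`` hours after first dose.

    Superposition of one-compartment first-order-absorption doses:
    ``C(t) = sum_i F*D*ka / (V*(ka-ke)) * (exp(-ke*dt_i) - exp(-ka*dt_i))``
    over doses with ``dt_i = t - tau_i >= 0``; the ka == ke degenerate case
    uses the limiting form ``F*D/V * ke*dt*exp(-ke*dt)``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr < 0).any():
        raise ValidationError("t must be >= 0")
    taus = regimen.dose_times_h()
    amount_nmol = mg_to_nmol(regimen.dose_mg, pk.mw)
    ke, ka = pk.ke, pk.ka
    dt = t_arr[:, None] - taus[None, :]
    active = dt >= 0
    dt = np.where(active, dt, 0.0)
    if np.isclose(ka, ke, rtol=1e-9):
        term = ke * dt * np.exp(-ke * dt)
        c = pk.f * amount_nmol / pk.v * np.where(active, term, 0.0).sum(axis=1)
    else:
        term = np.exp(-ke * dt) - np.exp(-ka * dt)
        coef = pk.f * amount_nmol * ka / (pk.v * (ka - ke))
        c = coef * np.where(active, term, 0.0).sum(axis=1)
    c = np.maximum(c, 0.0)
    return c if np.ndim(t) else float(c[0])


def make_concentration_fn(pk: PKParameters, regimen: DoseRegimen):
    """Closure ``t_hours -> nM`` (scalar in, scalar out) for ODE forcing."""
    taus = regimen.dose_times_h()
    amount_nmol = mg_to_nmol(regimen.dose_mg, pk.mw)
    ke, ka = pk.ke, pk.ka
    if regimen.dose_mg == 0 or len(taus) == 0:
        return lambda t: 0.0
    if np.isclose(ka, ke, rtol=1e-9):
        scale = pk.f * amount_nmol / pk.v

        def conc(t: float) -> float:
            dt = t - taus
            dt = dt[dt >= 0]
            return float(scale * np.sum(ke * dt * np.exp(-ke * dt)))

    else:
        coef = pk.f * amount_nmol * ka / (pk.v * (ka - ke))

        def conc(t: float) -> float:
            dt = t - taus
            dt = dt[dt >= 0]
            return max(float(coef * np.sum(np.exp(-ke * dt) - np.exp(-ka * dt))), 0.0)

    return conc
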