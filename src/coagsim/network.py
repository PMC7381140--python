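"""Coagulation reaction network: data model, TSV loading, ODE compilation.

The network is defined entirely in data (a delimited parameter table); this
module compiles it into a right-hand-side function for a stiff ODE solver.

Two time bases are used:

* ``in_vivo``  — time in **hours**; zero-order production and first-order
  degradation are active and drug pharmacokinetics may force the system.
* ``in_vitro`` — time in **seconds**; a closed test tube: production is
  zeroed, degradation is retained (factors are consumed, not synthesised).

Reaction rate constants are stored on the seconds base and converted with
1 h = 3600 s.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import SchemaError, SolverError, ValidationError

HOURS_TO_SECONDS = 3600.0

ROLES = frozenset(
    {"zymogen", "active", "complex", "cofactor", "vitamin", "drug", "fibrin-related"}
)
REACTION_KINDS = frozenset({"mm_activation", "complex_formation", "first_order"})

#: roles whose members must start at zero concentration
_ZERO_AT_INIT_ROLES = frozenset({"active", "complex"})

#: reporting tolerance for negative concentrations (nM)
TOL_NEG = 1e-9
#: hard-error threshold for negative concentrations (nM)
HARD_NEG = -1e-6


@dataclass
class Species:
    """One chemical species (compartment) of the network.

    ``production_rate`` is the zero-order in-vivo synthesis rate in nM/h.
    When ``None`` it is derived from the steady-state turnover relation
    ``production = kdeg * baseline_conc``.
    """

    id: str
    role: str
    baseline_conc: float = 0.0  # nM
    kdeg: float = 0.0  # 1/h
    production_rate: float | None = None  # nM/h
    vk_dependent: bool = False

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("species id must be non-empty")
        if self.role not in ROLES:
            raise ValidationError(f"species {self.id!r}: unknown role {self.role!r}")
        if self.baseline_conc < 0:
            raise ValidationError(f"species {self.id!r}: baseline_conc < 0")
        if self.kdeg < 0:
            raise ValidationError(f"species {self.id!r}: kdeg < 0")
        if self.production_rate is not None and self.production_rate < 0:
            raise ValidationError(f"species {self.id!r}: production_rate < 0")
        if self.role in _ZERO_AT_INIT_ROLES and self.baseline_conc != 0:
            raise ValidationError(
                f"species {self.id!r}: role {self.role!r} requires baseline_conc = 0"
            )


@dataclass
class Reaction:
    """One reaction.  Rate constants are on the seconds time base.

    * ``mm_activation``: catalyst converts substrate to product with rate
      ``kcat*[catalyst]*[S]/(km+[S])`` (nM/s).
    * ``complex_formation``: two substrates combine 1:1 into the product
      with rate ``k*[A]*[B]`` (k in 1/(nM*s)); both substrates are removed.
    * ``first_order``: substrate converts to product with rate ``k*[S]``
      (k in 1/s).
    """

    kind: str
    substrates: tuple[str, ...]
    product: str
    catalyst: str | None = None
    kcat: float = 0.0  # 1/s
    km: float | None = None  # nM
    k: float | None = None  # 1/(nM*s) or 1/s

    def validate(self, species_ids: frozenset[str]) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValidationError(f"unknown reaction kind {self.kind!r}")
        refs = list(self.substrates) + [self.product]
        if self.catalyst is not None:
            refs.append(self.catalyst)
        for ref in refs:
            if ref not in species_ids:
                raise SchemaError(
                    f"reaction references undeclared species {ref!r} "
                    f"({self.kind} -> {self.product})"
                )
        if self.kind == "mm_activation":
            if self.catalyst is None:
                raise ValidationError("mm_activation requires a catalyst")
            if len(self.substrates) != 1:
                raise ValidationError("mm_activation requires exactly one substrate")
            if self.kcat < 0:
                raise ValidationError("mm_activation: kcat < 0")
            if self.km is None or self.km <= 0:
                raise ValidationError("mm_activation: km must be > 0")
        elif self.kind == "complex_formation":
            if len(self.substrates) != 2:
                raise ValidationError(
                    "complex_formation requires exactly two substrates"
                )
            if self.k is None or self.k < 0:
                raise ValidationError("complex_formation: k must be >= 0")
        else:  # first_order
            if len(self.substrates) != 1:
                raise ValidationError("first_order requires exactly one substrate")
            if self.k is None or self.k < 0:
                raise ValidationError("first_order: k must be >= 0")


@dataclass
class PlasmaState:
    """Concentrations of every network species at a blood draw (nM).

    The handoff object between the in-vivo dosing simulation and the
    in-vitro clotting assays.  Drug concentration rides along separately:
    the drugs are forced algebraically, not integrated as network species.
    """

    table_version: str
    time_of_draw_h: float
    concentrations: dict[str, float]
    drug: str | None = None
    drug_conc_nM: float = 0.0

    def vector(self, network: "NetworkModel") -> np.ndarray:
        missing = [s.id for s in network.species if s.id not in self.concentrations]
        if missing:
            raise ValidationError(f"plasma state missing species: {missing}")
        return np.array(
            [self.concentrations[s.id] for s in network.species], dtype=float
        )


class NetworkModel:
    """Species + reactions defining the coagulation cascade ODE system."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        version: str = "unversioned",
        drug_params=None,
        pk_defaults: dict | None = None,
    ):
        self.species = list(species)
        self.reactions = list(reactions)
        self.version = version
        self.drug_params = drug_params  # DrugActionParams or None
        self.pk_defaults = pk_defaults or {}
        self.validate()

    # -- basic API ---------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get(self, species_id: str) -> Species:
        for s in self.species:
            if s.id == species_id:
                return s
        raise KeyError(species_id)

    def validate(self) -> None:
        ids = [s.id for s in self.species]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate species ids: {sorted(dup)}")
        for s in self.species:
            s.validate()
        id_set = frozenset(ids)
        for r in self.reactions:
            r.validate(id_set)

    def copy(self) -> "NetworkModel":
        net = NetworkModel.__new__(NetworkModel)
        net.species = [replace(s) for s in self.species]
        net.reactions = [replace(r) for r in self.reactions]
        net.version = self.version
        net.drug_params = self.drug_params
        net.pk_defaults = dict(self.pk_defaults)
        return net

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        write_network(self, path)


_NA = "."


def _fmt(x) -> str:
    if x is None:
        return _NA
    return repr(float(x))


def _parse_float(tok: str, what: str, row: int) -> float | None:
    if tok == _NA:
        return None
    try:
        return float(tok)
    except ValueError:
        raise SchemaError(f"row {row}: cannot parse {what} value {tok!r}") from None


def write_network(network: NetworkModel, path: str | Path) -> None:
    """Serialize a NetworkModel to the TSV table format (round-trippable)."""
    lines = ["# coagsim parameter table", f"version\t{network.version}"]
    for s in network.species:
        lines.append(
            "\t".join(
                [
                    "species",
                    s.id,
                    s.role,
                    _fmt(s.baseline_conc),
                    _fmt(s.kdeg),
                    "1" if s.vk_dependent else "0",
                ]
            )
        )
    for r in network.reactions:
        sub_a = r.substrates[0]
        sub_b = r.substrates[1] if len(r.substrates) > 1 else None
        lines.append(
            "\t".join(
                [
                    "reaction",
                    r.kind,
                    r.catalyst or _NA,
                    sub_a,
                    sub_b or _NA,
                    r.product,
                    _fmt(r.kcat),
                    _fmt(r.km),
                    _fmt(r.k),
                ]
            )
        )
    if network.drug_params is not None:
        for name, value in network.drug_params.as_table_rows():
            lines.append(f"param\t{name}\t{value}")
    for drug, pk in network.pk_defaults.items():
        lines.append(
            "\t".join(
                ["pk", drug]
                + [_fmt(v) for v in (pk.cl, pk.v, pk.f, pk.ka, pk.mw)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_network(path: str | Path) -> NetworkModel:
    """Load and validate a network from a TSV parameter table.

    Table rows (tab-separated, ``#`` comments, ``.`` for not-applicable):

    * ``version <id>``
    * ``species <id> <role> <baseline_nM> <kdeg_per_h> <vk_dep 0|1>``
    * ``reaction <kind> <catalyst> <substrate_a> <substrate_b> <product>
      <kcat_per_s> <km_nM> <k>``
    * ``param <name> <value>``       (drug-action / PD parameters)
    * ``pk <drug> <cl_L_per_h> <v_L> <f> <ka_per_h> <mw_g_per_mol>``
    """
    from .drug_effects import DrugActionParams
    from .pk import PKParameters

    path = Path(path)
    if not path.exists():
        raise SchemaError(f"parameter table not found: {path}")
    version = "unversioned"
    species: list[Species] = []
    reactions: list[Reaction] = []
    params: dict[str, str] = {}
    pk_defaults: dict[str, PKParameters] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split("\t")
        kind = toks[0]
        if kind == "version":
            version = toks[1]
        elif kind == "species":
            if len(toks) != 6:
                raise SchemaError(f"row {lineno}: species row needs 6 fields")
            species.append(
                Species(
                    id=toks[1],
                    role=toks[2],
                    baseline_conc=_parse_float(toks[3], "baseline_nM", lineno) or 0.0,
                    kdeg=_parse_float(toks[4], "kdeg_per_h", lineno) or 0.0,
                    vk_dependent=toks[5] == "1",
                )
            )
        elif kind == "reaction":
            if len(toks) != 9:
                raise SchemaError(f"row {lineno}: reaction row needs 9 fields")
            subs = tuple(t for t in (toks[3], toks[4]) if t != _NA)
            reactions.append(
                Reaction(
                    kind=toks[1],
                    catalyst=None if toks[2] == _NA else toks[2],
                    substrates=subs,
                    product=toks[5],
                    kcat=_parse_float(toks[6], "kcat_per_s", lineno) or 0.0,
                    km=_parse_float(toks[7], "km_nM", lineno),
                    k=_parse_float(toks[8], "k", lineno),
                )
            )
        elif kind == "param":
            if len(toks) != 3:
                raise SchemaError(f"row {lineno}: param row needs 3 fields")
            params[toks[1]] = toks[2]
        elif kind == "pk":
            if len(toks) != 7:
                raise SchemaError(f"row {lineno}: pk row needs 7 fields")
            pk_defaults[toks[1]] = PKParameters(
                drug=toks[1],
                cl=float(toks[2]),
                v=float(toks[3]),
                f=float(toks[4]),
                ka=float(toks[5]),
                mw=float(toks[6]),
            )
        else:
            raise SchemaError(f"row {lineno}: unknown record type {kind!r}")
    drug_params = DrugActionParams.from_table_params(params) if params else None
    try:
        return NetworkModel(
            species, reactions, version=version,
            drug_params=drug_params, pk_defaults=pk_defaults,
        )
    except (SchemaError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def default_network() -> NetworkModel:
    """Load the versioned parameter table shipped with the package."""
    ref = importlib.resources.files("coagsim") / "data" / "default_network.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_network(p)


# ---------------------------------------------------------------------------
# ODE compilation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverConfig:
    """Stiff-solver settings; dense output is always on."""

    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-9  # nM
    max_step: float = np.inf


DEFAULT_SOLVER = SolverConfig()


def build_rhs(
    network: NetworkModel,
    mode: str,
    coupling=None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the network into a derivative function ``f(t, y) -> dy``.

    ``mode``:
      * ``"in_vivo"``  — time in hours; production on; drug forcing via
        ``coupling`` (a :class:`~coagsim.drug_effects.DrugCoupling`).
      * ``"in_vitro"`` — time in seconds; production off; a rivaroxaban
        coupling (constant concentration) scales Xa-catalysed kcats.

    When the network declares VK-dependent species and its drug parameters
    name a vitamin K species, the in-vivo production of those species is
    scaled by the saturable availability factor
    ``phi(VK)/phi(VK_baseline)`` with ``phi(v) = v/(vk_km+v)``, so the
    drug-free baseline is an exact fixed point.
    """
    if mode not in ("in_vivo", "in_vitro"):
        raise ValidationError(f"unknown mode {mode!r}")
    in_vivo = mode == "in_vivo"
    n = len(network.species)
    idx = network.index

    production = np.array(
        [
            s.production_rate
            if s.production_rate is not None
            else s.kdeg * s.baseline_conc
            for s in network.species
        ]
    )
    kdeg = np.array([s.kdeg for s in network.species])

    mm = [r for r in network.reactions if r.kind == "mm_activation"]
    cx = [r for r in network.reactions if r.kind == "complex_formation"]
    fo = [r for r in network.reactions if r.kind == "first_order"]

    mm_cat = np.array([idx[r.catalyst] for r in mm], dtype=int)
    mm_sub = np.array([idx[r.substrates[0]] for r in mm], dtype=int)
    mm_prod = np.array([idx[r.product] for r in mm], dtype=int)
    mm_kcat = np.array([r.kcat for r in mm])
    mm_km = np.array([r.km for r in mm])

    cx_a = np.array([idx[r.substrates[0]] for r in cx], dtype=int)
    cx_b = np.array([idx[r.substrates[1]] for r in cx], dtype=int)
    cx_p = np.array([idx[r.product] for r in cx], dtype=int)
    cx_k = np.array([r.k for r in cx])

    fo_s = np.array([idx[r.substrates[0]] for r in fo], dtype=int)
    fo_p = np.array([idx[r.product] for r in fo], dtype=int)
    fo_k = np.array([r.k for r in fo])

    # time-base scaling: reaction constants are per second
    rxn_scale = HOURS_TO_SECONDS if in_vivo else 1.0
    deg = kdeg if in_vivo else kdeg / HOURS_TO_SECONDS

    dp = network.drug_params

    # rivaroxaban: scale every Xa-catalysed kcat
    riva_mask = np.zeros(len(mm), dtype=bool)
    riva_conc_fn = None
    if coupling is not None and coupling.drug == "rivaroxaban":
        targets = set(dp.xa_catalysts) if dp else {"Xa", "Xa_Va"}
        riva_mask = np.array([r.catalyst in targets for r in mm], dtype=bool)
        riva_conc_fn = coupling.concentration
        ki = coupling.params.rivaroxaban_ki

    # warfarin: scale the VK-epoxide -> VK regeneration rate
    warf_mask = np.zeros(len(fo), dtype=bool)
    warf_conc_fn = None
    if coupling is not None and coupling.drug == "warfarin":
        if dp is None:
            raise ValidationError("warfarin coupling requires drug params in table")
        warf_mask = np.array(
            [
                r.substrates[0] == dp.vko_species and r.product == dp.vk_species
                for r in fo
            ],
            dtype=bool,
        )
        if not warf_mask.any():
            raise SchemaError(
                f"no {dp.vko_species}->{dp.vk_species} regeneration reaction in table"
            )
        warf_conc_fn = coupling.concentration
        imax, ic50 = coupling.params.warfarin_imax, coupling.params.warfarin_ic50

    # vitamin-K-limited production of VK-dependent factors (in vivo only)
    vk_dep = np.array([s.vk_dependent for s in network.species], dtype=bool)
    vk_enabled = (
        in_vivo and vk_dep.any() and dp is not None and dp.vk_species in idx
    )
    if vk_enabled:
        vk_idx = idx[dp.vk_species]
        vk_km = dp.vk_km
        vk_ref = network.get(dp.vk_species).baseline_conc
        if vk_ref <= 0:
            raise ValidationError("VK baseline must be > 0 for VK-dependent coupling")
        phi_ref = vk_ref / (vk_km + vk_ref)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if y.shape != (n,):
            raise ValidationError(
                f"state vector length {y.shape} does not match network size {n}"
            )
        c = np.maximum(y, 0.0)
        dy = np.zeros(n)
        if len(mm):
            kcat = mm_kcat
            if riva_conc_fn is not None:
                kcat = kcat.copy()
                kcat[riva_mask] *= 1.0 / (1.0 + riva_conc_fn(t) / ki)
            r = rxn_scale * kcat * c[mm_cat] * c[mm_sub] / (mm_km + c[mm_sub])
            np.add.at(dy, mm_prod, r)
            np.subtract.at(dy, mm_sub, r)
        if len(cx):
            r = rxn_scale * cx_k * c[cx_a] * c[cx_b]
            np.add.at(dy, cx_p, r)
            np.subtract.at(dy, cx_a, r)
            np.subtract.at(dy, cx_b, r)
        if len(fo):
            k = fo_k
            if warf_conc_fn is not None:
                k = k.copy()
                cw = warf_conc_fn(t)
                k[warf_mask] *= 1.0 - imax * cw / (ic50 + cw)
            r = rxn_scale * k * c[fo_s]
            np.add.at(dy, fo_p, r)
            np.subtract.at(dy, fo_s, r)
        if in_vivo:
            p = production
            if vk_enabled:
                vk = c[vk_idx]
                psi = (vk / (vk_km + vk)) / phi_ref
                p = np.where(vk_dep, production * psi, production)
            dy += p - deg * c
        else:
            dy -= deg * c
        return dy

    return rhs


def steady_state_init(network: NetworkModel) -> PlasmaState:
    """Initialize the network at its drug-free, non-clotting steady state.

    Enforces ``production_rate = kdeg * baseline_conc`` on every species
    (mutating the network's derived production rates) and returns a plasma
    state with zymogens/cofactors at baseline and every active species and
    complex at zero.
    """
    for s in network.species:
        if s.kdeg == 0 and (s.production_rate or 0) > 0:
            raise ValidationError(
                f"species {s.id!r}: production > 0 with kdeg = 0 has no "
                "finite steady state"
            )
        s.production_rate = s.kdeg * s.baseline_conc
    conc = {s.id: (0.0 if s.role in _ZERO_AT_INIT_ROLES else s.baseline_conc)
            for s in network.species}
    return PlasmaState(
        table_version=network.version, time_of_draw_h=0.0, concentrations=conc
    )


class Trajectory:
    """Dense ODE solution over a network; interpolates at arbitrary times.

    Reported concentrations are clamped to zero within ``TOL_NEG``;
    excursions below ``HARD_NEG`` raise at construction (solver
    misconfiguration).
    """

    def __init__(self, network: NetworkModel, sol, t0: float, t1: float, mode: str):
        self.network = network
        self._sol = sol
        self.t0 = t0
        self.t1 = t1
        self.mode = mode
        self._index = network.index
        check = self.states(np.linspace(t0, t1, 512), clamp=False)
        worst = check.min()
        if worst < HARD_NEG:
            raise SolverError(
                f"concentration fell to {worst:.3g} nM (below {HARD_NEG} nM); "
                "solver tolerances are misconfigured",
                last_time=t1,
            )

    def states(self, t, clamp: bool = True) -> np.ndarray:
        """State matrix at times ``t`` (shape: n_species x n_times)."""
        y = self._sol(np.atleast_1d(np.asarray(t, dtype=float)))
        return np.maximum(y, 0.0) if clamp else y

    def at(self, t: float) -> np.ndarray:
        return self.states(t)[:, 0]

    def series(self, species_id: str) -> Callable[[np.ndarray], np.ndarray]:
        """Vectorized time -> concentration function for one species."""
        i = self._index[species_id]
        return lambda t: self.states(t)[i]

    def value(self, species_id: str, t: float) -> float:
        return float(self.series(species_id)(t)[0])

    def final_state(self) -> np.ndarray:
        return self.at(self.t1)

    def to_frame(self, times: Iterable[float]):
        """Tidy export: columns (time, species, concentration_nM)."""
        import pandas as pd

        times = np.asarray(list(times), dtype=float)
        y = self.states(times)
        rows = []
        for i, s in enumerate(self.network.species):
            for j, t in enumerate(times):
                rows.append((t, s.id, y[i, j]))
        return pd.DataFrame(rows, columns=["time", "species", "concentration_nM"])


def simulate(
    network: NetworkModel,
    state0,
    duration: float,
    mode: str,
    coupling=None,
    solver: SolverConfig = DEFAULT_SOLVER,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate the network ODEs and return a dense trajectory.

    ``state0`` may be a :class:`PlasmaState` or a raw state vector aligned
    with ``network.species``; ``duration`` is in the mode's time base
    (hours in vivo, seconds in vitro).
    """
    if isinstance(state0, PlasmaState):
        y0 = state0.vector(network)
    else:
        y0 = np.asarray(state0, dtype=float)
        if y0.shape != (len(network.species),):
            raise ValidationError(
                f"state vector length {y0.shape[0]} does not match network "
                f"size {len(network.species)}"
            )
    if (y0 < 0).any():
        raise ValidationError("initial state has negative concentrations")
    rhs = build_rhs(network, mode, coupling=coupling)
    res = solve_ivp(
        rhs,
        (t0, t0 + duration),
        y0,
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
        dense_output=True,
    )
    if not res.success:
        last = float(res.t[-1]) if len(res.t) else t0
        raise SolverError(f"ODE solver failed: {res.message}", last_time=last)
    return Trajectory(network, res.sol, t0, t0 + duration, mode)
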