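"""coag_network: loading, validation, RHS semantics, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coagsim import (
    NetworkModel,
    PlasmaState,
    Reaction,
    SchemaError,
    SolverConfig,
    Species,
    ValidationError,
    build_rhs,
    load_network,
    simulate,
    steady_state_init,
    write_network,
)
from conftest import make_complex_toy, make_decay_toy, make_mm_toy

# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------

TOY_TABLE = """# toy table
version\ttoy-0
species\tE\tzymogen\t5.0\t0.0\t0
species\tS\tzymogen\t50.0\t0.0\t0
species\tP\tactive\t0.0\t0.0\t0
reaction\tmm_activation\tE\tS\t.\tP\t2.0\t50.0\t.
"""


def test_load_default_table_covers_cascade(default_net):
    assert len(default_net.species) >= 30
    ids = set(default_net.ids)
    # extrinsic, intrinsic, common pathway, vitamin K cycle, PC/PS
    required = {
        "TF", "CA", "II", "V", "VII", "VIII", "IX", "X", "XI", "XII",
        "XIII", "PC", "PS", "Fg", "Fbn", "VK", "VKO",
    }
    assert required <= ids
    assert default_net.drug_params is not None
    assert {"warfarin", "rivaroxaban"} <= set(default_net.pk_defaults)


def test_load_toy_table(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(TOY_TABLE)
    net = load_network(p)
    assert len(net.species) == 3
    assert len(net.reactions) == 1
    assert net.version == "toy-0"


def test_undeclared_species_is_schema_error(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(TOY_TABLE.replace("\tS\t.\tP\t", "\tXQ\t.\tP\t"))
    with pytest.raises(SchemaError, match="XQ"):
        load_network(p)


def test_negative_rate_is_validation_error(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(TOY_TABLE.replace("\t2.0\t50.0\t.", "\t-2.0\t50.0\t."))
    with pytest.raises(ValidationError):
        load_network(p)


def test_duplicate_species_id_is_error(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(TOY_TABLE + "species\tE\tzymogen\t5.0\t0.0\t0\n")
    with pytest.raises(ValidationError, match="duplicate"):
        load_network(p)


def test_missing_table_is_schema_error(tmp_path):
    with pytest.raises(SchemaError):
        load_network(tmp_path / "nope.tsv")


def test_active_species_with_nonzero_baseline_rejected():
    with pytest.raises(ValidationError):
        NetworkModel([Species("Xa", "active", baseline_conc=1.0)], [])


def test_complex_formation_needs_two_substrates():
    sp = [Species("A", "zymogen", 1.0), Species("C", "complex")]
    with pytest.raises(ValidationError):
        NetworkModel(sp, [Reaction("complex_formation", ("A",), "C", k=1.0)])


def test_roundtrip_identity(default_net, tmp_path):
    p = tmp_path / "rt.tsv"
    write_network(default_net, p)
    net2 = load_network(p)
    assert net2.version == default_net.version
    assert [s.__dict__ for s in net2.species] == [
        s.__dict__ for s in default_net.species
    ]
    assert [r.__dict__ for r in net2.reactions] == [
        r.__dict__ for r in default_net.reactions
    ]
    assert net2.drug_params == default_net.drug_params
    assert net2.pk_defaults == default_net.pk_defaults
    # second round trip is byte-identical
    p2 = tmp_path / "rt2.tsv"
    write_network(net2, p2)
    assert p.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# RHS semantics (rates on the rate vector, not trajectories)
# ---------------------------------------------------------------------------


def test_rhs_mm_activation_rate(mm_toy):
    # kcat=2/s, [E]=5, [S]=50, km=50 -> 2*5*50/(50+50) = 5 nM/s
    rhs = build_rhs(mm_toy, "in_vitro")
    dy = rhs(0.0, np.array([5.0, 50.0, 0.0]))
    assert dy[1] == pytest.approx(-5.0)
    assert dy[2] == pytest.approx(5.0)
    assert dy[0] == 0.0  # catalyst is not consumed


def test_rhs_complex_formation_rate():
    net = make_complex_toy(k=0.1)
    rhs = build_rhs(net, "in_vitro")
    dy = rhs(0.0, np.array([2.0, 3.0, 0.0]))
    assert dy[2] == pytest.approx(0.6)
    assert dy[0] == pytest.approx(-0.6)
    assert dy[1] == pytest.approx(-0.6)


def test_rhs_mass_action_consistency():
    # d[complex] contribution == -d[A] == -d[B], exactly
    net = make_complex_toy(k=0.037)
    rhs = build_rhs(net, "in_vitro")
    dy = rhs(0.0, np.array([1.7, 4.2, 0.0]))
    assert dy[2] == -dy[0]
    assert dy[2] == -dy[1]


def test_rhs_turnover_balance():
    net = NetworkModel(
        [Species("A", "zymogen", baseline_conc=100.0, kdeg=0.01,
                 production_rate=1.0)],
        [],
    )
    rhs = build_rhs(net, "in_vivo")
    assert rhs(0.0, np.array([100.0])) == pytest.approx(0.0)


def test_rhs_state_length_mismatch(mm_toy):
    rhs = build_rhs(mm_toy, "in_vitro")
    with pytest.raises(ValidationError, match="length"):
        rhs(0.0, np.zeros(5))


def test_rhs_unknown_mode(mm_toy):
    with pytest.raises(ValidationError):
        build_rhs(mm_toy, "ex_vivo")


@settings(max_examples=40, deadline=None)
@given(data=st.data())
def test_rhs_matches_bruteforce_oracle(data):
    """build_rhs equals a naive per-reaction loop on random networks."""
    n = data.draw(st.integers(3, 6))
    ids = [f"s{i}" for i in range(n)]
    pos = st.floats(0.01, 50.0, allow_nan=False)
    species = [
        Species(
            sid, "zymogen",
            baseline_conc=data.draw(pos),
            kdeg=data.draw(st.floats(0.0, 2.0)),
            production_rate=data.draw(st.floats(0.0, 5.0)),
        )
        for sid in ids
    ]
    n_rxn = data.draw(st.integers(1, 5))
    reactions = []
    for _ in range(n_rxn):
        kind = data.draw(st.sampled_from(sorted(
            ["mm_activation", "complex_formation", "first_order"])))
        if kind == "mm_activation":
            cat, sub, prod = (data.draw(st.sampled_from(ids)) for _ in range(3))
            reactions.append(Reaction(kind, (sub,), prod, catalyst=cat,
                                      kcat=data.draw(pos), km=data.draw(pos)))
        elif kind == "complex_formation":
            a, b, prod = (data.draw(st.sampled_from(ids)) for _ in range(3))
            reactions.append(Reaction(kind, (a, b), prod, k=data.draw(pos)))
        else:
            sub, prod = (data.draw(st.sampled_from(ids)) for _ in range(2))
            reactions.append(Reaction(kind, (sub,), prod, k=data.draw(pos)))
    net = NetworkModel(species, reactions)
    y = np.array([data.draw(pos) for _ in ids])
    mode = data.draw(st.sampled_from(["in_vivo", "in_vitro"]))

    # independent oracle: dict-based per-reaction accumulation
    expect = {}
    tsc = 3600.0 if mode == "in_vivo" else 1.0
    conc = dict(zip(ids, y))
    for s in species:
        if mode == "in_vivo":
            expect[s.id] = s.production_rate - s.kdeg * conc[s.id]
        else:
            expect[s.id] = -s.kdeg / 3600.0 * conc[s.id]
    for r in reactions:
        if r.kind == "mm_activation":
            rate = (r.kcat * conc[r.catalyst] * conc[r.substrates[0]]
                    / (r.km + conc[r.substrates[0]]))
        elif r.kind == "complex_formation":
            rate = r.k * conc[r.substrates[0]] * conc[r.substrates[1]]
        else:
            rate = r.k * conc[r.substrates[0]]
        rate *= tsc
        for sub in r.substrates:
            expect[sub] -= rate
        expect[r.product] += rate

    got = build_rhs(net, mode)(0.0, y)
    # accumulation order differs between the vectorized RHS and the loop,
    # so allow float summation noise
    np.testing.assert_allclose(got, [expect[i] for i in ids], rtol=1e-9,
                               atol=1e-9)


# ---------------------------------------------------------------------------
# steady-state initialization
# ---------------------------------------------------------------------------


def test_steady_state_sets_production():
    net = NetworkModel([Species("F", "zymogen", baseline_conc=80.0, kdeg=0.05)], [])
    steady_state_init(net)
    assert net.get("F").production_rate == pytest.approx(4.0)


def test_steady_state_active_species_zero(default_net):
    state = steady_state_init(default_net.copy())
    for s in default_net.species:
        if s.role in ("active", "complex"):
            assert state.concentrations[s.id] == 0.0


def test_steady_state_no_finite_fixed_point():
    net = NetworkModel(
        [Species("F", "zymogen", baseline_conc=1.0, kdeg=0.0,
                 production_rate=2.0)],
        [],
    )
    with pytest.raises(ValidationError, match="steady state"):
        steady_state_init(net)


def test_steady_state_is_rhs_fixed_point(default_net):
    """Drug-free in-vivo rate vector vanishes at the initial state."""
    net = default_net.copy()
    state = steady_state_init(net)
    rhs = build_rhs(net, "in_vivo")
    rates = rhs(0.0, state.vector(net))
    assert np.max(np.abs(rates)) < 1e-9  # nM/h


def test_drug_free_drift_480h(default_net):
    """20 days of drug-free in-vivo integration stays within 0.1%."""
    net = default_net.copy()
    state = steady_state_init(net)
    traj = simulate(net, state, 480.0, "in_vivo")
    y0 = state.vector(net)
    yT = traj.final_state()
    nz = y0 > 0
    assert np.max(np.abs(yT[nz] - y0[nz]) / y0[nz]) < 1e-3


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def test_pure_decay_matches_closed_form():
    k = 0.25  # 1/h
    net = make_decay_toy(k=k, x0=100.0)
    tight = SolverConfig(rtol=1e-10, atol=1e-13)
    traj = simulate(net, np.array([100.0]), 24.0, "in_vivo", solver=tight)
    t = np.linspace(0.1, 24.0, 40)
    np.testing.assert_allclose(
        traj.states(t)[0], 100.0 * np.exp(-k * t), rtol=1e-6
    )


def test_complex_toy_conservation():
    net = make_complex_toy(k=0.01)
    traj = simulate(net, np.array([10.0, 7.0, 0.0]), 500.0, "in_vitro")
    t = np.linspace(0, 500.0, 100)
    y = traj.states(t)
    total_a = y[0] + y[2]
    total_b = y[1] + y[2]
    np.testing.assert_allclose(total_a, 10.0, rtol=1e-6)
    np.testing.assert_allclose(total_b, 7.0, rtol=1e-6)


def test_negative_initial_state_rejected(mm_toy):
    with pytest.raises(ValidationError):
        simulate(mm_toy, np.array([1.0, -1.0, 0.0]), 1.0, "in_vitro")


def test_reported_concentrations_nonnegative(default_net, assay_cfg):
    net = default_net.copy()
    state = steady_state_init(net)
    y0 = state.vector(net)
    y0[net.index["TF"]] = assay_cfg.tf_trigger
    traj = simulate(net, y0, 60.0, "in_vitro")
    t = np.linspace(0, 60.0, 400)
    assert traj.states(t).min() >= 0.0


def test_plasma_state_vector_checks_coverage(mm_toy):
    state = PlasmaState("v", 0.0, {"E": 1.0})
    with pytest.raises(ValidationError, match="missing"):
        state.vector(mm_toy)


def test_trajectory_tidy_export(mm_toy):
    traj = simulate(mm_toy, np.array([5.0, 50.0, 0.0]), 10.0, "in_vitro")
    df = traj.to_frame([0.0, 5.0, 10.0])
    assert list(df.columns) == ["time", "species", "concentration_nM"]
    assert len(df) == 3 * 3
    assert (df["concentration_nM"] >= 0).all()
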