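"""Simulator: balance equations, bolus feeding, integration, observation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choflux.network import (
    BiomassComposition,
    Metabolite,
    MetabolicNetwork,
    RateLawSpec,
    Reaction,
    SubstrateTerm,
)
from choflux.parameters import ParameterSet
from choflux.simulator import (
    CultureExperiment,
    FeedComposition,
    FeedPolicy,
    InvalidPolicyError,
    apply_bolus,
    feed_volume_for_target,
    observe,
    rhs,
    simulate,
)


def _mini_network(growth_vmax=0.0):
    """One glucose-uptake reaction plus an optional clamped growth rate."""
    mets = [
        Metabolite("GLC", "extracellular"),
        Metabolite("DUM", "extracellular"),
        Metabolite("Xv", "scalar", "1e6 cells/mL"),
        Metabolite("mAb", "scalar", "mg/L"),
        Metabolite("V", "scalar", "L"),
    ]
    rxns = [
        Reaction(
            id="V_upt",
            stoichiometry={"GLC": -1.0},
            rate_law=RateLawSpec(
                vmax="VmaxUpt", substrates=(SubstrateTerm("GLC", "KmUpt"),)
            ),
        ),
        Reaction(
            id="V_growth",
            stoichiometry={"DUM": -1e-12},
            rate_law=RateLawSpec(vmax="Vmaxgrowth", substrates=()),
        ),
    ]
    net = MetabolicNetwork(
        name="mini", metabolites=mets, reactions=rxns,
        biomass=BiomassComposition(3.15e-4, 107.5, 2.93e-3, 9.17e-3),
    )
    params = ParameterSet(
        names=["VmaxUpt", "KmUpt", "Vmaxgrowth"],
        values=np.array([4.0e-4, 10.0, growth_vmax]),
    )
    return net, params


def test_rhs_unit_algebra_for_extracellular_uptake():
    # flux 2e-4 mmol/1e6cells/h at Xv=2 -> dGLC/dt = -0.4 mM/h
    net, params = _mini_network()
    state = {"GLC": 10.0, "DUM": 1.0, "Xv": 2.0, "mAb": 0.0, "V": 1.0}
    comp = net.compiled(params)
    vec = np.array([state[s] for s in comp.species] + [2.0, 0.0, 1.0])
    d = rhs(vec, net, params)
    assert d[comp.sidx["GLC"]] == pytest.approx(-0.4)
    assert d[-1] == 0.0  # volume constant between events


def test_clamped_growth_matches_exponential_closed_form():
    net, params = _mini_network(growth_vmax=0.03)
    exp = CultureExperiment(
        name="exp", mode="batch", duration_h=24.0,
        initial_state={"GLC": 100.0, "DUM": 1.0, "Xv": 0.2, "mAb": 0.0, "V": 1.0},
    )
    traj = simulate(net, params, exp)
    assert traj.state_series("Xv")[-1] == pytest.approx(0.2 * np.exp(0.72), rel=1e-6)


def test_bolus_mixing_formula():
    state = {"GLC": 10.0, "Xv": 1.0, "mAb": 0.0, "V": 1.0}
    feed = FeedComposition({"GLC": 130.0})
    out = apply_bolus(state, 0.1, feed, ext_species=["GLC"])
    assert out["GLC"] == pytest.approx((10.0 * 1.0 + 130.0 * 0.1) / 1.1)
    assert out["GLC"] == pytest.approx(20.909, abs=1e-3)
    assert apply_bolus(state, 0.0, feed)["GLC"] == 10.0  # identity


@given(
    V=st.floats(0.5, 3.0), vol=st.floats(0.0, 1.0),
    conc=st.floats(0.0, 50.0), feed_conc=st.floats(0.0, 200.0),
    xv=st.floats(0.1, 10.0),
)
@settings(max_examples=200, deadline=None)
def test_bolus_conserves_mass_and_cells(V, vol, conc, feed_conc, xv):
    state = {"GLC": conc, "Xv": xv, "mAb": 5.0, "V": V}
    out = apply_bolus(state, vol, FeedComposition({"GLC": feed_conc}),
                      ext_species=["GLC"])
    before = conc * V + feed_conc * vol
    after = out["GLC"] * out["V"]
    assert after == pytest.approx(before, rel=1e-12, abs=1e-12)
    assert out["Xv"] * out["V"] == pytest.approx(xv * V, rel=1e-12)
    assert out["mAb"] * out["V"] == pytest.approx(5.0 * V, rel=1e-12)


def test_negative_bolus_volume_rejected():
    with pytest.raises(ValueError):
        apply_bolus({"V": 1.0, "Xv": 1.0, "mAb": 0.0}, -0.1, FeedComposition({}))


def test_feed_volume_for_target():
    state = {"GLC": 8.0, "V": 1.0}
    feed = FeedComposition({"GLC": 130.0})
    v = feed_volume_for_target(state, feed, 15.0)
    assert v == pytest.approx(7.0 / 115.0)
    # round trip: bolus with that volume lands exactly on target
    out = apply_bolus({**state, "Xv": 1.0, "mAb": 0.0}, v, feed, ext_species=["GLC"])
    assert out["GLC"] == pytest.approx(15.0, rel=1e-12)
    assert feed_volume_for_target({"GLC": 20.0, "V": 1.0}, feed, 15.0) == 0.0
    with pytest.raises(InvalidPolicyError):
        feed_volume_for_target(state, feed, 200.0)


def test_zero_vmax_keeps_concentrations_constant(ref_net, ref_params, ref_exps):
    frozen = ref_params.copy()
    for r in ref_net.reactions:
        frozen[r.rate_law.vmax] = 0.0
    exp = ref_exps[0]
    traj = simulate(ref_net, frozen, exp, max_grid_step_h=24.0)
    for sp in ("GLC", "GLN", "ATP", "Xv"):
        s = traj.state_series(sp)
        assert np.allclose(s, s[0], rtol=1e-9)


def test_conditional_policy_without_glucose_shortage_never_feeds():
    exp = CultureExperiment(
        name="fb", mode="fed-batch", duration_h=72.0,
        initial_state={"GLC": 500.0, "DUM": 0.0, "Xv": 1.0, "mAb": 0.0, "V": 1.0},
        feed=FeedComposition({"GLC": 1000.0}),
        policy=FeedPolicy(mode="threshold", set_point_mM=600.0),
    )
    net, params = _mini_network()
    traj = simulate(net, params, exp)
    assert traj.feed_events == []


def test_fed_batch_daily_policy_feeds_to_set_point(ref_net, ref_params, ref_exps):
    fb = [e for e in ref_exps if e.mode == "fed-batch"][0]
    traj = simulate(ref_net, ref_params, fb)
    assert len(traj.feed_events) >= 1
    glc = traj.state_series("GLC")
    set_point = fb.initial_state["GLC"]
    for t_feed, vol, _ in traj.feed_events:
        idx = np.searchsorted(traj.times, t_feed)
        assert glc[idx] == pytest.approx(set_point, rel=1e-6)  # post-bolus value


def test_observe_interpolation_and_errors(biogro_batch_traj):
    traj = biogro_batch_traj
    t_on = traj.times[10]
    val = observe(traj, ["GLC"], [t_on])[0, 0]
    assert val == traj.state_series("GLC")[10]
    # midpoint of a linear segment is the mean of its endpoints
    t0, t1 = traj.times[3], traj.times[4]
    mid = observe(traj, ["GLC"], [(t0 + t1) / 2])[0, 0]
    assert mid == pytest.approx(
        (traj.state_series("GLC")[3] + traj.state_series("GLC")[4]) / 2
    )
    with pytest.raises(ValueError):
        observe(traj, ["GLC"], [traj.times[-1] + 10.0])
    with pytest.raises(KeyError):
        observe(traj, ["NOPE"], [0.0])


def test_solver_tolerance_convergence(toy):
    net, params, exp = toy
    t = np.arange(0.0, 48.1, 6.0)
    a = observe(simulate(net, params, exp), ["S", "P", "M"], t)
    b = observe(simulate(net, params, exp, rtol=5e-9, atol_scale=5e-11),
                ["S", "P", "M"], t)
    assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-12)) < 1e-3


def test_trajectory_bitwise_reproducible(toy):
    net, params, exp = toy
    t1 = simulate(net, params, exp)
    t2 = simulate(net, params, exp)
    assert np.array_equal(t1.states, t2.states)
    assert np.array_equal(t1.times, t2.times)


def test_reference_batch_stays_finite_nonnegative_over_360h(ref_net, ref_params, ref_exps):
    exp = ref_exps[0]
    long_exp = CultureExperiment(
        name="long", initial_state=dict(exp.initial_state), mode="batch",
        duration_h=360.0,
    )
    traj = simulate(ref_net, ref_params, long_exp, max_grid_step_h=4.0)
    assert np.all(np.isfinite(traj.states))
    assert np.all(traj.states >= 0.0)


def test_batch_mode_rejects_feed_definition():
    with pytest.raises(ValueError):
        CultureExperiment(
            name="bad", initial_state={"Xv": 1, "V": 1}, mode="batch",
            duration_h=24.0, feed=FeedComposition({"GLC": 100.0}),
        )
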