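"""Water and solute flux operators: clamps, chain identities, mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nephroflow as nf
from nephroflow.model_core import TUBULAR_COMPARTMENTS, osmolality
from nephroflow.transport import (
    SimulationFault, body_rhs, compute_flows, flux_terms, interstitial_rhs,
    peritubular_rhs, tubular_rhs, vasa_recta_rhs, water_reabsorption,
)


def perturbed_state(params, rng):
    """A physically plausible but non-stationary state."""
    state = nf.ModelState.uniform(params)
    state.c_tub *= rng.uniform(0.5, 2.0, state.c_tub.shape)
    state.c_int *= rng.uniform(0.5, 2.0, state.c_int.shape)
    state.c_peritub *= rng.uniform(0.8, 1.2, 3)
    state.c_dvr *= rng.uniform(0.8, 1.2, state.c_dvr.shape)
    state.c_avr *= rng.uniform(0.8, 1.2, state.c_avr.shape)
    state.c_tub[:, 2] = rng.uniform(0, 5e4, 16)
    state.a_plasma = 500.0
    return state


class TestWaterReabsorption:
    def test_zero_gradient_gives_zero(self):
        assert water_reabsorption(1e-8, 3e5, 3e5, 1e-3) == 0.0

    def test_reverse_gradient_is_clamped_to_zero(self):
        assert water_reabsorption(1e-8, 2e5, 3e5, 1e-3) == 0.0

    def test_direct_arithmetic(self):
        # R * (osm_int - osm_tub) below the inflow clamp
        assert water_reabsorption(1.0e-8, 3.2e5, 3.0e5, 1e-3) == pytest.approx(2.0e-4)

    @given(r=st.floats(0, 1e-6), osm_int=st.floats(0, 2e6), osm_tub=st.floats(0, 2e6),
           q_in=st.floats(0, 1e-2))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_always_within_zero_and_inflow(self, r, osm_int, osm_tub, q_in):
        q = water_reabsorption(r, osm_int, osm_tub, q_in)
        assert 0.0 <= q <= q_in


class TestFlowField:
    def test_chain_continuity_and_volume_balance(self, params, topo, rng):
        flows = compute_flows(perturbed_state(params, rng), params, topo)
        assert np.allclose(flows.q_out, flows.q_in - flows.q_reabs)
        for chain in ((0, 1, 2, 3), (4, 5, 6, 7, 8, 9, 10, 11), (12, 13, 14, 15)):
            for a, b in zip(chain[:-1], chain[1:]):
                assert flows.q_in[b] == pytest.approx(flows.q_out[a])
        assert flows.q_in[12] == pytest.approx(flows.q_out[3] + flows.q_out[11])
        assert np.all(flows.q_reabs >= 0) and np.all(flows.q_reabs <= flows.q_in)

    def test_peritubular_inflow_at_rest(self, params, topo):
        # u_in = f_peritub * (RPF - GFR) with GFR at its start value
        state = nf.ModelState.uniform(params)
        flows = compute_flows(state, params, topo)
        assert flows.u_in_peritub == pytest.approx(0.85 * (5.06e-3 - 1.31e-3))
        assert flows.u_in_peritub == pytest.approx(3.1875e-3)

    def test_dvr_inflow_is_the_complement(self, params, topo):
        state = nf.ModelState.uniform(params)
        flows = compute_flows(state, params, topo)
        assert flows.u_dvr_in[0] == pytest.approx(0.15 * (5.06e-3 - 1.31e-3))
        assert flows.u_dvr_in[0] == pytest.approx(5.625e-4)

    def test_avr_volume_identity(self, params, topo, rng):
        # u_out - u_in = DVR reabsorption + regional tubular reabsorption
        state = perturbed_state(params, rng)
        flows = compute_flows(state, params, topo)
        for m, region_idx in enumerate((1, 2, 3)):
            med = flows.q_reabs[topo.region == region_idx].sum()
            assert flows.u_avr_out[m] - flows.u_avr_in[m] == pytest.approx(
                flows.u_dvr_reabs[m] + med)
        assert np.all(flows.u_avr_out >= 0) and np.all(flows.u_dvr_out >= 0)

    def test_filtration_reaching_plasma_flow_is_a_fault(self, params, topo):
        state = nf.ModelState.uniform(params)
        state.sngfr_s = state.sngfr_l = 1.01 * params.rpf / params.n_nephrons
        with pytest.raises(SimulationFault):
            compute_flows(state, params, topo)


class TestTubularRHS:
    def test_steady_compartment_has_zero_derivative(self, params, topo):
        # equal in/out flow, upstream concentration equal, no transport: dC/dt = 0
        state = nf.ModelState.uniform(params)
        flows = compute_flows(state, params, topo)
        # descending IM-II has water but no sodium transport; at the uniform
        # state all gradients vanish, so every no-transport solute is steady
        d = tubular_rhs("descending_henle_long_im2", state, flows, params, topo)
        assert d[2] == pytest.approx(0.0, abs=1e-12)  # drug

    def test_scalar_oracle_proximal_sodium(self, params, topo, rng):
        """Term-by-term hand evaluation of the proximal balance."""
        state = perturbed_state(params, rng)
        flows = compute_flows(state, params, topo)
        i = TUBULAR_COMPARTMENTS.index("proximal_short")
        # independent scalar evaluation
        q_in = params.n_short * max(state.sngfr_s, 0.0)
        osm_int = osmolality(*state.c_int[0])
        osm_tub = osmolality(*state.c_tub[i])
        q_reabs = min(max(topo.r_water[i] * (osm_int - osm_tub), 0.0), q_in)
        q_out = q_in - q_reabs
        k_active = 0.7 * params.pair_gain * 2.48e-4
        c = state.c_tub[i, 0]
        expected = (q_in * params.c_na_systemic - q_out * c - k_active * c) / topo.v_tub[i]
        assert tubular_rhs("proximal_short", state, flows, params, topo)[0] == \
            pytest.approx(expected, rel=1e-12)

    def test_flux_term_introspection_is_consistent(self, params, topo, rng):
        state = perturbed_state(params, rng)
        flows = compute_flows(state, params, topo)
        for name in ("proximal_short", "cd_cortex", "ascending_henle_long_im2"):
            i = TUBULAR_COMPARTMENTS.index(name)
            t = flux_terms(name, state, flows, params, topo)
            recomposed = (t["advection_in"] - t["advection_out"]
                          - t["active"] - t["passive"]) / topo.v_tub[i]
            assert np.allclose(recomposed,
                               tubular_rhs(name, state, flows, params, topo))


class TestInterstitialAndVascularRHS:
    def test_equilibrium_without_transport(self, params, topo):
        # all concentrations equal: urea and drug interstitial derivatives
        # vanish (no active source); sodium is driven by the active pumps
        state = nf.ModelState.uniform(params)
        state.a_plasma = 0.0
        flows = compute_flows(state, params, topo)
        for region in ("cortex", "outer_medulla"):
            d = interstitial_rhs(region, state, flows, params, topo)
            assert d[1] == pytest.approx(0.0, abs=1e-9)
            assert d[2] == pytest.approx(0.0, abs=1e-9)
            assert d[0] > 0  # active sodium accumulates

    def test_om_urea_oracle(self, params, topo, rng):
        """Hand-coded medullary interstitial balance for urea."""
        state = perturbed_state(params, rng)
        flows = compute_flows(state, params, topo)
        om = 1
        members = [i for i in range(16) if topo.region[i] == om]
        passive = sum(topo.k_passive_urea[i] * (state.c_tub[i, 1] - state.c_int[om, 1])
                      for i in members)
        convective = flows.q_reabs[members].sum() * state.c_int[om, 1]
        dvr_x = topo.ps_dvr[0, 1] * (state.c_int[om, 1] - state.c_dvr[0, 1])
        avr_x = topo.ps_avr[0] * (state.c_int[om, 1] - state.c_avr[0, 1])
        expected = (passive - convective - dvr_x - avr_x) / topo.v_int[om]
        assert interstitial_rhs("outer_medulla", state, flows, params, topo)[1] == \
            pytest.approx(expected, rel=1e-10)

    def test_peritubular_balance_at_arterial_equality(self, params, topo):
        # all concentrations at arterial values: only the reabsorption-inflow
        # imbalance term remains (u_out > u_in at equal concentrations)
        state = nf.ModelState.uniform(params)
        state.c_tub[:, 0] = 1.0e5  # force a cortical osmotic gradient
        flows = compute_flows(state, params, topo)
        d = peritubular_rhs(state, flows, params, topo)
        cortical = flows.q_reabs[topo.region == 0].sum()
        expected = (flows.u_in_peritub * params.c_urea_systemic
                    - flows.u_out_peritub * params.c_urea_systemic
                    + cortical * params.c_urea_systemic) / topo.v_peritub
        assert d[1] == pytest.approx(expected)

    def test_exchange_antisymmetry_conserves_drug(self, params, topo, rng):
        """Internal exchange cancels: kidney drug changes only via boundaries."""
        state = perturbed_state(params, rng)
        flows = compute_flows(state, params, topo)
        model = nf.KidneyModel(params)
        from nephroflow.transport import solute_derivatives
        dc_tub, dc_int, dc_per, dc_dvr, dc_avr = solute_derivatives(
            state, flows, params, topo)
        internal = (np.dot(topo.v_tub, dc_tub[:, 2])
                    + np.dot(topo.v_int, dc_int[:, 2])
                    + topo.v_peritub * dc_per[2]
                    + np.dot(topo.v_dvr, dc_dvr[:, 2])
                    + np.dot(topo.v_avr, dc_avr[:, 2]))
        c_art = state.a_plasma / params.v_plasma
        influx = params.rpf * c_art
        outflux = (flows.u_out_peritub * state.c_peritub[2]
                   + flows.u_avr_out[0] * state.c_avr[0, 2]
                   + flows.urine_flow * state.c_tub[15, 2])
        assert internal == pytest.approx(influx - outflux, rel=1e-9)

    def test_vasa_recta_rhs_advection_only_at_equality(self, params, topo):
        state = nf.ModelState.uniform(params)
        flows = compute_flows(state, params, topo)
        # equal osmolality everywhere: u_reabs = 0, exchange terms vanish
        assert np.allclose(flows.u_dvr_reabs, 0.0)
        d = vasa_recta_rhs("dvr_outer_medulla", state, flows, params, topo)
        assert np.allclose(d, 0.0, atol=1e-9)


class TestBodyRHS:
    def test_no_dose_no_drug_gives_zero(self, params, topo):
        state = nf.ModelState.uniform(params)
        flows = compute_flows(state, params, topo)
        assert body_rhs(state, flows, 0.0, params) == (0.0, 0.0)

    def test_isolated_plasma_conserves_amount(self, params, topo):
        import dataclasses
        isolated = dataclasses.replace(params, rpf=params.rpf, q_exchange=1e-30)
        state = nf.ModelState.uniform(params)
        state.a_plasma = 100.0
        flows = compute_flows(state, params, topo)
        da_pl, da_ec = body_rhs(state, flows, 0.0, isolated)
        # only the renal artery drains the plasma compartment
        assert da_pl == pytest.approx(-params.rpf * 100.0 / params.v_plasma, rel=1e-6)
        assert da_ec == pytest.approx(0.0, abs=1e-20)
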