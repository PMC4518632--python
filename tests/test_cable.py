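import math

import numpy as np
import pytest
from scipy.sparse.linalg import spsolve

from inhibmap.cable import (
    BiophysicsConfig,
    ClampProtocol,
    CurrentInjection,
    Site,
    SynapticInput,
    attenuation_map,
    discretize,
    input_resistance,
    simulate,
    space_constant,
)
from inhibmap.morphology import Morphology, Section, attach_spine
from inhibmap.synapse import KineticSynapseParams, conductance_waveform
from inhibmap.synthdata import SyntheticConfig, make_pyramidal_morphology


def single_compartment(area_um2=100.0):
    """One soma cylinder with the requested membrane area."""
    d = 10.0
    return Morphology(
        [Section(id=1, parent_id=None, kind="soma",
                 length=area_um2 / (math.pi * d), diameter=d)]
    )


def cable_morphology(length, diameter, stub=True):
    """A uniform unbranched cable (with a vanishing soma stub as root)."""
    m = Morphology(
        [Section(id=1, parent_id=None, kind="soma", length=1e-2, diameter=1e-2)]
    )
    m.add(Section(id=2, parent_id=1, kind="basal", length=length, diameter=diameter))
    return m


class TestDiscretize:
    def test_compartment_count(self):
        m = cable_morphology(100.0, 1.0)
        sys_ = discretize(m, max_compartment_length=10.0, lambda_fraction=1.0)
        assert np.sum(sys_.comp_section == 2) == 10

    def test_membrane_area_conserved(self):
        d, L = 1.2, 87.0
        m = cable_morphology(L, d)
        sys_ = discretize(m, max_compartment_length=3.0)
        bio = sys_.biophysics
        idx = sys_.comp_section == 2
        total_g = sys_.g_m[idx].sum()
        assert total_g == pytest.approx(bio.g_leak * 10.0 * math.pi * d * L, rel=1e-12)

    def test_axial_conductance_closed_form(self):
        m = cable_morphology(10.0, 1.0)
        sys_ = discretize(m, max_compartment_length=10.0, lambda_fraction=1.0)
        # single cable compartment attached to the soma stub: check the
        # intra-section formula on a two-compartment split instead
        sys2 = discretize(m, max_compartment_length=5.0, lambda_fraction=1.0)
        idx = np.flatnonzero(sys2.comp_section == 2)
        g = [g for (i, j, g) in sys2.edges if i in idx and j in idx]
        assert g[0] == pytest.approx(1e5 * math.pi * 1.0**2 / (4 * 100.0 * 5.0), rel=1e-12)

    def test_density_scale_raises_membrane_load(self):
        m = cable_morphology(50.0, 1.0)
        m[2].density_scale = 1.5
        sys_ = discretize(m, max_compartment_length=5.0)
        m2 = cable_morphology(50.0, 1.0)
        ref = discretize(m2, max_compartment_length=5.0)
        idx = sys_.comp_section == 2
        assert sys_.g_m[idx].sum() == pytest.approx(1.5 * ref.g_m[idx].sum())
        assert sys_.c[idx].sum() == pytest.approx(1.5 * ref.c[idx].sum())


class TestRestAndRC:
    def test_rest_without_stimulus(self):
        sys_ = discretize(single_compartment(), max_compartment_length=1e3)
        ts = simulate(sys_, [], ClampProtocol(duration=50.0))
        assert np.allclose(ts.voltage, -65.0)

    def test_voltage_clamp_at_rest_draws_no_current(self):
        sys_ = discretize(single_compartment(), max_compartment_length=1e3)
        proto = ClampProtocol(mode="voltage_clamp", site=Site(1, 0.5),
                              hold=-65.0, duration=50.0)
        ts = simulate(sys_, [], proto)
        assert np.allclose(ts.clamp_current, 0.0, atol=1e-12)

    def test_rc_step_response_within_one_percent(self):
        """100 µm² compartment: R = 10 GΩ, τ = c_m/g_leak = 10 ms."""
        sys_ = discretize(single_compartment(100.0), max_compartment_length=1e3)
        inj = CurrentInjection(Site(1, 0.5), amplitude=1.0, start=5.0, stop=1e9)
        ts = simulate(sys_, [inj], ClampProtocol(duration=105.0, dt=0.025))
        v = ts.voltage_at(Site(1, 0.5))
        # steady state: E + I·R = -65 + 1 pA x 10 GΩ = -55 mV
        assert v[-1] == pytest.approx(-55.0, abs=0.01)
        idx = np.searchsorted(ts.time, 15.0)
        assert (v[idx] + 65.0) / 10.0 == pytest.approx(1 - math.exp(-1), abs=0.01)

    def test_input_resistance_single_compartment(self):
        sys_ = discretize(single_compartment(100.0), max_compartment_length=1e3)
        assert input_resistance(sys_, Site(1, 0.5)) == pytest.approx(1e4, rel=1e-9)

    def test_doubling_leak_halves_input_resistance(self):
        bio2 = BiophysicsConfig(g_leak=2e-4)
        s1 = discretize(single_compartment(), max_compartment_length=1e3)
        s2 = discretize(single_compartment(), max_compartment_length=1e3, biophysics=bio2)
        assert input_resistance(s2, Site(1, 0.5)) == pytest.approx(
            input_resistance(s1, Site(1, 0.5)) / 2.0, rel=1e-9
        )


class TestAnalyticCable:
    def test_sealed_end_steady_state_attenuation(self):
        """Sealed-end finite cable: V(x)/V(0) = cosh((l-x)/λ)/cosh(l/λ)."""
        L, d = 500.0, 1.0
        m = cable_morphology(L, d)
        sys_ = discretize(m, max_compartment_length=2.0, lambda_fraction=1.0)
        lam = space_constant(d, 100.0, 1e-4)
        rhs = np.zeros(sys_.n)
        src = sys_.locate(Site(2, 0.0))
        rhs[src] = 1.0
        dv = spsolve(sys_.G.tocsc(), rhs)
        for x_frac in (0.25, 0.5, 1.0):
            x = x_frac * L
            measured = dv[sys_.locate(Site(2, x_frac))] / dv[src]
            analytic = math.cosh((L - x) / lam) / math.cosh(L / lam)
            assert measured == pytest.approx(analytic, rel=0.01)

    def test_long_cable_input_resistance_near_semi_infinite(self):
        d = 1.0
        lam = space_constant(d, 100.0, 1e-4)
        m = cable_morphology(6 * lam, d)
        sys_ = discretize(m, max_compartment_length=2.0, lambda_fraction=1.0)
        r_in = input_resistance(sys_, Site(2, 0.0))
        # R_inf = sqrt(r_m r_a)/... = 1/(g'·λ·tanh(l/λ)) with g' per length
        g_per_um = 1e-4 * 10.0 * math.pi * d  # nS/µm
        r_inf = 1e3 / (g_per_um * lam)  # MΩ
        assert r_in == pytest.approx(r_inf / math.tanh(6.0), rel=0.02)

    def test_dt_halving_convergence(self):
        """Peak IPSP changes by <0.1% when dt is halved at the default."""
        m = make_pyramidal_morphology(SyntheticConfig(seed=5, n_basal_dendrites=3))
        sec = m.sections("basal")[1]
        sys_ = discretize(m)
        params = KineticSynapseParams()
        syn = SynapticInput(
            Site(sec.id, 0.5),
            lambda t: conductance_waveform(params, 5.0, t, g_max=0.21),
            params.e_syn,
        )
        peaks = {}
        for dt in (0.025, 0.0125):
            ts = simulate(sys_, [syn], ClampProtocol(duration=80.0, dt=dt))
            peaks[dt] = np.max(np.abs(ts.voltage + 65.0))
        assert abs(peaks[0.025] - peaks[0.0125]) / peaks[0.0125] < 1e-3

    def test_backward_euler_agrees_with_cn(self):
        sys_ = discretize(single_compartment(), max_compartment_length=1e3)
        inj = CurrentInjection(Site(1, 0.5), amplitude=1.0, start=5.0, stop=1e9)
        v_cn = simulate(sys_, [inj], ClampProtocol(duration=60.0, method="cn"))
        v_be = simulate(sys_, [inj], ClampProtocol(duration=60.0, method="be"))
        assert np.allclose(v_cn.voltage, v_be.voltage, atol=0.05)


class TestVoltageClamp:
    def test_clamp_current_equals_synaptic_current_at_clamped_node(self):
        """With the synapse on the clamped compartment and the rest of the
        tree at the hold potential, I_clamp = g(t)·(V_hold − E_syn)."""
        m = make_pyramidal_morphology(SyntheticConfig(seed=2, n_basal_dendrites=2))
        sys_ = discretize(m)
        params = KineticSynapseParams()
        site = Site(m.root.id, 0.5)
        g_of_t = lambda t: conductance_waveform(params, 5.0, t, g_max=0.71)
        syn = SynapticInput(site, g_of_t, params.e_syn)
        proto = ClampProtocol(mode="voltage_clamp", site=site, hold=-65.0,
                              duration=60.0)
        ts = simulate(sys_, [syn], proto)
        expected = g_of_t(ts.time) * (-65.0 - params.e_syn)
        assert np.allclose(ts.clamp_current, expected, atol=1e-6)

    def test_series_resistance_reduces_measured_peak(self):
        m = make_pyramidal_morphology(SyntheticConfig(seed=2, n_basal_dendrites=2))
        sys_ = discretize(m)
        params = KineticSynapseParams()
        site = Site(m.root.id, 0.5)
        syn = SynapticInput(
            site, lambda t: conductance_waveform(params, 5.0, t, g_max=0.71),
            params.e_syn,
        )
        ideal = simulate(sys_, [syn], ClampProtocol(
            mode="voltage_clamp", site=site, duration=60.0))
        with_rs = simulate(sys_, [syn], ClampProtocol(
            mode="voltage_clamp", site=site, duration=60.0, series_resistance=15.0))
        assert np.max(np.abs(with_rs.clamp_current)) < np.max(np.abs(ideal.clamp_current))

    def test_divergence_reported(self):
        sys_ = discretize(single_compartment(), max_compartment_length=1e3)
        bad = SynapticInput(Site(1, 0.5), lambda t: np.full_like(t, np.nan), -77.5)
        with pytest.raises((FloatingPointError, ValueError)):
            simulate(sys_, [bad], ClampProtocol(duration=5.0))


class TestAttenuation:
    def test_source_attenuation_is_one(self, spiny_model):
        system, spine, shaft = spiny_model
        params = KineticSynapseParams()
        syn = SynapticInput(
            shaft, lambda t: conductance_waveform(params, 5.0, t, g_max=0.21),
            params.e_syn,
        )
        amap = attenuation_map(system, shaft, [syn])
        assert amap.attenuation(shaft) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_peak_deflection_monotone_away_from_source(self, seed):
        """On a passive tree the peak |ΔV| never grows along any path away
        from the source compartment."""
        m = make_pyramidal_morphology(
            SyntheticConfig(seed=seed, n_basal_dendrites=3)
        )
        sys_ = discretize(m)
        rng = np.random.default_rng(seed)
        basal = m.sections("basal")
        sec = basal[int(rng.integers(len(basal)))]
        src = Site(sec.id, float(rng.uniform()))
        params = KineticSynapseParams()
        syn = SynapticInput(
            src, lambda t: conductance_waveform(params, 5.0, t, g_max=0.3),
            params.e_syn,
        )
        amap = attenuation_map(sys_, src, [syn])
        peaks = amap.peak_deflection
        src_idx = sys_.locate(src)
        # BFS over the compartment adjacency from the source
        adj: dict[int, list[int]] = {}
        for i, j, _g in sys_.edges:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        seen = {src_idx}
        frontier = [src_idx]
        while frontier:
            nxt = []
            for i in frontier:
                for j in adj.get(i, []):
                    if j not in seen:
                        seen.add(j)
                        assert peaks[j] <= peaks[i] * (1 + 1e-9)
                        nxt.append(j)
            frontier = nxt

    def test_spine_neck_isolates_head(self, spiny_model):
        """Spine-head source: large local IPSP, strongly attenuated at the
        shaft; shaft source: reaches the spine head with no attenuation."""
        system, spine, shaft = spiny_model
        params = KineticSynapseParams()

        def syn_at(site):
            return SynapticInput(
                site, lambda t: conductance_waveform(params, 5.0, t, g_max=0.11),
                params.e_syn,
            )

        from_spine = attenuation_map(system, spine, [syn_at(spine)])
        assert from_spine.attenuation(shaft) < 0.7
        from_shaft = attenuation_map(system, shaft, [syn_at(shaft)])
        assert from_shaft.attenuation(spine) > 0.95
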