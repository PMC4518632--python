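"""In-silico IPSC conduction experiments: spine/shaft/soma injection,
attenuation quantification, multi-synapse summation and the spine E/I veto.

Each experiment injects the kinetic IPSC waveform at a chosen site on a
passive model cell and reports the peak voltage deflection at the source,
the parent dendrite and the soma (current clamp), and the peak amplifier
current under somatic voltage clamp. Attenuation is reported both as the
transmitted fraction (peak downstream / peak at source) and as its
complement, the lost fraction, since both conventions appear in the
literature. For the excitation/inhibition interaction, an AMPA-like EPSC on
a spine head is paired with a coincident GABA_A IPSC either on the same
head or on the parent shaft; the suppression fraction measures how much of
the local EPSP the inhibition removes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cable import (
    AttenuationMap,
    BiophysicsConfig,
    ClampProtocol,
    CompartmentSystem,
    Site,
    SynapticInput,
    attenuation_map,
    discretize,
    simulate,
)
from .morphology import Morphology
from .synapse import EXCITATORY_DEFAULTS, KineticSynapseParams, conductance_waveform

__all__ = [
    "PropagationSummary",
    "EIVetoResult",
    "run_injection_experiment",
    "summate_synapses",
    "spine_veto",
    "equivalent_excitatory_inputs",
    "kinetic_input",
]


@dataclass
class PropagationSummary:
    """Result of one injection experiment (deflections in mV from rest,
    currents in pA; attenuation fractions are transmitted fractions)."""

    source_label: str
    source_site: Site
    peak_v_source: float
    peak_v_dendrite: float
    peak_v_soma: float
    peak_i_soma_clamp: float | None
    attenuation_to_dendrite: float
    attenuation_to_soma: float

    @property
    def loss_to_dendrite(self) -> float:
        """Lost fraction 1 − transmitted (the complementary convention)."""
        return 1.0 - self.attenuation_to_dendrite

    @property
    def loss_to_soma(self) -> float:
        return 1.0 - self.attenuation_to_soma


@dataclass
class EIVetoResult:
    """Spine E/I interaction: EPSP peaks with and without the coincident
    IPSC, at the spine head and at the soma."""

    epsp_spine_alone: float
    epsp_spine_with_ipsc: float
    epsp_soma_alone: float
    epsp_soma_with_ipsc: float
    suppression_spine: float
    suppression_soma: float


def kinetic_input(
    site: Site,
    g_max: float,
    params: KineticSynapseParams | None = None,
    onset: float = 5.0,
    shape: str = "pulse",
) -> SynapticInput:
    """Package a kinetic conductance waveform as a cable synaptic input."""
    p = params or KineticSynapseParams()
    return SynapticInput(
        site=site,
        conductance=lambda t: conductance_waveform(p, onset, t, g_max=g_max, shape=shape),
        e_syn=p.e_syn,
    )


def _soma_site(system: CompartmentSystem) -> Site:
    return Site(system.morphology.root.id, 0.5)


def _parent_dendrite_site(m: Morphology, site: Site) -> Site:
    """The dendritic shaft location electrically closest to a site: for a
    spine-head or neck site, the neck's insertion point on the parent
    dendrite; for a dendritic site, the site itself; for a somatic site,
    the soma."""
    sec = m[site.section]
    while sec.kind in ("spine_head", "spine_neck"):
        pos = sec.parent_position
        sec = m[sec.parent_id]
        site = Site(sec.id, pos)
    return site


def run_injection_experiment(
    system: CompartmentSystem,
    site: Site,
    g_max_i: float,
    params: KineticSynapseParams | None = None,
    onset: float = 5.0,
    duration: float = 120.0,
    dt: float = 0.025,
    label: str = "",
    voltage_clamp: bool = True,
    shape: str = "pulse",
) -> PropagationSummary:
    """Inject one kinetic IPSC at ``site``: current clamp gives the IPSP and
    its attenuation to the parent dendrite and soma; an optional somatic
    voltage clamp at the leak reversal gives the somatically recorded
    IPSC."""
    params = params or KineticSynapseParams()
    syn = kinetic_input(site, g_max_i, params, onset, shape)
    cc = ClampProtocol(mode="current_clamp", duration=duration, dt=dt)
    amap = attenuation_map(system, site, [syn], cc)
    m = system.morphology
    soma = _soma_site(system)
    dend = _parent_dendrite_site(m, site)
    src_peak = float(amap.peak_deflection[system.locate(site)])
    dend_peak = float(amap.peak_deflection[system.locate(dend)])
    soma_peak = float(amap.peak_deflection[system.locate(soma)])

    i_peak = None
    if voltage_clamp:
        vc = ClampProtocol(
            mode="voltage_clamp",
            site=soma,
            hold=system.biophysics.e_leak,
            duration=duration,
            dt=dt,
        )
        ts = simulate(system, [syn], vc)
        i_peak = float(np.max(np.abs(ts.clamp_current)))

    return PropagationSummary(
        source_label=label,
        source_site=site,
        peak_v_source=src_peak,
        peak_v_dendrite=dend_peak,
        peak_v_soma=soma_peak,
        peak_i_soma_clamp=i_peak,
        attenuation_to_dendrite=dend_peak / src_peak if src_peak else float("nan"),
        attenuation_to_soma=soma_peak / src_peak if src_peak else float("nan"),
    )


def summate_synapses(
    system: CompartmentSystem,
    sites: list[Site],
    g_max_list: list[float],
    onsets: list[float] | None = None,
    params: KineticSynapseParams | None = None,
    duration: float = 120.0,
    dt: float = 0.025,
    shape: str = "pulse",
) -> dict[str, float]:
    """Simultaneous (or offset) activation of several synapses: returns the
    summed somatic peak deflection, the sum of the individual peaks and the
    sublinearity index (summed / linear sum, ≤ 1 on a passive tree)."""
    if not sites:
        raise ValueError("need at least one synapse")
    if len(g_max_list) != len(sites):
        raise ValueError("one g_max per site")
    onsets = onsets if onsets is not None else [5.0] * len(sites)
    params = params or KineticSynapseParams()
    soma = _soma_site(system)
    cc = ClampProtocol(mode="current_clamp", duration=duration, dt=dt)
    rest = system.biophysics.e_leak

    def soma_peak(inputs) -> float:
        ts = simulate(system, inputs, cc)
        return float(np.max(np.abs(ts.voltage[system.locate(soma)] - rest)))

    all_inputs = [
        kinetic_input(s, g, params, o, shape)
        for s, g, o in zip(sites, g_max_list, onsets)
    ]
    combined = soma_peak(all_inputs)
    individual = [soma_peak([inp]) for inp in all_inputs]
    linear_sum = float(sum(individual))
    return {
        "combined_peak_mV": combined,
        "individual_peaks_mV": individual,
        "linear_sum_mV": linear_sum,
        "sublinearity_index": combined / linear_sum if linear_sum else float("nan"),
    }


def spine_veto(
    system: CompartmentSystem,
    spine_site: Site,
    ipsc_site: Site | None = None,
    epsc_params: KineticSynapseParams = EXCITATORY_DEFAULTS,
    ipsc_params: KineticSynapseParams | None = None,
    ipsc_g_max: float = 0.11,
    dt_offset: float = 0.0,
    onset: float = 5.0,
    duration: float = 60.0,
    dt: float = 0.025,
    shape: str = "pulse",
) -> EIVetoResult:
    """EPSP suppression by a coincident IPSC.

    The EPSC (default 0.2 nS, reversal 0 mV) is injected at the spine head;
    the IPSC (default at the same site, offset by ``dt_offset`` ms) uses the
    GABA_A kinetics. Suppression fraction = 1 − (peak depolarisation with
    IPSC)/(peak depolarisation alone), measured at the spine head and soma.
    """
    ipsc_params = ipsc_params or KineticSynapseParams()
    ipsc_site = ipsc_site or spine_site
    rest = system.biophysics.e_leak
    soma = _soma_site(system)
    cc = ClampProtocol(mode="current_clamp", duration=duration, dt=dt)
    epsc = kinetic_input(spine_site, epsc_params.g_max, epsc_params, onset, shape)

    def depol_peaks(inputs) -> tuple[float, float]:
        ts = simulate(system, inputs, cc)
        v_sp = ts.voltage[system.locate(spine_site)] - rest
        v_so = ts.voltage[system.locate(soma)] - rest
        return float(np.max(v_sp)), float(np.max(v_so))

    sp_alone, so_alone = depol_peaks([epsc])
    ipsc = kinetic_input(ipsc_site, ipsc_g_max, ipsc_params, onset + dt_offset, shape)
    sp_both, so_both = depol_peaks([epsc, ipsc])

    def suppression(alone: float, both: float) -> float:
        if alone <= 0:
            return 0.0
        return min(max(1.0 - both / alone, 0.0), 1.0)

    return EIVetoResult(
        epsp_spine_alone=sp_alone,
        epsp_spine_with_ipsc=sp_both,
        epsp_soma_alone=so_alone,
        epsp_soma_with_ipsc=so_both,
        suppression_spine=suppression(sp_alone, sp_both),
        suppression_soma=suppression(so_alone, so_both),
    )


def equivalent_excitatory_inputs(
    somatic_inhibition_mv: float, single_spine_epsp_mv: float
) -> float:
    """How many single-spine EPSPs the somatic inhibitory deflection can
    cancel: the ratio of the two somatic deflection magnitudes."""
    if not (somatic_inhibition_mv > 0 and single_spine_epsp_mv > 0):
        raise ValueError("deflections must be positive magnitudes")
    return somatic_inhibition_mv / single_spine_epsp_mv
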