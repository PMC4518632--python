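"""Passive branched-cable solver with current-clamp and somatic
voltage-clamp protocols.

The morphology is discretised into iso-potential compartments and the
passive cable equation

    c_m dV/dt = -g_leak (V - E_leak) + axial coupling + synaptic/injected currents

is integrated implicitly (Crank-Nicolson by default, backward Euler
optionally). Synapses are conductance-based: their time course enters the
system matrix, so strong inputs on stiff structures (0.07 µm spine necks)
remain unconditionally stable. The constant part of the system matrix is
LU-factorised once; the few time-varying synaptic conductances are folded
in with a Woodbury rank-k update, so each time step costs two triangular
solves.

Public units: mV, ms, nS, pA, pF, µm. These are mutually consistent
(pA/mV = nS, pF·mV/ms = pA), so no conversion factors appear inside the
integrator. Axial resistivity is quoted in Ω·cm as is conventional.

Sign conventions: the solver works with outward-positive membrane current;
exported IPSC traces follow the electrophysiological convention (inward
negative) via :func:`traces` utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu, spsolve

from .morphology import Morphology

__all__ = [
    "BiophysicsConfig",
    "ClampProtocol",
    "Site",
    "SynapticInput",
    "CurrentInjection",
    "TraceSet",
    "AttenuationMap",
    "CompartmentSystem",
    "discretize",
    "simulate",
    "input_resistance",
    "attenuation_map",
    "space_constant",
]

#: nS/µm² per S/cm² and pF/µm² per µF/cm².
_NS_PER_UM2 = 10.0
_PF_PER_UM2 = 0.01


@dataclass(frozen=True)
class BiophysicsConfig:
    """Passive membrane parameters (pre-adjustment densities; per-section
    ``density_scale`` factors multiply the two densities)."""

    g_leak: float = 1e-4        # S/cm²
    c_m: float = 1.0            # µF/cm²
    r_a_dendrite: float = 100.0  # Ω·cm (soma, basal, apical, axon default)
    r_a_spine: float = 385.0     # Ω·cm (spine neck and head)
    e_leak: float = -65.0        # mV

    def __post_init__(self) -> None:
        for name in ("g_leak", "c_m", "r_a_dendrite", "r_a_spine"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def membrane_time_constant(self) -> float:
        """c_m / g_leak in ms (10 ms at the defaults)."""
        return (self.c_m * _PF_PER_UM2) / (self.g_leak * _NS_PER_UM2)


def space_constant(diameter: float, resistivity: float, g_leak: float) -> float:
    """Steady-state space constant λ (µm) of a uniform cylinder:
    λ = sqrt(d / (4·Ra·g_leak)). diameter µm, Ra Ω·cm, g_leak S/cm²."""
    d_cm = diameter * 1e-4
    lam_cm = math.sqrt(d_cm / (4.0 * resistivity * g_leak))
    return lam_cm * 1e4


def _axial_g(diameter: float, length: float, resistivity: float) -> float:
    """Axial conductance (nS) of a cylinder: g = π d² / (4 Ra L)."""
    return 1e5 * math.pi * diameter**2 / (4.0 * resistivity * length)


@dataclass(frozen=True)
class Site:
    """A point on the morphology: section id plus fraction along it."""

    section: int
    position: float = 0.5


@dataclass
class SynapticInput:
    """Conductance-based synaptic source: ``conductance(t)`` returns nS on an
    arbitrary time grid; the synaptic current is g(t)·(V − e_syn) computed
    from the local instantaneous membrane potential."""

    site: Site
    conductance: Callable[[np.ndarray], np.ndarray]
    e_syn: float  # mV


@dataclass
class CurrentInjection:
    """Injected current source (pA, inward-depolarising positive). Either a
    constant step between ``start`` and ``stop`` or an arbitrary waveform."""

    site: Site
    amplitude: float = 0.0
    start: float = 0.0
    stop: float = math.inf
    waveform: Callable[[np.ndarray], np.ndarray] | None = None

    def current(self, t: np.ndarray) -> np.ndarray:
        if self.waveform is not None:
            return np.asarray(self.waveform(t), dtype=float)
        return np.where((t >= self.start) & (t < self.stop), self.amplitude, 0.0)


@dataclass(frozen=True)
class ClampProtocol:
    """Recording protocol. ``voltage_clamp`` pins ``site`` at ``hold`` (an
    ideal clamp unless ``series_resistance`` (MΩ) is given) and reports the
    amplifier current; ``current_clamp`` lets all compartments evolve
    freely."""

    mode: str = "current_clamp"
    site: Site | None = None
    hold: float = -65.0        # mV
    duration: float = 100.0    # ms
    dt: float = 0.025          # ms
    v_init: float | None = None
    method: str = "cn"         # "cn" (Crank-Nicolson) or "be" (backward Euler)
    series_resistance: float | None = None  # MΩ

    def __post_init__(self) -> None:
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown clamp mode {self.mode!r}")
        if not self.dt > 0 or not self.duration > 0:
            raise ValueError("dt and duration must be > 0")
        if self.mode == "voltage_clamp" and self.site is None:
            raise ValueError("voltage clamp needs a site")
        if self.method not in ("cn", "be"):
            raise ValueError("method must be 'cn' or 'be'")


@dataclass
class TraceSet:
    """Simulation output: uniform time grid (ms), per-compartment voltages
    (mV, shape n_comp x n_t) and, under voltage clamp, the amplifier current
    (pA, outward positive at the pipette)."""

    time: np.ndarray
    voltage: np.ndarray
    system: "CompartmentSystem"
    clamp_current: np.ndarray | None = None

    def voltage_at(self, site: Site) -> np.ndarray:
        return self.voltage[self.system.locate(site)]

    def to_frame(self, sites: dict[str, Site] | None = None):
        import pandas as pd

        data = {"time_ms": self.time}
        if sites:
            for name, site in sites.items():
                data[f"v_{name}_mV"] = self.voltage_at(site)
        else:
            for i in range(self.voltage.shape[0]):
                data[f"v_comp{i}_mV"] = self.voltage[i]
        if self.clamp_current is not None:
            data["clamp_current_pA"] = self.clamp_current
        return pd.DataFrame(data)

    def to_hdf5(self, path) -> None:
        """Write the full trace set (time, all voltages, clamp current) to
        an HDF5 file."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_ms", data=self.time)
            fh.create_dataset("voltage_mV", data=self.voltage)
            fh.create_dataset("section_id", data=self.system.comp_section)
            fh.create_dataset("section_position", data=self.system.comp_pos)
            if self.clamp_current is not None:
                fh.create_dataset("clamp_current_pA", data=self.clamp_current)


@dataclass
class AttenuationMap:
    """Per-compartment peak |ΔV| for one stimulation experiment, relative to
    rest; ``attenuation(site)`` is the transmitted fraction peak(site)/
    peak(source) in [0, 1] on a passive tree."""

    system: "CompartmentSystem"
    source: Site
    peak_deflection: np.ndarray  # mV, per compartment

    def attenuation(self, site: Site) -> float:
        src = self.peak_deflection[self.system.locate(self.source)]
        if src == 0:
            return float("nan")
        return float(self.peak_deflection[self.system.locate(site)] / src)


class CompartmentSystem:
    """Discretised morphology: compartment membrane parameters plus the
    axial-coupling graph, ready for implicit integration."""

    def __init__(
        self,
        morphology: Morphology,
        biophysics: BiophysicsConfig,
        comp_section: np.ndarray,
        comp_pos: np.ndarray,
        c: np.ndarray,
        g_m: np.ndarray,
        edges: list[tuple[int, int, float]],
    ) -> None:
        self.morphology = morphology
        self.biophysics = biophysics
        self.comp_section = comp_section  # section id per compartment
        self.comp_pos = comp_pos          # centre fraction along section
        self.c = c                        # pF
        self.g_m = g_m                    # nS (leak)
        self.edges = edges
        self.n = len(c)
        self._by_section: dict[int, np.ndarray] = {}
        for sid in np.unique(comp_section):
            self._by_section[int(sid)] = np.flatnonzero(comp_section == sid)
        # Laplacian of axial coupling + leak conductance on the diagonal
        rows, cols, vals = [], [], []
        for i, j, g in edges:
            rows += [i, j, i, j]
            cols += [j, i, i, j]
            vals += [-g, -g, g, g]
        lap = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n)
        ) if edges else sparse.csr_matrix((self.n, self.n))
        self.G = (lap + sparse.diags(g_m)).tocsr()

    def locate(self, site: Site) -> int:
        """Index of the compartment containing ``site``."""
        if site.section not in self._by_section:
            raise KeyError(f"no section {site.section} in system")
        idx = self._by_section[site.section]
        return int(idx[np.argmin(np.abs(self.comp_pos[idx] - site.position))])

    def total_membrane_conductance(self) -> float:
        return float(self.g_m.sum())

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for a, b, g in self.edges:
            if a == i:
                out.append((b, g))
            elif b == i:
                out.append((a, g))
        return out


def discretize(
    m: Morphology,
    max_compartment_length: float = 5.0,
    biophysics: BiophysicsConfig | None = None,
    lambda_fraction: float = 1.0 / 40.0,
) -> CompartmentSystem:
    """Split each section into compartments no longer than
    ``min(max_compartment_length, λ·lambda_fraction)`` and assemble membrane
    and axial parameters. Membrane densities are multiplied by the section's
    ``density_scale``; the axial path uses the circular-equivalent diameter.
    """
    bio = biophysics or BiophysicsConfig()
    m.validate()
    comp_section: list[int] = []
    comp_pos: list[float] = []
    c: list[float] = []
    g_m: list[float] = []
    edges: list[tuple[int, int, float]] = []
    first_comp: dict[int, int] = {}
    last_comp: dict[int, int] = {}
    comp_len: dict[int, float] = {}

    for sec in m:
        if not sec.diameter > 0:
            raise ValueError(f"section {sec.id}: zero diameter")
        lam = space_constant(sec.diameter, sec.axial_resistivity, bio.g_leak)
        target = min(max_compartment_length, lam * lambda_fraction)
        n_seg = max(1, int(math.ceil(sec.length / target)))
        seg_len = sec.length / n_seg
        area = math.pi * sec.diameter * seg_len * sec.density_scale
        base = len(comp_section)
        for k in range(n_seg):
            comp_section.append(sec.id)
            comp_pos.append((k + 0.5) / n_seg)
            c.append(bio.c_m * _PF_PER_UM2 * area)
            g_m.append(bio.g_leak * _NS_PER_UM2 * area)
            if k > 0:
                g_ax = _axial_g(sec.diameter, seg_len, sec.axial_resistivity)
                edges.append((base + k - 1, base + k, g_ax))
        first_comp[sec.id] = base
        last_comp[sec.id] = base + n_seg - 1
        comp_len[sec.id] = seg_len

        if sec.parent_id is not None:
            parent = m[sec.parent_id]
            pidx = first_comp[parent.id] + min(
                int(sec.parent_position * (last_comp[parent.id] - first_comp[parent.id] + 1)),
                last_comp[parent.id] - first_comp[parent.id],
            )
            # half-compartment resistances in series across the junction
            r_child = 1.0 / _axial_g(sec.diameter, seg_len / 2.0, sec.axial_resistivity)
            r_parent = 1.0 / _axial_g(
                parent.diameter, comp_len[parent.id] / 2.0, parent.axial_resistivity
            )
            edges.append((pidx, base, 1.0 / (r_child + r_parent)))

    return CompartmentSystem(
        m,
        bio,
        np.asarray(comp_section),
        np.asarray(comp_pos),
        np.asarray(c),
        np.asarray(g_m),
        edges,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def simulate(
    system: CompartmentSystem,
    stimuli: Sequence[SynapticInput | CurrentInjection] = (),
    protocol: ClampProtocol | None = None,
) -> TraceSet:
    """Integrate the passive system under the given protocol.

    Implicit θ-method (θ = 0.5 Crank-Nicolson, θ = 1 backward Euler) with
    the synaptic conductances treated implicitly via a Woodbury update of a
    single LU factorisation. Under ideal voltage clamp the clamped
    compartment is pinned to ``hold`` and the amplifier current required to
    do so is reported (sum of leak, axial, synaptic and injected currents at
    the pinned node).
    """
    proto = protocol or ClampProtocol()
    bio = system.biophysics
    n = system.n
    theta = 0.5 if proto.method == "cn" else 1.0
    dt = proto.dt
    nt = int(round(proto.duration / dt)) + 1
    t = np.arange(nt) * dt
    v_init = bio.e_leak if proto.v_init is None else proto.v_init

    syn = [s for s in stimuli if isinstance(s, SynapticInput)]
    inj = [s for s in stimuli if isinstance(s, CurrentInjection)]
    syn_comp = np.array([system.locate(s.site) for s in syn], dtype=int)
    syn_g = np.array([s.conductance(t) for s in syn]) if syn else np.zeros((0, nt))
    if np.any(syn_g < -1e-12):
        raise ValueError("negative synaptic conductance")
    syn_e = np.array([s.e_syn for s in syn])
    inj_comp = np.array([system.locate(s.site) for s in inj], dtype=int)
    inj_i = np.array([s.current(t) for s in inj]) if inj else np.zeros((0, nt))

    clamp_idx = None
    g_series = None
    if proto.mode == "voltage_clamp":
        clamp_idx = system.locate(proto.site)
        if proto.series_resistance is not None:
            g_series = 1e3 / proto.series_resistance  # MΩ -> nS

    C_dt = sparse.diags(system.c / dt)
    A0 = (C_dt + theta * system.G).tocsc()
    M = (C_dt - (1.0 - theta) * system.G).tocsr()
    b_const = system.g_m * bio.e_leak  # pA, leak reversal drive

    ideal_clamp = clamp_idx is not None and g_series is None
    if ideal_clamp:
        A0 = A0.tolil()
        A0[clamp_idx, :] = 0.0
        A0[clamp_idx, clamp_idx] = 1.0
        A0 = A0.tocsc()
    elif g_series is not None:
        # clamp through a series resistance: extra conductance to the hold
        A0 = (A0 + theta * sparse.diags(
            np.bincount([clamp_idx], [g_series], n)
        )).tocsc()

    lu = splu(A0)

    # Woodbury columns for the time-varying synaptic diagonal entries
    active_nodes = sorted(set(int(cpos) for cpos in syn_comp) - (
        {clamp_idx} if ideal_clamp else set()
    ))
    if active_nodes:
        E = np.zeros((n, len(active_nodes)))
        for j, node in enumerate(active_nodes):
            E[node, j] = 1.0
        Z = lu.solve(E)
        Zc = Z[active_nodes, :]

    V = np.empty((n, nt))
    V[:, 0] = v_init
    if clamp_idx is not None and g_series is None:
        V[clamp_idx, 0] = proto.hold
    Iclamp = np.zeros(nt) if clamp_idx is not None else None

    def synaptic_drive(step: int) -> tuple[np.ndarray, np.ndarray]:
        """(diagonal conductance per compartment, current drive g·E_syn)."""
        g_node = np.zeros(n)
        drive = np.zeros(n)
        for j in range(len(syn)):
            g = syn_g[j, step]
            cidx = syn_comp[j]
            g_node[cidx] += g
            drive[cidx] += g * syn_e[j]
        return g_node, drive

    g_prev, drive_prev = synaptic_drive(0)
    for k in range(1, nt):
        g_now, drive_now = synaptic_drive(k)
        rhs = M @ V[:, k - 1]
        rhs -= (1.0 - theta) * g_prev * V[:, k - 1]
        rhs += theta * (b_const + drive_now) + (1.0 - theta) * (b_const + drive_prev)
        if len(inj):
            np.add.at(rhs, inj_comp, theta * inj_i[:, k] + (1 - theta) * inj_i[:, k - 1])
        if g_series is not None:
            rhs[clamp_idx] += g_series * proto.hold
            rhs[clamp_idx] -= (1.0 - theta) * g_series * V[clamp_idx, k - 1]
        if ideal_clamp:
            rhs[clamp_idx] = proto.hold

        if active_nodes:
            g_active = np.array([theta * g_now[node] for node in active_nodes])
            y = lu.solve(rhs)
            on = g_active > 0
            if np.any(on):
                idx = np.flatnonzero(on)
                small = np.diag(1.0 / g_active[idx]) + Zc[np.ix_(idx, idx)]
                yc = y[[active_nodes[i] for i in idx]]
                corr = np.linalg.solve(small, yc)
                y = y - Z[:, idx] @ corr
            V[:, k] = y
        else:
            V[:, k] = lu.solve(rhs)

        if not np.all(np.isfinite(V[:, k])):
            finite = np.abs(V[:, k][np.isfinite(V[:, k])])
            worst = f"{finite.max():.3g}" if finite.size else "nan"
            raise FloatingPointError(
                f"integration diverged at t = {t[k]:.3f} ms "
                f"(max finite |V| = {worst} mV); check dt, stimuli and geometry"
            )
        g_prev, drive_prev = g_now, drive_now

    if clamp_idx is not None:
        if g_series is not None:
            Iclamp = g_series * (proto.hold - V[clamp_idx])
        else:
            # amplifier current = total current leaving the pinned node
            k_ = clamp_idx
            axial = np.zeros(nt)
            for jn, g in system.neighbors(k_):
                axial += g * (V[k_] - V[jn])
            leak = system.g_m[k_] * (V[k_] - bio.e_leak)
            syn_cur = np.zeros(nt)
            for j in range(len(syn)):
                if syn_comp[j] == k_:
                    syn_cur += syn_g[j] * (V[k_] - syn_e[j])
            injected = np.zeros(nt)
            for j in range(len(inj)):
                if inj_comp[j] == k_:
                    injected += inj_i[j]
            Iclamp = leak + axial + syn_cur - injected

    return TraceSet(time=t, voltage=V, system=system, clamp_current=Iclamp)


def input_resistance(system: CompartmentSystem, site: Site) -> float:
    """Steady-state input resistance (MΩ) at a site: ΔV/ΔI for a small test
    current, from the steady-state linear system G·ΔV = I·e."""
    i = system.locate(site)
    rhs = np.zeros(system.n)
    rhs[i] = 1.0  # pA
    dv = spsolve(system.G.tocsc(), rhs)
    return float(dv[i]) * 1e3  # mV/pA = GΩ -> MΩ


def attenuation_map(
    system: CompartmentSystem,
    source_site: Site,
    stimuli: Sequence[SynapticInput | CurrentInjection],
    protocol: ClampProtocol | None = None,
) -> AttenuationMap:
    """Peak |ΔV| over the whole tree for one stimulation experiment under
    current clamp. The attenuation fraction at any site is its peak
    deflection divided by the peak at the source."""
    proto = protocol or ClampProtocol(mode="current_clamp")
    ts = simulate(system, stimuli, proto)
    v0 = system.biophysics.e_leak if proto.v_init is None else proto.v_init
    peaks = np.max(np.abs(ts.voltage - v0), axis=1)
    return AttenuationMap(system=system, source=source_site, peak_deflection=peaks)
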