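"""Synthetic inputs for every pipeline stage: branched pyramidal-cell
morphologies with spines, EM-style synapse tables, IPSC sweeps and trial
ensembles — all seeded and reproducible, so the whole analysis is testable
without any external reconstruction.

The generator emulates the study conditions: ~6 basal dendrites of
100-250 µm with diameters and membrane-density scales derived from the
distal-length relations S(R)/L(R), per-class junction-area ranges spanning
the measured EM tables (soma 0.05-0.45 µm², shaft 0.04-0.18 µm², spine
0.04-0.10 µm²), and trial ensembles drawn from the Bernoulli-sum release
model with a ~5 pA recording-noise floor. What it does not emulate: real
dendritic tortuosity and diameter noise, correlated release, and recording
artefacts beyond additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import (
    Morphology,
    MorphometricRelations,
    Section,
    SpineGeometry,
    attach_spine,
    elliptical_equivalent,
    section_geometry_from_distal_length,
)
from .synapse import KineticSynapseParams, SynapseSite, conductance_waveform
from .traces import IPSCTrace
from .stochastic import TrialEnsemble, simulate_trials
from .cable import Site

__all__ = [
    "SyntheticConfig",
    "make_pyramidal_morphology",
    "make_synapse_table",
    "place_synapses",
    "make_trial_ensemble",
    "make_ipsc_trace",
]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic generators (defaults follow the study
    conditions; area ranges span the per-class EM measurements)."""

    seed: int = 0
    n_basal_dendrites: int = 6
    dendrite_length: tuple[float, float] = (100.0, 250.0)  # µm, uniform
    include_apical: bool = False
    apical_length: float = 400.0
    taper: float = 0.0            # extra per-µm diameter taper fraction
    spine_density: float = 0.0    # spines per µm of basal dendrite
    soma_diameter: float = 15.0   # µm; cylinder with length = diameter
    synapse_counts: dict = field(
        default_factory=lambda: {"soma": 4, "shaft": 1, "spine": 3}
    )
    area_ranges: dict = field(
        default_factory=lambda: {
            "soma": (0.05, 0.45),
            "shaft": (0.04, 0.18),
            "spine": (0.04, 0.10),
        }
    )
    trial_noise_sd: float = 5.0   # pA recording-noise floor
    noise_charge_ms: float = 2.0  # effective ms converting pA noise to fC
    n_trials: int = 60

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _tilted(direction: np.ndarray, angle: float, rng: np.random.Generator) -> np.ndarray:
    """A unit vector at ``angle`` radians from ``direction``."""
    perp = np.cross(direction, _unit_vector(rng))
    n = np.linalg.norm(perp)
    if n < 1e-9:
        perp = np.cross(direction, [1.0, 0.0, 0.0])
        n = np.linalg.norm(perp)
    perp /= n
    out = math.cos(angle) * direction + math.sin(angle) * perp
    return out / np.linalg.norm(out)


def _dendrite_section(
    m: Morphology,
    parent_id: int,
    kind: str,
    length: float,
    distal_length: float,
    origin: np.ndarray,
    direction: np.ndarray,
    relations: MorphometricRelations,
    taper: float,
    n_points: int = 5,
) -> Section:
    """Add one dendritic section whose diameter/density scale come from the
    distal-length relations evaluated at ``distal_length`` (the summed
    dendritic length distal to the section's origin, itself included)."""
    area, circumference = section_geometry_from_distal_length(
        distal_length, relations
    )
    diameter, scale = elliptical_equivalent(area, circumference)
    if taper > 0:
        diameter = max(diameter * (1.0 - taper * length / 2.0), 0.1)
    ts = np.linspace(0.0, 1.0, n_points)
    pts = np.array([origin + t * length * direction for t in ts])
    pts = np.column_stack([pts, np.full(n_points, diameter / 2.0)])
    sec = Section(
        id=m.next_id(),
        parent_id=parent_id,
        kind=kind,
        length=length,
        diameter=diameter,
        density_scale=scale,
        points=pts,
    )
    m.add(sec)
    return sec


def make_pyramidal_morphology(
    cfg: SyntheticConfig | None = None,
    relations: MorphometricRelations | None = None,
) -> Morphology:
    """Soma plus branched, tapered basal dendrites (optional apical trunk
    and spines), SWC-writable with full 3D polylines. Deterministic under
    the config seed."""
    cfg = cfg or SyntheticConfig()
    rel = relations or MorphometricRelations()
    rng = cfg.rng()
    m = Morphology(name=f"synthetic-pyramid-seed{cfg.seed}")
    r_soma = cfg.soma_diameter / 2.0
    m.add(
        Section(
            id=1,
            parent_id=None,
            kind="soma",
            length=cfg.soma_diameter,
            diameter=cfg.soma_diameter,
            points=np.array([[0.0, 0.0, 0.0, r_soma]]),
        )
    )
    lo, hi = cfg.dendrite_length
    for _ in range(cfg.n_basal_dendrites):
        total = float(rng.uniform(lo, hi))
        direction = _unit_vector(rng)
        origin = direction * r_soma
        trunk_len = 0.30 * total
        daughter_len = 0.35 * total
        trunk = _dendrite_section(
            m, 1, "basal", trunk_len, total, origin, direction, rel, cfg.taper
        )
        tip = origin + trunk_len * direction
        for _d in range(2):
            ddir = _tilted(direction, math.radians(30.0), rng)
            _dendrite_section(
                m, trunk.id, "basal", daughter_len, daughter_len, tip, ddir,
                rel, cfg.taper,
            )
    if cfg.include_apical:
        direction = np.array([0.0, 0.0, 1.0])
        origin = direction * r_soma
        half = cfg.apical_length / 2.0
        trunk = _dendrite_section(
            m, 1, "apical", half, cfg.apical_length, origin, direction, rel,
            cfg.taper,
        )
        _dendrite_section(
            m, trunk.id, "apical", half, half, origin + half * direction,
            direction, rel, cfg.taper,
        )
    if cfg.spine_density > 0:
        geom = SpineGeometry()
        for sec in list(m.sections("basal")):
            n_spines = int(round(cfg.spine_density * sec.length))
            for _ in range(n_spines):
                attach_spine(m, sec.id, float(rng.uniform()), geom)
    m.validate()
    return m


def make_synapse_table(
    cfg: SyntheticConfig | None = None,
    morphology: Morphology | None = None,
) -> list[SynapseSite]:
    """EM-style synapse table: per-class areas drawn uniformly within the
    configured ranges; somatic contacts at distance 0, dendritic ones at
    path distances taken from the morphology when given (uniform 5-150 µm
    otherwise)."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    basal = morphology.sections("basal") if morphology is not None else []
    sites: list[SynapseSite] = []
    counters = {"soma": 0, "shaft": 0, "spine": 0}
    prefixes = {"soma": "S", "shaft": "D", "spine": "Sp"}
    for cls in ("soma", "shaft", "spine"):
        count = int(cfg.synapse_counts.get(cls, 0))
        lo, hi = cfg.area_ranges[cls]
        for _ in range(count):
            counters[cls] += 1
            area = float(rng.uniform(lo, hi))
            if cls == "soma":
                dist = 0.0
            elif basal:
                sec = basal[int(rng.integers(len(basal)))]
                pos = float(rng.uniform())
                dist = morphology.path_distance(sec.id, pos)
            else:
                dist = float(rng.uniform(5.0, 150.0))
            sites.append(
                SynapseSite(
                    label=f"{prefixes[cls]}{counters[cls]}",
                    target=cls,
                    junction_area=area,
                    distance_from_soma=dist,
                )
            )
    return sites


def place_synapses(
    m: Morphology,
    sites: list[SynapseSite],
    seed: int = 0,
    spine_geometry: SpineGeometry | None = None,
) -> dict[str, Site]:
    """Map each synapse site onto the morphology: somatic contacts at the
    soma, shaft contacts on a basal section near the stated path distance,
    spine contacts on the head of a spine attached at that distance.
    Modifies ``m`` (spine attachment) and returns {label: Site}."""
    rng = np.random.default_rng(seed)
    geom = spine_geometry or SpineGeometry()
    basal = m.sections("basal")
    if not basal:
        raise ValueError("morphology has no basal dendrites")
    placements: dict[str, Site] = {}
    for s in sites:
        if s.target == "soma":
            placements[s.label] = Site(m.root.id, 0.5)
            continue
        # choose the basal section whose span best covers the stated distance
        best, best_pos, best_err = None, 0.5, math.inf
        order = list(rng.permutation(len(basal)))
        for i in order:
            sec = basal[i]
            d0 = m.path_distance(sec.id, 0.0)
            d1 = m.path_distance(sec.id, 1.0)
            pos = (s.distance_from_soma - d0) / max(d1 - d0, 1e-9)
            pos_c = min(max(pos, 0.0), 1.0)
            err = abs(d0 + pos_c * (d1 - d0) - s.distance_from_soma)
            if err < best_err:
                best, best_pos, best_err = sec, pos_c, err
        if s.target == "shaft":
            placements[s.label] = Site(best.id, best_pos)
        else:
            _neck, head = attach_spine(m, best.id, best_pos, geom)
            placements[s.label] = Site(head, 0.5)
    return placements


def make_trial_ensemble(
    sites: list[SynapseSite],
    cfg: SyntheticConfig | None = None,
) -> tuple[TrialEnsemble, dict]:
    """Synthetic 'recorded' ensemble from the Bernoulli-sum generative model
    plus Gaussian charge noise emulating the recording-noise floor
    (sd = trial_noise_sd × noise_charge_ms, i.e. 5 pA × 2 ms → 10 fC).
    Returns the ensemble and the ground-truth parameters that generated it.
    """
    cfg = cfg or SyntheticConfig()
    noise_fc = cfg.trial_noise_sd * cfg.noise_charge_ms
    ens = simulate_trials(
        sites, n_trials=cfg.n_trials, seed=cfg.seed + 2, noise_sd=noise_fc
    )
    truth = {
        "p": [s.release_p for s in sites],
        "q": [s.charge_i for s in sites],
        "labels": [s.label for s in sites],
        "noise_sd_fC": noise_fc,
    }
    return ens, truth


def make_ipsc_trace(
    params: KineticSynapseParams | None = None,
    onset: float = 5.0,
    duration: float = 100.0,
    dt: float = 0.05,
    holding: float = -65.0,
    g_max: float | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sign: float = -1.0,
    shape: str = "pulse",
) -> IPSCTrace:
    """Synthetic somatic voltage-clamp IPSC sweep: conductance waveform ×
    driving force, inward-negative by default (the recorded convention),
    plus optional Gaussian noise."""
    params = params or KineticSynapseParams()
    t = np.arange(0.0, duration + dt / 2, dt)
    g = conductance_waveform(params, onset, t, g_max=g_max, shape=shape)
    i = sign * g * abs(params.driving_force(holding))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=len(t))
    return IPSCTrace(
        time=t, current=i, presyn_spike_time=max(onset - 1.0, 0.0),
        noise_sd=noise_sd,
    )
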