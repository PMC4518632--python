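"""End-to-end orchestration: run the calibration, Monte Carlo, propagation,
morphometry and trace-analysis stages from a single declarative config and
write per-stage tables plus a machine-readable run manifest.

Config schema (YAML, every key optional — the defaults reproduce the
reference model settings):

    morphology: cs56-like | path/to/cell.swc
    synapse_table: cs56 | cs55 | path/to/table.tsv
    stages: [calibrate, montecarlo, propagation, morphometry, traces]
    seed: 1
    out_dir: results/
    n_trials: 10000
    proximal_threshold_um: 33.0
    rounded_probabilities: true
    q_max_fC: null          # default: the pair's recorded maximal charge
    biophysics: {g_leak: 1.0e-4, c_m: 1.0, r_a_dendrite: 100.0,
                 r_a_spine: 385.0, e_leak: -65.0}
    synapse_kinetics: {pulse_duration: 2.3, tau_rise: 0.45,
                       tau_decay: 14.17, g_max: 1.92, e_syn: -77.5}
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cable import BiophysicsConfig, discretize
from .calibrate import (
    PROXIMAL_THRESHOLD_UM,
    calibrate_sites,
    calibration_report,
    overall_release_probability,
)
from .datasets import ipsc_stat, load_cs55_synapses, load_cs56_synapses
from .morphology import Morphology, read_swc, write_swc
from .morphometry import basket_terminal_proportion, class_area_comparison
from .propagation import run_injection_experiment, summate_synapses
from .stochastic import ks_two_sample, simulate_trials
from .synapse import (
    KineticSynapseParams,
    fit_double_exponential,
    fit_kinetic_params,
    load_synapse_table,
)
from .synthdata import (
    SyntheticConfig,
    make_ipsc_trace,
    make_pyramidal_morphology,
    place_synapses,
)
from .traces import ensemble_stats

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("inhibmap")

_ALL_STAGES = ("calibrate", "montecarlo", "propagation", "morphometry", "traces")


@dataclass
class PipelineConfig:
    morphology: str = "cs56-like"
    synapse_table: str = "cs56"
    stages: tuple = _ALL_STAGES
    seed: int = 1
    out_dir: str = "results"
    n_trials: int = 10_000
    trial_noise_sd_fC: float = 0.0
    proximal_threshold_um: float = PROXIMAL_THRESHOLD_UM
    rounded_probabilities: bool = True
    q_max_fC: float | None = None
    biophysics: dict = field(default_factory=dict)
    synapse_kinetics: dict = field(default_factory=dict)

    def biophysics_config(self) -> BiophysicsConfig:
        return BiophysicsConfig(**self.biophysics)

    def kinetics(self) -> KineticSynapseParams:
        return KineticSynapseParams(**self.synapse_kinetics)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    pass


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _resolve_sites(cfg: PipelineConfig):
    name = cfg.synapse_table
    if name == "cs56":
        return load_cs56_synapses(), "CS56"
    if name == "cs55":
        return load_cs55_synapses(), "CS55"
    p = Path(name)
    if not p.exists():
        raise ConfigError(f"synapse_table: no such file {name!r}")
    return load_synapse_table(p), p.stem


def _resolve_morphology(cfg: PipelineConfig) -> Morphology:
    if cfg.morphology == "cs56-like":
        return make_pyramidal_morphology(SyntheticConfig(seed=cfg.seed))
    p = Path(cfg.morphology)
    if not p.exists():
        raise ConfigError(f"morphology: no such file {cfg.morphology!r}")
    return read_swc(p)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; writes per-stage
    delimited tables under ``cfg.out_dir`` and returns the in-memory
    results keyed by stage."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(cfg.stages) - set(_ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    results: dict = {}
    kinetics = cfg.kinetics()
    bio = cfg.biophysics_config()
    log.info(
        "pipeline start: seed=%d kinetics=%s biophysics=%s",
        cfg.seed, kinetics, bio,
    )

    sites, pair = _resolve_sites(cfg)
    try:
        q_max = cfg.q_max_fC if cfg.q_max_fC is not None else ipsc_stat(pair, "max")
        mean_q = ipsc_stat(pair, "mean")
    except KeyError:
        if cfg.q_max_fC is None:
            raise ConfigError(
                f"no recorded maximal charge for {pair!r}: set q_max_fC"
            )
        q_max, mean_q = cfg.q_max_fC, None

    calibrated, uc = calibrate_sites(
        sites,
        q_max=q_max,
        g_max=kinetics.g_max,
        rounded_probabilities=cfg.rounded_probabilities,
        proximal_threshold=cfg.proximal_threshold_um,
        pair_label=pair,
    )
    if "calibrate" in cfg.stages:
        report = calibration_report(calibrated, uc)
        report.to_csv(out / "calibration.tsv", sep="\t", index=False)
        summary = {
            "pair": pair,
            "q_max_fC": q_max,
            "total_area_um2": round(uc.total_area, 3),
            "q_unit_fC_per_um2": round(uc.q_unit, 1),
        }
        if mean_q is not None:
            summary["overall_release_p"] = round(
                overall_release_probability(mean_q, q_max), 3
            )
        pd.DataFrame([summary]).to_csv(out / "unit_charge.tsv", sep="\t", index=False)
        results["calibrate"] = {"report": report, **summary}
        log.info("calibrate: q_unit=%.1f fC/um2", uc.q_unit)

    if "montecarlo" in cfg.stages:
        proximal = [
            s for s in calibrated
            if s.distance_from_soma <= cfg.proximal_threshold_um
        ]
        ens = simulate_trials(
            proximal, n_trials=cfg.n_trials, seed=cfg.seed,
            noise_sd=cfg.trial_noise_sd_fC,
        )
        stats = ensemble_stats(charges=ens.charges)
        pd.DataFrame({"charge_fC": ens.charges}).to_csv(
            out / "montecarlo_trials.tsv", sep="\t", index=False
        )
        stats.to_frame().to_csv(out / "montecarlo_summary.tsv", sep="\t")
        results["montecarlo"] = {"ensemble": ens, "stats": stats}
        log.info("montecarlo: mean charge %.1f fC over %d trials",
                 stats.mean_charge, ens.n_trials)

    if "propagation" in cfg.stages:
        m = _resolve_morphology(cfg)
        placements = place_synapses(m, calibrated, seed=cfg.seed)
        system = discretize(m, biophysics=bio)
        rows = []
        for s in calibrated:
            summ = run_injection_experiment(
                system, placements[s.label], s.g_max_i, kinetics,
                label=s.label,
            )
            rows.append(
                {
                    "label": s.label,
                    "target": s.target,
                    "gmax_nS": round(s.g_max_i, 3),
                    "peak_v_source_mV": round(summ.peak_v_source, 4),
                    "peak_v_dendrite_mV": round(summ.peak_v_dendrite, 4),
                    "peak_v_soma_mV": round(summ.peak_v_soma, 4),
                    "peak_i_soma_pA": round(summ.peak_i_soma_clamp, 3),
                    "transmitted_to_soma": round(summ.attenuation_to_soma, 4),
                }
            )
        somatic = [s for s in calibrated if s.target == "soma"]
        summation = summate_synapses(
            system,
            [placements[s.label] for s in somatic],
            [s.g_max_i for s in somatic],
            params=kinetics,
        )
        df = pd.DataFrame(rows)
        df.to_csv(out / "propagation.tsv", sep="\t", index=False)
        write_swc(m, out / "model_cell.swc")
        results["propagation"] = {"table": df, "summation": summation}
        log.info("propagation: somatic co-activation peak %.3f mV",
                 summation["combined_peak_mV"])

    if "morphometry" in cfg.stages:
        summary = class_area_comparison(
            [_to_morph_record(s) for s in sites]
        )
        summary.to_csv(out / "morphometry_classes.tsv", sep="\t")
        from .datasets import load_basket_proportions

        props = basket_terminal_proportion(load_basket_proportions())
        props.to_csv(out / "basket_proportions.tsv", sep="\t", index=False)
        results["morphometry"] = {
            "classes": summary,
            "proportions": props,
            "mean_percent": props.attrs["mean_percent"],
        }

    if "traces" in cfg.stages:
        tr = make_ipsc_trace(
            kinetics, noise_sd=0.5, seed=cfg.seed,
            holding=bio.e_leak,
        )
        fit = fit_kinetic_params(tr.time, tr.current, holding=bio.e_leak,
                                 e_syn=kinetics.e_syn)
        dexp = fit_double_exponential(tr.time, tr.current)
        df = pd.DataFrame(
            [
                {
                    "fitted_tau_rise_ms": round(fit.tau_rise, 3),
                    "fitted_tau_decay_ms": round(fit.tau_decay, 3),
                    "fitted_gmax_nS": round(fit.g_max, 3),
                    "decay_tau_fast_ms": round(dexp["tau_fast"], 3),
                    "decay_tau_slow_ms": round(dexp["tau_slow"], 3),
                    "amplitude_pA": round(dexp["amplitude"], 2),
                }
            ]
        )
        df.to_csv(out / "trace_fits.tsv", sep="\t", index=False)
        results["traces"] = {"kinetic_fit": fit, "double_exp": dexp}

    manifest = {
        "package": "inhibmap",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": list(cfg.stages),
        "pair": pair,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results


def _to_morph_record(site):
    from .morphometry import SynapseMorphometryRecord

    # the EM synapse tables carry no target-size covariate; use a unit
    # placeholder so class comparisons (which ignore it) still run
    size = None if site.target == "soma" else 1.0
    return SynapseMorphometryRecord(
        junction_area=site.junction_area,
        target_class=site.target,
        target_size=size,
    )
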