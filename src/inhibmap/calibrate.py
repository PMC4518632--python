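"""EM-area calibration: unit charge, per-synapse charge and conductance,
and release probabilities from junction area.

The calibration rests on one empirical constant per connection, the *unit
IPSC electric charge*: the maximal IPSC charge (all proximal terminals
releasing) divided by the summed junction area of those terminals. For the
reference pairs it is 326.1 fC / 0.950 µm² = 343.3 fC·µm⁻² and
1057.8 fC / 3.011 µm² = 351.3 fC·µm⁻² — similar enough to treat inhibitory
charge as proportional to junction area. Each synapse's charge is then
area × unit charge, its peak conductance is the unitary maximal conductance
(1.92 nS) split by area share, and its release probability comes from a
terminal-size→release-probability line rescaled to match the recorded
overall release probability:

    p(area) = 3.271 · 0.68 · area + 0.018     (clipped to [0, 1])

which, rounded to the nearest 0.05, reproduces the per-synapse values used
in the Monte Carlo release simulations (0.80/0.40/0.45/0.55 for the four
somatic junctions of the reference pair).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synapse import SynapseSite, scale_gmax

__all__ = [
    "UnitCharge",
    "ReleaseProbabilityLine",
    "unit_charge",
    "per_synapse_charge",
    "release_probability",
    "overall_release_probability",
    "round_to_nearest",
    "calibrate_sites",
    "calibration_report",
    "PROXIMAL_THRESHOLD_UM",
]

#: Path distance (µm) within which dendritic/spine terminals are pooled
#: with somatic ones as contributors to the somatically recorded IPSC.
PROXIMAL_THRESHOLD_UM = 33.0


@dataclass(frozen=True)
class UnitCharge:
    """IPSC charge transferred per µm² of synaptic junction area."""

    q_max: float        # fC, maximal IPSC charge
    total_area: float   # µm², summed junction area of contributing terminals
    pair_label: str = ""

    @property
    def q_unit(self) -> float:
        return self.q_max / self.total_area


@dataclass(frozen=True)
class ReleaseProbabilityLine:
    """Area→release-probability line: p = base_slope·scale·area + intercept.

    ``base_slope`` is the slope of the terminal-size/release-probability
    relation taken from calyx-type excitatory data; ``scale`` rescales it so
    the line reproduces the overall release probability measured in the
    paired recordings."""

    base_slope: float = 3.271   # per µm²
    scale: float = 0.68
    intercept: float = 0.018

    @property
    def slope(self) -> float:
        return self.base_slope * self.scale

    def __call__(self, area: float) -> float:
        return float(np.clip(self.slope * area + self.intercept, 0.0, 1.0))


def unit_charge(q_max: float, areas, pair_label: str = "") -> UnitCharge:
    """Unit electric charge from the maximal IPSC charge and the junction
    areas of the terminals assumed to generate it."""
    if not q_max > 0:
        raise ValueError("q_max must be > 0")
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one junction area")
    total = float(areas.sum())
    if not total > 0:
        raise ValueError("total junction area must be > 0")
    return UnitCharge(q_max=q_max, total_area=total, pair_label=pair_label)


def per_synapse_charge(site_area: float, q_unit: UnitCharge | float) -> float:
    """Electric charge (fC) assigned to one synapse: junction area × unit
    charge."""
    if site_area < 0:
        raise ValueError("junction area must be >= 0")
    q = q_unit.q_unit if isinstance(q_unit, UnitCharge) else float(q_unit)
    return site_area * q


def release_probability(
    area: float,
    line: ReleaseProbabilityLine | None = None,
    rounded: bool = False,
) -> float:
    """Release probability assigned to a junction of the given area; with
    ``rounded=True`` the value is rounded to the nearest 0.05 (the
    convention used when quoting per-synapse probabilities)."""
    if area < 0:
        raise ValueError("junction area must be >= 0")
    line = line or ReleaseProbabilityLine()
    p = line(area)
    return round_to_nearest(p, 0.05) if rounded else p


def round_to_nearest(x: float, step: float) -> float:
    """Round to the nearest multiple of ``step`` (half away from zero)."""
    return float(np.floor(x / step + 0.5) * step)


def overall_release_probability(mean_charge: float, max_charge: float) -> float:
    """Connection-level release probability: average IPSC charge divided by
    the maximal (all-terminals-release) charge."""
    if not 0 < mean_charge <= max_charge:
        raise ValueError("need 0 < mean_charge <= max_charge")
    return mean_charge / max_charge


def calibrate_sites(
    sites: list[SynapseSite],
    q_max: float,
    g_max: float = 1.92,
    reference_area: float | None = None,
    line: ReleaseProbabilityLine | None = None,
    rounded_probabilities: bool = True,
    proximal_threshold: float = PROXIMAL_THRESHOLD_UM,
    pair_label: str = "",
) -> tuple[list[SynapseSite], UnitCharge]:
    """Full calibration of a synapse table.

    The unit charge is computed over the proximal terminals (path distance
    ≤ ``proximal_threshold``), the ones assumed to generate the somatically
    recorded maximal IPSC. Every site then gets charge = area × unit charge,
    g_max_i = g_max × area / reference_area (reference defaults to the
    summed somatic junction area) and a release probability from the line.
    Returns calibrated copies of the sites plus the :class:`UnitCharge`.
    """
    proximal = [s for s in sites if s.distance_from_soma <= proximal_threshold]
    if not proximal:
        raise ValueError("no proximal synapses within the threshold")
    uc = unit_charge(q_max, [s.junction_area for s in proximal], pair_label)
    if reference_area is None:
        soma_areas = [s.junction_area for s in sites if s.target == "soma"]
        if not soma_areas:
            raise ValueError("no somatic synapses to define the reference area")
        reference_area = float(sum(soma_areas))
    out = []
    for s in sites:
        out.append(
            replace(
                s,
                charge_i=per_synapse_charge(s.junction_area, uc),
                g_max_i=scale_gmax(s.junction_area, reference_area, g_max),
                release_p=release_probability(
                    s.junction_area, line, rounded=rounded_probabilities
                ),
            )
        )
    return out, uc


def calibration_report(
    sites: list[SynapseSite], uc: UnitCharge | None = None
) -> pd.DataFrame:
    """Per-synapse calibration table (one row per contact, columns mirroring
    the EM synapse-property tables)."""
    rows = [
        {
            "label": s.label,
            "target": s.target,
            "area_um2": s.junction_area,
            "charge_fC": None if s.charge_i is None else round(s.charge_i, 1),
            "gmax_nS": None if s.g_max_i is None else round(s.g_max_i, 2),
            "release_p": None if s.release_p is None else round(s.release_p, 3),
            "distance_um": s.distance_from_soma,
        }
        for s in sites
    ]
    df = pd.DataFrame(rows)
    if uc is not None:
        df.attrs["q_unit_fC_per_um2"] = uc.q_unit
        df.attrs["q_max_fC"] = uc.q_max
        df.attrs["total_area_um2"] = uc.total_area
    return df
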