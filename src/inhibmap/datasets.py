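"""Bundled reference tables from the serial-EM / paired-recording dataset:
per-synapse junction areas and distances for the two fully reconstructed
connections (CS56, CS55), their IPSC ensemble summaries, the unit-IPSC
calibration table and the basket-terminal proportions across all pairs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .synapse import SynapseSite, load_synapse_table

__all__ = [
    "fixture_path",
    "load_cs56_synapses",
    "load_cs55_synapses",
    "load_ipsc_summary",
    "load_unit_ipsc",
    "load_basket_proportions",
]


def fixture_path(name: str):
    """Filesystem path of a bundled data file."""
    return resources.files("inhibmap.data") / name


def load_cs56_synapses() -> list[SynapseSite]:
    """EM synapse table of pair CS56: 4 somatic, 1 shaft and 3 spine
    contacts (µm², µm)."""
    return load_synapse_table(fixture_path("cs56_synapses.tsv"))


def load_cs55_synapses() -> list[SynapseSite]:
    """EM synapse table of pair CS55: 13 perisomatic plus 11 dendritic/spine
    contacts."""
    return load_synapse_table(fixture_path("cs55_synapses.tsv"))


def load_ipsc_summary() -> pd.DataFrame:
    """Recorded IPSC ensemble summaries per pair (mean/sd/max/min charge and
    peak, trial counts)."""
    return pd.read_csv(fixture_path("ipsc_summary.tsv"), sep="\t")


def ipsc_stat(pair: str, stat: str, column: str = "charge_fC") -> float:
    """One entry of the IPSC summary, e.g. ipsc_stat('CS56', 'max')."""
    df = load_ipsc_summary()
    row = df[(df["pair"] == pair) & (df["stat"] == stat)]
    if row.empty:
        raise KeyError(f"no {stat!r} entry for pair {pair!r}")
    return float(row.iloc[0][column])


def load_unit_ipsc() -> pd.DataFrame:
    """Unit-IPSC calibration table: maximal charge and summed junction area
    per pair (the printed totals)."""
    return pd.read_csv(fixture_path("unit_ipsc.tsv"), sep="\t")


def load_basket_proportions() -> pd.DataFrame:
    """Basket-terminal counts per recorded pair (soma-targeting terminals
    vs all boutons)."""
    return pd.read_csv(fixture_path("basket_proportions.tsv"), sep="\t")
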