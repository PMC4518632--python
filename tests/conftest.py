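import numpy as np
import pytest

from inhibmap.cable import Site, discretize
from inhibmap.calibrate import calibrate_sites
from inhibmap.datasets import ipsc_stat, load_cs56_synapses
from inhibmap.morphology import attach_spine
from inhibmap.synthdata import SyntheticConfig, make_pyramidal_morphology


@pytest.fixture(scope="session")
def cs56_sites():
    """CS56 synapse table with calibrated charges, conductances and rounded
    release probabilities."""
    sites, uc = calibrate_sites(
        load_cs56_synapses(), q_max=ipsc_stat("CS56", "max"), pair_label="CS56"
    )
    return sites


@pytest.fixture(scope="session")
def cs56_somatic(cs56_sites):
    return [s for s in cs56_sites if s.target == "soma"]


@pytest.fixture(scope="session")
def spiny_model():
    """Small synthetic pyramidal cell with one instrumented spine: returns
    (compartment system, spine-head site, parent shaft site)."""
    m = make_pyramidal_morphology(SyntheticConfig(seed=7, n_basal_dendrites=4))
    shaft = m.sections("basal")[1]
    _neck, head = attach_spine(m, shaft.id, 0.5)
    system = discretize(m)
    return system, Site(head, 0.5), Site(shaft.id, 0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
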