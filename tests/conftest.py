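import numpy as np
import pandas as pd
import pytest

from methpop.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort: shifts, heritable sites, mSNPs,
    population-specific mSNPs and artifact probes all planted."""
    cfg = SimConfig(
        n_trios_per_pop=10,
        n_sites=120,
        n_snps=360,
        n_msnp_sites=8,
        frac_pop_shift_sites=0.1,
        frac_heritable_sites=0.1,
        frac_probe_overlap=0.1,
        seed=42,
    )
    return simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects at all: every site is pure noise."""
    cfg = SimConfig(
        n_trios_per_pop=10,
        n_sites=200,
        n_snps=400,
        n_msnp_sites=0,
        frac_pop_shift_sites=0.0,
        frac_heritable_sites=0.0,
        frac_probe_overlap=0.0,
        seed=7,
    )
    return simulate_cohort(cfg), cfg
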