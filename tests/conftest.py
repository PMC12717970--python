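from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mutload.variant_io import (
    GenotypeMatrix,
    PolarizedSiteTable,
    PopulationAssignment,
)


def make_matrix(dosage, accessions=None, chrom="chr01", start_pos=100, step=100):
    """GenotypeMatrix from a (sites x accessions) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_acc = dosage.shape
    if accessions is None:
        accessions = [f"acc{i}" for i in range(n_acc)]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + step * np.arange(n_sites),
            "ref": "A",
            "alt": "G",
            "is_indel": False,
            "is_multiallelic": False,
        }
    )
    return GenotypeMatrix(accessions=list(accessions), sites=sites, dosage=dosage)


def make_polarized(dosage, accessions=None, chrom="chr01", start_pos=100, step=100,
                   status="ok"):
    """PolarizedSiteTable straight from a derived-dosage array (all ok)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_acc = dosage.shape
    if accessions is None:
        accessions = [f"acc{i}" for i in range(n_acc)]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + step * np.arange(n_sites),
            "ref": "A",
            "alt": "G",
            "ancestral": "A",
            "derived": "G",
            "status": status,
        }
    )
    return PolarizedSiteTable(
        accessions=list(accessions), sites=sites, derived_dosage=dosage
    )


def make_categories(polarized, labels):
    """Category frame aligned with a polarized table."""
    return pd.DataFrame(
        {
            "chrom": polarized.sites["chrom"],
            "pos": polarized.sites["pos"],
            "ancestral": polarized.sites["ancestral"],
            "derived": polarized.sites["derived"],
            "category": list(labels),
            "sift_label": pd.NA,
            "provean_score": np.nan,
        }
    )


def make_assignment(mapping, outgroup=None):
    mapping = dict(mapping)
    if outgroup is None:
        outgroup = "OG"
        mapping.setdefault("OG", "outgroup")
    return PopulationAssignment(mapping=mapping, outgroup=outgroup)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """One small two-population simulation shared by several tests."""
    from mutload.simulate import DemographyEpoch, SimConfig, simulate_populations

    cfg = SimConfig(
        seed=7,
        n_sites=600,
        n_generations=60,
        n_chromosomes=3,
        chrom_length=300_000,
        mut_rate=2e-4,
        init_freq=0.1,
        sel_coeff=-0.05,
        epochs={
            "wild": [DemographyEpoch(0, 60)],
            "dom": [DemographyEpoch(30, 12, source_pop="wild")],
        },
        selfing_rate={"wild": 0.0, "dom": 0.8},
        n_sampled={"wild": 10, "dom": 8},
    )
    return simulate_populations(cfg)
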