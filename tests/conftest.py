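import numpy as np
import pytest

from pedflow.genome import GenomeMap, PedigreeGraph
from pedflow.simulate import SimConfig, simulate_pedigree_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_pedigree():
    ped = PedigreeGraph()
    ped.add_accession("A", "exotic_founder")
    ped.add_accession("B", "exotic_founder")
    ped.add_accession("C", "backbone", ["A", "B"])
    return ped


def make_trio(seed=5, length=10_000_000, n_snps=10_000, recomb=30.0, **kw):
    """A two-parent cross on one chromosome, returning (gm, haps, truth, cfg)."""
    ped = PedigreeGraph()
    ped.add_accession("A", "exotic_founder")
    ped.add_accession("B", "exotic_founder")
    ped.add_accession("C", "backbone", ["A", "B"])
    genome = GenomeMap([("A01", length)])
    cfg = SimConfig(
        genome=genome,
        snp_count={"A01": n_snps},
        pedigree=ped,
        recomb_rate=recomb,
        seed=seed,
        **kw,
    )
    gm, haps, truth = simulate_pedigree_genotypes(cfg)
    return gm, haps, truth, cfg
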