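import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from poolgen import HerdConfig, LocusSpec, TraitSpec, simulate_genotypes, simulate_traits

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# the study population: 640 head, two low-frequency InDels, mutant-allele
# frequencies and sex composition matching the cohort the package emulates
PAPER_SEXES = {"male": 172, "female": 466, "missing": 2}
P1 = LocusSpec("P1-Ins-4-bp", mutant_allele="I", mutant_freq=0.052)
P2 = LocusSpec("P2-Del-8-bp", mutant_allele="D", mutant_freq=0.009)


@pytest.fixture
def paper_config():
    return HerdConfig(
        n_individuals=640,
        sex_counts=dict(PAPER_SEXES),
        loci=[P1, P2],
        d_prime=1.0,
        seed=20230412,
    )


@pytest.fixture
def paper_herd(paper_config):
    return simulate_genotypes(paper_config)


@pytest.fixture
def beef_shoulder_spec():
    # heterozygotes heavier than the common homozygote, moments as reported
    # for the female stratum (common homozygote at this locus is DD)
    return TraitSpec(
        name="beef_shoulder",
        locus="P1-Ins-4-bp",
        genotype_params={"ID": (1.30, 0.1, 29), "DD": (1.02, 0.02, 163)},
        sex_restriction="female",
    )


@pytest.fixture
def herd_with_trait(paper_herd, beef_shoulder_spec):
    return simulate_traits(paper_herd, [beef_shoulder_spec], seed=11)
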