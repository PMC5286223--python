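import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from telodrip import (
    CohortDesign,
    CompositionBlock,
    LocusSpec,
    SubtelomereRecord,
    SyntheticSubteloConfig,
    make_subtelomere,
)

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def simple_record():
    """A 2 kb uniform-composition record with 40 telomere repeats and full
    annotations (TSS at 1000, amplicon 1300-1400)."""
    cfg = SyntheticSubteloConfig(
        record_id="testq",
        blocks=[CompositionBlock(2000, 0.25, 0.25, 0.25, 0.25)],
        telomere_repeats=40,
        tss_pos=1000,
        promoter=(850, 1000),
        amplicon=(1300, 1400),
        seed=7,
    )
    record, truth = make_subtelomere(cfg)
    return record, truth


def tfree_record(record_id="acq", planted_sites=(), seed=11, g=0.3, c=0.2,
                 telomere_repeats=40, tss_pos=1000, amplicon=(1300, 1400)):
    """Record whose subtelomeric portion contains no T, hence no cocktail or
    HinfI recognition site (all six sites contain a T) other than the
    planted ones — a controlled background for digestion tests."""
    cfg = SyntheticSubteloConfig(
        record_id=record_id,
        blocks=[CompositionBlock(2000, g, c, 1 - g - c, 0.0)],
        telomere_repeats=telomere_repeats,
        planted_sites=list(planted_sites),
        tss_pos=tss_pos,
        promoter=(850, 1000),
        amplicon=amplicon,
        seed=seed,
    )
    return make_subtelomere(cfg)


@pytest.fixture
def basic_design():
    return CohortDesign(
        loci=[
            LocusSpec("10q", level_wt=1.0, level_icf=3.0, telomere_linked=True),
            LocusSpec("4p", level_wt=0.5, level_icf=0.5, telomere_linked=False),
        ],
        n_wt=4, n_icf=4,
        rnaseh_ablation=0.05, hinfi_linked_reduction=0.3,
        ct_noise_sd=0.0, seed=1,
    )
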