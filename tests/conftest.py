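import numpy as np
import pytest

from guqtl.locus import (
    CovariateModel,
    EffectDef,
    GeneDef,
    LDBlock,
    LocusModel,
    SNVDef,
    SVAllele,
    SVDef,
    default_model,
)
from guqtl.simulate import simulate_haplotypes


def make_tiny_model(
    del_freq: float = 0.4,
    effect: float = 1.8,
    platform_effect: tuple[float, float, float] = (1.0, 1.05, 0.95),
) -> LocusModel:
    """A hand-sized locus: 4 V + 3 D + 2 J genes, one deletion SV over one D
    gene with two SNVs inside its span, three LD blocks outside, and one cis
    effect on a V gene."""
    genes = [
        GeneDef("IGHJ4", "J", 1_000),
        GeneDef("IGHJ6", "J", 2_000),
        GeneDef("IGHD3-10", "D", 10_000),
        GeneDef("IGHD3-22", "D", 12_000),
        GeneDef("IGHD2-2", "D", 14_000),
        GeneDef("IGHV1-2", "V", 30_000),
        GeneDef("IGHV3-7", "V", 40_000),
        GeneDef("IGHV4-34", "V", 50_000),
        GeneDef("IGHV3-53", "V", 60_000),
    ]
    sv = SVDef(
        id="sv_del",
        span=(13_500, 14_500),
        alleles=(
            SVAllele("REF", 1.0 - del_freq, {"IGHD2-2": 1}),
            SVAllele("DEL", del_freq, {"IGHD2-2": 0}, deletes_snvs=True),
        ),
    )
    blocks = [
        LDBlock("b0", (0.6, 0.4)),
        LDBlock("b1", (0.5, 0.5)),
        LDBlock("b2", (0.7, 0.2, 0.1)),
        LDBlock("b_in_sv", (0.5, 0.5)),
    ]
    snvs = [
        SNVDef("s0a", 31_000, "b0", (1,)),
        SNVDef("s0b", 31_100, "b0", (1,)),
        SNVDef("s1a", 41_000, "b1", (1,)),
        SNVDef("s2a", 51_000, "b2", (1,)),
        SNVDef("s2b", 51_100, "b2", (1, 2)),
        SNVDef("in_sv_1", 13_900, "b_in_sv", (1,), containing_sv="sv_del"),
        SNVDef("in_sv_2", 14_100, "b_in_sv", (1,), containing_sv="sv_del"),
    ]
    baseline = {g.name: 1.0 for g in genes}
    baseline["IGHV1-2"] = 2.0
    model = LocusModel(
        genes=genes,
        sv_defs=[sv],
        blocks=blocks,
        snv_defs=snvs,
        effect_map=[EffectDef("s0a", "IGHV3-53", effect)],
        baseline_weights=baseline,
        covariate_model=CovariateModel(
            platform_effect={"IGHV3-7": platform_effect}
        ),
        coding_tag={g.name: "b1" for g in genes},
    )
    model.validate()
    return model


@pytest.fixture(scope="session")
def tiny_model():
    return make_tiny_model()


@pytest.fixture(scope="session")
def tiny_cohort(tiny_model):
    return simulate_haplotypes(tiny_model, 120, seed=7)


@pytest.fixture(scope="session")
def default_locus_model():
    return default_model()


@pytest.fixture(scope="session")
def default_cohort(default_locus_model):
    return simulate_haplotypes(default_locus_model, 150, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
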