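import pytest
from hypothesis import settings

from mrscore import (
    ConversionConstants,
    PooledEstimate,
    VariantPanel,
    ivw_combine,
    load_ld_flags,
    load_table1,
    load_table2,
    wald_ratio,
)

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# Published tables were built with 2-decimal rounding; 1.96 matches them.
TABLE_CONSTANTS = ConversionConstants(z_95=1.96)


@pytest.fixture(scope="session")
def constants() -> ConversionConstants:
    return TABLE_CONSTANTS


@pytest.fixture(scope="session")
def table1(constants) -> VariantPanel:
    return load_table1(constants)


@pytest.fixture(scope="session")
def table2(constants) -> VariantPanel:
    return load_table2(constants)


@pytest.fixture(scope="session")
def ld_flags():
    return load_ld_flags()


def score_panel(
    exposure_panel: VariantPanel,
    outcome_panel: VariantPanel,
    trait: str,
    variants: list[str],
    z: float = TABLE_CONSTANTS.z_95,
) -> PooledEstimate:
    """IVW genetic score for one outcome trait over the given variants.

    Exposure (LDL-C) records come from ``exposure_panel``; outcome records
    from ``outcome_panel``.  Records are already oriented to the lowering
    allele in the packaged fixtures.
    """
    scaled = []
    for vid in variants:
        exposure = exposure_panel.get(vid, "LDL-C")
        outcome = outcome_panel.get(vid, trait)
        scaled.append(
            wald_ratio(outcome.beta, outcome.se, exposure.beta, variant_id=vid, trait=trait)
        )
    return ivw_combine(scaled, z=z, trait=trait)
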