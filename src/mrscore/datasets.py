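"""Packaged summary-statistics fixtures.

The package ships the published per-variant associations of six PCSK9
variants (per effect allele, effect alleles being the LDL-lowering ones):

* ``table1.tsv`` — LDL-C (mmol/L), coronary heart disease and ischaemic
  stroke, per variant;
* ``table2.tsv`` — cardioembolic, large-artery and small-vessel ischaemic
  stroke subtypes, per variant;
* ``ld_flags.tsv`` — qualitative D' > 0.6 flags of each variant against
  the index loss-of-function variant rs11591147 (numeric D'/r-squared for
  this panel were never published).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .effects import ConversionConstants, DEFAULT_CONSTANTS
from .ld import LdRecord, read_ld_flags
from .sumstats import VariantPanel, read_sumstats

__all__ = ["fixture_path", "load_table1", "load_table2", "load_ld_flags", "INDEX_VARIANT"]

INDEX_VARIANT = "rs11591147"


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (``table1.tsv`` etc.)."""
    path = resources.files("mrscore").joinpath("data", name)
    return Path(str(path))


def load_table1(constants: ConversionConstants = DEFAULT_CONSTANTS) -> VariantPanel:
    """Six-variant panel with LDL-C, CHD and IS associations."""
    return read_sumstats(fixture_path("table1.tsv"), constants=constants, index_variant=INDEX_VARIANT)


def load_table2(constants: ConversionConstants = DEFAULT_CONSTANTS) -> VariantPanel:
    """Six-variant panel with the three ischaemic-stroke subtypes."""
    return read_sumstats(fixture_path("table2.tsv"), constants=constants, index_variant=INDEX_VARIANT)


def load_ld_flags() -> list[LdRecord]:
    """Qualitative D'-threshold flags against the index variant."""
    return read_ld_flags(fixture_path("ld_flags.tsv"))
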