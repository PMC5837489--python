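"""Summary-statistics data model and tab-delimited I/O.

A :class:`VariantAssociation` holds one variant x one trait: the per-allele
effect with its uncertainty, the allele pair, the effect-allele frequency,
sample sizes and units.  A :class:`VariantPanel` groups associations for a
set of variants, optionally tagging an index variant used as the reference
for LD-independence decisions.

File format ("v1" dialect): tab-separated, fixed header::

    variant_id  effect_allele  other_allele  eaf  trait  measure  estimate
    ci_lower  ci_upper  se  n_case  n_control  n_total  unit

Odds ratios and their CI bounds are stored on the published (OR) scale and
converted to natural-log odds in memory, so fixture files remain visually
checkable against printed tables.  Frequencies may be written either as
proportions (``0.015``) or percentages (``1.5%``).  Missing optional values
are encoded as ``NA``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .effects import (
    ConversionConstants,
    DEFAULT_CONSTANTS,
    ci_to_se,
    ci_to_se_linear,
    or_to_logor,
)
from .errors import SchemaError, ValidationError

__all__ = [
    "VariantAssociation",
    "VariantPanel",
    "read_sumstats",
    "write_sumstats",
    "COLUMNS",
]

COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "trait",
    "measure",
    "estimate",
    "ci_lower",
    "ci_upper",
    "se",
    "n_case",
    "n_control",
    "n_total",
    "unit",
]

_MANDATORY = ["variant_id", "effect_allele", "other_allele", "eaf", "trait", "measure", "estimate", "unit"]
_ALLELES = frozenset("ACGT")
_MEASURES = frozenset({"beta_continuous", "log_odds"})
_UNITS = frozenset({"sd", "mmol_per_l", "log_or"})
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclass
class VariantAssociation:
    """One variant x one trait association on the analysis scale.

    ``beta`` is the per-allele effect: mmol/L for ``beta_continuous``
    records and natural-log odds for ``log_odds`` records.  CI bounds, when
    present, stay on the published scale (OR scale for ``log_odds``).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    trait: str
    measure: str
    beta: float
    se: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    n_case: Optional[int] = None
    n_control: Optional[int] = None
    n_total: Optional[int] = None
    unit: str = "log_or"

    def validate(self) -> None:
        if self.effect_allele not in _ALLELES or self.other_allele not in _ALLELES:
            raise ValidationError(
                f"{self.variant_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: effect and other allele identical")
        if self.measure not in _MEASURES:
            raise ValidationError(f"{self.variant_id}: unknown measure {self.measure!r}")
        if self.unit not in _UNITS:
            raise ValidationError(f"{self.variant_id}: unknown unit {self.unit!r}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")
        if self.se is not None and not self.se > 0:
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if self.ci_lower is not None and self.ci_upper is not None:
            if not self.ci_lower < self.ci_upper:
                raise ValidationError(
                    f"{self.variant_id}: CI bounds inverted ({self.ci_lower}, {self.ci_upper})"
                )
            if self.measure == "log_odds" and self.ci_lower <= 0:
                raise ValidationError(
                    f"{self.variant_id}: OR-scale CI bounds must be positive"
                )
        if self.se is None and (self.ci_lower is None or self.ci_upper is None):
            raise ValidationError(
                f"{self.variant_id} ({self.trait}): need se or a complete CI"
            )
        if {self.effect_allele, self.other_allele} in _PALINDROMIC:
            warnings.warn(
                f"{self.variant_id}: palindromic allele pair "
                f"{self.effect_allele}/{self.other_allele}; strand ambiguity unresolved",
                stacklevel=2,
            )


@dataclass
class VariantPanel:
    """An ordered collection of associations, at most one per (variant, trait)."""

    associations: list[VariantAssociation] = field(default_factory=list)
    index_variant: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        alleles: dict[str, frozenset[str]] = {}
        for a in self.associations:
            key = (a.variant_id, a.trait)
            if key in seen:
                raise ValidationError(f"duplicate record for variant {key[0]}, trait {key[1]}")
            seen.add(key)
            pair = frozenset((a.effect_allele, a.other_allele))
            if alleles.setdefault(a.variant_id, pair) != pair:
                raise ValidationError(
                    f"{a.variant_id}: inconsistent allele pairs across traits"
                )

    def variant_ids(self) -> list[str]:
        """Unique variant IDs in first-appearance order."""
        out: list[str] = []
        for a in self.associations:
            if a.variant_id not in out:
                out.append(a.variant_id)
        return out

    def traits(self) -> list[str]:
        out: list[str] = []
        for a in self.associations:
            if a.trait not in out:
                out.append(a.trait)
        return out

    def get(self, variant_id: str, trait: str) -> VariantAssociation:
        for a in self.associations:
            if a.variant_id == variant_id and a.trait == trait:
                return a
        raise KeyError(f"no record for variant {variant_id!r}, trait {trait!r}")

    def subset(self, *, trait: Optional[str] = None, variants: Optional[Iterable[str]] = None) -> "VariantPanel":
        keep = list(variants) if variants is not None else None
        assocs = [
            a
            for a in self.associations
            if (trait is None or a.trait == trait)
            and (keep is None or a.variant_id in keep)
        ]
        return VariantPanel(assocs, index_variant=self.index_variant)

    def merge(self, other: "VariantPanel") -> "VariantPanel":
        return VariantPanel(
            self.associations + other.associations,
            index_variant=self.index_variant or other.index_variant,
        )

    def __len__(self) -> int:
        return len(self.associations)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{f.name: getattr(a, f.name) for f in fields(a)} for a in self.associations])


def _parse_float(raw: str, column: str, row: int) -> Optional[float]:
    if raw == "NA" or raw == "":
        return None
    text = raw.strip()
    percent = text.endswith("%")
    if percent:
        text = text[:-1]
    try:
        value = float(text)
    except ValueError as exc:
        raise ValidationError(f"row {row}: cannot parse {column}={raw!r}") from exc
    return value / 100.0 if percent else value


def _parse_int(raw: str, column: str, row: int) -> Optional[int]:
    if raw == "NA" or raw == "":
        return None
    try:
        return int(raw)
    except ValueError as exc:
        raise ValidationError(f"row {row}: cannot parse {column}={raw!r}") from exc


def read_sumstats(
    path: str | Path,
    dialect: str = "v1",
    constants: ConversionConstants = DEFAULT_CONSTANTS,
    index_variant: Optional[str] = None,
) -> VariantPanel:
    """Read a tab-delimited summary-statistics file into a validated panel.

    After loading, every record carries a populated ``se``: records shipped
    with only a 95% CI get their standard error reconstructed with
    ``constants.z_95`` (log scale for odds ratios, linear scale otherwise).
    Row order is preserved.

    Raises
    ------
    SchemaError
        If the dialect is unknown or a mandatory column is missing.
    ValidationError
        On unparseable or out-of-range values (message carries the
        1-based data row number) and duplicate (variant, trait) pairs.
    """
    if dialect != "v1":
        raise SchemaError(f"unknown sumstats dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _MANDATORY:
        if column not in frame.columns:
            raise SchemaError(f"missing mandatory column {column!r}")
    associations: list[VariantAssociation] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        get = lambda col: getattr(row, col, "NA")  # noqa: E731
        measure = get("measure")
        estimate = _parse_float(get("estimate"), "estimate", i)
        if estimate is None:
            raise ValidationError(f"row {i}: estimate is mandatory")
        ci_lower = _parse_float(get("ci_lower"), "ci_lower", i)
        ci_upper = _parse_float(get("ci_upper"), "ci_upper", i)
        se = _parse_float(get("se"), "se", i)
        eaf = _parse_float(get("eaf"), "eaf", i)
        if eaf is not None and not 0.0 <= eaf <= 1.0:
            raise ValidationError(f"row {i}: eaf {eaf} outside [0, 1]")
        if measure == "log_odds":
            if estimate <= 0:
                raise ValidationError(f"row {i}: odds ratio must be positive, got {estimate}")
            beta = or_to_logor(estimate)
            if se is None:
                if ci_lower is None or ci_upper is None:
                    raise ValidationError(f"row {i}: need se or complete CI")
                se = ci_to_se(ci_lower, ci_upper, z=constants.z_95)
        else:
            beta = estimate
            if se is None:
                if ci_lower is None or ci_upper is None:
                    raise ValidationError(f"row {i}: need se or complete CI")
                se = ci_to_se_linear(ci_lower, ci_upper, z=constants.z_95)
        assoc = VariantAssociation(
            variant_id=get("variant_id"),
            effect_allele=get("effect_allele"),
            other_allele=get("other_allele"),
            eaf=eaf,
            trait=get("trait"),
            measure=measure,
            beta=beta,
            se=se,
            ci_lower=ci_lower,
            ci_upper=ci_upper,
            n_case=_parse_int(get("n_case"), "n_case", i),
            n_control=_parse_int(get("n_control"), "n_control", i),
            n_total=_parse_int(get("n_total"), "n_total", i),
            unit=get("unit"),
        )
        try:
            assoc.validate()
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        associations.append(assoc)
    return VariantPanel(associations, index_variant=index_variant)


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return "NA"
    return f"{value:.12g}"


def _fmt_int(value: Optional[int]) -> str:
    return "NA" if value is None else str(value)


def write_sumstats(panel: VariantPanel, path: str | Path) -> None:
    """Write a panel back to the "v1" tab-delimited format.

    The operation is the inverse of :func:`read_sumstats` to 12 significant
    digits: log-odds effects are re-exponentiated to the OR scale for the
    ``estimate`` column, frequencies are written as proportions.
    """
    panel.validate()
    lines = ["\t".join(COLUMNS)]
    for a in panel.associations:
        estimate = math.exp(a.beta) if a.measure == "log_odds" else a.beta
        lines.append(
            "\t".join(
                [
                    a.variant_id,
                    a.effect_allele,
                    a.other_allele,
                    _fmt(a.eaf),
                    a.trait,
                    a.measure,
                    _fmt(estimate),
                    _fmt(a.ci_lower),
                    _fmt(a.ci_upper),
                    _fmt(a.se),
                    _fmt_int(a.n_case),
                    _fmt_int(a.n_control),
                    _fmt_int(a.n_total),
                    a.unit,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
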