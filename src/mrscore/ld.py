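"""Pairwise linkage disequilibrium and instrument-independence filtering.

D and its normalizations from a table of two-locus haplotype frequencies::

    D   = p_AB - p_A p_B
    r^2 = D^2 / (p_A p_a p_B p_b)
    D'  = |D| / D_max,  D_max = min(p_A p_b, p_a p_B)  if D > 0
                        D_max = min(p_A p_B, p_a p_b)  if D < 0

The independence rule used to pick genetic-score members keeps the index
variant and every variant whose D' with the index is <= the threshold
(default 0.6); D' strictly greater than the threshold excludes.  LD may be
supplied numerically or as precomputed boolean flags (the situation when
only qualitative supplement footnotes are available).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import LdUndefinedError, MissingLdError, ValidationError
from .sumstats import VariantPanel

__all__ = [
    "HaplotypeTable",
    "LdRecord",
    "ld_from_haplotypes",
    "select_independent",
    "read_ld_flags",
]

D_PRIME_THRESHOLD = 0.6


@dataclass(frozen=True)
class HaplotypeTable:
    """Frequencies of the four two-locus haplotypes AB, Ab, aB, ab."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float

    def __post_init__(self) -> None:
        freqs = (self.p_AB, self.p_Ab, self.p_aB, self.p_ab)
        if any(f < 0 for f in freqs):
            raise ValidationError("haplotype frequencies must be non-negative")
        if abs(sum(freqs) - 1.0) > 1e-12:
            raise ValidationError(f"haplotype frequencies must sum to 1, got {sum(freqs)!r}")

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB


@dataclass(frozen=True)
class LdRecord:
    """Pairwise LD between two variants; numeric values may be absent when
    only a qualitative exceeds-threshold flag is known."""

    variant_a: str
    variant_b: str
    d_prime: Optional[float] = None
    r_squared: Optional[float] = None
    exceeds_threshold: Optional[bool] = None

    def __post_init__(self) -> None:
        for name, value in (("d_prime", self.d_prime), ("r_squared", self.r_squared)):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")


def ld_from_haplotypes(
    h: HaplotypeTable, variant_a: str = "A", variant_b: str = "B"
) -> LdRecord:
    """Compute D' and r-squared from a haplotype-frequency table.

    Both loci must be polymorphic.  Outputs are clamped to [0, 1] against
    floating-point rounding.
    """
    p_a_marg, p_b_marg = h.p_A, h.p_B
    if not (0.0 < p_a_marg < 1.0 and 0.0 < p_b_marg < 1.0):
        raise LdUndefinedError("LD undefined: at least one locus is monomorphic")
    d = h.p_AB - p_a_marg * p_b_marg
    qa, qb = 1.0 - p_a_marg, 1.0 - p_b_marg
    r2 = d * d / (p_a_marg * qa * p_b_marg * qb)
    if d > 0:
        d_max = min(p_a_marg * qb, qa * p_b_marg)
    elif d < 0:
        d_max = min(p_a_marg * p_b_marg, qa * qb)
    else:
        d_max = 0.0
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    clamp = lambda x: min(1.0, max(0.0, x))  # noqa: E731
    return LdRecord(variant_a, variant_b, clamp(d_prime), clamp(r2))


def _pair_lookup(records: Sequence[LdRecord], a: str, b: str) -> Optional[LdRecord]:
    for rec in records:
        if {rec.variant_a, rec.variant_b} == {a, b}:
            return rec
    return None


def select_independent(
    panel: VariantPanel,
    ld: Sequence[LdRecord],
    threshold: float = D_PRIME_THRESHOLD,
) -> list[str]:
    """Variants retained for the genetic score under the D' rule.

    Keeps the panel's index variant plus every other variant whose D' with
    the index is <= ``threshold`` (a precomputed ``exceeds_threshold`` flag
    takes precedence over a numeric D').  Output preserves panel order.

    Raises
    ------
    MissingLdError
        If a non-index variant has no LD record against the index.
    """
    index = panel.index_variant
    if index is None or index not in panel.variant_ids():
        raise ValidationError(f"index variant {index!r} not present in panel")
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    selected: list[str] = []
    for vid in panel.variant_ids():
        if vid == index:
            selected.append(vid)
            continue
        rec = _pair_lookup(ld, index, vid)
        if rec is None:
            raise MissingLdError(f"no LD record between index {index} and {vid}")
        if rec.exceeds_threshold is not None:
            excluded = rec.exceeds_threshold
        elif rec.d_prime is not None:
            excluded = rec.d_prime > threshold
        else:
            raise MissingLdError(
                f"LD record for {vid} carries neither d_prime nor exceeds_threshold"
            )
        if not excluded:
            selected.append(vid)
    return selected


def read_ld_flags(path: str | Path) -> list[LdRecord]:
    """Read pairwise LD records from a tab-delimited flags file.

    Columns ``variant_a``, ``variant_b`` are mandatory; ``d_prime``,
    ``r_squared`` and boolean ``exceeds_threshold`` are optional per row
    (``NA`` for absent).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in ("variant_a", "variant_b"):
        if column not in frame.columns:
            raise ValidationError(f"LD flags file missing column {column!r}")
    records: list[LdRecord] = []
    for _, row in frame.iterrows():
        def opt_float(col: str) -> Optional[float]:
            raw = str(row[col]).strip() if col in frame.columns else "NA"
            return None if raw in ("NA", "") else float(raw)

        raw_flag = str(row["exceeds_threshold"]).strip().lower() if "exceeds_threshold" in frame.columns else "na"
        if raw_flag in ("na", ""):
            flag = None
        elif raw_flag in ("true", "1", "yes"):
            flag = True
        elif raw_flag in ("false", "0", "no"):
            flag = False
        else:
            raise ValidationError(f"cannot parse exceeds_threshold={row['exceeds_threshold']!r}")
        records.append(
            LdRecord(
                variant_a=row["variant_a"],
                variant_b=row["variant_b"],
                d_prime=opt_float("d_prime"),
                r_squared=opt_float("r_squared"),
                exceeds_threshold=flag,
            )
        )
    return records
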