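"""Deterministic effect-size algebra for GWAS summary statistics.

Conversions between the representations in which per-allele effects are
published: odds ratio vs. natural-log odds, 95% confidence interval vs.
standard error, standard-deviation units vs. mmol/L for LDL cholesterol,
and re-orientation of exposure/outcome pairs to the LDL-lowering allele.

All functions are pure and operate on scalars or on
:class:`~mrscore.sumstats.VariantAssociation` records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

from .errors import HarmonizationError

if TYPE_CHECKING:  # pragma: no cover
    from .sumstats import VariantAssociation

__all__ = [
    "ConversionConstants",
    "DEFAULT_CONSTANTS",
    "or_to_logor",
    "logor_to_or",
    "ci_to_se",
    "ci_to_se_linear",
    "sd_units_to_mmol",
    "flip_association",
    "harmonize_to_lowering_allele",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Scalar constants shared across an analysis.

    Attributes
    ----------
    sd_to_mmol:
        mmol/L of LDL-C per standard deviation, from the pooled SD of the
        lipid-consortium studies (1.0083).
    z_95:
        Normal quantile used to build / invert 95% confidence intervals.
        The exact two-sided 97.5% quantile is 1.959964; published tables
        are typically reconstructed with 1.96.
    alpha_adjusted:
        Multiplicity-adjusted two-sided significance level (0.008).
    """

    sd_to_mmol: float = 1.0083
    z_95: float = 1.959964
    alpha_adjusted: float = 0.008

    def __post_init__(self) -> None:
        if not self.sd_to_mmol > 0:
            raise ValueError("sd_to_mmol must be positive")
        if not self.z_95 > 0:
            raise ValueError("z_95 must be positive")
        if not 0 < self.alpha_adjusted < 1:
            raise ValueError("alpha_adjusted must lie in (0, 1)")


DEFAULT_CONSTANTS = ConversionConstants()


def or_to_logor(or_value: float) -> float:
    """Natural-log odds from an odds ratio; ``or_value`` must be > 0."""
    if not or_value > 0:
        raise ValueError(f"odds ratio must be positive, got {or_value!r}")
    return math.log(or_value)


def logor_to_or(log_or: float) -> float:
    """Inverse of :func:`or_to_logor`."""
    return math.exp(log_or)


def ci_to_se(ci_lower: float, ci_upper: float, z: float = DEFAULT_CONSTANTS.z_95) -> float:
    """Log-scale standard error reconstructed from an OR-scale 95% CI.

    ``se = (ln(upper) - ln(lower)) / (2 z)``.  Invariant under rescaling
    both bounds by a positive constant (only the log-width matters).
    """
    if not (0 < ci_lower < ci_upper):
        raise ValueError(
            f"CI bounds must satisfy 0 < lower < upper, got ({ci_lower!r}, {ci_upper!r})"
        )
    return (math.log(ci_upper) - math.log(ci_lower)) / (2.0 * z)


def ci_to_se_linear(ci_lower: float, ci_upper: float, z: float = DEFAULT_CONSTANTS.z_95) -> float:
    """Standard error from a symmetric CI on a linear (e.g. mmol/L) scale."""
    if not ci_lower < ci_upper:
        raise ValueError(f"CI bounds inverted: ({ci_lower!r}, {ci_upper!r})")
    return (ci_upper - ci_lower) / (2.0 * z)


def sd_units_to_mmol(beta_sd: float, sd_to_mmol: float = DEFAULT_CONSTANTS.sd_to_mmol) -> float:
    """Convert a per-allele LDL-C effect from SD units to mmol/L.

    Standard errors scale by the same factor.
    """
    if not math.isfinite(beta_sd):
        raise ValueError("beta_sd must be finite")
    return beta_sd * sd_to_mmol


def flip_association(assoc: "VariantAssociation") -> "VariantAssociation":
    """Re-express a record with respect to the other allele.

    Swaps effect/other alleles, replaces the effect-allele frequency by its
    complement, negates the effect, and mirrors the CI bounds (sign flip on
    a linear scale, reciprocal-and-swap on the OR scale).  ``|beta|`` and
    ``se`` are unchanged.
    """
    if assoc.measure == "log_odds":
        lo = 1.0 / assoc.ci_upper if assoc.ci_upper is not None else None
        hi = 1.0 / assoc.ci_lower if assoc.ci_lower is not None else None
    else:
        lo = -assoc.ci_upper if assoc.ci_upper is not None else None
        hi = -assoc.ci_lower if assoc.ci_lower is not None else None
    return replace(
        assoc,
        effect_allele=assoc.other_allele,
        other_allele=assoc.effect_allele,
        eaf=1.0 - assoc.eaf if assoc.eaf is not None else None,
        beta=-assoc.beta,
        ci_lower=lo,
        ci_upper=hi,
    )


def harmonize_to_lowering_allele(
    assoc_exposure: "VariantAssociation",
    assoc_outcome: "VariantAssociation",
) -> tuple["VariantAssociation", "VariantAssociation"]:
    """Orient an exposure/outcome record pair to the exposure-lowering allele.

    The pair must refer to the same variant with identical or exactly
    swapped allele labels.  The outcome record is first brought onto the
    exposure's allele orientation; both are then flipped together if the
    exposure effect is positive, so that the returned exposure beta is
    <= 0 (the effect allele lowers the exposure).  Idempotent.
    """
    if assoc_exposure.variant_id != assoc_outcome.variant_id:
        raise HarmonizationError(
            f"variant mismatch: {assoc_exposure.variant_id} vs {assoc_outcome.variant_id}"
        )
    exp_pair = (assoc_exposure.effect_allele, assoc_exposure.other_allele)
    out_pair = (assoc_outcome.effect_allele, assoc_outcome.other_allele)
    if out_pair == exp_pair:
        outcome = assoc_outcome
    elif out_pair == exp_pair[::-1]:
        outcome = flip_association(assoc_outcome)
    else:
        raise HarmonizationError(
            f"{assoc_exposure.variant_id}: allele pairs incompatible "
            f"({exp_pair} vs {out_pair})"
        )
    exposure = assoc_exposure
    if exposure.beta > 0:
        exposure = flip_association(exposure)
        outcome = flip_association(outcome)
    return exposure, outcome
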