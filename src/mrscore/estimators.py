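"""Core two-sample MR estimators.

Three stages, all on the natural-log-odds scale:

* :func:`wald_ratio` rescales a per-allele outcome effect to a 1 mmol/L
  difference in the exposure (effect per 1 mmol/L *lower* LDL-C by
  default), dividing both the effect and its standard error by the
  magnitude of the per-allele exposure effect (first-order: exposure
  uncertainty is ignored).
* :func:`ivw_combine` pools Wald ratios across variants with
  inverse-variance weights — the "weighted genetic risk score".
* :func:`fixed_effects_meta` applies identical mathematics to per-study
  estimates of one variant, kept as a named stage so pipelines distinguish
  across-study pooling from across-variant scoring.

Pooled results carry Cochran's Q heterogeneity diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .effects import DEFAULT_CONSTANTS
from .errors import ValidationError, WeakInstrumentError

__all__ = ["ScaledEstimate", "PooledEstimate", "wald_ratio", "ivw_combine", "fixed_effects_meta"]


@dataclass(frozen=True)
class ScaledEstimate:
    """A log-odds effect per 1 mmol/L lower exposure, with first-order SE."""

    variant_id: str
    trait: str
    beta_per_mmol: float
    se_per_mmol: float

    def __post_init__(self) -> None:
        if not self.se_per_mmol > 0:
            raise ValidationError(f"{self.variant_id}: se_per_mmol must be > 0")

    @property
    def weight(self) -> float:
        """Inverse-variance weight, ``se_per_mmol ** -2``."""
        return self.se_per_mmol ** -2


@dataclass(frozen=True)
class PooledEstimate:
    """An inverse-variance combination with CI, p-value and Q diagnostics.

    ``q_p`` is 1.0 by convention when ``q_df == 0`` (a single input carries
    no heterogeneity information).
    """

    beta: float
    se: float
    or_value: float
    ci_lower: float
    ci_upper: float
    p_value: float
    q_stat: float
    q_df: int
    q_p: float
    k: int


def wald_ratio(
    outcome_beta: float,
    outcome_se: float,
    exposure_beta_mmol: float,
    *,
    per_lower: bool = True,
    variant_id: str = "",
    trait: str = "",
) -> ScaledEstimate:
    """Scale a per-allele outcome effect by the per-allele exposure effect.

    ``exposure_beta_mmol`` is the per-allele LDL-C change in mmol/L; its
    sign is immaterial (records harmonized to the lowering allele carry a
    negative value, but the magnitude is what scales).  With
    ``per_lower=True`` (default) the result keeps the outcome effect's
    orientation per 1 mmol/L **lower** exposure, matching records
    harmonized to the lowering allele; ``per_lower=False`` flips the sign
    to express the effect per 1 mmol/L higher exposure.
    """
    if exposure_beta_mmol == 0:
        raise WeakInstrumentError(
            f"{variant_id or 'variant'}: zero exposure effect, Wald ratio undefined"
        )
    if not outcome_se > 0:
        raise ValidationError(f"{variant_id or 'variant'}: outcome se must be > 0")
    scale = abs(exposure_beta_mmol)
    beta = outcome_beta / scale
    if not per_lower:
        beta = -beta
    return ScaledEstimate(variant_id, trait, beta, outcome_se / scale)


def _pool(betas: Sequence[float], ses: Sequence[float], z: float, k: int) -> PooledEstimate:
    weights = [s ** -2 for s in ses]
    w_sum = sum(weights)
    beta = sum(w * b for w, b in zip(weights, betas)) / w_sum
    se = w_sum ** -0.5
    q = sum(w * (b - beta) ** 2 for w, b in zip(weights, betas))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    p = 2.0 * float(stats.norm.sf(abs(beta) / se))
    return PooledEstimate(
        beta=beta,
        se=se,
        or_value=math.exp(beta),
        ci_lower=math.exp(beta - z * se),
        ci_upper=math.exp(beta + z * se),
        p_value=p,
        q_stat=q,
        q_df=df,
        q_p=q_p,
        k=k,
    )


def ivw_combine(
    estimates: Sequence[ScaledEstimate],
    z: float = DEFAULT_CONSTANTS.z_95,
    trait: Optional[str] = None,
) -> PooledEstimate:
    """Inverse-variance-weighted combination of scaled per-variant estimates.

    All inputs must share one trait (checked; pass ``trait`` to assert a
    specific one).  Fixed-effects weights ``1/se^2``; the pooled SE is
    ``(sum of weights)^-1/2`` and Q is evaluated against the pooled mean.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValidationError("cannot combine an empty list of estimates")
    traits = {e.trait for e in estimates}
    if len(traits) > 1:
        raise ValidationError(f"mixed traits in combination: {sorted(traits)}")
    if trait is not None and traits != {trait}:
        raise ValidationError(f"expected trait {trait!r}, got {traits}")
    return _pool(
        [e.beta_per_mmol for e in estimates],
        [e.se_per_mmol for e in estimates],
        z,
        len(estimates),
    )


def fixed_effects_meta(
    study_estimates: Iterable[tuple[float, float]],
    z: float = DEFAULT_CONSTANTS.z_95,
) -> PooledEstimate:
    """Fixed-effects meta-analysis of per-study ``(beta, se)`` pairs."""
    pairs = list(study_estimates)
    if not pairs:
        raise ValidationError("cannot meta-analyse an empty list of studies")
    betas, ses = zip(*pairs)
    if any(not s > 0 for s in ses):
        raise ValidationError("all study standard errors must be > 0")
    return _pool(betas, ses, z, len(pairs))
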