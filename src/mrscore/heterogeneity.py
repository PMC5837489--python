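"""Cochran's Q heterogeneity tests and analytic power for per-allele tests.

Two flavours of Q are used in a two-outcome MR comparison:

* :func:`q_between` — 1-df contrast of two pooled estimates, e.g. the CHD
  genetic-score effect against the ischaemic-stroke one;
* :func:`q_across` — (k-1)-df heterogeneity of k per-variant estimates
  around their inverse-variance-weighted mean, after scaling every variant
  to the same exposure difference.

:func:`binary_trait_power` gives the closed-form power of a two-sided
per-allele Wald test in a case-control sample, with the expected standard
error derived from the effect-allele frequency and the case/control
counts::

    se = sqrt( 1 / (2 p (1-p)) * (1/n_case + 1/n_control) )
    power = Phi( |log OR| / se - z_{1-alpha/2} )

The second (opposite-sign) rejection tail is omitted; it is negligible at
any useful power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from scipy import stats

from .errors import ValidationError
from .estimators import PooledEstimate, ScaledEstimate, ivw_combine

__all__ = [
    "HeterogeneityResult",
    "PowerSpec",
    "q_between",
    "q_across",
    "binary_trait_power",
    "significance_gate",
]

Estimate = Union[PooledEstimate, tuple]


@dataclass(frozen=True)
class HeterogeneityResult:
    """A Cochran's Q statistic with its chi-square reference."""

    q_stat: float
    df: int
    p_value: float
    contrast: str = ""


@dataclass(frozen=True)
class PowerSpec:
    """Design of a per-allele case-control test of a binary trait.

    ``alt_log_or`` is the per-allele log odds ratio under the alternative;
    ``alpha`` the two-sided significance level.
    """

    eaf: float
    n_case: int
    n_control: int
    alt_log_or: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ValidationError(f"eaf must be in (0, 1), got {self.eaf}")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValidationError("case and control counts must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def expected_se(self) -> float:
        """Expected SE of the per-allele log OR under allele-count testing."""
        return math.sqrt(
            (1.0 / (2.0 * self.eaf * (1.0 - self.eaf)))
            * (1.0 / self.n_case + 1.0 / self.n_control)
        )


def _beta_se(estimate: Estimate) -> tuple[float, float]:
    if isinstance(estimate, PooledEstimate):
        return estimate.beta, estimate.se
    beta, se = estimate
    return float(beta), float(se)


def q_between(est_a: Estimate, est_b: Estimate, contrast: str = "") -> HeterogeneityResult:
    """1-df Cochran's Q between two independent estimates.

    Accepts ``(beta, se)`` tuples or :class:`PooledEstimate` objects.
    Symmetric in its arguments.
    """
    beta_a, se_a = _beta_se(est_a)
    beta_b, se_b = _beta_se(est_b)
    if not (se_a > 0 and se_b > 0):
        raise ValidationError("standard errors must be > 0")
    q = (beta_a - beta_b) ** 2 / (se_a ** 2 + se_b ** 2)
    return HeterogeneityResult(q, 1, float(stats.chi2.sf(q, 1)), contrast)


def q_across(estimates: Sequence[ScaledEstimate], contrast: str = "") -> HeterogeneityResult:
    """(k-1)-df Q of k scaled estimates around their IVW mean, k >= 2."""
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValidationError("q_across needs at least two estimates")
    pooled = ivw_combine(estimates)
    q = sum(e.weight * (e.beta_per_mmol - pooled.beta) ** 2 for e in estimates)
    df = len(estimates) - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)), contrast)


def binary_trait_power(spec: PowerSpec, se: Optional[float] = None) -> float:
    """Analytic power of the two-sided per-allele Wald test.

    By default the expected SE is derived from the allele frequency and
    the case/control counts (``spec.expected_se``); pass ``se`` to use an
    observed standard error instead.  Returns a probability in (0, 1);
    equals ``alpha / 2`` at a null alternative.  Monotone increasing in
    ``|alt_log_or|`` and in both sample sizes, invariant under swapping
    cases with controls and under the sign of the alternative.
    """
    se_used = spec.expected_se if se is None else se
    if not se_used > 0:
        raise ValidationError("standard error must be > 0")
    z_crit = float(stats.norm.ppf(1.0 - spec.alpha / 2.0))
    return float(stats.norm.cdf(abs(spec.alt_log_or) / se_used - z_crit))


def significance_gate(p_value: float, alpha: float) -> bool:
    """True iff ``p_value < alpha`` (strict, matching a predefined gate)."""
    if not 0.0 < p_value <= 1.0:
        raise ValidationError(f"p-value must be in (0, 1], got {p_value}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    return p_value < alpha
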