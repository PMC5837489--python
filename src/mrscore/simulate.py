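"""Synthetic individual-level cohorts with known generating truth.

The generator emulates the statistical structure a two-sample MR analysis
assumes: biallelic genotypes for a handful of variants (optionally in LD),
a continuous exposure (LDL-C, mmol/L) built additively from per-allele
effects plus Gaussian noise, and binary outcomes drawn from a logistic
model whose log-odds depend linearly on the *genetic* LDL-lowering
component with outcome-specific slopes.  Because the outcome depends on
the genetic component only, the generating slope ``theta`` is exactly the
estimand the genetic-score pipeline targets.

Default parameters mirror the PCSK9 study conditions: two independent
variants with lowering-allele frequencies 0.015 and 0.965 and LDL effects
of -0.50 and -0.09 mmol/L per allele, a CHD slope of -0.51 log-odds per
1 mmol/L lower genetic LDL-C, and a null ischaemic-stroke slope.

Genotypes are drawn as two haplotypes per individual.  Pairwise LD targets
are honoured by sampling each haplotype as a first-order Markov chain over
adjacent variants, conditioning each locus on its predecessor through the
supplied two-locus haplotype table (phase is therefore known by
construction and empirical LD can be read off the haplotypes directly).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .effects import ConversionConstants, DEFAULT_CONSTANTS
from .errors import ValidationError
from .ld import HaplotypeTable, LdRecord, ld_from_haplotypes
from .sumstats import VariantAssociation, VariantPanel

__all__ = [
    "GeneratingModel",
    "SyntheticCohort",
    "simulate_cohort",
    "cohort_to_sumstats",
    "empirical_ld",
]

# non-palindromic allele pair assigned to every synthetic variant
_EFFECT_ALLELE, _OTHER_ALLELE = "T", "C"


@dataclass(frozen=True)
class GeneratingModel:
    """Ground truth for a synthetic cohort.

    ``variants`` pairs each variant ID with its lowering-allele frequency;
    ``per_allele_ldl_effects`` are the matching mmol/L effects per lowering
    allele (negative = lowering).  ``theta_by_trait`` gives, per outcome,
    the log-odds change per 1 mmol/L *lower* genetic LDL-C.
    ``ld_structure`` is either ``"independent"`` or a mapping from adjacent
    variant-ID pairs to :class:`~mrscore.ld.HaplotypeTable` targets whose
    marginals must match the variant frequencies.
    """

    n_individuals: int = 100_000
    variants: tuple[tuple[str, float], ...] = (("rs11591147", 0.015), ("rs505151", 0.965))
    per_allele_ldl_effects: tuple[float, ...] = (-0.50, -0.09)
    ld_structure: Union[str, Mapping[tuple[str, str], HaplotypeTable]] = "independent"
    ldl_mean: float = 3.6
    ldl_noise_sd: float = 1.0
    theta_by_trait: Mapping[str, float] = field(
        default_factory=lambda: {"CHD": -0.51, "IS": 0.0}
    )
    baseline_log_odds: Mapping[str, float] = field(
        default_factory=lambda: {"CHD": -1.0, "IS": -1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValidationError("n_individuals must be positive")
        if len(self.variants) != len(self.per_allele_ldl_effects):
            raise ValidationError("one LDL effect is required per variant")
        for vid, freq in self.variants:
            if not 0.0 < freq < 1.0:
                raise ValidationError(f"{vid}: frequency must be in (0, 1), got {freq}")
        if not self.ldl_noise_sd > 0:
            raise ValidationError("ldl_noise_sd must be > 0")
        if set(self.theta_by_trait) != set(self.baseline_log_odds):
            raise ValidationError("theta_by_trait and baseline_log_odds must share traits")

    def variant_ids(self) -> list[str]:
        return [vid for vid, _ in self.variants]

    def to_dict(self) -> dict:
        """JSON-serializable record of the generating truth."""
        ld: object
        if isinstance(self.ld_structure, str):
            ld = self.ld_structure
        else:
            ld = {
                f"{a}|{b}": [t.p_AB, t.p_Ab, t.p_aB, t.p_ab]
                for (a, b), t in self.ld_structure.items()
            }
        return {
            "n_individuals": self.n_individuals,
            "variants": [[vid, freq] for vid, freq in self.variants],
            "per_allele_ldl_effects": list(self.per_allele_ldl_effects),
            "ld_structure": ld,
            "ldl_mean": self.ldl_mean,
            "ldl_noise_sd": self.ldl_noise_sd,
            "theta_by_trait": dict(self.theta_by_trait),
            "baseline_log_odds": dict(self.baseline_log_odds),
            "seed": self.seed,
        }


@dataclass
class SyntheticCohort:
    """Individual-level data plus the model that generated it."""

    variant_ids: list[str]
    haplotypes: np.ndarray  # (n, 2, m) 0/1 lowering-allele indicators
    ldl: np.ndarray  # (n,) mmol/L
    outcomes: dict[str, np.ndarray]  # trait -> (n,) 0/1
    truth: GeneratingModel

    @property
    def genotypes(self) -> np.ndarray:
        """(n, m) lowering-allele counts in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1)

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]


def _pair_table(model: GeneratingModel, a: str, b: str) -> Optional[HaplotypeTable]:
    if isinstance(model.ld_structure, str):
        if model.ld_structure != "independent":
            raise ValidationError(f"unknown ld_structure {model.ld_structure!r}")
        return None
    return model.ld_structure.get((a, b)) or model.ld_structure.get((b, a))


def simulate_cohort(model: GeneratingModel) -> SyntheticCohort:
    """Draw a cohort from the generating model; fixed seed, fixed output."""
    rng = np.random.default_rng(model.seed)
    n, m = model.n_individuals, len(model.variants)
    freqs = np.array([f for _, f in model.variants])
    ids = model.variant_ids()

    hap = np.empty((n, 2, m), dtype=np.int8)
    hap[:, :, 0] = rng.random((n, 2)) < freqs[0]
    for j in range(1, m):
        table = _pair_table(model, ids[j - 1], ids[j])
        if table is None:
            hap[:, :, j] = rng.random((n, 2)) < freqs[j]
        else:
            if abs(table.p_A - freqs[j - 1]) > 1e-9 or abs(table.p_B - freqs[j]) > 1e-9:
                raise ValidationError(
                    f"haplotype table marginals for ({ids[j-1]}, {ids[j]}) do not "
                    "match the variant frequencies"
                )
            p_b_given_a = table.p_AB / table.p_A
            p_b_given_not_a = table.p_aB / (1.0 - table.p_A)
            prev = hap[:, :, j - 1]
            cond = np.where(prev == 1, p_b_given_a, p_b_given_not_a)
            hap[:, :, j] = rng.random((n, 2)) < cond

    genotypes = hap.sum(axis=1)
    effects = np.asarray(model.per_allele_ldl_effects, dtype=float)
    genetic_component = genotypes @ effects  # mmol/L change, <= 0 for lowering
    ldl = model.ldl_mean + genetic_component + rng.normal(0.0, model.ldl_noise_sd, size=n)

    lowering = -genetic_component  # mmol/L of genetically conferred lowering
    outcomes: dict[str, np.ndarray] = {}
    for trait, theta in model.theta_by_trait.items():
        logit = model.baseline_log_odds[trait] + theta * lowering
        prob = 1.0 / (1.0 + np.exp(-logit))
        outcomes[trait] = (rng.random(n) < prob).astype(np.int8)

    return SyntheticCohort(ids, hap, ldl, outcomes, model)


def empirical_ld(cohort: SyntheticCohort, variant_a: str, variant_b: str) -> LdRecord:
    """D'/r-squared from the cohort's phased haplotypes (phase is known
    by construction, so no EM frequency estimation is needed)."""
    ia, ib = cohort.variant_ids.index(variant_a), cohort.variant_ids.index(variant_b)
    ha = cohort.haplotypes[:, :, ia].ravel().astype(bool)
    hb = cohort.haplotypes[:, :, ib].ravel().astype(bool)
    total = ha.size
    table = HaplotypeTable(
        p_AB=np.count_nonzero(ha & hb) / total,
        p_Ab=np.count_nonzero(ha & ~hb) / total,
        p_aB=np.count_nonzero(~ha & hb) / total,
        p_ab=np.count_nonzero(~ha & ~hb) / total,
    )
    return ld_from_haplotypes(table, variant_a, variant_b)


def _exposure_association(
    g: np.ndarray, ldl: np.ndarray, vid: str, eaf: float, z: float
) -> VariantAssociation:
    # closed-form simple-regression slope and SE of ldl on allele count
    n = g.size
    var_g = g.var()
    beta = np.cov(g, ldl, ddof=0)[0, 1] / var_g
    resid = ldl - ldl.mean() - beta * (g - g.mean())
    se = float(np.sqrt((resid @ resid) / (n - 2) / (n * var_g)))
    return VariantAssociation(
        variant_id=vid,
        effect_allele=_EFFECT_ALLELE,
        other_allele=_OTHER_ALLELE,
        eaf=eaf,
        trait="LDL-C",
        measure="beta_continuous",
        beta=float(beta),
        se=se,
        ci_lower=float(beta - z * se),
        ci_upper=float(beta + z * se),
        n_total=n,
        unit="mmol_per_l",
    )


def _outcome_association(
    g: np.ndarray, y: np.ndarray, trait: str, vid: str, eaf: float, z: float
) -> VariantAssociation:
    # log OR from the 2x2 lowering-allele-count x case/control table
    cases = y == 1
    n_case = int(np.count_nonzero(cases))
    n_control = y.size - n_case
    a = float(g[cases].sum())  # lowering alleles among cases
    b = 2.0 * n_case - a
    c = float(g[~cases].sum())
    d = 2.0 * n_control - c
    if min(a, b, c, d) == 0:
        warnings.warn(
            f"{vid} ({trait}): empty cell in 2x2 allele table, "
            "continuity correction (+0.5) applied",
            stacklevel=2,
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    beta = float(np.log((a / b) / (c / d)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return VariantAssociation(
        variant_id=vid,
        effect_allele=_EFFECT_ALLELE,
        other_allele=_OTHER_ALLELE,
        eaf=eaf,
        trait=trait,
        measure="log_odds",
        beta=beta,
        se=se,
        ci_lower=float(np.exp(beta - z * se)),
        ci_upper=float(np.exp(beta + z * se)),
        n_case=n_case,
        n_control=n_control,
        unit="log_or",
    )


def cohort_to_sumstats(
    cohort: SyntheticCohort,
    split: Optional[int] = None,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> list[VariantPanel]:
    """Extract per-variant summary statistics, one panel per pseudo-study.

    ``split`` divides the cohort into that many equal consecutive
    pseudo-studies (default 1).  Per variant and pseudo-study: the exposure
    effect is the closed-form regression slope of LDL-C on allele count
    with its standard error; each outcome log OR comes from the 2x2
    lowering-allele x case/control table with SE ``sqrt(sum of 1/cells)``
    (continuity correction +0.5 on an empty cell, with a warning).
    Monomorphic variants are dropped with a warning.  Every pseudo-study
    must retain at least 100 cases and 100 controls per trait.
    """
    k = 1 if split is None else int(split)
    if k < 1:
        raise ValidationError("split must be a positive integer")
    genotypes = cohort.genotypes
    bounds = np.linspace(0, cohort.n, k + 1, dtype=int)
    panels: list[VariantPanel] = []
    for s in range(k):
        lo, hi = bounds[s], bounds[s + 1]
        g_chunk = genotypes[lo:hi]
        ldl_chunk = cohort.ldl[lo:hi]
        for trait, y in cohort.outcomes.items():
            y_chunk = y[lo:hi]
            n_case = int(y_chunk.sum())
            if n_case < 100 or (y_chunk.size - n_case) < 100:
                raise ValidationError(
                    f"pseudo-study {s}: fewer than 100 cases or controls for {trait}"
                )
        assocs: list[VariantAssociation] = []
        for j, vid in enumerate(cohort.variant_ids):
            g = g_chunk[:, j].astype(float)
            if g.var() == 0:
                warnings.warn(f"{vid}: monomorphic in pseudo-study {s}, dropped", stacklevel=2)
                continue
            eaf = float(g.mean() / 2.0)
            assocs.append(_exposure_association(g, ldl_chunk, vid, eaf, constants.z_95))
            for trait, y in cohort.outcomes.items():
                assocs.append(
                    _outcome_association(g, y[lo:hi], trait, vid, eaf, constants.z_95)
                )
        panels.append(VariantPanel(assocs, index_variant=cohort.variant_ids[0]))
    return panels


def write_truth(model: GeneratingModel, path) -> None:
    """Write the generating model to a JSON file."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
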