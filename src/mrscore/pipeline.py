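"""Config-driven orchestration of the full genetic-score analysis.

The pipeline reproduces, from summary-statistics files, the comparison of
variant effects on two (or more) outcomes per unit of exposure: load and
harmonize panels, reconstruct standard errors, scale each variant's
outcome effect per 1 mmol/L lower exposure, drop variants in LD with the
index variant, combine the survivors into an inverse-variance-weighted
genetic score per outcome, and test heterogeneity both between outcomes
and across variants.

Outputs: a per-variant report table, a score table, a machine-readable
JSON with all unrounded values, and a plain-text log of every decision
(LD exclusions, continuity corrections).  Displayed odds ratios and CI
bounds are rounded half-up to a configurable number of decimals; all
comparisons should be made against the unrounded JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from scipy import stats

from .datasets import fixture_path
from .effects import ConversionConstants, harmonize_to_lowering_allele
from .errors import PipelineError
from .estimators import PooledEstimate, ScaledEstimate, ivw_combine, wald_ratio
from .heterogeneity import HeterogeneityResult, q_across, q_between, significance_gate
from .ld import read_ld_flags, select_independent
from .sumstats import VariantPanel, read_sumstats

__all__ = ["AnalysisConfig", "run_pipeline", "round_half_up", "format_p"]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (so 0.605 -> 0.61), as tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float, decimals: int = 2) -> str:
    """P-value display: scientific with one significant digit below 1e-4."""
    if p < 1e-4:
        return f"{p:.0e}"
    return f"{round_half_up(p, decimals):.{decimals}f}"


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs, optionally read from YAML.

    ``inputs`` are summary-statistics TSV paths; the token
    ``packaged:<name>`` refers to a fixture shipped with the package.
    ``ld_flags`` is mandatory for scoring: the pipeline refuses to build a
    score without an explicit LD source rather than assume independence.
    """

    inputs: list[str] = field(default_factory=lambda: ["packaged:table1.tsv"])
    ld_flags: Optional[str] = "packaged:ld_flags.tsv"
    index_variant: str = "rs11591147"
    d_prime_threshold: float = 0.6
    exposure_trait: str = "LDL-C"
    outcome_traits: Optional[list[str]] = None
    heterogeneity_pairs: list[tuple[str, str]] = field(default_factory=lambda: [("CHD", "IS")])
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    out_dir: Optional[str] = None
    decimals: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        base = Path(path).parent
        raw = yaml.safe_load(Path(path).read_text()) or {}
        consts = ConversionConstants(**raw.get("constants", {}))

        def resolve(p: Optional[str]) -> Optional[str]:
            if p is None or p.startswith("packaged:"):
                return p
            return str((base / p).resolve()) if not Path(p).is_absolute() else p

        pairs = [tuple(pair) for pair in raw.get("heterogeneity_pairs", [("CHD", "IS")])]
        return cls(
            inputs=[resolve(p) for p in raw.get("inputs", ["packaged:table1.tsv"])],
            ld_flags=resolve(raw.get("ld_flags", "packaged:ld_flags.tsv")),
            index_variant=raw.get("index_variant", "rs11591147"),
            d_prime_threshold=float(raw.get("d_prime_threshold", 0.6)),
            exposure_trait=raw.get("exposure_trait", "LDL-C"),
            outcome_traits=raw.get("outcome_traits"),
            heterogeneity_pairs=pairs,
            constants=consts,
            out_dir=resolve(raw.get("out_dir")),
            decimals=int(raw.get("decimals", 2)),
        )


def _resolve_path(token: str) -> Path:
    if token.startswith("packaged:"):
        return fixture_path(token.split(":", 1)[1])
    return Path(token)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis and return a report bundle.

    The bundle maps: ``panel`` (harmonized input), ``scaled`` (per-variant
    per-trait :class:`ScaledEstimate`), ``selected`` (score members),
    ``scores`` (trait -> :class:`PooledEstimate`), ``per_variant`` /
    ``score_table`` (report DataFrames), ``json`` (unrounded values) and
    ``log`` (decision lines).  When ``config.out_dir`` is set the tables,
    JSON and log are also written there.
    """
    log: list[str] = []
    z = config.constants.z_95
    alpha = config.constants.alpha_adjusted

    # -- load and merge ------------------------------------------------
    panel = VariantPanel([], index_variant=config.index_variant)
    for token in config.inputs:
        path = _resolve_path(token)
        if not path.exists():
            raise PipelineError(f"input file not found: {token}")
        panel = panel.merge(
            read_sumstats(path, constants=config.constants, index_variant=config.index_variant)
        )
        log.append(f"loaded {token}")
    exposure_trait = config.exposure_trait
    if exposure_trait not in panel.traits():
        raise PipelineError(f"exposure trait {exposure_trait!r} absent from inputs")
    outcome_traits = config.outcome_traits or [
        t for t in panel.traits() if t != exposure_trait
    ]

    # -- harmonize to the lowering allele and scale --------------------
    harmonized: list = []
    scaled: dict[tuple[str, str], ScaledEstimate] = {}
    exposures: dict[str, object] = {}
    for vid in panel.variant_ids():
        exposure = panel.get(vid, exposure_trait)
        for trait in outcome_traits:
            try:
                outcome = panel.get(vid, trait)
            except KeyError:
                continue
            exp_h, out_h = harmonize_to_lowering_allele(exposure, outcome)
            exposures[vid] = exp_h
            harmonized.append(out_h)
            scaled[(vid, trait)] = wald_ratio(
                out_h.beta, out_h.se, exp_h.beta, variant_id=vid, trait=trait
            )
    panel_h = VariantPanel(
        list(exposures.values()) + harmonized, index_variant=config.index_variant
    )

    # -- LD-based independence filter ----------------------------------
    if config.ld_flags is None:
        raise PipelineError(
            "no LD source configured: refusing to score without an explicit "
            "independence assessment"
        )
    ld_path = _resolve_path(config.ld_flags)
    if not ld_path.exists():
        raise PipelineError(f"LD flags file not found: {config.ld_flags}")
    ld_records = read_ld_flags(ld_path)
    selected = select_independent(panel_h, ld_records, threshold=config.d_prime_threshold)
    for vid in panel_h.variant_ids():
        if vid not in selected:
            log.append(
                f"excluded {vid} from the genetic score "
                f"(D' with {config.index_variant} > {config.d_prime_threshold})"
            )
    log.append(f"score members: {', '.join(selected)}")

    # -- genetic score per outcome trait -------------------------------
    scores: dict[str, PooledEstimate] = {}
    for trait in outcome_traits:
        members = [scaled[(vid, trait)] for vid in selected if (vid, trait) in scaled]
        if members:
            scores[trait] = ivw_combine(members, z=z, trait=trait)

    # -- heterogeneity --------------------------------------------------
    per_variant_het: dict[tuple[str, str, str], HeterogeneityResult] = {}
    score_het: dict[tuple[str, str], HeterogeneityResult] = {}
    for a, b in config.heterogeneity_pairs:
        if a not in outcome_traits or b not in outcome_traits:
            continue
        for vid in panel_h.variant_ids():
            if (vid, a) in scaled and (vid, b) in scaled:
                sa, sb = scaled[(vid, a)], scaled[(vid, b)]
                per_variant_het[(vid, a, b)] = q_between(
                    (sa.beta_per_mmol, sa.se_per_mmol),
                    (sb.beta_per_mmol, sb.se_per_mmol),
                    contrast=f"{vid}: {a} vs {b}",
                )
        if a in scores and b in scores:
            score_het[(a, b)] = q_between(
                scores[a], scores[b], contrast=f"genetic score: {a} vs {b}"
            )
    across_het: dict[str, HeterogeneityResult] = {}
    for trait in outcome_traits:
        members = [scaled[(vid, trait)] for vid in panel_h.variant_ids() if (vid, trait) in scaled]
        if len(members) >= 2:
            across_het[trait] = q_across(members, contrast=f"across {len(members)} variants, {trait}")

    # -- report tables ---------------------------------------------------
    nd = config.decimals
    rows = []
    for vid in panel_h.variant_ids():
        exp_h = exposures[vid]
        row: dict[str, object] = {
            "variant_id": vid,
            "effect_allele": exp_h.effect_allele,
            "other_allele": exp_h.other_allele,
            "eaf": exp_h.eaf,
            "ldl_beta": round_half_up(exp_h.beta, nd),
            "ldl_se": exp_h.se,
        }
        for trait in outcome_traits:
            est = scaled.get((vid, trait))
            if est is None:
                continue
            out_h = panel_h.get(vid, trait)
            or_pt = math.exp(out_h.beta)
            lo = math.exp(out_h.beta - z * out_h.se)
            hi = math.exp(out_h.beta + z * out_h.se)
            p = 2.0 * float(stats.norm.sf(abs(out_h.beta) / out_h.se))
            row[f"{trait}_or"] = round_half_up(or_pt, nd)
            row[f"{trait}_ci"] = (
                f"{round_half_up(lo, nd):.{nd}f}-{round_half_up(hi, nd):.{nd}f}"
            )
            row[f"{trait}_p"] = format_p(p, nd)
            row[f"{trait}_significant"] = significance_gate(min(p, 1.0), alpha)
        for (a, b) in config.heterogeneity_pairs:
            het = per_variant_het.get((vid, a, b))
            if het is not None:
                row[f"p_het_{a}_vs_{b}"] = format_p(het.p_value, nd)
        rows.append(row)
    per_variant = pd.DataFrame(rows)

    score_rows = []
    for trait, est in scores.items():
        score_rows.append(
            {
                "trait": trait,
                "k": est.k,
                "beta": est.beta,
                "se": est.se,
                "or": round_half_up(est.or_value, nd),
                "ci_lower": round_half_up(est.ci_lower, nd),
                "ci_upper": round_half_up(est.ci_upper, nd),
                "p": format_p(est.p_value, nd),
                "q": est.q_stat,
                "q_df": est.q_df,
                "q_p": format_p(est.q_p, nd),
            }
        )
    for (a, b), het in score_het.items():
        score_rows.append(
            {
                "trait": f"{a} vs {b} (score heterogeneity)",
                "k": 2,
                "q": het.q_stat,
                "q_df": het.df,
                "q_p": format_p(het.p_value, nd),
            }
        )
    score_table = pd.DataFrame(score_rows)

    unrounded = {
        "constants": {
            "sd_to_mmol": config.constants.sd_to_mmol,
            "z_95": z,
            "alpha_adjusted": alpha,
        },
        "selected_variants": selected,
        "scores": {
            trait: {
                "beta": est.beta,
                "se": est.se,
                "or": est.or_value,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
                "p": est.p_value,
                "q": est.q_stat,
                "q_df": est.q_df,
                "q_p": est.q_p,
                "k": est.k,
            }
            for trait, est in scores.items()
        },
        "score_heterogeneity": {
            f"{a}_vs_{b}": {"q": h.q_stat, "df": h.df, "p": h.p_value}
            for (a, b), h in score_het.items()
        },
        "across_variant_heterogeneity": {
            trait: {"q": h.q_stat, "df": h.df, "p": h.p_value}
            for trait, h in across_het.items()
        },
        "per_variant_heterogeneity": {
            f"{vid}:{a}_vs_{b}": {"q": h.q_stat, "df": h.df, "p": h.p_value}
            for (vid, a, b), h in per_variant_het.items()
        },
        "scaled_estimates": {
            f"{vid}:{trait}": {"beta_per_mmol": e.beta_per_mmol, "se_per_mmol": e.se_per_mmol}
            for (vid, trait), e in scaled.items()
        },
    }

    bundle = {
        "panel": panel_h,
        "scaled": scaled,
        "selected": selected,
        "scores": scores,
        "score_heterogeneity": score_het,
        "across_heterogeneity": across_het,
        "per_variant_heterogeneity": per_variant_het,
        "per_variant": per_variant,
        "score_table": score_table,
        "json": unrounded,
        "log": log,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_variant.to_csv(out / "variants.tsv", sep="\t", index=False)
        score_table.to_csv(out / "scores.tsv", sep="\t", index=False)
        (out / "results.json").write_text(json.dumps(unrounded, indent=2) + "\n")
        (out / "pipeline.log").write_text("\n".join(log) + "\n")
        log.append(f"wrote report bundle to {out}")
    return bundle
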