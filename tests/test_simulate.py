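"""Synthetic cohorts: genotype/LD structure, exposure model, sumstats extraction."""

import math

import numpy as np
import pytest

from mrscore import (
    GeneratingModel,
    HaplotypeTable,
    SyntheticCohort,
    ValidationError,
    cohort_to_sumstats,
    empirical_ld,
    fixed_effects_meta,
    ld_from_haplotypes,
    simulate_cohort,
    write_sumstats,
)
from mrscore.simulate import _outcome_association


def _single_variant_model(**kw):
    defaults = dict(
        n_individuals=50_000,
        variants=(("v1", 0.5),),
        per_allele_ldl_effects=(-0.5,),
        theta_by_trait={"CHD": -0.5, "IS": 0.0},
        baseline_log_odds={"CHD": -1.0, "IS": -1.0},
        seed=11,
    )
    defaults.update(kw)
    return GeneratingModel(**defaults)


def test_allele_frequency_recovery():
    cohort = simulate_cohort(_single_variant_model())
    freq = cohort.genotypes[:, 0].mean() / 2
    se = math.sqrt(0.5 * 0.5 / (2 * cohort.n))
    assert abs(freq - 0.5) < 3 * se


def test_null_trait_recovers_zero_log_or():
    cohort = simulate_cohort(_single_variant_model())
    panel = cohort_to_sumstats(cohort)[0]
    record = panel.get("v1", "IS")
    assert abs(record.beta) < 3 * record.se


def test_ld_structure_is_honoured():
    table = HaplotypeTable(0.2, 0.1, 0.1, 0.6)
    target = ld_from_haplotypes(table)
    model = GeneratingModel(
        n_individuals=50_000,
        variants=(("v1", 0.3), ("v2", 0.3)),
        per_allele_ldl_effects=(-0.5, -0.1),
        ld_structure={("v1", "v2"): table},
        seed=5,
    )
    cohort = simulate_cohort(model)
    observed = empirical_ld(cohort, "v1", "v2")
    # ~1e5 haplotypes: generous Monte-Carlo band
    assert observed.r_squared == pytest.approx(target.r_squared, abs=0.02)
    assert observed.d_prime == pytest.approx(target.d_prime, abs=0.03)


def test_perfect_ld_copies_haplotypes_exactly():
    table = HaplotypeTable(0.3, 0.0, 0.0, 0.7)
    model = GeneratingModel(
        n_individuals=20_000,
        variants=(("v1", 0.3), ("v2", 0.3)),
        per_allele_ldl_effects=(-0.5, -0.1),
        ld_structure={("v1", "v2"): table},
        seed=6,
    )
    cohort = simulate_cohort(model)
    assert empirical_ld(cohort, "v1", "v2").r_squared == pytest.approx(1.0)


def test_mismatched_ld_marginals_rejected():
    table = HaplotypeTable(0.2, 0.1, 0.1, 0.6)  # marginals 0.3 / 0.3
    model = GeneratingModel(
        n_individuals=1000,
        variants=(("v1", 0.4), ("v2", 0.3)),
        per_allele_ldl_effects=(-0.5, -0.1),
        ld_structure={("v1", "v2"): table},
    )
    with pytest.raises(ValidationError, match="marginals"):
        simulate_cohort(model)


def test_noiseless_exposure_slope_is_exact():
    base = simulate_cohort(_single_variant_model(n_individuals=2000))
    g = base.genotypes[:, 0].astype(float)
    rng = np.random.default_rng(0)
    cohort = SyntheticCohort(
        variant_ids=["v1"],
        haplotypes=base.haplotypes,
        ldl=g * -0.5,
        outcomes={"T": (rng.random(base.n) < 0.3).astype(np.int8)},
        truth=base.truth,
    )
    panel = cohort_to_sumstats(cohort)[0]
    assert panel.get("v1", "LDL-C").beta == pytest.approx(-0.5, abs=1e-12)


def test_allele_table_log_or_matches_hand_calculation():
    # 15 cases carrying 10 lowering alleles, 15 controls carrying 20:
    # OR = (10x10)/(20x20) = 0.25
    g = np.array([2] * 5 + [0] * 10 + [2] * 10 + [0] * 5, dtype=float)
    y = np.array([1] * 15 + [0] * 15)
    record = _outcome_association(g, y, "T", "v1", eaf=0.5, z=1.96)
    assert record.beta == pytest.approx(math.log(0.25), abs=1e-12)


def test_empty_cell_triggers_continuity_correction_warning():
    g = np.array([0] * 20 + [1] * 10 + [0] * 10, dtype=float)
    y = np.array([1] * 20 + [0] * 20)
    with pytest.warns(UserWarning, match="continuity"):
        record = _outcome_association(g, y, "T", "v1", eaf=0.125, z=1.96)
    assert math.isfinite(record.beta) and record.se > 0


def test_monomorphic_variant_dropped_with_warning():
    base = simulate_cohort(_single_variant_model(n_individuals=2000))
    hap = base.haplotypes.copy()
    hap[:, :, 0] = 0  # force monomorphism
    cohort = SyntheticCohort(["v1"], hap, base.ldl, base.outcomes, base.truth)
    with pytest.warns(UserWarning, match="monomorphic"):
        panels = cohort_to_sumstats(cohort)
    assert len(panels[0]) == 0


def test_split_meta_analysis_agrees_with_unsplit_estimate():
    cohort = simulate_cohort(_single_variant_model(n_individuals=60_000))
    whole = cohort_to_sumstats(cohort)[0].get("v1", "CHD")
    parts = cohort_to_sumstats(cohort, split=3)
    pooled = fixed_effects_meta(
        [(p.get("v1", "CHD").beta, p.get("v1", "CHD").se) for p in parts]
    )
    assert abs(pooled.beta - whole.beta) < 3 * whole.se


def test_too_few_cases_per_pseudo_study_rejected():
    cohort = simulate_cohort(_single_variant_model(n_individuals=600))
    with pytest.raises(ValidationError, match="100"):
        cohort_to_sumstats(cohort, split=3)


def test_same_seed_gives_identical_cohorts_and_files(tmp_path):
    model = _single_variant_model(n_individuals=5000)
    a, b = simulate_cohort(model), simulate_cohort(model)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert np.array_equal(a.ldl, b.ldl)
    assert all(np.array_equal(a.outcomes[t], b.outcomes[t]) for t in a.outcomes)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_sumstats(cohort_to_sumstats(a)[0], pa)
    write_sumstats(cohort_to_sumstats(b)[0], pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_truth_round_trips_to_json(tmp_path):
    from mrscore.simulate import write_truth
    import json

    model = GeneratingModel(seed=3)
    write_truth(model, tmp_path / "truth.json")
    loaded = json.loads((tmp_path / "truth.json").read_text())
    assert loaded["seed"] == 3
    assert loaded["theta_by_trait"] == {"CHD": -0.51, "IS": 0.0}
    assert loaded["variants"] == [["rs11591147", 0.015], ["rs505151", 0.965]]


def test_model_validation():
    with pytest.raises(ValidationError):
        GeneratingModel(variants=(("v1", 1.5),), per_allele_ldl_effects=(-0.5,))
    with pytest.raises(ValidationError):
        GeneratingModel(per_allele_ldl_effects=(-0.5,))  # length mismatch
    with pytest.raises(ValidationError):
        GeneratingModel(ldl_noise_sd=0.0)
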