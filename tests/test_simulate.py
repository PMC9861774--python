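"""Synthetic-cohort generator: determinism, marginals, planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fingopred.labels import classify_followups
from fingopred.selection import point_biserial
from fingopred.simulate import (
    PRIOR_TREATMENTS,
    SimulationSpec,
    simulate_clinical,
    simulate_cohort,
    simulate_genotypes,
    simulate_outcome,
)


@pytest.mark.parametrize(
    "field,value",
    [
        ("maf_range", (0.0, 0.5)),
        ("maf_range", (0.1, 0.6)),
        ("missing_genotype_rate", 1.5),
        ("clinical_missing_rate", -0.1),
        ("causal_snp_count", 501),
        ("ld_within_block_r2", 1.2),
        ("n_snps", 0),
    ],
)
def test_invalid_spec_names_field(field, value):
    spec = SimulationSpec(n_snps=500)
    setattr(spec, field, value)
    with pytest.raises(ValueError, match=field.split("_")[0]):
        spec.validate()


def test_deterministic_given_seed(small_spec):
    g1, c1, f1 = simulate_cohort(small_spec)
    g2, c2, f2 = simulate_cohort(dataclasses.replace(small_spec))
    np.testing.assert_array_equal(g1.dosage, g2.dosage)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(f1.frame, f2.frame)
    pd.testing.assert_series_equal(f1.latent_status, f2.latent_status)


def test_zero_missing_rate_gives_complete_matrix():
    spec = SimulationSpec(
        n_samples_per_cohort=(50, 20), n_snps=100, missing_genotype_rate=0.0, seed=1
    )
    gm = simulate_genotypes(spec)
    assert not np.isnan(gm.dosage).any()


def test_perfect_ld_duplicates_block_columns():
    spec = SimulationSpec(
        n_samples_per_cohort=(150, 50),
        n_snps=20,
        ld_block_size=2,
        ld_within_block_r2=1.0,
        missing_genotype_rate=0.0,
        seed=3,
    )
    gm = simulate_genotypes(spec)
    for b in range(10):
        np.testing.assert_array_equal(gm.dosage[:, 2 * b], gm.dosage[:, 2 * b + 1])


def test_intermediate_ld_approximates_target_r2():
    spec = SimulationSpec(
        n_samples_per_cohort=(4000, 1000),
        n_snps=40,
        ld_block_size=4,
        ld_within_block_r2=0.5,
        missing_genotype_rate=0.0,
        seed=5,
    )
    gm = simulate_genotypes(spec)
    r2 = []
    for b in range(10):
        block = gm.dosage[:, 4 * b : 4 * b + 4]
        c = np.corrcoef(block.T)
        r2.extend(c[np.triu_indices(4, 1)] ** 2)
    assert abs(np.mean(r2) - 0.5) < 0.1


def test_empirical_mafs_stay_near_requested_range():
    """Binomial sampling keeps >= 99% of empirical MAFs within a small slack."""
    hits = total = 0
    for seed in range(20):
        spec = SimulationSpec(
            n_samples_per_cohort=(1600, 400),
            n_snps=1000,
            maf_range=(0.1, 0.5),
            missing_genotype_rate=0.0,
            seed=seed,
        )
        gm = simulate_genotypes(spec)
        p = gm.dosage.mean(axis=0) / 2
        maf = np.minimum(p, 1 - p)
        hits += int(((maf >= 0.08) & (maf <= 0.5)).sum())
        total += len(maf)
    assert hits / total >= 0.99


def test_clinical_marginals_and_one_hot():
    spec = SimulationSpec(n_samples_per_cohort=(8000, 2000), n_snps=10, seed=7)
    clin = simulate_clinical(spec)
    onehot = clin[[f"prior_tx_{t}" for t in PRIOR_TREATMENTS]]
    assert (onehot.sum(axis=1) == 1).all()
    assert abs(clin["age_at_onset"].mean() - 29.0) < 0.5
    assert abs(clin["arr_prior_2y"].mean() - 0.82) < 0.1
    assert set(clin["edss_baseline"] * 2) <= set(range(0, 15))
    assert 0.25 < clin["gdplus_baseline"].mean() < 0.42


def test_zero_clinical_missing_rate_means_all_classifiable(complete_cohort):
    _, (_, _, followups) = complete_cohort
    labels = classify_followups(followups.frame)
    assert (labels["status"] != "UNCLASSIFIABLE").all()


def test_null_model_gives_balanced_outcome():
    spec = SimulationSpec(
        n_samples_per_cohort=(3000, 1000),
        n_snps=20,
        causal_effect_sizes=0.0,
        clinical_effects={},
        intercept=0.0,
        clinical_missing_rate=0.0,
        seed=11,
    )
    _, _, followups = simulate_cohort(spec)
    frac = (followups.latent_status == "EDA").mean()
    assert abs(frac - 0.5) < 0.03


def test_strong_negative_intercept_saturates_to_neda():
    spec = SimulationSpec(
        n_samples_per_cohort=(400, 100),
        n_snps=20,
        causal_effect_sizes=0.0,
        clinical_effects={},
        intercept=-10.0,
        clinical_missing_rate=0.0,
        seed=13,
    )
    _, _, followups = simulate_cohort(spec)
    assert (followups.latent_status == "NEDA").mean() > 0.99


def test_labels_round_trip_for_classifiable_patients(small_cohort):
    _, _, followups = small_cohort
    labels = classify_followups(followups.frame).set_index("patient_id")["status"]
    classifiable = labels[labels != "UNCLASSIFIABLE"]
    truth = followups.latent_status.loc[classifiable.index]
    assert (classifiable == truth).all()


def test_misaligned_ids_raise(small_spec, small_cohort):
    genotypes, clinical, _ = small_cohort
    shuffled = clinical.iloc[::-1].reset_index(drop=True)
    with pytest.raises(ValueError, match="misaligned"):
        simulate_outcome(genotypes, shuffled, small_spec)


def test_planted_snps_separate_from_null_correlations():
    """Causal SNPs' |r| with the label clears the null 95th percentile."""
    wins = 0
    for seed in range(3):
        spec = SimulationSpec(
            n_samples_per_cohort=(900, 300),
            n_snps=400,
            causal_snp_count=8,
            causal_effect_sizes=0.5,
            clinical_effects={},
            missing_genotype_rate=0.0,
            clinical_missing_rate=0.0,
            seed=seed,
        )
        genotypes, _, followups = simulate_cohort(spec)
        y = (followups.latent_status == "EDA").to_numpy().astype(int)
        r = np.abs(point_biserial(genotypes.dosage, y))
        causal = [list(genotypes.variants["id"]).index(s) for s in followups.causal_snp_ids]
        null = np.delete(r, causal)
        wins += int((r[causal] > np.quantile(null, 0.95)).all())
    assert wins >= 2
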