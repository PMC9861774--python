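"""Genotype QC: MAF, exact HWE, filters, relatedness/MDS, LD pruning."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fingopred.qc import (
    QCThresholds,
    compute_maf,
    filter_samples,
    filter_snps,
    hwe_test,
    ld_prune,
    ld_prune_indices,
    run_qc,
    snp_call_rates,
)

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# MAF


def test_maf_hand_counts():
    col = np.zeros((100, 1))
    col[0] = 1  # 1 minor allele among 200
    gm = make_genotypes(col)
    assert compute_maf(gm)[0] == pytest.approx(0.005)

    gm = make_genotypes(np.ones((10, 1)))
    assert compute_maf(gm)[0] == pytest.approx(0.5)

    gm = make_genotypes(np.array([[0.0], [1.0], [2.0], [np.nan]]))
    assert compute_maf(gm)[0] == pytest.approx(0.5)  # 3/6 among non-missing


def test_maf_undefined_for_all_missing():
    gm = make_genotypes(np.full((5, 1), np.nan))
    assert np.isnan(compute_maf(gm)[0])
    assert snp_call_rates(gm)[0] == 0.0


# ---------------------------------------------------------------------------
# HWE exact test


def hwe_oracle(hom_minor: int, het: int, hom_major: int) -> float:
    """Independent brute-force enumeration with exact rational arithmetic."""
    n = hom_minor + het + hom_major
    n_minor = 2 * hom_minor + het
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    weights = {}
    for nab in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        naa = (n_minor - nab) // 2
        nbb = n - naa - nab
        weights[nab] = (
            math.factorial(n)
            // (math.factorial(naa) * math.factorial(nab) * math.factorial(nbb))
            * 2**nab
        )
    total = sum(weights.values())
    obs = weights[het]
    return float(Fraction(sum(w for w in weights.values() if w <= obs), total))


def test_hwe_monomorphic_is_one():
    assert hwe_test(0, 0, 100) == 1.0
    assert hwe_test(100, 0, 0) == 1.0


def test_hwe_extreme_heterozygote_deficit_fails_threshold():
    p = hwe_test(50, 0, 50)
    assert p == pytest.approx(hwe_oracle(50, 0, 50), abs=1e-12)
    assert p < 1e-4


def test_hwe_equilibrium_table_retained():
    p = hwe_test(25, 50, 25)
    assert p == pytest.approx(hwe_oracle(25, 50, 25), abs=1e-12)
    assert p > 0.5


@given(
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
)
def test_hwe_matches_enumeration_oracle(hom_minor, het, hom_major):
    if hom_minor + het + hom_major == 0:
        return
    assert hwe_test(hom_minor, het, hom_major) == pytest.approx(
        hwe_oracle(hom_minor, het, hom_major), abs=1e-10
    )


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# SNP filter


def _snp_fixture():
    rng = np.random.default_rng(0)
    n = 200
    clean = rng.binomial(2, 0.3, n).astype(float)
    rare = np.zeros(n)  # MAF 0 < 0.01
    rare[0] = 1.0
    low_call = rng.binomial(2, 0.3, n).astype(float)
    low_call[: int(n * 0.1)] = np.nan  # call rate 0.9
    hwe_bad = np.repeat([0.0, 2.0], n // 2)  # no heterozygotes at MAF 0.5
    dosage = np.column_stack([clean, rare, low_call, hwe_bad])
    return make_genotypes(dosage, maf_ids=["clean", "rare", "lowcall", "hwebad"])


def test_filter_snps_reason_codes():
    gm = _snp_fixture()
    kept, removed = filter_snps(gm, QCThresholds())
    assert dict(zip(removed["id"], removed["reason"])) == {
        "rare": "maf",
        "lowcall": "call_rate",
        "hwebad": "hwe",
    }
    assert list(kept.variants["id"]) == ["clean"]


def test_filter_snps_disabled_thresholds_keep_everything():
    gm = _snp_fixture()
    thr = QCThresholds(maf_min=0.0, snp_call_rate_min=0.0, hwe_p_min=0.0)
    kept, removed = filter_snps(gm, thr)
    assert removed.empty
    assert kept.n_snps == gm.n_snps


def test_filter_snps_idempotent():
    gm = _snp_fixture()
    kept, _ = filter_snps(gm, QCThresholds())
    again, removed = filter_snps(kept, QCThresholds())
    assert removed.empty
    assert again.n_snps == kept.n_snps


# ---------------------------------------------------------------------------
# sample filter


def test_duplicate_sample_removed_as_related():
    rng = np.random.default_rng(1)
    dosage = rng.binomial(2, 0.4, (20, 80)).astype(float)
    dosage[1] = dosage[0]  # duplicate pair, IBS = 1
    gm = make_genotypes(dosage)
    kept, removed = filter_samples(gm, QCThresholds())
    assert list(removed["reason"]) == ["relatedness"]
    assert removed["id"].iloc[0] in ("p0", "p1")
    assert kept.n_samples == 19


def test_clean_homogeneous_samples_all_kept():
    rng = np.random.default_rng(2)
    gm = make_genotypes(rng.binomial(2, 0.4, (30, 100)).astype(float))
    kept, removed = filter_samples(gm, QCThresholds())
    assert removed.empty
    assert kept.n_samples == 30


def test_low_call_rate_sample_removed():
    rng = np.random.default_rng(3)
    dosage = rng.binomial(2, 0.4, (10, 100)).astype(float)
    dosage[4, :90] = np.nan
    gm = make_genotypes(dosage)
    _, removed = filter_samples(gm, QCThresholds())
    assert ("p4", "call_rate") in list(zip(removed["id"], removed["reason"]))


# ---------------------------------------------------------------------------
# LD pruning


def test_identical_columns_prune_to_one():
    rng = np.random.default_rng(4)
    col = rng.binomial(2, 0.4, 100).astype(float)
    gm = make_genotypes(np.column_stack([col, col]))
    pruned, removed_ids = ld_prune(gm, QCThresholds())
    assert pruned.n_snps == 1
    assert len(removed_ids) == 1


def test_independent_columns_all_retained():
    rng = np.random.default_rng(5)
    gm = make_genotypes(rng.binomial(2, 0.4, (500, 30)).astype(float))
    pruned, removed_ids = ld_prune(gm, QCThresholds())
    assert removed_ids == []
    assert pruned.n_snps == 30


def test_correlated_pair_drops_lower_maf_member():
    rng = np.random.default_rng(6)
    n = 400
    a = rng.binomial(2, 0.45, n).astype(float)
    b = a.copy()
    flip = rng.random(n) < 0.05
    b[flip] = np.clip(b[flip] - 1, 0, 2)  # high r2 with A, lower MAF
    c = rng.binomial(2, 0.4, n).astype(float)
    gm = make_genotypes(np.column_stack([a, b, c]), maf_ids=["A", "B", "C"])
    # verify the fixture by exhaustive pairwise correlation
    r2 = np.corrcoef(np.column_stack([a, b, c]).T) ** 2
    assert r2[0, 1] > 0.2 and r2[0, 2] < 0.2 and r2[1, 2] < 0.2
    maf = compute_maf(gm)
    assert maf[0] > maf[1]
    pruned, removed_ids = ld_prune(gm, QCThresholds())
    assert removed_ids == ["B"]
    assert list(pruned.variants["id"]) == ["A", "C"]


def _processed_windows(n, window, step):
    for start in range(0, n, step):
        yield list(range(start, min(start + window, n)))
        if start + window >= n:
            break


def brute_force_window_violations(gm, thresholds):
    """All retained within-window pairs exceeding the r2 cap."""
    bad = []
    d = gm.dosage
    for window in _processed_windows(gm.n_snps, thresholds.ld_window, thresholds.ld_step):
        for i in window:
            for j in window:
                if i >= j:
                    continue
                x, y = d[:, i], d[:, j]
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
                if np.corrcoef(x, y)[0, 1] ** 2 > thresholds.ld_r2_max:
                    bad.append((i, j))
    return bad


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_pruned_panel_has_no_window_pair_above_threshold(seed):
    from fingopred.simulate import SimulationSpec, simulate_genotypes

    spec = SimulationSpec(
        n_samples_per_cohort=(150, 50),
        n_snps=200,
        ld_block_size=8,
        ld_within_block_r2=0.6,
        missing_genotype_rate=0.0,
        seed=seed,
    )
    gm = simulate_genotypes(spec)
    thr = QCThresholds(ld_window=25, ld_step=5)
    pruned, removed_ids = ld_prune(gm, thr)
    assert len(removed_ids) > 0  # blocks at r2 0.6 must lose SNPs
    assert brute_force_window_violations(pruned, thr) == []


def test_zero_variance_snp_is_never_a_pruning_victim():
    rng = np.random.default_rng(8)
    col = rng.binomial(2, 0.4, 50).astype(float)
    const = np.ones(50)
    gm = make_genotypes(np.column_stack([col, const, col]))
    _, removed_ids = ld_prune(gm, QCThresholds())
    assert "s1" not in removed_ids


def test_unsorted_positions_rejected():
    rng = np.random.default_rng(9)
    gm = make_genotypes(
        rng.binomial(2, 0.4, (20, 3)).astype(float), pos=[3000, 1000, 2000]
    )
    with pytest.raises(ValueError, match="ordered"):
        ld_prune_indices(gm, QCThresholds())


# ---------------------------------------------------------------------------
# full QC partition + threshold invariants


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=15)
def test_qc_partitions_variants_and_enforces_thresholds(seed):
    rng = np.random.default_rng(seed)
    n, p = 60, 40
    dosage = rng.binomial(2, rng.uniform(0.02, 0.5, p), (n, p)).astype(float)
    dosage[rng.random((n, p)) < 0.05] = np.nan
    gm = make_genotypes(dosage)
    thr = QCThresholds(ld_window=10, ld_step=2, maf_min=0.05, hwe_p_min=1e-3)
    report = run_qc(gm, thr)

    removed = set(report.removed_snps["id"])
    pruned = set(report.pruned_snps)
    retained = set(report.retained.variants["id"])
    assert removed | pruned | retained == set(gm.variants["id"])
    assert not (removed & pruned) and not (removed & retained) and not (pruned & retained)

    from fingopred.qc import hwe_pvalues

    final = report.retained
    if final.n_snps:
        assert (compute_maf(final) >= thr.maf_min - 1e-12).all()
        assert (snp_call_rates(final) >= thr.snp_call_rate_min - 1e-12).all()
        assert (hwe_pvalues(final) >= thr.hwe_p_min).all()
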