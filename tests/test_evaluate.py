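"""Metrics, tertile stratification, group comparisons, transfer evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from fingopred.evaluate import (
    accuracy,
    auprc,
    auroc,
    compare_groups,
    evaluate_scores,
    f_score,
    tertile_sizes,
    tertile_stratify,
    transfer_evaluate,
)


def auroc_pair_counting(scores, labels):
    """Brute-force oracle: fraction of correctly ordered +/- pairs, ties half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_auroc_hand_examples():
    assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auroc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)
    assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == pytest.approx(0.5)


def test_auroc_single_class_rejected():
    with pytest.raises(ValueError):
        auroc([0.1, 0.2], [1, 1])


@given(
    n=st.integers(min_value=2, max_value=40),
    seed=st.integers(min_value=0, max_value=10_000),
)
@settings(max_examples=60)
def test_auroc_equals_pair_counting_oracle(n, seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    s = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)  # force ties
    assert auroc(s, y) == pytest.approx(auroc_pair_counting(s, y), abs=1e-12)


@given(seed=st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30)
def test_label_inversion_flips_auroc(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, 30)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    s = rng.normal(size=30)
    assert auroc(s, y) == pytest.approx(1 - auroc(s, 1 - y), abs=1e-12)


def test_confusion_matrix_fixture():
    pred = [1, 1, 0, 0]
    y = [1, 0, 1, 0]
    assert f_score(pred, y) == pytest.approx(0.5)
    assert accuracy(pred, y) == pytest.approx(0.5)


def test_all_negative_predictions_give_zero_f():
    assert f_score([0, 0, 0], [1, 0, 1]) == 0.0


def test_perfect_classifier_metrics():
    rep = evaluate_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], "TEset")
    assert rep.auroc == 1.0
    assert rep.auprc == 1.0
    assert rep.f_score == 1.0
    assert rep.accuracy == 1.0
    assert rep.prevalence == 0.5


def test_status_string_labels_accepted():
    rep = evaluate_scores([0.9, 0.2], ["EDA", "NEDA"], "TEset")
    assert rep.auroc == 1.0


# ---------------------------------------------------------------------------
# tertiles


def test_tertile_sizes_follow_extremes_first_rule():
    assert tertile_sizes(77) == (26, 25, 26)
    assert tertile_sizes(9) == (3, 3, 3)
    assert tertile_sizes(10) == (4, 3, 3)


def test_tertile_partition_and_score_ordering():
    rng = np.random.default_rng(0)
    scores = pd.Series(rng.random(77), index=[f"p{i:03d}" for i in range(77)])
    groups = tertile_stratify(scores)
    assert groups.sizes == (26, 25, 26)
    all_ids = groups.prnr_ids + groups.middle_ids + groups.prr_ids
    assert sorted(all_ids) == sorted(scores.index)
    assert scores[groups.prnr_ids].mean() >= scores[groups.prr_ids].mean()
    assert scores[groups.prnr_ids].min() >= scores[groups.middle_ids].max()


def test_constant_scores_still_split_deterministically():
    scores = pd.Series(0.5, index=[f"p{i}" for i in range(9)])
    with pytest.warns(UserWarning, match="tied"):
        groups = tertile_stratify(scores)
    assert groups.sizes == (3, 3, 3)
    with pytest.warns(UserWarning, match="tied"):
        again = tertile_stratify(scores)
    assert again.prnr_ids == groups.prnr_ids


def test_too_few_patients_rejected():
    with pytest.raises(ValueError):
        tertile_stratify(pd.Series([0.1, 0.9]))


# ---------------------------------------------------------------------------
# group comparison


def _followups(ids, relapses, t2_counts, labels_):
    n = len(ids)
    fu = pd.DataFrame(
        {
            "patient_id": ids,
            "relapse_count_2y": relapses,
            "new_t2_flag": [1 if c > 0 else 0 for c in t2_counts],
            "gdplus_flag": 0,
            "active_t2_count_2y": t2_counts,
            "edss_baseline": [2.0] * n,
            "edss_2y": [2.0] * n,
            "months_since_ntz_stop": [np.nan] * n,
        }
    )
    lab = pd.DataFrame({"patient_id": ids, "status": labels_})
    return fu, lab


def yates_chi2_p(a, b, c, d):
    """Closed-form continuity-corrected chi-square p for a 2x2 table."""
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    stat = num / den
    return 2 * norm.sf(np.sqrt(stat))


def test_identical_groups_mann_whitney_p_is_one():
    ids = [f"p{i}" for i in range(12)]
    fu, lab = _followups(
        ids,
        relapses=[0, 1, 2, 0, 1, 2] * 2,
        t2_counts=[0, 1, 3, 0, 1, 3] * 2,
        labels_=["NEDA", "EDA", "EDA"] * 4,
    )
    out = compare_groups(ids[:6], ids[6:], fu, lab)
    assert out.p_relapse_count == pytest.approx(1.0)
    assert out.p_t2_count == pytest.approx(1.0)


def test_chi_square_matches_textbook_yates_formula():
    # PrNR: 18 of 24 active; PrR: 7 of 26 active
    ids = [f"p{i}" for i in range(50)]
    status = ["EDA"] * 18 + ["NEDA"] * 6 + ["EDA"] * 7 + ["NEDA"] * 19
    varied = [i % 2 for i in range(50)]  # keeps the other 2x2 margins non-zero
    fu, lab = _followups(ids, varied, varied, status)
    out = compare_groups(ids[:24], ids[24:], fu, lab)
    assert out.p_eda == pytest.approx(yates_chi2_p(18, 6, 7, 19), rel=1e-10)
    assert out.eda_prop["PrNR"] == pytest.approx(18 / 24)
    assert out.eda_prop["PrR"] == pytest.approx(7 / 26)


def test_zero_margin_table_raises():
    ids = [f"p{i}" for i in range(10)]
    fu, lab = _followups(ids, [0] * 10, [0] * 10, ["NEDA"] * 10)
    with pytest.raises(ValueError, match="zero margin"):
        compare_groups(ids[:5], ids[5:], fu, lab)


def test_empty_or_overlapping_groups_rejected():
    ids = [f"p{i}" for i in range(6)]
    fu, lab = _followups(ids, [0] * 6, [0] * 6, ["EDA", "NEDA"] * 3)
    with pytest.raises(ValueError):
        compare_groups([], ids, fu, lab)
    with pytest.raises(ValueError):
        compare_groups(ids[:4], ids[3:], fu, lab)


# ---------------------------------------------------------------------------
# transfer


def test_identity_transfer_reproduces_te_report(complete_cohort):
    from fingopred.forest import RFParams, impute_mode, train_rf

    _, (genotypes, _, followups) = complete_cohort
    y = (followups.latent_status == "EDA").astype(int)
    X = impute_mode(genotypes.dosage_frame())
    signature = list(X.columns[:25])
    model = train_rf(X.iloc[:100][signature], y.iloc[:100], RFParams(ntree=20, seed=0))
    te_ids = y.index[100:]
    s = model.predict_proba1({"genetic": X.loc[te_ids, signature]})
    direct = evaluate_scores(s, y.loc[te_ids], "TEset")
    via_transfer = transfer_evaluate(model, genotypes, y.loc[te_ids])
    assert via_transfer.auroc == pytest.approx(direct.auroc)
    assert via_transfer.accuracy == pytest.approx(direct.accuracy)


def test_transfer_with_missing_signature_snps_raises(complete_cohort):
    from fingopred.forest import RFParams, impute_mode, train_rf

    _, (genotypes, _, followups) = complete_cohort
    y = (followups.latent_status == "EDA").astype(int)
    X = impute_mode(genotypes.dosage_frame())
    model = train_rf(X.iloc[:100, :10], y.iloc[:100], RFParams(ntree=5, seed=0))
    smaller = genotypes.subset(snp_idx=np.arange(5, genotypes.n_snps))
    with pytest.raises(KeyError, match="missing signature"):
        transfer_evaluate(model, smaller, y.iloc[100:])
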