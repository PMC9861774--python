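"""Model evaluation: ranking metrics, tertile stratification, transfer.

The positive class throughout is EDA (evidence of disease activity, i.e.
non-response), so model scores are predicted probabilities of non-response.
AUROC is computed with the rank (Mann-Whitney) formula with ties counted
half; AUPRC is step-wise precision-recall integration without interpolation;
F-score and accuracy threshold the consensus probability at 0.5 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu, rankdata
from sklearn.metrics import average_precision_score

POSITIVE_STATUS = "EDA"


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":  # status strings
        return (arr == POSITIVE_STATUS).astype(int)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("labels must be 0/1 or EDA/NEDA status strings")
    return arr.astype(int)


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals U / (n_pos * n_neg) with tied scores counted half.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise, no interpolation)."""
    y = _as_binary(labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("AUPRC needs both classes present")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def f_score(pred, labels) -> float:
    """F1 for the positive (EDA / non-response) class; 0 when P + R = 0."""
    y = _as_binary(labels)
    p = _as_binary(pred)
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def accuracy(pred, labels) -> float:
    y = _as_binary(labels)
    p = _as_binary(pred)
    return float((p == y).mean())


@dataclass
class MetricsReport:
    """AUROC / AUPRC / F / accuracy for one model on one evaluation set."""

    auroc: float
    auprc: float
    f_score: float
    accuracy: float
    n: int
    prevalence: float
    set_label: str

    def as_dict(self) -> dict:
        return {
            "set": self.set_label,
            "n": self.n,
            "prevalence": round(self.prevalence, 4),
            "auroc": round(self.auroc, 4),
            "auprc": round(self.auprc, 4),
            "f_score": round(self.f_score, 4),
            "accuracy": round(self.accuracy, 4),
        }


def evaluate_scores(
    scores, labels, set_label: str = "", threshold: float = 0.5
) -> MetricsReport:
    """All four metrics from continuous non-response scores."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    return MetricsReport(
        auroc=auroc(s, y),
        auprc=auprc(s, y),
        f_score=f_score(pred, y),
        accuracy=accuracy(pred, y),
        n=len(y),
        prevalence=float(y.mean()),
        set_label=set_label,
    )


# ---------------------------------------------------------------------------
# tertile stratification (PrNR / PrR)


@dataclass
class TertileGroups:
    """Predicted non-responder (PrNR) / responder (PrR) tertiles."""

    prnr_ids: list  # highest tertile of predicted non-response probability
    middle_ids: list
    prr_ids: list  # lowest tertile

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.prnr_ids), len(self.middle_ids), len(self.prr_ids))


def tertile_sizes(n: int) -> tuple[int, int, int]:
    """(high, middle, low) group sizes; remainders go to the extremes first."""
    base, rem = divmod(n, 3)
    if rem == 0:
        return (base, base, base)
    if rem == 1:
        return (base + 1, base, base)
    return (base + 1, base, base + 1)


def tertile_stratify(scores: pd.Series) -> TertileGroups:
    """Split patients into tertiles of the predicted non-response probability.

    Patients are ordered by decreasing score (ties by patient id); the top
    tertile is PrNR, the bottom PrR.  Ties spanning a tertile boundary are
    resolved deterministically by that ordering, with a warning.
    """
    scores = pd.Series(scores)
    n = len(scores)
    if n < 3:
        raise ValueError("tertile stratification needs at least 3 patients")
    order = scores.reset_index()
    order.columns = ["patient_id", "score"]
    order = order.sort_values(
        ["score", "patient_id"], ascending=[False, True], kind="mergesort"
    )
    hi, mid, lo = tertile_sizes(n)
    ranked = order["patient_id"].tolist()
    svals = order["score"].to_numpy()
    for boundary in (hi, hi + mid):
        if 0 < boundary < n and svals[boundary - 1] == svals[boundary]:
            warnings.warn(
                "tied scores span a tertile boundary; resolved by patient id",
                stacklevel=2,
            )
    return TertileGroups(
        prnr_ids=ranked[:hi],
        middle_ids=ranked[hi : hi + mid],
        prr_ids=ranked[hi + mid :],
    )


def _chi2_2x2(a_pos: int, a_neg: int, b_pos: int, b_neg: int) -> float:
    """Two-sided p of the Yates-corrected chi-square test on a 2x2 table."""
    table = np.array([[a_pos, a_neg], [b_pos, b_neg]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square table has a zero margin")
    _, p, _, _ = chi2_contingency(table, correction=True)
    return float(p)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p, normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in Mann-Whitney comparison")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: no variation at all
        return 1.0
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=False)
    return float(res.pvalue)


@dataclass
class TertileComparison:
    """Disease-activity contrast between the PrNR and PrR tertiles."""

    n_prnr: int
    n_prr: int
    eda_prop: dict  # group -> proportion with EDA
    mri_active_prop: dict  # group -> proportion with MRI activity
    clinical_active_prop: dict  # group -> proportion with >= 1 relapse
    mean_t2_count: dict  # group -> mean new/enlarging T2 count
    mean_relapse_count: dict  # group -> mean relapse count
    p_eda: float  # chi-square (Yates) p-values
    p_mri_active: float
    p_clinical_active: float
    p_t2_count: float  # Mann-Whitney p-values
    p_relapse_count: float

    def as_dict(self) -> dict:
        return {
            "n_prnr": self.n_prnr,
            "n_prr": self.n_prr,
            "eda_prop": self.eda_prop,
            "mri_active_prop": self.mri_active_prop,
            "clinical_active_prop": self.clinical_active_prop,
            "mean_t2_count": self.mean_t2_count,
            "mean_relapse_count": self.mean_relapse_count,
            "p_eda": self.p_eda,
            "p_mri_active": self.p_mri_active,
            "p_clinical_active": self.p_clinical_active,
            "p_t2_count": self.p_t2_count,
            "p_relapse_count": self.p_relapse_count,
        }


def compare_groups(
    prnr_ids, prr_ids, followups: pd.DataFrame, labels: pd.DataFrame
) -> TertileComparison:
    """Compare disease activity between the PrNR and PrR tertiles.

    Counts (new/enlarging T2 lesions, relapses) are compared with the
    two-sided Mann-Whitney test; the proportions of patients with EDA, MRI
    activity and clinical activity with the Yates-corrected chi-square test.
    Missing follow-up fields are dropped pairwise.
    """
    prnr_ids, prr_ids = list(prnr_ids), list(prr_ids)
    if not prnr_ids or not prr_ids:
        raise ValueError("both tertile groups must be non-empty")
    if set(prnr_ids) & set(prr_ids):
        raise ValueError("tertile groups overlap")
    fu = followups.set_index("patient_id")
    lab = labels.set_index("patient_id")["status"]

    def group_frame(ids):
        g = fu.loc[ids].copy()
        g["eda"] = (lab.loc[ids] == POSITIVE_STATUS).astype(int)
        g["mri_active"] = (
            (g["new_t2_flag"] == 1) | (g["gdplus_flag"] == 1)
        ).astype(int)
        g["clin_active"] = (g["relapse_count_2y"] >= 1).astype(int)
        return g

    a, b = group_frame(prnr_ids), group_frame(prr_ids)

    def prop_test(col):
        ap, bp = int(a[col].sum()), int(b[col].sum())
        p = _chi2_2x2(ap, len(a) - ap, bp, len(b) - bp)
        return {"PrNR": ap / len(a), "PrR": bp / len(b)}, p

    eda_prop, p_eda = prop_test("eda")
    mri_prop, p_mri = prop_test("mri_active")
    clin_prop, p_clin = prop_test("clin_active")

    t2_a = a["active_t2_count_2y"].dropna().to_numpy()
    t2_b = b["active_t2_count_2y"].dropna().to_numpy()
    rel_a = a["relapse_count_2y"].dropna().to_numpy()
    rel_b = b["relapse_count_2y"].dropna().to_numpy()
    return TertileComparison(
        n_prnr=len(a),
        n_prr=len(b),
        eda_prop=eda_prop,
        mri_active_prop=mri_prop,
        clinical_active_prop=clin_prop,
        mean_t2_count={"PrNR": float(np.mean(t2_a)), "PrR": float(np.mean(t2_b))},
        mean_relapse_count={
            "PrNR": float(np.mean(rel_a)),
            "PrR": float(np.mean(rel_b)),
        },
        p_eda=p_eda,
        p_mri_active=p_mri,
        p_clinical_active=p_clin,
        p_t2_count=_mannwhitney(t2_a, t2_b),
        p_relapse_count=_mannwhitney(rel_a, rel_b),
    )


def transfer_evaluate(
    model, genotypes, labels: pd.Series, threshold: float = 0.5
) -> MetricsReport:
    """Apply a frozen genetic model to another cohort without retraining.

    ``genotypes`` is the transfer cohort's GenotypeMatrix; its panel must
    contain every SNP of the model's genetic signature (missing ids raise).
    Missing calls are mode-imputed per SNP before prediction.
    """
    from .forest import impute_mode  # local import to avoid a cycle

    labels = pd.Series(labels)
    signature = model.feature_names_["genetic"]
    panel = genotypes.dosage_frame().loc[labels.index]
    absent = [s for s in signature if s not in panel.columns]
    if absent:
        raise KeyError(f"transfer cohort is missing signature SNPs: {absent[:10]}")
    X = impute_mode(panel[signature])
    scores = model.predict_proba1({"genetic": X})
    return evaluate_scores(scores, labels, set_label="transfer", threshold=threshold)
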