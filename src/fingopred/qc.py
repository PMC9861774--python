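"""Genotype quality control and LD pruning.

Per-SNP filters (MAF, call rate, exact Hardy-Weinberg test), per-sample
filters (call rate, IBS-based relatedness, MDS ancestry outliers) and greedy
sliding-window LD pruning on the dosage correlation.  Filters follow the
conventional order MAF -> call rate -> HWE for reason codes; after sample
removal the per-SNP filters are re-applied so that every retained SNP
satisfies all thresholds on the final sample set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .data import GenotypeMatrix


@dataclass
class QCThresholds:
    """Thresholds for SNP/sample QC and LD pruning.

    Defaults mirror standard array-QC practice: drop SNPs with MAF < 0.01,
    call rate < 0.97 or HWE exact p < 1e-4; drop samples with call rate
    < 0.95, pairwise IBS sharing above ``relatedness_max`` or lying more than
    ``mds_outlier_sd`` SDs from the MDS centroid; prune SNP pairs with
    r^2 > 0.2 in sliding windows of 50 SNPs advanced by 5.
    """

    maf_min: float = 0.01
    snp_call_rate_min: float = 0.97
    hwe_p_min: float = 1e-4
    sample_call_rate_min: float = 0.95
    relatedness_max: float = 0.9
    mds_outlier_sd: float = 6.0
    ld_r2_max: float = 0.2
    ld_window: int = 50
    ld_step: int = 5

    def validate(self) -> None:
        for name in (
            "maf_min",
            "snp_call_rate_min",
            "hwe_p_min",
            "sample_call_rate_min",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ld_window < 1 or self.ld_step < 1:
            raise ValueError("ld_window and ld_step must be >= 1")
        if self.ld_step > self.ld_window:
            raise ValueError("ld_step must not exceed ld_window")


@dataclass
class QCReport:
    """Outcome of the full QC stage.

    ``removed_snps``/``removed_samples`` carry one row per removal with a
    reason code; ``pruned_snps`` lists SNPs dropped by LD pruning only.  The
    input variant set is partitioned into removed + pruned + retained.
    """

    removed_snps: pd.DataFrame
    removed_samples: pd.DataFrame
    pruned_snps: list
    retained: GenotypeMatrix
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-SNP statistics


def compute_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per SNP: min(p, 1-p) over non-missing calls.

    SNPs with zero non-missing calls get NaN (they fall to the call-rate
    rule).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(gm.dosage, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def snp_call_rates(gm: GenotypeMatrix) -> np.ndarray:
    return 1.0 - np.isnan(gm.dosage).mean(axis=0)


def sample_call_rates(gm: GenotypeMatrix) -> np.ndarray:
    return 1.0 - np.isnan(gm.dosage).mean(axis=1)


def genotype_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hom coded-allele, het, hom other-allele) counts per SNP."""
    d = gm.dosage
    hom_minor = np.nansum(d == 2, axis=0).astype(int)
    het = np.nansum(d == 1, axis=0).astype(int)
    hom_major = np.nansum(d == 0, axis=0).astype(int)
    return hom_minor, het, hom_major


def _hwe_het_weights(n_minor: int, n_total: int) -> tuple[np.ndarray, list[int]]:
    """Conditional distribution of the heterozygote count given allele counts.

    Returns the admissible heterozygote counts (same parity as ``n_minor``)
    and exact integer weights proportional to the conditional null
    P(n_het | n_minor, N) = N! / (nAA! nAB! nBB!) * 2^nAB * nA! nB! / (2N)!.
    Integer weights keep probability ties exact, so the "probability <=
    observed" summation has no floating-point ambiguity.
    """
    n_major = 2 * n_total - n_minor
    if n_minor < 0 or n_major < 0:
        raise ValueError("allele counts out of range")
    n_eff = min(n_minor, n_major)
    het = np.arange(n_eff % 2, n_eff + 1, 2)
    weights = []
    for nab in het:
        naa = (n_minor - nab) // 2
        weights.append(
            math.comb(n_total, naa) * math.comb(n_total - naa, int(nab)) * 2 ** int(nab)
        )
    return het, weights


def hwe_pvalues_for_allele_count(n_minor: int, n_total: int) -> np.ndarray:
    """Exact-test p-value for every admissible heterozygote count.

    p(nAB) = sum of the conditional probabilities of all heterozygote counts
    whose probability does not exceed that of nAB.
    """
    _, weights = _hwe_het_weights(n_minor, n_total)
    total = sum(weights)
    order = sorted(range(len(weights)), key=lambda i: weights[i])
    pvals = np.empty(len(weights))
    csum = 0
    j = 0
    while j < len(order):
        k = j
        tie = weights[order[j]]
        while k < len(order) and weights[order[k]] == tie:
            csum += tie
            k += 1
        p = float(Fraction(csum, total))
        for i in order[j:k]:
            pvals[i] = p
        j = k
    return np.minimum(pvals, 1.0)


def hwe_test(hom_minor: int, het: int, hom_major: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, probability mass).

    Monomorphic SNPs return p = 1 by convention.
    """
    if min(hom_minor, het, hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n_total = hom_minor + het + hom_major
    if n_total == 0:
        raise ValueError("at least one genotype is required")
    n_minor = 2 * hom_minor + het
    if n_minor == 0 or n_minor == 2 * n_total:
        return 1.0
    het_values, _ = _hwe_het_weights(n_minor, n_total)
    pvals = hwe_pvalues_for_allele_count(n_minor, n_total)
    idx = np.searchsorted(het_values, het)
    if idx >= len(het_values) or het_values[idx] != het:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(pvals[idx])


def hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    hom_minor, het, hom_major = genotype_counts(gm)
    out = np.ones(gm.n_snps)
    for j in range(gm.n_snps):
        total = hom_minor[j] + het[j] + hom_major[j]
        if total > 0:
            out[j] = hwe_test(int(hom_minor[j]), int(het[j]), int(hom_major[j]))
    return out


# ---------------------------------------------------------------------------
# SNP and sample filters


def filter_snps(
    gm: GenotypeMatrix, thresholds: QCThresholds
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove SNPs failing MAF, call-rate or HWE rules (in that order).

    The reason code records the first failing rule.  Returns the retained
    matrix and a (id, reason) frame of removals.
    """
    thresholds.validate()
    maf = compute_maf(gm)
    rate = snp_call_rates(gm)
    reasons = np.full(gm.n_snps, "", dtype=object)
    fail_maf = ~np.isnan(maf) & (maf < thresholds.maf_min)
    reasons[fail_maf] = "maf"
    fail_rate = (reasons == "") & (rate < thresholds.snp_call_rate_min)
    reasons[fail_rate] = "call_rate"
    todo = np.flatnonzero(reasons == "")
    if thresholds.hwe_p_min > 0 and todo.size:
        hom_minor, het, hom_major = genotype_counts(gm)
        for j in todo:
            total = hom_minor[j] + het[j] + hom_major[j]
            if total == 0:
                continue
            if hwe_test(int(hom_minor[j]), int(het[j]), int(hom_major[j])) < (
                thresholds.hwe_p_min
            ):
                reasons[j] = "hwe"
    removed_mask = reasons != ""
    removed = pd.DataFrame(
        {
            "id": gm.variants.loc[removed_mask, "id"].to_numpy(),
            "reason": reasons[removed_mask],
        }
    )
    return gm.subset(snp_idx=~removed_mask), removed


def ibs_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state sharing: mean of 1 - |d_i - d_j| / 2.

    Computed over SNPs non-missing in both samples; pairs with no shared
    calls get NaN.
    """
    d = gm.dosage
    obs = ~np.isnan(d)
    filled = np.where(obs, d, 0.0)
    # sum |di - dj| over shared SNPs, accumulated per dosage level to stay
    # vectorised: |a-b| = a + b - 2*min(a,b); easier via one-hot levels
    n = gm.n_samples
    shared = obs.astype(float) @ obs.astype(float).T
    absdiff = np.zeros((n, n))
    levels = [0.0, 1.0, 2.0]
    onehot = {v: (np.where(obs, d == v, False)).astype(float) for v in levels}
    for a in levels:
        for b in levels:
            w = abs(a - b)
            if w:
                absdiff += w * (onehot[a] @ onehot[b].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - absdiff / (2.0 * shared)
    ibs[shared == 0] = np.nan
    return ibs


def classical_mds(distance: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix."""
    d2 = np.asarray(distance, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_axes]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def filter_samples(
    gm: GenotypeMatrix, thresholds: QCThresholds
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove samples by call rate, excess relatedness and ancestry outliers.

    Relatedness: pairs with IBS sharing above ``relatedness_max`` lose the
    member with the lower call rate (tie: the later sample).  Ancestry:
    classical MDS on 1 - IBS; samples farther than ``mds_outlier_sd`` SDs
    from the centroid on either of the first two axes are dropped.
    """
    thresholds.validate()
    if gm.n_samples < 2:
        raise ValueError("sample QC needs at least 2 samples")
    removed: list[tuple[str, str]] = []

    rate = sample_call_rates(gm)
    keep = rate >= thresholds.sample_call_rate_min
    removed += [(sid, "call_rate") for sid in gm.samples.loc[~keep, "id"]]
    current = gm.subset(sample_idx=keep)
    cur_rate = rate[keep]

    if current.n_samples >= 2 and thresholds.relatedness_max < 1:
        ibs = ibs_matrix(current)
        np.fill_diagonal(ibs, np.nan)
        drop = np.zeros(current.n_samples, dtype=bool)
        pairs = np.argwhere(
            np.triu(np.nan_to_num(ibs, nan=-1.0), k=1) > thresholds.relatedness_max
        )
        for i, j in pairs:
            if drop[i] or drop[j]:
                continue
            # remove the lower-call-rate member; ties remove the later sample
            victim = j if cur_rate[j] <= cur_rate[i] else i
            drop[victim] = True
        removed += [(sid, "relatedness") for sid in current.samples.loc[drop, "id"]]
        current = current.subset(sample_idx=~drop)

    if current.n_samples >= 3 and np.isfinite(thresholds.mds_outlier_sd):
        ibs = ibs_matrix(current)
        np.fill_diagonal(ibs, 1.0)
        dist = 1.0 - np.nan_to_num(ibs, nan=1.0)
        coords = classical_mds(dist, n_axes=2)
        sd = coords.std(axis=0, ddof=0)
        z = np.zeros_like(coords)
        nonzero = sd > 0
        z[:, nonzero] = np.abs(
            coords[:, nonzero] - coords[:, nonzero].mean(axis=0)
        ) / sd[nonzero]
        out = (z > thresholds.mds_outlier_sd).any(axis=1)
        removed += [(sid, "ancestry") for sid in current.samples.loc[out, "id"]]
        current = current.subset(sample_idx=~out)

    removed_df = pd.DataFrame(removed, columns=["id", "reason"])
    return current, removed_df


# ---------------------------------------------------------------------------
# LD pruning


def _window_r2(dosage: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns.

    Missing calls are mean-imputed per column; zero-variance columns get
    r^2 = 0 with every partner.
    """
    x = dosage.copy()
    mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    idx = np.nonzero(np.isnan(x))
    x[idx] = mean[idx[1]]
    x = x - x.mean(axis=0)
    ss = (x**2).sum(axis=0)
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x.T @ x) / denom
    r2 = r**2
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune_indices(gm: GenotypeMatrix, thresholds: QCThresholds) -> np.ndarray:
    """Positional indices of SNPs removed by greedy windowed pruning.

    Windows of ``ld_window`` SNPs advance by ``ld_step`` within each
    chromosome (SNPs must be ordered by chromosome and position).  Within a
    window, while any retained pair exceeds ``ld_r2_max``, the pair with the
    highest r^2 is resolved by removing its lower-MAF member (ties: the SNP
    at the later position).
    """
    thresholds.validate()
    chrom = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    for ch in np.unique(chrom):
        p = pos[chrom == ch]
        if np.any(np.diff(p) < 0):
            raise ValueError("SNPs must be ordered by chromosome and position")
    maf = compute_maf(gm)
    maf = np.where(np.isnan(maf), 0.0, maf)
    removed = np.zeros(gm.n_snps, dtype=bool)
    for ch in pd.unique(pd.Series(chrom)):
        snps = np.flatnonzero(chrom == ch)
        n = len(snps)
        for start in range(0, n, thresholds.ld_step):
            window = snps[start : start + thresholds.ld_window]
            active = window[~removed[window]]
            if len(active) < 2:
                if start + thresholds.ld_window >= n:
                    break
                continue
            r2 = _window_r2(gm.dosage[:, active])
            alive = np.ones(len(active), dtype=bool)
            while True:
                sub = np.where(np.outer(alive, alive), r2, 0.0)
                i, j = np.unravel_index(np.argmax(sub), sub.shape)
                if sub[i, j] <= thresholds.ld_r2_max:
                    break
                a, b = active[i], active[j]
                if maf[a] < maf[b] or (maf[a] == maf[b] and pos[a] > pos[b]):
                    victim_local, victim = i, a
                else:
                    victim_local, victim = j, b
                alive[victim_local] = False
                removed[victim] = True
            if start + thresholds.ld_window >= n:
                break
    return np.flatnonzero(removed)


def ld_prune(
    gm: GenotypeMatrix, thresholds: QCThresholds
) -> tuple[GenotypeMatrix, list]:
    """Prune LD-redundant SNPs; returns the pruned panel and removed ids."""
    idx = ld_prune_indices(gm, thresholds)
    pruned_ids = gm.variants["id"].iloc[idx].tolist()
    keep = np.ones(gm.n_snps, dtype=bool)
    keep[idx] = False
    return gm.subset(snp_idx=keep), pruned_ids


# ---------------------------------------------------------------------------
# full QC driver


def run_qc(gm: GenotypeMatrix, thresholds: QCThresholds | None = None) -> QCReport:
    """SNP filters -> sample filters -> SNP filters (re-check) -> LD pruning."""
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    step1, removed_snps = filter_snps(gm, thresholds)
    step2, removed_samples = filter_samples(step1, thresholds)
    # sample removal shifts per-SNP statistics; re-apply so retained SNPs
    # satisfy every threshold on the final sample set
    step3, removed_again = filter_snps(step2, thresholds)
    removed_snps = pd.concat([removed_snps, removed_again], ignore_index=True)
    retained, pruned_ids = ld_prune(step3, thresholds)
    summary = {
        "snps_in": gm.n_snps,
        "samples_in": gm.n_samples,
        "snps_removed": int(len(removed_snps)),
        "samples_removed": int(len(removed_samples)),
        "snps_pruned": len(pruned_ids),
        "snps_out": retained.n_snps,
        "samples_out": retained.n_samples,
    }
    return QCReport(
        removed_snps=removed_snps,
        removed_samples=removed_samples,
        pruned_snps=pruned_ids,
        retained=retained,
        summary=summary,
    )
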