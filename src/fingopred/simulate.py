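"""Two-center synthetic cohort generator.

Emulates the kind of data the pipeline is built for: an LD-pruned autosomal
SNP panel coded as additive minor-allele dosages, 17 baseline clinical
features, and 2-year follow-up records from which the NEDA-3 response label
is derived.  Two cohorts of unequal size stand in for the two recruiting
centers; a sparse set of causal SNPs plus a handful of clinical features act
on a latent logistic liability for disease activity (EDA).

The generator's defaults reflect the study conditions the pipeline targets:
cohort sizes 342/78, a near-balanced outcome (~52% EDA), AAO 29 +/- 9.5 years,
ARR 0.82 +/- 0.84, ~33% Gd+ and ~49% new-T2 at baseline, one prior-treatment
category per patient, and a clinical missing-data rate that leaves roughly 9%
of patients unclassifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

#: the nine mutually exclusive prior-treatment categories (one-hot per patient)
PRIOR_TREATMENTS = [
    "naive",
    "none",
    "ifn",
    "ga",
    "dmf",
    "teriflunomide",
    "immunosuppressant",
    "natalizumab",
    "other",
]
#: whole-cohort category frequencies the generator draws from
PRIOR_TREATMENT_PROBS = [0.079, 0.068, 0.391, 0.273, 0.034, 0.029, 0.045, 0.076, 0.005]

#: 17 baseline features, in canonical order (9 one-hot prior-treatment flags)
CLINICAL_FEATURES = [
    "sex_female",
    "age_at_onset",
    "age_at_fty_start",
    "disease_duration",
    "arr_prior_2y",
    "edss_baseline",
    "t2_baseline",
    "gdplus_baseline",
] + [f"prior_tx_{t}" for t in PRIOR_TREATMENTS]

#: fixed (mean, sd) used to put clinical effects on a standardized scale
CLINICAL_STANDARDIZATION = {
    "age_at_fty_start": (39.5, 9.5),
    "arr_prior_2y": (0.82, 0.84),
    "t2_baseline": (0.491, 0.5),
    "gdplus_baseline": (0.335, 0.472),
    "edss_baseline": (2.2, 1.4),
    "age_at_onset": (29.0, 9.5),
    "disease_duration": (10.5, 7.6),
    "sex_female": (0.709, 0.454),
}


def _default_clinical_effects() -> dict:
    # log-odds of EDA per SD of the (standardized) feature; the informative
    # features mirror the clinically established activity predictors: age at
    # treatment start (protective), prior relapse rate and baseline MRI
    # activity (risk).
    return {
        "age_at_fty_start": -0.37,
        "arr_prior_2y": 0.60,
        "t2_baseline": 0.67,
        "gdplus_baseline": 0.52,
    }


@dataclass
class SimulationSpec:
    """Parameters of the two-center synthetic cohort.

    ``causal_effect_sizes`` is either a scalar (applied to every causal SNP
    with alternating sign) or a sequence of per-SNP log-odds.  Clinical
    effects are log-odds per standard deviation of the feature.
    """

    n_samples_per_cohort: tuple[int, int] = (342, 78)
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_within_block_r2: float = 0.1
    missing_genotype_rate: float = 0.01
    causal_snp_count: int = 10
    causal_effect_sizes: float | tuple = 0.5
    clinical_effects: dict = field(default_factory=_default_clinical_effects)
    intercept: float = 0.1
    clinical_missing_rate: float = 0.04
    #: multinomial over which activity component(s) fire for an EDA patient:
    #: (relapse only, MRI only, relapse+MRI, EDSS progression)
    eda_component_probs: tuple = (0.3, 0.35, 0.25, 0.1)
    seed: int = 2023

    def validate(self) -> None:
        if len(self.n_samples_per_cohort) != 2 or any(
            int(n) <= 0 for n in self.n_samples_per_cohort
        ):
            raise ValueError("n_samples_per_cohort must be two positive counts")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0 <= self.ld_within_block_r2 <= 1:
            raise ValueError("ld_within_block_r2 must be in [0, 1]")
        for name in ("missing_genotype_rate", "clinical_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.causal_snp_count <= self.n_snps:
            raise ValueError("causal_snp_count must be between 0 and n_snps")
        if len(self.eda_component_probs) != 4 or not math.isclose(
            sum(self.eda_component_probs), 1.0, abs_tol=1e-9
        ):
            raise ValueError("eda_component_probs must be 4 probabilities summing to 1")

    def causal_effect_vector(self) -> np.ndarray:
        """Per-causal-SNP log-odds; scalar input alternates sign across SNPs."""
        if np.isscalar(self.causal_effect_sizes):
            signs = np.where(np.arange(self.causal_snp_count) % 2 == 0, 1.0, -1.0)
            return float(self.causal_effect_sizes) * signs
        betas = np.asarray(self.causal_effect_sizes, dtype=float)
        if betas.shape != (self.causal_snp_count,):
            raise ValueError(
                "causal_effect_sizes must be scalar or one value per causal SNP"
            )
        return betas


def _stage_rng(spec: SimulationSpec, stage: int, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stage, offset]))


def causal_snp_indices(spec: SimulationSpec) -> np.ndarray:
    """Deterministic causal SNP positions, spread evenly across the panel."""
    if spec.causal_snp_count == 0:
        return np.array([], dtype=int)
    return np.floor(
        np.linspace(0, spec.n_snps, spec.causal_snp_count, endpoint=False)
    ).astype(int)


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Draw the two-cohort SNP panel with block LD and random missingness.

    SNPs are organised in consecutive blocks of ``ld_block_size``.  All SNPs
    of a block share the block allele frequency, and each haploid allele is
    copied from a latent block founder haplotype with probability
    ``r2 ** 0.25`` (else drawn independently), which makes the within-block
    pairwise genotype r-squared approximate ``ld_within_block_r2``.  The
    second cohort redraws block frequencies with a small perturbation to
    emulate center heterogeneity.
    """
    spec.validate()
    rng = _stage_rng(spec, 1)
    p = spec.n_snps
    n_blocks = math.ceil(p / spec.ld_block_size)
    block_of = np.minimum(np.arange(p) // spec.ld_block_size, n_blocks - 1)
    lo, hi = spec.maf_range
    base_freq = rng.uniform(lo, hi, size=n_blocks)
    copy_prob = spec.ld_within_block_r2 ** 0.25

    cohort_names = ("A", "B")
    dosage_parts, sample_parts = [], []
    for c, (name, n) in enumerate(zip(cohort_names, spec.n_samples_per_cohort)):
        n = int(n)
        crng = _stage_rng(spec, 1, offset=c + 1)
        if c == 0:
            freq = base_freq
        else:  # center heterogeneity: jitter block frequencies within range
            freq = np.clip(base_freq + crng.uniform(-0.02, 0.02, n_blocks), lo, hi)
        snp_freq = freq[block_of]
        dose = np.zeros((n, p))
        for _hap in range(2):
            founder = crng.random((n, n_blocks)) < freq  # latent block haplotype
            fresh = crng.random((n, p)) < snp_freq
            copied = crng.random((n, p)) < copy_prob
            allele = np.where(copied, founder[:, block_of], fresh)
            dose += allele
        if spec.missing_genotype_rate > 0:
            mask = crng.random((n, p)) < spec.missing_genotype_rate
            dose[mask] = np.nan
        dosage_parts.append(dose)
        # sex comes from its own stream so .fam and the clinical table agree
        sex_draw = _stage_rng(spec, 4, offset=c + 1).random(n)
        sex = np.where(sex_draw < 0.709, "F", "M")
        sample_parts.append(
            pd.DataFrame(
                {
                    "id": [f"{name}{i + 1:05d}" for i in range(n)],
                    "cohort": name,
                    "sex": sex,
                }
            )
        )

    allele_pairs = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")])
    pair_idx = rng.integers(0, len(allele_pairs), size=p)
    chrom = (block_of % 22) + 1
    # positions increase within each chromosome
    pos = np.zeros(p, dtype=int)
    for ch in np.unique(chrom):
        m = chrom == ch
        pos[m] = 10_000 * (1 + np.arange(m.sum()))
    variants = pd.DataFrame(
        {
            "id": [f"snp{j + 1:06d}" for j in range(p)],
            "chrom": chrom,
            "pos": pos,
            "allele1": allele_pairs[pair_idx, 0],
            "allele2": allele_pairs[pair_idx, 1],
            "minor_allele": allele_pairs[pair_idx, 0],
        }
    )
    return GenotypeMatrix(
        dosage=np.vstack(dosage_parts),
        variants=variants,
        samples=pd.concat(sample_parts, ignore_index=True),
    )


def simulate_clinical(spec: SimulationSpec) -> pd.DataFrame:
    """Draw the 17 baseline clinical features for both cohorts.

    Marginals loosely match the study population: age at onset 29 +/- 9.5,
    disease duration 10.5 +/- 7.6 (gamma), ARR 0.82 +/- 0.84 (gamma), EDSS on
    the half-point grid with median ~2, baseline MRI flags at 49%/34%, and
    exactly one prior-treatment category per patient.  Cohort B's means are
    shifted slightly (AAO +0.5, ARR +0.05) to emulate center heterogeneity.
    """
    spec.validate()
    frames = []
    for c, (name, n) in enumerate(zip(("A", "B"), spec.n_samples_per_cohort)):
        n = int(n)
        rng = _stage_rng(spec, 2, offset=c + 1)
        aao_shift, arr_shift = (0.0, 0.0) if c == 0 else (0.5, 0.05)
        sex = (_stage_rng(spec, 4, offset=c + 1).random(n) < 0.709).astype(int)
        aao = np.clip(rng.normal(29.0 + aao_shift, 9.5, n), 5.0, None)
        dd = rng.gamma(shape=(10.5 / 7.6) ** 2, scale=7.6**2 / 10.5, size=n)
        arr = np.clip(
            rng.gamma(shape=(0.82 / 0.84) ** 2, scale=0.84**2 / 0.82, size=n)
            + arr_shift,
            0.0,
            None,
        )
        edss = np.clip(np.round(rng.normal(2.2, 1.4, n) * 2) / 2, 0.0, 7.0)
        t2 = (rng.random(n) < 0.491).astype(int)
        gd = (rng.random(n) < 0.335).astype(int)
        prior = rng.choice(len(PRIOR_TREATMENTS), size=n, p=PRIOR_TREATMENT_PROBS)
        frame = pd.DataFrame(
            {
                "patient_id": [f"{name}{i + 1:05d}" for i in range(n)],
                "cohort": name,
                "sex_female": sex,
                "age_at_onset": np.round(aao, 2),
                "age_at_fty_start": np.round(aao + dd, 2),
                "disease_duration": np.round(dd, 2),
                "arr_prior_2y": np.round(arr, 3),
                "edss_baseline": edss,
                "t2_baseline": t2,
                "gdplus_baseline": gd,
            }
        )
        for k, t in enumerate(PRIOR_TREATMENTS):
            frame[f"prior_tx_{t}"] = (prior == k).astype(int)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


@dataclass
class FollowUpTable:
    """Simulated 2-year follow-up plus the latent ground truth."""

    frame: pd.DataFrame  # the observable follow-up CSV columns
    latent_status: pd.Series  # patient_id -> "EDA" | "NEDA" (pre-missingness truth)
    eda_probability: pd.Series  # patient_id -> latent P(EDA)
    causal_snp_ids: list[str]


def _edss_progression_step(baseline: float) -> float:
    if baseline == 0:
        return 1.5
    if baseline <= 5.0:
        return 1.0
    return 0.5


def simulate_outcome(
    genotypes: GenotypeMatrix, clinical: pd.DataFrame, spec: SimulationSpec
) -> FollowUpTable:
    """Sample follow-up activity from the latent liability model.

    liability = intercept + sum(causal dosages x effects)
              + sum(standardized clinical features x effects); the EDA label
    is Bernoulli(sigmoid(liability)) (equivalently, liability plus logistic
    noise thresholded at zero).  EDA patients receive activity components
    drawn from ``eda_component_probs`` so that NEDA-3 classification of the
    complete record reproduces the latent label exactly; NEDA patients get
    zero relapses, negative MRI flags and a non-progressing EDSS.  Follow-up
    fields are then blanked at ``clinical_missing_rate`` to create
    unclassifiable patients.
    """
    spec.validate()
    ids = list(genotypes.samples["id"])
    if list(clinical["patient_id"]) != ids:
        raise ValueError("genotype and clinical sample ids are misaligned")
    rng = _stage_rng(spec, 3)
    n = len(ids)

    causal_idx = causal_snp_indices(spec)
    betas = spec.causal_effect_vector()
    X = genotypes.dosage[:, causal_idx].copy()
    if X.size:
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
        X = X - col_mean  # centred so the intercept controls the EDA rate
    genetic_part = X @ betas if X.size else np.zeros(n)

    clinical_part = np.zeros(n)
    for feat, beta in spec.clinical_effects.items():
        if feat not in clinical.columns:
            raise ValueError(f"clinical_effects references unknown feature {feat!r}")
        mu, sd = CLINICAL_STANDARDIZATION.get(feat, (0.0, 1.0))
        clinical_part += beta * (clinical[feat].to_numpy(dtype=float) - mu) / sd

    liability = spec.intercept + genetic_part + clinical_part
    p_eda = 1.0 / (1.0 + np.exp(-liability))
    is_eda = rng.random(n) < p_eda

    edss_base = clinical["edss_baseline"].to_numpy(dtype=float)
    relapse = np.zeros(n)
    t2_flag = np.zeros(n, dtype=bool)
    gd_flag = np.zeros(n, dtype=bool)
    t2_count = np.zeros(n)
    edss_2y = edss_base.copy()

    # stable NEDA patients occasionally improve by half a point
    improve = (~is_eda) & (rng.random(n) < 0.2) & (edss_base >= 0.5)
    edss_2y[improve] -= 0.5

    component = rng.choice(4, size=n, p=spec.eda_component_probs)
    for i in np.flatnonzero(is_eda):
        comp = component[i]
        if comp in (0, 2):  # relapse
            relapse[i] = 1 + rng.poisson(0.5)
        if comp in (1, 2):  # MRI activity
            t2 = rng.random() < 0.8
            gd = rng.random() < 0.5
            if not (t2 or gd):
                t2 = True
            t2_flag[i], gd_flag[i] = t2, gd
        if comp == 3:  # EDSS progression
            extra = 0.5 if rng.random() < 0.3 else 0.0
            edss_2y[i] = min(
                10.0, edss_base[i] + _edss_progression_step(edss_base[i]) + extra
            )
    t2_counts = 1 + rng.poisson(1.5, size=n)
    t2_count[t2_flag] = t2_counts[t2_flag]

    ntz_prior = clinical["prior_tx_natalizumab"].to_numpy(dtype=int) == 1
    months = np.full(n, np.nan)
    months[ntz_prior] = np.round(rng.uniform(9, 48, ntz_prior.sum()), 1)

    frame = pd.DataFrame(
        {
            "patient_id": ids,
            "relapse_count_2y": relapse,
            "new_t2_flag": t2_flag.astype(float),
            "gdplus_flag": gd_flag.astype(float),
            "active_t2_count_2y": t2_count,
            "edss_baseline": edss_base,
            "edss_2y": edss_2y,
            "months_since_ntz_stop": months,
        }
    )
    if spec.clinical_missing_rate > 0:
        miss = rng.random((n, 4)) < spec.clinical_missing_rate
        frame.loc[miss[:, 0], "relapse_count_2y"] = np.nan
        frame.loc[miss[:, 1], ["new_t2_flag", "active_t2_count_2y"]] = np.nan
        frame.loc[miss[:, 2], "gdplus_flag"] = np.nan
        frame.loc[miss[:, 3], "edss_2y"] = np.nan

    status = pd.Series(
        np.where(is_eda, "EDA", "NEDA"), index=pd.Index(ids, name="patient_id")
    )
    return FollowUpTable(
        frame=frame,
        latent_status=status,
        eda_probability=pd.Series(p_eda, index=status.index),
        causal_snp_ids=[genotypes.variants["id"].iloc[j] for j in causal_idx],
    )


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[GenotypeMatrix, pd.DataFrame, FollowUpTable]:
    """Convenience wrapper: genotypes, clinical table and follow-up records."""
    genotypes = simulate_genotypes(spec)
    clinical = simulate_clinical(spec)
    followups = simulate_outcome(genotypes, clinical, spec)
    return genotypes, clinical, followups
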