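# Methods

## Problem and outcome model

The pipeline predicts, at treatment start, whether an RRMS patient will
show evidence of disease activity (EDA) during the first two years of
fingolimod therapy. The outcome is the NEDA-3 criterion: a patient is NEDA
iff all three components are observed and negative — (i) no relapses,
(ii) no new/enlarging T2 and no Gd-enhancing lesions on brain MRI,
(iii) no EDSS progression. Classification is deliberately asymmetric under
missing data: one observed positive component suffices to label a patient
EDA, whereas NEDA requires complete observation; patients with a missing
component and no observed positive are UNCLASSIFIABLE and leave the
analysis. EDSS progression uses the standard baseline-dependent ladder
(+1.5 points from baseline 0, +1.0 from baseline in (0, 5.0],
+0.5 from ≥ 5.5) at a single unconfirmed 2-year timepoint, because only
one follow-up EDSS is collected. Both the progression rule and the
positive-dominance policy are design choices exposed in code; confirmed
progression with intermediate visits is out of scope. Patients who
discontinued natalizumab fewer than 9 months before fingolimod start are
excluded; the boundary reads "within the 9 months prior" as [0, 9), so a
9.0-month washout is retained.

## Genotype QC

Genotypes are additive minor-allele dosages (0/1/2, NaN missing). Per-SNP
filters run in the order MAF → call rate → Hardy–Weinberg, and the reason
code records the first failing rule; the order affects only the codes, not
the retained set. Defaults: MAF ≥ 0.01, SNP call rate ≥ 0.97, HWE exact
p ≥ 1e-4. The HWE test is the exact conditional test (sum of the
probabilities of all heterozygote counts no more probable than the
observed one, conditional on the allele counts), matching the behaviour of
the standard array-QC tooling for small counts; it is computed with exact
integer weights so probability ties are unambiguous. Monomorphic SNPs get
p = 1 by convention.

Per-sample filters: call rate ≥ 0.95; pairwise relatedness measured as IBS
sharing (mean of 1 − |d_i − d_j|/2 over shared calls) with pairs above
0.9 losing the lower-call-rate member; ancestry outliers via classical
(Torgerson) MDS on the 1 − IBS distance matrix, removing samples more than
6 SD from the centroid on either of the first two axes. The relatedness
statistic and both thresholds are package defaults — explicit
configuration, not claims about any particular study. The sex-mismatch
check reduces to comparing reported sex columns because the simulation is
autosomal. After sample removal the per-SNP filters are re-applied so
every retained SNP satisfies all thresholds on the final sample set; this
keeps the QC report's partition invariant (removed ∪ pruned ∪ retained =
input panel) intact.

LD pruning is greedy within sliding windows of 50 SNPs advanced by 5
(conventional defaults; only the r² > 0.2 cap is dictated by the method).
Within a window the currently worst pair (highest dosage r², computed on
mean-imputed dosages) is resolved by removing its lower-MAF member, ties
by later position; zero-variance columns count as r² = 0. The "no
retained pair above the cap" guarantee is stated — and brute-force
verified in tests — with respect to the processed windows.

## Cohort split

The 40/40/20 training/validation/test partition is stratified jointly by
(cohort, outcome). Per stratum, set counts come from largest-remainder
rounding; strata are processed from largest to smallest, and remainder
ties go to the set with the smallest running global total, then by set
order (TR, V, TE). With 381 analyzable patients split as
(164, 156, 33, 28) across (cohortA-EDA, cohortA-NEDA, cohortB-EDA,
cohortB-NEDA), this yields set sizes 152/152/77. Those four stratum counts
are a convention: they are consistent with every published margin of the
motivating study (cohort totals 320/61, outcome totals 197/184), whose
per-cohort outcome counts are not public.

## Stability selection

Features (SNPs, or clinical variables) are ranked per CV fold by
|point-biserial correlation| between feature and 0/1 outcome, computed on
the fold's training portion only; constant columns get r = 0 and ties
break by feature index. One "fold-instance" is one fold of one
repetition; frequency(feature) = #(top-k appearances) / (n_folds ×
n_repeats), and the signature keeps features with frequency ≥ f. Folds
are outcome-stratified and reshuffled each repetition. Defaults k = 500,
f = 0.1, 10 folds × 100 repetitions; the test and acceptance runs use 20
repetitions, which leaves the selection frequencies' Monte-Carlo error at
the ±0.01–0.02 level — immaterial for thresholds ≥ 0.05. Which set feeds
the selection CV is configurable (`selection_set`), defaulting to the
validation set so that training and test sets stay blind to selection.

## Forests and the multi-view ensemble

Forests are assembled tree by tree: each tree gets its own bootstrap
sample (with replacement, original size) and is grown with sklearn's CART
under `maxn` (maximum terminal nodes — `maxnodes` semantics), `nodesize`
(minimum samples per leaf) and `mtry` (features per split, default
⌊√p⌋). `maxn = 1` and single-class bootstraps yield constant trees
predicting the bootstrap class frequency. The predicted non-response
probability is the unweighted mean of per-tree class-1 probabilities
(soft voting — the continuous score the AUROC and tertile analyses need).
Genotype missingness is mode-imputed per SNP after QC (QC caps SNP
missingness at 3%, so imputation touches little).

In the multi-view ensemble every tree is tagged with the single view
(genetic or clinical) whose bootstrap it saw; consensus averages over all
trees regardless of view. The default combined model keeps each view's
full tree count (200 trees at allocation 0.5 fuses two 100-tree
single-view forests), mirroring the combination of two already-selected
single-view models.

Model search trains every (signature × RF-parameter) candidate on the
training set and ranks by validation AUROC, ties by AUPRC then F-score
then model id; the four best are retained and only they are evaluated on
the test set. Training/validation overlap raises immediately (leakage
guard). The full ~2000-candidate grid is config-driven; the default
configuration uses a reduced grid (2 signatures × 8 parameter settings
per view) to keep a complete run under half a minute.

## Evaluation

AUROC is the Mann–Whitney form (ties ½), verified exactly against
pair-counting oracles; AUPRC is step-wise precision–recall integration
(sklearn's average-precision, no interpolation); F-score and accuracy
threshold the consensus probability at 0.5 (configurable), with F = 0 when
precision + recall = 0. The positive class is EDA (non-response)
throughout. Tertiles of the test-set predicted non-response probability
define PrNR (top) and PrR (bottom) groups; group sizes follow
largest-remainder with extremes first (77 → 26/25/26), boundary ties
resolve by patient id with a warning. Group contrasts use the two-sided
Mann–Whitney test (normal approximation with tie correction) for lesion
and relapse counts and the Yates-corrected chi-square test for the EDA,
MRI-activity and clinical-activity proportions; zero-margin tables raise.
Transfer evaluation applies a frozen genetic model to another cohort
without retraining and errors if any signature SNP is absent there.

## Synthetic cohort generator

The generator is the package's study stand-in and is itself first-class,
tested code. It emulates:

- **Panel**: 2000 autosomal SNPs (a scaled-down post-QC, LD-pruned array)
  in blocks of 10 sharing a block allele frequency drawn from
  U(0.05, 0.5). Each haploid allele copies a latent block founder with
  probability r2^(1/4), making within-block genotype r² ≈ the target
  (default 0.1, i.e. an already-pruned panel); cross-cohort block
  frequencies are jittered by ±0.02 for center heterogeneity. Genotype
  missingness 1% at random.
- **Cohorts**: 342 + 78 samples, cohort B with slightly shifted clinical
  means (AAO +0.5 y, ARR +0.05).
- **Clinical baseline** (17 features): sex (71% F), age at onset
  N(29, 9.5²) years, disease duration Gamma matching 10.5 ± 7.6 years
  (age at start = onset + duration), prior-2-year ARR Gamma matching
  0.82 ± 0.84, EDSS on the half-point grid (median ≈ 2), new-T2 49% and
  Gd+ 34% at baseline, and exactly one of nine prior-treatment categories
  at the observed frequencies.
- **Outcome**: latent liability = intercept + Σ β_j (x_j − x̄_j) over 10
  causal SNPs (alternating sign, 0.5 log-odds each) + Σ β_c · standardized
  clinical features (age at start −0.37, ARR +0.60, baseline T2 +0.67,
  Gd+ +0.52 per SD) + logistic noise; EDA ~ Bernoulli(sigmoid(liability)).
  The genetic term is centred so the intercept (0.1) pins the EDA rate
  near the observed 52%. Effect scales were fixed once so the latent
  view discriminations sit in the regime the application reports
  (oracle AUROC ≈ 0.69 genetic, ≈ 0.73 clinical, ≈ 0.80 combined);
  fitted forests land a few points below these ceilings.
- **Activity components**: EDA patients draw which component fires from a
  multinomial (relapse only 0.30, MRI only 0.35, both 0.25, EDSS
  progression 0.10 — a free choice, as no component mix is published);
  counts and flags are then sampled so that NEDA-3 classification of a
  complete record reproduces the latent label exactly. NEDA patients get
  zero relapses, negative flags, non-progressing EDSS.
- **Missing follow-up**: each of the four follow-up fields is blanked
  independently at 4%, which makes ≈ 9% of patients unclassifiable —
  matching the study's 39/420 flow. Patients with prior natalizumab get a
  washout ≥ 9 months by default, so exclusions are exercised by explicit
  fixtures rather than the default run.

What the generator does **not** emulate: realistic population structure
and admixture (cohorts differ only by small frequency jitter), linkage
maps beyond uniform blocks, genotyping batch effects, X-chromosome
variation, informative (non-random) clinical missingness, correlated
onset-age/duration, and MRI lesion counts beyond a simple Poisson for
active scans. Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under planted sparse signals — not clinical
performance on real cohorts.

## Problem sizes used by the test and acceptance runs

Monte-Carlo checks run at sizes chosen to keep the whole suite fast while
leaving comfortable statistical margins: stability-selection recovery at
600 samples × 2000 SNPs with 10 planted SNPs of 1.2 log-odds (realized
marginal |r| ≈ 0.2–0.25), 10 folds × 20 repetitions, 20 seeds; the
multi-view comparison at 400 training / 300 test samples over 20 seeds
(per-seed AUROC SE ≈ 0.03, so a 0.04 mean gain is ≈ 5 SE of the mean);
the transfer-null band at 300 samples × 20 seeds; the HWE oracle sweep
over every genotype table with ≤ 200 samples. The default end-to-end
pipeline configuration (420 patients, 2000 SNPs, reduced grids) completes
in ~20 s.

## Known limitations

- Test-set metrics at n ≈ 77 carry sampling SD ≈ 0.06 AUROC; single-seed
  end-to-end numbers are illustrative, not stable estimates.
- The default genetic panel (2000 SNPs with 10 weak causal variants) makes
  the end-to-end genetic model's test AUROC fluctuate around the
  0.55–0.65 band depending on the seed; the planted-signal properties are
  asserted over seeds, not per seed.
- The exact HWE test computes one conditional distribution per SNP; for
  panels of millions of SNPs a vectorised mid-p or chi-square screen would
  be preferable.
- Model persistence uses Python pickles inside the run directory; they are
  run artifacts, not an interchange format.
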