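# Methods

## Scope and data model

All analyses operate on a genus-level taxa × samples abundance table
(integer counts or per-sample relative abundances) plus per-sample
metadata linking each specimen to a patient, one of six specimen types
(saliva, tumor-surface swab, outer tumor tissue, inner tumor tissue,
adjacent normal tissue, lymph node), and optional clinical variables.
The orientation is fixed as taxa × samples and never auto-detected;
transposed input fails validation rather than silently transposing.
Counts are total-sum scaled to relative abundance; no rarefaction is
performed anywhere, since every statistic here is defined on relative
abundances and rarefaction would only discard counts.  Missing clinical
values map to `unknown` and are excluded per analysis (complete-case),
never imputed.

## Paired differential-genus calling

The core procedure compares matched specimens of two types from the same
patients (e.g. outer tumor vs adjacent normal margin).  Rationale: human
tissue is an ultra-low-biomass substrate, so a genus detected only on one
side of a contrast, or at trace abundance, is more plausibly sampling or
contamination noise than biology; and the per-patient community signature
is the dominant source of variance, so unpaired group comparisons mostly
measure which patients happened to land in which group.

Parameters, defaults and meaning:

| parameter | default | meaning |
|---|---|---|
| `min_mean_abundance` | 0.001 | predominance floor: mean relative abundance required in *each* group |
| `min_detection_fraction` | 0.5 | fraction of each group's samples in which the genus must be detected (> 0) |
| `pseudocount` | 1e-5 | additive ε on relative abundances before the ratio; bounds a from-zero fold change at ~(a+ε)/ε |
| `fold_threshold` | 2.0 | per-pair fold change that counts as supporting a direction (≥ t supports A, ≤ 1/t supports B) |
| `majority_fraction` | 0.5 | a call requires the supporting fraction of pairs to strictly exceed this, and the opposing fraction to stay ≤ 1 − it |

`majority_fraction` is accepted in [0.5, 1) and used with a strict `>`
comparison, so the default means "more than half of pairs"; the opposing
cap guarantees at most one enrichment direction per genus.  The
pseudocount is applied identically to both pair members, which keeps the
procedure antisymmetric under group exchange (calls flip, fold changes
invert) and invariant to per-sample count scaling.  Zero-handling by
pseudocount rather than pair exclusion keeps the pair count — the unit of
evidence — constant across genera.  When a patient contributes several
specimens of one type, the lexicographically smallest sample id is used,
deterministically, with a warning.  The rule is descriptive; no p-values
are attached and no multiple-testing correction applies.

## Diversity and ordination

Shannon index H = −Σ p_i ln p_i (natural log) on relative abundances;
zero-abundance taxa contribute nothing, so H is invariant to padding the
taxon panel.  Group contrasts of per-sample H use the two-sided
Mann-Whitney U test — exact enumeration when both groups have ≤ 8
observations and no ties, otherwise the normal approximation with
midranks and tie correction.  A rank test is used because Shannon values
over small specimen groups have no reason to be normal.

Bray-Curtis dissimilarity is computed on relative abundances (on raw
counts it would partly measure sequencing depth).  Classical PCoA
double-centers −D²/2 and eigendecomposes; negative eigenvalues — expected,
since Bray-Curtis is a semimetric — are dropped without Cailliez/Lingoes
correction, and their summed magnitude is reported as a distortion
diagnostic.  For Euclidean-embeddable inputs the embedding reproduces the
distances to < 1e-8.

PERMANOVA is self-contained: pseudo-F = (SS_between/(g−1)) /
(SS_within/(n−g)) with sums of squares computed from squared pairwise
distances (SS over a set = Σ d²/|set|), and p from label permutations.
All permutation tests use the add-one estimator
p = (1 + #{F* ≥ F}) / (1 + P), bounded below by 1/(P+1); seeds are
explicit arguments with default 0.

The patient-clustering statistic is mean(between-patient d) −
mean(within-patient d) with a patient-label permutation null.  It
formalizes the qualitative observation that specimens from the same
patient cluster together in ordination space: a positive statistic with
small p means patient identity structures the community more than
specimen type does.

## Clinical association screen

Outcome: bacterial culture result (pathogenic bacteria absent/present).
Categorical variables: chi-square on the outcome × variable crosstab,
with Yates continuity correction for 2×2 tables and the Pearson statistic
for r×c — the convention of mainstream clinical statistics packages, and
the one under which the packaged cohort's 2×2 rows reproduce their
published p-values.  Expected cells below 1 set a caveat flag rather than
aborting.  Continuous variables: pooled-variance two-sample t-test, which
is a pure function of (n, mean, SD) per group, so a cohort available only
as a published summary table is screened identically to patient-level
data.  N staging is screened as the printed four-level table; no ordinal
trend test.  No multiplicity correction by default (the screen mirrors a
single-table report); `fit(fdr=True)` adds Benjamini-Hochberg adjusted
p-values without changing the unadjusted flags.

The packaged 218-patient cohort stores per-level counts by outcome group
and per-group summary statistics for the continuous rows.  Patient-level
categorical assignments are expanded deterministically from the counts;
any expansion reproduces every variable-by-outcome margin exactly, which
is the sufficient statistic for every test in the screen.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, with
known planted truth:

- **Latent model (default `logistic_normal`).**  Per patient, a log-scale
  profile = base community + N(0, `patient_effect_sd`) per genus, shared
  by all of that patient's specimens; per specimen, specimen-type effects
  and planted differentials add on the log scale; counts are multinomial
  at a log-normal depth.  The shared patient effect is what produces
  patient-dominant clustering; it cancels inside matched pairs, which is
  exactly why the paired caller works.  A `dirichlet` mode without
  patient correlation is kept for simplicity checks.
- **Base community**: log-abundances decline linearly over the core panel
  (most-abundant ≈ 400× the rarest core genus), a generic steep
  rank-abundance curve.  The default panel of 40 genera names
  oral-cancer-associated taxa first (Fusobacterium, Prevotella,
  Porphyromonas, Streptococcus, Neisseria, …) for readable outputs.
- **Planted differentials**: ± ½ log f on the two specimen types of the
  contrast, so the expected paired fold change is exactly f and other
  specimen types are unaffected.
- **Defaults**: 10 patients × {outer_tumor, adjacent_normal};
  `patient_effect_sd` = 1.0 (log scale); depth log-normal with median
  50 000 and 0.5 log-SD, floored at 1000; 5 % of the panel are "rare"
  genera absent from the core community that spike independently per
  sample (probability 0.3) at trace abundance 0.005–0.05 % — the sampling
  bias the predominance filter exists to remove.
- **Clinical cohorts**: outcome at a configurable prevalence (default
  105/218), binary variables from logistic models with specified odds
  ratios (OR = 1 ⇒ independence), continuous variables normal per group.

What the generator does *not* emulate: taxon-taxon correlation beyond the
compositional constraint, overdispersion beyond the log-normal latent
(e.g. zero-inflation mechanisms), phylogenetic signal, batch effects, and
real contamination structure (correlated across samples of a run rather
than independent).  Passing recovery tests on this generator shows the
pipeline recovers planted structure under its own assumptions; it does not
certify performance on real amplicon data.

## Problem sizes and numerical choices

Validation suites use deliberately desk-scale designs: type-I calibration
of PERMANOVA and the patient-clustering test on a 24-sample exchangeable
population with 300 relabelled replicates × 999 permutations; caller
recovery on 50 simulated studies of 10 pairs with 3-fold planted effects;
patient-dominance on 100 default-parameter replicates.  Eigenvalues are
considered positive above a relative tolerance of 1e-12 of the spectral
radius.  Tie-breaks in ranked reports are deterministic: supporting-pair
count, then median fold change toward the group, then genus name.
Degenerate inputs (all-zero samples, constant distance matrices,
single-level variables, < 3 pairs) raise typed validation errors rather
than propagating NaNs.

## Known limitations

- The paired caller is a descriptive rule; it reports no uncertainty and
  its thresholds ("predominant", "most pairs") are conventions exposed as
  parameters, not estimated quantities.
- Bray-Curtis + PCoA without eigenvalue correction can distort when
  negative eigenvalues are large; the reported magnitude should be checked.
- The chi-square screen is complete-case and unadjusted for confounding;
  it establishes association, not mechanism.
- TSV only; BIOM/HDF5 inputs and phylogeny-aware (UniFrac) distances are
  out of scope.
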