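# oralmicro

Genus-level analysis of oral-cancer tumor microbiomes: paired
("alignment-based") differential-genus calling over matched specimens from
the same patients, alpha/beta diversity with permutation inference, a
patient-clustering statistic, and a clinicopathology association screen —
plus a synthetic-data generator with known planted truth so every stage can
be exercised and validated without sequencing data.

## Who this is for

Researchers analysing 16S amplicon studies of oral squamous cell carcinoma
(or similar low-biomass tissue microbiomes) who collect several specimen
types per patient — saliva, tumor-surface swabs, outer tumor tissue, inner
tumor tissue, adjacent normal margins, lymph nodes — together with
clinicopathological records (TNM stage, extranodal extension, cervical
lymphatic metastasis, bacterial culture results).

## The methods

**Paired differential genera.** Low-biomass tissue sequencing is dominated
by sporadic contamination: genera seen only on one side of a contrast, or
at trace abundance, are more plausibly sampling bias than biology.  The
caller therefore (1) restricts to predominant genera shared by both
specimen groups — mean relative abundance ≥ 0.1 % in *each* group and
detection in ≥ 50 % of *each* group's samples; (2) computes per-pair fold
changes of relative abundance within matched specimens of the same patient,
`(a + ε)/(b + ε)` with pseudocount ε = 10⁻⁵; and (3) calls a genus enriched
in a group when at least a two-fold change in its favour occurs in more
than half of the pairs while the opposing direction stays in the minority.
Pairing within patients cancels the strong per-patient community signature,
which otherwise swamps specimen-type differences.

**Diversity.**  Alpha diversity is the Shannon index
H = −Σᵢ pᵢ ln pᵢ on per-sample relative abundances (group contrasts by
two-sided Mann-Whitney U).  Beta diversity is Bray-Curtis dissimilarity
BC(x, y) = 1 − 2 Σᵢ min(xᵢ, yᵢ) / (Σx + Σy), embedded by classical PCoA and
tested by PERMANOVA (pseudo-F with label permutations, 999 by default).
The tendency of specimens from the same patient to cluster together is
quantified as mean(between-patient distance) − mean(within-patient
distance) with a patient-label permutation null.

**Clinical screen.**  Each clinicopathological variable is tested against
the bacterial culture outcome: chi-square with Yates continuity correction
for 2×2 tables and Pearson chi-square for larger ones, pooled-variance
t-tests for continuous variables (computable from group summary statistics
alone).  A transcribed 218-patient cohort ships as a packaged fixture.

## Worked example

```python
from oralmicro import (MicrobiomeSimSpec, PlantedDifferential,
                       PairedDifferential, simulate_paired_study,
                       distance_matrix, patient_clustering_test)

spec = MicrobiomeSimSpec(
    n_patients=10,
    planted_differentials=[
        PlantedDifferential("Fusobacterium", "outer_tumor",
                            "adjacent_normal", 3.0),
        PlantedDifferential("Streptococcus", "adjacent_normal",
                            "outer_tumor", 3.0)],
    seed=0)
table, metadata, truth = simulate_paired_study(spec)

results = PairedDifferential(table, metadata,
                             "outer_tumor", "adjacent_normal").fit()
print(results.summary())

dm = distance_matrix(table.to_relative())
pc = patient_clustering_test(dm, metadata.set_index("sample_id")["patient_id"],
                             n_permutations=999, seed=0)
print(f"patient clustering: statistic={pc.statistic:.3f} p={pc.p_value:.4f}")
```

prints

```
Paired differential-genus analysis (outer_tumor [A] vs adjacent_normal [B])
  pairs: 10   genera: 40   kept after filter: 31
  fold threshold 2.0, majority fraction 0.5, pseudocount 1e-05
  enriched in outer_tumor: Fusobacterium
  enriched in adjacent_normal: Streptococcus

patient clustering: statistic=0.379 p=0.0010
```

Both planted genera are recovered with the right direction, no null genus
is called, and the within-patient distances are on average 0.379 smaller
than between-patient ones (p = 0.001, the permutation floor at 999
permutations) — the patient-dominant structure the generator plants.

The clinical screen on the packaged cohort:

```python
from oralmicro import ClinicalAssociationScreen, load_table1
print(ClinicalAssociationScreen(load_table1()).fit().summary())
```

flags exactly three variables at the two-tailed 0.05 level —

```
  diabetes                chi2_yates    stat=   6.499 df= 1 p=0.011 *
  t_stage                 chi2_pearson  stat=  24.976 df= 2 p=<0.001 *
  lymph_node_metastasis   chi2_yates    stat=   4.198 df= 1 p=0.040 *
```

— i.e. pathogenic bacteria on culture associate with diabetes, higher T
stage and cervical lymph node metastasis in this cohort.

A command-line interface wraps the same stages:

```sh
oralmicro simulate --out-dir sim/ --seed 0
oralmicro paired-diff --table sim/table.tsv --metadata sim/metadata.tsv \
    --group-a outer_tumor --group-b adjacent_normal --out calls.tsv
oralmicro clinical --fixture table1 --out-dir clin/
oralmicro run-contrast --table sim/table.tsv --metadata sim/metadata.tsv \
    --group-a outer_tumor --group-b adjacent_normal --out-dir contrast/
```

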