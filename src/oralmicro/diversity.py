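"""Alpha and beta diversity with permutation inference.

Alpha diversity is the Shannon index H = -sum p_i ln p_i on per-sample
relative abundances.  Beta diversity is Bray-Curtis dissimilarity
BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum x + sum y), computed on relative
abundances so that library size never enters.  Ordination is classical PCoA
(metric multidimensional scaling).  Group structure on the distance matrix
is tested with a self-contained PERMANOVA (pseudo-F with label
permutations); the tendency of specimens from the same patient to cluster
together is quantified by a within- versus between-patient distance
permutation test.

All permutation p-values use the add-one estimator
p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations),
so p is never exactly zero and is bounded below by 1/(n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from skbio import DistanceMatrix

from .io import AbundanceTable, ValidationError

DEFAULT_PERMUTATIONS = 999
DEFAULT_SEED = 0


@dataclass(frozen=True)
class PermutationTestResult:
    """Outcome of a label-permutation test."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "method": self.method,
        }


@dataclass(frozen=True)
class LocationTestResult:
    """Two-sample rank test outcome (no permutations involved)."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str


@dataclass
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix."""

    sample_ids: list
    coordinates: np.ndarray          # samples x retained axes
    eigenvalues: np.ndarray          # retained (positive), descending
    proportion_explained: np.ndarray
    negative_eigenvalue_magnitude: float

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids,
                            columns=cols)


def shannon_index(p) -> float:
    """Shannon diversity H (nats) of a relative-abundance vector.

    Zero-abundance taxa contribute nothing; 0 <= H <= ln(S), with the
    maximum attained only by the uniform composition.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("negative relative abundance")
    total = p.sum()
    if total <= 0:
        raise ValidationError("zero-sum abundance vector")
    if abs(total - 1.0) > 1e-9:
        raise ValidationError("relative abundances must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shannon_per_sample(table: AbundanceTable) -> pd.Series:
    rel = table if table.unit_kind == "relative" else table.to_relative()
    return pd.Series(
        [shannon_index(rel.data[c].to_numpy()) for c in rel.sample_ids],
        index=rel.sample_ids, name="shannon",
    )


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two non-negative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("negative abundance")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def distance_matrix(table: AbundanceTable) -> DistanceMatrix:
    """All pairwise Bray-Curtis dissimilarities over a table's samples.

    Counts are converted to relative abundance first: Bray-Curtis is
    scale-dependent, and on raw counts it would partly measure sequencing
    depth instead of composition.
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    rel = table if table.unit_kind == "relative" else table.to_relative()
    condensed = pdist(rel.data.to_numpy().T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=rel.sample_ids)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical (Torgerson) principal coordinate analysis.

    Double-centers -D^2/2, eigendecomposes, and keeps positive eigenvalues;
    coordinates are eigenvectors scaled by sqrt(eigenvalue).  Negative
    eigenvalues (Bray-Curtis is a semimetric, so they occur) are dropped
    without Cailliez/Lingoes correction; their summed magnitude is reported
    so the user can judge the distortion.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValidationError("PCoA needs at least 2 samples")
    if n_axes is not None and not (0 < n_axes < n):
        raise ValidationError("n_axes must be in [1, n_samples)")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-12
    pos = evals > tol
    if not pos.any():
        raise ValidationError("degenerate geometry: no positive eigenvalues")
    pos_evals = evals[pos]
    coords = evecs[:, pos] * np.sqrt(pos_evals)
    neg_mag = float(np.abs(evals[evals < -tol]).sum())
    if n_axes is not None:
        k = min(n_axes, coords.shape[1])
        coords, pos_evals = coords[:, :k], pos_evals[:k]
    prop = pos_evals / evals[evals > tol].sum()
    return OrdinationResult(
        sample_ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=pos_evals,
        proportion_explained=prop,
        negative_eigenvalue_magnitude=neg_mag,
    )


def _group_indices(labels) -> list[np.ndarray]:
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == g) for g in pd.unique(labels)]


def _permanova_f(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    # Gower-centered identity: SS over a sample set = sum of squared
    # pairwise distances within the set divided by the set size.
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for idx in groups:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    ss_between = ss_total - ss_within
    g = len(groups)
    if ss_within <= 0:
        raise ValidationError("pseudo-F undefined: zero within-group variation")
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    dm: DistanceMatrix,
    labels,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
) -> PermutationTestResult:
    """One-way PERMANOVA: pseudo-F on a distance matrix, p by permutation.

    The pseudo-F ratio is (SS_between/(g-1)) / (SS_within/(n-g)) with sums
    of squares computed directly from squared pairwise distances.  The null
    distribution permutes group labels over samples.
    """
    labels = np.asarray(labels)
    d = np.asarray(dm.data, dtype=float)
    if labels.shape[0] != d.shape[0]:
        raise ValidationError("one label per sample required")
    if n_permutations < 99:
        raise ValidationError("need at least 99 permutations")
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    small = [labels[idx[0]] for idx in groups if idx.size < 2]
    if small:
        raise ValidationError(f"groups with fewer than 2 samples: {small}")
    off_diagonal = d[~np.eye(d.shape[0], dtype=bool)]
    if np.ptp(off_diagonal) == 0:
        raise ValidationError("constant distance matrix: statistic undefined")
    d2 = d ** 2
    observed = _permanova_f(d2, groups)
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        perm_groups = [perm[idx] for idx in groups]
        if _permanova_f(d2, perm_groups) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationTestResult(observed, p, n_permutations, seed,
                                 method="permanova")


def alpha_group_test(values_a, values_b) -> LocationTestResult:
    """Two-sided Mann-Whitney U comparison of two sets of diversity values.

    Exact null distribution when both groups have <= 8 observations and no
    ties; otherwise the normal approximation with midranks and tie
    correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs at least 3 values")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size <= 8 and b.size <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return LocationTestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                              a.size, b.size, method=f"mannwhitneyu-{method}")


def patient_clustering_test(
    dm: DistanceMatrix,
    patient_of: dict | pd.Series,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
) -> PermutationTestResult:
    """Do specimens from the same patient sit closer than those from others?

    Statistic: mean(between-patient distances) - mean(within-patient
    distances).  A large positive value with a small permutation p indicates
    patient-dominant community structure.  The null permutes the patient
    labels over samples.
    """
    if isinstance(patient_of, pd.Series):
        patient_of = patient_of.to_dict()
    ids = list(dm.ids)
    missing = [s for s in ids if s not in patient_of]
    if missing:
        raise ValidationError(f"samples without patient assignment: {missing}")
    labels = np.asarray([patient_of[s] for s in ids])
    counts = pd.Series(labels).value_counts()
    if (counts >= 2).sum() < 2:
        raise ValidationError(
            "need at least 2 patients contributing >= 2 specimens each")
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    dist_flat = d[iu]

    def stat(lab) -> float:
        same = lab[iu[0]] == lab[iu[1]]
        return float(dist_flat[~same].mean() - dist_flat[same].mean())

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if stat(rng.permutation(labels)) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationTestResult(observed, p, n_permutations, seed,
                                 method="patient_clustering")


def composition_summary(
    table: AbundanceTable,
    groups: dict | pd.Series,
    level_map: dict | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Mean relative abundance per taxon (or higher rank) per sample group.

    ``level_map`` collapses taxa to a higher rank (e.g. genus -> phylum);
    taxa missing from the map go to "Unclassified" with a warning.  With
    ``top_k``, all but the k most abundant rows collapse into "Other".
    Rows are taxa, columns groups; every column sums to 1.
    """
    rel = table if table.unit_kind == "relative" else table.to_relative()
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    unassigned = [s for s in rel.sample_ids if s not in groups]
    if unassigned:
        raise ValidationError(f"samples without group assignment: {unassigned}")
    df = rel.data
    if level_map is not None:
        missing = [t for t in df.index if t not in level_map]
        if missing:
            import warnings

            warnings.warn(
                f"taxa missing from level_map mapped to Unclassified: {missing}")
        ranks = [level_map.get(t, "Unclassified") for t in df.index]
        df = df.groupby(pd.Index(ranks, name="taxon"), sort=False).sum()
    out = {}
    for g in pd.unique(pd.Series([groups[s] for s in rel.sample_ids])):
        cols = [s for s in rel.sample_ids if groups[s] == g]
        out[g] = df[cols].mean(axis=1)
    summary = pd.DataFrame(out)
    if top_k is not None and top_k < len(summary):
        top = summary.mean(axis=1).nlargest(top_k).index
        other = summary.drop(index=top).sum()
        summary = summary.loc[top]
        summary.loc["Other"] = other
    return summary
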