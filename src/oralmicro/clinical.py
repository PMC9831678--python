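"""Clinicopathology association screen against bacterial culture status.

The outcome is the inpatient bacterial culture test (pathogenic bacteria
absent/present).  Categorical patient variables are cross-tabulated against
it and tested with the chi-square test — Yates continuity correction for
2x2 tables and the plain Pearson statistic for larger ones, the SPSS
convention.  Continuous variables (age, BMI, blood panel) are compared with
the pooled-variance two-sample t-test, which is computable from group
summary statistics (n, mean, SD) alone, so a cohort transcribed from a
published table can be screened without patient-level values.

Missing values are excluded per analysis (complete-case); no multiplicity
correction is applied by default, with an optional Benjamini-Hochberg flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ContingencyTable, ValidationError

ALPHA = 0.05
MISSING = ("unknown", "", None)
OUTCOME_LEVELS = ("negative", "positive")


@dataclass(frozen=True)
class GroupSummary:
    """Per-outcome-group summary of a continuous variable."""

    n_negative: int
    mean_negative: float
    sd_negative: float
    n_positive: int
    mean_positive: float
    sd_positive: float


@dataclass
class ClinicalCohort:
    """Patient-level clinical table keyed by bacterial culture outcome.

    ``patients`` must contain ``patient_id`` and ``culture_result``
    (negative/positive) plus any categorical variables; continuous
    variables live either as patient-level columns or, when only published
    group summaries exist, in ``continuous_summaries``.
    ``variable_levels`` fixes the column order of every crosstab.
    """

    patients: pd.DataFrame
    categorical_vars: list[str] = field(default_factory=list)
    continuous_vars: list[str] = field(default_factory=list)
    variable_levels: dict[str, list[str]] = field(default_factory=dict)
    continuous_summaries: dict[str, GroupSummary] | None = None

    def __post_init__(self) -> None:
        for col in ("patient_id", "culture_result"):
            if col not in self.patients.columns:
                raise ValidationError(f"cohort missing column {col!r}")
        bad = set(self.patients["culture_result"]) - set(OUTCOME_LEVELS)
        if bad:
            raise ValidationError(
                f"culture_result must be negative/positive; found {sorted(bad)}")
        if "age" in self.patients.columns:
            ages = pd.to_numeric(self.patients["age"], errors="coerce")
            if (ages <= 0).any():
                raise ValidationError("ages must be positive")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def outcome_counts(self) -> pd.Series:
        return self.patients["culture_result"].value_counts().reindex(
            OUTCOME_LEVELS, fill_value=0)


@dataclass
class AssociationResult:
    """One screened variable: its table or group stats, test and verdict."""

    variable: str
    kind: str                       # "categorical" | "continuous"
    statistic: float
    dof: int
    p_value: float
    significant: bool
    test: str
    table: ContingencyTable | None = None
    group_stats: GroupSummary | None = None
    small_expected: bool = False

    def __post_init__(self) -> None:
        self.significant = bool(self.p_value < ALPHA)


def crosstab(cohort: ClinicalCohort, variable: str) -> ContingencyTable:
    """Outcome x variable contingency table, complete-case.

    Rows are culture result (negative, positive); columns follow the
    cohort's declared level order, else first-appearance order.
    """
    if variable not in cohort.patients.columns:
        raise ValidationError(f"unknown variable {variable!r}")
    df = cohort.patients[["culture_result", variable]]
    df = df[~df[variable].isin(MISSING) & df[variable].notna()]
    if df.empty:
        raise ValidationError(f"no observations for {variable!r}")
    levels = cohort.variable_levels.get(
        variable, list(pd.unique(df[variable])))
    levels = [lv for lv in levels if lv in set(df[variable])]
    if len(levels) < 2:
        raise ValidationError(
            f"variable {variable!r} has a single observed level")
    counts = np.array([
        [int(((df["culture_result"] == out) & (df[variable] == lv)).sum())
         for lv in levels]
        for out in OUTCOME_LEVELS
    ])
    return ContingencyTable(list(OUTCOME_LEVELS), levels, counts)


def chi_square_test(table: ContingencyTable,
                    variable: str = "") -> AssociationResult:
    """Chi-square independence test: Yates-corrected for 2x2, Pearson
    otherwise; a flag (not an error) marks expected cells below 1."""
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("chi-square needs at least a 2x2 table")
    correction = counts.shape == (2, 2)
    chi2, p, dof, expected = stats.chi2_contingency(counts,
                                                    correction=correction)
    return AssociationResult(
        variable=variable, kind="categorical", statistic=float(chi2),
        dof=int(dof), p_value=float(p), significant=p < ALPHA,
        test="chi2_yates" if correction else "chi2_pearson",
        table=table, small_expected=bool((expected < 1).any()))


def two_sample_location_test(values_neg, values_pos,
                             variable: str = "") -> AssociationResult:
    """Pooled-variance two-sided t-test on patient-level values."""
    a = np.asarray(values_neg, dtype=float)
    b = np.asarray(values_pos, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    summary = GroupSummary(a.size, float(a.mean()), float(a.std(ddof=1)),
                           b.size, float(b.mean()), float(b.std(ddof=1)))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if a.mean() == b.mean() else np.inf
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return AssociationResult(
        variable=variable, kind="continuous", statistic=float(t),
        dof=a.size + b.size - 2, p_value=float(p), significant=p < ALPHA,
        test="t_pooled", group_stats=summary)


def two_sample_location_test_from_stats(summary: GroupSummary,
                                        variable: str = "") -> AssociationResult:
    """Pooled-variance t-test from published group summaries (n, mean, SD)."""
    t, p = stats.ttest_ind_from_stats(
        summary.mean_negative, summary.sd_negative, summary.n_negative,
        summary.mean_positive, summary.sd_positive, summary.n_positive,
        equal_var=True)
    return AssociationResult(
        variable=variable, kind="continuous", statistic=float(t),
        dof=summary.n_negative + summary.n_positive - 2, p_value=float(p),
        significant=p < ALPHA, test="t_pooled_from_stats", group_stats=summary)


def cohort_summary(cohort: ClinicalCohort) -> dict:
    """Whole-cohort totals: outcome split, per-level counts with one-decimal
    percentages, pooled means of continuous variables (size-weighted means
    of the group means when only summaries exist)."""
    if cohort.n_patients == 0:
        raise ValidationError("empty cohort")
    out = cohort.outcome_counts()
    n = cohort.n_patients
    summary: dict = {
        "n_patients": n,
        "n_culture_negative": int(out["negative"]),
        "n_culture_positive": int(out["positive"]),
        "positive_culture_pct": round(100.0 * out["positive"] / n, 1),
        "categorical": {},
        "continuous_means": {},
    }
    for var in cohort.categorical_vars:
        col = cohort.patients[var]
        col = col[~col.isin(MISSING) & col.notna()]
        levels = cohort.variable_levels.get(var, list(pd.unique(col)))
        counts = {lv: int((col == lv).sum()) for lv in levels}
        total = sum(counts.values())
        summary["categorical"][var] = {
            lv: {"count": c, "pct": round(100.0 * c / total, 1)}
            for lv, c in counts.items()
        }
    for var in cohort.continuous_vars:
        if var in cohort.patients.columns:
            vals = pd.to_numeric(cohort.patients[var], errors="coerce")
            summary["continuous_means"][var] = round(float(vals.mean()), 1)
        elif cohort.continuous_summaries and var in cohort.continuous_summaries:
            s = cohort.continuous_summaries[var]
            pooled = (s.n_negative * s.mean_negative
                      + s.n_positive * s.mean_positive) / (
                          s.n_negative + s.n_positive)
            summary["continuous_means"][var] = round(pooled, 1)
    return summary


class ClinicalAssociationScreen:
    """Screen every declared clinical variable against culture outcome.

    statsmodels-style: construct from a :class:`ClinicalCohort`, call
    :meth:`fit`, read the per-variable results off the returned
    :class:`ScreenResults`.
    """

    def __init__(self, cohort: ClinicalCohort) -> None:
        self.cohort = cohort

    def fit(self, variables: list[str] | None = None,
            fdr: bool = False) -> "ScreenResults":
        """Test each variable in declared order; ``fdr=True`` additionally
        reports Benjamini-Hochberg adjusted p-values (the unadjusted
        significance flags are kept, mirroring a no-correction screen)."""
        cohort = self.cohort
        if variables is None:
            variables = list(cohort.categorical_vars) + list(
                cohort.continuous_vars)
        results = []
        for var in variables:
            if var in cohort.categorical_vars:
                results.append(chi_square_test(crosstab(cohort, var), var))
            elif var in cohort.continuous_vars:
                if var in cohort.patients.columns:
                    df = cohort.patients
                    vals = pd.to_numeric(df[var], errors="coerce")
                    res = two_sample_location_test(
                        vals[df["culture_result"] == "negative"],
                        vals[df["culture_result"] == "positive"], var)
                else:
                    res = two_sample_location_test_from_stats(
                        cohort.continuous_summaries[var], var)
                results.append(res)
            else:
                raise ValidationError(f"unknown variable {var!r}")
        adjusted = None
        if fdr and results:
            adjusted = dict(zip(
                [r.variable for r in results],
                stats.false_discovery_control(
                    [r.p_value for r in results], method="bh")))
        return ScreenResults(results, adjusted_p=adjusted)


@dataclass
class ScreenResults:
    results: list[AssociationResult]
    adjusted_p: dict | None = None

    @property
    def significant(self) -> list[str]:
        return [r.variable for r in self.results if r.significant]

    def significant_categorical(self) -> set[str]:
        return {r.variable for r in self.results
                if r.significant and r.kind == "categorical"}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "variable": r.variable, "kind": r.kind, "test": r.test,
                "statistic": r.statistic, "dof": r.dof, "p_value": r.p_value,
                "significant": r.significant,
                "small_expected": r.small_expected,
                "p_adjusted": (self.adjusted_p or {}).get(r.variable, np.nan),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Clinicopathology association screen "
                 "(outcome: bacterial culture result)"]
        for r in self.results:
            star = " *" if r.significant else ""
            p = "<0.001" if r.p_value < 0.001 else f"{r.p_value:.3f}"
            lines.append(f"  {r.variable:32s} {r.test:20s} "
                         f"stat={r.statistic:8.3f} df={r.dof:2d} p={p}{star}")
        sig = self.significant
        lines.append("  significant at two-tailed 0.05: "
                     + (", ".join(sig) if sig else "(none)"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def association_screen(cohort: ClinicalCohort,
                       variables: list[str] | None = None) -> ScreenResults:
    """Functional wrapper over :class:`ClinicalAssociationScreen`."""
    return ClinicalAssociationScreen(cohort).fit(variables)
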