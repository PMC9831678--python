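"""Alignment-based paired differential-genus analysis.

Matched specimens from the same patient (e.g. outer tumor tissue vs the
adjacent normal margin) are compared genus by genus.  The procedure is a
descriptive rule, not a p-value machine:

1. Restrict to the predominant genera shared by both specimen groups:
   mean relative abundance at or above a floor in *each* group, and
   detection (> 0) in at least half the samples of *each* group.  Rare
   genera, and genera found only on one side, are treated as sampling
   bias from ultra-low-biomass tissue and discarded.
2. For every surviving genus compute a per-pair fold change
   (a + eps) / (b + eps) of relative abundances within each matched pair,
   with a small pseudocount eps guarding the zeros.
3. Call a genus enriched in a group when at least a two-fold change in its
   favour occurs in most matched pairs, and the opposing direction stays
   in the minority.

The model/results split mirrors statsmodels: build a
:class:`PairedDifferential` from the abundance table and metadata, call
:meth:`~PairedDifferential.fit`, and read calls off the returned
:class:`PairedDifferentialResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceTable, ValidationError

DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_MAJORITY_FRACTION = 0.5
DEFAULT_MIN_MEAN_ABUNDANCE = 1e-3
DEFAULT_MIN_DETECTION_FRACTION = 0.5
DEFAULT_PSEUDOCOUNT = 1e-5

CALLS = ("enriched_in_A", "enriched_in_B", "not_different", "filtered_out")


@dataclass(frozen=True)
class SpecimenPair:
    patient_id: str
    sample_a: str
    sample_b: str


@dataclass
class PairedSpecimenSet:
    """Matched specimen pairs plus the relative-abundance table covering them."""

    pairs: list[SpecimenPair]
    group_labels: tuple[str, str]
    abundance: AbundanceTable

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError("empty pair list")
        patients = [p.patient_id for p in self.pairs]
        if len(set(patients)) != len(patients):
            raise ValidationError("a patient contributes more than one pair")
        sample_set = set(self.abundance.sample_ids)
        for p in self.pairs:
            for s in (p.sample_a, p.sample_b):
                if s not in sample_set:
                    raise ValidationError(f"pair sample {s!r} absent from table")
        a_side = {p.sample_a for p in self.pairs}
        b_side = {p.sample_b for p in self.pairs}
        if a_side & b_side:
            raise ValidationError("groups must be disjoint sample sets")
        if self.abundance.unit_kind != "relative":
            self.abundance = self.abundance.to_relative()

    @property
    def samples_a(self) -> list[str]:
        return [p.sample_a for p in self.pairs]

    @property
    def samples_b(self) -> list[str]:
        return [p.sample_b for p in self.pairs]

    @classmethod
    def from_metadata(
        cls,
        table: AbundanceTable,
        metadata: pd.DataFrame,
        group_a: str,
        group_b: str,
    ) -> "PairedSpecimenSet":
        """Build pairs from per-sample metadata: one specimen of each type
        per patient.  When a patient has several specimens of one type the
        lexicographically earliest sample id is used (deterministic) and a
        warning is emitted.
        """
        in_table = metadata[metadata["sample_id"].isin(table.sample_ids)]
        pairs = []
        for patient, sub in in_table.groupby("patient_id", sort=True):
            chosen = {}
            for grp in (group_a, group_b):
                cand = sorted(sub.loc[sub["specimen_type"] == grp, "sample_id"])
                if not cand:
                    break
                if len(cand) > 1:
                    warnings.warn(
                        f"patient {patient!r} has {len(cand)} {grp!r} "
                        f"specimens; using {cand[0]!r}")
                chosen[grp] = cand[0]
            if len(chosen) == 2:
                pairs.append(SpecimenPair(str(patient), chosen[group_a],
                                          chosen[group_b]))
        if not pairs:
            raise ValidationError(
                f"no patient has both a {group_a!r} and a {group_b!r} specimen")
        used = [s for p in pairs for s in (p.sample_a, p.sample_b)]
        return cls(pairs, (group_a, group_b), table.subset_samples(used))


def filter_predominant_shared(
    pset: PairedSpecimenSet,
    min_mean_abundance: float = DEFAULT_MIN_MEAN_ABUNDANCE,
    min_detection_fraction: float = DEFAULT_MIN_DETECTION_FRACTION,
) -> list[str]:
    """Genera predominant in BOTH groups of a paired set.

    Keeps a genus iff its mean relative abundance reaches
    ``min_mean_abundance`` in each group AND it is detected (> 0) in at
    least ``min_detection_fraction`` of each group's samples.
    """
    for name, v in (("min_mean_abundance", min_mean_abundance),
                    ("min_detection_fraction", min_detection_fraction)):
        if not (0 < v < 1):
            raise ValidationError(f"{name} must lie in (0, 1), got {v}")
    df = pset.abundance.data
    kept = []
    for grp_samples in (pset.samples_a, pset.samples_b):
        sub = df[grp_samples]
        ok = (sub.mean(axis=1) >= min_mean_abundance) & (
            (sub > 0).mean(axis=1) >= min_detection_fraction)
        kept.append(ok)
    mask = kept[0] & kept[1]
    return [t for t in df.index if mask[t]]


def paired_fold_changes(
    pset: PairedSpecimenSet,
    genus: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Per-pair fold change (a + eps)/(b + eps) for one genus, pair order
    preserved."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if genus not in pset.abundance.data.index:
        raise ValidationError(f"genus {genus!r} absent from table")
    row = pset.abundance.data.loc[genus]
    a = row[pset.samples_a].to_numpy(dtype=float)
    b = row[pset.samples_b].to_numpy(dtype=float)
    return (a + pseudocount) / (b + pseudocount)


class PairedDifferential:
    """Paired differential-genus model over two specimen groups.

    Parameters
    ----------
    table : AbundanceTable
        Genus-level counts or relative abundances covering all specimens.
    metadata : pandas.DataFrame
        Validated per-sample metadata (sample_id, patient_id, specimen_type).
    group_a, group_b : str
        Specimen types to contrast; each patient with one specimen of each
        type contributes a matched pair.
    """

    def __init__(self, table: AbundanceTable, metadata: pd.DataFrame,
                 group_a: str, group_b: str) -> None:
        self.pset = PairedSpecimenSet.from_metadata(table, metadata,
                                                    group_a, group_b)
        self.group_a = group_a
        self.group_b = group_b

    @classmethod
    def from_pairs(cls, pset: PairedSpecimenSet) -> "PairedDifferential":
        obj = cls.__new__(cls)
        obj.pset = pset
        obj.group_a, obj.group_b = pset.group_labels
        return obj

    def fit(
        self,
        fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
        majority_fraction: float = DEFAULT_MAJORITY_FRACTION,
        min_mean_abundance: float = DEFAULT_MIN_MEAN_ABUNDANCE,
        min_detection_fraction: float = DEFAULT_MIN_DETECTION_FRACTION,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PairedDifferentialResults":
        """Run the filter + fold-change + majority rule over every genus.

        A genus is called enriched in group A when the fraction of pairs
        with fold change >= ``fold_threshold`` strictly exceeds
        ``majority_fraction`` while the fraction supporting B stays at or
        below ``1 - majority_fraction`` (and symmetrically for B).
        """
        pset = self.pset
        if len(pset.pairs) < 3:
            raise ValidationError("need at least 3 matched pairs")
        if fold_threshold <= 1:
            raise ValidationError("fold_threshold must exceed 1")
        if not (0.5 <= majority_fraction < 1):
            raise ValidationError("majority_fraction must lie in [0.5, 1)")
        kept = set(filter_predominant_shared(pset, min_mean_abundance,
                                             min_detection_fraction))
        n_pairs = len(pset.pairs)
        records = []
        fold_changes: dict[str, np.ndarray] = {}
        for genus in pset.abundance.taxon_ids:
            if genus not in kept:
                records.append((genus, False, n_pairs, 0, 0, np.nan,
                                "filtered_out"))
                continue
            fc = paired_fold_changes(pset, genus, pseudocount)
            fold_changes[genus] = fc
            n_a = int((fc >= fold_threshold).sum())
            n_b = int((fc <= 1.0 / fold_threshold).sum())
            frac_a, frac_b = n_a / n_pairs, n_b / n_pairs
            if frac_a > majority_fraction and frac_b <= 1 - majority_fraction:
                call = "enriched_in_A"
            elif frac_b > majority_fraction and frac_a <= 1 - majority_fraction:
                call = "enriched_in_B"
            else:
                call = "not_different"
            records.append((genus, True, n_pairs, n_a, n_b,
                            float(np.median(fc)), call))
        frame = pd.DataFrame(
            records,
            columns=["genus", "kept_after_filter", "n_pairs", "n_support_a",
                     "n_support_b", "median_fold_change", "call"],
        ).set_index("genus")
        params = {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "fold_threshold": fold_threshold,
            "majority_fraction": majority_fraction,
            "min_mean_abundance": min_mean_abundance,
            "min_detection_fraction": min_detection_fraction,
            "pseudocount": pseudocount,
        }
        return PairedDifferentialResults(frame, fold_changes, params)


@dataclass
class PairedDifferentialResults:
    """Per-genus calls from a fitted :class:`PairedDifferential`."""

    frame: pd.DataFrame
    fold_changes: dict[str, np.ndarray]
    params: dict = field(default_factory=dict)

    def enriched(self, group: str) -> list[str]:
        """Genera called enriched in ``'A'`` or ``'B'``, ranked by number of
        supporting pairs, then effect size (median fold change toward the
        group), then name."""
        if group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")
        call = f"enriched_in_{group}"
        sub = self.frame[self.frame["call"] == call]
        support = sub[f"n_support_{group.lower()}"]
        effect = (sub["median_fold_change"] if group == "A"
                  else 1.0 / sub["median_fold_change"])
        order = pd.DataFrame({"s": support, "e": effect, "g": sub.index})
        order = order.sort_values(by=["s", "e", "g"],
                                  ascending=[False, False, True])
        return list(order["g"])

    def summary(self) -> str:
        p = self.params
        lines = [
            "Paired differential-genus analysis "
            f"({p.get('group_a')} [A] vs {p.get('group_b')} [B])",
            f"  pairs: {int(self.frame['n_pairs'].iloc[0])}   genera: "
            f"{len(self.frame)}   kept after filter: "
            f"{int(self.frame['kept_after_filter'].sum())}",
            f"  fold threshold {p.get('fold_threshold')}, majority fraction "
            f"{p.get('majority_fraction')}, pseudocount {p.get('pseudocount')}",
        ]
        for grp in ("A", "B"):
            name = p.get(f"group_{grp.lower()}", grp)
            genera = self.enriched(grp)
            lines.append(f"  enriched in {name}: "
                         + (", ".join(genera) if genera else "(none)"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["fold_changes"] = [
            ";".join(f"{v:.6g}" for v in self.fold_changes[g])
            if g in self.fold_changes else ""
            for g in out.index
        ]
        out.to_csv(path, sep="\t")


def summarize_calls(results: PairedDifferentialResults) -> pd.DataFrame:
    """Machine-readable ranked report of enriched genera per group."""
    rows = []
    for grp in ("A", "B"):
        group_name = results.params.get(f"group_{grp.lower()}", grp)
        for rank, genus in enumerate(results.enriched(grp), start=1):
            rec = results.frame.loc[genus]
            rows.append({
                "group": group_name,
                "rank": rank,
                "genus": genus,
                "n_support": int(rec[f"n_support_{grp.lower()}"]),
                "n_pairs": int(rec["n_pairs"]),
                "median_fold_change": float(rec["median_fold_change"]),
            })
    return pd.DataFrame(
        rows, columns=["group", "rank", "genus", "n_support", "n_pairs",
                       "median_fold_change"])
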