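"""End-to-end contrast runner wiring the analysis stages together.

A contrast (e.g. outer tumor tissue vs adjacent normal tissue) produces,
in one output directory: per-sample Shannon diversity with a group test,
the Bray-Curtis distance matrix, PCoA coordinates, a PERMANOVA on the
contrast groups, a composition summary, and — whenever at least three
complete matched pairs exist — the paired differential-genus report.
Every run persists its configuration and a manifest (seed, config hash,
package version, per-stage sample counts) so results are reproducible
from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clinical import ClinicalAssociationScreen, ClinicalCohort, cohort_summary
from .diversity import (alpha_group_test, composition_summary,
                        distance_matrix, patient_clustering_test, pcoa,
                        permanova, shannon_per_sample, write_distance_matrix)
from .io import (AbundanceTable, ValidationError, align_samples,
                 read_abundance_table, read_metadata)
from .paired import PairedDifferential, ValidationError as PairedError
from .table1 import load_table1

log = logging.getLogger("oralmicro")


@dataclass
class RunConfig:
    """Everything one contrast run needs; serialized into its output dir."""

    table_path: str = ""
    metadata_path: str = ""
    group_by: str = "specimen_type"
    group_a: str = "outer_tumor"
    group_b: str = "adjacent_normal"
    fold_threshold: float = 2.0
    majority_fraction: float = 0.5
    min_mean_abundance: float = 1e-3
    min_detection_fraction: float = 0.5
    pseudocount: float = 1e-5
    n_permutations: int = 999
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValidationError("fold_threshold must exceed 1")
        if not (0.5 <= self.majority_fraction < 1):
            raise ValidationError("majority_fraction must lie in [0.5, 1)")
        if self.n_permutations < 99:
            raise ValidationError("n_permutations must be >= 99")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analysis-relevant parameters (output location
        excluded, so reruns into different directories compare equal)."""
        params = dataclasses.asdict(self)
        params.pop("out_dir")
        blob = json.dumps(params, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)


def run_contrast(config: RunConfig,
                 table: AbundanceTable | None = None,
                 metadata=None) -> dict:
    """Run the full contrast pipeline; returns the manifest dict.

    ``table``/``metadata`` may be passed in-memory (e.g. fresh from the
    simulator); otherwise they are read from the configured paths.
    """
    if table is None:
        table = read_abundance_table(config.table_path, unit_kind="counts")
    if metadata is None:
        metadata = read_metadata(config.metadata_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = align_samples(table, metadata)
    if config.group_by not in meta.columns:
        raise ValidationError(
            f"grouping column {config.group_by!r} missing from metadata")
    groups = meta.set_index("sample_id")[config.group_by]
    wanted = groups[groups.isin([config.group_a, config.group_b])]
    unknown = wanted.index[wanted.isna() | (wanted == "unknown")]
    if len(unknown):
        raise ValidationError(
            f"samples with unknown {config.group_by!r}: {list(unknown)}")
    for g in (config.group_a, config.group_b):
        if (wanted == g).sum() < 3:
            raise ValidationError(
                f"group {g!r} resolves to fewer than 3 samples")
    sub = table.subset_samples(list(wanted.index)).to_relative()
    labels = wanted.loc[sub.sample_ids]
    log.info("contrast %s vs %s: %d + %d samples", config.group_a,
             config.group_b, (labels == config.group_a).sum(),
             (labels == config.group_b).sum())

    alpha = shannon_per_sample(sub)
    alpha.to_frame().assign(group=labels).to_csv(out / "alpha_diversity.tsv",
                                                 sep="\t")
    alpha_res = alpha_group_test(alpha[labels == config.group_a],
                                 alpha[labels == config.group_b])
    _write_json({"statistic": alpha_res.statistic,
                 "p_value": alpha_res.p_value, "method": alpha_res.method},
                out / "alpha_test.json")

    dm = distance_matrix(sub)
    write_distance_matrix(dm, out / "bray_curtis.tsv")
    ord_res = pcoa(dm)
    coords = ord_res.to_frame()
    coords.index.name = "sample_id"
    with open(out / "pcoa.tsv", "w", encoding="utf-8") as fh:
        fh.write("# eigenvalues\t"
                 + "\t".join(f"{v:.10g}" for v in ord_res.eigenvalues) + "\n")
        fh.write("# proportion_explained\t"
                 + "\t".join(f"{v:.10g}"
                             for v in ord_res.proportion_explained) + "\n")
        fh.write(f"# negative_eigenvalue_magnitude\t"
                 f"{ord_res.negative_eigenvalue_magnitude:.10g}\n")
        coords.to_csv(fh, sep="\t")
    perm = permanova(dm, labels.to_numpy(), config.n_permutations,
                     config.seed)
    _write_json(perm.to_dict(), out / "permanova.json")

    clustering = None
    patient_of = meta.set_index("sample_id")["patient_id"]
    n_multi = (patient_of.loc[sub.sample_ids].value_counts() >= 2).sum()
    if n_multi >= 2:
        clustering = patient_clustering_test(
            dm, patient_of.loc[sub.sample_ids], config.n_permutations,
            config.seed)
        _write_json(clustering.to_dict(), out / "patient_clustering.json")

    comp = composition_summary(sub, labels)
    comp.index.name = "taxon_id"
    comp.to_csv(out / "composition.tsv", sep="\t")

    paired_done = False
    try:
        model = PairedDifferential(table, meta, config.group_a,
                                   config.group_b)
        if len(model.pset.pairs) >= 3:
            results = model.fit(
                fold_threshold=config.fold_threshold,
                majority_fraction=config.majority_fraction,
                min_mean_abundance=config.min_mean_abundance,
                min_detection_fraction=config.min_detection_fraction,
                pseudocount=config.pseudocount)
            results.to_tsv(out / "paired_differential.tsv")
            (out / "paired_summary.txt").write_text(results.summary() + "\n")
            paired_done = True
        else:
            log.info("paired stage skipped: only %d complete pairs",
                     len(model.pset.pairs))
    except PairedError as exc:
        log.info("paired stage skipped: %s", exc)

    config.to_yaml(out / "config.yaml")
    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_samples": int(len(labels)),
        "n_taxa": table.n_taxa,
        "groups": {config.group_a: int((labels == config.group_a).sum()),
                   config.group_b: int((labels == config.group_b).sum())},
        "paired_analysis": paired_done,
        "patient_clustering": clustering is not None,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def run_clinical(cohort: ClinicalCohort | None = None,
                 cohort_path: str | None = None,
                 fixture: str | None = None,
                 out_dir: str = "results") -> dict:
    """Run the clinicopathology screen; returns a summary dict."""
    if cohort is None:
        if fixture == "table1":
            cohort = load_table1()
        elif cohort_path:
            cohort = _read_cohort_tsv(cohort_path)
        else:
            raise ValidationError("provide a cohort, a path, or a fixture")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    screen = ClinicalAssociationScreen(cohort).fit()
    screen.to_tsv(out / "association_screen.tsv")
    (out / "association_summary.txt").write_text(screen.summary() + "\n")
    summary = cohort_summary(cohort)
    _write_json(summary, out / "cohort_summary.json")
    return {"significant": screen.significant,
            "n_patients": cohort.n_patients,
            "out_dir": str(out)}


def _read_cohort_tsv(path) -> ClinicalCohort:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"could not parse cohort TSV: {exc}") from exc
    for i, row in df.iterrows():
        if row.isna().all():
            raise ValidationError(f"blank cohort row at line {i + 2}")
    required = {"patient_id", "culture_result"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"cohort TSV missing columns: {sorted(required - set(df.columns))}")
    other = [c for c in df.columns if c not in required]
    continuous, categorical = [], []
    for c in other:
        as_num = pd.to_numeric(df[c], errors="coerce")
        if as_num.notna().all():
            df[c] = as_num
            continuous.append(c)
        else:
            categorical.append(c)
    return ClinicalCohort(patients=df, categorical_vars=categorical,
                          continuous_vars=continuous)
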