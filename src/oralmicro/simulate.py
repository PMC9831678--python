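"""Synthetic paired microbiome studies and clinical cohorts with known truth.

The microbiome generator emulates the structure the analyses assume: several
specimen types per patient, a strong shared patient signature (specimens
from the same patient cluster together), specimen-type enrichments planted
at known fold changes, sporadic trace detections of rare genera (the
"sampling bias" the predominance filter exists to remove), and multinomial
sequencing noise at realistic, variable library sizes.

The default generative model is logistic-normal-multinomial: each patient
draws a latent log-abundance profile (base community + patient effect);
each specimen adds its specimen-type and planted-differential effects; a
sample's counts are multinomial draws from the softmax of its latent
profile at a log-normally distributed depth.  A plain Dirichlet-multinomial
mode (no patient correlation) is kept for simplicity checks.

Every simulation returns a :class:`SimTruth` recording exactly what was
planted, so recovery can be scored without peeking at the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import ClinicalCohort
from .io import AbundanceTable, ValidationError, validate_metadata

#: genus panel: oral-cancer-associated taxa first, synthetic fillers after
NAMED_GENERA = (
    "Fusobacterium", "Prevotella", "Porphyromonas", "Streptococcus",
    "Neisseria", "Alloprevotella", "Selenomonas", "Parvimonas",
    "Capnocytophaga", "Veillonella", "Gemella", "Haemophilus",
    "Leptotrichia", "Actinomyces", "Rothia", "Granulicatella",
    "Campylobacter", "Treponema", "Aggregatibacter", "Tannerella",
)


def default_genus_names(n: int) -> list[str]:
    names = list(NAMED_GENERA[:n])
    names += [f"Genus_{i + 1:03d}" for i in range(len(names), n)]
    return names


@dataclass(frozen=True)
class PlantedDifferential:
    """A genus planted ``fold_change``-fold higher in ``specimen_a`` than
    in ``specimen_b``."""

    genus: str
    specimen_a: str
    specimen_b: str
    fold_change: float


@dataclass
class MicrobiomeSimSpec:
    """Parameters of a simulated paired-specimen study.

    ``patient_effect_sd`` is the SD (log scale) of the per-patient,
    per-genus community shift shared by all of that patient's specimens;
    at the default 1.0 it dominates specimen-level effects, reproducing
    patient-dominant clustering.  ``rare_genus_rate`` is the fraction of
    the genus panel that never belongs to the core community and appears
    only as sporadic trace spikes below 0.05% relative abundance.
    """

    n_patients: int = 10
    specimen_types: tuple[str, ...] = ("outer_tumor", "adjacent_normal")
    n_genera: int = 40
    base_log_profile: np.ndarray | None = None
    patient_effect_sd: float = 1.0
    specimen_effects: dict = field(default_factory=dict)
    planted_differentials: list[PlantedDifferential] = field(
        default_factory=list)
    depth_mean: float = 50_000.0
    depth_log_sd: float = 0.5
    rare_genus_rate: float = 0.05
    rare_spike_probability: float = 0.3
    mode: str = "logistic_normal"
    dirichlet_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.specimen_types:
            raise ValidationError("specimen_types must not be empty")
        if self.depth_mean < 1000:
            raise ValidationError("mean sequencing depth must be >= 1000")
        if self.patient_effect_sd < 0:
            raise ValidationError("patient_effect_sd must be >= 0")
        if self.mode not in ("logistic_normal", "dirichlet"):
            raise ValidationError(f"unknown simulation mode {self.mode!r}")
        names = default_genus_names(self.n_genera)
        for pd_ in self.planted_differentials:
            if pd_.fold_change <= 0:
                raise ValidationError("planted fold changes must be positive")
            if pd_.genus not in names:
                raise ValidationError(
                    f"planted genus {pd_.genus!r} outside the genus panel")
            for t in (pd_.specimen_a, pd_.specimen_b):
                if t not in self.specimen_types:
                    raise ValidationError(
                        f"planted specimen type {t!r} not simulated")

    @property
    def genus_names(self) -> list[str]:
        return default_genus_names(self.n_genera)

    @property
    def n_rare(self) -> int:
        return int(round(self.rare_genus_rate * self.n_genera))


@dataclass
class SimTruth:
    """Planted parameters of a simulated study (the answer key)."""

    taxon_ids: list[str] = field(default_factory=list)
    planted: list[dict] = field(default_factory=list)
    patient_of: dict = field(default_factory=dict)
    expected_composition: dict = field(default_factory=dict)
    rare_genera: list[str] = field(default_factory=list)
    variable_odds_ratios: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        known = set(self.taxon_ids)
        for rec in self.planted:
            if rec["genus"] not in known:
                raise ValidationError(
                    f"truth references absent genus {rec['genus']!r}")


def write_truth(truth: SimTruth, path) -> None:
    truth.validate()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1)


def read_truth(path) -> SimTruth:
    with open(path, encoding="utf-8") as fh:
        return SimTruth(**json.load(fh))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def simulate_paired_study(
    spec: MicrobiomeSimSpec,
) -> tuple[AbundanceTable, pd.DataFrame, SimTruth]:
    """Simulate one study: counts table, sample metadata, and truth.

    Deterministic under ``spec.seed``: the same spec yields bit-identical
    tables.  Sample ids are ``<patient>_<specimen_type>``.
    """
    rng = np.random.default_rng(spec.seed)
    genera = spec.genus_names
    n_rare = spec.n_rare
    n_core = spec.n_genera - n_rare
    core_names = genera[:n_core]
    rare_names = genera[n_core:]
    if spec.base_log_profile is not None:
        base = np.asarray(spec.base_log_profile, dtype=float)
        if base.shape != (n_core,):
            raise ValidationError(
                f"base_log_profile must have length {n_core} (core genera)")
    else:
        # geometric rank-abundance: most abundant genus ~400x the rarest core
        base = -np.linspace(0.0, 6.0, n_core)
    patients = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    patient_effects = rng.normal(0.0, spec.patient_effect_sd,
                                 size=(spec.n_patients, n_core))
    genus_index = {g: i for i, g in enumerate(core_names)}

    specimen_logit = {t: np.zeros(n_core) for t in spec.specimen_types}
    for (genus, s_type), log_fc in spec.specimen_effects.items():
        if genus in genus_index and s_type in specimen_logit:
            specimen_logit[s_type][genus_index[genus]] += float(log_fc)
    planted_records = []
    for p in spec.planted_differentials:
        if p.genus not in genus_index:
            raise ValidationError(
                f"planted genus {p.genus!r} is in the rare tail; plant on a "
                "core genus")
        j = genus_index[p.genus]
        half = 0.5 * np.log(p.fold_change)
        specimen_logit[p.specimen_a][j] += half
        specimen_logit[p.specimen_b][j] -= half
        planted_records.append({
            "genus": p.genus, "specimen_a": p.specimen_a,
            "specimen_b": p.specimen_b, "fold_change": p.fold_change,
            "enriched_in": p.specimen_a,
        })

    sample_ids, columns, meta_rows, expected = [], [], [], {}
    for i, patient in enumerate(patients):
        for s_type in spec.specimen_types:
            if spec.mode == "logistic_normal":
                logits = base + patient_effects[i] + specimen_logit[s_type]
                p_core = _softmax(logits)
            else:
                mean_p = _softmax(base + specimen_logit[s_type])
                alpha = spec.dirichlet_concentration * mean_p
                p_core = rng.dirichlet(alpha)
            traces = np.zeros(n_rare)
            if n_rare:
                spike = rng.random(n_rare) < spec.rare_spike_probability
                traces[spike] = rng.uniform(5e-5, 5e-4, size=spike.sum())
            p_full = np.concatenate([p_core * (1.0 - traces.sum()), traces])
            depth = max(1000, int(round(rng.lognormal(
                np.log(spec.depth_mean), spec.depth_log_sd))))
            counts = rng.multinomial(depth, p_full)
            sid = f"{patient}_{s_type}"
            sample_ids.append(sid)
            columns.append(counts)
            expected[sid] = [float(v) for v in p_full]
            meta_rows.append({"sample_id": sid, "patient_id": patient,
                              "specimen_type": s_type})
    table = AbundanceTable(
        pd.DataFrame(np.column_stack(columns), index=genera,
                     columns=sample_ids),
        unit_kind="counts")
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    truth = SimTruth(
        taxon_ids=genera,
        planted=planted_records,
        patient_of={r["sample_id"]: r["patient_id"] for r in meta_rows},
        expected_composition=expected,
        rare_genera=list(rare_names),
        seed=spec.seed,
    )
    return table, metadata, truth


@dataclass(frozen=True)
class CohortVariableSpec:
    """One simulated clinical variable and its true relation to outcome.

    Categorical (binary yes/no): ``baseline_prob`` is P(yes | culture
    negative) and ``odds_ratio`` multiplies the odds of "yes" in the
    culture-positive group (1.0 means independence).  Continuous: normal
    with per-group means and SDs.
    """

    name: str
    kind: str = "categorical"
    baseline_prob: float = 0.3
    odds_ratio: float = 1.0
    mean_negative: float = 0.0
    sd_negative: float = 1.0
    mean_positive: float = 0.0
    sd_positive: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValidationError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical":
            if not (0 < self.baseline_prob < 1):
                raise ValidationError("baseline_prob must lie in (0, 1)")
            if self.odds_ratio <= 0:
                raise ValidationError("odds ratios must be positive")


def simulate_clinical_cohort(
    n_patients: int,
    variables: list[CohortVariableSpec],
    outcome_prevalence: float = 105 / 218,
    seed: int = 0,
) -> tuple[ClinicalCohort, SimTruth]:
    """Simulate a patient cohort with planted variable-outcome associations."""
    if n_patients < 20:
        raise ValidationError("need at least 20 patients")
    if not (0 < outcome_prevalence < 1):
        raise ValidationError("outcome prevalence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    outcome = np.where(rng.random(n_patients) < outcome_prevalence,
                       "positive", "negative")
    data = {"patient_id": [f"S{i + 1:04d}" for i in range(n_patients)],
            "culture_result": outcome}
    categorical, continuous, levels = [], [], {}
    for v in variables:
        if v.kind == "categorical":
            odds = v.baseline_prob / (1 - v.baseline_prob) * np.where(
                outcome == "positive", v.odds_ratio, 1.0)
            p_yes = odds / (1 + odds)
            data[v.name] = np.where(rng.random(n_patients) < p_yes,
                                    "yes", "no")
            categorical.append(v.name)
            levels[v.name] = ["yes", "no"]
        else:
            mean = np.where(outcome == "positive", v.mean_positive,
                            v.mean_negative)
            sd = np.where(outcome == "positive", v.sd_positive,
                          v.sd_negative)
            data[v.name] = rng.normal(mean, sd)
            continuous.append(v.name)
    cohort = ClinicalCohort(
        patients=pd.DataFrame(data),
        categorical_vars=categorical,
        continuous_vars=continuous,
        variable_levels=levels,
    )
    truth = SimTruth(
        variable_odds_ratios={
            v.name: (v.odds_ratio if v.kind == "categorical" else None)
            for v in variables},
        seed=seed,
    )
    return cohort, truth
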