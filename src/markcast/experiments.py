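"""End-to-end experiment grid over a study.

Reproduces the full analysis layout on any study (synthetic or user
supplied): three feature scenarios (same-tissue lineage contexts, other
tissues, cross-species contexts) crossed with two negative-set types
(matched genomic background, other-tissue enhancers), a six-classifier
sweep on identical folds, per-dataset enrichment statistics, and
leave-one-context-out prediction of the histone marks themselves.

Every stochastic component takes a seed derived deterministically from
one master seed by stable hashing of the component's name, so the whole
report is reproducible bit-for-bit and re-ordering scenarios cannot
change results.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np

from .background import SamplerConfig, sample_matched_negatives
from .enrichment import EnrichmentResult, enrich_all
from .errors import ConfigurationError
from .features import LabeledFeatureMatrix, build_feature_matrix
from .intervals import RegionSet
from .manifest import ContextMeta
from .model import ALGORITHMS, ClassifierSpec, CVConfig, CVReport, cross_validate
from .simulate import CROSS_SPECIES, NATIVE_SPECIES, TARGET_TISSUE, SyntheticStudy

NEGATIVE_MODES = ("genomic_background", "other_enhancers")

#: Named feature-subset predicates over :class:`ContextMeta`.
FEATURE_FILTERS: dict[str, Callable[[ContextMeta], bool]] = {
    "heart_stages": lambda m: m.tissue == TARGET_TISSUE
    and m.species == NATIVE_SPECIES,
    "other_tissues": lambda m: m.tissue != TARGET_TISSUE
    and m.species == NATIVE_SPECIES,
    "cross_species": lambda m: m.species == CROSS_SPECIES,
    "all": lambda m: True,
}


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-component seed: crc32 of the label folded into the master."""
    return (zlib.crc32(label.encode()) ^ (master_seed * 0x9E3779B1)) % (2**31)


@dataclass(frozen=True)
class ScenarioConfig:
    """One classification scenario: a feature subset, a negative-set type,
    a classifier and the evaluation setup."""

    name: str
    feature_filter: str = "heart_stages"
    negative_mode: str = "genomic_background"
    algorithm: str = "random_forest"
    n_folds: int = 5
    sampler_ratio: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_filter not in FEATURE_FILTERS:
            raise ConfigurationError(
                f"unknown feature filter {self.feature_filter!r}; "
                f"expected one of {sorted(FEATURE_FILTERS)}"
            )
        if self.negative_mode not in NEGATIVE_MODES:
            raise ConfigurationError(
                f"unknown negative mode {self.negative_mode!r}"
            )

    @property
    def seed(self) -> int:
        return derive_seed(self.master_seed, self.name)


def _scenario_inputs(
    study: SyntheticStudy, config: ScenarioConfig
) -> LabeledFeatureMatrix:
    """Positives, negatives and filtered features for one scenario."""
    positives = study.target_enhancers
    if config.negative_mode == "genomic_background":
        exclusions = RegionSet(
            list(study.target_enhancers) + list(study.other_enhancers),
            "known_active",
        )
        negatives = sample_matched_negatives(
            positives,
            study.genome,
            exclusions,
            SamplerConfig(ratio=config.sampler_ratio, seed=config.seed),
        )
    else:
        negatives = study.other_enhancers
    meta = [m for m in study.manifest if FEATURE_FILTERS[config.feature_filter](m)]
    if not meta:
        raise ConfigurationError(
            f"feature filter {config.feature_filter!r} matches no dataset"
        )
    return build_feature_matrix(positives, negatives, study.peak_sets, meta)


def run_scenario(study: SyntheticStudy, config: ScenarioConfig) -> CVReport:
    """Featurize, sample negatives and cross-validate one scenario."""
    matrix = _scenario_inputs(study, config)
    spec = ClassifierSpec(config.algorithm)
    return cross_validate(
        spec, matrix, CVConfig(n_folds=config.n_folds, seed=config.seed)
    )


def _fold_digest(labels: np.ndarray, cv: CVConfig) -> str:
    from .model import stratified_folds

    h = hashlib.sha256()
    for _, test in stratified_folds(labels, cv):
        h.update(np.asarray(test, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


def run_classifier_sweep(
    study: SyntheticStudy,
    feature_filter: str = "heart_stages",
    negative_modes: Sequence[str] = NEGATIVE_MODES,
    n_folds: int = 5,
    sampler_ratio: int = 10,
    master_seed: int = 0,
) -> dict:
    """All six classifiers on identical folds, per negative-set type.

    Returns ``{"auc": {mode: {algorithm: mean_auc}}, "fold_digest":
    {mode: hex}}``; the digest certifies that every algorithm within a
    mode saw the same folds.
    """
    aucs: dict[str, dict[str, float]] = {}
    digests: dict[str, str] = {}
    for mode in negative_modes:
        cfg = ScenarioConfig(
            name=f"sweep_{feature_filter}_{mode}",
            feature_filter=feature_filter,
            negative_mode=mode,
            n_folds=n_folds,
            sampler_ratio=sampler_ratio,
            master_seed=master_seed,
        )
        matrix = _scenario_inputs(study, cfg)
        cv = CVConfig(n_folds=n_folds, seed=cfg.seed)
        digests[mode] = _fold_digest(matrix.labels, cv)
        aucs[mode] = {}
        for algorithm in ALGORITHMS:
            report = cross_validate(
                ClassifierSpec(algorithm), matrix, cv, compute_importances=False
            )
            aucs[mode][algorithm] = report.mean_auc
    return {"auc": aucs, "fold_digest": digests}


def run_mark_leaveout(
    study: SyntheticStudy,
    algorithm: str = "random_forest",
    n_folds: int = 5,
    sampler_ratio: int = 10,
    master_seed: int = 0,
) -> dict[str, float]:
    """Leave-one-context-out mark prediction over the native lineage.

    For each lineage (context, mark) dataset in turn: positives are that
    dataset's peak regions, negatives a fresh matched background draw,
    features the overlaps with every other lineage dataset. Returns
    ``dataset_id -> mean CV AUC``.
    """
    heart_ids = study.heart_dataset_ids()
    if len(heart_ids) < 2:
        raise ConfigurationError("mark leave-out needs >= 2 lineage datasets")
    out: dict[str, float] = {}
    for did in heart_ids:
        seed = derive_seed(master_seed, f"leaveout_{did}")
        positives = study.peak_sets[did]
        negatives = sample_matched_negatives(
            positives,
            study.genome,
            positives,
            SamplerConfig(ratio=sampler_ratio, seed=seed),
        )
        meta = [m for m in study.manifest if m.dataset_id in heart_ids
                and m.dataset_id != did]
        matrix = build_feature_matrix(positives, negatives, study.peak_sets, meta)
        report = cross_validate(
            ClassifierSpec(algorithm),
            matrix,
            CVConfig(n_folds=n_folds, seed=seed),
            compute_importances=False,
        )
        out[did] = report.mean_auc
    return out


def study_digest(study: SyntheticStudy) -> str:
    """SHA-256 digest of the study's full interval content."""
    h = hashlib.sha256()
    for rs in (study.target_enhancers, study.other_enhancers):
        for r in rs:
            h.update(f"{r.chrom}:{r.start}-{r.end}:{r.name}:{r.label};".encode())
    for did in sorted(study.peak_sets):
        h.update(did.encode())
        for r in study.peak_sets[did]:
            h.update(f"{r.chrom}:{r.start}-{r.end};".encode())
    return h.hexdigest()


@dataclass
class ExperimentReport:
    """The full grid: scenario CV reports, classifier sweep, enrichment,
    mark leave-out AUCs, and complete provenance."""

    scenarios: dict[str, CVReport]
    sweep: dict
    enrichment: list[EnrichmentResult]
    mark_leaveout: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scenarios": {k: v.to_dict() for k, v in self.scenarios.items()},
            "sweep": self.sweep,
            "enrichment": [
                {
                    "dataset_id": r.dataset_id,
                    "table": [r.table.a, r.table.b, r.table.c, r.table.d],
                    "odds_ratio": "inf"
                    if np.isinf(r.odds_ratio)
                    else float(r.odds_ratio),
                    "p_two_sided": float(r.p_two_sided),
                }
                for r in self.enrichment
            ],
            "mark_leaveout": {k: float(v) for k, v in self.mark_leaveout.items()},
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_report(
    study: SyntheticStudy,
    master_seed: int = 0,
    n_folds: int = 5,
    sampler_ratio: int = 10,
) -> ExperimentReport:
    """Run the complete experiment grid on one study.

    Six scenarios (three feature subsets x two negative modes, random
    forest), the six-classifier sweep on lineage features, lineage-dataset
    enrichment vs matched background, and mark leave-out - all seeded from
    ``master_seed``.
    """
    scenarios: dict[str, CVReport] = {}
    for ff in ("heart_stages", "other_tissues", "cross_species"):
        for mode in NEGATIVE_MODES:
            name = f"{ff}__{mode}"
            cfg = ScenarioConfig(
                name=name,
                feature_filter=ff,
                negative_mode=mode,
                n_folds=n_folds,
                sampler_ratio=sampler_ratio,
                master_seed=master_seed,
            )
            scenarios[name] = run_scenario(study, cfg)

    sweep = run_classifier_sweep(
        study,
        feature_filter="heart_stages",
        n_folds=n_folds,
        sampler_ratio=sampler_ratio,
        master_seed=master_seed,
    )

    enr_seed = derive_seed(master_seed, "enrichment")
    exclusions = RegionSet(
        list(study.target_enhancers) + list(study.other_enhancers), "known_active"
    )
    enr_negatives = sample_matched_negatives(
        study.target_enhancers,
        study.genome,
        exclusions,
        SamplerConfig(ratio=sampler_ratio, seed=enr_seed),
    )
    heart_meta = [
        m for m in study.manifest if m.dataset_id in study.heart_dataset_ids()
    ]
    enrichment = enrich_all(
        study.target_enhancers, enr_negatives, study.peak_sets, heart_meta
    )

    leaveout = run_mark_leaveout(
        study,
        n_folds=n_folds,
        sampler_ratio=sampler_ratio,
        master_seed=master_seed,
    )

    provenance = {
        "master_seed": master_seed,
        "n_folds": n_folds,
        "sampler_ratio": sampler_ratio,
        "study_config": asdict(study.config),
        "study_digest": study_digest(study),
        "scenario_seeds": {
            name: derive_seed(master_seed, name) for name in scenarios
        },
    }
    return ExperimentReport(scenarios, sweep, enrichment, leaveout, provenance)
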