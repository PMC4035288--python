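"""End-to-end orchestration of the five grading approaches.

Feature sets evaluated by the classifier:

    I   all differentially expressed mRNAs (G1 vs G3)
    II  stage-II genes (expression call concordant with a copy-number call)
    III the stage-III gene signature (stage II restricted to targets of
        oppositely-directed miRNAs)
    IV  the stage-III miRNA signature, using miRNA expression features
    V   the downsized gene signature (III intersected with the union of
        reference signatures)

Each approach routes through the same operations: stratified CV on
G1/G3, reclassification of G2 into G1*/G3*, retraining on the
relabelled set and testing on the original G1/G3 samples, and the
three survival comparisons.  On consistently planted synthetic data
the feature sets nest: V ⊆ III ⊆ II ⊆ I.

One master seed fans out deterministically to per-stage sub-seeds
(CRC32 of ``"stage:seed"``), so every stage is independently
reproducible and a report re-runs byte-identically.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import cna as cna_mod
from .classify import ClassifierConfig, SVMGradeClassifier
from .cna import CnaThresholds
from .diffexpr import ContrastSpec, SamModel, batch_adjust
from .integrate import Signature, stage2_sets, stage3_classes, downsize_signature
from .io import ExpressionMatrix, SampleTable, TargetMap
from .survival import compare_reclassified_groups

__all__ = ["PipelineConfig", "ApproachReport", "balance_groups", "run_approach", "run_all", "stage_seed"]

log = logging.getLogger(__name__)

APPROACHES = ("I", "II", "III", "IV", "V")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic sub-seed for a named stage (CRC32 fan-out, < 2^31)."""
    return zlib.crc32(f"{stage}:{master_seed}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    q_threshold: float = 0.01
    sam_B: int = 300
    batch_mode: str = "eb"
    cna_thresholds: CnaThresholds = field(default_factory=CnaThresholds)
    cna_top_k: int = 6000
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    approach: str = "III"
    reference_signatures: list = field(default_factory=list)   # Signature objects
    balanced_n: Optional[int] = None
    seed: int = 0

    def validate(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")
        if self.approach == "V" and not self.reference_signatures:
            raise ValueError("approach V requires at least one reference signature")
        if not (0.0 < self.q_threshold <= 1.0):
            raise ValueError("q threshold must lie in (0, 1]")


@dataclass
class ApproachReport:
    approach: str
    features: list
    cv: dict
    reclassification: Optional[dict]
    survival: Optional[list]
    set_sizes: dict
    seed: int

    def as_dict(self) -> dict:
        return {
            "approach": self.approach,
            "features": self.features,
            "cv": self.cv,
            "reclassification": self.reclassification,
            "survival": self.survival,
            "set_sizes": self.set_sizes,
            "seed": self.seed,
        }


def balance_groups(
    sample_table: SampleTable, grades: Sequence[str], n: int, seed: int
) -> list:
    """Sample exactly n ids per grade without replacement, seeded."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for grade in grades:
        ids = sample_table.ids_of_grade(grade)
        if len(ids) < n:
            raise ValueError(f"grade {grade} has only {len(ids)} samples, need {n}")
        picks = rng.choice(len(ids), size=n, replace=False)
        chosen.extend(ids[k] for k in sorted(picks))
    return chosen


@dataclass
class _Stages:
    """Shared intermediate results reused across approaches."""

    mrna_de: object
    mirna_de: object
    stage2: object
    classes: object
    adjusted_mrna: ExpressionMatrix
    adjusted_mirna: ExpressionMatrix
    samples: SampleTable


def _run_shared_stages(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    segments,
    samples: SampleTable,
    genes,
    targets: TargetMap,
    config: PipelineConfig,
) -> _Stages:
    if config.balanced_n is not None:
        keep = balance_groups(
            samples, ("G1", "G2", "G3"), config.balanced_n, stage_seed(config.seed, "balance")
        )
        samples = samples.subset(keep)
        mrna = mrna.subset_samples(keep)
        mirna = mirna.subset_samples(keep)

    batches = [
        dict(zip(samples.df["sample_id"], samples.df["batch"]))[s] for s in mrna.sample_ids
    ]
    mrna = batch_adjust(mrna, batches, mode=config.batch_mode)
    mirna_batches = [
        dict(zip(samples.df["sample_id"], samples.df["batch"]))[s] for s in mirna.sample_ids
    ]
    mirna = batch_adjust(mirna, mirna_batches, mode=config.batch_mode)

    contrast = ContrastSpec("G1", "G3")
    grade_of = dict(zip(samples.df["sample_id"], samples.df["grade"]))

    mrna_de = SamModel(mrna, [grade_of[s] for s in mrna.sample_ids], contrast).fit(
        q_threshold=config.q_threshold, B=config.sam_B, seed=stage_seed(config.seed, "sam_mrna")
    )
    mirna_de = SamModel(mirna, [grade_of[s] for s in mirna.sample_ids], contrast).fit(
        q_threshold=config.q_threshold, B=config.sam_B, seed=stage_seed(config.seed, "sam_mirna")
    )
    log.info("SAM calls: %d mRNA up, %d mRNA down, %d miRNA up, %d miRNA down",
             len(mrna_de.up), len(mrna_de.down), len(mirna_de.up), len(mirna_de.down))

    status = cna_mod.gene_alteration_status(genes, segments, config.cna_thresholds)
    cna_sets = {}
    for grade in ("G1", "G3"):
        freq = cna_mod.alteration_frequencies(status, samples, grade)
        cna_sets[grade] = cna_mod.select_top_altered(freq, K=config.cna_top_k)
        log.info("CNA %s: %d amplified, %d deleted",
                 grade, len(cna_sets[grade][0]), len(cna_sets[grade][1]))

    stage2 = stage2_sets(mrna_de, cna_sets["G1"], cna_sets["G3"])
    classes = stage3_classes(stage2, mirna_de, targets)
    log.info("stage II union: %d genes; signature: %d genes, %d miRNAs",
             len(stage2.union_genes), len(classes.gene_signature), len(classes.mirna_signature))
    return _Stages(mrna_de, mirna_de, stage2, classes, mrna, mirna, samples)


def _approach_features(approach: str, stages: _Stages, config: PipelineConfig) -> tuple[list, ExpressionMatrix]:
    """Feature ids and the matrix they come from for one approach."""
    if approach == "I":
        feats = sorted(stages.mrna_de.up | stages.mrna_de.down)
        return feats, stages.adjusted_mrna
    if approach == "II":
        return sorted(stages.stage2.union_genes), stages.adjusted_mrna
    if approach == "III":
        return sorted(stages.classes.gene_signature), stages.adjusted_mrna
    if approach == "IV":
        return sorted(stages.classes.mirna_signature), stages.adjusted_mirna
    if approach == "V":
        candidate = Signature("stage3", stages.classes.gene_signature)
        downsized, _report = downsize_signature(candidate, config.reference_signatures)
        return sorted(downsized.genes), stages.adjusted_mrna
    raise ValueError(f"unknown approach {approach!r}")


def _classify_and_validate(
    features: list, matrix: ExpressionMatrix, samples: SampleTable, config: PipelineConfig
) -> tuple[dict, Optional[dict], Optional[list]]:
    if not features:
        raise ValueError("empty feature set for this approach")
    sub = matrix.subset_features(features)
    g1 = samples.ids_of_grade("G1")
    g3 = samples.ids_of_grade("G3")
    g2 = samples.ids_of_grade("G2")
    train = sub.subset_samples(g1 + g3)
    clf_config = ClassifierConfig(
        kernels=config.classifier.kernels,
        c_grid=config.classifier.c_grid,
        gamma_grid=config.classifier.gamma_grid,
        anova_degree=config.classifier.anova_degree,
        k_folds=config.classifier.k_folds,
        seed=stage_seed(config.seed, "classifier"),
    )
    model = SVMGradeClassifier(
        train.values.T, samples.grades_for(train.sample_ids), clf_config
    )
    cv_report = model.fit_cv().as_dict()
    reclass_dict, surv_list = None, None
    if g2:
        g2_matrix = sub.subset_samples(g2)
        reclass = model.reclassify(g2_matrix.values.T, g2_ids=g2)
        reclass_dict = reclass.as_dict()
        surv = compare_reclassified_groups(samples, reclass)
        surv_list = [c.as_dict() for c in surv["comparisons"]]
    return cv_report, reclass_dict, surv_list


def run_approach(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    segments,
    samples: SampleTable,
    genes,
    targets: TargetMap,
    config: PipelineConfig,
    _stages: Optional[_Stages] = None,
) -> ApproachReport:
    """Run one approach end to end and return its report."""
    config.validate()
    stages = _stages or _run_shared_stages(mrna, mirna, segments, samples, genes, targets, config)
    features, feat_matrix = _approach_features(config.approach, stages, config)
    cv, reclass, surv = _classify_and_validate(features, feat_matrix, stages.samples, config)
    set_sizes = {
        "de_mrna_up": len(stages.mrna_de.up),
        "de_mrna_down": len(stages.mrna_de.down),
        "de_mirna_up": len(stages.mirna_de.up),
        "de_mirna_down": len(stages.mirna_de.down),
        "stage2_union": len(stages.stage2.union_genes),
        "gene_signature": len(stages.classes.gene_signature),
        "mirna_signature": len(stages.classes.mirna_signature),
        "features_used": len(features),
    }
    return ApproachReport(
        approach=config.approach,
        features=features,
        cv=cv,
        reclassification=reclass,
        survival=surv,
        set_sizes=set_sizes,
        seed=config.seed,
    )


def run_all(
    mrna, mirna, segments, samples, genes, targets, config: PipelineConfig,
    approaches: Sequence[str] = ("I", "II", "III", "IV"),
) -> dict:
    """Run several approaches on shared intermediate stages.

    Approach V is included only when reference signatures are
    configured.  The returned dict is JSON-serialisable and
    byte-reproducible for a fixed config.
    """
    stages = _run_shared_stages(mrna, mirna, segments, samples, genes, targets, config)
    approaches = list(approaches)
    if config.reference_signatures and "V" not in approaches:
        approaches.append("V")
    reports = {}
    for ap in approaches:
        cfg = PipelineConfig(
            q_threshold=config.q_threshold,
            sam_B=config.sam_B,
            batch_mode=config.batch_mode,
            cna_thresholds=config.cna_thresholds,
            cna_top_k=config.cna_top_k,
            classifier=config.classifier,
            approach=ap,
            reference_signatures=config.reference_signatures,
            balanced_n=config.balanced_n,
            seed=config.seed,
        )
        reports[ap] = run_approach(
            mrna, mirna, segments, samples, genes, targets, cfg, _stages=stages
        ).as_dict()
    return {"seed": config.seed, "approaches": reports}


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
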