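"""Clinical-style workflow: score reads, estimate contamination, check
read sufficiency, filter, and reconstruct the copy-number profile —
one call with a machine-readable report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .classifier import ReadOriginClassifier
from .cnvrecon import (
    call_and_classify,
    count_in_bins,
    gc_correct,
    normalize_to_reference,
    segment,
    segments_to_frame,
)
from .deconv import map_estimate
from .readfilter import RETAIN_ALL, ThresholdPolicy, choose_threshold, filter_reads, sufficiency_check
from .readio import ReadSet

logger = logging.getLogger("decent.pipeline")

__all__ = ["RunReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial_report: dict):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.partial_report = partial_report


@dataclass
class RunReport:
    version: str
    seed: int
    parameters: dict
    contamination: float | None = None
    log_posterior: float | None = None
    threshold: float | None = None
    retain_all: bool = False
    n_reads_in: int = 0
    n_reads_retained: int = 0
    sufficiency: dict = field(default_factory=dict)
    karyotype: str | None = None
    event_labels: list = field(default_factory=list)
    sex: str | None = None
    stages_completed: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_pipeline(
    readset: ReadSet,
    classifier: ReadOriginClassifier,
    bin_grid: pd.DataFrame,
    reference_profile: pd.DataFrame,
    policy: ThresholdPolicy = ThresholdPolicy(),
    cytobands: pd.DataFrame | None = None,
    reference_sex: str = "XY",
    lowess_span: float = 0.3,
    seg_alpha: float = 0.01,
    seg_min_bins: int = 3,
    seed: int = 0,
) -> tuple[RunReport, pd.DataFrame, list]:
    """Run score -> estimate -> threshold -> sufficiency -> filter -> CNV.

    Returns ``(report, per-bin profile, segments)``.  Any stage failure
    raises :class:`PipelineError` carrying the stage name and the partial
    report.  Deterministic given the inputs and seed.
    """
    params = {
        "policy": dataclasses.asdict(policy),
        "reference_sex": reference_sex,
        "lowess_span": lowess_span,
        "seg_alpha": seg_alpha,
        "seg_min_bins": seg_min_bins,
        "classifier": classifier.get_params(),
    }
    report = RunReport(version=__version__, seed=seed, parameters=params, n_reads_in=len(readset))
    stage = "score_reads"
    try:
        logger.info("scoring %d reads", len(readset))
        scores = classifier.score_reads(readset)

        stage = "map_estimate"
        est = map_estimate(scores)
        report.contamination = est.r_star
        report.log_posterior = est.log_posterior
        logger.info("estimated contamination %.3f", est.r_star)

        stage = "choose_threshold"
        thr = choose_threshold(est.r_star, policy)
        report.threshold = None if thr is RETAIN_ALL else float(thr)
        report.retain_all = thr is RETAIN_ALL

        stage = "sufficiency_check"
        report.sufficiency = sufficiency_check(len(readset), est.r_star)

        stage = "filter_reads"
        retained = filter_reads(readset, scores, thr)
        report.n_reads_retained = len(retained)
        logger.info("retained %d / %d reads", len(retained), len(readset))

        stage = "cnv_reconstruction"
        profile = count_in_bins(retained, bin_grid)
        profile = gc_correct(profile, span=lowess_span)
        profile = normalize_to_reference(profile, reference_profile, reference_sex=reference_sex)
        segments = segment(profile, alpha=seg_alpha, min_bins=seg_min_bins)
        calls = call_and_classify(segments, profile, cytobands=cytobands)
        report.karyotype = calls["karyotype"]
        report.event_labels = calls["event_labels"]
        report.sex = calls["sex"]
        report.stages_completed = [
            "score_reads",
            "map_estimate",
            "choose_threshold",
            "sufficiency_check",
            "filter_reads",
            "cnv_reconstruction",
        ]
        return report, profile, segments
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - every stage failure is reported
        raise PipelineError(stage, exc, report.to_dict()) from exc


def build_reference_profile(
    reference_reads: ReadSet,
    bin_grid: pd.DataFrame,
    classifier: ReadOriginClassifier | None = None,
    threshold: float | None = 0.15,
    lowess_span: float = 0.3,
) -> pd.DataFrame:
    """GC-corrected bin profile of a diploid reference read pool.

    When a classifier and threshold are given the reference is filtered
    the same way as the samples so both sides see the same retention bias.
    """
    reads = reference_reads
    if classifier is not None and threshold is not None:
        scores = classifier.score_reads(reads)
        reads = filter_reads(reads, scores, threshold)
    profile = count_in_bins(reads, bin_grid)
    return gc_correct(profile, span=lowess_span)
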