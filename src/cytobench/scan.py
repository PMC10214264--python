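"""Parallel scanning of the workflow space.

Each workflow is evaluated end-to-end (preprocess -> criteria) as an
independent task with a seed derived deterministically from the base seed
and the workflow string, so the ranked result is invariant to the worker
count and task scheduling.  Failures are isolated per workflow and recorded
without aborting the scan.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml
from joblib import Parallel, delayed

from .csi import KnownMarkerSet, evaluate_csi, read_known_markers
from .errors import ArgumentError, CytobenchError
from .fcs import MergedData, StudyKind, merge_samples, read_fcs, read_metadata, select_markers
from .pipeline import WorkflowResources, run_workflow
from .pti import PathwayHierarchy, evaluate_pti, read_pathway_hierarchy
from .ranking import CategoryCutoffs, RankedTable, WorkflowReport, apply_categories, rank_workflows
from .registry import WorkflowSpec, format_workflow, parse_workflow
from .space import enumerate_workflows, validate_workflow

__all__ = ["RunConfig", "workflow_seed", "evaluate_workflow", "scan", "load_data"]

log = logging.getLogger(__name__)


def workflow_seed(base_seed: int, workflow: str) -> int:
    """Stable per-workflow seed below 2**31, independent of scheduling."""
    digest = hashlib.sha256(f"{base_seed}:{workflow}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one scan needs; loadable from YAML."""

    study_kind: StudyKind = StudyKind.CSI
    input_dir: str = "."
    metadata_path: str = "metadata.csv"
    markers: list[str] | None = None
    workflows: list[str] | None = None  # None = full space for the technique
    per_file_n: int = 500
    downsample_strategy: str = "uniform_random"
    seed: int = 0
    workers: int = 1
    reps: int = 5
    k: int | None = None
    known_markers_path: str | None = None
    hierarchy_path: str | None = None
    spillover_path: str | None = None
    cutoffs: CategoryCutoffs = field(default_factory=CategoryCutoffs)
    output_dir: str = "results"
    method_params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ArgumentError("workers must be >= 1")
        self.study_kind = StudyKind(self.study_kind)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cutoffs = CategoryCutoffs()
        if "cutoffs_path" in raw:
            cutoffs = CategoryCutoffs.from_yaml(raw.pop("cutoffs_path"))
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        cfg = {k: v for k, v in raw.items() if k in known}
        return cls(cutoffs=cutoffs, **cfg)


def load_data(config: RunConfig) -> tuple[MergedData, KnownMarkerSet | None, PathwayHierarchy | None]:
    """Read FCS files + metadata per the config and build the merged matrix."""
    annotation = read_metadata(config.metadata_path, config.study_kind)
    frames = [
        read_fcs(os.path.join(config.input_dir, f"{name}.fcs"))
        for name in annotation.filenames
    ]
    merged = merge_samples(
        frames, annotation, per_file_n=config.per_file_n,
        strategy=config.downsample_strategy, seed=config.seed,
    )
    if config.markers:
        merged = select_markers(merged, config.markers)
    known = read_known_markers(config.known_markers_path) if config.known_markers_path else None
    hierarchy = read_pathway_hierarchy(config.hierarchy_path) if config.hierarchy_path else None
    return merged, known, hierarchy


def evaluate_workflow(
    data: MergedData,
    spec: WorkflowSpec,
    study_kind: StudyKind,
    seed: int,
    reps: int = 5,
    k: int | None = None,
    resources: WorkflowResources | None = None,
    known: KnownMarkerSet | None = None,
    hierarchy: PathwayHierarchy | None = None,
) -> WorkflowReport:
    """Preprocess with ``spec`` and score all applicable criteria.

    Errors become a report with ``error`` set instead of propagating, so a
    single numerically fragile method cannot invalidate a scan.
    """
    try:
        processed = run_workflow(data, spec, resources=resources)
        if study_kind == StudyKind.CSI:
            results = evaluate_csi(
                processed, data.annotation, k=k, seed=seed, reps=reps, known=known
            )
        else:
            results = evaluate_pti(
                processed, data.annotation, seed=seed, reps=reps, hierarchy=hierarchy
            )
        return WorkflowReport(spec=spec, results=results)
    except CytobenchError as exc:
        return WorkflowReport(spec=spec, results=[], error=str(exc))


def scan(
    config: RunConfig,
    data: MergedData | None = None,
    known: KnownMarkerSet | None = None,
    hierarchy: PathwayHierarchy | None = None,
    resources: WorkflowResources | None = None,
    progress: bool = False,
) -> tuple[RankedTable, list[WorkflowReport]]:
    """Evaluate the selected workflows and rank the successful ones.

    Returns ``(ranked_table, failed_reports)``.  Identical configs give
    bit-identical tables regardless of ``workers``.
    """
    if data is None:
        data, file_known, file_hier = load_data(config)
        known = known or file_known
        hierarchy = hierarchy or file_hier
    technique = data.technique

    if config.workflows is None:
        specs = enumerate_workflows(technique).specs
    else:
        specs = [parse_workflow(w) for w in config.workflows]
    valid, skipped = [], []
    for s in specs:
        ok, reasons = validate_workflow(s, technique)
        if ok:
            valid.append(s)
        else:
            skipped.append(WorkflowReport(spec=s, results=[], error="; ".join(reasons)))
    if not valid:
        raise ArgumentError(f"no valid workflows for technique {technique.value}")

    if resources is None:
        resources = WorkflowResources(params=config.method_params)
        if config.spillover_path:
            from .compensate import read_spillover_csv

            resources.spillover = read_spillover_csv(config.spillover_path)

    def _task(spec: WorkflowSpec) -> WorkflowReport:
        wf_seed = workflow_seed(config.seed, format_workflow(spec))
        return evaluate_workflow(
            data, spec, config.study_kind, seed=wf_seed, reps=config.reps,
            k=config.k, resources=resources, known=known, hierarchy=hierarchy,
        )

    if config.workers == 1:
        iterator = valid
        if progress:
            from tqdm import tqdm

            iterator = tqdm(valid, desc="workflows", unit="wf")
        reports = [_task(s) for s in iterator]
    else:
        reports = Parallel(n_jobs=config.workers, verbose=10 if progress else 0)(
            delayed(_task)(s) for s in valid
        )

    succeeded = [r for r in reports if r.error is None and r.results]
    failed = skipped + [r for r in reports if r.error is not None]
    for r in failed:
        log.warning("workflow %s failed: %s", r.workflow, r.error)
    if not succeeded:
        details = "; ".join(f"{r.workflow}: {r.error}" for r in failed[:10])
        raise CytobenchError(f"all workflows failed ({details})")

    cutoffs = config.cutoffs
    if cutoffs.mode == "quantile":
        by_crit: dict[str, list[float]] = {}
        for rep in succeeded:
            for res in rep.results:
                by_crit.setdefault(res.criterion, []).append(res.value)
        cutoffs.fit_quantiles(config.study_kind.value, by_crit)
    for rep in succeeded:
        apply_categories(rep.results, cutoffs, config.study_kind)
    table = rank_workflows(succeeded)
    return table, failed


def report_to_dict(report: WorkflowReport) -> dict:
    return {
        "workflow": report.workflow,
        "error": report.error,
        "results": [
            {"criterion": r.criterion, "value": r.value, "category": r.category}
            for r in report.results
        ],
        "category_score": report.category_score,
        "metric_sum": report.metric_sum,
    }


def write_report_json(report: WorkflowReport, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=1)
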