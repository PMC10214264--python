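"""Workflow execution: compensation -> transformation -> normalization -> signal clean."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compensate import SpilloverMatrix, apply_compensation
from .errors import CytobenchError
from .fcs import ExpressionFrame, MergedData
from .normalize import apply_normalization
from .registry import NON, WorkflowSpec, default_registry, format_workflow, lookup
from .signal_clean import apply_signal_clean
from .space import validate_workflow
from .transforms import apply_transform

__all__ = ["ProcessedData", "WorkflowResources", "run_workflow"]


@dataclass
class WorkflowResources:
    """External inputs some methods need, plus per-method parameter overrides."""

    spillover: SpilloverMatrix | None = None
    controls: dict[str, ExpressionFrame] | None = None
    params: dict[str, dict] = field(default_factory=dict)

    def params_for(self, method_id: str, registry=None) -> dict:
        try:
            base = dict(lookup(method_id, registry).params)
        except CytobenchError:
            base = {}
        base.update(self.params.get(method_id, {}))
        return base


@dataclass
class StepRecord:
    step: str
    method: str
    params: dict
    events_in: int
    events_out: int


@dataclass
class ProcessedData:
    """Output of one workflow: the processed data, the signal-clean removal
    mask (aligned to the pre-cleaning merged event order) and a 4-entry log."""

    data: MergedData
    removed_mask: np.ndarray
    log: list[StepRecord]

    @property
    def workflow(self) -> str:
        return "+".join(rec.method for rec in self.log)


def run_workflow(
    data: MergedData,
    spec: WorkflowSpec,
    resources: WorkflowResources | None = None,
    registry=None,
) -> ProcessedData:
    """Apply the four steps of ``spec`` in their fixed order.

    The all-NON workflow is the identity on values.  Any step failure is
    re-raised with the step and method attached.  Deterministic: no step
    draws random numbers.
    """
    registry = registry if registry is not None else default_registry()
    ok, reasons = validate_workflow(spec, data.technique, registry)
    if not ok:
        raise CytobenchError(
            f"workflow {format_workflow(spec)} invalid for {data.technique.value}: "
            + "; ".join(reasons)
        )
    resources = resources or WorkflowResources()
    log: list[StepRecord] = []
    current = data

    def _record(step: str, method: str, params: dict, n_in: int, n_out: int) -> None:
        log.append(StepRecord(step, method, params, n_in, n_out))

    def _run(step_name: str, method: str, fn):
        nonlocal current
        n_in = current.n_events
        params = resources.params_for(method, registry) if method != NON else {}
        try:
            result = fn(params)
        except CytobenchError as exc:
            raise type(exc)(f"[{step_name}:{method}] {exc}") from exc
        _record(step_name, method, params, n_in, result.n_events)
        current = result

    _run("compensation", spec.compensation, lambda p: apply_compensation(
        current, spec.compensation, spill=resources.spillover,
        controls=resources.controls,
        **({"autofluor_percentile": p["autofluor_percentile"]} if "autofluor_percentile" in p else {}),
    ))
    _run("transformation", spec.transformation, lambda p: current.copy(
        values=apply_transform(current.values, spec.transformation, current.technique, p)
    ))
    _run("normalization", spec.normalization, lambda p: apply_normalization(
        current, spec.normalization, p
    ))

    n_before = current.n_events
    params = resources.params_for(spec.signal_clean, registry) if spec.signal_clean != NON else {}
    try:
        cleaned, mask = apply_signal_clean(current, spec.signal_clean, params)
    except CytobenchError as exc:
        raise type(exc)(f"[signal_clean:{spec.signal_clean}] {exc}") from exc
    _record("signal_clean", spec.signal_clean, params, n_before, cleaned.n_events)
    return ProcessedData(data=cleaned, removed_mask=mask, log=log)
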