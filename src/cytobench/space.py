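"""Enumeration of the full preprocessing-workflow space.

Per technique, each step offers its applicable methods plus the no-op, and
the space is the Cartesian product over the four steps: 720 workflows for
flow cytometry (4 x 15 x 4 x 3), 540 for mass cytometry (3 x 15 x 3 x 4)
and 135 usable on both (1 x 15 x 3 x 3), i.e. 1125 distinct workflows in
the union.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

from .errors import ArgumentError
from .fcs import Technique
from .registry import (
    NON,
    Applicability,
    MethodDescriptor,
    STEP_ORDER,
    Step,
    WorkflowSpec,
    default_registry,
    format_workflow,
)

__all__ = ["WorkflowSpace", "enumerate_workflows", "validate_workflow"]

_EXPECTED_COMPOSITION = {
    Step.COMPENSATION: 5,
    Step.TRANSFORMATION: 14,
    Step.NORMALIZATION: 3,
    Step.SIGNAL_CLEAN: 3,
}


@dataclass
class WorkflowSpace:
    technique: str  # "FC", "MC" or "both"
    specs: list[WorkflowSpec]

    def __len__(self) -> int:
        return len(self.specs)

    def strings(self) -> list[str]:
        return [format_workflow(s) for s in self.specs]


def _check_composition(registry: list[MethodDescriptor]) -> None:
    counts = Counter(m.step for m in registry)
    if dict(counts) != _EXPECTED_COMPOSITION:
        raise ArgumentError(
            f"registry composition {dict(counts)} does not match the expected "
            f"per-step tallies {_EXPECTED_COMPOSITION}"
        )
    ids = [m.id for m in registry]
    if len(set(ids)) != len(ids) or NON in ids:
        raise ArgumentError("registry ids must be unique and must not include NON")


def _options(registry, step: Step, technique: str) -> list[str]:
    if technique == "both":
        ids = [m.id for m in registry if m.step == step and m.applicability == Applicability.BOTH]
    else:
        tech = Technique(technique)
        ids = [m.id for m in registry if m.step == step and m.applicability.allows(tech)]
    return sorted(ids) + [NON]


def enumerate_workflows(
    technique: str | Technique,
    registry: list[MethodDescriptor] | None = None,
) -> WorkflowSpace:
    """All valid workflows for ``technique`` ("FC", "MC" or "both").

    The "both" space contains the workflows whose every non-NON method is
    applicable to both techniques.  Output is lexicographically ordered by
    the workflow string and free of duplicates by construction.
    """
    technique = technique.value if isinstance(technique, Technique) else str(technique)
    if technique not in ("FC", "MC", "both"):
        raise ArgumentError(f"technique must be FC, MC or both, got {technique!r}")
    registry = registry if registry is not None else default_registry()
    _check_composition(registry)
    per_step = [_options(registry, step, technique) for step in STEP_ORDER]
    specs = [WorkflowSpec(*combo) for combo in itertools.product(*per_step)]
    specs.sort(key=format_workflow)
    return WorkflowSpace(technique=technique, specs=specs)


def validate_workflow(
    spec: WorkflowSpec,
    technique: str | Technique,
    registry: list[MethodDescriptor] | None = None,
) -> tuple[bool, list[str]]:
    """True iff every non-NON method in ``spec`` applies to ``technique``.

    Returns ``(ok, reasons)`` where ``reasons`` lists each offending method.
    """
    registry = registry if registry is not None else default_registry()
    tech = Technique(technique.value if isinstance(technique, Technique) else technique)
    by_id = {m.id: m for m in registry}
    reasons: list[str] = []
    for token, step in zip(spec.as_tuple(), STEP_ORDER):
        if token == NON:
            continue
        desc = by_id.get(token)
        if desc is None:
            reasons.append(f"{token}: not in registry")
        elif desc.step != step:
            reasons.append(f"{token}: belongs to step {desc.step.value}, not {step.value}")
        elif not desc.applicability.allows(tech):
            reasons.append(f"{token}: {desc.applicability.value}, not applicable to {tech.value}")
    return (len(reasons) == 0, reasons)
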