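"""The registry of 25 preprocessing methods and the workflow grammar.

A preprocessing workflow is one choice per step in the fixed order
compensation -> transformation -> normalization -> signal clean, written as
four three-letter codes joined by "+", e.g. ``ATS+BOX+GSN+NON``.  ``NON``
is the reserved no-op in every slot.  Each real method carries an FC/MC
applicability flag because flow and mass cytometry differ in negative
values, autofluorescence and crosstalk, so not every method is meaningful
for both techniques.

Registry composition: 5 compensations (3 FC-only, 2 MC-only), 14
transformations (all both), 3 normalizations (1 FC-only, 2 both), 3 signal
cleans (1 MC-only, 2 both).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import yaml

from .errors import ArgumentError, StepMismatchError, UnknownMethodError
from .fcs import Technique

__all__ = [
    "Step",
    "Applicability",
    "MethodDescriptor",
    "WorkflowSpec",
    "NON",
    "default_registry",
    "lookup",
    "parse_workflow",
    "format_workflow",
    "registry_to_yaml",
    "registry_from_yaml",
]

NON = "NON"


class Step(str, enum.Enum):
    COMPENSATION = "compensation"
    TRANSFORMATION = "transformation"
    NORMALIZATION = "normalization"
    SIGNAL_CLEAN = "signal_clean"


STEP_ORDER: tuple[Step, ...] = (
    Step.COMPENSATION,
    Step.TRANSFORMATION,
    Step.NORMALIZATION,
    Step.SIGNAL_CLEAN,
)


class Applicability(str, enum.Enum):
    FC_ONLY = "FC_only"
    MC_ONLY = "MC_only"
    BOTH = "both"

    def allows(self, technique: Technique) -> bool:
        if self == Applicability.BOTH:
            return True
        if self == Applicability.FC_ONLY:
            return technique == Technique.FC
        return technique == Technique.MC


@dataclass(frozen=True)
class MethodDescriptor:
    id: str
    step: Step
    applicability: Applicability
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.id) == 3 and self.id.isupper()):
            raise ArgumentError(f"method id must be 3 uppercase letters, got {self.id!r}")


def default_registry() -> list[MethodDescriptor]:
    """The 25 bundled methods.

    CMP (plain spillover-keyword inversion for MC) and FDN (cross-sample
    quantile normalization for FC) round out the per-step tallies so the
    full workflow space is enumerable.
    """
    C, T, N, S = Step.COMPENSATION, Step.TRANSFORMATION, Step.NORMALIZATION, Step.SIGNAL_CLEAN
    FC, MC, BOTH = Applicability.FC_ONLY, Applicability.MC_ONLY, Applicability.BOTH
    reg = [
        # --- compensation -------------------------------------------------
        MethodDescriptor("ATS", C, FC, {}),                      # spillover refit from single stains
        MethodDescriptor("FLC", C, FC, {}),                      # direct matrix inversion
        MethodDescriptor("MTC", C, FC, {"autofluor_percentile": 1.0}),
        MethodDescriptor("CTS", C, MC, {}),                      # non-negative least squares unmix
        MethodDescriptor("CMP", C, MC, {}),                      # keyword-matrix inversion
        # --- transformation (all applicable to FC and MC) -----------------
        MethodDescriptor("ACS", T, BOTH, {"cofactor": None}),    # asinh, fixed cofactor
        MethodDescriptor("ANN", T, BOTH, {}),                    # asinh, automatic cofactor
        MethodDescriptor("ARN", T, BOTH, {"cofactor": None}),    # asinh + [0,1] rescale
        MethodDescriptor("BEP", T, BOTH, {"a": 0.5, "b": 1.0, "c": 0.5, "d": 1.0, "f": 0.0}),
        MethodDescriptor("BOX", T, BOTH, {"subsample": 1000}),   # Box-Cox, MLE lambda
        MethodDescriptor("FVS", T, BOTH, {"k": 5}),              # variance-stabilizing asinh
        MethodDescriptor("HPL", T, BOTH, {"T": None}),           # hyperlog-style signed log
        MethodDescriptor("LGT", T, BOTH, {"T": 262144.0, "W": 0.5, "M": 4.5, "A": 0.0}),
        MethodDescriptor("LIN", T, BOTH, {"lo": 0.0, "hi": 4.5}),
        MethodDescriptor("LNT", T, BOTH, {}),
        MethodDescriptor("LOG", T, BOTH, {}),
        MethodDescriptor("QUA", T, BOTH, {}),                    # rank -> standard normal
        MethodDescriptor("SCA", T, BOTH, {}),                    # z-score
        MethodDescriptor("TRU", T, BOTH, {"t": 1.0}),            # truncate below threshold
        # --- normalization -------------------------------------------------
        MethodDescriptor("GSN", N, BOTH, {"max_peaks": 2}),      # density-peak alignment
        MethodDescriptor("WPS", N, BOTH, {"n_anchors": 9}),      # decile warping
        MethodDescriptor("FDN", N, FC, {"n_anchors": 101}),      # quantile normalization
        # --- signal clean ---------------------------------------------------
        MethodDescriptor("FAI", S, BOTH, {"k": 3.0, "bins": None}),
        MethodDescriptor("FCU", S, BOTH, {"threshold": 2.0, "max_removed_fraction": 0.5, "bins": None}),
        MethodDescriptor("FCL", S, MC, {"threshold": 3.0, "min_run": 2, "bins": None}),
    ]
    return reg


def lookup(method_id: str, registry: list[MethodDescriptor] | None = None) -> MethodDescriptor:
    registry = registry if registry is not None else default_registry()
    for m in registry:
        if m.id == method_id:
            return m
    raise UnknownMethodError(f"unknown method id {method_id!r}")


@dataclass(frozen=True)
class WorkflowSpec:
    """One ordered method choice per step; ``NON`` means skip the step."""

    compensation: str = NON
    transformation: str = NON
    normalization: str = NON
    signal_clean: str = NON

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.compensation, self.transformation, self.normalization, self.signal_clean)

    def __str__(self) -> str:
        return format_workflow(self)


def parse_workflow(text: str, registry: list[MethodDescriptor] | None = None) -> WorkflowSpec:
    """Parse ``"AAA+BBB+CCC+DDD"`` into a validated :class:`WorkflowSpec`."""
    registry = registry if registry is not None else default_registry()
    tokens = [t.strip() for t in text.split("+")]
    if len(tokens) != 4:
        raise ArgumentError(
            f"workflow string must have exactly 4 '+'-separated tokens, got {text!r}"
        )
    for pos, (tok, step) in enumerate(zip(tokens, STEP_ORDER), start=1):
        if tok == NON:
            continue
        desc = None
        for m in registry:
            if m.id == tok:
                desc = m
                break
        if desc is None:
            raise UnknownMethodError(f"unknown method {tok!r} at position {pos} in {text!r}")
        if desc.step != step:
            raise StepMismatchError(
                f"method {tok!r} is a {desc.step.value} method but sits in the "
                f"{step.value} slot (position {pos}) of {text!r}"
            )
    return WorkflowSpec(*tokens)


def format_workflow(spec: WorkflowSpec) -> str:
    return "+".join(spec.as_tuple())


# ---------------------------------------------------------------------------
# YAML (de)serialization so users can override per-method parameters
# ---------------------------------------------------------------------------

def registry_to_yaml(registry: list[MethodDescriptor] | None = None) -> str:
    registry = registry if registry is not None else default_registry()
    payload = [
        {
            "id": m.id,
            "step": m.step.value,
            "applicability": m.applicability.value,
            "params": dict(m.params),
        }
        for m in registry
    ]
    return yaml.safe_dump(payload, sort_keys=False)


def registry_from_yaml(text: str) -> list[MethodDescriptor]:
    payload = yaml.safe_load(text)
    return [
        MethodDescriptor(
            id=item["id"],
            step=Step(item["step"]),
            applicability=Applicability(item["applicability"]),
            params=dict(item.get("params") or {}),
        )
        for item in payload
    ]
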