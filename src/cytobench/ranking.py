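"""Performance categorization and overall workflow ranking.

Each criterion value (already rounded to three decimals) is classified as
superior, good or poor by per-criterion cutoffs; categories carry weights
1, 0.8 and 0.1.  Workflows are ranked by the weighted category sum, with
the sum of the metric values breaking ties, and the workflow string as the
final deterministic tie-break.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .csi import CriterionResult
from .errors import ArgumentError, EvaluationError
from .fcs import StudyKind
from .registry import WorkflowSpec, format_workflow

__all__ = [
    "CATEGORY_WEIGHTS",
    "CategoryCutoffs",
    "WorkflowReport",
    "RankedTable",
    "categorize",
    "apply_categories",
    "overall_score",
    "rank_workflows",
    "export_results",
]

CATEGORY_WEIGHTS = {"superior": 1.0, "good": 0.8, "poor": 0.1}

# Fixed default cutoffs (superior_cutoff, good_cutoff) per study kind and
# criterion.  Chosen to be interval-consistent with every published category
# label available for these criteria; Cd defaults are conventional.
DEFAULT_CUTOFFS: dict[tuple[str, str], tuple[float, float]] = {
    ("CSI", "Ca"): (0.85, 0.71),
    ("CSI", "Cb"): (0.75, 0.62),
    ("CSI", "Cc"): (0.30, 0.20),
    ("CSI", "Cd"): (0.90, 0.70),
    ("PTI", "Ca"): (0.75, 0.60),
    ("PTI", "Cb"): (0.98, 0.90),
    ("PTI", "Cc"): (0.86, 0.50),
    ("PTI", "Cd"): (0.90, 0.70),
}


@dataclass
class CategoryCutoffs:
    """Superior/good cutoffs per (study_kind, criterion).

    ``mode="fixed"`` uses the stored table; ``mode="quantile"`` derives the
    cutoffs per criterion as the 90th/70th percentiles of the evaluated
    cohort's values (set via :meth:`fit_quantiles`).
    """

    table: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFFS)
    )
    mode: str = "fixed"

    def __post_init__(self) -> None:
        for key, (sup, good) in self.table.items():
            if not (0.0 <= good < sup <= 1.0):
                raise ArgumentError(f"cutoffs for {key} must satisfy 0 <= good < superior <= 1")
        if self.mode not in ("fixed", "quantile"):
            raise ArgumentError(f"cutoff mode must be fixed or quantile, got {self.mode!r}")

    def get(self, study_kind: str, criterion: str) -> tuple[float, float]:
        try:
            return self.table[(str(study_kind), criterion)]
        except KeyError:
            raise ArgumentError(f"no cutoffs for ({study_kind}, {criterion})") from None

    def fit_quantiles(self, study_kind: str, values_by_criterion: dict[str, list[float]]) -> None:
        """Set per-criterion cutoffs to the cohort's 90th/70th percentiles."""
        for crit, vals in values_by_criterion.items():
            v = np.asarray(vals, dtype=np.float64)
            sup = float(np.quantile(v, 0.90))
            good = float(np.quantile(v, 0.70))
            if good >= sup:  # degenerate cohort: collapse to a thin band
                good = max(0.0, sup - 1e-9)
            self.table[(str(study_kind), crit)] = (min(sup, 1.0), max(good, 0.0))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CategoryCutoffs":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        table = {}
        for kind, crits in raw.get("cutoffs", {}).items():
            for crit, pair in crits.items():
                table[(str(kind), str(crit))] = (float(pair[0]), float(pair[1]))
        base = dict(DEFAULT_CUTOFFS)
        base.update(table)
        return cls(table=base, mode=str(raw.get("mode", "fixed")))


def categorize(
    value: float,
    cutoffs: CategoryCutoffs,
    criterion: str,
    study_kind: str | StudyKind,
) -> str:
    """superior iff value >= superior cutoff, good iff >= good cutoff, else poor."""
    if not (0.0 <= value <= 1.0):
        raise ArgumentError(f"criterion value {value} outside [0, 1]")
    kind = study_kind.value if isinstance(study_kind, StudyKind) else str(study_kind)
    sup, good = cutoffs.get(kind, criterion)
    if value >= sup:
        return "superior"
    if value >= good:
        return "good"
    return "poor"


def apply_categories(
    results: list[CriterionResult],
    cutoffs: CategoryCutoffs,
    study_kind: str | StudyKind,
) -> list[CriterionResult]:
    for r in results:
        r.category = categorize(r.value, cutoffs, r.criterion, study_kind)
    return results


@dataclass
class WorkflowReport:
    spec: WorkflowSpec
    results: list[CriterionResult]
    category_score: float = 0.0
    metric_sum: float = 0.0
    error: str | None = None

    @property
    def workflow(self) -> str:
        return format_workflow(self.spec)

    def finalize(self) -> "WorkflowReport":
        self.category_score, self.metric_sum = overall_score(self.results)
        return self


def overall_score(results: list[CriterionResult]) -> tuple[float, float]:
    """(weighted category sum, sum of 3-decimal metric values)."""
    if not results:
        raise ArgumentError("no criterion results to score")
    missing = [r.criterion for r in results if r.category is None]
    if missing:
        raise EvaluationError(f"criteria not categorized yet: {missing}")
    category_score = sum(CATEGORY_WEIGHTS[r.category] for r in results)
    metric_sum = round(sum(round(r.value, 3) for r in results), 3)
    return category_score, metric_sum


@dataclass
class RankedTable:
    reports: list[WorkflowReport]
    weights: dict[str, float] = field(default_factory=lambda: dict(CATEGORY_WEIGHTS))

    def __len__(self) -> int:
        return len(self.reports)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, rep in enumerate(self.reports, start=1):
            row: dict = {"rank": rank, "workflow": rep.workflow}
            for r in rep.results:
                row[f"{r.criterion}_value"] = r.value
                row[f"{r.criterion}_category"] = r.category
            row["category_score"] = rep.category_score
            row["metric_sum"] = rep.metric_sum
            rows.append(row)
        return pd.DataFrame(rows)


def rank_workflows(reports: list[WorkflowReport]) -> RankedTable:
    """Total deterministic order: category score desc, metric sum desc,
    workflow string asc."""
    if not reports:
        raise ArgumentError("no workflow reports to rank")
    criteria_sets = {tuple(sorted(r.criterion for r in rep.results)) for rep in reports}
    if len(criteria_sets) > 1:
        raise ArgumentError(
            f"heterogeneous criteria sets cannot be ranked together: {sorted(criteria_sets)}"
        )
    for rep in reports:
        rep.finalize()
    ordered = sorted(
        reports,
        key=lambda rep: (-rep.category_score, -rep.metric_sum, rep.workflow),
    )
    return RankedTable(reports=ordered)


def export_results(
    table: RankedTable,
    out_dir: str | os.PathLike,
    heatmap: bool = False,
) -> list[str]:
    """Write ranking.csv + categories.csv (and optionally heatmap.png)."""
    if not table.reports:
        raise ArgumentError("cannot export an empty ranked table")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written = []

    ranking_path = os.path.join(out_dir, "ranking.csv")
    table.to_frame().to_csv(ranking_path, index=False)
    written.append(ranking_path)

    crits = [r.criterion for r in table.reports[0].results]
    cat = pd.DataFrame(
        [[r.category for r in rep.results] for rep in table.reports],
        index=[rep.workflow for rep in table.reports],
        columns=crits,
    )
    cat.index.name = "workflow"
    cat_path = os.path.join(out_dir, "categories.csv")
    cat.to_csv(cat_path)
    written.append(cat_path)

    if heatmap:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        levels = {"superior": 2, "good": 1, "poor": 0}
        M = cat.map(levels.get).to_numpy(dtype=float)
        fig, ax = plt.subplots(
            figsize=(1.5 + 0.6 * len(crits), 1.0 + 0.25 * len(table.reports))
        )
        cmap = ListedColormap(["#d62728", "#98df8a", "#2ca02c"])  # poor, good, superior
        ax.imshow(M, aspect="auto", cmap=cmap, vmin=0, vmax=2)
        ax.set_xticks(range(len(crits)), crits)
        ax.set_yticks(range(len(table.reports)), cat.index, fontsize=6)
        fig.tight_layout()
        png = os.path.join(out_dir, "heatmap.png")
        fig.savefig(png, dpi=120)
        plt.close(fig)
        written.append(png)
    return written
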