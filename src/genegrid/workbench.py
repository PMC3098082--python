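"""Procedure-grid enumeration, execution, ranking and reporting.

The grid crosses feature-selection statistic x expression pattern x
discretization x feature-vector addition x classifier, with the constraint
that feature-vector addition only combines with up- or down-regulated
selection.  With all defaults and a single k this yields exactly 60
procedures: 12 with the total pattern (3 x 2 x 2, no FVA) and 24 each for
up and down (3 x 2 x 2 x 2).  Each procedure is scored by the .632+
bootstrap; the best procedures are those with the smallest error, and the
smallest k among those, all ties reported.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from . import __version__
from .dataio import ExpressionDataset
from .evaluation import (
    BootstrapPlan,
    ProcedureResult,
    derive_seed,
    evaluate_procedure,
)
from .procedures import ProcedureSpec

__all__ = [
    "GridReport",
    "enumerate_procedures",
    "run_grid",
    "rank_results",
    "write_report",
]

DEFAULT_METHODS = ("ttest", "wilcoxon", "infogain")
DEFAULT_PATTERNS = ("total", "up", "down")
DEFAULT_CLASSIFIERS = ("svm", "random_forest")
DEFAULT_K_GRID = (10, 15, 20, 25, 30, 50, 70, 100, 200)


def enumerate_procedures(
    k_grid=DEFAULT_K_GRID,
    methods=DEFAULT_METHODS,
    patterns=DEFAULT_PATTERNS,
    discretize=(False, True),
    fva=(False, True),
    classifiers=DEFAULT_CLASSIFIERS,
) -> list[ProcedureSpec]:
    """All procedure specs for the chosen option subsets, in canonical order.

    Canonical order iterates k (ascending), then method, pattern,
    discretize, fva, classifier in their listed order; specs pairing
    feature-vector addition with the total pattern are never generated.
    """
    for name, vals in (
        ("k_grid", k_grid), ("methods", methods), ("patterns", patterns),
        ("discretize", discretize), ("fva", fva), ("classifiers", classifiers),
    ):
        if not tuple(vals):
            raise ValueError(f"empty option subset: {name}")
    specs: list[ProcedureSpec] = []
    for k in sorted(set(int(k) for k in k_grid)):
        for m in methods:
            for pattern in patterns:
                for disc in discretize:
                    for f in fva:
                        if f and pattern == "total":
                            continue
                        for clf in classifiers:
                            specs.append(
                                ProcedureSpec(
                                    fs_method=m,
                                    pattern=pattern,
                                    k=k,
                                    discretize=bool(disc),
                                    fva=bool(f),
                                    classifier=clf,
                                )
                            )
    return specs


@dataclasses.dataclass
class GridReport:
    """Ordered grid results plus everything needed to reproduce them."""

    results: list[ProcedureResult]
    fingerprint: dict
    plan: BootstrapPlan
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "fingerprint": self.fingerprint,
            "plan": dataclasses.asdict(self.plan),
            "results": [
                {
                    "spec": r.spec.to_dict(),
                    "estimate": None
                    if r.estimate is None
                    else dataclasses.asdict(r.estimate),
                    "genes": list(r.genes),
                    "truncated": r.truncated,
                    "status": r.status,
                    "canonical_index": r.canonical_index,
                }
                for r in self.results
            ],
        }

    def body_text(self) -> str:
        """Deterministic serialization (no timestamps) for byte comparisons."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def _result_sort_key(r: ProcedureResult):
    err = r.estimate.err632plus if r.estimate is not None else np.inf
    return (err, r.spec.k, r.canonical_index)


def _evaluate_one(i, spec, ds, plan, estimator_kwargs):
    sub_plan = BootstrapPlan(
        B=plan.B,
        master_seed=derive_seed(plan.master_seed, i),
        max_redraws=plan.max_redraws,
    )
    try:
        return evaluate_procedure(
            spec, ds, sub_plan, canonical_index=i, **estimator_kwargs
        )
    except Exception as exc:  # failures annotate the grid, never abort it
        return ProcedureResult(
            spec=spec,
            estimate=None,
            genes=(),
            truncated=False,
            status=f"failed:{exc}",
            canonical_index=i,
        )


def run_grid(
    specs: list[ProcedureSpec],
    ds: ExpressionDataset,
    plan: BootstrapPlan,
    workers: int = 1,
    estimator_kwargs: dict | None = None,
) -> GridReport:
    """Evaluate every spec; deterministic for any worker count.

    Per-procedure seeds derive from (master_seed, canonical index), so the
    report body is byte-identical whether the grid runs serially or across
    processes.
    """
    if not specs:
        raise ValueError("empty procedure list")
    estimator_kwargs = estimator_kwargs or {}
    if workers == 1:
        results = [
            _evaluate_one(i, s, ds, plan, estimator_kwargs)
            for i, s in enumerate(specs)
        ]
    else:
        results = Parallel(n_jobs=workers, backend="loky")(
            delayed(_evaluate_one)(i, s, ds, plan, estimator_kwargs)
            for i, s in enumerate(specs)
        )
    results = sorted(results, key=_result_sort_key)
    classes = ds.classes
    fingerprint = {
        "n_genes": ds.n_genes,
        "n_samples": ds.n_samples,
        "class_counts": {c: ds.labels.count(c) for c in classes},
        "positive_class": ds.positive_class,
    }
    return GridReport(results=results, fingerprint=fingerprint, plan=plan)


def rank_results(report: GridReport) -> list[ProcedureResult]:
    """Best procedures: minimal err632plus, then minimal k; all ties returned."""
    ok = [r for r in report.results if r.ok and r.estimate is not None]
    if not ok:
        raise RuntimeError("all procedures failed; nothing to rank")
    best_err = min(r.estimate.err632plus for r in ok)
    tied = [r for r in ok if r.estimate.err632plus == best_err]
    best_k = min(r.spec.k for r in tied)
    final = [r for r in tied if r.spec.k == best_k]
    return sorted(final, key=lambda r: r.canonical_index)


_GRID_COLUMNS = [
    "fs_method", "k", "pattern", "discretize", "fva", "classifier",
    "err632plus", "err_bar", "err1", "gamma", "R", "w", "status", "genes",
]


def _result_row(r: ProcedureResult) -> list[str]:
    e = r.estimate
    fmt = lambda v: "" if v is None else f"{v:.6g}"
    return [
        r.spec.fs_method,
        str(r.spec.k),
        r.spec.pattern,
        str(r.spec.discretize).lower(),
        str(r.spec.fva).lower(),
        r.spec.classifier,
        fmt(None if e is None else e.err632plus),
        fmt(None if e is None else e.err_bar),
        fmt(None if e is None else e.err1),
        fmt(None if e is None else e.gamma),
        fmt(None if e is None else e.R),
        fmt(None if e is None else e.w),
        r.status,
        ";".join(r.genes),
    ]


def write_report(report: GridReport, out_dir: str | Path) -> dict[str, Path]:
    """Write grid.tsv, best.tsv, report.json and run.log into out_dir."""
    import datetime

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def tsv(path: Path, rows: list[ProcedureResult]) -> None:
        lines = ["\t".join(_GRID_COLUMNS)]
        lines += ["\t".join(_result_row(r)) for r in rows]
        path.write_text("\n".join(lines) + "\n")

    paths["grid"] = out / "grid.tsv"
    tsv(paths["grid"], report.results)
    paths["best"] = out / "best.tsv"
    tsv(paths["best"], rank_results(report))
    paths["json"] = out / "report.json"
    paths["json"].write_text(report.body_text() + "\n")
    paths["log"] = out / "run.log"
    paths["log"].write_text(
        "\n".join(
            [
                f"timestamp: {datetime.datetime.now().isoformat()}",
                f"version: {report.version}",
                f"plan: B={report.plan.B} master_seed={report.plan.master_seed} "
                f"max_redraws={report.plan.max_redraws}",
                f"dataset: {report.fingerprint}",
                f"procedures: {len(report.results)}",
            ]
        )
        + "\n"
    )
    return paths
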