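"""Allele-call confidence via near-optimal ILP solutions.

Call stability is probed by re-solving the assignment model under a floor that
forces the objective to be at least 2%, 4%, 6% and 8% worse than the optimum
(a "pseudobootstrap" over ILP solutions, not over reads).  An allele call's
*prefix consistency* is the number of consecutive bands, starting from the
optimum, in which it remains present — alleles that vanish as soon as the
solution is perturbed score 0.  Per-gene thresholds on this score are
calibrated against labelled calls by maximising the F-beta score (beta = 0.5,
weighting precision over recall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ilp_core import AssignmentSolution, IlpModel, ModelParams, solve

DEFAULT_DELTAS = (0.02, 0.04, 0.06, 0.08)


@dataclass(frozen=True)
class SolutionBand:
    delta: float
    objective_bound: float
    present_alleles: frozenset[str]
    status: str  # 'optimal' | 'feasible' | 'infeasible'


@dataclass(frozen=True)
class LabelledCall:
    gene_id: str
    allele_id: str
    prefix_consistency: int
    is_true_positive: bool


@dataclass
class ConfidenceReport:
    """Per-gene calibration table and chosen thresholds."""

    table: pd.DataFrame  # gene, threshold, ppv, recall, f_beta, passing_proportion, is_optimal
    optimal_thresholds: dict[str, int]
    beta: float


def near_optimal_solutions(
    model: IlpModel,
    optimal: AssignmentSolution,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    params: ModelParams | None = None,
) -> list[SolutionBand]:
    """Solve the model under progressively worse objective floors.

    The floor for band ``delta`` is ``optimal.objective * (1 + delta)``; for a
    degenerate zero optimum the multiplicative scale collapses, so
    ``delta * P * n_reads`` substitutes an additive scale (one discarded read
    is roughly one penalty unit P).  Each band is solved independently to
    optimality subject to its floor; an infeasible band (the model cannot be
    made that much worse) is recorded with an empty present set.
    """
    if optimal.status not in ("optimal", "feasible"):
        raise ValueError("need an optimal base solution to band around")
    if list(deltas) != sorted(set(d for d in deltas if d > 0)):
        raise ValueError("deltas must be strictly increasing and positive")
    params = params or model.params
    n_reads = len(model.read_ids) + len(model.zero_candidate_reads)
    bands: list[SolutionBand] = []
    for delta in deltas:
        if optimal.objective > 0:
            bound = optimal.objective * (1 + delta)
        else:
            bound = delta * params.penalty * n_reads
        banded = model.with_objective_floor(bound)
        sol = solve(banded, params, allow_infeasible=True)
        bands.append(
            SolutionBand(
                delta=delta,
                objective_bound=bound,
                present_alleles=frozenset(sol.present_alleles),
                status=sol.status,
            )
        )
    return bands


def prefix_consistency(allele_id: str, optimal: AssignmentSolution,
                       bands: Sequence[SolutionBand]) -> int:
    """Count of consecutive bands (in delta order) retaining the allele.

    Counting starts after the optimal solution and stops at the first band
    from which the allele is absent; an allele present only in the optimum
    scores 0.
    """
    if allele_id not in optimal.present_alleles:
        raise ValueError(f"{allele_id} is not called in the optimal solution")
    count = 0
    for band in bands:
        if allele_id in band.present_alleles:
            count += 1
        else:
            break
    return count


def attach_prefix_consistency(calls, optimal: AssignmentSolution,
                              bands: Sequence[SolutionBand]):
    """Return calls with their prefix_consistency fields filled in."""
    from dataclasses import replace

    return [
        replace(c, prefix_consistency=prefix_consistency(c.allele_id, optimal, bands))
        for c in calls
    ]


def f_beta(ppv: float, recall: float, beta: float) -> float:
    if ppv == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * ppv * recall / (b2 * ppv + recall)


def calibrate_thresholds(
    calls_with_truth: Iterable[LabelledCall],
    beta: float = 0.5,
    n_bands: int = len(DEFAULT_DELTAS),
    recall_denominator: str = "tp_total",
    truth_counts: dict[str, int] | None = None,
) -> ConfidenceReport:
    """Per-gene PPV / passing-proportion curves and F-beta-optimal thresholds.

    For every gene and threshold t in [0, n_bands], calls with prefix
    consistency >= t pass; PPV(t) is the true-positive fraction among passing
    calls.  Recall counts passing true positives against the gene's total
    true-positive calls (``recall_denominator='tp_total'``, the default) or
    against the gene's truth-set size (``'truth'``; requires ``truth_counts``,
    a mapping gene -> number of truth alleles).  The optimal threshold
    maximises F-beta, ties resolved toward the lower threshold.
    """
    if recall_denominator not in ("tp_total", "truth"):
        raise ValueError("recall_denominator must be 'tp_total' or 'truth'")
    if recall_denominator == "truth" and truth_counts is None:
        raise ValueError("recall_denominator='truth' requires truth_counts")
    by_gene: dict[str, list[LabelledCall]] = {}
    for call in calls_with_truth:
        by_gene.setdefault(call.gene_id, []).append(call)
    rows = []
    optimal_thresholds: dict[str, int] = {}
    for gene in sorted(by_gene):
        calls = by_gene[gene]
        if recall_denominator == "truth":
            tp_total = truth_counts.get(gene, 0)
        else:
            tp_total = sum(c.is_true_positive for c in calls)
        best_t, best_f = None, -1.0
        gene_rows = []
        for t in range(n_bands + 1):
            passing = [c for c in calls if c.prefix_consistency >= t]
            if not passing:
                continue  # PPV undefined at this threshold
            tp_pass = sum(c.is_true_positive for c in passing)
            ppv = tp_pass / len(passing)
            recall = tp_pass / tp_total if tp_total else 0.0
            f = f_beta(ppv, recall, beta)
            gene_rows.append(
                {
                    "gene": gene,
                    "threshold": t,
                    "ppv": ppv,
                    "recall": recall,
                    "f_beta": f,
                    "passing_proportion": len(passing) / len(calls),
                }
            )
            if f > best_f + 1e-12:
                best_f, best_t = f, t
        for row in gene_rows:
            row["is_optimal"] = row["threshold"] == best_t
        rows.extend(gene_rows)
        if best_t is not None:
            optimal_thresholds[gene] = best_t
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "threshold", "ppv", "recall", "f_beta",
            "passing_proportion", "is_optimal",
        ],
    )
    return ConfidenceReport(table=table, optimal_thresholds=optimal_thresholds, beta=beta)


def write_confidence_tsv(report: ConfidenceReport, path: str | Path,
                         header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        report.table.to_csv(fh, sep="\t", index=False)
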