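"""ILP read assignment and allele calling with depth-consistency constraints.

The model assigns every recruited read to exactly one allele (or discards it at
a fixed penalty), minimising total edit distance, subject to each chosen allele
carrying a copy number c whose expected coverage window contains the observed
read depth at every landmark group:

    min   sum_{r,a} e_{r,a} x_{r,a}  +  P * sum_r d_r
    s.t.  sum_a x_{r,a} + d_r = 1                       for every read r
          x_{r,a} <= z_a ;  z_a <= c_a <= C_max * z_a
          z_a <= sum_r x_{r,a}                          (no empty calls)
          c_a (mu - s*sigma) <= cov_{a,g} <= c_a (mu + s*sigma)
                                                        for every allele a, group g

where cov_{a,g} is the mean, over the group's landmarks, of the number of
assigned reads covering each landmark, and mu/sigma are the *per-copy* depth
mean/SD derived from the genome-wide depth profile.  Discarding is a last
resort: P defaults to 2*max_distance + 1, strictly worse than accepting any
single read.  A brute-force enumerator over tiny instances serves as an
independent oracle for the solver path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .allele_db import AlleleDatabase
from .candidate_mapping import CandidateAssignment, CandidateTable
from .recruitment import DepthProfile

DISCARDED = "DISCARDED"


class IlpError(RuntimeError):
    pass


class InfeasibleModelError(IlpError):
    pass


@dataclass(frozen=True)
class ModelParams:
    """Tunable knobs of the assignment model.

    sd_scaling is the depth-window half-width in units of the per-copy SD;
    discard_penalty None resolves to 2*max_distance + 1.
    """

    n_groups: int = 6
    per_group: int = 6
    sd_scaling: float = 1.5
    max_distance: int = 25
    discard_penalty: float | None = None
    copy_max: int = 4
    time_limit: float = 600.0
    mip_gap: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.per_group < 1:
            raise ValueError("n_groups and per_group must be >= 1")
        if self.sd_scaling <= 0:
            raise ValueError("sd_scaling must be > 0")
        if self.copy_max < 1:
            raise ValueError("copy_max must be >= 1")
        if self.discard_penalty is not None and self.discard_penalty <= 0:
            raise ValueError("discard_penalty must be > 0")

    @property
    def penalty(self) -> float:
        return (
            self.discard_penalty
            if self.discard_penalty is not None
            else 2 * self.max_distance + 1
        )


@dataclass
class IlpModel:
    """Assembled MILP: column order is [x (candidates) | d (reads) | z | c]."""

    candidates: list[CandidateAssignment]
    read_ids: list[str]
    allele_ids: list[str]
    zero_candidate_reads: list[str]
    obj: np.ndarray
    A: sparse.csc_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    var_ub: np.ndarray
    objective_constant: float
    mu: float
    sigma: float
    params: ModelParams

    @property
    def n_var(self) -> int:
        return len(self.obj)

    def with_objective_floor(self, bound: float) -> "IlpModel":
        """Clone the model, requiring total objective >= ``bound``."""
        row = sparse.csc_matrix(self.obj.reshape(1, -1))
        return replace(
            self,
            A=sparse.vstack([self.A, row], format="csc"),
            row_lb=np.append(self.row_lb, bound - self.objective_constant),
            row_ub=np.append(self.row_ub, np.inf),
        )


@dataclass
class AssignmentSolution:
    status: str  # 'optimal' | 'feasible' | 'infeasible'
    objective: float
    assignments: dict[str, tuple[str, int] | None]  # read -> (allele, distance) | discarded
    copy_numbers: dict[str, int]  # allele -> c >= 1

    @property
    def present_alleles(self) -> set[str]:
        return set(self.copy_numbers)

    @property
    def n_discarded(self) -> int:
        return sum(1 for v in self.assignments.values() if v is None)


@dataclass(frozen=True)
class GenotypeCall:
    gene_id: str
    allele_id: str
    copy_number: int
    n_assigned_reads: int
    mean_edit_distance: float
    prefix_consistency: int | None = None


def _group_cover_counts(
    cand: CandidateAssignment, groups: list[list[int]]
) -> dict[int, int]:
    counts: dict[int, int] = {}
    for g, _p in cand.covered_landmarks:
        counts[g] = counts.get(g, 0) + 1
    return counts


def build_model(
    table: CandidateTable,
    db: AlleleDatabase,
    depth: DepthProfile,
    params: ModelParams = ModelParams(),
) -> IlpModel:
    """Assemble the MILP from a candidate table and a depth profile."""
    read_ids = table.read_ids
    allele_ids = table.allele_ids
    for aid in allele_ids:
        if not db.landmarks.get(aid):
            raise IlpError(f"allele {aid} has no landmarks (database invariant)")
    candidates: list[CandidateAssignment] = []
    cand_by_read: dict[str, list[int]] = {}
    cand_by_allele: dict[str, list[int]] = {}
    for rid in read_ids:
        for c in table.candidates[rid]:
            j = len(candidates)
            candidates.append(c)
            cand_by_read.setdefault(rid, []).append(j)
            cand_by_allele.setdefault(c.allele_id, []).append(j)

    n_x, n_r, n_a = len(candidates), len(read_ids), len(allele_ids)
    off_d, off_z, off_c = n_x, n_x + n_r, n_x + n_r + n_a
    n_var = n_x + n_r + 2 * n_a
    P = params.penalty
    obj = np.zeros(n_var)
    obj[:n_x] = [c.edit_distance for c in candidates]
    obj[off_d:off_z] = P
    var_ub = np.ones(n_var)
    var_ub[off_c:] = params.copy_max

    mu, sigma = depth.copy_mean, depth.copy_sd
    s = params.sd_scaling
    lo_bound, hi_bound = mu - s * sigma, mu + s * sigma

    rows, cols, vals, lbs, ubs = [], [], [], [], []

    def add_row(entries: list[tuple[int, float]], lb: float, ub: float) -> None:
        r = len(lbs)
        for col, val in entries:
            rows.append(r)
            cols.append(col)
            vals.append(val)
        lbs.append(lb)
        ubs.append(ub)

    a_index = {aid: i for i, aid in enumerate(allele_ids)}
    # (i) each read assigned exactly once (or discarded)
    for i, rid in enumerate(read_ids):
        add_row([(j, 1.0) for j in cand_by_read[rid]] + [(off_d + i, 1.0)], 1.0, 1.0)
    # (ii) linking: x <= z ; z <= c <= C_max z ; z <= sum x
    for j, c in enumerate(candidates):
        add_row([(j, 1.0), (off_z + a_index[c.allele_id], -1.0)], -np.inf, 0.0)
    for aid, i in a_index.items():
        add_row([(off_z + i, 1.0), (off_c + i, -1.0)], -np.inf, 0.0)
        add_row([(off_c + i, 1.0), (off_z + i, -params.copy_max)], -np.inf, 0.0)
        add_row(
            [(off_z + i, 1.0)] + [(j, -1.0) for j in cand_by_allele[aid]],
            -np.inf, 0.0,
        )
    # (iii) depth windows per allele and landmark group
    for aid, i in a_index.items():
        groups = db.landmarks[aid]
        per_group_cols: dict[int, list[tuple[int, float]]] = {
            g: [] for g in range(len(groups))
        }
        for j in cand_by_allele[aid]:
            for g, m in _group_cover_counts(candidates[j], groups).items():
                per_group_cols[g].append((j, m / len(groups[g])))
        for g, entries in per_group_cols.items():
            add_row(entries + [(off_c + i, -hi_bound)], -np.inf, 0.0)
            if lo_bound > 0:
                add_row(entries + [(off_c + i, -lo_bound)], 0.0, np.inf)

    A = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(lbs), n_var)
    ).tocsc()
    return IlpModel(
        candidates=candidates,
        read_ids=read_ids,
        allele_ids=allele_ids,
        zero_candidate_reads=sorted(table.zero_candidate_reads),
        obj=obj,
        A=A,
        row_lb=np.array(lbs),
        row_ub=np.array(ubs),
        var_ub=var_ub,
        objective_constant=P * len(table.zero_candidate_reads),
        mu=mu,
        sigma=sigma,
        params=params,
    )


def _extract_solution(model: IlpModel, x: np.ndarray) -> AssignmentSolution:
    n_x = len(model.candidates)
    off_d = n_x
    off_c = n_x + len(model.read_ids) + len(model.allele_ids)
    assignments: dict[str, tuple[str, int] | None] = {
        rid: None for rid in model.zero_candidate_reads
    }
    per_read: dict[str, tuple[float, int]] = {}
    for j, c in enumerate(model.candidates):
        if x[j] > 0.5 and (
            c.read_id not in per_read or x[j] > per_read[c.read_id][0]
        ):
            per_read[c.read_id] = (x[j], j)
    n_assigned_by_allele: dict[str, int] = {}
    for rid in model.read_ids:
        if rid in per_read:
            c = model.candidates[per_read[rid][1]]
            assignments[rid] = (c.allele_id, c.edit_distance)
            n_assigned_by_allele[c.allele_id] = (
                n_assigned_by_allele.get(c.allele_id, 0) + 1
            )
        else:
            assignments[rid] = None
    copy_numbers = {}
    for i, aid in enumerate(model.allele_ids):
        c_val = int(round(x[off_c + i]))
        if c_val >= 1 and n_assigned_by_allele.get(aid, 0) > 0:
            copy_numbers[aid] = c_val
    P = model.params.penalty
    objective = sum(
        d for v in assignments.values() if v is not None for d in [v[1]]
    ) + P * sum(1 for v in assignments.values() if v is None)
    return AssignmentSolution(
        status="optimal",
        objective=float(objective),
        assignments=assignments,
        copy_numbers=copy_numbers,
    )


def solve(
    model: IlpModel,
    params: ModelParams | None = None,
    allow_infeasible: bool = False,
) -> AssignmentSolution:
    """Solve the MILP with the HiGHS backend (deterministic, single-thread).

    Raises InfeasibleModelError on infeasibility unless ``allow_infeasible``
    (band models constrained away from the optimum can legitimately be
    infeasible; the base model never is, since all-discard always satisfies
    the constraints).
    """
    params = params or model.params
    if model.n_var == 0:
        # Nothing but zero-candidate reads: everything is discarded.
        return AssignmentSolution(
            status="optimal",
            objective=model.objective_constant,
            assignments={rid: None for rid in model.zero_candidate_reads},
            copy_numbers={},
        )
    res = milp(
        c=model.obj,
        constraints=[LinearConstraint(model.A, model.row_lb, model.row_ub)],
        integrality=np.ones(model.n_var),
        bounds=Bounds(np.zeros(model.n_var), model.var_ub),
        options={"time_limit": params.time_limit, "mip_rel_gap": params.mip_gap},
    )
    if res.status == 2 or res.x is None and res.status != 0:
        if res.status == 2 and allow_infeasible:
            return AssignmentSolution(
                status="infeasible", objective=np.inf, assignments={}, copy_numbers={}
            )
        if res.status == 2:
            raise InfeasibleModelError(
                "assignment model infeasible; consider a larger sd_scaling "
                "(depth tolerance)"
            )
        raise IlpError(f"solver failed without incumbent: {res.message}")
    sol = _extract_solution(model, res.x)
    sol.status = "optimal" if res.status == 0 else "feasible"
    return sol


def brute_force_solve(
    table: CandidateTable,
    db: AlleleDatabase,
    depth: DepthProfile,
    params: ModelParams = ModelParams(),
    objective_floor: float | None = None,
    max_reads: int = 10,
    max_combos: int = 500_000,
) -> AssignmentSolution:
    """Exhaustive-enumeration oracle for tiny instances.

    Enumerates every read assignment/discard combination, checks the depth
    windows for every copy number directly, and returns a minimum-objective
    feasible solution (ties broken toward lexicographically earlier allele
    assignments).  Guard rails reject instances too large to enumerate.
    """
    read_ids = table.read_ids
    if len(read_ids) > max_reads:
        raise IlpError(f"brute force limited to {max_reads} reads")
    options: list[list[CandidateAssignment | None]] = []
    for rid in read_ids:
        opts: list[CandidateAssignment | None] = sorted(
            table.candidates[rid], key=lambda c: c.allele_id
        )
        opts.append(None)
        options.append(opts)
    combos = int(np.prod([len(o) for o in options])) if options else 1
    if combos > max_combos:
        raise IlpError(f"instance too large to enumerate ({combos} combinations)")
    P = params.penalty
    mu, sigma, s = depth.copy_mean, depth.copy_sd, params.sd_scaling
    constant = P * len(table.zero_candidate_reads)
    best: tuple[float, dict, dict] | None = None
    for combo in itertools.product(*options):
        objective = constant
        by_allele: dict[str, list[CandidateAssignment]] = {}
        for choice in combo:
            if choice is None:
                objective += P
            else:
                objective += choice.edit_distance
                by_allele.setdefault(choice.allele_id, []).append(choice)
        if best is not None and objective >= best[0]:
            continue
        if objective_floor is not None and objective < objective_floor:
            continue
        copy_numbers: dict[str, int] = {}
        feasible = True
        for aid, cands in by_allele.items():
            groups = db.landmarks[aid]
            covs = []
            for g, group in enumerate(groups):
                n_cover = sum(
                    _group_cover_counts(c, groups).get(g, 0) for c in cands
                )
                covs.append(n_cover / len(group))
            ok_c = [
                c
                for c in range(1, params.copy_max + 1)
                if all(
                    c * (mu - s * sigma) <= cov <= c * (mu + s * sigma)
                    for cov in covs
                )
            ]
            if not ok_c:
                feasible = False
                break
            copy_numbers[aid] = ok_c[0]
        if not feasible:
            continue
        assignments: dict[str, tuple[str, int] | None] = {
            rid: None for rid in table.zero_candidate_reads
        }
        for rid, choice in zip(read_ids, combo):
            assignments[rid] = (
                None if choice is None else (choice.allele_id, choice.edit_distance)
            )
        best = (objective, assignments, copy_numbers)
    if best is None:
        return AssignmentSolution(
            status="infeasible", objective=np.inf, assignments={}, copy_numbers={}
        )
    return AssignmentSolution(
        status="optimal",
        objective=float(best[0]),
        assignments=best[1],
        copy_numbers=best[2],
    )


def calls_from_solution(
    solution: AssignmentSolution, db: AlleleDatabase
) -> list[GenotypeCall]:
    """One genotype call per present allele, sorted by (gene, allele)."""
    if solution.status == "infeasible":
        raise IlpError("cannot derive calls from an infeasible solution")
    stats: dict[str, list[int]] = {}
    for v in solution.assignments.values():
        if v is not None:
            stats.setdefault(v[0], []).append(v[1])
    calls = [
        GenotypeCall(
            gene_id=db[aid].gene_id,
            allele_id=aid,
            copy_number=cn,
            n_assigned_reads=len(stats.get(aid, [])),
            mean_edit_distance=float(np.mean(stats[aid])) if aid in stats else 0.0,
        )
        for aid, cn in solution.copy_numbers.items()
    ]
    return sorted(calls, key=lambda c: (c.gene_id, c.allele_id))


def write_calls_tsv(
    calls: Sequence[GenotypeCall],
    path: str | Path,
    sample_id: str = "sample",
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "sample\tgene\tallele\tcopy_number\tn_reads\tmean_edit\tprefix_consistency\n"
        )
        for c in calls:
            pc = "" if c.prefix_consistency is None else c.prefix_consistency
            fh.write(
                f"{sample_id}\t{c.gene_id}\t{c.allele_id}\t{c.copy_number}"
                f"\t{c.n_assigned_reads}\t{c.mean_edit_distance:.3f}\t{pc}\n"
            )


def write_assignments_tsv(
    solution: AssignmentSolution, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("read_id\tallele_id\tedit_distance\n")
        for rid in sorted(solution.assignments):
            v = solution.assignments[rid]
            if v is None:
                fh.write(f"{rid}\t{DISCARDED}\t\n")
            else:
                fh.write(f"{rid}\t{v[0]}\t{v[1]}\n")
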