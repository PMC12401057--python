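import numpy as np
import pytest

import vgenotyper as vg
from vgenotyper.confidence import (
    LabelledCall,
    SolutionBand,
    calibrate_thresholds,
    f_beta,
    near_optimal_solutions,
    prefix_consistency,
)
from vgenotyper.ilp_core import ModelParams, brute_force_solve, build_model, solve
from vgenotyper.recruitment import DepthProfile


def profile(mu, sd):
    return DepthProfile(mean_depth=mu, sd_depth=sd, n_positions_sampled=10, ploidy=1)


@pytest.fixture
def two_allele_instance(db_factory, table_factory):
    """Two alleles of one gene; every read at distance 1 to A, 2 to B.

    The optimum assigns everything to A.  The depth windows forbid splitting
    reads between the alleles, so the cheapest way to satisfy a 2% objective
    floor is to move everything to B: A vanishes from the first band.
    """
    db = db_factory({"GENEX*01": "A" * 300, "GENEX*02": "C" * 300}, pad_len=10)
    rows = []
    for i in range(20):
        rows += [(f"r{i:02d}", "GENEX*01", 1, None), (f"r{i:02d}", "GENEX*02", 2, None)]
    table = table_factory(db, rows)
    params = ModelParams()
    model = build_model(table, db, profile(20, 4), params)
    optimal = solve(model, params)
    return db, table, model, optimal, params


class TestNearOptimalBands:
    def test_unstable_allele_absent_from_first_band(self, two_allele_instance):
        _, _, model, optimal, params = two_allele_instance
        assert optimal.copy_numbers == {"GENEX*01": 1}
        assert optimal.objective == 20
        bands = near_optimal_solutions(model, optimal, params=params)
        assert bands[0].status != "infeasible"
        assert "GENEX*01" not in bands[0].present_alleles
        assert "GENEX*02" in bands[0].present_alleles
        assert prefix_consistency("GENEX*01", optimal, bands) == 0

    def test_band_solutions_match_brute_force_band_oracle(self, two_allele_instance):
        db, table, model, optimal, params = two_allele_instance
        # Shrink to a brute-force-enumerable copy of the same structure.
        small_rows = {rid: cands for rid, cands in list(table.candidates.items())[:6]}
        from vgenotyper.candidate_mapping import CandidateTable

        small = CandidateTable(small_rows, set(), 150)
        sparams = ModelParams(sd_scaling=1.0)
        sdepth = profile(6, 1)
        smodel = build_model(small, db, sdepth, sparams)
        sopt = solve(smodel, sparams)
        bands = near_optimal_solutions(smodel, sopt, deltas=[0.02], params=sparams)
        bound = sopt.objective * 1.02
        bf = brute_force_solve(small, db, sdepth, sparams, objective_floor=bound)
        assert bands[0].status == "infeasible" or bf.status == "optimal"
        if bands[0].status != "infeasible":
            banded = smodel.with_objective_floor(bound)
            assert solve(banded, sparams).objective == pytest.approx(bf.objective)

    def test_bands_ordered_by_increasing_bound(self, two_allele_instance):
        _, _, model, optimal, params = two_allele_instance
        bands = near_optimal_solutions(model, optimal, params=params)
        bounds = [b.objective_bound for b in bands]
        assert bounds == sorted(bounds)
        assert [b.delta for b in bands] == [0.02, 0.04, 0.06, 0.08]

    def test_degenerate_zero_objective_uses_additive_scale(
        self, db_factory, table_factory
    ):
        db = db_factory({"G*01": "A" * 300}, pad_len=10)
        rows = [(f"r{i}", "G*01", 0, None) for i in range(20)]
        table = table_factory(db, rows)
        params = ModelParams()
        model = build_model(table, db, profile(20, 4), params)
        optimal = solve(model, params)
        assert optimal.objective == 0
        bands = near_optimal_solutions(model, optimal, deltas=[0.02], params=params)
        assert bands[0].objective_bound == pytest.approx(0.02 * params.penalty * 20)

    def test_unordered_deltas_rejected(self, two_allele_instance):
        _, _, model, optimal, params = two_allele_instance
        with pytest.raises(ValueError):
            near_optimal_solutions(model, optimal, deltas=[0.04, 0.02], params=params)


class TestPrefixConsistency:
    def _bands(self, present_flags):
        return [
            SolutionBand(
                delta=0.02 * (i + 1),
                objective_bound=100.0 * (i + 1),
                present_alleles=frozenset({"A*01"} if flag else set()),
                status="optimal",
            )
            for i, flag in enumerate(present_flags)
        ]

    def _optimal(self):
        from vgenotyper.ilp_core import AssignmentSolution

        return AssignmentSolution(
            status="optimal", objective=10.0,
            assignments={"r": ("A*01", 1)}, copy_numbers={"A*01": 1},
        )

    def test_first_absence_terminates_count(self):
        # present in 2% and 4%, absent at 6%, present again at 8% -> 2
        assert prefix_consistency(
            "A*01", self._optimal(), self._bands([True, True, False, True])
        ) == 2

    def test_saturation_and_zero(self):
        assert prefix_consistency(
            "A*01", self._optimal(), self._bands([True] * 4)
        ) == 4
        assert prefix_consistency(
            "A*01", self._optimal(), self._bands([False, True, True, True])
        ) == 0

    def test_allele_not_in_optimum_is_an_error(self):
        with pytest.raises(ValueError):
            prefix_consistency("B*01", self._optimal(), self._bands([True]))

    def test_stable_single_allele_saturates(self, db_factory, table_factory):
        db = db_factory({"G*01": "A" * 300}, pad_len=10)
        rows = [(f"r{i}", "G*01", 1, None) for i in range(20)]
        table = table_factory(db, rows)
        params = ModelParams()
        model = build_model(table, db, profile(20, 4), params)
        optimal = solve(model, params)
        bands = near_optimal_solutions(model, optimal, params=params)
        # The only way to get worse is discarding reads; the allele persists.
        assert prefix_consistency("G*01", optimal, bands) == 4


class TestCalibration:
    def test_all_true_positives_saturated(self):
        calls = [LabelledCall("g", f"g*{i:02d}", 4, True) for i in range(5)]
        report = calibrate_thresholds(calls)
        tab = report.table
        assert (tab.ppv == 1.0).all()
        assert (tab.passing_proportion == 1.0).all()
        assert report.optimal_thresholds == {"g": 0}

    def test_fbeta_equals_ppv_when_ppv_equals_recall(self):
        for beta in (0.5, 1.0, 2.0):
            assert f_beta(0.7, 0.7, beta) == pytest.approx(0.7)

    def test_optimal_threshold_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        calls = [
            LabelledCall("g", f"g*{i:02d}", int(rng.integers(0, 5)),
                         bool(rng.random() < 0.6))
            for i in range(10)
        ]
        report = calibrate_thresholds(calls, beta=0.5)
        # independent scan
        best_t, best_f = None, -1
        tp_total = sum(c.is_true_positive for c in calls)
        for t in range(5):
            passing = [c for c in calls if c.prefix_consistency >= t]
            if not passing:
                continue
            ppv = sum(c.is_true_positive for c in passing) / len(passing)
            rec = sum(c.is_true_positive for c in passing) / tp_total
            f = f_beta(ppv, rec, 0.5)
            if f > best_f + 1e-12:
                best_f, best_t = f, t
        assert report.optimal_thresholds["g"] == best_t

    def test_tiny_beta_converges_to_ppv_maximisation(self):
        calls = (
            [LabelledCall("g", f"a{i}", 4, True) for i in range(3)]
            + [LabelledCall("g", f"b{i}", 0, False) for i in range(3)]
        )
        report = calibrate_thresholds(calls, beta=1e-6)
        tab = report.table
        best_ppv_t = tab.loc[tab.ppv.idxmax(), "threshold"]
        assert report.optimal_thresholds["g"] == best_ppv_t

    def test_passing_proportion_is_one_at_threshold_zero_and_monotone(self):
        rng = np.random.default_rng(3)
        calls = [
            LabelledCall("g", f"g*{i}", int(rng.integers(0, 5)), True)
            for i in range(12)
        ]
        tab = calibrate_thresholds(calls).table
        assert tab.loc[tab.threshold == 0, "passing_proportion"].iloc[0] == 1.0
        assert (tab.passing_proportion.diff().dropna() <= 1e-12).all()

    def test_truth_denominator_switch(self):
        calls = [LabelledCall("g", "g*01", 4, True)]
        report = calibrate_thresholds(
            calls, recall_denominator="truth", truth_counts={"g": 2}
        )
        assert report.table.recall.iloc[0] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            calibrate_thresholds(calls, recall_denominator="truth")
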