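import itertools
import json

import numpy as np
import pytest

from genegrid.evaluation import BootstrapPlan
from genegrid.procedures import ProcedureSpec
from genegrid.workbench import (
    enumerate_procedures,
    rank_results,
    run_grid,
    write_report,
)


class TestEnumeration:
    def test_default_grid_has_sixty_procedures(self):
        specs = enumerate_procedures(k_grid=[10])
        assert len(specs) == 60
        assert sum(1 for s in specs if s.pattern == "total") == 12
        assert sum(1 for s in specs if s.pattern in ("up", "down")) == 48

    def test_total_only_grid_has_twelve(self):
        assert len(enumerate_procedures(k_grid=[10], patterns=("total",))) == 12

    def test_grid_scales_linearly_in_k(self):
        assert len(enumerate_procedures(k_grid=[10, 15, 20, 25, 30])) == 300

    def test_fva_never_paired_with_total_pattern(self):
        specs = enumerate_procedures(k_grid=[10, 20])
        assert not any(s.fva and s.pattern == "total" for s in specs)

    def test_count_formula_over_all_subset_configurations(self):
        methods = ("ttest", "wilcoxon", "infogain")
        classifiers = ("svm", "random_forest")
        patterns_all = ["total", "up", "down"]
        for r in (1, 2, 3):
            for patterns in itertools.combinations(patterns_all, r):
                for disc in [(False,), (False, True)]:
                    for fva in [(False,), (False, True)]:
                        specs = enumerate_procedures(
                            k_grid=[10], methods=methods, patterns=patterns,
                            discretize=disc, fva=fva, classifiers=classifiers,
                        )
                        m, d, f, c = len(methods), len(disc), len(fva), len(classifiers)
                        n_total = (1 if "total" in patterns else 0) * m * d * c
                        n_updown = sum(p in ("up", "down") for p in patterns) * m * d * f * c
                        assert len(specs) == n_total + n_updown

    def test_enumeration_is_deterministic_and_canonical(self):
        a = enumerate_procedures(k_grid=[20, 10])
        b = enumerate_procedures(k_grid=[10, 20])
        assert a == b  # k sorted ascending
        assert [s.k for s in a] == sorted(s.k for s in a)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enumerate_procedures(k_grid=[10], methods=())

    def test_invalid_spec_combination_rejected(self):
        with pytest.raises(ValueError):
            ProcedureSpec("ttest", "total", 10, False, True, "svm")


@pytest.fixture(scope="module")
def small_grid_run(signal_ds_module):
    ds, _ = signal_ds_module
    specs = enumerate_procedures(
        k_grid=[5, 10], methods=("ttest", "wilcoxon"), patterns=("total", "up"),
        discretize=(False,), fva=(False, True),
    )
    plan = BootstrapPlan(B=8, master_seed=21)
    report = run_grid(specs, ds, plan, workers=1, estimator_kwargs={"rf_trees": 50})
    return specs, plan, report


@pytest.fixture(scope="module")
def signal_ds_module():
    from genegrid.synthetic import SimulationConfig, generate_dataset

    return generate_dataset(
        SimulationConfig(n_genes=200, n1=15, n2=15, n_informative_up=8,
                         n_informative_down=8, effect_size=3.0, seed=17)
    )


class TestGridRun:
    def test_every_spec_gets_a_result(self, small_grid_run):
        specs, _, report = small_grid_run
        assert len(report.results) == len(specs)

    def test_results_ordered_by_error_then_k(self, small_grid_run):
        _, _, report = small_grid_run
        keys = [
            (r.estimate.err632plus if r.estimate else np.inf, r.spec.k, r.canonical_index)
            for r in report.results
        ]
        assert keys == sorted(keys)

    def test_truncated_pool_recorded_not_fatal(self, signal_ds_module):
        ds, _ = signal_ds_module
        # k = 150 exceeds the ~100-gene up pool on a 200-gene dataset
        specs = [
            ProcedureSpec("ttest", "up", 150, False, False, "svm"),
            ProcedureSpec("ttest", "total", 5, False, False, "svm"),
        ]
        report = run_grid(specs, ds, BootstrapPlan(B=4, master_seed=2))
        statuses = {r.spec.k: r.status for r in report.results}
        assert statuses[150] == "truncated-k"
        assert statuses[5] == "ok"

    def test_empty_spec_list_rejected(self, signal_ds_module):
        ds, _ = signal_ds_module
        with pytest.raises(ValueError, match="empty"):
            run_grid([], ds, BootstrapPlan(B=2, master_seed=0))

    def test_parallel_run_reproduces_serial_report_bytes(self, signal_ds_module):
        ds, _ = signal_ds_module
        specs = enumerate_procedures(
            k_grid=[5], methods=("ttest",), patterns=("total", "down"),
            discretize=(False,), fva=(False, True),
        )
        plan = BootstrapPlan(B=5, master_seed=33)
        kw = {"rf_trees": 30}
        serial = run_grid(specs, ds, plan, workers=1, estimator_kwargs=kw)
        parallel = run_grid(specs, ds, plan, workers=2, estimator_kwargs=kw)
        assert serial.body_text() == parallel.body_text()


class TestRanking:
    def _mk(self, err, k, idx):
        from genegrid.evaluation import BootstrapEstimate, ProcedureResult

        est = BootstrapEstimate(0.0, err, 0.5, 0.0, 0.632, err)
        spec = ProcedureSpec("ttest", "total", k, False, False, "svm")
        return ProcedureResult(spec, est, ("g0",), False, "ok", idx)

    def test_minimal_error_then_minimal_k_all_ties(self, small_grid_run):
        from genegrid.workbench import GridReport

        results = [
            self._mk(0.02, 10, 0), self._mk(0.02, 10, 1), self._mk(0.02, 10, 2),
            self._mk(0.02, 20, 3), self._mk(0.05, 10, 4),
        ]
        report = GridReport(results, {}, BootstrapPlan(B=1, master_seed=0))
        best = rank_results(report)
        assert [r.canonical_index for r in best] == [0, 1, 2]

    def test_single_strict_minimum(self):
        from genegrid.workbench import GridReport

        results = [self._mk(0.3, 10, 0), self._mk(0.1, 20, 1)]
        report = GridReport(results, {}, BootstrapPlan(B=1, master_seed=0))
        assert [r.canonical_index for r in rank_results(report)] == [1]

    def test_all_failed_raises(self):
        from genegrid.evaluation import ProcedureResult
        from genegrid.workbench import GridReport

        spec = ProcedureSpec("ttest", "total", 10, False, False, "svm")
        results = [ProcedureResult(spec, None, (), False, "failed:boom", 0)]
        report = GridReport(results, {}, BootstrapPlan(B=1, master_seed=0))
        with pytest.raises(RuntimeError, match="failed"):
            rank_results(report)


class TestReportFiles:
    def test_written_files_are_consistent(self, small_grid_run, tmp_path):
        specs, _, report = small_grid_run
        paths = write_report(report, tmp_path)
        grid_lines = paths["grid"].read_text().strip().splitlines()
        best_lines = paths["best"].read_text().strip().splitlines()
        assert len(grid_lines) == len(specs) + 1  # header + one row per spec
        assert set(best_lines[1:]) <= set(grid_lines[1:])
        data = json.loads(paths["json"].read_text())
        assert len(data["results"]) == len(specs)
        assert data["fingerprint"]["positive_class"] == "case"

    def test_rewriting_is_deterministic_modulo_log(self, small_grid_run, tmp_path):
        _, _, report = small_grid_run
        p1 = write_report(report, tmp_path / "a")
        p2 = write_report(report, tmp_path / "b")
        for key in ("grid", "best", "json"):
            assert p1[key].read_bytes() == p2[key].read_bytes()
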