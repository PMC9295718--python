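"""Scenario presets, condition sweeps, and the workload x frequency grid."""

import numpy as np
import pandas as pd
import pytest

from ocbdyn import (
    CONDITIONS,
    ParameterSet,
    RandomInputs,
    TimeGrid,
    cumulative_ocb,
    ocb_accumulation_grid,
    optimal_frequency,
    optimal_frequency_by_workload,
    run_condition,
    run_preset_scenario,
    simulate,
    stressor_sweep,
)
from ocbdyn.experiments import _cell_seed


class TestPresets:
    def test_condition_table(self):
        assert (CONDITIONS[1].initial_equilibrium_level,
                CONDITIONS[1].importance_challenge_appraisal) == (4.0, 0.4)
        assert (CONDITIONS[2].initial_equilibrium_level,
                CONDITIONS[2].importance_challenge_appraisal) == (4.0, 0.2)
        assert (CONDITIONS[3].initial_equilibrium_level,
                CONDITIONS[3].importance_challenge_appraisal) == (0.0, 0.4)
        assert (CONDITIONS[4].initial_equilibrium_level,
                CONDITIONS[4].importance_challenge_appraisal) == (0.0, 0.2)
        for preset in CONDITIONS.values():
            assert preset.expected_satisfaction_init == 2.0
            assert preset.importance_strain == 0.29

    def test_figure4_ocb_stays_zero(self, mean_inputs):
        traj = run_preset_scenario("figure4", mean_inputs)
        assert np.all(traj.series("ocb") == 0.0)

    def test_figure4_satisfaction_u_shape(self, mean_inputs):
        """Satisfaction dips below zero, then recovers toward equilibrium."""
        j = run_preset_scenario("figure4", mean_inputs).series("job_satisfaction")
        k = int(j.argmin())
        assert 0 < k < len(j) - 1
        assert j[k] < 0.0
        assert abs(j[-1]) < 1e-6

    def test_figure5_horizon(self, mean_inputs):
        assert len(run_preset_scenario("figure5", mean_inputs)) == 21

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            run_preset_scenario("figure12")


class TestConditionRuns:
    @pytest.mark.parametrize("s0", [0.0, 2.71, 10.0])
    @pytest.mark.parametrize("seed", [0, 9])
    def test_condition4_never_produces_ocb(self, s0, seed):
        traj = run_condition(CONDITIONS[4], s0, RandomInputs(seed=seed))
        assert traj.series("ocb").max() == 0.0

    def test_condition1_no_stressor_declines(self, mean_inputs):
        """With satisfaction above expectation and nothing to cope with,
        OCB starts positive and only declines."""
        ocb = run_condition(CONDITIONS[1], 0.0, mean_inputs).series("ocb")
        assert ocb[0] > 0
        assert np.all(np.diff(ocb) <= 0)

    def test_condition3_baseline_stressor_silent(self, mean_inputs):
        """At the baseline stressor 2.71 condition 3 never lifts
        satisfaction above its expectation, so OCB stays at zero."""
        traj = run_condition(CONDITIONS[3], 2.71, mean_inputs)
        assert traj.series("ocb").max() == 0.0

    def test_negative_s0_rejected(self):
        with pytest.raises(ValueError):
            run_condition(CONDITIONS[1], -1.0)


class TestStressorSweep:
    def test_cardinality(self, mean_inputs):
        sweep = stressor_sweep(CONDITIONS[1], list(range(1, 19)), mean_inputs)
        assert len(sweep) == 18

    def test_same_stream_per_value(self):
        """Every sweep member replays the same seed, so a repeated value
        reproduces the same trajectory."""
        inputs = RandomInputs(seed=3)
        sweep = stressor_sweep(CONDITIONS[1], [2.0, 5.0], inputs)
        again = run_condition(CONDITIONS[1], 5.0, RandomInputs(seed=3))
        assert sweep[5.0].data.equals(again.data)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stressor_sweep(CONDITIONS[1], [])


class TestAccumulationGrid:
    def test_batch_matches_scalar_run(self):
        """One grid cell equals a scalar simulation with the cell's seed."""
        w, f, rep = 6.0, 25.0, 3
        grid = ocb_accumulation_grid(CONDITIONS[1], workloads=[w],
                                     frequencies=[f], n_seeds=5, base_seed=11)
        cell = grid.replicates.query("replicate == @rep")["cumulative_ocb"].iloc[0]
        params = CONDITIONS[1].to_params(initial_stressor=0.0,
                                         new_task_workload=w,
                                         new_task_frequency=f)
        traj = simulate(params, TimeGrid(),
                        RandomInputs(seed=_cell_seed(11, w, f, rep)))
        assert cell == pytest.approx(cumulative_ocb(traj), abs=1e-12)

    def test_zero_workload_matches_no_task_run(self, mean_inputs):
        grid = ocb_accumulation_grid(CONDITIONS[1], workloads=[0.0],
                                     frequencies=[10.0], mode="mean")
        reference = cumulative_ocb(run_condition(CONDITIONS[1], 0.0, mean_inputs))
        assert grid.replicates["cumulative_ocb"].iloc[0] == pytest.approx(reference, abs=1e-12)

    def test_cells_independent_of_execution_order(self):
        """Per-cell seeds depend only on (base seed, W, f, replicate), so
        subgrids computed separately agree with the joint grid."""
        joint = ocb_accumulation_grid(CONDITIONS[1], workloads=[2.0, 7.0],
                                      frequencies=[5.0, 40.0], n_seeds=3,
                                      base_seed=4)
        solo = ocb_accumulation_grid(CONDITIONS[1], workloads=[7.0],
                                     frequencies=[40.0], n_seeds=3, base_seed=4)
        key = ["workload", "frequency", "replicate"]
        merged = joint.replicates.merge(solo.replicates, on=key, suffixes=("_j", "_s"))
        assert np.array_equal(merged["cumulative_ocb_j"], merged["cumulative_ocb_s"])

    def test_mean_mode_invariant_to_base_seed(self):
        a = ocb_accumulation_grid(CONDITIONS[1], workloads=[3.0],
                                  frequencies=[10.0], mode="mean", base_seed=1)
        b = ocb_accumulation_grid(CONDITIONS[1], workloads=[3.0],
                                  frequencies=[10.0], mode="mean", base_seed=99)
        assert a.replicates.equals(b.replicates)

    def test_condition4_grid_identically_zero(self):
        grid = ocb_accumulation_grid(CONDITIONS[4], workloads=[1.0, 5.0, 8.0],
                                     frequencies=[1.0, 50.0, 100.0], n_seeds=3)
        assert grid.replicates["cumulative_ocb"].max() == 0.0

    def test_grid_complete_and_nonnegative(self):
        grid = ocb_accumulation_grid(CONDITIONS[1], workloads=[1.0, 2.0],
                                     frequencies=[1.0, 2.0, 3.0], n_seeds=2)
        assert len(grid.replicates) == 2 * 3 * 2
        assert not grid.mean_matrix.isna().any().any()
        assert (grid.replicates["cumulative_ocb"] >= 0).all()


class TestOptimalFrequency:
    def test_argmax(self):
        assert optimal_frequency(pd.Series([0, 5, 9, 7], index=[1, 2, 3, 4])) == 3

    def test_all_zero_picks_smallest(self):
        assert optimal_frequency(pd.Series([0, 0, 0], index=[1, 2, 3])) == 1

    def test_tie_breaks_toward_smaller(self):
        assert optimal_frequency(pd.Series([4, 9, 9], index=[1, 2, 3])) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            optimal_frequency(pd.Series(dtype=float))

    def test_by_workload(self):
        grid = ocb_accumulation_grid(CONDITIONS[1], workloads=[1.0, 8.0],
                                     frequencies=[1.0, 10.0, 50.0], mode="mean")
        opt = optimal_frequency_by_workload(grid)
        assert list(opt.index) == [1.0, 8.0]
        assert set(opt) <= {1.0, 10.0, 50.0}
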