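import math

import numpy as np
import pytest

from sexratiosim import (
    CaptureLog,
    Population,
    SimulationConfig,
    Transect,
    TrapLayout,
    apply_active_capture,
    apply_passive_capture,
    build_distance_kernel,
    build_trap_layout,
    choose_active_transect,
    init_population,
    run_sampling_phase,
)


def make_population(N: int, cells, is_male) -> Population:
    cells = np.asarray(cells)
    return Population(
        N=N,
        ids=np.arange(1, cells.size + 1),
        is_male=np.asarray(is_male, dtype=bool),
        cell=cells.copy(),
    )


class TestTrapLayout:
    def test_single_transect_on_8x8_at_ten_percent_effort(self, rng):
        # effort 0.10 on an 8-row grid rounds 0.8 up to one transect of
        # length 4 carrying 2 alternating stations
        cfg = SimulationConfig(grid_resolution=8, passive_effort=0.10)
        layout = build_trap_layout(cfg, rng)
        assert len(layout.transects) == 1
        tr = layout.transects[0]
        assert tr.length == 4
        assert layout.trap_cell_mask.sum() == 2

    def test_five_transects_on_distinct_rows(self, rng):
        cfg = SimulationConfig(grid_resolution=10, passive_effort=0.50)
        layout = build_trap_layout(cfg, rng)
        assert len(layout.transects) == 5
        rows = [tr.row for tr in layout.transects]
        assert len(set(rows)) == 5
        for tr in layout.transects:
            assert tr.length == 5
            # stations on alternating cells starting at the first cell
            stations = [c for c in tr.cells if c in layout.trap_cells]
            assert stations == list(tr.cells[::2])
            assert len(stations) == math.ceil(tr.length / 2) == 3

    def test_degenerate_two_by_two_full_effort(self, rng):
        cfg = SimulationConfig(grid_resolution=2, passive_effort=1.0)
        layout = build_trap_layout(cfg, rng)
        assert len(layout.transects) == 2
        assert all(tr.length == 1 for tr in layout.transects)
        assert layout.trap_cell_mask.sum() == 2

    def test_all_cells_inside_domain(self, rng):
        for N in (5, 9, 16):
            cfg = SimulationConfig(grid_resolution=N, passive_effort=0.55)
            layout = build_trap_layout(cfg, rng)
            for tr in layout.transects:
                for r, c in tr.cells:
                    assert 1 <= r <= N and 1 <= c <= N


class TestActiveTransect:
    def test_length_is_half_the_grid(self, rng):
        cfg = SimulationConfig(grid_resolution=8)
        tr = choose_active_transect(cfg, rng)
        assert tr.length == 4
        assert len(tr.cells) == 4
        rows = {r for r, _ in tr.cells}
        assert len(rows) == 1

    def test_single_cell_on_two_by_two(self, rng):
        cfg = SimulationConfig(grid_resolution=2)
        tr = choose_active_transect(cfg, rng)
        assert tr.length == 1

    def test_daily_redraw_covers_rows_uniformly(self, rng):
        cfg = SimulationConfig(grid_resolution=10)
        n = 10_000
        rows = np.array([choose_active_transect(cfg, rng).row for _ in range(n)])
        freqs = np.bincount(rows, minlength=11)[1:] / n
        se = 3 * math.sqrt(0.1 * 0.9 / n)
        assert np.all(np.abs(freqs - 0.1) < se)
        # consecutive draws generally differ
        assert len({(r, s) for r, s in zip(rows[:50], rows[1:51])}) > 1


class TestPassiveCapture:
    def _layout_with_trap(self, N, trap_cell):
        mask = np.zeros(N * N, dtype=bool)
        mask[trap_cell] = True
        return TrapLayout(N=N, transects=(), trap_cell_mask=mask)

    def test_arrival_on_trap_cell_captures(self):
        pop = make_population(4, cells=[5], is_male=[True])
        log = CaptureLog.empty(1)
        apply_passive_capture(pop, np.array([True]), self._layout_with_trap(4, 5), log)
        assert log.passive_ids(pop) == {1}

    def test_sitting_on_trap_without_moving_is_not_captured(self):
        pop = make_population(4, cells=[5], is_male=[True])
        log = CaptureLog.empty(1)
        apply_passive_capture(pop, np.array([False]), self._layout_with_trap(4, 5), log)
        assert log.passive_ids(pop) == frozenset()

    def test_no_arrivals_leaves_log_unchanged(self):
        pop = make_population(4, cells=[0, 1], is_male=[True, False])
        log = CaptureLog.empty(2)
        apply_passive_capture(pop, np.array([True, True]), self._layout_with_trap(4, 9), log)
        assert log.passive_ids(pop) == frozenset()

    def test_capture_does_not_remove_individuals(self):
        pop = make_population(4, cells=[5, 5], is_male=[True, False])
        log = CaptureLog.empty(2)
        apply_passive_capture(pop, np.array([True, True]), self._layout_with_trap(4, 5), log)
        assert pop.size == 2 and log.passive_mask.all()


class TestActiveCapture:
    def test_certain_detection_captures_everyone_on_transect(self, rng):
        cfg = SimulationConfig(
            grid_resolution=4, male_detectability=1.0, female_detectability=1.0
        )
        tr = Transect(row=2, start_col=1, length=2)  # cells 4, 5 flat
        pop = make_population(4, cells=[4, 5, 9], is_male=[True, False, True])
        log = CaptureLog.empty(3)
        apply_active_capture(pop, tr, cfg, rng, log)
        assert log.active_ids(pop) == {1, 2}

    def test_zero_male_detectability_never_captures_males(self, rng):
        cfg = SimulationConfig(
            grid_resolution=4, male_detectability=0.0, female_detectability=1.0
        )
        tr = Transect(row=1, start_col=1, length=2)
        pop = make_population(4, cells=[0, 1], is_male=[True, False])
        log = CaptureLog.empty(2)
        for _ in range(50):
            apply_active_capture(pop, tr, cfg, rng, log)
        assert log.active_ids(pop) == {2}

    def test_detection_frequencies_match_detectabilities(self):
        # frozen occupancy, many independent trials: per-sex detection
        # frequencies within 3 Monte-Carlo standard errors of (0.1, 0.9)
        cfg = SimulationConfig(
            grid_resolution=4, male_detectability=0.1, female_detectability=0.9
        )
        tr = Transect(row=1, start_col=1, length=2)
        pop = make_population(4, cells=[0, 1], is_male=[True, False])
        rng = np.random.default_rng(11)
        n = 20_000
        caught = np.zeros(2)
        for _ in range(n):
            log = CaptureLog.empty(2)
            apply_active_capture(pop, tr, cfg, rng, log)
            caught += log.active_mask
        for i, p in enumerate((0.1, 0.9)):
            se = 3 * math.sqrt(p * (1 - p) / n)
            assert abs(caught[i] / n - p) < se


class TestSamplingPhase:
    def test_zero_days_gives_empty_log(self, rng, tiny_config):
        cfg = tiny_config.replace(sampling_days=0)
        pop = init_population(cfg, rng)
        kernel = build_distance_kernel(cfg.grid_resolution)
        layout = build_trap_layout(cfg, rng)
        log = run_sampling_phase(pop, kernel, layout, cfg, rng)
        assert not log.passive_mask.any() and not log.active_mask.any()

    def test_unique_counts_grow_and_stay_subsets(self, small_config):
        cfg = small_config
        rng = np.random.default_rng(cfg.seed)
        pop = init_population(cfg, rng)
        kernel = build_distance_kernel(cfg.grid_resolution)
        layout = build_trap_layout(cfg, rng)
        log = CaptureLog.empty(pop.size)
        from sexratiosim.sampling import apply_passive_capture as passive
        from sexratiosim.population import step_movement

        counts = []
        for _ in range(cfg.sampling_days):
            moved = step_movement(pop, kernel, cfg, rng)
            passive(pop, moved, layout, log)
            tr = choose_active_transect(cfg, rng)
            apply_active_capture(pop, tr, cfg, rng, log)
            counts.append((int(log.passive_mask.sum()), int(log.active_mask.sum())))
        arr = np.array(counts)
        assert np.all(np.diff(arr, axis=0) >= 0)  # sets never shrink
        assert arr[-1, 0] > 0 and arr[-1, 1] > 0
        # saturation: the first half of the survey adds more unique
        # captures than the second half
        half = len(arr) // 2
        assert arr[half, 0] - arr[0, 0] > arr[-1, 0] - arr[half, 0]
        assert log.passive_ids(pop) <= set(pop.ids.tolist())
        assert log.active_ids(pop) <= set(pop.ids.tolist())

    def test_passive_counts_monotone_in_effort(self):
        # larger trap effort yields at least as many unique passive
        # captures on average (Monte-Carlo over replicates)
        totals = {}
        for effort in (0.10, 0.55):
            cfg = SimulationConfig(
                grid_resolution=10, passive_effort=effort, sampling_days=50,
                burn_in_steps=20, seed=5,
            )
            caught = 0
            for rep in range(10):
                rng = np.random.default_rng(cfg.seed + rep)
                pop = init_population(cfg, rng)
                kernel = build_distance_kernel(10)
                layout = build_trap_layout(cfg, rng)
                log = run_sampling_phase(pop, kernel, layout, cfg, rng)
                caught += int(log.passive_mask.sum())
            totals[effort] = caught
        assert totals[0.55] >= totals[0.10]

    def test_passive_captures_independent_of_detectability(self):
        # detectability has no effect on the passive method by construction
        masks = []
        for det in (0.1, 1.0):
            cfg = SimulationConfig(
                grid_resolution=8, male_detectability=det, female_detectability=det,
                sampling_days=30, burn_in_steps=10, seed=9,
            )
            rng = np.random.default_rng(cfg.seed)
            pop = init_population(cfg, rng)
            kernel = build_distance_kernel(8)
            layout = build_trap_layout(cfg, rng)
            log = run_sampling_phase(pop, kernel, layout, cfg, rng)
            masks.append(log.passive_mask.copy())
        np.testing.assert_array_equal(masks[0], masks[1])
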