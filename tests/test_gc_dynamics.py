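"""Single-GC stochastic dynamics: contracts, bookkeeping, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from gcbrainbow.gc_dynamics import SimConfig, influx_founders, init_gc, run_gc, step
from gcbrainbow.metrics import clonal_dominance, records_to_frame
from gcbrainbow.staining import StainingProtocol, get_scheme


def proto(**kw):
    kw.setdefault("mode", "one_shot")
    kw.setdefault("scheme", get_scheme("tamoxifen"))
    kw.setdefault("t_start", 48.0)
    return StainingProtocol(**kw)


class TestConfig:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(dz_division_rate=-0.1)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(p_recycle=1.5)

    def test_bad_division_bounds_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(d_min=4, d_max=2)


class TestInflux:
    def test_empty_start(self):
        state = init_gc(SimConfig(), seed=0)
        assert state.n_cells == 0 and state.time == 0.0

    def test_zero_dt_is_noop(self):
        state = init_gc(SimConfig(), seed=0)
        assert influx_founders(state, SimConfig(), 0.0) == 0

    def test_no_influx_after_window(self):
        config = SimConfig()
        state = init_gc(config, seed=0)
        state.time = 5 * 24.0  # day 5 is past the 4-day influx window
        assert influx_founders(state, config, 1.0) == 0

    def test_total_founders_near_rate_times_window(self):
        """2 founders/h over 96 h gives ~192 founders (Poisson)."""
        config = SimConfig()
        totals = []
        for seed in range(20):
            state = init_gc(config, seed)
            got = 0
            while state.time < config.influx_window:
                got += influx_founders(state, config, 1.0)
                state.time += 1.0
            totals.append(got)
        mean = np.mean(totals)
        # cohort mean of Poisson(192): 4 sigma over 20 GCs
        assert abs(mean - 192) < 4 * np.sqrt(192 / 20)

    def test_founders_enter_dark_zone_with_burst(self):
        config = SimConfig()
        state = init_gc(config, seed=3)
        while state.n_cells == 0:
            influx_founders(state, config, config.dt)
        assert (state.zone == 0).all()
        assert (state.divisions_left == config.initial_division_burst).all()
        assert (state.color == 0).all()
        assert len(set(state.clone_id.tolist())) == state.n_cells


class TestStep:
    def test_division_inheritance(self):
        """A dividing cell yields two daughters with one budget less and
        identical clone, lineage and color."""
        config = SimConfig(
            dz_division_rate=1e6,  # certain division in one step
            mutation_prob_per_division=0.0,
            founder_influx_rate=0.0,
        )
        state = init_gc(config, seed=0)
        state._append(
            position=np.array([[5, 0, 0, 0]]),
            cell_id=np.array([0]), parent_id=np.array([-1]),
            clone_id=np.array([9]), lineage_id=np.array([4]),
            color=np.array([2], dtype=np.int16),
            zone=np.array([0], dtype=np.int8),
            divisions_left=np.array([2], dtype=np.int16),
            birth_time=np.zeros(1), lz_time=np.zeros(1),
            help_signal=np.zeros(1), aff=np.array([0.5]),
        )
        step(state, config)
        assert state.n_cells == 2
        assert (state.divisions_left == 1).all()
        assert (state.clone_id == 9).all()
        assert (state.lineage_id == 4).all()
        assert (state.color == 2).all()

    def test_without_mutation_clone_shares_position(self):
        config = SimConfig(mutation_prob_per_division=0.0)
        _, state = run_gc(config, None, seed=2, record_times=[48.0])
        frame = pd.DataFrame(state.position)
        frame["clone"] = state.clone_id
        for _, grp in frame.groupby("clone"):
            assert (grp.drop(columns="clone").nunique() == 1).all()

    def test_exhausted_budget_moves_to_light_zone(self):
        config = SimConfig(founder_influx_rate=0.0, dz_division_rate=0.0)
        state = init_gc(config, seed=0)
        state._append(
            position=np.zeros((1, 4), dtype=np.int64),
            cell_id=np.array([0]), parent_id=np.array([-1]),
            clone_id=np.array([0]), lineage_id=np.array([-1]),
            color=np.array([0], dtype=np.int16),
            zone=np.array([0], dtype=np.int8),
            divisions_left=np.array([0], dtype=np.int16),
            birth_time=np.zeros(1), lz_time=np.zeros(1),
            help_signal=np.zeros(1), aff=np.array([1.0]),
        )
        step(state, config)
        assert state.zone[0] == 1

    def test_selection_prefers_high_affinity(self):
        """In one LZ step, cells at the optimum are selected more often
        than low-affinity cells in the same competition context."""
        config = SimConfig(founder_influx_rate=0.0, dz_division_rate=0.0,
                           lz_selection_rate=30.0, lz_death_rate=0.0)
        state = init_gc(config, seed=8)
        n = 4000
        pos = np.zeros((n, 4), dtype=np.int64)
        pos[n // 2:, 0] = 4  # low-affinity half
        from gcbrainbow.shape_space import affinity

        state._append(
            position=pos,
            cell_id=np.arange(n), parent_id=np.full(n, -1),
            clone_id=np.zeros(n, dtype=np.int64),
            lineage_id=np.full(n, -1),
            color=np.zeros(n, dtype=np.int16),
            zone=np.ones(n, dtype=np.int8),
            divisions_left=np.zeros(n, dtype=np.int16),
            birth_time=np.zeros(n), lz_time=np.zeros(n),
            help_signal=np.zeros(n),
            aff=np.atleast_1d(affinity(state.model, pos)),
        )
        step(state, config)
        # selected cells either recycled to DZ or left as output
        high_sel = (state.help_signal[state.aff > 0.5] > 0).mean()
        low_sel = (state.help_signal[state.aff < 0.5] > 0).mean()
        assert high_sel > low_sel

    def test_conservation_identity(self):
        """N equals founders + divisions - deaths - outputs at all times."""
        config = SimConfig()
        _, state = run_gc(config, None, seed=5, record_times=[6 * 24.0])
        assert state.n_cells == (
            len(state.founder_log)
            + state.n_divisions_cumulative
            - state.n_deaths_cumulative
            - state.n_output_cumulative
        )

    def test_clone_ids_trace_to_founders(self):
        _, state = run_gc(SimConfig(), None, seed=6, record_times=[5 * 24.0])
        founders = {c for c, _ in state.founder_log}
        assert set(state.clone_id.tolist()) <= founders


class TestRunGC:
    def test_determinism_and_seed_sensitivity(self):
        config = SimConfig()
        p = proto()
        rec_a, _ = run_gc(config, p, seed=11, record_times=[96.0])
        rec_b, _ = run_gc(config, p, seed=11, record_times=[96.0])
        rec_c, _ = run_gc(config, p, seed=12, record_times=[96.0])
        assert records_to_frame(rec_a).equals(records_to_frame(rec_b))
        assert not records_to_frame(rec_a).equals(records_to_frame(rec_c))

    def test_record_time_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            run_gc(SimConfig(duration=24.0), proto(), 0, record_times=[48.0])

    def test_single_founder_is_fully_dominant(self):
        """With exactly one founder clone, clonal dominance is pinned at 1."""
        config = SimConfig(founder_influx_rate=0.0)
        state = init_gc(config, seed=0)
        influx = SimConfig(founder_influx_rate=1e4)
        n = influx_founders(state, influx, 1e-4)  # Poisson(1)
        if n == 0:  # deterministic for this seed; guard anyway
            n = influx_founders(state, influx, 1e-4)
        state.clone_id = np.zeros(state.n_cells, dtype=np.int64)
        for _ in range(2000):
            step(state, config)
        if state.n_cells:
            F, _ = clonal_dominance(
                {"clone_id": state.clone_id, "color": state.color,
                 "lineage_id": state.lineage_id}
            )
            assert F == 1.0

    def test_snapshot_n_matches_population(self):
        recs, state = run_gc(SimConfig(), proto(), seed=4,
                             record_times=[48.0, 96.0])
        assert recs[-1].t == 96.0
        assert recs[-1].n == state.n_cells
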