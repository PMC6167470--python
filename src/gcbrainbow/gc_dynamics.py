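"""Stochastic germinal-center reaction at single-cell resolution.

The GC is modeled as a well-mixed two-compartment (dark zone / light zone)
birth-death process advanced in discrete time steps ``dt``.  All events are
Bernoulli trials with rate-derived probabilities ``p = 1 - exp(-rate*dt)``:

* founder influx: new clones enter at a constant rate during an initial
  window, start in the DZ with a division burst, and carry a low-affinity
  shape-space position;
* DZ: cells with division budget divide (daughters inherit clone, lineage
  and color and independently hypermutate with a per-division probability);
  cells with exhausted budget move to the LZ;
* LZ: cells compete for T-follicular-helper help.  The selection hazard of
  a cell scales with its affinity relative to the current LZ mean (soft
  competition) and with an antigen availability factor that decays late in
  the reaction, which terminates the response.  A selected cell receives a
  help signal ``s`` and a new division budget that increases with ``s``
  (dynamic number of divisions), then recycles to the DZ or exits as an
  output cell; unselected cells die at a constant hazard and are evicted
  after a maximum LZ dwell time.

State is held in flat numpy arrays (struct-of-arrays) so one simulated GC
over three weeks runs in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from gcbrainbow._kernel import seed_kernel, step_kernel
from gcbrainbow.shape_space import (
    AffinityModel,
    affinity,
    sample_founder_positions,
)
from gcbrainbow.staining import (
    StainingProtocol,
    apply_staining,
    draw_founder_colors,
)

__all__ = ["SimConfig", "GCState", "init_gc", "influx_founders", "step", "run_gc"]

DZ, LZ = 0, 1


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one GC simulation.  All times in hours, rates per hour."""

    duration: float = 21 * 24.0
    dt: float = 0.1
    # founder influx
    founder_influx_rate: float = 2.0
    influx_window: float = 96.0
    initial_division_burst: int = 6
    # dark zone
    dz_division_rate: float = 1 / 6.0
    mutation_prob_per_division: float = 0.5
    # light zone / selection
    lz_selection_rate: float = 0.3
    lz_capacity: float = 30.0
    lz_death_rate: float = 0.15
    lz_max_dwell: float = 30.0
    p_recycle: float = 0.8
    d_min: int = 1
    d_max: int = 6
    selection_affinity_dependent: bool = True
    # antigen availability decays late in the reaction and ends the response
    antigen_decay_start: float = 156.0
    antigen_tau: float = 180.0
    # shape space
    dimension: int = 4
    gamma: float = 2.8
    founder_distance: tuple[float, float] = (5.0, 7.0)
    # bookkeeping
    track_genealogy: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        for name in (
            "founder_influx_rate", "influx_window", "dz_division_rate",
            "lz_selection_rate", "lz_death_rate", "lz_max_dwell",
            "antigen_decay_start", "antigen_tau",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lz_capacity <= 0:
            raise ValueError("lz_capacity must be > 0")
        for name in ("mutation_prob_per_division", "p_recycle"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 1 <= self.d_min <= self.d_max:
            raise ValueError("need 1 <= d_min <= d_max")

    def affinity_model(self) -> AffinityModel:
        return AffinityModel(dimension=self.dimension, width=self.gamma)

    def with_(self, **kw) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


_FIELDS = (
    "cell_id", "parent_id", "clone_id", "lineage_id", "color",
    "zone", "divisions_left", "birth_time", "lz_time", "help_signal", "aff",
)

_DTYPES = {
    "cell_id": np.int64, "parent_id": np.int64, "clone_id": np.int64,
    "lineage_id": np.int64, "color": np.int16, "zone": np.int8,
    "divisions_left": np.int16, "birth_time": np.float64,
    "lz_time": np.float64, "help_signal": np.float64, "aff": np.float64,
}


class GCState:
    """Mutable state of one simulated GC.

    Cell attributes live in fixed-capacity backing arrays; the public
    attributes (``clone_id``, ``color``, ``position``, ...) are views of
    the live prefix ``[0:n_cells]``, so reads and in-place writes by the
    staining and lineage layers work transparently.  Cell removal swaps
    tail rows into the holes (cost proportional to the number of removals,
    not the population), which keeps long simulations cheap; the live-cell
    ORDER is therefore arbitrary and nothing may depend on it.
    """

    __slots__ = (
        "time", "rng", "config", "model", "n", "_cap", "_buf", "_pos_buf",
        "next_cell_id", "next_clone_id", "next_lineage_id",
        "n_output_cumulative", "n_deaths_cumulative", "n_divisions_cumulative",
        "founder_log", "lineage_defined", "lineage_t0", "include_late_founders",
        "genealogy",
    )

    def __init__(self, config: SimConfig, rng: np.random.Generator,
                 capacity: int = 4096):
        self.time = 0.0
        self.rng = rng
        self.config = config
        self.model = config.affinity_model()
        self.n = 0
        self._cap = capacity
        self._buf = {
            name: np.zeros(capacity, dtype=_DTYPES[name]) for name in _FIELDS
        }
        self._pos_buf = np.zeros((capacity, config.dimension), dtype=np.int64)
        self.next_cell_id = 0
        self.next_clone_id = 0
        self.next_lineage_id = 0
        self.n_output_cumulative = 0
        self.n_deaths_cumulative = 0
        self.n_divisions_cumulative = 0
        self.founder_log: list[tuple[int, float]] = []
        self.lineage_defined = False
        self.lineage_t0: float | None = None
        self.include_late_founders = False
        # (cell_id, parent_id, clone_id, birth_time) for every cell ever born
        self.genealogy: list[tuple[int, int, int, float]] = []

    def __getattr__(self, name):
        if name in _FIELDS:
            return self._buf[name][: self.n]
        if name == "position":
            return self._pos_buf[: self.n]
        raise AttributeError(name)

    def __setattr__(self, name, value):
        # assignment to a cell-attribute replaces the live prefix
        if name in _FIELDS:
            self._buf[name][: self.n] = value
        elif name == "position":
            self._pos_buf[: self.n] = value
        else:
            object.__setattr__(self, name, value)

    @property
    def n_cells(self) -> int:
        return self.n

    def affinities(self) -> np.ndarray:
        """Affinity of every live cell (cached; updated on mutation)."""
        return self._buf["aff"][: self.n]

    def _grow(self, need: int) -> None:
        cap = self._cap
        while cap < need:
            cap *= 2
        for name in _FIELDS:
            new = np.zeros(cap, dtype=_DTYPES[name])
            new[: self.n] = self._buf[name][: self.n]
            self._buf[name] = new
        new_pos = np.zeros((cap, self.config.dimension), dtype=np.int64)
        new_pos[: self.n] = self._pos_buf[: self.n]
        self._pos_buf = new_pos
        self._cap = cap

    def _append(self, position: np.ndarray, **arrays) -> None:
        k = arrays["cell_id"].size
        if k == 0:
            return
        if self.n + k > self._cap:
            self._grow(self.n + k)
        sl = slice(self.n, self.n + k)
        for name in _FIELDS:
            self._buf[name][sl] = arrays[name]
        self._pos_buf[sl] = position
        self.n += k
        if self.config.track_genealogy:
            self.genealogy.extend(
                zip(
                    arrays["cell_id"].tolist(),
                    arrays["parent_id"].tolist(),
                    arrays["clone_id"].tolist(),
                    [self.time] * k,
                )
            )

    def _remove(self, idx: np.ndarray) -> None:
        """Drop the given live rows (swap-from-tail; order not preserved)."""
        k = idx.size
        if k == 0:
            return
        n_new = self.n - k
        holes = idx[idx < n_new]
        tail_hits = idx[idx >= n_new] - n_new
        mask = np.ones(k, dtype=bool)
        mask[tail_hits] = False
        movers = n_new + np.flatnonzero(mask)[: holes.size]
        if holes.size:
            for name in _FIELDS:
                buf = self._buf[name]
                buf[holes] = buf[movers]
            self._pos_buf[holes] = self._pos_buf[movers]
        self.n = n_new


def init_gc(config: SimConfig, seed: int) -> GCState:
    """Create an empty GC at t = 0 with seeded random streams.

    Two deterministic streams derive from ``seed``: a numpy Generator used
    by influx and staining, and the compiled step kernel's stream.  The
    same (config, seed) pair therefore reproduces the trajectory exactly.
    """
    seed_kernel(int(seed) % (2**32 - 1))
    return GCState(config, np.random.default_rng(seed))


def influx_founders(
    state: GCState, config: SimConfig, dt: float,
    protocol: StainingProtocol | None = None,
) -> int:
    """Add Poisson(rate*dt) founder cells while within the influx window.

    Each founder gets a fresh clone id, a low-affinity shape-space position
    and a full division burst, and starts in the DZ.  Founders arrive
    unstained except under founder staining, where each founder draws one
    color (black possible) from the full scheme at entry; under one-shot
    and decay staining a founder can only be stained by staining calls that
    happen while it is inside the GC.  Returns the number of founders
    added.
    """
    if dt <= 0 or state.time >= config.influx_window:
        return 0
    n = int(state.rng.poisson(config.founder_influx_rate * dt))
    if n == 0:
        return 0
    clone_ids = np.arange(state.next_clone_id, state.next_clone_id + n, dtype=np.int64)
    cell_ids = np.arange(state.next_cell_id, state.next_cell_id + n, dtype=np.int64)
    state.next_clone_id += n
    state.next_cell_id += n
    if state.lineage_defined and state.include_late_founders:
        lineage = np.arange(
            state.next_lineage_id, state.next_lineage_id + n, dtype=np.int64
        )
        state.next_lineage_id += n
    else:
        lineage = np.full(n, -1, dtype=np.int64)
    colors = np.zeros(n, dtype=np.int16)
    if protocol is not None and protocol.mode == "founder":
        colors = draw_founder_colors(protocol.scheme, n, state.rng)
    positions = sample_founder_positions(
        state.model, n, state.rng, config.founder_distance
    )
    state._append(
        cell_id=cell_ids,
        parent_id=np.full(n, -1, dtype=np.int64),
        clone_id=clone_ids,
        lineage_id=lineage,
        color=colors,
        position=positions,
        zone=np.zeros(n, dtype=np.int8),
        divisions_left=np.full(n, config.initial_division_burst, dtype=np.int16),
        birth_time=np.full(n, state.time),
        lz_time=np.zeros(n),
        help_signal=np.zeros(n),
        aff=np.atleast_1d(affinity(state.model, positions)),
    )
    state.founder_log.extend((int(c), state.time) for c in clone_ids)
    return n


def step(state: GCState, config: SimConfig) -> None:
    """Advance the GC by one time step ``dt`` (in place).

    All per-cell events of one step — DZ division with hypermutation,
    DZ->LZ transition, competitive LZ selection with dynamic division
    numbers, recycling, output and death — run in a compiled kernel
    directly on the state's backing arrays.
    """
    dt = config.dt
    n = state.n
    if n:
        if 2 * n + 1 > state._cap:
            state._grow(2 * n + 1)
        antigen = np.exp(
            -max(0.0, state.time - config.antigen_decay_start)
            / config.antigen_tau
        )
        remove = np.zeros(2 * n + 1, dtype=np.bool_)
        born_cell = np.empty(n, dtype=np.int64)
        born_parent = np.empty(n, dtype=np.int64)
        born_clone = np.empty(n, dtype=np.int64)
        buf = state._buf
        n_new, next_id, n_div, n_death, n_out = step_kernel(
            state._pos_buf,
            buf["cell_id"],
            buf["parent_id"],
            buf["clone_id"],
            buf["lineage_id"],
            buf["color"],
            buf["zone"],
            buf["divisions_left"],
            buf["birth_time"],
            buf["lz_time"],
            buf["help_signal"],
            buf["aff"],
            remove,
            born_cell,
            born_parent,
            born_clone,
            n,
            state.next_cell_id,
            state.time,
            dt,
            1.0 - np.exp(-config.dz_division_rate * dt),
            config.mutation_prob_per_division,
            config.lz_selection_rate,
            config.lz_capacity,
            config.lz_death_rate,
            config.lz_max_dwell,
            config.p_recycle,
            float(config.d_min),
            float(config.d_max),
            antigen,
            config.gamma**2,
            config.selection_affinity_dependent,
        )
        if config.track_genealogy and n_div:
            state.genealogy.extend(
                zip(
                    born_cell[:n_div].tolist(),
                    born_parent[:n_div].tolist(),
                    born_clone[:n_div].tolist(),
                    [state.time] * n_div,
                )
            )
        state.n = n_new
        state.next_cell_id = next_id
        state.n_divisions_cumulative += n_div
        state.n_deaths_cumulative += n_death
        state.n_output_cumulative += n_out

    state.time += dt


def _snapshot(state: GCState, gc_id: int, t: float):
    from gcbrainbow.metrics import snapshot_record

    return snapshot_record(state, gc_id=gc_id, t=t)


def run_gc(
    config: SimConfig,
    protocol: StainingProtocol | None,
    seed: int,
    record_times: Sequence[float],
    gc_id: int = 0,
    lineage_t0: float | None = None,
    include_late_founders: bool = False,
):
    """Simulate one GC and return ``(records, state)``.

    The loop interleaves founder influx, the staining protocol's schedule,
    lineage definition at ``lineage_t0`` (defaults to the protocol's
    ``t_start`` for one-shot and decay staining) and the stochastic update,
    and emits one :class:`~gcbrainbow.metrics.DominanceRecord` per entry of
    ``record_times``.  The trajectory is reproducible from
    ``(config, protocol, seed)``; the simulation stops after the latest
    record time (or the configured duration if no record is requested).
    """
    from gcbrainbow.lineage_tracking import define_lineages

    dt = config.dt
    record_times = sorted(float(t) for t in record_times)
    for t in record_times:
        if t < 0 or t > config.duration:
            raise ValueError(f"record time {t} outside [0, {config.duration}]")
    t_end = record_times[-1] if record_times else config.duration

    if protocol is not None and lineage_t0 is None and protocol.mode != "founder":
        lineage_t0 = protocol.t_start

    def step_index(t: float) -> int:
        return int(round(t / dt))

    stain_steps = (
        {step_index(t) for t in protocol.staining_times()}
        if protocol is not None
        else set()
    )
    record_steps: dict[int, list[float]] = {}
    for t in record_times:
        record_steps.setdefault(step_index(t), []).append(t)
    lineage_step = step_index(lineage_t0) if lineage_t0 is not None else None

    state = init_gc(config, seed)
    state.include_late_founders = include_late_founders
    records = []
    n_steps = step_index(t_end)
    for i in range(n_steps + 1):
        if lineage_step is not None and i == lineage_step:
            define_lineages(state, state.time, include_late_founders)
        if i in stain_steps and state.n_cells:
            apply_staining(state, protocol, state.rng, t=state.time)
        for t_rec in record_steps.get(i, ()):
            records.append(_snapshot(state, gc_id, t_rec))
        if i < n_steps:
            influx_founders(state, config, dt, protocol=protocol)
            step(state, config)
    return records, state
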