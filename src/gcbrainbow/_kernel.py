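"""Numba inner loop for the per-step GC update.

The kernel advances every live cell by one time step directly on the
state's backing arrays: DZ division (with per-daughter hypermutation and
affinity refresh), DZ->LZ transition on budget exhaustion, LZ selection
against the competition-scaled hazard, recycling/output, death and dwell
eviction, followed by in-place swap-remove compaction.  It draws from
numba's own MT19937 stream, seeded once per GC via :func:`seed_kernel`.

Newly born cells are reported through the ``born_*`` scratch arrays so the
caller can maintain an optional genealogy log.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["seed_kernel", "step_kernel"]


@njit(cache=True)
def seed_kernel(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def step_kernel(
    position,
    cell_id,
    parent_id,
    clone_id,
    lineage_id,
    color,
    zone,
    divisions_left,
    birth_time,
    lz_time,
    help_signal,
    aff,
    remove,
    born_cell,
    born_parent,
    born_clone,
    n,
    next_cell_id,
    time,
    dt,
    p_div,
    p_mut,
    sel_rate,
    lz_capacity,
    death_rate,
    max_dwell,
    p_recycle,
    d_min,
    d_max,
    antigen,
    gamma_sq,
    affinity_dependent,
):
    d = position.shape[1]
    n0 = n
    n_div = 0
    n_death = 0
    n_out = 0

    for i in range(n):
        remove[i] = False

    # --- DZ division (original cells only; daughters wait one step) -------
    for i in range(n0):
        if zone[i] == 0 and divisions_left[i] > 0 and np.random.random() < p_div:
            divisions_left[i] -= 1
            j = n
            for k in range(d):
                position[j, k] = position[i, k]
            cell_id[j] = next_cell_id
            parent_id[j] = cell_id[i]
            clone_id[j] = clone_id[i]
            lineage_id[j] = lineage_id[i]
            color[j] = color[i]
            zone[j] = 0
            divisions_left[j] = divisions_left[i]
            birth_time[j] = time
            lz_time[j] = 0.0
            help_signal[j] = help_signal[i]
            aff[j] = aff[i]
            remove[j] = False
            born_cell[n_div] = next_cell_id
            born_parent[n_div] = cell_id[i]
            born_clone[n_div] = clone_id[i]
            next_cell_id += 1
            n += 1
            n_div += 1
            # both daughters hypermutate independently
            for jj in (i, j):
                if np.random.random() < p_mut:
                    dim = np.random.randint(0, d)
                    if np.random.random() < 0.5:
                        position[jj, dim] += 1
                    else:
                        position[jj, dim] -= 1
                    sq = 0.0
                    for k in range(d):
                        delta = float(position[jj, k])
                        sq += delta * delta
                    aff[jj] = math.exp(-sq / gamma_sq)

    # --- DZ -> LZ on exhausted budget, then LZ census ----------------------
    lz_count = 0
    lz_aff_sum = 0.0
    for i in range(n):
        if zone[i] == 0 and divisions_left[i] <= 0:
            zone[i] = 1
            lz_time[i] = 0.0
        if zone[i] == 1:
            lz_count += 1
            lz_aff_sum += aff[i]

    # --- LZ selection, recycling, output, death ----------------------------
    if lz_count > 0:
        mean_aff = lz_aff_sum / lz_count
        competition = 1.0 + lz_count / lz_capacity
        base = sel_rate * antigen / competition
        p_die = 1.0 - math.exp(-death_rate * dt)
        for i in range(n):
            if zone[i] != 1:
                continue
            if affinity_dependent:
                s = aff[i] / (aff[i] + mean_aff)
            else:
                s = 0.5
            p_sel = 1.0 - math.exp(-base * 2.0 * s * dt)
            if np.random.random() < p_sel:
                help_signal[i] = s
                if np.random.random() < p_recycle:
                    zone[i] = 0
                    # dynamic number of divisions: the division budget
                    # grows linearly with the help signal, so cells with
                    # above-average affinity are amplified more strongly
                    divisions_left[i] = int(
                        math.floor(d_min + (d_max - d_min) * s + 0.5)
                    )
                else:
                    remove[i] = True
                    n_out += 1
            else:
                if np.random.random() < p_die or lz_time[i] >= max_dwell:
                    remove[i] = True
                    n_death += 1
                else:
                    lz_time[i] += dt

    # --- compact (swap-from-tail; live order is arbitrary) -----------------
    i = 0
    last = n - 1
    while i <= last:
        if remove[i]:
            if i < last:
                for k in range(d):
                    position[i, k] = position[last, k]
                cell_id[i] = cell_id[last]
                parent_id[i] = parent_id[last]
                clone_id[i] = clone_id[last]
                lineage_id[i] = lineage_id[last]
                color[i] = color[last]
                zone[i] = zone[last]
                divisions_left[i] = divisions_left[last]
                birth_time[i] = birth_time[last]
                lz_time[i] = lz_time[last]
                help_signal[i] = help_signal[last]
                aff[i] = aff[last]
                remove[i] = remove[last]
                last -= 1
                continue  # re-examine the swapped-in row
            last -= 1
        i += 1
    n = last + 1

    return n, next_cell_id, n_div, n_death, n_out
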