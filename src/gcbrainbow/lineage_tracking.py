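"""Clone and lineage bookkeeping.

A *clone* is the set of descendants of one GC founder cell; clone identity
is fixed at influx.  A *lineage* is the set of descendants of one cell
present in the GC at a chosen definition time ``t0`` (typically the time of
tamoxifen injection): every cell alive at ``t0`` founds its own lineage, so
two sisters alive at ``t0`` found different lineages even though they share
a clone.  Lineage identity is inherited unchanged at division.  Founders
entering after ``t0`` carry no lineage unless ``include_late_founders`` is
set, in which case each late founder starts a fresh lineage at entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["LineageRegistry", "define_lineages", "export_newick"]


@dataclass(frozen=True)
class LineageRegistry:
    """Record of one lineage definition event."""

    t0: float
    lineage_ids: dict[int, int]  # cell_id at t0 -> lineage id
    include_late_founders: bool = False

    @property
    def n_lineages(self) -> int:
        return len(self.lineage_ids)


def define_lineages(
    state, t0: float, include_late_founders: bool = False
) -> LineageRegistry:
    """Assign a distinct lineage id to every cell alive at ``t0``.

    Must be called exactly once per run, when ``state.time == t0``.  After
    this call division copies lineage ids to both daughters, and — when
    ``include_late_founders`` is set — founders entering after ``t0`` get
    fresh lineage ids at influx.
    """
    if state.lineage_defined:
        raise RuntimeError("lineages already defined for this GC")
    if abs(state.time - t0) > state.config.dt / 2:
        raise ValueError(
            f"define_lineages called at t={state.time}, expected t0={t0}"
        )
    n = state.n_cells
    ids = np.arange(n, dtype=np.int64)
    state.lineage_id = ids.copy()
    state.next_lineage_id = n
    state.lineage_defined = True
    state.lineage_t0 = t0
    state.include_late_founders = include_late_founders
    return LineageRegistry(
        t0=t0,
        lineage_ids=dict(zip(state.cell_id.tolist(), ids.tolist())),
        include_late_founders=include_late_founders,
    )


def export_newick(state, path: str | Path | None = None) -> str:
    """Write the cell genealogy of one GC as a Newick tree.

    Requires the simulation to have been run with
    ``SimConfig(track_genealogy=True)``.  Every cell ever born is a node;
    a cell's children are the daughters it spawned (the dividing cell
    itself continues under its own id).  Founders are attached to a
    synthetic root.  Live cells are labelled ``cellID|clone|lineage|color``;
    cells that died or left the GC are labelled by cell id alone.  Branch
    lengths are birth-time differences in hours.
    """
    import dendropy

    if not state.genealogy:
        raise ValueError(
            "no genealogy recorded; run with SimConfig(track_genealogy=True)"
        )
    tree = dendropy.Tree()
    nodes: dict[int, "dendropy.Node"] = {}
    birth: dict[int, float] = {}
    alive = {
        int(cid): (int(cl), int(li), int(co))
        for cid, cl, li, co in zip(
            state.cell_id, state.clone_id, state.lineage_id, state.color
        )
    }
    for cell_id, parent_id, clone_id, t_birth in state.genealogy:
        node = dendropy.Node()
        if cell_id in alive:
            cl, li, co = alive[cell_id]
            node.label = f"{cell_id}|{cl}|{li}|{co}"
        else:
            node.label = str(cell_id)
        nodes[cell_id] = node
        birth[cell_id] = t_birth
        if parent_id < 0:
            tree.seed_node.add_child(node)
            node.edge.length = t_birth
        else:
            nodes[parent_id].add_child(node)
            node.edge.length = t_birth - birth[parent_id]
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(newick)
    return newick
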