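"""Dominance statistics on a GC snapshot.

For a snapshot of N live GC B cells the statistics are

* clonal dominance   ``F = max_i F_i / N`` — largest fraction of cells from
  a single founder clone;
* lineage dominance  ``L = max_i L_i / N`` — largest fraction from a single
  lineage (cells without a lineage count in N but in no ``L_i``);
* color dominance    ``C = max_i C_i / N`` over *non-black* colors;
* color density      ``D`` — fraction of cells with any non-black color;
* PDD                ``C * D`` — the product of color dominance and color
  density, a proxy for the in-vivo normalized density score;
* the staining threshold filter ``D > T`` (strict), which restricts an
  analysis to sufficiently stained GCs.

Cell populations are passed either as a pandas DataFrame with columns
``clone_id`` / ``lineage_id`` / ``color`` (color 0 or ``"black"`` meaning
unstained, lineage -1 meaning unassigned) or as plain arrays on a
simulation state; ties are broken deterministically toward the lowest id /
earliest scheme color.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from gcbrainbow.staining import BLACK

__all__ = [
    "BLACK",
    "DominanceRecord",
    "clonal_dominance",
    "lineage_dominance",
    "color_dominance",
    "color_density",
    "passes_threshold",
    "color_switched",
    "snapshot_record",
    "records_to_frame",
]


class EmptyGCError(ValueError):
    """Raised when a dominance statistic is requested on an empty GC."""


@dataclass(frozen=True)
class DominanceRecord:
    """One (GC, time) snapshot of the dominance statistics."""

    gc_id: int
    t: float
    n: int
    F: float
    L: float  # NaN before lineages are defined
    C: float
    D: float
    pdd: float
    dominant_clone: int  # -1 if undefined
    dominant_lineage: int  # -1 if undefined
    dominant_color: object  # color code/label, or None if no cell stained
    mean_affinity: float


def _get(cells, name: str) -> np.ndarray:
    if isinstance(cells, pd.DataFrame):
        if name not in cells.columns:
            raise KeyError(f"cell table has no column {name!r}")
        return cells[name].to_numpy()
    return np.asarray(cells[name])


def _max_count(values: np.ndarray) -> tuple[int, int]:
    """(max count, value attaining it); ties resolved to the lowest value."""
    uniq, counts = np.unique(values, return_counts=True)
    i = int(np.argmax(counts))  # np.unique sorts, argmax takes the first max
    return int(counts[i]), uniq[i]


def clonal_dominance(cells) -> tuple[float, int]:
    """Largest single-clone fraction and the clone id attaining it."""
    clones = _get(cells, "clone_id")
    if clones.size == 0:
        raise EmptyGCError("clonal dominance of an empty GC is undefined")
    count, winner = _max_count(clones)
    return count / clones.size, int(winner)


def lineage_dominance(cells, registry=None) -> tuple[float, int]:
    """Largest single-lineage fraction; unassigned cells dilute but never win.

    Cells with ``lineage_id < 0`` (e.g. progeny of founders that entered
    after the lineage-definition time) count in the denominator N but
    belong to no lineage.  Returns ``(0.0, -1)`` if no cell has a lineage.
    """
    try:
        lineages = _get(cells, "lineage_id")
    except KeyError as err:
        raise ValueError("lineages are not defined for this population") from err
    if lineages.size == 0:
        raise EmptyGCError("lineage dominance of an empty GC is undefined")
    assigned = lineages[lineages >= 0]
    if assigned.size == 0:
        return 0.0, -1
    count, winner = _max_count(assigned)
    return count / lineages.size, int(winner)


def _color_rank(colors: np.ndarray, order: Sequence | None):
    """Map color values to sortable ranks honouring a scheme order."""
    if order is None:
        return colors
    rank = {c: i for i, c in enumerate(order)}
    return np.asarray([rank.get(c, len(order)) for c in colors])


def _is_black(colors: np.ndarray) -> np.ndarray:
    if colors.dtype.kind in "iu":
        return colors == 0
    return np.asarray([str(c).lower() == BLACK for c in colors])


def color_dominance(cells, order: Sequence | None = None) -> tuple[float, object]:
    """Largest single non-black-color fraction (of all N cells).

    ``order`` optionally gives the scheme's color order for tie-breaking
    (earlier wins); integer color codes break ties toward the lower code,
    which is scheme order for simulated populations.  Returns ``(0.0,
    None)`` when no cell is stained.
    """
    colors = _get(cells, "color")
    if colors.size == 0:
        raise EmptyGCError("color dominance of an empty GC is undefined")
    stained = colors[~_is_black(colors)]
    if stained.size == 0:
        return 0.0, None
    if order is not None:
        ranks = _color_rank(stained, order)
        count, winner_rank = _max_count(ranks)
        winner = order[int(winner_rank)]
    else:
        count, winner = _max_count(stained)
        winner = winner.item() if hasattr(winner, "item") else winner
    return count / colors.size, winner


def color_density(cells) -> float:
    """Fraction of cells carrying any non-black color."""
    colors = _get(cells, "color")
    if colors.size == 0:
        raise EmptyGCError("color density of an empty GC is undefined")
    return float((~_is_black(colors)).sum() / colors.size)


def passes_threshold(record, T: float) -> bool:
    """Staining-threshold filter: keep the GC iff ``D > T`` (strict)."""
    if not 0.0 <= T <= 1.0:
        raise ValueError("threshold T must lie in [0, 1]")
    D = record.D if hasattr(record, "D") else record["D"]
    return bool(D > T)


def color_switched(record_at_staining, record_at_analysis) -> bool | None:
    """Did the dominant color change between the two records?

    Returns None (excluded from switch statistics) if either record has no
    dominant color.
    """
    a = (
        record_at_staining.dominant_color
        if hasattr(record_at_staining, "dominant_color")
        else record_at_staining["dominant_color"]
    )
    b = (
        record_at_analysis.dominant_color
        if hasattr(record_at_analysis, "dominant_color")
        else record_at_analysis["dominant_color"]
    )
    if a is None or b is None:
        return None
    if isinstance(a, float) and np.isnan(a) or isinstance(b, float) and np.isnan(b):
        return None
    return bool(a != b)


def snapshot_record(state, gc_id: int, t: float) -> DominanceRecord:
    """Compute all dominance statistics for a live simulation state."""
    n = state.n_cells
    if n == 0:
        return DominanceRecord(
            gc_id=gc_id, t=t, n=0, F=np.nan, L=np.nan, C=np.nan, D=np.nan,
            pdd=np.nan, dominant_clone=-1, dominant_lineage=-1,
            dominant_color=None, mean_affinity=np.nan,
        )
    cells = {
        "clone_id": state.clone_id,
        "lineage_id": state.lineage_id,
        "color": state.color,
    }
    F, dom_clone = clonal_dominance(cells)
    if state.lineage_defined:
        L, dom_lineage = lineage_dominance(cells)
    else:
        L, dom_lineage = np.nan, -1
    C, dom_color = color_dominance(cells)
    D = color_density(cells)
    return DominanceRecord(
        gc_id=gc_id,
        t=t,
        n=n,
        F=F,
        L=L,
        C=C,
        D=D,
        pdd=C * D,
        dominant_clone=dom_clone,
        dominant_lineage=dom_lineage,
        dominant_color=int(dom_color) if dom_color is not None else None,
        mean_affinity=float(state.affinities().mean()),
    )


def records_to_frame(records: Sequence[DominanceRecord]) -> pd.DataFrame:
    """Stack DominanceRecords into a tidy DataFrame (one row per GC x time)."""
    rows = []
    for rec in records:
        row = asdict(rec)
        if row["dominant_color"] is None:
            row["dominant_color"] = -1
        rows.append(row)
    frame = pd.DataFrame(
        rows,
        columns=[
            "gc_id", "t", "n", "F", "L", "C", "D", "pdd",
            "dominant_clone", "dominant_lineage", "dominant_color",
            "mean_affinity",
        ],
    )
    return frame
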