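"""Cohort-level experiments on simulated GCs.

This layer runs cohorts of independent GC simulations and quantifies how
well the observable color statistics (color dominance ``C``, color density
``D``, their product ``PDD``) report on the hidden clonal (``F``) and
lineage (``L``) dominance: Pearson correlations with Fisher-transform
confidence intervals, sweeps over the staining threshold, staining day and
stained fraction, kept-vs-deleted distribution comparisons, and
dominant-color switch statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gcbrainbow.gc_dynamics import SimConfig, run_gc
from gcbrainbow.metrics import color_switched, records_to_frame
from gcbrainbow.staining import ColorScheme, StainingProtocol

__all__ = [
    "CorrelationResult",
    "pearson_with_fisher_ci",
    "run_cohort",
    "realized_stained_fraction",
    "correlate_dominance",
    "staining_time_sweep",
    "stained_fraction_sweep",
    "scheme_sweep",
    "threshold_sweep",
    "kept_vs_deleted",
    "max_lineage_dominance",
    "switch_fraction",
]

HOURS_PER_DAY = 24.0

_METRIC_COLUMNS = {
    "F": "F", "L": "L", "C": "C", "D": "D",
    "PDD": "pdd", "pdd": "pdd", "N": "n",
}


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with a Fisher-transform confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    n: int


def pearson_with_fisher_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Sample Pearson correlation with the Fisher z approximate CI.

    The 1-alpha interval is ``tanh(atanh(r) +/- z_{1-alpha/2}/sqrt(n-3))``.
    Requires non-degenerate inputs; with n < 4 the point estimate is
    returned without an interval (NaN bounds).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    if n < 4:
        return CorrelationResult(r=r, ci_low=np.nan, ci_high=np.nan, n=n)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z / np.sqrt(n - 3)
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    return CorrelationResult(
        r=r,
        ci_low=float(np.tanh(zr - half)),
        ci_high=float(np.tanh(zr + half)),
        n=n,
    )


def run_cohort(
    config: SimConfig,
    protocol: StainingProtocol | None,
    n_gc: int,
    base_seed: int,
    record_times: Sequence[float],
    lineage_t0: float | None = None,
    include_late_founders: bool = False,
) -> pd.DataFrame:
    """Simulate ``n_gc`` independent GCs and stack their dominance records.

    GC ``i`` uses seed ``base_seed + i`` so cohorts are reproducible and
    trivially parallelizable.  Returns a tidy DataFrame with one row per
    (gc_id, record time).
    """
    records = []
    for i in range(n_gc):
        recs, _ = run_gc(
            config,
            protocol,
            seed=base_seed + i,
            record_times=record_times,
            gc_id=i,
            lineage_t0=lineage_t0,
            include_late_founders=include_late_founders,
        )
        records.extend(recs)
    return records_to_frame(records)


def realized_stained_fraction(
    config: SimConfig,
    protocol: StainingProtocol,
    n_gc: int,
    base_seed: int,
    full_exposure_only: bool = True,
) -> float:
    """Cohort-mean stained fraction at the end of the staining procedure.

    With ``full_exposure_only`` (default) the fraction is computed among
    descendants of the cells already in the GC at ``t_start`` — the
    population whose staining probability the decay calibration actually
    fixes at ``f_stained``.  Founders that enter the GC during the staining
    window only see the remaining staining calls, so the whole-GC fraction
    (``full_exposure_only=False``) is lower whenever staining overlaps the
    founder-influx window.
    """
    t_end = protocol.end_of_staining()
    fractions = []
    for i in range(n_gc):
        _, state = run_gc(
            config, protocol, seed=base_seed + i, record_times=[t_end], gc_id=i
        )
        if state.n_cells == 0:
            continue
        stained = state.color > 0
        if full_exposure_only:
            entry = dict(state.founder_log)
            exposed = np.asarray(
                [entry[c] <= protocol.t_start for c in state.clone_id]
            )
            if not exposed.any():
                continue
            fractions.append(stained[exposed].mean())
        else:
            fractions.append(stained.mean())
    return float(np.mean(fractions))


def _rows_at(cohort: pd.DataFrame, t: float) -> pd.DataFrame:
    rows = cohort[np.isclose(cohort["t"], t, atol=1e-6)]
    if rows.empty:
        raise ValueError(f"cohort has no records at t={t}")
    return rows


def correlate_dominance(
    cohort: pd.DataFrame,
    x_metric: str,
    y_metric: str,
    T: float,
    t: float,
) -> CorrelationResult:
    """Correlate two dominance metrics across GCs at time ``t``.

    GCs are first filtered by the staining threshold (color density
    ``D > T`` at ``t``); the result reports the post-filter sample size.
    """
    rows = _rows_at(cohort, t)
    rows = rows[rows["D"] > T]
    x = rows[_METRIC_COLUMNS[x_metric]].to_numpy(dtype=float)
    y = rows[_METRIC_COLUMNS[y_metric]].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        r = (
            float(stats.pearsonr(x, y).statistic)
            if x.size >= 2 and np.std(x) > 0 and np.std(y) > 0
            else np.nan
        )
        return CorrelationResult(r=r, ci_low=np.nan, ci_high=np.nan, n=int(x.size))
    return pearson_with_fisher_ci(x, y)


def threshold_sweep(
    cohort: pd.DataFrame,
    x_metric: str,
    y_metric: str,
    thresholds: Iterable[float],
    t: float,
) -> pd.DataFrame:
    """Correlation of two metrics at ``t`` for each staining threshold."""
    rows = []
    for T in thresholds:
        res = correlate_dominance(cohort, x_metric, y_metric, T, t)
        rows.append(
            {"threshold": T, "r": res.r, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "n": res.n}
        )
    return pd.DataFrame(rows)


def staining_time_sweep(
    config: SimConfig,
    protocol_template: StainingProtocol,
    days: Sequence[float],
    n_gc: int,
    thresholds: Sequence[float],
    base_seed: int = 0,
    analysis_day: float = 11.0,
    include_late_founders: bool = False,
) -> pd.DataFrame:
    """Sweep the staining-initiation day.

    For each day the protocol is restarted at ``day * 24`` hours post GC
    onset, lineages are defined at injection, a fresh cohort is simulated,
    and L is correlated with PDD at ``analysis_day`` days post staining for
    every threshold.  Returns one row per (day, threshold) with r, its CI,
    the post-filter n and the cohort maximum of L.
    """
    rows = []
    for j, day in enumerate(days):
        t0 = day * HOURS_PER_DAY
        protocol = replace(protocol_template, t_start=t0)
        t_eval = t0 + analysis_day * HOURS_PER_DAY
        cohort = run_cohort(
            config,
            protocol,
            n_gc,
            base_seed + j * n_gc,
            record_times=[t_eval],
            include_late_founders=include_late_founders,
        )
        max_L = max_lineage_dominance(cohort, t_eval)
        for T in thresholds:
            res = correlate_dominance(cohort, "L", "PDD", T, t_eval)
            rows.append(
                {"staining_day": day, "threshold": T, "r": res.r,
                 "ci_low": res.ci_low, "ci_high": res.ci_high,
                 "n": res.n, "max_L": max_L}
            )
    return pd.DataFrame(rows)


def stained_fraction_sweep(
    config: SimConfig,
    protocol_template: StainingProtocol,
    fractions: Sequence[float],
    n_gc: int,
    thresholds: Sequence[float],
    base_seed: int = 0,
    analysis_day: float = 11.0,
) -> pd.DataFrame:
    """Sweep the target stained fraction at fixed staining time."""
    rows = []
    for j, f in enumerate(fractions):
        if not 0 < f <= 1:
            raise ValueError("stained fractions must lie in (0, 1]")
        protocol = replace(protocol_template, f_stained=f)
        t_eval = protocol.t_start + analysis_day * HOURS_PER_DAY
        cohort = run_cohort(
            config, protocol, n_gc, base_seed + j * n_gc, record_times=[t_eval]
        )
        for T in thresholds:
            res = correlate_dominance(cohort, "L", "PDD", T, t_eval)
            rows.append(
                {"f_stained": f, "threshold": T, "r": res.r,
                 "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n}
            )
    return pd.DataFrame(rows)


def scheme_sweep(
    config: SimConfig,
    protocol_template: StainingProtocol,
    schemes: Sequence[ColorScheme],
    n_gc: int,
    thresholds: Sequence[float],
    base_seed: int = 0,
    analysis_day: float = 11.0,
) -> pd.DataFrame:
    """Compare color schemes (e.g. 4-color vs 10-color vs 10-equal).

    Every scheme keeps the template's target stained fraction so schemes
    differ only in how the stained mass is split into colors.
    """
    rows = []
    f = protocol_template.f_stained
    for j, scheme in enumerate(schemes):
        protocol = replace(protocol_template, scheme=scheme, f_stained=f)
        t_eval = protocol.t_start + analysis_day * HOURS_PER_DAY
        cohort = run_cohort(
            config, protocol, n_gc, base_seed + j * n_gc, record_times=[t_eval]
        )
        for T in thresholds:
            res = correlate_dominance(cohort, "L", "PDD", T, t_eval)
            rows.append(
                {"scheme": scheme.name, "threshold": T, "r": res.r,
                 "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n}
            )
    return pd.DataFrame(rows)


def kept_vs_deleted(
    cohort: pd.DataFrame,
    T: float,
    t: float,
    bin_width: float = 0.05,
):
    """Compare lineage-dominance distributions above vs below the threshold.

    Splits the GCs at time ``t`` by the staining-threshold filter
    (``D > T``), bins the lineage dominance of each side on ``[0, 1]`` and
    returns ``(hist_kept, hist_deleted, distance)`` where the histograms
    are normalized bin probabilities and ``distance`` is their
    total-variation distance (None when either side is empty).
    """
    rows = _rows_at(cohort, t)
    L = rows["L"].to_numpy(dtype=float)
    kept_mask = rows["D"].to_numpy() > T
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    kept = L[kept_mask & ~np.isnan(L)]
    deleted = L[~kept_mask & ~np.isnan(L)]
    hist_kept, _ = np.histogram(kept, bins=edges)
    hist_deleted, _ = np.histogram(deleted, bins=edges)
    if kept.size == 0 or deleted.size == 0:
        return hist_kept, hist_deleted, None
    p = hist_kept / kept.size
    q = hist_deleted / deleted.size
    return hist_kept, hist_deleted, float(0.5 * np.abs(p - q).sum())


def max_lineage_dominance(cohort: pd.DataFrame, t: float) -> float:
    """Largest lineage dominance across the cohort at time ``t``."""
    rows = _rows_at(cohort, t)
    return float(np.nanmax(rows["L"].to_numpy(dtype=float)))


def switch_fraction(
    cohort: pd.DataFrame, t_stain: float, t_analysis: float, T: float
) -> float | None:
    """Fraction of above-threshold GCs whose dominant color changed.

    A GC enters the statistic if it passes the staining threshold at the
    analysis time and has a dominant color at both times.  Returns None if
    no GC qualifies.
    """
    at_stain = _rows_at(cohort, t_stain).set_index("gc_id")
    at_analysis = _rows_at(cohort, t_analysis).set_index("gc_id")
    common = at_stain.index.intersection(at_analysis.index)
    n_eligible = 0
    n_switched = 0
    for gc in common:
        row_a = at_analysis.loc[gc]
        if not row_a["D"] > T:
            continue
        a = at_stain.loc[gc]["dominant_color"]
        b = row_a["dominant_color"]
        if a == -1 or b == -1:  # no dominant color on one side
            continue
        switched = color_switched(
            {"dominant_color": a}, {"dominant_color": b}
        )
        if switched is None:
            continue
        n_eligible += 1
        n_switched += int(switched)
    if n_eligible == 0:
        return None
    return n_switched / n_eligible
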