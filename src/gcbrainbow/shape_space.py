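"""Shape-space affinity model.

Each B cell carries a position on an integer lattice of dimension ``d``
(default 4).  Affinity for the antigen is a Gaussian function of the
Euclidean distance to the optimal binder,

    affinity(x) = exp(-||x - x*||^2 / Gamma^2),

so the optimum has affinity 1 and affinity decays smoothly with mutational
distance.  Somatic hypermutation is a unit step (+1 or -1) along one
uniformly chosen lattice dimension, i.e. an unbiased nearest-neighbour
random walk.  The lattice is unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AffinityModel",
    "affinity",
    "mutate",
    "mutate_many",
    "sample_founder_positions",
]


@dataclass(frozen=True)
class AffinityModel:
    """Gaussian affinity landscape on an integer lattice.

    Parameters
    ----------
    dimension
        Number of lattice dimensions ``d`` (default 4).
    width
        Gaussian width ``Gamma`` in lattice units; must be positive.
    optimum
        Lattice position of the optimal binder. Defaults to the origin.
    """

    dimension: int = 4
    width: float = 2.8
    optimum: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")
        if not self.width > 0:
            raise ValueError("width Gamma must be > 0")
        opt = self.optimum
        if opt is None:
            opt = np.zeros(self.dimension, dtype=np.int64)
        else:
            opt = np.asarray(opt, dtype=np.int64)
            if opt.shape != (self.dimension,):
                raise ValueError(
                    f"optimum has shape {opt.shape}, expected ({self.dimension},)"
                )
        object.__setattr__(self, "optimum", opt)


def affinity(model: AffinityModel, pos: np.ndarray) -> np.ndarray | float:
    """Affinity of one position or an ``(n, d)`` batch of positions.

    Returns values in ``[0, 1]``; 1 exactly at the optimum, strictly
    decreasing in the Euclidean distance to it.
    """
    pos = np.asarray(pos)
    if pos.shape[-1] != model.dimension:
        raise ValueError(
            f"position dimension {pos.shape[-1]} != model dimension {model.dimension}"
        )
    delta = pos - model.optimum
    sq = np.sum(delta * delta, axis=-1, dtype=np.float64)
    out = np.exp(-sq / (model.width**2))
    if pos.ndim == 1:
        return float(out)
    return out


def mutate(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Return a copy of ``pos`` displaced by +/-1 in one random dimension."""
    pos = np.asarray(pos)
    out = pos.copy()
    dim = rng.integers(pos.shape[-1])
    out[dim] += 1 if rng.random() < 0.5 else -1
    return out


def mutate_many(
    positions: np.ndarray, which: np.ndarray, rng: np.random.Generator
) -> None:
    """Apply one hypermutation step in place to ``positions[which]``.

    ``positions`` is an ``(n, d)`` array; ``which`` is a boolean mask or
    index array selecting the rows to displace.  Each selected row moves by
    +/-1 in one independently chosen dimension.
    """
    idx = np.flatnonzero(which) if which.dtype == bool else np.asarray(which)
    if idx.size == 0:
        return
    d = positions.shape[1]
    dims = rng.integers(0, d, size=idx.size)
    signs = rng.integers(0, 2, size=idx.size) * 2 - 1
    positions[idx, dims] += signs


def sample_founder_positions(
    model: AffinityModel,
    n: int,
    rng: np.random.Generator,
    distance_range: tuple[float, float] = (5.0, 7.0),
) -> np.ndarray:
    """Sample ``n`` founder positions at moderate distance from the optimum.

    Positions are integer lattice points whose Euclidean distance to the
    optimum lies in ``distance_range``, sampled by drawing isotropic
    directions at a uniform radius and rounding to the lattice (rejecting
    rounded points that fall outside the range).  Founders therefore start
    with low affinity but can reach the optimum within a handful of
    mutations, which lets affinity maturation complete within the first
    1-2 weeks of the reaction.
    """
    lo, hi = distance_range
    if not (0 <= lo <= hi):
        raise ValueError("invalid distance_range")
    out = np.empty((n, model.dimension), dtype=np.int64)
    got = 0
    while got < n:
        m = max(8, 2 * (n - got))
        vec = rng.normal(size=(m, model.dimension))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        radius = rng.uniform(lo, hi, size=(m, 1))
        pts = np.rint(vec * radius).astype(np.int64) + model.optimum
        dist = np.linalg.norm(pts - model.optimum, axis=1)
        ok = (dist >= lo) & (dist <= hi)
        take = min(n - got, int(ok.sum()))
        out[got : got + take] = pts[ok][:take]
        got += take
    return out
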