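"""Brainbow color schemes and staining protocols.

Staining is the stochastic, heritable attribution of one of 4 (single
brainbow/confetti allele) or 10 (both alleles) fluorescent colors to a B
cell; "black" means no recombination happened and the cell stays unstained.
Three protocols are supported:

``founder``
    every GC founder cell draws a color (black included) from the scheme at
    GC entry, emulating recombination before the reaction starts;
``one_shot``
    a single staining call at ``t_start`` stains each cell with probability
    ``f_stained``;
``decay``
    tamoxifen-induced recombination whose probability decays exponentially
    with time constant ``tau_tamoxifen`` and is switched off at
    ``tau_stainstop``, applied in discrete calls every ``dt_stain`` hours.

For the decay protocol the initial per-call probability is calibrated so a
target fraction ``f_stained`` of cells ends up stained.  The closed-form
calibration

    p_stain_0 * dt_stain = f_stained / (tau * (1 - exp(-stop/tau)))

treats the per-call probabilities as additive, which overshoots unless the
cumulative probability is small: with no restaining a cell's realized
staining probability is ``1 - prod_k (1 - p_k)``, about 0.39 rather than
0.48 at the default settings.  The default calibration therefore inverts
the product form numerically ("exact"), so the cohort-mean stained
fraction matches ``f_stained``; ``calibration="linear"`` selects the
closed-form value instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

BLACK = "black"

__all__ = [
    "BLACK",
    "ColorScheme",
    "StainingProtocol",
    "builtin_schemes",
    "get_scheme",
    "load_scheme_csv",
    "initial_staining_probability",
    "staining_probability_at",
    "apply_staining",
    "draw_founder_colors",
]


@dataclass(frozen=True)
class ColorScheme:
    """An ordered color palette with attribution probabilities.

    ``colors[0]`` is always ``"black"`` (no recombination); the remaining
    entries are the visible colors in a fixed order used for deterministic
    tie-breaking.  Probabilities must sum to 1 within 1e-9.
    """

    name: str
    colors: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=np.float64)
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "colors", tuple(self.colors))
        if len(self.colors) != probs.size:
            raise ValueError("colors and probabilities differ in length")
        if self.colors[0] != BLACK:
            raise ValueError("first scheme entry must be 'black'")
        if BLACK in self.colors[1:]:
            raise ValueError("'black' listed more than once")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {probs.sum()}, not 1")

    @property
    def n_colors(self) -> int:
        """Number of visible (non-black) colors."""
        return len(self.colors) - 1

    @property
    def stained_fraction(self) -> float:
        """1 - P(black): expected stained fraction under a full-scheme draw."""
        return float(1.0 - self.probabilities[0])

    def non_black_probabilities(self) -> np.ndarray:
        """Visible-color distribution renormalized to sum to 1."""
        p = self.probabilities[1:]
        return p / p.sum()


# Printed attribution probabilities (means over AID-KO GCs for the in-vivo
# columns).  The tamoxifen and founder columns as printed sum to 0.989 and
# 0.995; the visible-color mass is renormalized to 1 - P(black) so each
# scheme is a proper distribution while the printed black fraction — which
# fixes the stained fraction f_stained — is preserved exactly.
_TEN_COLORS = ("YFP", "RFP", "CFP", "GFP", "C/R", "C/Y", "Y/R", "G/R", "C/G", "G/Y")

_RAW_SCHEMES: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "4-color": (
        (BLACK, "YFP", "RFP", "CFP", "GFP"),
        (0.40, 0.18, 0.18, 0.18, 0.06),
    ),
    "tamoxifen": (
        (BLACK,) + _TEN_COLORS,
        (0.52, 0.13, 0.12, 0.10, 0.056, 0.027, 0.016, 0.014, 0.0032, 0.0018, 0.001),
    ),
    "founder": (
        (BLACK,) + _TEN_COLORS,
        (0.11, 0.17, 0.17, 0.17, 0.051, 0.080, 0.080, 0.028, 0.080, 0.028, 0.028),
    ),
    "10-equal": (
        (BLACK,) + _TEN_COLORS,
        (0.52,) + (0.048,) * 10,
    ),
}


def builtin_schemes() -> list[ColorScheme]:
    """The built-in palettes: 4-color, tamoxifen, founder, and 10-equal.

    The first three are the measured attribution probabilities (4-color
    values as assumed in silico); "10-equal" keeps the tamoxifen black
    fraction but splits the stained mass equally over the 10 colors.
    """
    out = []
    for name, (colors, probs) in _RAW_SCHEMES.items():
        arr = np.asarray(probs, dtype=np.float64)
        black = arr[0]
        arr = np.concatenate([[black], arr[1:] * (1.0 - black) / arr[1:].sum()])
        out.append(ColorScheme(name, colors, arr))
    return out


def get_scheme(name: str) -> ColorScheme:
    """Look up a built-in scheme by name."""
    for scheme in builtin_schemes():
        if scheme.name == name:
            return scheme
    raise KeyError(f"unknown color scheme {name!r}; "
                   f"choose from {sorted(_RAW_SCHEMES)}")


def load_scheme_csv(path: str | Path, name: str | None = None) -> ColorScheme:
    """Read a scheme from a two-column CSV (``color,probability``)."""
    path = Path(path)
    colors: list[str] = []
    probs: list[float] = []
    with path.open(newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or row[0].strip().lower() == "color":
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{i + 1}: expected 'color,probability'")
            colors.append(row[0].strip())
            probs.append(float(row[1]))
    return ColorScheme(name or path.stem, tuple(colors), np.asarray(probs))


def initial_staining_probability(
    f_stained: float,
    tau_tamoxifen: float = 24.0,
    tau_stainstop: float = 48.0,
    dt_stain: float = 1.0,
) -> float:
    """Closed-form initial staining rate ``p_stain_0`` (per hour).

    Inverts the additive (no-double-staining) approximation of the stained
    fraction accumulated by an exponentially decaying recombination
    probability that is cut off at ``tau_stainstop``:

        p_stain_0 * dt_stain = f_stained / (tau * (1 - exp(-stop/tau)))

    As ``tau_stainstop -> inf`` this reduces to ``f_stained / tau`` per
    unit ``dt_stain``.
    """
    if f_stained <= 0 or f_stained >= 1:
        raise ValueError("f_stained must lie in (0, 1)")
    if tau_tamoxifen <= 0 or tau_stainstop <= 0 or dt_stain <= 0:
        raise ValueError("time constants must be positive")
    denom = tau_tamoxifen * (1.0 - np.exp(-tau_stainstop / tau_tamoxifen))
    return float(f_stained / denom / dt_stain)


def _exact_initial_probability(
    f_stained: float, tau: float, stop: float, dt: float
) -> float:
    """Per-call initial probability with the product form inverted exactly.

    Solves ``1 - prod_k (1 - q * exp(-k*dt/tau)) = f_stained`` over the
    staining calls ``k = 0..K-1`` for the initial per-call probability
    ``q = p_stain_0 * dt_stain``, so that a cell exposed to the whole
    staining window is stained with probability exactly ``f_stained``.
    """
    k = np.arange(int(np.ceil(stop / dt)))
    decay = np.exp(-k * dt / tau)

    def realized(q: float) -> float:
        return 1.0 - np.prod(1.0 - q * decay) - f_stained

    return float(brentq(realized, 0.0, 1.0, xtol=1e-14))


@dataclass(frozen=True)
class StainingProtocol:
    """A staining experiment design.

    Parameters
    ----------
    mode
        ``"founder"``, ``"one_shot"`` or ``"decay"``.
    scheme
        Color palette with attribution probabilities.
    t_start
        Staining time t0 in hours post GC onset (founder mode ignores it).
    f_stained
        Target stained fraction; defaults to the scheme's ``1 - P(black)``.
    tau_tamoxifen, tau_stainstop, dt_stain
        Decay constant, activity cut-off and call interval (hours) of the
        decay protocol.
    allow_restain
        If True, already-stained cells may redraw a visible color at later
        staining calls (a recombined allele cannot revert to black).
    calibration
        ``"exact"`` (default) or ``"linear"`` (closed form above).
    """

    mode: str
    scheme: ColorScheme
    t_start: float = 48.0
    f_stained: float | None = None
    tau_tamoxifen: float = 24.0
    tau_stainstop: float = 48.0
    dt_stain: float = 1.0
    allow_restain: bool = False
    calibration: str = "exact"
    p_stain_0: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.mode not in ("founder", "one_shot", "decay"):
            raise ValueError(f"unknown staining mode {self.mode!r}")
        if self.f_stained is None:
            object.__setattr__(self, "f_stained", self.scheme.stained_fraction)
        if not (0.0 < self.f_stained <= 1.0):
            raise ValueError("f_stained must lie in (0, 1]")
        if self.mode == "decay":
            if self.calibration == "linear":
                p0 = initial_staining_probability(
                    self.f_stained, self.tau_tamoxifen,
                    self.tau_stainstop, self.dt_stain,
                )
            elif self.calibration == "exact":
                p0 = _exact_initial_probability(
                    self.f_stained, self.tau_tamoxifen,
                    self.tau_stainstop, self.dt_stain,
                ) / self.dt_stain
            else:
                raise ValueError(f"unknown calibration {self.calibration!r}")
            if p0 * self.dt_stain > 1.0:
                raise ValueError("initial per-call staining probability > 1")
            object.__setattr__(self, "p_stain_0", p0)

    def staining_times(self) -> np.ndarray:
        """Scheduled staining call times (hours post GC onset)."""
        if self.mode == "decay":
            n = int(np.ceil(self.tau_stainstop / self.dt_stain))
            return self.t_start + np.arange(n) * self.dt_stain
        if self.mode == "one_shot":
            return np.asarray([self.t_start])
        return np.asarray([])  # founder mode stains at influx

    def end_of_staining(self) -> float:
        """Time at which the staining procedure is over."""
        if self.mode == "decay":
            return self.t_start + self.tau_stainstop
        if self.mode == "one_shot":
            return self.t_start
        return 0.0


def staining_probability_at(protocol: StainingProtocol, t: float) -> float:
    """Per-call staining probability of the decay protocol at time ``t``.

    ``p(t) = p_stain_0 * dt_stain * exp(-(t - t_start)/tau_tamoxifen)`` for
    ``t_start <= t < t_start + tau_stainstop`` and 0 outside the window.
    """
    if protocol.mode != "decay":
        raise ValueError("staining_probability_at applies to decay mode only")
    dt_rel = t - protocol.t_start
    if dt_rel < 0 or dt_rel >= protocol.tau_stainstop:
        return 0.0
    return float(
        protocol.p_stain_0
        * protocol.dt_stain
        * np.exp(-dt_rel / protocol.tau_tamoxifen)
    )


def draw_founder_colors(
    scheme: ColorScheme, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` color codes from the full scheme (black = 0 possible)."""
    return rng.choice(len(scheme.colors), size=n, p=scheme.probabilities).astype(
        np.int16
    )


def apply_staining(
    state, protocol: StainingProtocol, rng: np.random.Generator, t: float | None = None
) -> int:
    """Run one staining call on the live cells of ``state`` in place.

    ``state`` exposes a ``color`` integer array (0 = black/unstained, k >= 1
    indexes ``scheme.colors``).  Eligible cells — unstained ones, or all
    cells when restaining is allowed — are independently stained with the
    protocol's current probability; a stained cell draws its visible color
    from the scheme's non-black distribution renormalized.  Returns the
    number of staining events.
    """
    if protocol.mode == "one_shot":
        p = protocol.f_stained
    elif protocol.mode == "decay":
        if t is None:
            raise ValueError("decay mode needs the current time t")
        p = staining_probability_at(protocol, t)
    else:
        raise ValueError("founder mode stains at influx, not via apply_staining")
    if p <= 0.0:
        return 0
    color = state.color
    eligible = np.ones(color.size, dtype=bool) if protocol.allow_restain else color == 0
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return 0
    hit = idx[rng.random(idx.size) < p]
    if hit.size:
        color[hit] = (
            rng.choice(
                protocol.scheme.n_colors,
                size=hit.size,
                p=protocol.scheme.non_black_probabilities(),
            )
            + 1
        ).astype(np.int16)
    return int(hit.size)
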