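"""Configuration files, cohort CSV round-trips and run manifests.

The configuration is one YAML file with two sections::

    sim:                      # SimConfig fields, e.g.
      duration: 504.0         # hours
      dt: 0.1
      founder_influx_rate: 2.0
    staining:                 # StainingProtocol fields
      mode: decay             # founder | one_shot | decay
      scheme: tamoxifen       # builtin name, or path to a scheme CSV
      t_start: 48.0           # hours post GC onset
      f_stained: 0.48

Unknown keys are rejected with the offending key named; omitted keys take
the package defaults.  Cohort tables are written as tidy CSV, one row per
(gc_id, record time), comma-separated, UTF-8, times in hours.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gcbrainbow import __version__ as _version
from gcbrainbow.gc_dynamics import SimConfig
from gcbrainbow.staining import ColorScheme, StainingProtocol, get_scheme, load_scheme_csv

__all__ = [
    "ConfigError",
    "load_config",
    "default_config",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_manifest",
]

_COHORT_COLUMNS = [
    "gc_id", "t", "n", "F", "L", "C", "D", "pdd",
    "dominant_clone", "dominant_lineage", "dominant_color", "mean_affinity",
]


class ConfigError(ValueError):
    """Raised on malformed or invalid configuration input."""


def default_config() -> tuple[SimConfig, StainingProtocol]:
    """The shipped default experiment: tamoxifen decay staining at day 2."""
    return SimConfig(), StainingProtocol(mode="decay", scheme=get_scheme("tamoxifen"))


def _build_dataclass(cls, section: dict, name: str, **extra):
    fields = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}' section: {sorted(unknown)}")
    try:
        return cls(**section, **extra)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid '{name}' configuration: {err}") from err


def _resolve_scheme(value, base: Path) -> ColorScheme:
    if isinstance(value, ColorScheme):
        return value
    try:
        return get_scheme(str(value))
    except KeyError:
        path = (base / str(value)) if not Path(str(value)).is_absolute() else Path(value)
        if path.exists():
            return load_scheme_csv(path)
        raise ConfigError(
            f"color scheme {value!r} is neither a builtin name nor a CSV file"
        )


def load_config(path: str | Path) -> tuple[SimConfig, StainingProtocol]:
    """Parse and validate a YAML configuration file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"sim", "staining"}
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")
    sim_section = dict(raw.get("sim") or {})
    stain_section = dict(raw.get("staining") or {})
    config = _build_dataclass(SimConfig, sim_section, "sim")
    scheme = _resolve_scheme(stain_section.pop("scheme", "tamoxifen"), path.parent)
    stain_section.setdefault("mode", "decay")
    protocol = _build_dataclass(
        StainingProtocol, stain_section, "staining", scheme=scheme
    )
    return config, protocol


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as tidy CSV (lossless for all record fields)."""
    out = cohort.reindex(columns=_COHORT_COLUMNS)
    out.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort_csv`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed cohort CSV {path}: {err}") from err
    missing = set(_COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("gc_id", "n", "dominant_clone", "dominant_lineage", "dominant_color"):
        bad = frame[frame[col].isna()]
        if not bad.empty:
            raise ValueError(
                f"{path}: line {int(bad.index[0]) + 2}: missing value in '{col}'"
            )
        frame[col] = frame[col].astype(np.int64)
    return frame


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: SimConfig,
    protocol: StainingProtocol | None,
    seeds: list[int],
    outputs: list[str | Path],
) -> dict:
    """Write a JSON run manifest: config snapshot, seeds, output checksums."""
    manifest = {
        "gcbrainbow_version": _version,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": dataclasses.asdict(config),
        "protocol": (
            {
                **{
                    k: v
                    for k, v in dataclasses.asdict(protocol).items()
                    if k != "scheme"
                },
                "scheme": protocol.scheme.name,
            }
            if protocol is not None
            else None
        ),
        "seeds": [int(s) for s in seeds],
        "outputs": {
            str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
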