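"""Run configuration, result serialization, and logging setup.

Configurations are flat YAML mappings validated against the RunConfig
schema; unknown keys are rejected and every error names its field.  All
results are written as diffable TSV tables plus a JSON metadata sidecar
carrying the exact parameters and seed needed to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger("avbmc")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

_POSITIVE = ("temperature", "reservoir_density", "radius", "spacing",
             "cutoff", "sweeps", "moves")
_NONNEG = ("pressure", "equilibration")


@dataclass
class RunConfig:
    """Flat parameter set shared by the simulation subcommands."""

    seed: int
    mode: str | None = None            # liquid | solid (cluster runs)
    phase: str | None = None           # liquid | fcc_solid (bulk runs)
    temperature: float | None = None
    reservoir_density: float | None = None
    radius: float | None = None        # R (liquid) or r (solid)
    spacing: float | None = None       # FCC nearest-neighbor distance
    window: tuple[int, int] | None = None
    moves: int | None = None
    sweeps: int | None = None
    equilibration: int | None = None
    n_particles: int | None = None
    cutoff: float | None = None
    pressure: float | None = None
    max_displacement: float = 0.2
    bias_file: str | None = None
    out_dir: str = "."

    def validate(self) -> None:
        errors = []
        if self.seed is None:
            errors.append("seed: required")
        for name in _POSITIVE:
            v = getattr(self, name, None)
            if v is not None and v <= 0:
                errors.append(f"{name}: must be > 0, got {v}")
        for name in _NONNEG:
            v = getattr(self, name, None)
            if v is not None and v < 0:
                errors.append(f"{name}: must be >= 0, got {v}")
        if self.mode is not None and self.mode not in ("liquid", "solid"):
            errors.append(f"mode: must be liquid|solid, got {self.mode!r}")
        if self.phase is not None and self.phase not in ("liquid", "fcc_solid"):
            errors.append(f"phase: must be liquid|fcc_solid, got {self.phase!r}")
        if self.window is not None:
            lo, hi = self.window
            if not 1 <= lo <= hi:
                errors.append(f"window: need 1 <= n_min <= n_max, got {self.window}")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("window") is not None:
            d["window"] = list(d["window"])
        return {k: v for k, v in d.items() if v is not None}


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
    if "seed" not in raw:
        raise ValueError("invalid configuration:\n  seed: required")
    if "window" in raw and raw["window"] is not None:
        raw["window"] = tuple(int(v) for v in raw["window"])
    cfg = RunConfig(**raw)
    cfg.validate()
    logger.info("loaded config %s: %s", path, cfg.to_dict())
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def write_metadata(path: str | Path, **payload) -> None:
    """JSON run-metadata sidecar (parameters, seed, package version)."""
    from . import __version__
    payload.setdefault("package_version", __version__)

    def default(o):
        import numpy as np
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=default) + "\n")


def write_results(out_dir: str | Path, *, histogram=None, stats=None,
                  series=None, fit=None, profile=None, bias=None,
                  metadata: dict | None = None) -> Path:
    """Write whichever run outputs are present as TSV/JSON under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if histogram is not None:
        histogram.to_tsv(out / "size_histogram.tsv")
    if series is not None:
        series.to_tsv(out / "delta_g_series.tsv")
    if profile is not None:
        profile.to_tsv(out / "free_energy_profile.tsv")
    if bias is not None:
        bias.to_tsv(out / "bias.tsv")
    meta = dict(metadata or {})
    if stats is not None:
        meta["move_stats"] = stats.as_dict()
    if fit is not None:
        meta["fit"] = dataclasses.asdict(fit)
    write_metadata(out / "metadata.json", **meta)
    return out
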