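"""Config loading/validation and CSV readers/writers for run artifacts.

Configs are YAML key-value files validated strictly (unknown keys are
rejected, all physical invariants enforced before any solve).  Histories
are RFC-4180 CSV with a ``#``-prefixed metadata header carrying the run
provenance, including a content hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .params import SOLUTE_MWS, PRESET_REGISTRY
from .solver import ConcentrationHistory

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "write_history_csv",
    "read_history_csv",
]


@dataclass
class RunConfig:
    """Validated top-level run configuration."""

    preset: str = "table1_baseline"
    tests: tuple[str, ...] = ("test1", "test2", "test3", "tpeak")
    solutes: tuple[float, ...] = tuple(SOLUTE_MWS)
    # geometry overrides
    config: str | None = None          # single-run mode: SBC | 2BC | BC_LC
    flow_mode: str | None = None
    L_um: float | None = None
    D_um: float | None = None
    # numerical profile
    nr: int = 40
    nz: int = 40
    dt_s: float = 0.5
    duration_s: float = 4.0 * 3600.0
    output_dt_s: float = 6.0
    fast: bool = False
    # solute-parameter overrides (applied to every solute; validation only)
    sigma: float | None = None
    # bookkeeping
    outdir: str = "out"
    seed: int = 0
    exclude_ld125: bool = False

    def validate(self) -> None:
        if self.preset not in PRESET_REGISTRY:
            raise ValueError(
                f"unknown preset {self.preset!r}; known: {sorted(PRESET_REGISTRY)}"
            )
        known_tests = {"test1", "test2", "test3", "tpeak", "all"}
        for t in self.tests:
            if t not in known_tests:
                raise ValueError(f"unknown test selection {t!r}; known: {sorted(known_tests)}")
        for mw in self.solutes:
            if float(mw) not in SOLUTE_MWS:
                raise ValueError(f"no solute preset for mw={mw!r} kDa")
        if self.config is not None and self.config not in ("SBC", "2BC", "BC_LC"):
            raise ValueError(f"unknown config {self.config!r}")
        if self.sigma is not None and not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")
        for name in ("nr", "nz"):
            if getattr(self, name) < 8:
                raise ValueError(f"{name} must be >= 8")
        for name in ("dt_s", "duration_s", "output_dt_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.L_um is not None and not self.L_um > 0:
            raise ValueError("L_um must be > 0")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys and invariant violations raise ``ValueError`` naming the
    offending key.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ValueError(f"cannot parse config {path}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    for key in ("tests", "solutes"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["tests"] = list(d["tests"])
    d["solutes"] = list(d["solutes"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(obj) -> str:
    """Short deterministic content hash of a config/metadata mapping."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ------------------------------------------------------------------ CSV IO

_COLUMNS = ("time_s", "c_norm_volume", "c_norm_surface_0.2L")


def write_history_csv(h: ConcentrationHistory, path: str | Path) -> None:
    """Write a concentration history with its metadata header.

    Refuses non-finite values; numeric columns are written at full (17
    significant digit) precision so that ``read . write`` is the identity.
    """
    arrs = [h.time_s, h.c_norm_volume, h.c_norm_surface]
    for name, a in zip(_COLUMNS, arrs):
        if not np.all(np.isfinite(a)):
            raise ValueError(f"history column {name} contains non-finite values")
    meta = dict(h.metadata)
    meta["config_hash"] = config_hash(meta)
    meta["peak_bracketed"] = h.peak_bracketed
    lines = [f"# {k}={v}" for k, v in sorted(meta.items())]
    lines.append(",".join(_COLUMNS))
    for row in zip(*arrs):
        lines.append(",".join(format(v, ".17g") for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_history_csv(path: str | Path) -> ConcentrationHistory:
    """Read a history written by :func:`write_history_csv`."""
    path = Path(path)
    meta: dict = {}
    rows: list[list[float]] = []
    header_seen = False
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = _parse_scalar(v.strip())
            continue
        if not header_seen:
            if line.split(",") != list(_COLUMNS):
                raise ValueError(f"{path}:{ln}: unexpected column header {line!r}")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != len(_COLUMNS):
            raise ValueError(f"{path}:{ln}: expected {len(_COLUMNS)} fields, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: {e}") from e
    if not header_seen:
        raise ValueError(f"{path}: missing column header line")
    data = np.asarray(rows, float).reshape(-1, len(_COLUMNS))
    bracketed = bool(meta.pop("peak_bracketed", True))
    meta.pop("config_hash", None)
    return ConcentrationHistory(
        time_s=data[:, 0],
        c_norm_volume=data[:, 1],
        c_norm_surface=data[:, 2],
        metadata=meta,
        peak_bracketed=bracketed,
    )


def _parse_scalar(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    if v in ("True", "False"):
        return v == "True"
    return v
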