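"""Shared I/O: long-format trace files, result tables, JSON artifacts,
run configuration.  Plain tab-separated text and JSON only; every writer
embeds a header with tool version, config hash and seed so runs are
reproducible and diffable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ChromatogramTrace

__version__ = "1.0.0"

TRACE_COLUMNS = ("sample", "analyte", "channel_role", "esi_mode", "time_min", "intensity")


def config_hash(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def header_lines(seed: int | None = None, cfg_hash: str | None = None) -> list[str]:
    lines = [f"tool: pupyscreen {__version__}"]
    if cfg_hash is not None:
        lines.append(f"config_hash: {cfg_hash}")
    if seed is not None:
        lines.append(f"seed: {seed}")
    return lines


def write_table(df: pd.DataFrame, path, meta: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in meta or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj, path, meta: dict | None = None) -> None:
    payload = {"_meta": meta, "data": obj} if meta is not None else obj
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_traces(
    traces: list[ChromatogramTrace], path, meta: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for line in meta or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for tr in traces:
            prefix = f"{tr.sample_label}\t{tr.analyte}\t{tr.channel_role}\t{tr.esi_mode}"
            for t, y in zip(tr.times, tr.intensities):
                fh.write(f"{prefix}\t{t:.17g}\t{y:.17g}\n")


def read_traces(path) -> dict[str, list[ChromatogramTrace]]:
    """Parse the long trace format, grouped by sample.

    Malformed rows are reported with their line number; channels whose
    time grid is not uniform are rejected.
    """
    groups: dict[tuple[str, str, str, str], list[tuple[float, float]]] = {}
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if tuple(header) != TRACE_COLUMNS:
                    raise ValueError(
                        f"{path}: line {lineno}: expected columns {TRACE_COLUMNS}"
                    )
                continue
            parts = line.split("\t")
            if len(parts) != len(TRACE_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(TRACE_COLUMNS)} fields, "
                    f"got {len(parts)}"
                )
            sample, analyte, role, mode, t_raw, y_raw = parts
            try:
                t, y = float(t_raw), float(y_raw)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric time/intensity"
                ) from None
            groups.setdefault((sample, analyte, role, mode), []).append((t, y))
    if not groups:
        warnings.warn(f"{path}: no trace rows found", stacklevel=2)
        return {}
    out: dict[str, list[ChromatogramTrace]] = {}
    for (sample, analyte, role, mode), points in groups.items():
        points.sort(key=lambda p: p[0])
        times = np.array([p[0] for p in points])
        intensities = np.array([p[1] for p in points])
        if times.size > 2:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError(
                    f"{path}: channel ({sample}, {analyte}, {role}) has a "
                    "non-uniform time grid"
                )
        out.setdefault(sample, []).append(
            ChromatogramTrace(
                sample_label=sample,
                analyte=analyte,
                channel_role=role,
                esi_mode=mode,
                times=times,
                intensities=intensities,
            )
        )
    return out


@dataclass
class RunConfig:
    """Workbench configuration (YAML key-value file)."""

    seed: int = 0
    panel: str = "bundled"
    out: str = "."
    weighting: str = "none"
    alpha: float = 0.05
    verbosity: int = 1
    paths: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        return config_hash(
            {
                "seed": self.seed,
                "panel": self.panel,
                "out": self.out,
                "weighting": self.weighting,
                "alpha": self.alpha,
                "paths": self.paths,
                "params": self.params,
            }
        )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        panel=str(raw.get("panel", "bundled")),
        out=str(raw.get("out", ".")),
        weighting=str(raw.get("weighting", "none")),
        alpha=float(raw.get("alpha", 0.05)),
        verbosity=int(raw.get("verbosity", 1)),
        paths={k: str(v) for k, v in (raw.get("paths") or {}).items()},
        params=raw.get("params") or {},
    )
    for name, p in cfg.paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
    if cfg.panel != "bundled" and not Path(cfg.panel).exists():
        raise FileNotFoundError(f"panel file does not exist: {cfg.panel}")
    return cfg
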