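"""Run persistence: tables, resolved config, seeds, and content hashes.

A run directory contains one file per output table (CSV for small tables,
parquet for large trajectory data), the fully resolved config
(``resolved_config.yaml``), and ``metadata.json`` with the seed, package
version and a sha256 per table so a run can be re-verified from the
directory alone.  Writes are staged behind an ``_INCOMPLETE`` marker that is
removed only once everything (including hashes) is on disk.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

__all__ = ["write_run", "read_run", "verify_run", "trajectory_frame"]

MARKER = "_INCOMPLETE"
METADATA = "metadata.json"
CONFIG_FILE = "resolved_config.yaml"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run(
    out_dir: str | Path,
    tables: Mapping[str, pd.DataFrame],
    resolved_config: Mapping[str, Any],
    seed: int,
    extra_metadata: Mapping[str, Any] | None = None,
    parquet: bool = False,
) -> Path:
    """Persist tables + reproducibility metadata; returns the run directory."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / MARKER
    marker.touch()
    try:
        files: dict[str, str] = {}
        for name, df in tables.items():
            fname = f"{name}.parquet" if parquet else f"{name}.csv"
            path = out / fname
            if parquet:
                df.to_parquet(path, index=False)
            else:
                df.to_csv(path, index=False)
            files[fname] = _sha256(path)
        (out / CONFIG_FILE).write_text(yaml.safe_dump(dict(resolved_config), sort_keys=True))
        meta = {
            "seed": int(seed),
            "package_version": __version__,
            "tables": files,
            "config_sha256": _sha256(out / CONFIG_FILE),
        }
        if extra_metadata:
            meta["extra"] = dict(extra_metadata)
        (out / METADATA).write_text(json.dumps(meta, indent=2, default=str))
    except BaseException:
        raise  # marker stays: directory is flagged incomplete
    marker.unlink()
    return out


def verify_run(run_dir: str | Path) -> None:
    """Raise if the run is incomplete or any table fails hash verification."""
    run = Path(run_dir)
    if (run / MARKER).exists():
        raise ValueError(f"run directory {run} is marked incomplete")
    meta = json.loads((run / METADATA).read_text())
    for fname, digest in meta["tables"].items():
        actual = _sha256(run / fname)
        if actual != digest:
            raise ValueError(f"hash mismatch for {fname}: expected {digest}, got {actual}")
    if _sha256(run / CONFIG_FILE) != meta["config_sha256"]:
        raise ValueError("hash mismatch for resolved config")


def read_run(run_dir: str | Path, verify: bool = True) -> tuple[dict[str, pd.DataFrame], dict]:
    """Load all tables and metadata from a run directory."""
    run = Path(run_dir)
    if verify:
        verify_run(run)
    meta = json.loads((run / METADATA).read_text())
    tables = {}
    for fname in meta["tables"]:
        path = run / fname
        name = path.stem
        tables[name] = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    return tables, meta


def trajectory_frame(times, snapshots, s_values=None, psi=None, group_ids=None) -> pd.DataFrame:
    """Tidy trajectory table: one row per (time step, agent).

    Columns: t, agent_id, x, y, vx, vy and optionally S, Psi, group_id.
    Lengths are in units of lr, time in units of tau."""
    frames = []
    for idx, (t, snap) in enumerate(zip(times, snapshots)):
        n = snap.positions.shape[0]
        d = {
            "t": t, "agent_id": range(n),
            "x": snap.positions[:, 0], "y": snap.positions[:, 1],
            "vx": snap.velocities[:, 0], "vy": snap.velocities[:, 1],
        }
        if s_values is not None:
            d["S"] = s_values[idx]
        if psi is not None:
            d["Psi"] = psi[idx]
        if group_ids is not None:
            d["group_id"] = group_ids[idx]
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)
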