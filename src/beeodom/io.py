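"""Delimited-text output of trajectories, sweep records and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .config import ScenarioConfig

__all__ = ["write_trajectory", "write_records", "read_records", "write_manifest"]

# units are embedded in the headers: angles in degrees, optic flow in rad/s
_TRAJ_UNITS = {
    "t": "s", "x": "m", "z": "m", "h": "m", "V_x": "m/s", "V_h": "m/s",
    "V_air": "m/s", "v_wind": "m/s", "u_theta": "deg", "u_dphi": "deg",
    "omega_T": "rad/s", "omega_div": "rad/s", "h_hat": "m", "v_h_hat": "m/s",
    "x_sofia": "m", "of_acc": "rad",
}


def write_trajectory(traj: pd.DataFrame, path: str | Path) -> None:
    out = traj.rename(columns={c: f"{c}[{u}]" for c, u in _TRAJ_UNITS.items() if c in traj})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, configs: ScenarioConfig | list[ScenarioConfig], extra: dict | None = None) -> None:
    """Write a machine-readable manifest (config hash, version, timestamp)."""
    if isinstance(configs, ScenarioConfig):
        configs = [configs]
    blob = json.dumps([c.to_dict() for c in configs], sort_keys=True).encode()
    manifest = {
        "beeodom_version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "n_configs": len(configs),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "first_config": configs[0].to_dict(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
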