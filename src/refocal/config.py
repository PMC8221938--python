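"""Configuration and file-format plumbing for the refocal pipeline.

Formats handled here (all plain text):

* system config — YAML/JSON mapping with keys ``f_mm``, ``n``,
  ``x_error_mm``, ``y_error_mm``, ``z_error_mm``;
* drive tables — CSV with columns ``plane_index``, ``z_cmd_um``,
  ``kappa_per_mm``, ``theta_x_rad``, ``theta_y_rad``;
* element sequences — JSON list of ``{"type": ..., ...}`` objects for the
  ray-trace oracle;
* fit / verify reports — JSON.

Every report written through :func:`write_report` embeds the SHA-256 of the
configuration that produced it plus the seed, so reruns are attributable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .model import Drive, OpticalSystem
from .rays import (ElementSequence, FreeSpace, Interface, RfOutput, ThinLens)

__all__ = [
    "load_config",
    "system_from_config",
    "system_to_config",
    "config_hash",
    "drives_to_dataframe",
    "drives_from_dataframe",
    "sequence_from_obj",
    "sequence_to_obj",
    "write_report",
]

_SYSTEM_KEYS = {"f_mm", "n", "x_error_mm", "y_error_mm", "z_error_mm"}


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return data


def system_from_config(cfg: dict) -> OpticalSystem:
    """Build an :class:`OpticalSystem` from a config mapping.

    Accepts either a flat mapping with the system keys or a mapping with a
    nested ``system`` block.
    """
    block = cfg.get("system", cfg)
    unknown = set(block) - _SYSTEM_KEYS
    if unknown and "f_mm" not in block:
        raise ValidationError(f"no optical system found in config (keys {sorted(cfg)})")
    try:
        return OpticalSystem(
            f=float(block["f_mm"]), n=float(block["n"]),
            x_error=float(block.get("x_error_mm", 0.0)),
            y_error=float(block.get("y_error_mm", 0.0)),
            z_error=float(block.get("z_error_mm", 0.0)))
    except KeyError as exc:
        raise ValidationError(f"missing system config key: {exc}") from exc


def system_to_config(system: OpticalSystem) -> dict:
    return {"f_mm": system.f, "n": system.n, "x_error_mm": system.x_error,
            "y_error_mm": system.y_error, "z_error_mm": system.z_error}


def config_hash(cfg: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def drives_to_dataframe(drives: list[Drive], z_cmd_um: list[float]) -> pd.DataFrame:
    if len(drives) != len(z_cmd_um):
        raise ValidationError("one drive per commanded plane required")
    return pd.DataFrame({
        "plane_index": range(len(drives)),
        "z_cmd_um": z_cmd_um,
        "kappa_per_mm": [d.kappa for d in drives],
        "theta_x_rad": [d.theta_x for d in drives],
        "theta_y_rad": [d.theta_y for d in drives],
    })


def drives_from_dataframe(df: pd.DataFrame) -> tuple[list[Drive], list[float]]:
    df = df.sort_values("plane_index")
    drives = [Drive(k, tx, ty) for k, tx, ty in
              zip(df["kappa_per_mm"], df["theta_x_rad"], df["theta_y_rad"])]
    return drives, [float(z) for z in df["z_cmd_um"]]


_ELEMENT_TYPES = {
    "free_space": lambda o: FreeSpace(d=float(o["d_mm"])),
    "thin_lens": lambda o: ThinLens(f=float(o["f_mm"]),
                                    offset_x=float(o.get("offset_x_mm", 0.0)),
                                    offset_y=float(o.get("offset_y_mm", 0.0))),
    "rf_output": lambda o: RfOutput(offset_x=float(o.get("offset_x_mm", 0.0)),
                                    offset_y=float(o.get("offset_y_mm", 0.0))),
    "interface": lambda o: Interface(n_ratio=float(o["n_ratio"])),
}


def sequence_from_obj(obj: list[dict]) -> ElementSequence:
    """Element sequence from its JSON representation."""
    elements = []
    for item in obj:
        kind = item.get("type")
        if kind not in _ELEMENT_TYPES:
            raise ValidationError(f"unknown element type {kind!r}")
        elements.append(_ELEMENT_TYPES[kind](item))
    return ElementSequence(elements)


def sequence_to_obj(seq: ElementSequence) -> list[dict]:
    out = []
    for el in seq.elements:
        if isinstance(el, FreeSpace):
            out.append({"type": "free_space", "d_mm": el.d})
        elif isinstance(el, ThinLens):
            out.append({"type": "thin_lens", "f_mm": el.f,
                        "offset_x_mm": el.offset_x, "offset_y_mm": el.offset_y})
        elif isinstance(el, RfOutput):
            out.append({"type": "rf_output", "offset_x_mm": el.offset_x,
                        "offset_y_mm": el.offset_y})
        elif isinstance(el, Interface):
            out.append({"type": "interface", "n_ratio": el.n_ratio})
    return out


def write_report(path: str | Path, payload: dict, cfg: dict | None = None,
                 seed: int | None = None) -> Path:
    """Write a JSON report embedding the config hash and seed."""
    path = Path(path)
    meta = dict(payload)
    if cfg is not None:
        meta["config_sha256"] = config_hash(cfg)
    if seed is not None:
        meta["seed"] = seed
    path.write_text(json.dumps(meta, indent=2, default=float))
    return path
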