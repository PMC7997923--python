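"""Readers and writers for volume series and fit results.

OME-TIFF (axes TZYX) is the canonical on-disk format for volume series;
plain multi-page TIFF is accepted when a JSON sidecar (``<stem>.json``)
carries the calibration.  Fit results serialize to a schema-versioned
JSON plus a per-mode CSV table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import ValidationError
from .frap3d_analysis import FitResult, VolumeSeries

__all__ = [
    "read_volume_series",
    "write_volume_series",
    "write_results",
    "RESULT_SCHEMA_VERSION",
]

log = logging.getLogger(__name__)

RESULT_SCHEMA_VERSION = "1.0.0"


def _package_version() -> str:
    try:
        return version("liftfrap")
    except PackageNotFoundError:  # running from a source tree
        return "0+unknown"


def write_volume_series(series: VolumeSeries, path: str | Path) -> Path:
    """Write a volume series as OME-TIFF (TZYX) plus a JSON sidecar.

    The sidecar carries calibration and free-form metadata (including the
    simulator's ground-truth tensor when present), so a write/read
    roundtrip is lossless.
    """
    path = Path(path)
    dz, dy, dx = series.voxel_um
    tifffile.imwrite(
        path,
        series.data,
        photometric="minisblack",
        metadata={
            "axes": "TZYX",
            "PhysicalSizeX": dx, "PhysicalSizeXUnit": "um",
            "PhysicalSizeY": dy, "PhysicalSizeYUnit": "um",
            "PhysicalSizeZ": dz, "PhysicalSizeZUnit": "um",
            "TimeIncrement": series.frame_interval_s,
            "TimeIncrementUnit": "s",
        },
    )
    sidecar = {
        "voxel_um": list(series.voxel_um),
        "frame_interval_s": series.frame_interval_s,
        "n_prebleach": series.n_prebleach,
        "bleach_duration_s": series.bleach_duration_s,
        "metadata": _jsonable(series.metadata),
    }
    spath = path.with_suffix(path.suffix + ".json")
    spath.write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume_series(
    path: str | Path,
    voxel_um: tuple[float, float, float] | None = None,
    frame_interval_s: float | None = None,
    n_prebleach: int | None = None,
    bleach_duration_s: float | None = None,
) -> VolumeSeries:
    """Read a TIFF/OME-TIFF stack into a :class:`VolumeSeries`.

    Calibration comes from the JSON sidecar written by
    :func:`write_volume_series` (or hand-authored); explicit arguments win
    over sidecar values (the conflict is logged).  Integer input is
    converted to float without clipping.  Missing calibration raises a
    :class:`ValidationError` naming the field.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[:, None]  # single-plane stack -> (t, 1, y, x)
    if data.ndim != 4:
        raise ValidationError(
            f"expected a 4D (t, z, y, x) stack, got shape {data.shape}"
        )
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64)

    sidecar: dict = {}
    spath = path.with_suffix(path.suffix + ".json")
    if spath.exists():
        sidecar = json.loads(spath.read_text())

    def pick(name, explicit):
        stored = sidecar.get(name)
        if explicit is not None:
            if stored is not None and not _close(stored, explicit):
                log.warning(
                    "%s: flag value %r overrides sidecar value %r",
                    name, explicit, stored,
                )
            return explicit
        return stored

    voxel = pick("voxel_um", list(voxel_um) if voxel_um else None)
    dt = pick("frame_interval_s", frame_interval_s)
    npre = pick("n_prebleach", n_prebleach)
    bdur = pick("bleach_duration_s", bleach_duration_s)
    for name, val in (("voxel_um", voxel), ("frame_interval_s", dt),
                      ("n_prebleach", npre)):
        if val is None:
            raise ValidationError(
                f"missing calibration field '{name}': provide it via the "
                "sidecar JSON or an explicit argument/flag"
            )
    return VolumeSeries(
        data=data,
        voxel_um=tuple(float(v) for v in voxel),
        frame_interval_s=float(dt),
        n_prebleach=int(npre),
        bleach_duration_s=float(bdur) if bdur is not None else 0.0,
        metadata=sidecar.get("metadata", {}),
    )


def _close(a, b) -> bool:
    try:
        return bool(np.allclose(np.asarray(a, float), np.asarray(b, float)))
    except (TypeError, ValueError):
        return a == b


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_results(
    result: FitResult,
    path: str | Path,
    frame: str = "lab",
    provenance: dict | None = None,
) -> dict[str, Path]:
    """Write a :class:`FitResult` as JSON + per-mode CSV.

    The JSON carries the flat tensor serialization (components,
    eigen-system, FA, mean diffusivity, units, frame), fit diagnostics, a
    schema version, and a provenance block (package version, config hash,
    any caller-supplied entries).  The CSV mirrors the per-mode table.
    Returns the written paths.
    """
    path = Path(path)
    csv_path = path.with_suffix(".modes.csv")
    table = result.mode_table()
    table.to_csv(csv_path, index=False)

    cfg = {k: getattr(result.config, k) for k in
           ("n_harm", "q_max_cycles_um", "bleach_extent_um",
            "noise_floor_factor", "min_points", "prebleach_floor_frac",
            "fit_offset")}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    payload = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "tensor": result.tensor.to_dict(frame=frame),
        "fa": result.fa,
        "mean_diffusivity": result.mean_diffusivity,
        "covariance": result.covariance.tolist(),
        "diagnostics": _jsonable(result.diagnostics),
        "config": cfg,
        "n_modes": len(result.modes),
        "mode_table_csv": csv_path.name,
        "provenance": {
            "package": "liftfrap",
            "version": _package_version(),
            "config_hash": cfg_hash,
            **(provenance or {}),
        },
    }
    path.write_text(json.dumps(payload, indent=2))
    log.info("wrote %s and %s", path, csv_path)
    return {"json": path, "csv": csv_path}
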