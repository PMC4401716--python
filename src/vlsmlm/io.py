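"""File formats: localization tables, image stacks, calibrations, configs.

Canonical on-disk units are fixed at nm for lengths and photons/um^2 for
amplitudes, so that calibration files are portable between fitting
programs.  Foreign localization tables (any delimited text with a header)
are imported through a :class:`TableSchema` that maps source column names
onto the canonical ones and applies per-column linear unit conversions.

Stacks are multi-page grayscale TIFF; a calibration stack's per-frame
stage z and a simulated stack's ground truth travel in sidecar CSV files
discovered by naming convention (``<stem>.z.csv``, ``<stem>.truth.csv``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import VlsCalibration
from .fitting import LOC_COLUMNS
from .models import CameraModel, FrameStack, GroundTruthEmitter

__all__ = [
    "SchemaError",
    "TableSchema",
    "read_localizations",
    "write_localizations",
    "read_stack",
    "write_stack",
    "save_calibrations",
    "load_calibrations",
    "load_config",
]

CALIBRATION_FORMAT_VERSION = 1

#: canonical columns that a table must provide to be filterable
MANDATORY_COLUMNS = ("x_nm", "y_nm", "sigma_nm", "amplitude_photons_um2")


class SchemaError(ValueError):
    """A foreign table cannot be mapped onto the canonical schema."""


@dataclass(frozen=True)
class TableSchema:
    """Column mapping and unit conversion for importing foreign tables.

    ``columns`` maps canonical names (see :data:`LOC_COLUMNS` plus the
    optional ``true_z_nm``) to source column names; ``converters`` maps
    canonical names to ``(scale, offset)`` pairs applied as
    ``canonical = scale * source + offset`` — e.g. a fitter reporting
    widths in pixels imports with ``{"sigma_nm": (pixel_size, 0.0)}``.
    """

    columns: dict = field(default_factory=dict)
    converters: dict = field(default_factory=dict)

    def source_name(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def read_localizations(path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read a delimited localization table into canonical form.

    The delimiter (comma or tab) is auto-detected; a header row is
    required.  Rows whose mandatory fields fail numeric conversion are
    kept but flagged ``fit_ok=False``.  Missing mandatory columns raise a
    :class:`SchemaError` naming them.
    """
    schema = schema or TableSchema()
    raw = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in MANDATORY_COLUMNS if schema.source_name(c) not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    out = pd.DataFrame(index=raw.index)
    for canonical in LOC_COLUMNS + ["true_z_nm"]:
        source = schema.source_name(canonical)
        if source not in raw.columns:
            continue
        if canonical == "fit_ok":
            out[canonical] = raw[source].astype(bool)
            continue
        col = pd.to_numeric(raw[source], errors="coerce")
        scale, offset = schema.converters.get(canonical, (1.0, 0.0))
        out[canonical] = scale * col + offset
    if "frame" in out.columns:
        out["frame"] = out["frame"].fillna(-1).astype(int)
    bad = out[list(MANDATORY_COLUMNS)].isna().any(axis=1)
    if "fit_ok" not in out.columns:
        out["fit_ok"] = True
    out.loc[bad, "fit_ok"] = False
    ordered = [c for c in LOC_COLUMNS if c in out.columns] + (
        ["true_z_nm"] if "true_z_nm" in out.columns else []
    )
    return out[ordered]


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a canonical localization table as comma-delimited text.

    Full float precision, stable canonical column order, no timestamps:
    identical tables produce byte-identical files.
    """
    cols = [c for c in LOC_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in LOC_COLUMNS
    ]
    table[cols].to_csv(path, index=False)


def _sidecar(path: Path, kind: str) -> Path:
    return path.with_suffix(f".{kind}.csv")


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as 16-bit multi-page TIFF plus sidecar tables."""
    path = Path(path)
    frames = np.clip(stack.frames, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    if stack.z_per_frame is not None:
        pd.DataFrame({"z_nm": stack.z_per_frame}).to_csv(_sidecar(path, "z"), index=False)
    if stack.truth is not None:
        rows = [
            {
                "id": e.id,
                "x_nm": e.x_nm,
                "y_nm": e.y_nm,
                "z_nm": e.z_nm,
                "photons": e.photons,
                "on_frames": (
                    ";".join(str(f) for f in sorted(e.on_frames))
                    if e.on_frames is not None
                    else ""
                ),
            }
            for e in stack.truth
        ]
        pd.DataFrame(rows).to_csv(_sidecar(path, "truth"), index=False)


def read_stack(path, camera: CameraModel | None = None) -> FrameStack:
    """Read a multi-page grayscale TIFF with optional sidecars.

    Raises a format error for RGB or zero-page files; a ``<stem>.z.csv``
    or ``<stem>.truth.csv`` next to the TIFF is attached when present.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise ValueError(f"{path.name}: zero-page TIFF")
        photometric = tif.pages[0].photometric
        if photometric not in (
            tifffile.PHOTOMETRIC.MINISBLACK,
            tifffile.PHOTOMETRIC.MINISWHITE,
        ):
            raise ValueError(
                f"{path.name}: expected a grayscale TIFF, got {photometric.name}"
            )
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a multi-page grayscale TIFF, got shape {frames.shape}"
        )

    z_path = _sidecar(path, "z")
    z_per_frame = None
    if z_path.exists():
        z_per_frame = pd.read_csv(z_path)["z_nm"].to_numpy(dtype=float)
        if len(z_per_frame) != len(frames):
            raise ValueError(
                f"{z_path.name}: {len(z_per_frame)} z entries for {len(frames)} frames"
            )

    truth_path = _sidecar(path, "truth")
    truth = None
    if truth_path.exists():
        ttab = pd.read_csv(truth_path)
        truth = [
            GroundTruthEmitter(
                id=int(row["id"]),
                x_nm=float(row["x_nm"]),
                y_nm=float(row["y_nm"]),
                z_nm=float(row["z_nm"]),
                photons=float(row["photons"]),
                on_frames=(
                    frozenset(int(s) for s in str(row["on_frames"]).split(";"))
                    if isinstance(row.get("on_frames"), str) and row["on_frames"] != ""
                    else None
                ),
            )
            for _, row in ttab.iterrows()
        ]

    return FrameStack(
        frames=frames,
        camera=camera or CameraModel(),
        z_per_frame=z_per_frame,
        truth=truth,
    )


def save_calibrations(modes: dict[str, VlsCalibration], path) -> None:
    """Persist per-mode calibrations as versioned JSON."""
    payload = {
        "format_version": CALIBRATION_FORMAT_VERSION,
        "modes": {name: cal.to_dict() for name, cal in modes.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_calibrations(path) -> dict[str, VlsCalibration]:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != CALIBRATION_FORMAT_VERSION:
        raise ValueError(f"unsupported calibration format version: {version}")
    return {name: VlsCalibration.from_dict(d) for name, d in payload["modes"].items()}


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import yaml

    loaded = yaml.safe_load(text)
    return loaded or {}
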