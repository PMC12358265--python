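"""Manifest and image file I/O.

Manifests are plain CSV with a fixed schema.  2D maps are stored as 32-bit
float TIFF or NPY with a JSON sidecar holding the geometry (ONH centre,
mm-per-pixel); volumes as NPY with a sidecar carrying the axial resolution,
lateral extent and the ILM surface path.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .types import EyeRecord, OCTVolume, TextureEnfaceMap, ThicknessMap

MANIFEST_COLUMNS = [
    "patient_id",
    "eye_id",
    "laterality",
    "diagnosis",
    "age",
    "axial_length",
    "quality",
    "image_path",
]


class ManifestSchemaError(ValueError):
    """A required manifest column is missing or malformed."""


def records_to_frame(records: Iterable[EyeRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[EyeRecord]:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(f"manifest missing required column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            EyeRecord(
                patient_id=str(row.patient_id),
                eye_id=str(row.eye_id),
                laterality=str(row.laterality),
                diagnosis=str(row.diagnosis),
                age=float(row.age),
                axial_length=float(row.axial_length),
                quality=float(row.quality),
                image_path="" if pd.isna(row.image_path) else str(row.image_path),
            )
        )
    ids = [r.eye_id for r in records]
    if len(set(ids)) != len(ids):
        raise ManifestSchemaError("eye_id values must be unique")
    return records


def write_manifest(records: Sequence[EyeRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records)
    # shortest round-trippable repr so floats survive the CSV exactly
    for col in ("age", "axial_length", "quality"):
        df[col] = df[col].map(repr)
    df.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> list[EyeRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str, "eye_id": str}, float_precision="round_trip")
    return frame_to_records(df)


# ---------------------------------------------------------------------------
# Maps


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_map(m: TextureEnfaceMap | ThicknessMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(m.values, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, values)
    elif path.suffix.lower() == ".npy":
        np.save(path, values)
    else:
        raise ValueError(f"unsupported map format {path.suffix!r}")
    meta = {
        "kind": "thickness" if isinstance(m, ThicknessMap) else "texture_enface",
        "onh_center": list(m.onh_center),
        "mm_per_px": list(m.mm_per_px),
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_map(path: str | Path) -> TextureEnfaceMap | ThicknessMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        values = np.load(path)
    else:
        raise ValueError(f"unsupported map format {path.suffix!r}")
    meta = json.loads(_sidecar_path(path).read_text())
    cls = ThicknessMap if meta.get("kind") == "thickness" else TextureEnfaceMap
    return cls(
        values=np.asarray(values, dtype=np.float64),
        onh_center=tuple(meta["onh_center"]),
        mm_per_px=tuple(meta["mm_per_px"]),
    )


# ---------------------------------------------------------------------------
# Volumes


def write_volume(vol: OCTVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, np.asarray(vol.intensities, dtype=np.float32))
    ilm_path = path.with_name(path.stem + "_ilm.npy")
    np.save(ilm_path, np.asarray(vol.ilm, dtype=np.int32))
    meta = {
        "axial_res_um": vol.axial_res_um,
        "mm_extent": vol.mm_extent,
        "ilm_path": ilm_path.name,
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_volume(path: str | Path) -> OCTVolume:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    intensities = np.load(path)
    ilm = np.load(path.with_name(meta["ilm_path"]))
    return OCTVolume(
        intensities=intensities,
        ilm=ilm,
        axial_res_um=float(meta["axial_res_um"]),
        mm_extent=float(meta["mm_extent"]),
    )
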