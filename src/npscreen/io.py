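"""Field-image container, TIFF I/O, plate layouts and the image manifest.

Images are written one grayscale TIFF per channel, named
``<plate>_<well>_r<replicate>_<field>_<channel>.tif``; a ``manifest.csv`` in
the same directory is the authoritative index mapping (plate, well,
replicate, field, channel) to file names, so downstream stages never parse
file names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FieldImage",
    "make_layout",
    "validate_layout",
    "write_field",
    "read_field",
    "write_manifest",
    "read_manifest",
]

LAYOUT_COLUMNS = [
    "plate_id", "well_id", "replicate_id", "treatment_id",
    "gene", "sirna_id", "is_negative_control",
]


@dataclass
class FieldImage:
    """One imaged field: named 2D intensity channels plus identifiers.

    Channels are float arrays of identical shape with non-negative values;
    the canonical channel names are ``nuclei`` (Hoechst), ``lamp1`` (organelle
    marker) and ``np`` (nanoparticle).
    """

    channels: dict[str, np.ndarray]
    plate_id: str = "P1"
    well_id: str = "A01"
    field_id: int = 1
    replicate_id: int = 1
    pixel_size_um: float = 0.16

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if np.any(np.asarray(ch) < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def make_layout(
    treatments: list[str] | dict[str, str],
    n_replicates: int = 3,
    n_neg_wells: int = 4,
    plate_id: str = "P1",
    neg_treatment: str = "NEG",
    sirna_ids: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build a single-plate layout table replicated across experiments.

    ``treatments`` maps treatment_id -> gene (a list means gene == treatment).
    Negative-control wells are appended after the treatment wells; wells are
    assigned row-major in 384-well coordinates (A01..P24, spilling over to a
    second plate id suffix if more than 384 wells are needed).
    """
    if not isinstance(treatments, dict):
        treatments = {t: t for t in treatments}
    entries = [(t, g, False) for t, g in treatments.items()]
    entries += [(neg_treatment, neg_treatment, True)] * max(1, n_neg_wells)

    rows = []
    for rep in range(1, n_replicates + 1):
        for i, (tid, gene, is_neg) in enumerate(entries):
            plate_no, idx = divmod(i, 384)
            r, c = divmod(idx, 24)
            pid = plate_id if plate_no == 0 else f"{plate_id}.{plate_no + 1}"
            rows.append({
                "plate_id": pid,
                "well_id": f"{chr(ord('A') + r)}{c + 1:02d}",
                "replicate_id": rep,
                "treatment_id": tid,
                "gene": gene,
                "sirna_id": (sirna_ids or {}).get(tid, tid),
                "is_negative_control": is_neg,
            })
    layout = pd.DataFrame(rows, columns=LAYOUT_COLUMNS)
    validate_layout(layout)
    return layout


def validate_layout(layout: pd.DataFrame) -> None:
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ValueError(f"layout is missing columns: {missing}")
    key = layout[["plate_id", "well_id", "replicate_id"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (plate, well, replicate) in layout: {dup}")
    for (plate, rep), grp in layout.groupby(["plate_id", "replicate_id"]):
        if not grp["is_negative_control"].any():
            raise ValueError(
                f"no negative-control well on plate {plate!r} replicate {rep}"
            )


def _to_dtype(arr: np.ndarray, bit_depth: int) -> np.ndarray:
    hi = 2 ** bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.clip(np.round(arr), 0, hi).astype(dtype)


def write_field(
    field: FieldImage, outdir: str | Path, bit_depth: int = 16
) -> list[dict]:
    """Write one TIFF per channel; return manifest rows."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, arr in field.channels.items():
        fname = (f"{field.plate_id}_{field.well_id}_r{field.replicate_id}"
                 f"_{field.field_id}_{name}.tif")
        tifffile.imwrite(outdir / fname, _to_dtype(arr, bit_depth))
        rows.append({
            "plate_id": field.plate_id,
            "well_id": field.well_id,
            "replicate_id": field.replicate_id,
            "field_id": field.field_id,
            "channel": name,
            "filename": fname,
        })
    return rows


def write_manifest(rows: list[dict], outdir: str | Path) -> Path:
    path = Path(outdir) / "manifest.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(imagedir: str | Path) -> pd.DataFrame:
    path = Path(imagedir) / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"image manifest not found: {path}")
    return pd.read_csv(path)


def read_field(imagedir: str | Path, manifest_rows: pd.DataFrame,
               pixel_size_um: float = 0.16) -> FieldImage:
    """Assemble a FieldImage from the manifest rows of one (well, field)."""
    imagedir = Path(imagedir)
    channels = {}
    first = manifest_rows.iloc[0]
    for _, row in manifest_rows.iterrows():
        path = imagedir / row["filename"]
        if not path.exists():
            raise FileNotFoundError(f"image file missing: {path}")
        channels[row["channel"]] = tifffile.imread(path).astype(float)
    return FieldImage(
        channels=channels,
        plate_id=str(first["plate_id"]),
        well_id=str(first["well_id"]),
        field_id=int(first["field_id"]),
        replicate_id=int(first["replicate_id"]),
        pixel_size_um=pixel_size_um,
    )
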