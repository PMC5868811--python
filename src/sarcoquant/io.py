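"""Reading and writing of all on-disk artefacts.

Images travel as TIFF / OME-TIFF (channel-first planes), per-fibre tables as
CSV, section summaries and configuration echoes as JSON.  Intensities are
never rescaled on I/O: the arbitrary units recorded by the detector are
preserved end to end, because downstream comparisons (fold changes, percent
reductions) are defined on absolute intensities.

Coordinates are 0-based (row, col) pixel indices; physical quantities (areas,
diameters) are derived with ``pixel_size_um`` and reported in um^2 / um.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

#: Channel roles every pipeline stage understands.
ROLE_MEMBRANE = "membrane"
ROLE_TARGET = "target"

#: Stable column set of the per-fibre table (order is part of the contract).
FIBRE_TABLE_COLUMNS = [
    "fibre_id",
    "sarc_mean_target",
    "cyto_mean_target",
    "corrected_target",
    "sarc_mean_membrane",
    "area_um2",
    "min_feret_um",
    "rim_completeness",
    "flags",
]


@dataclass
class SectionImage:
    """Two registered 2D channels of a transverse muscle section.

    channels
        Mapping of role ("membrane": fibre-identification marker, spectrin or
        laminin; "target": the quantified protein, e.g. dystrophin) to a 2D
        intensity array in arbitrary units.
    pixel_size_um
        Physical pixel size in micrometres per pixel.
    bit_depth
        Camera/scanner bit depth; intensities live in [0, 2**bit_depth - 1].
    provenance
        Free-text metadata (sample id, antibody names, generator seed, ...).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    bit_depth: int = 16
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("SectionImage requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shape mismatch: {sorted(shapes)}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        top = 2**self.bit_depth - 1
        for role, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {role!r} is not a 2D plane")
            if arr.size and (arr.min() < 0 or arr.max() > top):
                raise ValueError(
                    f"channel {role!r} intensities outside [0, {top}] "
                    f"for bit depth {self.bit_depth}"
                )
            self.channels[role] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def membrane(self) -> np.ndarray:
        return self._role(ROLE_MEMBRANE)

    @property
    def target(self) -> np.ndarray:
        return self._role(ROLE_TARGET)

    def _role(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(f"missing channel role {role!r}") from None


def _ome_channel_names(tif: tifffile.TiffFile) -> list[str]:
    """Channel names from OME-XML metadata, if any."""
    xml = tif.ome_metadata
    if not xml:
        return []
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return []
    names = []
    for ch in root.iter():
        if ch.tag.endswith("Channel"):
            names.append(ch.get("Name") or "")
    return names


def _ome_pixel_size(tif: tifffile.TiffFile) -> float | None:
    xml = tif.ome_metadata
    if not xml:
        return None
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            size = el.get("PhysicalSizeX")
            if size is not None:
                return float(size)
    return None


def read_section(
    path: str | Path,
    channel_map: Mapping[str, int | str] | None = None,
    pixel_size_um: float | None = None,
    bit_depth: int | None = None,
) -> SectionImage:
    """Read a multi-plane TIFF / OME-TIFF into a :class:`SectionImage`.

    ``channel_map`` assigns roles to plane indices (int) or OME channel names
    (str).  Defaults to ``{"membrane": 0, "target": 1}``.  Intensities are
    returned exactly as stored.  ``pixel_size_um`` / ``bit_depth`` override
    file metadata; each must be available from one source or the other.
    """
    path = Path(path)
    channel_map = dict(channel_map or {ROLE_MEMBRANE: 0, ROLE_TARGET: 1})
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        names = _ome_channel_names(tif)
        meta_px = _ome_pixel_size(tif)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with shape {data.shape}")
    # channel-first is the written convention; fall back to channel-last
    if data.shape[0] > data.shape[-1] and data.shape[-1] <= 4:
        data = np.moveaxis(data, -1, 0)

    channels: dict[str, np.ndarray] = {}
    for role, key in channel_map.items():
        if isinstance(key, str):
            if key not in names:
                raise ValueError(
                    f"missing channel role {role!r}: no plane named {key!r} "
                    f"(available: {names or 'none'})"
                )
            idx = names.index(key)
        else:
            idx = int(key)
        if idx >= data.shape[0]:
            raise ValueError(
                f"missing channel role {role!r}: plane index {idx} out of "
                f"range for {data.shape[0]} plane(s)"
            )
        channels[role] = data[idx]

    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise ValueError(
            "pixel size not recorded in file metadata; pass pixel_size_um"
        )
    depth = bit_depth
    if depth is None:
        depth = 12 if data.max() <= 4095 and data.dtype == np.uint16 else (
            np.dtype(data.dtype).itemsize * 8 if np.issubdtype(data.dtype, np.integer) else 16
        )
    return SectionImage(channels=channels, pixel_size_um=px, bit_depth=int(depth))


def write_section(section: SectionImage, path: str | Path) -> Path:
    """Write a SectionImage as OME-TIFF with named channels (lossless)."""
    path = Path(path)
    roles = sorted(
        section.channels, key=lambda r: {ROLE_MEMBRANE: 0, ROLE_TARGET: 1}.get(r, 2)
    )
    stack = np.stack([section.channels[r] for r in roles])
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": roles},
            "PhysicalSizeX": section.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": section.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )
    return path


def write_label_map(labels: np.ndarray, path: str | Path) -> Path:
    """Write a fibre label map as single-channel TIFF (0 = background)."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("label map contains negative labels")
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))
    return path


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_fibre_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-fibre table with the stable documented column order."""
    path = Path(path)
    missing = [c for c in FIBRE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fibre table missing columns: {missing}")
    extra = [c for c in table.columns if c not in FIBRE_TABLE_COLUMNS]
    table[FIBRE_TABLE_COLUMNS + extra].to_csv(path, index=False)
    return path


def read_fibre_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_summary(summary, path: str | Path) -> Path:
    """Write a section summary (dataclass or mapping) as JSON."""
    path = Path(path)
    if hasattr(summary, "to_dict"):
        payload = summary.to_dict()
    elif isinstance(summary, Mapping):
        payload = dict(summary)
    else:
        import dataclasses

        payload = dataclasses.asdict(summary)
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    return path


def write_outputs(
    label_map: np.ndarray,
    table: pd.DataFrame,
    summary,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write label map (TIFF), per-fibre table (CSV) and summary (JSON).

    Fibre ids must be consistent: the table must contain exactly one row per
    non-zero label in the map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(label_map)
    map_ids = set(np.unique(labels).tolist()) - {0}
    table_ids = set(int(i) for i in table["fibre_id"]) if len(table) else set()
    if map_ids != table_ids:
        raise ValueError(
            f"fibre id mismatch between label map ({len(map_ids)} ids) and "
            f"table ({len(table_ids)} ids)"
        )
    paths = {
        "label_map": write_label_map(labels, out_dir / "labels.tif"),
        "fibre_table": write_fibre_table(table, out_dir / "fibre_table.csv"),
        "summary": write_summary(summary, out_dir / "summary.json"),
    }
    return paths
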