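"""Image and table I/O: multi-page TIFF stacks, dataset manifests, results tables.

All coordinate and bit-depth conventions live here:

* axis order is ``(z, y, x)``, 0-based; TIFF page order equals ascending z;
* only unsigned-integer 8- or 16-bit grayscale voxels are accepted — float or
  RGB data are rejected rather than silently converted, so that threshold
  semantics stay well-defined;
* the manifest CSV, not filename parsing, is the single source of channel and
  group metadata.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, ParameterError, ValidationError

#: Columns of a dataset manifest, in canonical order.
MANIFEST_COLUMNS = (
    "image_id",
    "group_label",
    "replicate_id",
    "primary_channel",   # "nucleus" or "organelle"
    "organelle_kind",    # Rab5a | Rab7a | Lamp1 | "" for nucleus pairs
    "layout",            # "separate" (one file per channel) or "interleaved"
    "primary_file",
    "pla_file",          # equals primary_file for interleaved layout
)

_CHANNEL_NAMES = frozenset({"nucleus", "pla", "organelle"})


@dataclass
class VolumeChannel:
    """One 3D intensity grid with voxel-spacing metadata.

    Parameters
    ----------
    voxels
        Non-negative integer intensities, shape ``(z, y, x)``.
    z_spacing
        Distance between planes in µm (default 0.5, the acquisition spacing).
    xy_spacing
        In-plane pixel size in µm; informational only — all areas produced by
        the pipelines are voxel counts whose units cancel in ratios.
    bit_depth
        8 or 16 (unsigned).
    channel_name
        One of ``nucleus``, ``pla``, ``organelle``.
    """

    voxels: np.ndarray
    z_spacing: float = 0.5
    xy_spacing: float = 0.1
    bit_depth: int = 8
    channel_name: str = "pla"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"voxels must be 3D (z,y,x); got shape {self.voxels.shape}"
            )
        if self.voxels.shape[0] < 1:
            raise ValidationError("stack needs at least one z-plane")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(self.voxels.dtype, np.unsignedinteger):
            raise FormatError(
                f"voxels must be unsigned integer, got dtype {self.voxels.dtype}"
            )
        if self.voxels.size and int(self.voxels.max()) > self.intensity_max:
            raise ValidationError(
                f"intensity {int(self.voxels.max())} exceeds "
                f"{self.bit_depth}-bit range"
            )
        if self.channel_name not in _CHANNEL_NAMES:
            raise ValidationError(
                f"channel_name must be one of {sorted(_CHANNEL_NAMES)}"
            )

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]


@dataclass
class StackPair:
    """A two-channel acquisition: nucleus-or-organelle primary plus PLA."""

    primary_channel: VolumeChannel
    pla_channel: VolumeChannel
    image_id: str = ""
    group_label: str = ""
    organelle_kind: str | None = None

    def __post_init__(self) -> None:
        if self.primary_channel.shape != self.pla_channel.shape:
            raise ValidationError(
                f"channel shapes differ: primary {self.primary_channel.shape} "
                f"vs pla {self.pla_channel.shape}"
            )
        if self.pla_channel.channel_name != "pla":
            raise ValidationError("second channel must be the PLA channel")
        if self.primary_channel.channel_name not in ("nucleus", "organelle"):
            raise ValidationError("primary channel must be nucleus or organelle")


@dataclass
class DatasetManifest:
    """Tabular description of a dataset: one row per two-channel image.

    Wraps a :class:`pandas.DataFrame` with the columns in
    :data:`MANIFEST_COLUMNS`. ``image_id`` values must be unique and every
    referenced file must resolve (relative paths are resolved against
    ``root``).
    """

    table: pd.DataFrame
    root: str = "."

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        ids = self.table["image_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate image_ids in manifest: {dupes}")
        bad = set(self.table["primary_channel"]) - {"nucleus", "organelle"}
        if bad:
            raise ValidationError(f"unknown primary_channel values: {sorted(bad)}")
        bad_layout = set(self.table["layout"]) - {"separate", "interleaved"}
        if bad_layout:
            raise ValidationError(f"unknown layout values: {sorted(bad_layout)}")

    def __len__(self) -> int:
        return len(self.table)

    def rows(self) -> Iterable[pd.Series]:
        for _, row in self.table.iterrows():
            yield row

    def resolve(self, path: str) -> str:
        return path if os.path.isabs(path) else os.path.join(self.root, path)

    @classmethod
    def from_csv(cls, path: str) -> "DatasetManifest":
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls(table=table, root=os.path.dirname(os.path.abspath(path)))

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))


def _load_pages(path: str) -> np.ndarray:
    """Read a multi-page grayscale TIFF into a (pages, y, x) unsigned array."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"stack file not found: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages, got array of shape {data.shape}"
        )
    if not np.issubdtype(data.dtype, np.unsignedinteger):
        raise FormatError(
            f"{path}: only unsigned 8/16-bit grayscale TIFF accepted, "
            f"got dtype {data.dtype}"
        )
    if data.dtype.itemsize not in (1, 2):
        raise FormatError(f"{path}: unsupported bit depth {8 * data.dtype.itemsize}")
    return data


def _bit_depth_of(data: np.ndarray) -> int:
    return 8 * data.dtype.itemsize


def read_stack_pair(row: Mapping[str, str], root: str = ".") -> StackPair:
    """Build a :class:`StackPair` from one manifest row.

    Supports two file layouts, declared in the manifest: ``separate`` (one
    multi-page TIFF per channel) and ``interleaved`` (a single TIFF whose
    pages alternate primary, pla, primary, pla, ... in ascending z).
    """

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(root, p)

    layout = row["layout"]
    primary_name = row["primary_channel"]
    z_spacing = float(row.get("z_spacing", 0.5) or 0.5)

    if layout == "separate":
        primary = _load_pages(_resolve(row["primary_file"]))
        pla = _load_pages(_resolve(row["pla_file"]))
    elif layout == "interleaved":
        pages = _load_pages(_resolve(row["primary_file"]))
        if pages.shape[0] % 2:
            raise ValidationError(
                f"interleaved stack {row['primary_file']} has an odd page count"
            )
        primary, pla = pages[0::2], pages[1::2]
    else:  # pragma: no cover - manifest validation rejects this earlier
        raise ValidationError(f"unknown layout {layout!r}")

    if primary.shape != pla.shape:
        raise ValidationError(
            f"image {row['image_id']}: channel shapes differ "
            f"({primary.shape} vs {pla.shape})"
        )
    return StackPair(
        primary_channel=VolumeChannel(
            primary, z_spacing=z_spacing, bit_depth=_bit_depth_of(primary),
            channel_name=primary_name,
        ),
        pla_channel=VolumeChannel(
            pla, z_spacing=z_spacing, bit_depth=_bit_depth_of(pla),
            channel_name="pla",
        ),
        image_id=str(row["image_id"]),
        group_label=str(row.get("group_label", "")),
        organelle_kind=str(row.get("organelle_kind", "")) or None,
    )


def write_stack(path: str, voxels: np.ndarray) -> None:
    """Write a (z,y,x) unsigned-integer volume as a multi-page TIFF."""
    voxels = np.asarray(voxels)
    if not np.issubdtype(voxels.dtype, np.unsignedinteger):
        raise FormatError(f"refusing to write non-unsigned dtype {voxels.dtype}")
    tifffile.imwrite(path, voxels, photometric="minisblack")


def write_results_table(results: Sequence, destination: str) -> pd.DataFrame:
    """Serialize per-image result dataclasses to CSV, one row per image.

    Accepts any sequence of dataclasses exposing a ``to_record()`` method
    (``PlaImageResult``, ``OrganelleImageResult``). Numbers are written at
    full precision; the header is the union of record keys in first-seen
    order. Returns the DataFrame that was written.
    """
    if not results:
        raise ParameterError("cannot write an empty results table")
    records = []
    for r in results:
        if hasattr(r, "to_record"):
            records.append(r.to_record())
        elif dataclasses.is_dataclass(r):
            records.append(dataclasses.asdict(r))
        else:
            raise ParameterError(f"unsupported result object {type(r).__name__}")
    frame = pd.DataFrame.from_records(records)
    frame.to_csv(destination, index=False)  # default float repr round-trips
    return frame
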