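"""Streamline and label-volume I/O.

Streamlines travel through the package as ``(N, 3)`` float arrays of world-mm
coordinates (MRtrix TCK convention: scanner RAS, millimetres).  Label volumes
are integer grids with a NIfTI affine.  Voxel indices never leave this module:
every consumer resolves world points to labels through :func:`label_at`.

The TCK format is a text header terminated by ``END`` followed by
little-endian float32 triplets, with an all-NaN triplet separating streamlines
and an all-Inf triplet terminating the stream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TrackSet",
    "LabelVolume",
    "TckParseError",
    "read_tck",
    "write_tck",
    "read_label_volume",
    "write_label_volume",
    "read_parcel_lookup",
    "write_parcel_lookup",
    "label_at",
]

TCK_MAGIC = "mrtrix tracks"

TISSUE_LABELS = {
    "background": 0,
    "white_matter": 1,
    "cortex_left": 2,
    "cortex_right": 3,
    "subcortical": 4,
}

LOBE_GROUPS = ("frontal", "parietal", "temporal", "limbic", "insular", "occipital")


class TckParseError(ValueError):
    """Malformed TCK file; message carries the offending byte offset."""


@dataclass
class TrackSet:
    """An ordered collection of streamlines in one coordinate frame.

    Parameters
    ----------
    streamlines :
        List of ``(N_i, 3)`` float arrays, world mm, ``N_i >= 2``.
    space_id :
        Free-text coordinate-frame tag, e.g. ``"native"`` or ``"MNI"``.
    source_meta :
        Header key/value pairs preserved from the source file.
    """

    streamlines: list[np.ndarray]
    space_id: str = "native"
    source_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.space_id:
            raise ValueError("space_id must be non-empty")
        for i, s in enumerate(self.streamlines):
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(f"streamline {i}: need an (N>=2, 3) point array")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {i}: non-finite coordinates")
            self.streamlines[i] = s

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class LabelVolume:
    """Integer label grid plus world-from-index affine.

    ``role`` is ``"tissue"`` (labels 0..4: background, white matter, left
    cortex, right cortex, subcortical) or ``"parcellation"`` (atlas labels).
    """

    labels: np.ndarray
    affine: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")
        if np.any(self.labels < 0):
            raise ValueError("labels must be nonnegative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.role not in ("tissue", "parcellation"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "tissue" and self.labels.max(initial=0) > 4:
            raise ValueError("tissue labels must be within {0..4}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


# ---------------------------------------------------------------------------
# TCK read / write
# ---------------------------------------------------------------------------

_DTYPE_MAP = {"Float32LE": "<f4", "Float32BE": ">f4"}


def read_tck(path: str | Path) -> TrackSet:
    """Read an MRtrix ``.tck`` streamline file.

    Returns all streamlines in file order with coordinates as stored
    (world mm); header fields are preserved in ``source_meta``.
    """
    path = Path(path)
    raw = path.read_bytes()
    nl = raw.find(b"\n")
    if nl < 0 or raw[:nl].strip() != TCK_MAGIC.encode():
        raise TckParseError(f"{path}: missing '{TCK_MAGIC}' magic at byte 0")
    meta: dict[str, str] = {}
    pos = nl + 1
    data_offset = None
    while True:
        nl = raw.find(b"\n", pos)
        if nl < 0:
            raise TckParseError(f"{path}: header not terminated by END (byte {pos})")
        line = raw[pos:nl].decode("utf-8", errors="replace").strip()
        if line == "END":
            break
        if ":" not in line:
            raise TckParseError(f"{path}: malformed header line at byte {pos}: {line!r}")
        key, _, val = line.partition(":")
        meta[key.strip()] = val.strip()
        pos = nl + 1
    if "file" not in meta:
        raise TckParseError(f"{path}: header lacks 'file' field")
    m = re.match(r"^\.\s+(\d+)$", meta["file"])
    if not m:
        raise TckParseError(f"{path}: unsupported 'file' field {meta['file']!r}")
    data_offset = int(m.group(1))
    dtype = _DTYPE_MAP.get(meta.get("datatype", ""))
    if dtype is None:
        raise TckParseError(
            f"{path}: unsupported datatype {meta.get('datatype')!r} (byte {data_offset})"
        )
    blob = raw[data_offset:]
    if len(blob) % 12:
        raise TckParseError(
            f"{path}: truncated triplet stream at byte {data_offset + len(blob) - len(blob) % 12}"
        )
    pts = np.frombuffer(blob, dtype=dtype).reshape(-1, 3)
    streamlines: list[np.ndarray] = []
    start = 0
    terminated = False
    for i in range(pts.shape[0]):
        if np.all(np.isinf(pts[i])):
            if start < i:
                streamlines.append(pts[start:i].astype(np.float64))
            terminated = True
            break
        if np.all(np.isnan(pts[i])):
            if start < i:
                streamlines.append(pts[start:i].astype(np.float64))
            start = i + 1
    if not terminated and pts.shape[0] > 0:
        raise TckParseError(f"{path}: missing Inf terminator (byte {data_offset})")
    declared = meta.get("count")
    if declared is not None and int(declared) != len(streamlines):
        raise TckParseError(
            f"{path}: header count {declared} != {len(streamlines)} streamlines read"
        )
    return TrackSet(streamlines=streamlines, space_id="native", source_meta=meta)


def write_tck(trackset: TrackSet, path: str | Path) -> None:
    """Write a bit-valid MRtrix ``.tck`` file (Float32LE triplets)."""
    path = Path(path)
    meta = {
        k: v
        for k, v in trackset.source_meta.items()
        if k not in ("file", "datatype", "count")
    }
    lines = [TCK_MAGIC]
    for k, v in meta.items():
        lines.append(f"{k}: {v}")
    lines.append(f"count: {len(trackset.streamlines)}")
    lines.append("datatype: Float32LE")
    # 'file: . <offset>' points into its own file, so the offset depends on
    # the header length including the offset's digits: iterate to fixpoint.
    base = "\n".join(lines) + "\n"
    offset = len(base.encode()) + len("file: . \nEND\n") + 1
    while True:
        header_b = (base + f"file: . {offset}\nEND\n").encode()
        if len(header_b) == offset:
            break
        offset = len(header_b)
    chunks = []
    for s in trackset.streamlines:
        chunks.append(np.asarray(s, dtype="<f4"))
        chunks.append(np.full((1, 3), np.nan, dtype="<f4"))
    chunks.append(np.full((1, 3), np.inf, dtype="<f4"))
    with open(path, "wb") as fh:
        fh.write(header_b)
        fh.write(np.concatenate(chunks).tobytes())


# ---------------------------------------------------------------------------
# NIfTI label volumes and the parcel lookup table
# ---------------------------------------------------------------------------


def read_label_volume(path: str | Path, role: str) -> LabelVolume:
    """Read an integer-label NIfTI volume (tissue or parcellation)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if np.max(np.abs(data - rounded), initial=0.0) > 1e-6:
            raise ValueError(f"{path}: voxel values are not integers (tol 1e-6)")
        data = rounded.astype(np.int32)
    if img.affine is None:
        raise ValueError(f"{path}: NIfTI image lacks an affine")
    return LabelVolume(labels=data.astype(np.int32), affine=img.affine, role=role)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.labels.astype(np.int32), volume.affine)
    nib.save(img, str(path))


def read_parcel_lookup(path: str | Path):
    """Read a parcel lookup TSV (columns: label, name, hemisphere, lobe_group)."""
    import pandas as pd

    lut = pd.read_csv(path, sep="\t")
    required = {"label", "name", "hemisphere", "lobe_group"}
    missing = required - set(lut.columns)
    if missing:
        raise ValueError(f"{path}: lookup missing columns {sorted(missing)}")
    if lut["label"].duplicated().any():
        raise ValueError(f"{path}: duplicate parcel labels")
    return lut


def write_parcel_lookup(lookup, path: str | Path) -> None:
    lookup.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# World -> label lookup
# ---------------------------------------------------------------------------


def label_at(volume: LabelVolume, points: np.ndarray) -> np.ndarray | int:
    """Tissue/parcel label at world-mm point(s), nearest-voxel convention.

    The world point is mapped through the inverse affine and rounded to the
    nearest voxel index (``floor(idx + 0.5)``).  Points falling outside the
    array return 0 (background) by contract.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    inv = np.linalg.inv(volume.affine)
    ijk = pts @ inv[:3, :3].T + inv[:3, 3]
    idx = np.floor(ijk + 0.5).astype(np.int64)
    shape = np.asarray(volume.labels.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(pts), dtype=volume.labels.dtype)
    if inside.any():
        ii = idx[inside]
        out[inside] = volume.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return int(out[0]) if single else out
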