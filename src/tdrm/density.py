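"""Terminal-density computation: per 1 mm^3 voxel and per parcellation piece.

Track density is a raw count of classified streamline terminals: each
validated streamline's two endpoints increment the voxel (or atlas parcel)
that contains them, one channel per fiber class.  In *all-terminals* mode a
projection track contributes both its cortical and its subcortical terminal;
in *cortical-only* mode just the cortical one.  Parcel-level density is the
ratio tracks_amount / piece_volume (terminals per mm^3 of parcel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks_io import LabelVolume, TrackSet, label_at
from .validate_classify import CLASS_ORDER, CORTEX_LABELS

__all__ = [
    "DensityVolume",
    "DensityHistogram",
    "voxel_density",
    "parcel_density",
    "density_histogram",
    "read_density_volume",
    "write_density_volume",
    "CHANNEL_ORDER",
]

CHANNEL_ORDER = CLASS_ORDER  # (projection, commissural, short_assoc, long_assoc)


@dataclass
class DensityVolume:
    """4-channel terminal-count grid (one channel per fiber class)."""

    counts: np.ndarray  # (4, X, Y, Z)
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4 or self.counts.shape[0] != len(CHANNEL_ORDER):
            raise ValueError(f"counts must be ({len(CHANNEL_ORDER)}, X, Y, Z)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.affine = np.asarray(self.affine, dtype=float)

    def channel(self, name: str) -> np.ndarray:
        return self.counts[CHANNEL_ORDER.index(name)]

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class DensityHistogram:
    """Voxel-count frequencies per channel and for the total."""

    edges: np.ndarray
    frequencies: dict[str, np.ndarray]  # keys: channel names + "total"


def _classified_terminals(classified: pd.DataFrame, trackset: TrackSet):
    """World coordinates and class index of every counted terminal."""
    mask = classified["category"].isin(CHANNEL_ORDER).to_numpy()
    idx = classified.loc[mask, "index"].to_numpy()
    if len(idx) == 0:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    cat = classified.loc[mask, "category"].to_numpy()
    chan = np.array([CHANNEL_ORDER.index(c) for c in cat])
    firsts = np.array([trackset.streamlines[i][0] for i in idx])
    lasts = np.array([trackset.streamlines[i][-1] for i in idx])
    points = np.concatenate([firsts, lasts])
    channels = np.concatenate([chan, chan])
    return points, channels


def voxel_density(
    classified: pd.DataFrame,
    trackset: TrackSet,
    tissue: LabelVolume,
    grid: LabelVolume | None = None,
    cortical_only: bool = False,
) -> DensityVolume:
    """Count classified terminals on a 1 mm isotropic voxel grid.

    The grid defaults to the tissue volume's own grid (a warning is raised if
    its spacing is not 1 mm, since track-density is defined per mm^3).  Each
    terminal of each classified streamline increments its class channel at
    the voxel containing it; with ``cortical_only`` the count is restricted
    to terminals whose tissue label is cortex, so a projection track then
    contributes a single terminal.
    """
    ref = grid if grid is not None else tissue
    spacing = np.linalg.norm(ref.affine[:3, :3], axis=0)
    if not np.allclose(spacing, 1.0, atol=1e-6):
        warnings.warn(
            "density grid spacing is not 1 mm; track-density unit is per mm^3",
            stacklevel=2,
        )
    shape = ref.labels.shape
    if min(shape) < 1:
        raise ValueError("degenerate density grid")
    points, channels = _classified_terminals(classified, trackset)
    counts = np.zeros((len(CHANNEL_ORDER),) + tuple(shape), dtype=np.int64)
    if len(points):
        if cortical_only:
            tl = np.asarray(label_at(tissue, points))
            keep = np.isin(tl, CORTEX_LABELS)
            points, channels = points[keep], channels[keep]
        inv = np.linalg.inv(ref.affine)
        ijk = np.floor(points @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(np.int64)
        inside = np.all((ijk >= 0) & (ijk < np.asarray(shape)), axis=1)
        ijk, channels = ijk[inside], channels[inside]
        np.add.at(counts, (channels, ijk[:, 0], ijk[:, 1], ijk[:, 2]), 1)
    return DensityVolume(counts=counts, affine=ref.affine.copy())


def parcel_density(
    classified: pd.DataFrame,
    trackset: TrackSet,
    parcellation: LabelVolume,
    lookup: pd.DataFrame,
    cortical_only: bool = True,
    tissue: LabelVolume | None = None,
) -> pd.DataFrame:
    """Per-parcel terminal counts and relative densities.

    For every atlas parcel: ``tracks_amount_<class>`` is the number of
    terminals of that class whose containing voxel carries the parcel label,
    ``piece_volume_mm3`` the parcel's voxel count times the voxel volume, and
    ``relative_density_<class> = tracks_amount / piece_volume``.  Terminals
    in unlabeled voxels are tallied to an ``unassigned`` row (label 0).  With
    ``cortical_only`` and a tissue volume, terminals outside cortex are
    dropped before assignment.
    """
    points, channels = _classified_terminals(classified, trackset)
    if cortical_only and tissue is not None and len(points):
        tl = np.asarray(label_at(tissue, points))
        keep = np.isin(tl, CORTEX_LABELS)
        points, channels = points[keep], channels[keep]
    plabels = (
        np.asarray(label_at(parcellation, points)) if len(points) else np.empty(0, int)
    )

    voxvol = parcellation.voxel_volume_mm3
    lab_arr, lab_counts = np.unique(parcellation.labels, return_counts=True)
    volume_of = dict(zip(lab_arr.tolist(), (lab_counts * voxvol).tolist()))

    rows = []
    meta = lookup.set_index("label")
    all_labels = list(meta.index) + [0]
    for lab in all_labels:
        if lab == 0:
            name, hemi, lobe = "unassigned", "", ""
        else:
            name = meta.at[lab, "name"]
            hemi = meta.at[lab, "hemisphere"]
            lobe = meta.at[lab, "lobe_group"]
        vol = volume_of.get(lab, 0.0) if lab != 0 else np.nan
        sel = plabels == lab
        row: dict = {
            "label": lab,
            "name": name,
            "hemisphere": hemi,
            "lobe_group": lobe,
            "piece_volume_mm3": vol,
        }
        total_amt = 0
        for ci, cname in enumerate(CHANNEL_ORDER):
            amt = int(np.sum(sel & (channels == ci)))
            total_amt += amt
            row[f"tracks_amount_{cname}"] = amt
            if lab == 0 or vol <= 0:
                row[f"relative_density_{cname}"] = np.nan
            else:
                row[f"relative_density_{cname}"] = amt / vol
        row["tracks_amount_total"] = total_amt
        row["relative_density_total"] = (
            total_amt / vol if (lab != 0 and vol > 0) else np.nan
        )
        if lab != 0 and vol <= 0:
            warnings.warn(f"parcel {lab} ({name}) has zero volume", stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows)


def write_density_volume(volume: DensityVolume, path) -> None:
    """Write the 4-channel counts as a 4D NIfTI (4th dimension = class)."""
    import nibabel as nib

    data = np.moveaxis(volume.counts, 0, -1)
    if np.issubdtype(volume.counts.dtype, np.integer):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, volume.affine)
    img.header["descrip"] = ("channels:" + ",".join(CHANNEL_ORDER))[:79].encode()
    nib.save(img, str(path))


def read_density_volume(path) -> DensityVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != len(CHANNEL_ORDER):
        raise ValueError(f"{path}: expected a 4D volume with {len(CHANNEL_ORDER)} channels")
    return DensityVolume(counts=np.moveaxis(data, -1, 0), affine=img.affine)


def density_histogram(
    volume: DensityVolume,
    n_bins: int | None = None,
    include_zero: bool = False,
) -> DensityHistogram:
    """Frequency of per-voxel terminal counts, per channel and total.

    Zero-count voxels are excluded by default (background dominates any brain
    grid).  With ``n_bins=None`` each integer count gets its own unit bin;
    otherwise counts are histogrammed into ``n_bins`` equal-width bins.
    """
    if n_bins is not None and n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    total = volume.total
    lo = 0 if include_zero else 1
    hi = int(total.max(initial=0))
    if hi < lo:
        edges = np.array([lo, lo + 1], dtype=float)
        empty = np.zeros(1, dtype=np.int64)
        freqs = {name: empty.copy() for name in CHANNEL_ORDER}
        freqs["total"] = empty
        return DensityHistogram(edges=edges, frequencies=freqs)
    if n_bins is None:
        edges = np.arange(lo, hi + 2, dtype=float)
    else:
        edges = np.histogram_bin_edges(np.arange(lo, hi + 1), bins=n_bins)
    freqs = {}
    for ci, name in enumerate(CHANNEL_ORDER):
        ch = volume.counts[ci]
        vals = ch[ch >= lo] if include_zero else ch[ch > 0]
        freqs[name], _ = np.histogram(vals, bins=edges)
    vals = total[total >= lo] if include_zero else total[total > 0]
    freqs["total"], _ = np.histogram(vals, bins=edges)
    return DensityHistogram(edges=edges, frequencies=freqs)
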