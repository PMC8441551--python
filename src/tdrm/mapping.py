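"""Color mapping: exponential intensity transforms, RGB composition and
slice-stacked projection views.

Raw terminal counts follow an exponential-decay histogram, so linear scaling
would leave most of the map near black.  Intensity is therefore mapped as

    v = 1 - exp(-k * density / max_density)

with presets k=30 for voxel-level RGB maps, k=8 for parcel-level RGB maps and
k=2 for grayscale total maps.  Channel assignment for the composite map is
commissural=red, projection=green, association (short+long)=blue; the
association-only map uses short=red, long=green.

3D-like views are produced by a painter's algorithm: slices are stacked along
the viewing axis from the far side toward the viewer, each voxel overwriting
the pixel beneath it iff its pre-transform total density exceeds the minimum
density level (total count > 0 by default), so empty background never paints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .density import CHANNEL_ORDER, DensityVolume
from .tracks_io import LabelVolume

__all__ = [
    "K_VOXEL",
    "K_PARCEL",
    "K_GRAY",
    "VIEWS",
    "RGBVolume",
    "ProjectionImage",
    "intensity",
    "compose_rgb",
    "grayscale_total",
    "render_parcel_map",
    "stack_projection",
    "save_png",
]

K_VOXEL = 30.0  # voxel-based ratio density mapping
K_PARCEL = 8.0  # parcellation-based ratio density mapping
K_GRAY = 2.0    # grayscaled total density mapping

VIEWS = (
    "superior",
    "inferior",
    "anterior",
    "posterior",
    "left-lateral",
    "right-lateral",
    "medial-L",
    "medial-R",
)


def intensity(density, dmax: float, k: float):
    """Exponential contrast transform ``1 - exp(-k * density / dmax)``.

    Maps density 0 to 0 and density == dmax to ``1 - e^(-k)``; strictly
    increasing in density and invariant under joint rescaling of density and
    dmax.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive (empty maps are the caller's case)")
    if k <= 0:
        raise ValueError("k must be positive")
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be nonnegative")
    out = 1.0 - np.exp(-k * d / dmax)
    return float(out) if np.isscalar(density) else out


@dataclass
class RGBVolume:
    """3-channel float volume in [0, 1] with its channel assignment record."""

    rgb: np.ndarray  # (3, X, Y, Z)
    affine: np.ndarray
    assignment: dict[str, str]
    total_density: np.ndarray = field(default=None, repr=False)  # pre-transform

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 4 or self.rgb.shape[0] != 3:
            raise ValueError("rgb must be (3, X, Y, Z)")
        if np.any(self.rgb < 0) or np.any(self.rgb > 1):
            raise ValueError("rgb channels must lie in [0, 1]")
        if self.total_density is None:
            self.total_density = np.zeros(self.rgb.shape[1:])


def _channel_stack(volume: DensityVolume, mode: str):
    """Composed channel images and assignment for a display mode."""
    assoc = volume.channel("short_assoc") + volume.channel("long_assoc")
    if mode == "fiber":
        chans = [volume.channel("commissural"), volume.channel("projection"), assoc]
        assignment = {"R": "commissural", "G": "projection", "B": "association"}
    elif mode == "association":
        chans = [
            volume.channel("short_assoc"),
            volume.channel("long_assoc"),
            np.zeros_like(assoc),
        ]
        assignment = {"R": "short_assoc", "G": "long_assoc", "B": "none"}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [np.asarray(c, dtype=float) for c in chans], assignment


def compose_rgb(
    volume: DensityVolume,
    k: float = K_VOXEL,
    dmax_mode: str = "global",
    mode: str = "fiber",
) -> RGBVolume:
    """Density volume -> RGB volume through the intensity transform.

    ``dmax_mode="global"`` (default) resolves max_density as the maximum over
    all composed channels and voxels, preserving cross-class comparability;
    ``"per_channel"`` normalizes each channel by its own maximum.  An
    all-zero volume yields an all-zero image with a warning.
    """
    chans, assignment = _channel_stack(volume, mode)
    global_max = max(float(c.max(initial=0.0)) for c in chans)
    if global_max <= 0:
        warnings.warn("all-zero density volume; rendering a black image", stacklevel=2)
        rgb = np.zeros((3,) + chans[0].shape)
    else:
        out = []
        for c in chans:
            if dmax_mode == "global":
                dmax = global_max
            elif dmax_mode == "per_channel":
                dmax = float(c.max(initial=0.0)) or global_max
            else:
                raise ValueError(f"unknown dmax_mode {dmax_mode!r}")
            out.append(intensity(c, dmax, k))
        rgb = np.stack(out)
    return RGBVolume(
        rgb=rgb,
        affine=volume.affine.copy(),
        assignment=assignment,
        total_density=np.asarray(volume.total, dtype=float),
    )


def grayscale_total(volume: DensityVolume, k: float = K_GRAY) -> RGBVolume:
    """Grayscale total-density map (R = G = B, intensity of the channel sum)."""
    total = np.asarray(volume.total, dtype=float)
    dmax = float(total.max(initial=0.0))
    if dmax <= 0:
        warnings.warn("all-zero density volume; rendering a black image", stacklevel=2)
        gray = np.zeros_like(total)
    else:
        gray = intensity(total, dmax, k)
    return RGBVolume(
        rgb=np.stack([gray, gray, gray]),
        affine=volume.affine.copy(),
        assignment={"R": "total", "G": "total", "B": "total"},
        total_density=total,
    )


def render_parcel_map(
    table: pd.DataFrame,
    parcellation: LabelVolume,
    k: float = K_PARCEL,
    dmax_mode: str = "global",
    mode: str = "fiber",
) -> RGBVolume:
    """Paint each parcel with its relative densities pushed through intensity.

    max_density is the maximum relative density over parcels (global across
    the composed channels by default).  Parcels present in the table but
    missing from the volume trigger a warning; volume labels missing from the
    table stay black.
    """
    parcel_rows = table[table["label"] != 0]
    labels_in_volume = set(np.unique(parcellation.labels).tolist()) - {0}
    missing = set(parcel_rows["label"].tolist()) - labels_in_volume
    if missing:
        warnings.warn(
            f"table labels missing from parcellation volume: {sorted(missing)}",
            stacklevel=2,
        )

    if mode == "fiber":
        cols = [
            "relative_density_commissural",
            "relative_density_projection",
            None,  # association = short + long, filled below
        ]
        assignment = {"R": "commissural", "G": "projection", "B": "association"}
    elif mode == "association":
        cols = ["relative_density_short_assoc", "relative_density_long_assoc", None]
        assignment = {"R": "short_assoc", "G": "long_assoc", "B": "none"}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # per-parcel composed densities
    dens = {}
    for _, row in parcel_rows.iterrows():
        assoc = (
            row["relative_density_short_assoc"] + row["relative_density_long_assoc"]
        )
        if mode == "fiber":
            vals = [row[cols[0]], row[cols[1]], assoc]
        else:
            vals = [row[cols[0]], row[cols[1]], 0.0]
        dens[int(row["label"])] = np.nan_to_num(np.asarray(vals, dtype=float))

    arr = np.stack([np.stack(list(v)) for v in dens.values()]) if dens else np.zeros((1, 3))
    global_max = float(arr.max(initial=0.0))
    shape = parcellation.labels.shape
    rgb = np.zeros((3,) + shape)
    total_density = np.zeros(shape)
    if global_max > 0:
        per_channel_max = arr.max(axis=0)
        for lab, vals in dens.items():
            mask = parcellation.labels == lab
            if not mask.any():
                continue
            for ci in range(3):
                if dmax_mode == "global":
                    dmax = global_max
                elif dmax_mode == "per_channel":
                    dmax = float(per_channel_max[ci]) or global_max
                else:
                    raise ValueError(f"unknown dmax_mode {dmax_mode!r}")
                rgb[ci][mask] = intensity(float(vals[ci]), dmax, k)
            total_density[mask] = float(vals.sum())
    else:
        warnings.warn("all-zero parcel table; rendering a black image", stacklevel=2)
    return RGBVolume(
        rgb=rgb,
        affine=parcellation.affine.copy(),
        assignment=assignment,
        total_density=total_density,
    )


@dataclass
class ProjectionImage:
    """A 2D slice-stacked view; pixels in [0, 1], channels last."""

    pixels: np.ndarray  # (H, W, 3)
    view: str
    axis: int
    direction: int  # +1: ascending slice order, -1: descending


# view -> (world axis index, traversal sign, hemisphere mask sign or None);
# traversal runs far-side -> viewer so nearer slices overwrite.
_VIEW_SPEC = {
    "superior": (2, +1, None),
    "inferior": (2, -1, None),
    "anterior": (1, +1, None),
    "posterior": (1, -1, None),
    "right-lateral": (0, +1, None),
    "left-lateral": (0, -1, None),
    "medial-L": (0, +1, -1),  # left hemisphere (world x < 0), viewed from midline
    "medial-R": (0, -1, +1),
}


def _array_axis_for(affine: np.ndarray, world_axis: int) -> tuple[int, int]:
    """Array axis (and its world direction sign) best aligned with a world axis."""
    M = affine[:3, :3]
    ax = int(np.argmax(np.abs(M[world_axis, :])))
    sign = int(np.sign(M[world_axis, ax]) or 1)
    return ax, sign


def stack_projection(
    volume: RGBVolume, view: str, min_density: float = 0.0
) -> ProjectionImage:
    """Painter's-algorithm projection of an RGB volume along a view axis.

    Slices are traversed from the far side toward the viewer; a voxel paints
    its pixel iff its pre-transform total density exceeds ``min_density``.
    Unpainted pixels stay black.  Medial views mask to one hemisphere (by the
    world-x sign of voxel centers) and stack outward from the lateral side so
    the midline face is what remains visible.
    """
    if view not in _VIEW_SPEC:
        raise ValueError(f"unknown view {view!r}; choose from {VIEWS}")
    world_axis, world_dir, hemi_sign = _VIEW_SPEC[view]
    ax, axis_sign = _array_axis_for(volume.affine, world_axis)
    ascending = world_dir * axis_sign > 0

    rgb = np.moveaxis(volume.rgb, 0, -1)  # (X, Y, Z, 3)
    total = volume.total_density
    if hemi_sign is not None:
        shape = total.shape
        idx = np.indices(shape).reshape(3, -1).T.astype(float)
        worldx = (idx @ volume.affine[:3, :3].T + volume.affine[:3, 3])[:, 0]
        mask = (worldx * hemi_sign > 0).reshape(shape)
        total = np.where(mask, total, 0.0)

    n = rgb.shape[ax]
    order = range(n) if ascending else range(n - 1, -1, -1)
    img_shape = tuple(s for i, s in enumerate(total.shape) if i != ax)
    img = np.zeros(img_shape + (3,))
    for i in order:
        sl_rgb = np.take(rgb, i, axis=ax)
        sl_tot = np.take(total, i, axis=ax)
        paint = sl_tot > min_density
        img[paint] = sl_rgb[paint]
    return ProjectionImage(
        pixels=img, view=view, axis=ax, direction=+1 if ascending else -1
    )


def save_png(image: ProjectionImage, path) -> None:
    """Write an 8-bit PNG (values round(255 * v))."""
    arr = np.clip(np.round(255.0 * image.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(str(path), format="PNG")
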