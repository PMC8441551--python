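"""Synthetic brain phantom with known fiber-class ground truth.

The phantom emulates the compartment structure the classifier relies on: two
hemispheric cortical shells separated by an interhemispheric fissure at the
midline plane x=0, white matter filling each hemisphere interior, and a
central subcortical blob straddling the midline.  Streamlines are generated
class-by-class by sampling terminal voxels inside the compartments that
define the class (projection: cortex<->subcortical; commissural: left
cortex<->right cortex; associations: two same-hemisphere cortical terminals
with arc length forced below / at-or-above 60 mm), plus planted rejects
(noise tracks ending in white matter, ineffective tracks ending
subcortical<->subcortical).  Class membership is encoded purely by terminal
compartments and length — never by metadata — so the downstream classifier
is tested blind.

Paths are jittered polylines through deep white matter, resampled at 0.2 mm
steps (the step size of the probabilistic tractography the phantom stands in
for), and fully deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tracks_io import LOBE_GROUPS, LabelVolume, TrackSet

__all__ = [
    "PhantomSpec",
    "PhantomScene",
    "build_phantom_tissue",
    "generate_tracks",
    "build_phantom",
]

STEP_MM = 0.2          # resampling step, matches tractography step size
CORTEX_THICKNESS_MM = 2.5
TRUTH_CLASSES = (
    "projection",
    "commissural",
    "short_assoc",
    "long_assoc",
    "noise_wm",
    "ineffective",
)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic scene.

    counts maps each truth class (``projection``, ``commissural``,
    ``short_assoc``, ``long_assoc``, ``noise_wm``, ``ineffective``) to a
    nonnegative streamline count.  The grid uses 1 mm isotropic voxels.
    """

    grid_shape: tuple[int, int, int] = (80, 80, 80)
    counts: dict[str, int] = field(default_factory=dict)
    n_parcels_per_hemisphere: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(TRUTH_CLASSES)
        if unknown:
            raise ValueError(f"unknown phantom classes: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        if self.n_parcels_per_hemisphere < 1:
            raise ValueError("need at least one parcel per hemisphere")


@dataclass
class PhantomScene:
    """A complete synthetic dataset: volumes, streamlines and ground truth."""

    tissue: LabelVolume
    parcellation: LabelVolume
    lookup: pd.DataFrame
    tracks: TrackSet
    truth: list[str]


def _scene_geometry(shape):
    """World coordinates, ellipsoid radii and label thresholds for a grid."""
    shape = np.asarray(shape)
    if np.any(shape < 20):
        raise ValueError("grid too small: need >= 20 voxels per axis")
    # voxel centers at ijk - (shape-1)/2 -> midline plane x=0 between columns
    offset = -(shape - 1) / 2.0
    affine = np.eye(4)
    affine[:3, 3] = offset
    radii = 0.9 * (shape - 1) / 2.0
    rho_cortex = 1.0 - CORTEX_THICKNESS_MM / radii.min()
    r_subcortical = 0.2 * radii.min()
    return affine, radii, rho_cortex, r_subcortical


def build_phantom_tissue(spec: PhantomSpec):
    """Build the tissue and parcellation label volumes plus the lookup table.

    Returns ``(tissue, parcellation, lookup)``.  The cortex is an ellipsoidal
    shell ~2.5 mm thick split by a 2-voxel interhemispheric fissure; the
    parcellation tiles each hemisphere's shell into contiguous angular
    wedges around the left-right axis, with a cyclic lobe-group assignment.
    """
    affine, radii, rho_cortex, r_sub = _scene_geometry(spec.grid_shape)
    shape = tuple(spec.grid_shape)
    ii, jj, kk = np.indices(shape)
    x = ii + affine[0, 3]
    y = jj + affine[1, 3]
    z = kk + affine[2, 3]
    rho = np.sqrt((x / radii[0]) ** 2 + (y / radii[1]) ** 2 + (z / radii[2]) ** 2)
    r = np.sqrt(x**2 + y**2 + z**2)
    off_midline = np.abs(x) > 0.6

    labels = np.zeros(shape, dtype=np.int32)
    wm = (rho < rho_cortex) & off_midline
    labels[wm] = 1
    cortex = (rho >= rho_cortex) & (rho < 1.0) & off_midline
    labels[cortex & (x < 0)] = 2
    labels[cortex & (x > 0)] = 3
    labels[r < r_sub] = 4  # central blob wins, straddles the midline
    present = set(np.unique(labels).tolist())
    if present != {0, 1, 2, 3, 4}:
        raise ValueError(f"degenerate phantom: tissue labels {sorted(present)}")
    tissue = LabelVolume(labels=labels, affine=affine, role="tissue")

    # angular wedges around the x-axis: contiguous rings of the shell
    n = spec.n_parcels_per_hemisphere
    theta = np.arctan2(z, y)  # (-pi, pi]
    sector = np.clip(((theta + np.pi) / (2 * np.pi) * n).astype(int), 0, n - 1)
    parc = np.zeros(shape, dtype=np.int32)
    left = labels == 2
    right = labels == 3
    parc[left] = 2 * sector[left] + 1   # odd labels: left hemisphere
    parc[right] = 2 * sector[right] + 2  # even labels: right hemisphere
    parcellation = LabelVolume(labels=parc, affine=affine, role="parcellation")

    rows = []
    for i in range(n):
        lobe = LOBE_GROUPS[i % len(LOBE_GROUPS)]
        rows.append((2 * i + 1, f"parcel_{i + 1:03d}", "L", lobe))
        rows.append((2 * i + 2, f"parcel_{i + 1:03d}", "R", lobe))
    lookup = pd.DataFrame(rows, columns=["label", "name", "hemisphere", "lobe_group"])
    return tissue, parcellation, lookup


# ---------------------------------------------------------------------------
# streamline generation
# ---------------------------------------------------------------------------


def _voxel_centers(volume: LabelVolume, label: int) -> np.ndarray:
    idx = np.argwhere(volume.labels == label).astype(float)
    return idx + volume.affine[:3, 3]


def _resample(points: np.ndarray, step: float = STEP_MM) -> np.ndarray:
    """Resample a polyline at fixed arc-length steps; endpoints exact.

    The resampled points lie on the original polyline, so total arc length
    is preserved.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(np.ceil(total / step)), 1)
    t = np.linspace(0.0, total, n + 1)
    out = np.column_stack([np.interp(t, cum, points[:, a]) for a in range(3)])
    out[0], out[-1] = points[0], points[-1]
    return out


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


class _TrackFactory:
    """Samples class-consistent terminal pairs and builds jittered paths."""

    def __init__(self, tissue: LabelVolume, rng: np.random.Generator):
        self.tissue = tissue
        self.rng = rng
        _, self.radii, self.rho_cortex, self.r_sub = _scene_geometry(
            tissue.labels.shape
        )
        self.pools = {lab: _voxel_centers(tissue, lab) for lab in (1, 2, 3, 4)}
        for lab, pool in self.pools.items():
            if len(pool) == 0:
                raise ValueError(f"tissue label {lab} has no voxels")
        self.trees = {lab: cKDTree(self.pools[lab]) for lab in (2, 3)}

    def _rho(self, p: np.ndarray) -> float:
        return float(np.sqrt(np.sum((p / self.radii) ** 2)))

    def _at_rho(self, p: np.ndarray, rho_target: float) -> np.ndarray:
        """Point on the ray through p scaled to normalized radius rho_target."""
        rho = self._rho(p)
        if rho < 1e-9:
            return p.copy()
        return p * (rho_target / rho)

    def _pick(self, label: int) -> np.ndarray:
        pool = self.pools[label]
        return pool[self.rng.integers(len(pool))].copy()

    def _jitter(self, controls: np.ndarray) -> np.ndarray:
        """Perturb interior control points; endpoints stay voxel-exact."""
        if len(controls) > 2:
            controls = controls.copy()
            controls[1:-1] += self.rng.normal(0.0, 0.6, size=(len(controls) - 2, 3))
        return controls

    def _deep_path(self, a: np.ndarray, b: np.ndarray, dip: float) -> np.ndarray:
        """Controls a -> dip shell -> b, pushed off the subcortical blob."""
        qa = self._at_rho(a, dip)
        qb = self._at_rho(b, dip)
        mid = (qa + qb) / 2.0
        floor_rho = (self.r_sub + 3.0) / self.radii.min()
        if self._rho(mid) < floor_rho:
            mid = self._at_rho(mid + 1e-6, min(floor_rho + 0.1, 0.8))
        return np.array([a, qa, mid, qb, b])

    # -- one builder per truth class ------------------------------------

    def projection(self) -> np.ndarray:
        a = self._pick(self.rng.choice([2, 3]))
        b = self._pick(4)
        qa = self._at_rho(a, 0.6)
        return self._jitter(np.array([a, qa, b]))

    def commissural(self) -> np.ndarray:
        a, b = self._pick(2), self._pick(3)
        return self._jitter(self._deep_path(a, b, dip=0.6))

    def short_assoc(self, max_chord: float = 40.0) -> np.ndarray:
        hemi = int(self.rng.choice([2, 3]))
        pool, tree = self.pools[hemi], self.trees[hemi]
        for _ in range(50):
            a = pool[self.rng.integers(len(pool))]
            near = tree.query_ball_point(a, max_chord)
            b = pool[near[self.rng.integers(len(near))]]
            if np.linalg.norm(a - b) < 2.0:
                continue
            dip = max(self.rho_cortex - 0.08, 0.3)
            controls = self._jitter(
                np.array([a, self._at_rho(a, dip), self._at_rho(b, dip), b])
            )
            if _polyline_length(controls) < 56.0:
                return controls
        # straight chord fallback: length = |a-b| <= max_chord < 60
        while np.linalg.norm(a - b) < 1.0:
            b = pool[self.rng.integers(len(pool))]
        return np.array([a, (a + b) / 2.0, b])

    def long_assoc(self) -> np.ndarray:
        hemi = int(self.rng.choice([2, 3]))
        pool = self.pools[hemi]
        a = pool[self.rng.integers(len(pool))]
        b = pool[self.rng.integers(len(pool))]
        while np.linalg.norm(a - b) < 5.0:
            b = pool[self.rng.integers(len(pool))]
        base = self._jitter(self._deep_path(a, b, dip=0.65))
        if _polyline_length(base) >= 62.0:
            return base
        # inflate with a tangential zigzag between the dip points until the
        # arc crosses the long-association threshold with margin
        qa, qb = base[1], base[-2]
        chord = qb - qa
        d = np.linalg.norm(chord)
        mid_r = (qa + qb) / 2.0
        u = np.cross(chord, mid_r if np.linalg.norm(mid_r) > 1.0 else chord + [0.1, 1, 0])
        if np.linalg.norm(u) < 1e-6:  # chord parallel to the radial direction
            u = np.cross(chord, [0.0, 1.0, 0.0])
            if np.linalg.norm(u) < 1e-6:
                u = np.cross(chord, [1.0, 0.0, 0.0])
        u = u / max(np.linalg.norm(u), 1e-9)
        m = max(8, int(d))
        amp = 2.0
        for _ in range(60):
            t = np.linspace(0, 1, m + 2)[1:-1, None]
            zig = qa + t * chord + u * amp * (-1) ** np.arange(m)[:, None]
            controls = np.vstack([base[0], qa, zig, qb, base[-1]])
            if _polyline_length(controls) >= 62.0:
                return controls
            amp *= 1.4
        raise ValueError("long association track infeasible on this grid")

    def noise_wm(self) -> np.ndarray:
        a, b = self._pick(1), self._pick(1)
        while np.linalg.norm(a - b) < 2.0:
            b = self._pick(1)
        return self._jitter(self._deep_path(a, b, dip=min(self._rho(a), 0.7)))

    def ineffective(self) -> np.ndarray:
        a, b = self._pick(4), self._pick(4)
        while np.linalg.norm(a - b) < 1.0:
            b = self._pick(4)
        return np.array([a, (a + b) / 2.0, b])


def generate_tracks(spec: PhantomSpec, tissue: LabelVolume):
    """Generate the phantom streamlines and their ground-truth classes.

    Returns ``(TrackSet, truth)`` where ``truth[i]`` names the intended class
    or rejection reason of streamline ``i``.  Deterministic under
    ``spec.seed``; terminal points sit exactly on voxel centers of the
    defining compartments so ground truth is self-consistent by construction.
    """
    rng = np.random.default_rng(spec.seed)
    factory = _TrackFactory(tissue, rng)
    streamlines: list[np.ndarray] = []
    truth: list[str] = []
    for cls in TRUTH_CLASSES:
        builder = getattr(factory, cls)
        for _ in range(spec.counts.get(cls, 0)):
            controls = builder()
            streamlines.append(_resample(controls))
            truth.append(cls)
    tracks = TrackSet(
        streamlines=streamlines,
        space_id="phantom",
        source_meta={"phantom_seed": str(spec.seed)},
    )
    return tracks, truth


def build_phantom(spec: PhantomSpec) -> PhantomScene:
    """Convenience wrapper: volumes, lookup, tracks and truth in one scene."""
    tissue, parcellation, lookup = build_phantom_tissue(spec)
    tracks, truth = generate_tracks(spec, tissue)
    return PhantomScene(
        tissue=tissue,
        parcellation=parcellation,
        lookup=lookup,
        tracks=tracks,
        truth=truth,
    )
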