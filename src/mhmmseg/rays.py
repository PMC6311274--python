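"""Cross-sectional ray sampling along a vessel axis.

Each axis point defines a cross-section plane orthogonal to the local
tangent. Rays fan out from the axis point every ``angular_step_deg`` degrees
(72 rays at the default 5°) and along each ray 18 samples are collected at a
fixed radial step, forming the voxel series the HMMs consume. Tissue labels
along a ray follow the outward transition lumen → intima → {pathology,
adventitia}; the intima class is produced by stripping the outermost 2–4
vessel samples before the first non-vessel sample.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume

__all__ = [
    "STATE_NAMES",
    "VesselAxis",
    "Ray",
    "VoxelSeries",
    "RayBoundsError",
    "cross_section_frame",
    "parallel_frames",
    "cast_rays",
    "sample_series",
    "label_series",
    "wall_thickness_for_radius",
    "build_series_table",
    "read_axes_json",
    "write_axes_json",
]

#: HMM state order: T1..T4.
STATE_NAMES = ("lumen", "intima", "pathology", "adventitia")
LUMEN, INTIMA, PATHOLOGY, ADVENTITIA = range(4)

#: Default samples per ray.
N_SAMPLES = 18


class RayBoundsError(ValueError):
    """A ray sample falls outside the volume grid."""


@dataclass
class VesselAxis:
    """Ordered polyline of axis points (world mm) with unit tangents."""

    points: np.ndarray
    tangents: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("axis needs >= 2 three-dimensional points")
        seg = np.diff(self.points, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0):
            raise ValueError("consecutive axis points must be distinct")
        if self.tangents is None:
            t = np.gradient(self.points, axis=0)
            norm = np.linalg.norm(t, axis=1, keepdims=True)
            if np.any(norm == 0):
                raise ValueError("zero tangent on axis")
            self.tangents = t / norm
        else:
            self.tangents = np.asarray(self.tangents, dtype=float)
            norms = np.linalg.norm(self.tangents, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("tangents must be unit-norm")
        self._frames: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> np.ndarray:
        """Parallel-transported in-plane frames, shape (n, 2, 3)."""
        if self._frames is None:
            self._frames = parallel_frames(self)
        return self._frames

    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class Ray:
    """A single cast ray: origin at the axis point, unit direction in-plane."""

    origin: np.ndarray
    direction: np.ndarray
    n_samples: int = N_SAMPLES
    step_mm: float = 1.0
    axis_index: int = 0
    angle_deg: float = 0.0

    @property
    def points(self) -> np.ndarray:
        j = np.arange(self.n_samples)[:, None]
        return self.origin[None, :] + j * self.step_mm * self.direction[None, :]


@dataclass
class VoxelSeries:
    """Ordered samples along one ray: positions, intensities, optional labels."""

    ray_id: tuple[int, float]
    positions: np.ndarray
    intensities: np.ndarray
    step_mm: float
    labels: np.ndarray | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities length mismatch")


def parallel_frames(axis: VesselAxis) -> np.ndarray:
    """Parallel-transport an in-plane orthonormal frame along the axis.

    Avoids the frame flips a Frenet frame exhibits at inflection points: the
    previous in-plane vector is projected onto each new cross-section plane
    and renormalized.
    """
    t = axis.tangents
    n = len(axis)
    frames = np.empty((n, 2, 3))
    # seed: coordinate axis least aligned with the first tangent
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(t[0])))] = 1.0
    u = seed - np.dot(seed, t[0]) * t[0]
    u /= np.linalg.norm(u)
    for i in range(n):
        if i > 0:
            u = u - np.dot(u, t[i]) * t[i]
            norm = np.linalg.norm(u)
            if norm < 1e-12:  # 90° kink; fall back to a fresh seed
                seed = np.zeros(3)
                seed[int(np.argmin(np.abs(t[i])))] = 1.0
                u = seed - np.dot(seed, t[i]) * t[i]
                norm = np.linalg.norm(u)
            u = u / norm
        v = np.cross(t[i], u)
        frames[i, 0] = u
        frames[i, 1] = v
    return frames


def cross_section_frame(axis: VesselAxis, index: int) -> tuple[np.ndarray, np.ndarray]:
    """Two in-plane unit vectors orthogonal to the tangent at ``index``."""
    if not 0 <= index < len(axis):
        raise IndexError(f"axis index {index} out of range")
    if np.linalg.norm(axis.tangents[index]) == 0:
        raise ValueError(f"zero tangent at axis index {index}")
    u, v = axis.frames[index]
    return u, v


def cast_rays(
    frame: tuple[np.ndarray, np.ndarray],
    origin: np.ndarray,
    angular_step_deg: float = 5.0,
    n_samples: int = N_SAMPLES,
    step_mm: float = 1.0,
    axis_index: int = 0,
) -> list[Ray]:
    """Rays every ``angular_step_deg`` degrees in the cross-section plane."""
    if 360.0 % angular_step_deg != 0:
        raise ValueError(f"angular step {angular_step_deg} must divide 360")
    u, v = frame
    angles = np.arange(0.0, 360.0, angular_step_deg)
    rays = []
    for ang in angles:
        rad = np.deg2rad(ang)
        d = np.cos(rad) * u + np.sin(rad) * v
        rays.append(
            Ray(np.asarray(origin, dtype=float), d, n_samples, step_mm,
                axis_index, float(ang))
        )
    return rays


def _check_bounds(volume: Volume, idx: np.ndarray, ray: Ray) -> None:
    shape = np.asarray(volume.shape)
    bad = np.any((idx < -0.5) | (idx > shape - 0.5), axis=1)
    if np.any(bad):
        j = int(np.argmax(bad))
        raise RayBoundsError(
            f"ray (axis {ray.axis_index}, angle {ray.angle_deg}°) sample {j} "
            f"at index {idx[j]} outside volume of shape {tuple(volume.shape)}"
        )


def sample_series(volume: Volume, ray: Ray) -> VoxelSeries:
    """Trilinear intensity samples at the ray's points."""
    pts = ray.points
    idx = volume.world_to_index(pts)
    _check_bounds(volume, idx, ray)
    vals = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), idx.T, order=1, mode="nearest"
    )
    return VoxelSeries((ray.axis_index, ray.angle_deg), pts, vals, ray.step_mm)


def _sample_labels_raw(labels: Volume, ray: Ray) -> np.ndarray:
    idx = labels.world_to_index(ray.points)
    _check_bounds(labels, idx, ray)
    return ndimage.map_coordinates(
        np.asarray(labels.data), np.round(idx).T.astype(int), order=0, mode="nearest"
    )


def label_series(
    labels: Volume, ray: Ray, wall_thickness_vox: int
) -> tuple[np.ndarray, bool]:
    """Tissue-state sequence for one ray, with the intima stripping rule.

    The label volume uses 0=background, 1=lumen, 2=intima, 3=pathology;
    "vessel" is 1 or 2. Along the ray, the last ``wall_thickness_vox``
    consecutive vessel samples before the first non-vessel sample become
    intima, the earlier vessel samples lumen; past the boundary, samples keep
    pathology or become adventitia. Returns (state sequence in 0..3, valid):
    ``valid`` is False when the first sample is not vessel (the axis is
    assumed inside the lumen) or when vessel reappears after the boundary
    (the outward path must never return to lumen).
    """
    if wall_thickness_vox not in (2, 3, 4):
        raise ValueError(f"wall thickness must be 2, 3 or 4, got {wall_thickness_vox}")
    raw = _sample_labels_raw(labels, ray)
    n = len(raw)
    vessel = (raw == 1) | (raw == 2)
    states = np.empty(n, dtype=np.int8)
    valid = bool(vessel[0])

    nonvessel = np.flatnonzero(~vessel)
    if len(nonvessel) == 0:  # ray never leaves the vessel: no boundary present
        states[:] = LUMEN
        return states, valid
    b = int(nonvessel[0])
    k = min(wall_thickness_vox, b)
    states[:b - k] = LUMEN
    states[b - k:b] = INTIMA
    tail = raw[b:]
    states[b:] = np.where(tail == 3, PATHOLOGY, ADVENTITIA)
    if np.any((tail == 1) | (tail == 2)):  # vessel after boundary: backwards path
        valid = False
        states[b:][(tail == 1) | (tail == 2)] = ADVENTITIA
    return states, valid


def ray_grid(
    axis: VesselAxis,
    indices: np.ndarray | None = None,
    angular_step_deg: float = 5.0,
    n_samples: int = N_SAMPLES,
    step_mm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World positions of every ray sample over many cross-sections at once.

    Returns (positions (S, R, n, 3), axis indices (S,), angles_deg (R,)) for
    S cross-sections and R = 360 / angular_step_deg rays each.
    """
    if 360.0 % angular_step_deg != 0:
        raise ValueError(f"angular step {angular_step_deg} must divide 360")
    if indices is None:
        indices = np.arange(len(axis))
    indices = np.asarray(indices, dtype=int)
    frames = axis.frames[indices]          # (S, 2, 3)
    origins = axis.points[indices]         # (S, 3)
    angles = np.arange(0.0, 360.0, angular_step_deg)
    rad = np.deg2rad(angles)
    dirs = (
        np.cos(rad)[None, :, None] * frames[:, None, 0, :]
        + np.sin(rad)[None, :, None] * frames[:, None, 1, :]
    )                                      # (S, R, 3)
    steps = step_mm * np.arange(n_samples)
    pos = origins[:, None, None, :] + steps[None, None, :, None] * dirs[:, :, None, :]
    return pos, indices, angles


def sample_points(
    volume: Volume, positions: np.ndarray, order: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate a volume at world positions of any shape (..., 3).

    Returns (values shaped like positions[..., 0], inside-mask). Samples
    outside the voxel extent get nearest-edge values and inside=False.
    """
    pts = positions.reshape(-1, 3)
    idx = volume.world_to_index(pts)
    shape = np.asarray(volume.shape)
    inside = np.all((idx >= -0.5) & (idx <= shape - 0.5), axis=1)
    coords = np.round(idx).T.astype(int) if order == 0 else idx.T
    if order == 0:
        coords = np.clip(coords, 0, (shape - 1)[:, None])
        vals = volume.data[tuple(coords)]
    else:
        vals = ndimage.map_coordinates(
            np.asarray(volume.data, dtype=float), coords, order=order, mode="nearest"
        )
    lead = positions.shape[:-1]
    return vals.reshape(lead), inside.reshape(lead)


def strip_labels(raw: np.ndarray, wall_thickness_vox: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized intima-stripping over a batch of raw label rows (R, n).

    Same rule as :func:`label_series`; returns (states (R, n), valid (R,)).
    """
    raw = np.atleast_2d(raw)
    R, n = raw.shape
    vessel = (raw == 1) | (raw == 2)
    # first non-vessel position per row (n when the ray never leaves the vessel)
    nonv = ~vessel
    b = np.where(nonv.any(axis=1), np.argmax(nonv, axis=1), n)
    k = np.minimum(wall_thickness_vox, b)
    cols = np.arange(n)[None, :]
    states = np.full((R, n), ADVENTITIA, dtype=np.int8)
    states[cols < (b - k)[:, None]] = LUMEN
    states[(cols >= (b - k)[:, None]) & (cols < b[:, None])] = INTIMA
    after = cols >= b[:, None]
    states[after & (raw == 3)] = PATHOLOGY
    backwards = (after & vessel).any(axis=1)
    valid = vessel[:, 0] & ~backwards
    return states, valid


def wall_thickness_for_radius(
    radius_mm: float, thresholds_mm: tuple[float, float] = (1.5, 2.5)
) -> int:
    """Wall thickness in voxels from the local vessel radius (2/3/4)."""
    if radius_mm < thresholds_mm[0]:
        return 2
    if radius_mm < thresholds_mm[1]:
        return 3
    return 4


def build_series_table(
    volume: Volume,
    axis: VesselAxis,
    feature_volumes: dict[str, Volume],
    labels: Volume | None = None,
    wall_thickness_vox: int | None = None,
    angular_step_deg: float = 5.0,
    n_samples: int = N_SAMPLES,
    step_mm: float | None = None,
    axis_stride: int = 1,
    phantom_id: int = 0,
    local_radius_mm: np.ndarray | None = None,
    on_bounds_error: str = "raise",
) -> pd.DataFrame:
    """Tabulate ray series over the whole axis: the training/testing exchange format.

    One row per ray sample with columns phantom_id, axis_index, angle_deg,
    sample_index, x, y, z, intensity, one column per feature, and (when a
    label volume is given) ``state`` plus a per-ray ``valid`` flag. The radial
    step defaults to the smallest voxel dimension. ``on_bounds_error`` is
    "raise" (contract default) or "skip" (drop out-of-bounds rays, counting
    them in ``table.attrs['skipped_rays']``).
    """
    if step_mm is None:
        step_mm = min(volume.spacing)
    indices = np.arange(0, len(axis), axis_stride)
    pos, idxs, angles = ray_grid(axis, indices, angular_step_deg, n_samples, step_mm)
    S, R, n, _ = pos.shape

    intens, inside = sample_points(volume, pos)
    ray_ok = inside.all(axis=2)  # (S, R)
    if not ray_ok.all():
        if on_bounds_error != "skip":
            s, r = np.argwhere(~ray_ok)[0]
            raise RayBoundsError(
                f"ray (axis {idxs[s]}, angle {angles[r]}°) leaves the volume"
            )
    skipped = int((~ray_ok).sum())
    if not ray_ok.any():
        raise ValueError("no rays could be sampled inside the volume")

    feat_vals = {name: sample_points(fv, pos)[0] for name, fv in feature_volumes.items()}
    if labels is not None:
        raw = sample_points(labels, pos, order=0)[0]
        if wall_thickness_vox is not None:
            walls = np.full(S, wall_thickness_vox)
        elif local_radius_mm is not None:
            walls = np.array([
                wall_thickness_for_radius(float(local_radius_mm[i])) for i in idxs
            ])
        else:
            walls = np.full(S, 2)
        states = np.empty((S, R, n), dtype=np.int8)
        valid = np.empty((S, R), dtype=bool)
        for s in range(S):
            states[s], valid[s] = strip_labels(raw[s], int(walls[s]))

    keep = ray_ok.ravel()  # flatten (S, R) and drop out-of-bounds rays
    rep = np.repeat  # per-ray values repeated over the n samples
    rec = {
        "phantom_id": phantom_id,
        "axis_index": rep(np.repeat(idxs, R)[keep], n),
        "angle_deg": rep(np.tile(angles, S)[keep], n),
        "sample_index": np.tile(np.arange(n), int(keep.sum())),
        "x": pos.reshape(-1, n, 3)[keep, :, 0].ravel(),
        "y": pos.reshape(-1, n, 3)[keep, :, 1].ravel(),
        "z": pos.reshape(-1, n, 3)[keep, :, 2].ravel(),
        "intensity": intens.reshape(-1, n)[keep].ravel(),
    }
    for name, fv in feat_vals.items():
        rec[name] = fv.reshape(-1, n)[keep].ravel()
    if labels is not None:
        rec["state"] = states.reshape(-1, n)[keep].ravel()
        rec["valid"] = rep(valid.ravel()[keep], n)
    table = pd.DataFrame(rec)
    table.attrs["skipped_rays"] = skipped
    table.attrs["n_samples"] = n_samples
    return table


def write_axes_json(axes: list[VesselAxis], path: str | os.PathLike) -> None:
    """Axes as JSON [{"points": [[x, y, z], ...]}] in world mm coordinates."""
    payload = [{"points": ax.points.tolist()} for ax in axes]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_axes_json(path: str | os.PathLike) -> list[VesselAxis]:
    with open(path) as fh:
        payload = json.load(fh)
    return [VesselAxis(np.asarray(entry["points"])) for entry in payload]
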