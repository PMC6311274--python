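"""Synthetic vascular phantoms with ground-truth labels and axes.

Each phantom is a CT-like volume holding a bright tubular lumen around a
known axis (straight, helical, or bifurcating), a thin intima/wall shell of
2-4 voxels, optional hyperdense calcified arcs touching the wall, a darker
background, and optional additive Gaussian noise. Vessel radii span
0.35-3.0 mm (diameters 0.7-6.0 mm) and may dip along the axis to emulate
stenoses. Labels: 0 = background/adventitia, 1 = lumen, 2 = intima,
3 = pathology.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

from .rays import VesselAxis, parallel_frames, write_axes_json
from .volume import Volume, write_volume

__all__ = [
    "PlaqueArc",
    "PhantomConfig",
    "Phantom",
    "generate_phantom",
    "add_gaussian_noise",
    "write_phantom",
]

RADIUS_RANGE_MM = (0.35, 3.0)

#: CT-like tissue intensity defaults; calcification is hyperdense and the
#: wall darker than the contrast-filled lumen.
DEFAULT_INTENSITIES = {
    "background": 40.0,
    "lumen": 250.0,
    "wall": 120.0,
    "calcification": 1100.0,
}


@dataclass
class PlaqueArc:
    """A calcified arc hugging the outer wall.

    ``arc_frac``: (start, end) fractions of axis arclength; ``angle_deg``:
    (start, end) angular range in the cross-section plane; ``thickness_mm``:
    radial extent beyond the intima shell.
    """

    arc_frac: tuple[float, float] = (0.3, 0.7)
    angle_deg: tuple[float, float] = (0.0, 120.0)
    thickness_mm: float = 1.0


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 0.7)
    axis_spec: str | np.ndarray = "straight"
    radius_profile_mm: float | list[tuple[float, float]] = 2.0
    wall_thickness_vox: int = 2
    intensity_means: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    plaque_spec: list[PlaqueArc] = field(default_factory=list)
    #: how the intima shell is realized. "tissue": a distinct wall layer of
    #: intermediate intensity wrapped around the bright lumen (low-contrast
    #: outer boundary, as in clinical CT with a visible wall). "stripped":
    #: the outermost 2-4 voxels of the bright tube itself, as in synthetic
    #: vascular-tree volumes where the marked vessel is the bright structure
    #: and the boundary class is obtained by stripping.
    wall_mode: str = "tissue"
    #: emulate the scanner point-spread/partial-volume effect at the outer
    #: vessel boundary: boundary voxels take an occupancy-weighted blend of
    #: vessel and background intensity over one voxel width. Off by default
    #: (piecewise-constant tissues).
    partial_volume: bool = False
    noise_variance: float = 0.0
    blur_sigma_vox: float = 0.0
    helix_radius_mm: float = 3.0
    helix_turns: float = 1.0
    bifurcation_angle_deg: float = 35.0
    margin_vox: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wall_thickness_vox not in (2, 3, 4):
            raise ValueError("wall thickness must be 2, 3 or 4 voxels")
        radii = self.radius_values()
        if np.any(radii < RADIUS_RANGE_MM[0]) or np.any(radii > RADIUS_RANGE_MM[1]):
            raise ValueError(
                f"radius profile must stay within {RADIUS_RANGE_MM} mm, got "
                f"[{radii.min():.3f}, {radii.max():.3f}]"
            )
        im = self.intensity_means
        if not (im["calcification"] > im["lumen"] > im["wall"] >= im["background"]):
            raise ValueError(
                "intensities must be ordered calcification > lumen > wall >= background"
            )
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")

    def radius_values(self, frac: np.ndarray | None = None) -> np.ndarray:
        """Lumen radius (mm) at arclength fraction(s) ``frac`` in [0, 1]."""
        if frac is None:
            frac = np.linspace(0.0, 1.0, 101)
        frac = np.asarray(frac, dtype=float)
        if np.isscalar(self.radius_profile_mm) or isinstance(self.radius_profile_mm, (int, float)):
            return np.full(frac.shape, float(self.radius_profile_mm))
        prof = np.asarray(self.radius_profile_mm, dtype=float)
        return np.interp(frac, prof[:, 0], prof[:, 1])


@dataclass
class Phantom:
    volume: Volume
    labels: Volume
    axes: list[VesselAxis]
    config: PhantomConfig


#: radius ratio of child to parent branch at a symmetric bifurcation
#: (Murray's law: r_child = r_parent / 2^(1/3)).
MURRAY_RATIO = 2.0 ** (-1.0 / 3.0)


def _axis_points(config: PhantomConfig) -> list[np.ndarray]:
    """Axis polylines in world mm, one per vessel branch."""
    shape = np.asarray(config.grid_shape)
    sp = np.asarray(config.spacing_mm)
    extent = (shape - 1) * sp
    margin = config.margin_vox * sp
    center = extent / 2.0
    z = np.arange(margin[2], extent[2] - margin[2] + 1e-9, min(sp))
    if isinstance(config.axis_spec, np.ndarray):
        return [(np.asarray(config.axis_spec, dtype=float), None)]
    if config.axis_spec == "straight":
        pts = np.column_stack([np.full_like(z, center[0]), np.full_like(z, center[1]), z])
        return [(pts, None)]
    if config.axis_spec == "helical":
        theta = 2 * np.pi * config.helix_turns * (z - z[0]) / (z[-1] - z[0])
        pts = np.column_stack([
            center[0] + config.helix_radius_mm * np.cos(theta),
            center[1] + config.helix_radius_mm * np.sin(theta),
            z,
        ])
        return [(pts, None)]
    if config.axis_spec == "bifurcating":
        half = len(z) // 2
        parent = np.column_stack(
            [np.full(half, center[0]), np.full(half, center[1]), z[:half]]
        )
        ang = np.deg2rad(config.bifurcation_angle_deg)
        kids = []
        for sign in (+1, -1):
            zc = z[half - 1:]
            dx = sign * np.tan(ang) * (zc - zc[0])
            kids.append(np.column_stack(
                [center[0] + dx, np.full_like(zc, center[1]), zc]
            ))
        # children taper per Murray's law; taper fraction marks the branch point
        return [(np.vstack([parent, kids[0][1:]]), 0.5), (kids[1], 0.0)]
    raise ValueError(f"unknown axis spec: {config.axis_spec!r}")


def _check_axis_inside(config: PhantomConfig, pts: np.ndarray) -> None:
    shape = np.asarray(config.grid_shape)
    sp = np.asarray(config.spacing_mm)
    idx = pts / sp
    lo, hi = config.margin_vox, shape - 1 - config.margin_vox
    bad = np.any((idx < lo - 1e-6) | (idx > hi + 1e-6), axis=1)
    if np.any(bad):
        j = int(np.argmax(bad))
        raise ValueError(
            f"axis point {pts[j]} (index {idx[j]}) exits the grid margin "
            f"({config.margin_vox} voxels, shape {tuple(config.grid_shape)})"
        )


def _refine_polyline(pts: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline at roughly ``step_mm`` arclength spacing."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(s[-1] / step_mm)) + 1, 2)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, pts[:, a]) for a in range(3)])


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Build the labeled tube (plus optional plaque, blur, noise) for ``config``.

    Deterministic for a fixed seed. Voxels are labeled by their distance to
    the nearest axis point: lumen within the local radius r, intima within
    r + wall (wall thickness realized in voxels of the smallest spacing),
    plaque arcs in a further shell over their arclength/angular ranges.
    Overlapping branches resolve in favor of lumen, then intima, then plaque.
    """
    polylines = _axis_points(config)
    for pts, _ in polylines:
        _check_axis_inside(config, pts)

    sp = np.asarray(config.spacing_mm)
    wall_mm = config.wall_thickness_vox * float(min(sp))
    xs, ys, zs = np.meshgrid(
        *[sp[a] * np.arange(config.grid_shape[a]) for a in range(3)], indexing="ij"
    )
    voxels = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])

    labels = np.zeros(config.grid_shape, dtype=np.int8).ravel()
    occupancy = np.zeros(labels.shape)
    # priority: lumen(1) > intima(2) > pathology(3) > background(0)
    priority = np.array([0, 3, 2, 1])
    fine_step = float(min(sp)) / 3.0
    sp_min = float(min(sp))
    # half the voxel diagonal: a voxel whose center is this close to the axis
    # always contains it, so sub-voxel-caliber vessels voxelize to the line
    # of containing voxels instead of a broken dash
    c0 = 0.5 * sp_min * np.sqrt(3.0)

    axes = []
    for pts, taper_frac in polylines:
        axes.append(VesselAxis(pts))
        fine = _refine_polyline(pts, fine_step)
        seg = np.linalg.norm(np.diff(fine, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        frac = s / s[-1]
        radii = config.radius_values(frac)
        if taper_frac is not None:
            radii = np.where(frac < taper_frac, radii, radii * MURRAY_RATIO)

        tree = cKDTree(fine)
        max_r = radii.max() + wall_mm + max(
            [p.thickness_mm for p in config.plaque_spec], default=0.0
        )
        dist, nearest = tree.query(voxels, distance_upper_bound=max_r + float(min(sp)))
        near = np.isfinite(dist)
        d = dist[near]
        j = nearest[near]
        r = radii[j]

        branch = np.zeros(len(d), dtype=np.int8)
        if config.wall_mode == "stripped":
            # intima = outermost shell of the bright tube; keep a lumen core
            # of at least one containing voxel around the axis
            label_r = np.maximum(r, c0)
            core = np.maximum(r - wall_mm, c0)
            branch[d <= label_r] = 2
            branch[d <= core] = 1
            outer = label_r
        elif config.wall_mode == "tissue":
            lumen_r = np.maximum(r, c0)  # lumen always holds its axis voxels
            branch[d <= lumen_r + wall_mm] = 2
            branch[d <= lumen_r] = 1
            outer = lumen_r + wall_mm
        else:
            raise ValueError(f"unknown wall mode: {config.wall_mode!r}")
        occ = np.clip((outer + 0.5 * sp_min - d) / sp_min, 0.0, 1.0)
        occupancy[np.flatnonzero(near)] = np.maximum(occupancy[near], occ)
        if config.plaque_spec:
            frames = parallel_frames(VesselAxis(fine))
            rel = voxels[near] - fine[j]
            ang = np.rad2deg(np.arctan2(
                np.einsum("ij,ij->i", rel, frames[j, 1]),
                np.einsum("ij,ij->i", rel, frames[j, 0]),
            )) % 360.0
            for plaque in config.plaque_spec:
                in_arc = (frac[j] >= plaque.arc_frac[0]) & (frac[j] <= plaque.arc_frac[1])
                a0, a1 = plaque.angle_deg
                in_ang = (ang >= a0 % 360) & (ang <= a1 % 360) if a0 % 360 <= a1 % 360 \
                    else (ang >= a0 % 360) | (ang <= a1 % 360)
                shell = (d > outer) & (d <= outer + plaque.thickness_mm)
                sel = in_arc & in_ang & shell & (branch == 0)
                branch[sel] = 3
        # merge with existing labels by priority
        cur = labels[near]
        take = priority[branch] > priority[cur]
        cur[take] = branch[take]
        labels[near] = cur

    labels = labels.reshape(config.grid_shape)
    im = config.intensity_means
    wall_intensity = im["lumen"] if config.wall_mode == "stripped" else im["wall"]
    lut = np.array([im["background"], im["lumen"], wall_intensity, im["calcification"]])
    if config.partial_volume:
        # occupancy-weighted blend at the outer vessel boundary; calcified
        # plaque keeps its full intensity
        occupancy = occupancy.reshape(config.grid_shape)
        tissue = np.where(labels > 0, lut[labels], wall_intensity)
        occ = np.where(labels == 3, 1.0, occupancy)
        intensity = im["background"] + (tissue - im["background"]) * occ
    else:
        intensity = lut[labels].astype(float)
    if config.blur_sigma_vox > 0:
        intensity = ndimage.gaussian_filter(intensity, config.blur_sigma_vox)

    volume = Volume(intensity, tuple(sp))
    if config.noise_variance > 0:
        volume = add_gaussian_noise(volume, config.noise_variance, config.seed)
    return Phantom(volume, Volume(labels, tuple(sp)), axes, config)


def add_gaussian_noise(volume: Volume, variance: float, seed: int) -> Volume:
    """Add an i.i.d. zero-mean Gaussian field of the given intensity variance."""
    if variance < 0:
        raise ValueError(f"noise variance must be >= 0, got {variance}")
    if variance == 0:
        return volume.like(volume.data.copy())
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(variance), size=volume.shape)
    return volume.like(np.asarray(volume.data, dtype=float) + noise)


def write_phantom(phantom: Phantom, outdir: str | os.PathLike, stem: str = "phantom") -> None:
    """Volume + labels as NIfTI, axes as world-mm JSON, config as YAML."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_volume(phantom.volume, os.path.join(outdir, f"{stem}.nii.gz"))
    write_volume(phantom.labels, os.path.join(outdir, f"{stem}_labels.nii.gz"))
    write_axes_json(phantom.axes, os.path.join(outdir, f"{stem}_axes.json"))
    cfg = phantom.config
    payload = {
        "grid_shape": list(cfg.grid_shape),
        "spacing_mm": list(cfg.spacing_mm),
        "axis_spec": cfg.axis_spec if isinstance(cfg.axis_spec, str) else
        np.asarray(cfg.axis_spec).tolist(),
        "radius_profile_mm": cfg.radius_profile_mm if np.isscalar(cfg.radius_profile_mm)
        else [list(map(float, p)) for p in cfg.radius_profile_mm],
        "wall_thickness_vox": cfg.wall_thickness_vox,
        "intensity_means": cfg.intensity_means,
        "plaque_spec": [
            {"arc_frac": list(p.arc_frac), "angle_deg": list(p.angle_deg),
             "thickness_mm": p.thickness_mm}
            for p in cfg.plaque_spec
        ],
        "noise_variance": cfg.noise_variance,
        "blur_sigma_vox": cfg.blur_sigma_vox,
        "seed": cfg.seed,
    }
    with open(os.path.join(outdir, f"{stem}_config.yaml"), "w") as fh:
        yaml.safe_dump(payload, fh)
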