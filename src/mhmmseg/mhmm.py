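"""The multiple-HMM classifier: five per-feature HMMs fused by precision weights.

One discrete HMM is trained per vesselness feature; the combined model is the
convex combination of their posterior similarity maps with weights
alpha_k = Precision_k / sum_w Precision_w, where Precision_k is the per-voxel
training precision of HMM k's vessel calls (decoded lumen or intima). Per-ray
posteriors are decoded by position-wise argmax, and the multi-ray labels are
fused into a volume by averaging the posterior 4-vectors of every ray sample
that maps to a voxel and taking the argmax of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_NAMES
from .hmm import (
    HmmModel,
    SimilarityMap,
    baum_welch,
    forward_backward_batch,
    init_hmm,
    map_decode,
    match_states,
    supervised_init,
)
from .quantize import (
    BinScheme,
    FeatureCalibration,
    default_bin_scheme,
    fit_calibration,
    fit_overlap_scheme,
    quantize_series,
)
from .rays import RayBoundsError, VesselAxis, ray_grid, sample_points
from .volume import Volume

__all__ = [
    "MhmmModel",
    "TrainConfig",
    "train_mhmm",
    "mhmm_posterior",
    "mhmm_posterior_batch",
    "segment_cross_section",
    "PosteriorAccumulator",
    "fuse_labels",
    "segment_volume",
]

#: fused HMM state -> output label-volume code (0 bg, 1 lumen, 2 intima, 3 pathology)
STATE_TO_LABEL = np.array([1, 2, 3, 0], dtype=np.int8)
VESSEL_STATES = (0, 1)


@dataclass
class TrainConfig:
    """Training options.

    ``supervised`` seeds A and B from labeled counts (fixing state
    semantics); ``max_iter`` bounds the Baum-Welch refinement on top of that
    seed (0 keeps the pure count estimates); ``scheme_mode`` selects the
    fixed overlap breakpoints ("fixed") or re-fits them from the training
    histograms per feature ("fitted").
    """

    features: tuple[str, ...] = FEATURE_NAMES
    supervised: bool = True
    max_iter: int = 20
    tol: float = 1e-5
    calibration_percentile: float = 99.5
    scheme_mode: str = "fixed"


@dataclass
class MhmmModel:
    """Phi = {phi_k, alpha_k}: one HMM, bin scheme and calibration per feature."""

    hmms: dict[str, HmmModel]
    weights: dict[str, float]
    bin_schemes: dict[str, BinScheme]
    calibrations: dict[str, FeatureCalibration]
    precisions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = set(self.hmms)
        if not (keys == set(self.weights) == set(self.bin_schemes) == set(self.calibrations)):
            raise ValueError("hmms, weights, schemes and calibrations must share keys")
        w = np.array([self.weights[k] for k in self.hmms])
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.hmms)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "features": list(self.hmms),
            "hmms": {k: m.to_dict() for k, m in self.hmms.items()},
            "weights": {k: float(v) for k, v in self.weights.items()},
            "bin_schemes": {k: s.to_dict() for k, s in self.bin_schemes.items()},
            "calibrations": {
                k: {"reference_value": c.reference_value, "percentile": c.percentile}
                for k, c in self.calibrations.items()
            },
            "precisions": {k: float(v) for k, v in self.precisions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MhmmModel":
        order = d.get("features", list(d["hmms"]))
        return cls(
            {k: HmmModel.from_dict(d["hmms"][k]) for k in order},
            {k: d["weights"][k] for k in order},
            {k: BinScheme.from_dict(d["bin_schemes"][k]) for k in order},
            {k: FeatureCalibration(**d["calibrations"][k]) for k in order},
            {k: d["precisions"][k] for k in order} if d.get("precisions") else {},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "MhmmModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def observations(self, feature: str, values: np.ndarray) -> np.ndarray:
        """Raw feature values -> normalized -> discrete symbols."""
        norm = np.maximum(self.calibrations[feature](values), 0.0)
        return quantize_series(norm, self.bin_schemes[feature])


def _series_matrix(table: pd.DataFrame, column: str, n: int) -> np.ndarray:
    return table[column].to_numpy().reshape(-1, n)


def train_mhmm(
    table: pd.DataFrame, config: TrainConfig | None = None
) -> tuple[MhmmModel, dict]:
    """Train the five per-feature HMMs and their precision weights.

    ``table`` is a ray-series table (see ``rays.build_series_table``) holding
    one raw-value column per feature plus ``state`` labels and a per-ray
    ``valid`` flag; invalid rays (axis not in lumen, or backward label paths)
    are excluded. Returns the fused model and a training-info dict.
    """
    config = config or TrainConfig()
    missing = [f for f in config.features if f not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from series table: {missing}")
    if "state" not in table.columns:
        raise ValueError("series table has no 'state' labels")
    n = int(table.attrs.get("n_samples", table["sample_index"].max() + 1))
    tab = table[table["valid"]] if "valid" in table.columns else table
    if not len(tab):
        raise ValueError("no valid training rays")
    states = _series_matrix(tab, "state", n).astype(int)

    hmms, weights, schemes, calibs, precisions, info = {}, {}, {}, {}, {}, {}
    for feat in config.features:
        vals = _series_matrix(tab, feat, n)
        calib = fit_calibration(vals.ravel(), config.calibration_percentile)
        norm = np.maximum(calib(vals), 0.0)
        if config.scheme_mode == "fitted":
            scheme = fit_overlap_scheme(feat, norm.ravel(), states.ravel())
        else:
            scheme = default_bin_scheme(feat)
        obs = quantize_series(norm, scheme)
        if config.supervised:
            model0 = supervised_init(obs, states, M=4, N_obs=scheme.n_symbols)
        else:
            model0 = init_hmm(M=4, N_obs=scheme.n_symbols)
        model, fit = baum_welch(model0, obs.astype(int), tol=config.tol,
                                max_iter=config.max_iter)
        ll = fit["log_likelihood"]
        if not np.all(np.isfinite(ll)):
            raise RuntimeError(f"HMM for feature {feat!r} failed to converge")
        if not config.supervised:
            model, _ = match_states(model, zip(obs.astype(int), states))

        post, _ = forward_backward_batch(model, obs.astype(int))
        decoded = map_decode(post)
        called = np.isin(decoded, VESSEL_STATES)
        truth = np.isin(states, VESSEL_STATES)
        tp = int(np.sum(called & truth))
        fp = int(np.sum(called & ~truth))
        prec = tp / (tp + fp) if tp + fp else 0.0

        hmms[feat], schemes[feat], calibs[feat] = model, scheme, calib
        precisions[feat] = prec
        info[feat] = fit

    total = sum(precisions.values())
    if total == 0:
        raise RuntimeError("all training precisions are zero; cannot weight HMMs")
    weights = {f: precisions[f] / total for f in config.features}
    model = MhmmModel(hmms, weights, schemes, calibs, precisions)
    return model, info


def mhmm_posterior_batch(
    model: MhmmModel, feature_series: dict[str, np.ndarray]
) -> np.ndarray:
    """Weighted per-feature posteriors for a batch of rays.

    ``feature_series`` maps feature name to an (R, n) array of raw values;
    returns the combined (R, n, 4) posterior, a convex combination whose rows
    sum to 1.
    """
    keys = tuple(model.features)
    shapes = {feature_series[k].shape for k in keys}
    if len(shapes) != 1:
        raise ValueError(f"feature series shapes differ: {shapes}")
    combined = None
    for feat in keys:
        obs = model.observations(feat, np.atleast_2d(feature_series[feat]))
        post, _ = forward_backward_batch(model.hmms[feat], obs.astype(int))
        term = model.weights[feat] * post
        combined = term if combined is None else combined + term
    return combined


def mhmm_posterior(
    model: MhmmModel, feature_series: dict[str, np.ndarray]
) -> SimilarityMap:
    """Combined similarity map for one ray (each series is a length-n vector)."""
    batch = {k: np.atleast_2d(v) for k, v in feature_series.items()}
    post = mhmm_posterior_batch(model, batch)[0]
    return SimilarityMap(post, float("nan"))


def segment_cross_section(
    model: MhmmModel,
    feature_volumes: dict[str, Volume],
    axis: VesselAxis,
    index: int,
    angular_step_deg: float = 5.0,
    n_samples: int = 18,
    step_mm: float = 1.0,
    on_bounds_error: str = "raise",
):
    """Decode all rays of one cross-section.

    Returns (decoded states (R, n), posteriors (R, n, 4), sample positions
    (R, n, 3)); R = 360 / angular_step_deg rays.
    """
    pos, _, angles = ray_grid(axis, np.array([index]), angular_step_deg,
                              n_samples, step_mm)
    some = next(iter(feature_volumes.values()))
    sampled = {f: sample_points(feature_volumes[f], pos) for f in model.features}
    inside = sample_points(some, pos)[1].all(axis=-1)[0]  # (R,)
    if not inside.all():
        if on_bounds_error != "skip":
            r = int(np.argmax(~inside))
            raise RayBoundsError(
                f"ray (axis {index}, angle {angles[r]}°) leaves the volume"
            )
        if not inside.any():
            raise ValueError(f"no in-bounds rays at cross-section {index}")
    batch = {f: sampled[f][0][0][inside] for f in model.features}
    post = mhmm_posterior_batch(model, batch)
    return map_decode(post), post, pos[0][inside]


class PosteriorAccumulator:
    """Per-voxel accumulation of ray-sample posteriors (nearest-voxel binning)."""

    def __init__(self, grid: Volume):
        self.grid = grid
        self.post_sum = np.zeros(grid.shape + (4,))
        self.counts = np.zeros(grid.shape, dtype=np.int64)

    def add(self, positions: np.ndarray, posteriors: np.ndarray) -> None:
        """``positions``: (..., 3) world mm; ``posteriors``: (..., 4)."""
        pts = positions.reshape(-1, 3)
        post = posteriors.reshape(-1, 4)
        idx = np.round(self.grid.world_to_index(pts)).astype(int)
        shape = np.asarray(self.grid.shape)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        np.add.at(self.post_sum, (idx[:, 0], idx[:, 1], idx[:, 2]), post[ok])
        np.add.at(self.counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)


def fuse_labels(accumulator: PosteriorAccumulator) -> tuple[Volume, np.ndarray]:
    """Mean-posterior argmax per touched voxel; untouched voxels stay background.

    Returns (label volume with codes 0 background/adventitia, 1 lumen,
    2 intima, 3 pathology; boolean vessel mask = lumen or intima). Ties in
    the mean go to the lower state index; a lumen/intima tie is vessel either
    way.
    """
    touched = accumulator.counts > 0
    mean = accumulator.post_sum / np.maximum(accumulator.counts[..., None], 1)
    state = np.argmax(mean, axis=-1)
    labels = np.where(touched, STATE_TO_LABEL[state], 0).astype(np.int8)
    vessel = touched & np.isin(state, VESSEL_STATES)
    return accumulator.grid.like(labels), vessel


def segment_volume(
    model: MhmmModel,
    volume: Volume,
    axes: VesselAxis | list[VesselAxis],
    feature_volumes: dict[str, Volume] | None = None,
    angular_step_deg: float = 5.0,
    n_samples: int = 18,
    step_mm: float | None = None,
    axis_stride: int = 1,
) -> tuple[Volume, np.ndarray]:
    """End-to-end volumetric segmentation along one or more axes.

    Computes the multiscale feature volumes if not supplied, decodes every
    cross-section (one per axis point by default), drops rays that leave the
    volume, and fuses the posteriors per voxel. Deterministic for fixed
    inputs. Returns (label volume, vessel mask).
    """
    from .features import multiscale_features

    if feature_volumes is None:
        feature_volumes = multiscale_features(volume, model.features)
    if step_mm is None:
        step_mm = min(volume.spacing)
    if isinstance(axes, VesselAxis):
        axes = [axes]
    acc = PosteriorAccumulator(volume)
    for axis in axes:
        indices = np.arange(0, len(axis), axis_stride)
        pos, _, _ = ray_grid(axis, indices, angular_step_deg, n_samples, step_mm)
        S, R, n, _ = pos.shape
        some = next(iter(feature_volumes.values()))
        inside = sample_points(some, pos)[1].all(axis=-1)  # (S, R)
        keep = inside.reshape(-1)
        if not keep.any():
            warnings.warn("axis has no in-bounds rays; skipped")
            continue
        batch = {
            f: sample_points(feature_volumes[f], pos)[0].reshape(-1, n)[keep]
            for f in model.features
        }
        post = mhmm_posterior_batch(model, batch)
        acc.add(pos.reshape(-1, n, 3)[keep], post)
    return fuse_labels(acc)
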