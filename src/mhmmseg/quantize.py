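"""Overlap-aware quantization of feature series into discrete HMM symbols.

Feature values are first normalized to a common 0–100 scale (a robust
99.5th-percentile calibration fitted on training data), then binned with a
scheme that concentrates resolution where the pathology distribution overlaps
the lumen and intima distributions: one bin below a1, K1 equal sub-bins on
[a1, a2), K2 equal sub-bins on [a2, a3), and one overflow bin above a3. With
the defaults K1=5, K2=3 every feature maps to N=10 symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "BinScheme",
    "FeatureCalibration",
    "default_bin_scheme",
    "fit_calibration",
    "normalize_feature",
    "quantize_series",
    "fit_overlap_scheme",
]

#: Overlap intervals [a1, a2) and [a2, a3) per feature, on the normalized
#: 0-100 scale.
DEFAULT_BREAKPOINTS = {
    "sato": (25.0, 35.0, 50.0),
    "frangi": (15.0, 20.0, 30.0),
    "shikata": (85.0, 95.0, 120.0),
    "li": (40.0, 45.0, 55.0),
    "manniesing": (15.0, 25.0, 45.0),
}


@dataclass
class BinScheme:
    """Binning breakpoints and sub-bin counts for one feature."""

    feature_id: str
    a1: float
    a2: float
    a3: float
    k1: int = 5
    k2: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.a1 < self.a2 < self.a3:
            raise ValueError(
                f"breakpoints must satisfy 0 < a1 < a2 < a3, got "
                f"({self.a1}, {self.a2}, {self.a3})"
            )
        if self.k1 < 1 or self.k2 < 1:
            raise ValueError("sub-bin counts must be >= 1")

    @property
    def n_symbols(self) -> int:
        return 1 + self.k1 + self.k2 + 1

    @property
    def edges(self) -> np.ndarray:
        """Strictly increasing interior edges a1 .. a2 .. a3 (left-closed bins)."""
        return np.concatenate([
            np.linspace(self.a1, self.a2, self.k1 + 1)[:-1],
            np.linspace(self.a2, self.a3, self.k2 + 1),
        ])

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "a1": self.a1, "a2": self.a2, "a3": self.a3,
            "k1": self.k1, "k2": self.k2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinScheme":
        return cls(**d)


def default_bin_scheme(feature_id: str) -> BinScheme:
    """The standard overlap intervals for the five vesselness features."""
    if feature_id not in DEFAULT_BREAKPOINTS:
        raise ValueError(f"unknown feature: {feature_id!r}")
    a1, a2, a3 = DEFAULT_BREAKPOINTS[feature_id]
    return BinScheme(feature_id, a1, a2, a3)


@dataclass
class FeatureCalibration:
    """Monotone map from raw feature values to the normalized 0-100 scale."""

    reference_value: float
    percentile: float = 99.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.reference_value) or self.reference_value <= 0:
            raise ValueError(
                f"degenerate calibration: reference value {self.reference_value}"
            )

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return 100.0 * np.asarray(values, dtype=float) / self.reference_value


def fit_calibration(values: np.ndarray, percentile: float = 99.5) -> FeatureCalibration:
    """Calibrate so the ``percentile``-th training value maps to 100."""
    ref = float(np.percentile(np.asarray(values, dtype=float), percentile))
    return FeatureCalibration(ref, percentile)


def normalize_feature(values: np.ndarray, calibration: FeatureCalibration) -> np.ndarray:
    """Apply a fitted calibration (reused unchanged at test time)."""
    return calibration(values)


def quantize_series(values: np.ndarray, scheme: BinScheme) -> np.ndarray:
    """Map normalized values to symbols 0 .. n_symbols-1 (half-open bins).

    Symbol 0 covers [0, a1); symbols 1..K1 the equal sub-bins of [a1, a2);
    K1+1..K1+K2 those of [a2, a3); the last symbol is [a3, inf).
    """
    vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative feature values cannot be quantized")
    return np.searchsorted(scheme.edges, vals, side="right").astype(np.int8)


def fit_overlap_scheme(
    feature_id: str,
    normalized_values: np.ndarray,
    states: np.ndarray,
    k1: int = 5,
    k2: int = 3,
) -> BinScheme:
    """Re-fit the overlap breakpoints from labeled training data.

    The overlap region — where the intima distribution meets the lumen
    distribution from below and the pathology distribution cuts across both —
    is bounded by distribution percentiles: a1 at the 10th percentile of the
    intima values, a2 at the median of the pooled lumen and intima values,
    a3 at the 90th percentile of the lumen values. Resolution is thereby
    concentrated on the boundary classes the model must separate. Falls back
    to the fixed defaults when lumen or intima samples are missing.
    """
    vals = np.asarray(normalized_values, dtype=float)
    states = np.asarray(states)
    lum, inti = vals[states == 0], vals[states == 1]
    if min(len(lum), len(inti)) < 10:
        return default_bin_scheme(feature_id)
    lo = float(np.percentile(inti, 10))
    mid = float(np.percentile(np.concatenate([inti, lum]), 50))
    hi = float(np.percentile(lum, 90))
    eps = 1e-6
    a1 = max(lo, eps)
    a2 = max(mid, a1 + eps)
    a3 = max(hi, a2 + eps)
    return BinScheme(feature_id, a1, a2, a3, k1, k2)


def write_bin_schemes(schemes: dict[str, BinScheme], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: s.to_dict() for k, s in schemes.items()}, fh)


def read_bin_schemes(path) -> dict[str, BinScheme]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: BinScheme.from_dict(v) for k, v in raw.items()}
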