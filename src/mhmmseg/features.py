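"""Multiscale Hessian vesselness features.

Five classical tube-enhancement responses (Sato, Frangi, Shikata, Li,
Manniesing) computed from the eigenvalues of the Gaussian-scale Hessian of a
3-D image. Eigenvalues are sorted by value, ``lambda1 > lambda2 > lambda3``,
so inside a bright tube the two cross-sectional eigenvalues (lambda2,
lambda3) are strongly negative and the axial one (lambda1) is near zero.
Every response is returned as a nonnegative magnitude so that downstream
binning operates on a single positive scale.

``hessian_eigenvalues`` returns *unnormalized* second derivatives (per mm²);
the multiscale maximum applies the standard gamma=2 scale normalization
(multiplication by s²) before evaluating the Sato/Frangi/Li/Manniesing
formulas, while the Shikata response carries its own explicit s² factor and
therefore receives the raw eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "FEATURE_NAMES",
    "FeatureParams",
    "HessianEigenvolumes",
    "hessian_eigenvalues",
    "gamma_from_eigenvalues",
    "gamma_from_volume",
    "sato_feature",
    "frangi_feature",
    "shikata_feature",
    "li_feature",
    "manniesing_feature",
    "multiscale_max",
    "multiscale_features",
]

FEATURE_NAMES = ("sato", "frangi", "shikata", "li", "manniesing")

#: Scale schedule in mm: s = 0.6 * 2**((w-1)/2), w = 1..6, covering vessel
#: diameters from 0.7 mm to 6.0 mm.
DEFAULT_SCALES_MM = tuple(0.6 * 2.0 ** ((w - 1) / 2.0) for w in range(1, 7))


@dataclass
class FeatureParams:
    """Tunable parameters of the five vesselness responses.

    alpha1/alpha2 steer the Sato asymmetry penalty (alpha1 < alpha2);
    alpha/beta are the Frangi plate/blob sensitivities; c is the Manniesing
    curvature sensitivity (``None`` means gamma/2 at each scale); scales_mm
    is the detection-scale schedule.
    """

    alpha1: float = 0.5
    alpha2: float = 2.0
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None
    scales_mm: tuple[float, ...] = DEFAULT_SCALES_MM

    def __post_init__(self) -> None:
        if not self.alpha1 < self.alpha2:
            raise ValueError("alpha1 must be < alpha2")
        if any(s <= 0 for s in self.scales_mm):
            raise ValueError("scales must be positive")


@dataclass
class HessianEigenvolumes:
    """Voxelwise Hessian eigenvalues at one scale, sorted lambda1 > lambda2 > lambda3."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    scale_s: float

    def scaled(self, factor: float) -> "HessianEigenvolumes":
        return HessianEigenvolumes(
            self.lambda1 * factor, self.lambda2 * factor,
            self.lambda3 * factor, self.scale_s,
        )


def hessian_eigenvalues(volume: Volume, scale_s: float) -> HessianEigenvolumes:
    """Eigenvalues of the Gaussian-smoothed Hessian at scale ``scale_s`` (mm).

    Derivatives are taken in world (mm) units, so the Gaussian kernel width
    per axis is ``scale_s / spacing`` voxels and second derivatives are
    divided by the corresponding spacing product.
    """
    if scale_s <= 0:
        raise ValueError(f"scale must be positive, got {scale_s}")
    data = np.asarray(volume.data, dtype=float)
    # mean subtraction cancels the truncated kernel's nonzero sum, so a
    # constant image has exactly zero derivatives; truncate=6 keeps the
    # kernel's second moment accurate to ~1e-6
    data = data - data.mean()
    sp = np.asarray(volume.spacing)
    sigma_vox = scale_s / sp

    orders = [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
    H = np.empty(data.shape + (3, 3))
    pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    for order, (a, b) in zip(orders, pairs):
        d = ndimage.gaussian_filter(data, sigma_vox, order=order,
                                    mode="nearest", truncate=6.0)
        d /= sp[a] * sp[b]
        H[..., a, b] = d
        if a != b:
            H[..., b, a] = d

    eig = np.linalg.eigvalsh(H)  # ascending
    return HessianEigenvolumes(eig[..., 2], eig[..., 1], eig[..., 0], float(scale_s))


def gamma_from_eigenvalues(eigs: HessianEigenvolumes) -> float:
    """Half the maximum Frobenius norm of the Hessian over the volume."""
    norm2 = eigs.lambda1**2 + eigs.lambda2**2 + eigs.lambda3**2
    return 0.5 * float(np.sqrt(norm2.max()))


def gamma_from_volume(volume: Volume, scale_s: float, normalized: bool = True) -> float:
    """Structureness scale gamma at ``scale_s``.

    With ``normalized`` (the multiscale-pipeline convention) the Hessian is
    s²-scaled before taking the norm, matching the eigenvalues the Frangi and
    Manniesing formulas see.
    """
    eigs = hessian_eigenvalues(volume, scale_s)
    if normalized:
        eigs = eigs.scaled(scale_s**2)
    return gamma_from_eigenvalues(eigs)


def sato_feature(eigs: HessianEigenvolumes, params: FeatureParams | None = None) -> np.ndarray:
    """Line filter |lambda2| * exp(-lambda1² / (2 a² lambda2²)).

    The asymmetry penalty ``a`` is alpha1 where lambda1 <= 0 (the bright-tube
    side) and alpha2 where lambda1 > 0; the response is 0 where lambda2 == 0.
    """
    params = params or FeatureParams()
    l1, l2 = eigs.lambda1, eigs.lambda2
    a = np.where(l1 <= 0, params.alpha1, params.alpha2)
    with np.errstate(divide="ignore", invalid="ignore"):
        expo = np.exp(-(l1**2) / (2.0 * a**2 * l2**2))
    out = np.abs(l2) * expo
    return np.where(l2 == 0, 0.0, out)


def _frangi_terms(eigs: HessianEigenvolumes, params: FeatureParams, gamma: float | None):
    """Common Frangi-form factors: returns (base response, magnitude-sorted |l2|,|l3|)."""
    mags = np.sort(
        np.abs(np.stack([eigs.lambda1, eigs.lambda2, eigs.lambda3], axis=-1)), axis=-1
    )
    m1, m2, m3 = mags[..., 0], mags[..., 1], mags[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ra2 = np.where(m3 > 0, (m2 / np.where(m3 > 0, m3, 1.0)) ** 2, 0.0)
        rb2 = np.where(m2 * m3 > 0, m1**2 / np.where(m2 * m3 > 0, m2 * m3, 1.0), 0.0)
    s2 = m1**2 + m2**2 + m3**2
    if gamma is None:
        gamma = 0.5 * float(np.sqrt(s2.max()))
    if gamma > 0:
        s_term = 1.0 - np.exp(-s2 / (2.0 * gamma**2))
    else:  # degenerate all-zero Hessian: structureness term is defined as 1
        s_term = np.ones_like(s2)
    base = (
        (1.0 - np.exp(-ra2 / (2.0 * params.alpha**2)))
        * np.exp(-rb2 / (2.0 * params.beta**2))
        * s_term
    )
    return base, m2, m3


def frangi_feature(
    eigs: HessianEigenvolumes,
    params: FeatureParams | None = None,
    gamma: float | None = None,
) -> np.ndarray:
    """Frangi tube response in [0, 1]; exactly 0 where lambda2 > 0 or lambda3 > 0.

    The plate/blob ratios R_A, R_B and the structureness S use
    magnitude-sorted eigenvalues; the sign guard uses value-sorted ones.
    """
    params = params or FeatureParams()
    base, _, _ = _frangi_terms(eigs, params, gamma)
    return np.where((eigs.lambda2 > 0) | (eigs.lambda3 > 0), 0.0, base)


def shikata_feature(
    volume: Volume, eigs: HessianEigenvolumes, intensity_floor: float = 1.0
) -> np.ndarray:
    """Small-vessel response s² |lambda2| / I(x).

    Intensities are shifted to be >= ``intensity_floor`` before division,
    since CT-like data may contain zero or negative values.
    """
    intens = np.asarray(volume.data, dtype=float)
    shift = intensity_floor - intens.min() if intens.min() < intensity_floor else 0.0
    denom = np.maximum(intens + shift, intensity_floor)
    return eigs.scale_s**2 * np.abs(eigs.lambda2) / denom


def li_feature(eigs: HessianEigenvolumes, params: FeatureParams | None = None) -> np.ndarray:
    """Curvature-ratio response |lambda2 (lambda2 - lambda3) / lambda1|.

    Defined only where lambda1 < 0 and lambda2 < 0 (bright curvilinear
    structure); 0 otherwise.
    """
    l1, l2, l3 = eigs.lambda1, eigs.lambda2, eigs.lambda3
    mask = (l1 < 0) & (l2 < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.abs(l2 * (l2 - l3) / np.where(mask, l1, -1.0))
    return np.where(mask, val, 0.0)


def manniesing_feature(
    eigs: HessianEigenvolumes,
    params: FeatureParams | None = None,
    gamma: float | None = None,
) -> np.ndarray:
    """Frangi-form response times the noise gate exp(-2c² / (|lambda2| lambda3²)).

    The gate suppresses voxels with weak cross-sectional curvature; c defaults
    to gamma/2 at the current scale. Zero where lambda2 >= 0 or lambda3 >= 0
    (a stricter guard than Frangi's).
    """
    params = params or FeatureParams()
    base, _, _ = _frangi_terms(eigs, params, gamma)
    if params.c is None:
        g = gamma if gamma is not None else gamma_from_eigenvalues(eigs)
        c = 0.5 * g
    else:
        c = params.c
    l2, l3 = eigs.lambda2, eigs.lambda3
    mask = (l2 < 0) & (l3 < 0)
    denom = np.abs(l2) * l3**2
    with np.errstate(divide="ignore", invalid="ignore"):
        gate = np.exp(-2.0 * c**2 / np.where(denom > 0, denom, 1.0))
    gate = np.where(denom > 0, gate, 0.0)
    return np.where(mask, base * gate, 0.0)


def _single_scale_response(
    volume: Volume,
    eigs: HessianEigenvolumes,
    feature_id: str,
    params: FeatureParams,
    gamma: float | None = None,
) -> np.ndarray:
    """One feature at one scale, with gamma=2 scale normalization applied."""
    if feature_id == "shikata":
        return shikata_feature(volume, eigs)
    eigs_n = eigs.scaled(eigs.scale_s**2)
    if feature_id == "sato":
        return sato_feature(eigs_n, params)
    if gamma is None:
        gamma = gamma_from_eigenvalues(eigs_n)
    if feature_id == "frangi":
        return frangi_feature(eigs_n, params, gamma=gamma)
    if feature_id == "li":
        return li_feature(eigs_n, params)
    if feature_id == "manniesing":
        return manniesing_feature(eigs_n, params, gamma=gamma)
    raise ValueError(f"unknown feature: {feature_id!r}")


def multiscale_max(
    volume: Volume, feature_id: str, params: FeatureParams | None = None
) -> Volume:
    """Voxelwise maximum of one feature over the scale schedule."""
    return multiscale_features(volume, [feature_id], params)[feature_id]


def multiscale_features(
    volume: Volume,
    feature_ids: tuple[str, ...] | list[str] = FEATURE_NAMES,
    params: FeatureParams | None = None,
) -> dict[str, Volume]:
    """All requested features, sharing one Hessian eigendecomposition per scale.

    The structureness scale gamma (and the Manniesing sensitivity c derived
    from it) is computed once per volume — half the maximum Frobenius norm of
    the scale-normalized Hessian over the whole image and the whole scale
    schedule — so that the structureness term retains its scale selectivity.
    """
    params = params or FeatureParams()
    for fid in feature_ids:
        if fid not in FEATURE_NAMES:
            raise ValueError(f"unknown feature: {fid!r}")
    per_scale = []
    gamma = 0.0
    for s in params.scales_mm:
        eigs = hessian_eigenvalues(volume, s)
        per_scale.append(eigs)
        gamma = max(gamma, gamma_from_eigenvalues(eigs.scaled(s**2)))
    out = {fid: None for fid in feature_ids}
    for eigs in per_scale:
        for fid in feature_ids:
            resp = _single_scale_response(volume, eigs, fid, params, gamma=gamma)
            out[fid] = resp if out[fid] is None else np.maximum(out[fid], resp)
    return {fid: volume.like(resp) for fid, resp in out.items()}


def argmax_scale(
    volume: Volume,
    feature_id: str,
    point_index: tuple[int, int, int],
    params: FeatureParams | None = None,
) -> float:
    """Scale (mm) at which the response at one voxel is largest."""
    params = params or FeatureParams()
    per_scale = []
    gamma = 0.0
    for s in params.scales_mm:
        eigs = hessian_eigenvalues(volume, s)
        per_scale.append(eigs)
        gamma = max(gamma, gamma_from_eigenvalues(eigs.scaled(s**2)))
    responses = [
        _single_scale_response(volume, eigs, feature_id, params, gamma=gamma)[point_index]
        for eigs in per_scale
    ]
    return params.scales_mm[int(np.argmax(responses))]
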