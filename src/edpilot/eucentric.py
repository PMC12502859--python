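"""Automatic eucentric-height estimation.

The eucentric height is the stage z at which the specimen plane contains
the goniometer tilt axis, so that tilting produces minimal lateral image
motion.  The estimator here mirrors the manual alignment procedure: image a
feature at two tilt angles (α₁, α₂) and two stage heights (z₁, z₂), and
exploit that the inter-tilt displacement Δd varies linearly with height::

    Δd(z) = m·z + c,   m = [Δd(z₂) − Δd(z₁)] / (z₂ − z₁),
    c = Δd(z₁) − m·z₁,   z_euc = −c / m

Under an orthographic projection with feature height h = z − z_euc the
model gives Δd(z) = s·(z − z_euc)·(sinα₂ − sinα₁): the slope depends only
on the tilt pair and pixel scale, the in-plane feature offset cancels in
the difference, and the root of the line is exactly the eucentric height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .virtual_microscope import DetectorFrame

__all__ = [
    "EucentricMeasurement",
    "EucentricFit",
    "estimate_eucentric",
    "auto_eucentric",
    "locate_feature",
]


class EucentricError(RuntimeError):
    pass


@dataclass(frozen=True)
class EucentricMeasurement:
    """Signed displacement readings d(α, z) for the 2×2 tilt/height design.

    ``d`` maps (tilt index, height index) → displacement in px along the
    direction perpendicular to the tilt axis (motion along the axis carries
    no height information).
    """

    alpha1: float
    alpha2: float
    z1: float
    z2: float
    d11: float  # d(α₁, z₁)
    d21: float  # d(α₂, z₁)
    d12: float  # d(α₁, z₂)
    d22: float  # d(α₂, z₂)

    def __post_init__(self) -> None:
        if self.alpha1 == self.alpha2:
            raise ValueError("the two tilt angles must differ")
        if self.z1 == self.z2:
            raise ValueError("the two stage heights must differ")


@dataclass(frozen=True)
class EucentricFit:
    delta_d_z1: float  # px
    delta_d_z2: float  # px
    delta_z: float  # µm
    m: float  # px/µm
    c: float  # px
    z_euc: float  # µm


def estimate_eucentric(meas: EucentricMeasurement, *, m_tol: float = 1e-9) -> EucentricFit:
    """Two-point linear regression of inter-tilt displacement on height.

    Raises when |m| < ``m_tol`` px/µm — the displacement shows no height
    sensitivity, so the eucentric plane cannot be located.
    """
    dd1 = meas.d21 - meas.d11
    dd2 = meas.d22 - meas.d12
    dz = meas.z2 - meas.z1
    m = (dd2 - dd1) / dz
    if abs(m) < m_tol:
        raise EucentricError("no height sensitivity: displacement slope is ~0")
    c = dd1 - m * meas.z1
    return EucentricFit(
        delta_d_z1=dd1, delta_d_z2=dd2, delta_z=dz, m=m, c=c, z_euc=-c / m
    )


def locate_feature(
    frame: DetectorFrame | np.ndarray,
    template: np.ndarray,
    *,
    search_center: tuple[float, float] | None = None,
    search_radius: float | None = None,
    min_score: float = 0.2,
) -> tuple[float, float]:
    """Find ``template`` in ``frame`` by normalized cross-correlation.

    Returns the sub-pixel (u, v) of the template centre, refined by a
    parabolic fit through the correlation peak and its neighbours.
    """
    pixels = frame.pixels if isinstance(frame, DetectorFrame) else np.asarray(frame)
    corr = match_template(pixels.astype(float), template.astype(float), pad_input=True)
    if search_center is not None and search_radius is not None:
        v = np.arange(corr.shape[0])[:, None]
        u = np.arange(corr.shape[1])[None, :]
        outside = (u - search_center[0]) ** 2 + (v - search_center[1]) ** 2 > search_radius**2
        corr = np.where(outside, -1.0, corr)
    pv, pu = np.unravel_index(np.argmax(corr), corr.shape)
    if corr[pv, pu] < min_score:
        raise EucentricError("tracking feature lost: correlation peak too weak")
    du = _parabolic_offset(corr[pv, max(pu - 1, 0)], corr[pv, pu],
                           corr[pv, min(pu + 1, corr.shape[1] - 1)])
    dv = _parabolic_offset(corr[max(pv - 1, 0), pu], corr[pv, pu],
                           corr[min(pv + 1, corr.shape[0] - 1), pu])
    return (pu + du, pv + dv)


def _parabolic_offset(left: float, center: float, right: float) -> float:
    denom = left - 2.0 * center + right
    if denom >= 0 or abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))


def auto_eucentric(
    scope,
    alphas: tuple[float, float] = (-10.0, 10.0),
    heights: tuple[float, float] = (0.0, 20.0),
    *,
    feature_pixel: tuple[float, float] | None = None,
    template_half: int = 24,
    exposure_ms: float = 100.0,
    move_stage: bool = True,
) -> EucentricFit:
    """Closed-loop eucentric-height routine on a (virtual) microscope.

    Acquires an image at each of the four (tilt, height) states, measures
    the tracked feature's displacement along the direction perpendicular to
    the tilt axis (the detector u axis in the canonical geometry), runs the
    two-point regression and, when ``move_stage`` is set, commands the stage
    to the estimated eucentric height.

    ``feature_pixel`` seeds the template extraction in the first image; when
    omitted, the darkest smoothed spot (an absorbing crystal) is used.
    """
    a1, a2 = alphas
    z1, z2 = heights
    if a1 == a2 or z1 == z2:
        raise ValueError("need two distinct tilts and two distinct heights")

    scope.set_mode("imaging")
    template = None
    readings = {}
    for zi, z in ((1, z1), (2, z2)):
        scope.move_stage(z=z)
        for ai, a in ((1, a1), (2, a2)):
            scope.move_stage(alpha=a)
            frame = scope.acquire_frame(exposure_ms)
            if template is None:
                seed = feature_pixel or _darkest_spot(frame.pixels)
                template = _extract_template(frame.pixels, seed, template_half)
            # locate on every frame, including the first, so all four
            # readings share the same sub-pixel convention
            u, v = locate_feature(frame, template)
            readings[(ai, zi)] = float(u)
    meas = EucentricMeasurement(
        alpha1=a1, alpha2=a2, z1=z1, z2=z2,
        d11=readings[(1, 1)], d21=readings[(2, 1)],
        d12=readings[(1, 2)], d22=readings[(2, 2)],
    )
    fit = estimate_eucentric(meas)
    if move_stage:
        scope.move_stage(z=fit.z_euc)
    return fit


def _darkest_spot(pixels: np.ndarray) -> tuple[float, float]:
    from scipy import ndimage

    smoothed = ndimage.gaussian_filter(pixels.astype(float), 3.0)
    # restrict to the interior of the illuminated region: erode the mask so
    # the smoothed intensity ramp at the disc edge cannot masquerade as a
    # dark feature
    illuminated = smoothed > 0.5 * smoothed.max()
    illuminated = ndimage.binary_erosion(illuminated, iterations=10)
    if not illuminated.any():
        raise EucentricError("no illuminated region to search for a feature")
    masked = np.where(illuminated, smoothed, np.inf)
    v, u = np.unravel_index(np.argmin(masked), masked.shape)
    return (float(u), float(v))


def _extract_template(
    pixels: np.ndarray, center: tuple[float, float], half: int
) -> np.ndarray:
    u, v = int(round(center[0])), int(round(center[1]))
    rows, cols = pixels.shape
    u = min(max(u, half), cols - half - 1)
    v = min(max(v, half), rows - half - 1)
    return pixels[v - half : v + half + 1, u - half : u + half + 1].astype(float)
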