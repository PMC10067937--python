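"""Line-profile morphometry of endothelial junctions.

Implements the standard 1-D quantifications used on junction images:
junction width as the full width at half maximum (FWHM) of a Gaussian
fitted to a line profile drawn perpendicular to the junction; staining
organisation as the coefficient of variance of a line profile
(optionally normalised to its minimum — lower variance indicates less
organised structure); junctional intensity normalised to a background
region via channel-derived masks; and the Boltzmann sigmoid
y = A2 + (A1 − A2)/(1 + exp((x − x0)/dx)) used for pressure–response
curves of mechanosensitive channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

from .detect import RegionMask
from .image import Image
from .synthgen import FWHM_FACTOR

__all__ = [
    "LineProfile", "GaussianFit", "BoltzmannParams",
    "extract_line_profile", "gaussian_fwhm", "profile_cov",
    "mask_from_channel", "normalised_junctional_intensity", "boltzmann_fit",
]


@dataclass
class LineProfile:
    """Intensity trace along a scan line: positions in µm, intensities in counts."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class GaussianFit:
    """offset + amplitude·exp(−(x − centre)²/(2σ²)) fitted to a profile."""

    amplitude: float
    centre: float
    sigma: float
    offset: float
    fwhm: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        expected = FWHM_FACTOR * self.sigma
        if not np.isclose(self.fwhm, expected, rtol=1e-12, atol=1e-15):
            raise ValueError("fwhm must equal 2*sqrt(2*ln 2)*sigma")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.offset + self.amplitude * np.exp(
            -((x - self.centre) ** 2) / (2.0 * self.sigma ** 2))


@dataclass
class BoltzmannParams:
    """Sigmoid y = A2 + (A1 − A2)/(1 + exp((x − x0)/dx)).

    A1 and A2 are the asymptotes approached for x ≪ x0 and x ≫ x0
    respectively, x0 the midpoint (e.g. mmHg) and dx the slope factor.
    """

    A1: float
    A2: float
    x0: float
    dx: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.dx == 0:
            raise ValueError("dx must be nonzero")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.A2 + (self.A1 - self.A2) / (1.0 + np.exp((x - self.x0) / self.dx))


def extract_line_profile(image: Image, p0, p1, width_px: int = 1) -> LineProfile:
    """Sample an intensity profile along the segment p0→p1 (µm points).

    Bilinear interpolation at pixel-size spacing along the segment,
    averaged across ``width_px`` parallel offsets (1-px spacing) placed
    symmetrically about the line.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    ps = image.pixel_size
    h_um, w_um = image.shape[0] * ps, image.shape[1] * ps
    for p in (p0, p1):
        if not (0 <= p[0] <= w_um and 0 <= p[1] <= h_um):
            raise ValueError("profile endpoints must lie inside the image")
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValueError("degenerate (zero-length) segment")

    n_samples = int(np.floor(length / ps)) + 1
    t = np.arange(n_samples) * ps
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) * ps

    acc = np.zeros(n_samples)
    for off in offsets:
        pts = p0[None, :] + t[:, None] * direction[None, :] + off * normal[None, :]
        rows = pts[:, 1] / ps - 0.5
        cols = pts[:, 0] / ps - 0.5
        acc += ndimage.map_coordinates(image.raster, [rows, cols],
                                       order=1, mode="nearest")
    return LineProfile(positions=t, intensities=acc / width_px)


def gaussian_fwhm(profile: LineProfile) -> GaussianFit:
    """Fit offset + Gaussian to a peaked profile; width as FWHM.

    Raises on profiles with fewer than 5 samples or no detectable peak;
    a fit that fails to converge is returned with ``converged=False``
    rather than silently substituting another estimate.
    """
    x = profile.positions
    y = profile.intensities
    if len(x) < 5:
        raise ValueError("profile needs at least 5 samples")
    amp0 = float(np.max(y) - np.min(y))
    if amp0 <= 0 or np.ptp(y) < 1e-12 * max(1.0, abs(float(np.max(y)))):
        raise ValueError("no detectable peak in profile")
    offset0 = float(np.min(y))
    centre0 = float(x[int(np.argmax(y))])
    above_half = y - offset0 > amp0 / 2.0
    sigma0 = max(float(np.count_nonzero(above_half)) * float(np.mean(np.diff(x)))
                 / FWHM_FACTOR, float(np.mean(np.diff(x))))

    def model(xv, amp, centre, sigma, offset):
        return offset + amp * np.exp(-((xv - centre) ** 2) / (2.0 * sigma ** 2))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, x, y, p0=[amp0, centre0, sigma0, offset0],
                bounds=([0.0, x[0] - (x[-1] - x[0]), 1e-9, -np.inf],
                        [np.inf, x[-1] + (x[-1] - x[0]), np.inf, np.inf]),
                maxfev=10000)
        converged = True
    except RuntimeError:
        popt = [amp0, centre0, sigma0, offset0]
        converged = False
    amp, centre, sigma, offset = (float(v) for v in popt)
    return GaussianFit(amplitude=amp, centre=centre, sigma=sigma, offset=offset,
                       fwhm=FWHM_FACTOR * sigma, converged=converged)


def profile_cov(profile: LineProfile, normalise: str = "min") -> float:
    """Coefficient of variance (sample SD / mean) of a line profile.

    With ``normalise="min"`` the trace is first divided by its minimum
    (which must be positive), making the metric invariant under global
    multiplicative gain.  A constant trace has CoV 0.
    """
    y = np.asarray(profile.intensities, dtype=float)
    if normalise == "min":
        m = float(np.min(y))
        if m <= 0:
            raise ValueError(
                "trace minimum must be > 0 for normalise='min'; add an offset "
                "or use normalise='none'")
        y = y / m
    elif normalise != "none":
        raise ValueError("normalise must be 'min' or 'none'")
    mean = float(np.mean(y))
    if mean == 0:
        raise ValueError("zero-mean trace has undefined CoV")
    if len(y) < 2:
        return 0.0
    return float(np.std(y, ddof=1) / mean)


def mask_from_channel(image: Image, smooth_sigma_um: float = 0.1,
                      dilation_um: float = 0.1,
                      kind: str = "junctional") -> RegionMask:
    """Derive a junction mask from a staining channel.

    Gaussian smoothing, Otsu threshold, then morphological dilation by
    ``dilation_um`` to include the junction shoulders.  A featureless
    image yields an empty mask with a warning.
    """
    data = image.raster
    ps = image.pixel_size
    if smooth_sigma_um > 0:
        data = ndimage.gaussian_filter(data, smooth_sigma_um / ps)
    if np.ptp(data) == 0:
        warnings.warn("image has no contrast; returning an empty mask")
        return RegionMask(raster=np.zeros(image.shape, dtype=bool),
                          kind=kind, pixel_size=ps)
    mask = data > threshold_otsu(data)
    if not mask.any():
        warnings.warn("empty foreground after thresholding")
    radius_px = int(round(dilation_um / ps))
    if radius_px > 0 and mask.any():
        mask = dilation(mask, disk(radius_px))
    return RegionMask(raster=mask, kind=kind, pixel_size=ps)


def normalised_junctional_intensity(signal: Image, junction_mask: RegionMask,
                                    background_mask: RegionMask) -> float:
    """Mean intensity in the junction mask over the background-mask mean.

    The ratio is invariant under global multiplicative gain changes.
    """
    jm = junction_mask.as_raster(signal.shape, signal.pixel_size)
    bm = background_mask.as_raster(signal.shape, signal.pixel_size)
    if not jm.any() or not bm.any():
        raise ValueError("masks must be non-empty")
    if np.any(jm & bm):
        raise ValueError("junction and background masks must not overlap")
    background = float(signal.raster[bm].mean())
    if background == 0:
        raise ValueError("background mean intensity is zero")
    return float(signal.raster[jm].mean()) / background


def boltzmann_fit(x, y) -> BoltzmannParams:
    """Least-squares Boltzmann sigmoid fit to a stimulus–response curve.

    At the midpoint the curve passes through (A1 + A2)/2 for any slope
    factor.  Requires at least 5 points spanning the transition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 points to fit 4 parameters")

    a1_0 = float(y[np.argmin(x)])
    a2_0 = float(y[np.argmax(x)])
    mid = 0.5 * (a1_0 + a2_0)
    x0_0 = float(x[int(np.argmin(np.abs(y - mid)))])
    dx_0 = float((np.max(x) - np.min(x)) / 10.0) or 1.0

    def model(xv, a1, a2, x0, dx):
        return a2 + (a1 - a2) / (1.0 + np.exp((xv - x0) / dx))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(model, x, y, p0=[a1_0, a2_0, x0_0, dx_0],
                                         maxfev=20000)
        converged = True
    except RuntimeError:
        popt = [a1_0, a2_0, x0_0, dx_0]
        converged = False
    a1, a2, x0, dx = (float(v) for v in popt)
    if dx == 0:
        dx = np.finfo(float).tiny
    return BoltzmannParams(A1=a1, A2=a2, x0=x0, dx=dx, converged=converged)
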