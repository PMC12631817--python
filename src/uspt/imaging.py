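"""Synthetic wide-field EMCCD imaging and single-particle photometry.

The forward model renders sub-diffraction emitters onto a pixel grid: expected
photons per pixel from an integrated 2-D Gaussian point-spread function plus a
uniform background, Poisson shot noise, electron-multiplying gain as a
gamma-distributed multiplication (the standard EMCCD approximation with excess
noise factor sqrt(2)), Gaussian read noise, and conversion to camera counts
(ADU) with an offset.  The inverse path detects spots with a
Laplacian-of-Gaussian filter on the temporal mean frame, refines centroids by
local Gaussian fitting, and quantifies brightness in photons per second (pps)
by aperture photometry with local annulus background subtraction — undoing
gain, quantum efficiency and exposure so that estimates are directly
comparable across camera settings.

Conventions: pixel coordinates are 0-based with pixel centers on integer
coordinates; emitter positions are stored in nm and converted through the
camera pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "CameraModel",
    "EmitterGroundTruth",
    "ImageStack",
    "SpotMeasurement",
    "render_stack",
    "detect_spots",
    "quantify_brightness",
    "rg_ratio",
    "enhancement_factor",
]


@dataclass(frozen=True)
class CameraModel:
    """EMCCD noise/gain contract (defaults typical of a back-illuminated
    512x512 EM camera operated for single-particle work)."""

    pixel_size: float = 160.0  # nm per pixel (100x objective)
    em_gain: float = 300.0
    electrons_per_adu: float = 12.0
    quantum_efficiency: float = 0.9
    read_noise: float = 50.0  # electrons rms (post-register, pre-gain-divide)
    offset: float = 100.0  # ADU
    exposure: float = 0.05  # s

    def __post_init__(self) -> None:
        for name in (
            "pixel_size", "em_gain", "electrons_per_adu",
            "quantum_efficiency", "read_noise", "offset", "exposure",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum_efficiency must lie in (0, 1]")


@dataclass(frozen=True)
class EmitterGroundTruth:
    """A point emitter with channel photon rates (photons per second)."""

    position: tuple[float, float]  # (x, y) in nm
    photon_rate_green: float = 0.0
    photon_rate_red: float = 0.0
    psf_sigma: float = 208.0  # nm (~1.3 px at 160 nm px)

    def __post_init__(self) -> None:
        if self.photon_rate_green < 0 or self.photon_rate_red < 0:
            raise ValueError("photon rates must be non-negative")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")

    def rate(self, channel: str) -> float:
        if channel == "green":
            return self.photon_rate_green
        if channel == "red":
            return self.photon_rate_red
        if channel == "broadband":
            return self.photon_rate_green + self.photon_rate_red
        raise ValueError(f"unknown channel {channel!r}")


@dataclass
class ImageStack:
    """A time series of camera frames (ADU) from one channel."""

    frames: np.ndarray  # (n_frames, ny, nx)
    frame_interval: float  # s
    channel: str = "broadband"
    saturated: np.ndarray | None = None  # bool mask of clipped pixels

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")
        if np.any(self.frames < 0):
            raise ValueError("pixel values must be non-negative")

    @property
    def mean_frame(self) -> np.ndarray:
        return self.frames.mean(axis=0)


@dataclass(frozen=True)
class SpotMeasurement:
    """Aperture-photometry result for one spot."""

    centroid: tuple[float, float]  # (x, y) nm
    integrated_photons_per_s: float
    background_per_pixel: float  # pps per pixel
    snr: float
    channel: str = "broadband"


def _integrated_gaussian(
    shape: tuple[int, int], x_px: float, y_px: float, sigma_px: float
) -> np.ndarray:
    """Fraction of a unit 2-D Gaussian falling in each pixel (erf integral)."""
    ny, nx = shape
    xs = np.arange(nx)
    ys = np.arange(ny)
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((xs - x_px + 0.5) / s) - erf((xs - x_px - 0.5) / s))
    fy = 0.5 * (erf((ys - y_px + 0.5) / s) - erf((ys - y_px - 0.5) / s))
    return np.outer(fy, fx)


def render_stack(
    emitters: list[EmitterGroundTruth],
    camera: CameraModel = CameraModel(),
    n_frames: int = 20,
    shape: tuple[int, int] = (64, 64),
    channel: str = "broadband",
    background_photons_per_px_s: float = 0.0,
    seed: int = 0,
    noiseless: bool = False,
    max_adu: float = 65535.0,
) -> ImageStack:
    """Render a synthetic EMCCD image stack.

    Per frame: expected photons = rate x exposure x QE over an integrated-
    Gaussian PSF plus uniform background; Poisson shot noise; gamma-
    distributed EM multiplication; Gaussian read noise; ADU conversion with
    offset, clipped at ``max_adu`` with a saturation mask.  Bit-identical for
    identical seeds.  With ``noiseless`` the expected ADU values are returned
    directly (no noise of any kind), which makes the photon bookkeeping
    exactly invertible for tests and calibration.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    expected_photons = np.full(
        shape, background_photons_per_px_s * camera.exposure, dtype=float
    )
    for em in emitters:
        x_px = em.position[0] / camera.pixel_size
        y_px = em.position[1] / camera.pixel_size
        if not (0 <= x_px < nx and 0 <= y_px < ny):
            raise ValueError(f"emitter at {em.position} outside the field of view")
        total = em.rate(channel) * camera.exposure
        expected_photons += total * _integrated_gaussian(
            shape, x_px, y_px, em.psf_sigma / camera.pixel_size
        )
    expected_electrons = expected_photons * camera.quantum_efficiency

    frames = np.empty((n_frames,) + shape)
    saturated = np.zeros((n_frames,) + shape, dtype=bool)
    for f in range(n_frames):
        if noiseless:
            out_e = expected_electrons * camera.em_gain
        else:
            n_e = rng.poisson(expected_electrons)
            # EM register: sum of n iid exponentials = gamma(shape=n, scale=gain)
            out_e = np.where(
                n_e > 0, rng.standard_gamma(n_e) * camera.em_gain, 0.0
            )
            out_e = out_e + camera.read_noise * rng.standard_normal(shape)
        adu = out_e / camera.electrons_per_adu + camera.offset
        saturated[f] = adu > max_adu
        frames[f] = np.clip(adu, 0.0, max_adu)
    return ImageStack(
        frames=frames,
        frame_interval=camera.exposure,
        channel=channel,
        saturated=saturated,
    )


def detect_spots(
    stack: ImageStack,
    camera: CameraModel = CameraModel(),
    detection_sigma: float = 1.3,  # px
    threshold: float | None = None,  # LoG response threshold (ADU); None = auto
    snr_threshold: float = 5.0,
) -> pd.DataFrame:
    """Detect sub-diffraction spots on the temporal mean frame.

    Laplacian-of-Gaussian blob detection followed by sub-pixel refinement via
    a local 2-D Gaussian least-squares fit in a 7x7 window.  When
    ``threshold`` is None it is set to ``snr_threshold`` times the robust
    (MAD-based) pixel noise of the background-subtracted mean frame.  Returns
    a DataFrame with columns (x_nm, y_nm, x_px, y_px, intensity), sorted by
    intensity, possibly empty.  Deterministic.
    """
    from skimage.feature import blob_log

    mean = stack.mean_frame.astype(float)
    if threshold is not None and not np.isfinite(threshold):
        return pd.DataFrame(columns=["x_nm", "y_nm", "x_px", "y_px", "intensity"])
    bg = np.median(mean)
    if threshold is None:
        noise = 1.4826 * np.median(np.abs(mean - bg))
        # LoG response of a matched Gaussian peak is ~half its amplitude
        threshold = 0.5 * snr_threshold * max(noise, 1e-12)
    blobs = blob_log(
        np.clip(mean - bg, 0, None),
        min_sigma=detection_sigma * 0.7,
        max_sigma=detection_sigma * 1.8,
        num_sigma=5,
        threshold=threshold,
    )
    rows = []
    ny, nx = mean.shape
    for y0, x0, _sig in blobs:
        yi, xi = int(round(y0)), int(round(x0))
        half = 3
        if not (half <= xi < nx - half and half <= yi < ny - half):
            continue
        window = mean[yi - half : yi + half + 1, xi - half : xi + half + 1] - bg
        xr, yr = _gaussian_refine(window, detection_sigma)
        x_px, y_px = xi + xr, yi + yr
        rows.append(
            {
                "x_nm": x_px * camera.pixel_size,
                "y_nm": y_px * camera.pixel_size,
                "x_px": x_px,
                "y_px": y_px,
                "intensity": float(window[half, half]),
            }
        )
    df = pd.DataFrame(rows, columns=["x_nm", "y_nm", "x_px", "y_px", "intensity"])
    return df.sort_values("intensity", ascending=False, ignore_index=True)


def _gaussian_refine(window: np.ndarray, sigma_px: float) -> tuple[float, float]:
    """Sub-pixel offset of a peak inside a centered odd-sized window."""
    from scipy.optimize import least_squares

    half = window.shape[0] // 2
    ys, xs = np.mgrid[-half : half + 1, -half : half + 1]
    amp0 = max(float(window[half, half]), 1e-9)

    def resid(p):
        a, x0, y0, s = p
        model = a * np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * s**2))
        return (model - window).ravel()

    fit = least_squares(
        resid,
        x0=[amp0, 0.0, 0.0, sigma_px],
        bounds=([0, -1.5, -1.5, 0.3], [np.inf, 1.5, 1.5, 4.0]),
        max_nfev=200,
    )
    return float(fit.x[1]), float(fit.x[2])


def quantify_brightness(
    stack: ImageStack,
    centroid_nm: tuple[float, float],
    camera: CameraModel = CameraModel(),
    aperture_radius_px: float | None = None,
    annulus_px: tuple[float, float] | None = None,
    psf_sigma_px: float = 1.3,
) -> SpotMeasurement:
    """Aperture photometry in photons per second.

    ADU are converted back to photons via (ADU - offset) * e_per_ADU /
    (EM gain * QE); the signal is integrated over a circular aperture
    (default radius 3 sigma) minus the per-pixel background estimated in an
    annulus (default 5-7 sigma), divided by the exposure.  SNR is the mean
    per-frame aperture signal over the standard deviation of the annulus-
    background-integrated aperture across frames.
    """
    if aperture_radius_px is None:
        aperture_radius_px = 3.0 * psf_sigma_px
    if annulus_px is None:
        annulus_px = (5.0 * psf_sigma_px, 7.0 * psf_sigma_px)
    ny, nx = stack.frames.shape[1:]
    x_px = centroid_nm[0] / camera.pixel_size
    y_px = centroid_nm[1] / camera.pixel_size
    r_out = annulus_px[1]
    if not (
        r_out <= x_px <= nx - 1 - r_out and r_out <= y_px <= ny - 1 - r_out
    ):
        raise ValueError("aperture/annulus clipped by the frame edge")

    ys, xs = np.mgrid[0:ny, 0:nx]
    r2 = (xs - x_px) ** 2 + (ys - y_px) ** 2
    ap = r2 <= aperture_radius_px**2
    ann = (r2 >= annulus_px[0] ** 2) & (r2 <= annulus_px[1] ** 2)
    n_ap = int(ap.sum())

    photons = (
        (stack.frames - camera.offset)
        * camera.electrons_per_adu
        / (camera.em_gain * camera.quantum_efficiency)
    )
    bg_per_px = photons[:, ann].mean(axis=1)  # per frame
    signal = photons[:, ap].sum(axis=1) - n_ap * bg_per_px  # photons per frame
    # aperture correction: fraction of an integrated Gaussian PSF inside r
    enclosed = 1.0 - np.exp(-(aperture_radius_px**2) / (2.0 * psf_sigma_px**2))
    signal = signal / enclosed
    pps = float(signal.mean() / camera.exposure)
    noise = float(signal.std(ddof=1)) if len(signal) > 1 else 0.0
    snr = float(signal.mean() / noise) if noise > 0 else np.inf
    return SpotMeasurement(
        centroid=tuple(centroid_nm),
        integrated_photons_per_s=max(pps, 0.0) if pps > -np.inf else pps,
        background_per_pixel=float(bg_per_px.mean() / camera.exposure),
        snr=snr,
        channel=stack.channel,
    )


def rg_ratio(
    green_stack: ImageStack,
    red_stack: ImageStack,
    centroid_nm: tuple[float, float],
    camera: CameraModel = CameraModel(),
    **kwargs,
) -> float:
    """Red-to-green brightness ratio of one particle from two channel stacks."""
    green = quantify_brightness(green_stack, centroid_nm, camera, **kwargs)
    red = quantify_brightness(red_stack, centroid_nm, camera, **kwargs)
    if green.integrated_photons_per_s <= 0:
        raise ValueError("green brightness is non-positive; R/G undefined")
    return red.integrated_photons_per_s / green.integrated_photons_per_s


def enhancement_factor(
    measurements_a: list[SpotMeasurement] | np.ndarray,
    measurements_b: list[SpotMeasurement] | np.ndarray,
) -> tuple[float, float]:
    """Ratio of mean brightness between two particle groups, with delta-method SD.

    Returns (mean_a / mean_b, sd) where the SD propagates the standard errors
    of both group means to first order.
    """
    def to_rates(ms):
        if len(ms) == 0:
            raise ValueError("empty measurement group")
        arr = np.asarray(
            [
                m.integrated_photons_per_s if isinstance(m, SpotMeasurement) else m
                for m in ms
            ],
            dtype=float,
        )
        return arr

    a, b = to_rates(measurements_a), to_rates(measurements_b)
    mean_a, mean_b = a.mean(), b.mean()
    if mean_b == 0:
        raise ValueError("reference group mean is zero; factor undefined")
    factor = mean_a / mean_b
    se_a = a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0
    se_b = b.std(ddof=1) / np.sqrt(len(b)) if len(b) > 1 else 0.0
    sd = abs(factor) * np.sqrt(
        (se_a / mean_a) ** 2 + (se_b / mean_b) ** 2 if mean_a != 0 else (se_b / mean_b) ** 2
    )
    return float(factor), float(sd)
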