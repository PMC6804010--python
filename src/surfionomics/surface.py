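"""Anatomical surface metrics for chemical images.

Four families of parameters describe the substrate surface as seen in a
total-ion or carbohydrate-fragment image:

* **Differential entropy** of the intensity distribution (plug-in binned
  estimator on normalized [0, 1] intensities, reported in nats), with a
  *deficit* against the maximum-entropy Gaussian reference of matched
  variance — amorphous deposits lower the entropy below that reference.
* **Roughness/waviness**: a Gaussian low-pass at a cutoff wavelength
  splits the intensity surface into a long-wavelength waviness component
  and a short-wavelength roughness residual (Ra = mean |residual|,
  Rq = RMS residual, Wa = mean |waviness − grand mean|).  The Gaussian
  sigma follows the metrology convention of 50% amplitude transmission
  at the cutoff, sigma = cutoff * sqrt(ln 2 / 2) / pi.
* **Periodic-structure area fraction**: the share of image windows whose
  autocorrelation, collapsed along sampled directions, shows a secondary
  peak — the signature of preserved parallel fibril/lattice ordering.
* **Excavation statistics**: roughly circular dark pits (inverted-IsoData
  segmentation, circularity-filtered), counted per 100×100 µm² with mean
  equivalent radius and an intensity depth *proxy* (background mean minus
  pit mean); true depth in nm would need calibrated depth profiling and
  is deliberately not reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import measure

from .exceptions import DegenerateImageError
from .imgio import ChemImage
from .segmentation import isodata_threshold

__all__ = [
    "SurfaceMetrics",
    "ExcavationStats",
    "surface_entropy",
    "roughness_waviness",
    "periodic_area_fraction",
    "detect_excavations",
    "compute_surface_metrics",
]

#: Gaussian sigma per unit cutoff wavelength (50% transmission at cutoff).
_SIGMA_PER_CUTOFF = float(np.sqrt(np.log(2.0) / 2.0) / np.pi)


@dataclass
class ExcavationStats:
    count_per_field: float  # normalized to a 100x100 um^2 field
    mean_radius_um: float
    mean_depth_proxy: float  # intensity units, NOT nm
    n_detected: int = 0


@dataclass
class SurfaceMetrics:
    """Per-image anatomical parameter set fed to the discriminant analysis."""

    entropy_nats: float
    entropy_deficit_nats: float
    roughness_Ra: float
    roughness_Rq: float
    waviness_Wa: float
    periodic_area_pct: float
    excavations: ExcavationStats

    def __post_init__(self) -> None:
        if not (self.roughness_Rq >= self.roughness_Ra >= 0.0):
            raise ValueError("require Rq >= Ra >= 0")
        if not 0.0 <= self.periodic_area_pct <= 100.0:
            raise ValueError("periodic_area_pct must lie in [0, 100]")


def surface_entropy(image: ChemImage | np.ndarray, bins: int = 64) -> tuple[float, float]:
    """Plug-in differential entropy (nats) and Gaussian-reference deficit.

    Intensities are normalized to [0, 1] and binned into ``bins`` equal
    widths Delta; H = -sum p_i ln(p_i / Delta).  The deficit is
    ``H_ref - H`` with ``H_ref = 0.5 * ln(2 pi e sigma^2)`` the entropy of
    a Gaussian with the image's variance.  The deficit can be marginally
    negative for truly Gaussian images (estimator discretization bias).
    """
    data = image.data if isinstance(image, ChemImage) else np.asarray(image)
    x = data.ravel().astype(np.float64) / 255.0
    if x.max() == x.min():
        raise DegenerateImageError("constant image: entropy undefined")
    counts, _ = np.histogram(x, bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    p = p[p > 0]
    delta = 1.0 / bins
    h = float(-(p * np.log(p / delta)).sum())
    sigma2 = float(np.var(x))
    h_ref = 0.5 * float(np.log(2.0 * np.pi * np.e * sigma2))
    return h, h_ref - h


def roughness_waviness(
    image: ChemImage, cutoff_um: float = 8.0
) -> tuple[float, float, float]:
    """Split the intensity surface at ``cutoff_um`` and summarize both parts.

    Returns ``(Ra, Rq, Wa)`` in intensity units (0–255 scale).
    """
    if not cutoff_um > 2.0 * image.pixel_size_um:
        raise ValueError("cutoff_um must exceed twice the pixel size")
    x = image.data.astype(np.float64)
    sigma_px = _SIGMA_PER_CUTOFF * cutoff_um / image.pixel_size_um
    waviness = ndimage.gaussian_filter(x, sigma_px, mode="reflect")
    residual = x - waviness
    ra = float(np.mean(np.abs(residual)))
    rq = float(np.sqrt(np.mean(residual**2)))
    wa = float(np.mean(np.abs(waviness - waviness.mean())))
    return ra, rq, wa


def _window_is_periodic(win: np.ndarray, prominence: float, n_angles: int = 24) -> bool:
    """Secondary-peak test on directionally collapsed autocorrelation."""
    w = win - win.mean()
    denom = float((w * w).sum())
    if denom <= 0.0:
        return False
    n0, n1 = w.shape
    f = np.fft.rfft2(w, s=(2 * n0, 2 * n1))
    ac = np.fft.irfft2(f * np.conj(f), s=(2 * n0, 2 * n1)) / denom
    ac = np.fft.fftshift(ac)
    c0, c1 = n0, n1  # center after fftshift of a (2n0, 2n1) array
    rmax = min(n0, n1) - 2
    if rmax < 3:
        return False
    radii = np.arange(0, rmax + 1, dtype=np.float64)
    for theta in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        rows = c0 + radii * np.sin(theta)
        cols = c1 + radii * np.cos(theta)
        profile = ndimage.map_coordinates(ac, [rows, cols], order=1, mode="nearest")
        peaks, _ = signal.find_peaks(profile, prominence=prominence)
        if peaks.size and np.any(peaks > 0):
            return True
    return False


def periodic_area_fraction(
    image: ChemImage, window_um: float = 12.5, prominence: float = 0.3
) -> float:
    """Percent of image windows showing periodic (fringe/lattice) ordering.

    The image is tiled into square windows of ``window_um``; a window is
    periodic when its normalized autocorrelation, sampled along a fan of
    directions, has a secondary peak with at least ``prominence``.  The
    window should fit >= 3 periods of the structure sought.
    """
    w_px = int(round(window_um / image.pixel_size_um))
    if w_px > min(image.shape):
        raise ValueError("window larger than image")
    if w_px < 8:
        raise ValueError("window too small to resolve periodicity")
    n_r = image.shape[0] // w_px
    n_c = image.shape[1] // w_px
    x = image.data.astype(np.float64)
    total = n_r * n_c
    periodic = 0
    for i in range(n_r):
        for j in range(n_c):
            win = x[i * w_px : (i + 1) * w_px, j * w_px : (j + 1) * w_px]
            if _window_is_periodic(win, prominence):
                periodic += 1
    return 100.0 * periodic / total


def detect_excavations(
    image: ChemImage, min_circularity: float = 0.5
) -> ExcavationStats:
    """Detect roughly circular dark pits and normalize their count per field.

    Dark blobs are segmented with the inverted IsoData threshold
    (foreground = intensity strictly below T); components with
    circularity 4*pi*A/P^2 >= ``min_circularity`` are retained.  The count
    is normalized to a 100×100 µm² field.
    """
    try:
        t = isodata_threshold(image)
    except DegenerateImageError:
        return ExcavationStats(0.0, 0.0, 0.0, 0)
    dark = image.data < t
    if dark.mean() > 0.25:
        # threshold fell inside a single intensity mode: no dark-pit phase
        return ExcavationStats(0.0, 0.0, 0.0, 0)
    labels = measure.label(dark, connectivity=2)
    px = image.pixel_size_um
    radii: list[float] = []
    depths: list[float] = []
    bg_mean = float(image.data[~dark].mean()) if (~dark).any() else float(image.data.mean())
    for rp in measure.regionprops(labels, intensity_image=image.data):
        per = rp.perimeter
        circ = 1.0 if per == 0 else 4.0 * np.pi * rp.area / per**2
        if circ < min_circularity:
            continue
        area = rp.area * px * px
        radii.append(float(np.sqrt(area / np.pi)))
        depths.append(bg_mean - float(rp.intensity_mean))
    n = len(radii)
    return ExcavationStats(
        count_per_field=n * 1.0e4 / image.field_area_um2,
        mean_radius_um=float(np.mean(radii)) if n else 0.0,
        mean_depth_proxy=float(np.mean(depths)) if n else 0.0,
        n_detected=n,
    )


def compute_surface_metrics(
    image: ChemImage,
    bins: int = 64,
    cutoff_um: float = 8.0,
    window_um: float = 12.5,
    prominence: float = 0.3,
    min_circularity: float = 0.5,
) -> SurfaceMetrics:
    """All anatomical parameters of one image in one call."""
    h, deficit = surface_entropy(image, bins=bins)
    ra, rq, wa = roughness_waviness(image, cutoff_um=cutoff_um)
    pct = periodic_area_fraction(image, window_um=window_um, prominence=prominence)
    exc = detect_excavations(image, min_circularity=min_circularity)
    return SurfaceMetrics(h, deficit, ra, rq, wa, pct, exc)
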