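"""IsoData thresholding, particle analysis, and co-location statistics.

The analysis chain reproduces the classic ImageJ workflow for ion maps:
an automatic intermeans (IsoData / Ridler–Calvard) threshold splits each
chemical image into a high-intensity foreground ("ionic spots") and
background; connected components of the foreground under 8-connectivity
are the ionic aggregates, summarized as count, total area, mean size and
densitometric intensity; pairs of binary maps give coverage fractions
(what share of one chemistry's sites a second ion sits on).

Conventions fixed here so results are bit-reproducible:

* foreground is *strictly greater than* the threshold;
* the IsoData iteration ``T <- round((mu_low + mu_high) / 2)`` rounds
  half-integer ties toward the smaller level;
* components use 8-connectivity (the particle-analysis default of the
  tool this mirrors);
* no minimum particle size is applied unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage import measure

from .exceptions import DegenerateImageError, EmptySitesError
from .imgio import ChemImage

__all__ = [
    "BinaryMap",
    "Particle",
    "ParticleStats",
    "isodata_threshold",
    "binarize",
    "isodata_binarize",
    "label_particles",
    "coverage_fraction",
    "free_fraction",
    "colocated_site_fraction",
]


def _round_half_down(x: float) -> int:
    """Round to nearest integer, half-integer ties toward the smaller value."""
    return int(np.ceil(x - 0.5))


def isodata_threshold(image: ChemImage | np.ndarray) -> int:
    """Iterative intermeans (IsoData) threshold on the 256-bin histogram.

    The map ``T <- round((mean(values <= T) + mean(values > T)) / 2)``
    (half-integer rounding toward the smaller level) is iterated from the
    midpoint of the occupied intensity range until it converges; the
    returned threshold is the smallest level of the contiguous plateau of
    fixed points containing the convergence point, so every tie resolves
    toward the smaller T.  On unimodal (noise-like) histograms all fixed
    points form one plateau and this equals the global smallest fixed
    point; on bimodal signal histograms the iteration keeps the
    between-modes solution.  All 256 levels participate in the histogram
    (no extreme-bin exclusion).  Raises for constant images.
    """
    data = image.data if isinstance(image, ChemImage) else np.asarray(image)
    hist = np.bincount(data.ravel(), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    occupied = np.nonzero(hist)[0]
    if occupied.size < 2:
        raise DegenerateImageError("constant image: IsoData threshold undefined")
    lo, hi = int(occupied[0]), int(occupied[-1])

    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * levels)
    total, moment = csum[-1], cmoment[-1]

    def step(t: int) -> int:
        m_lo = cmoment[t] / csum[t]
        m_hi = (moment - cmoment[t]) / (total - csum[t])
        return min(max(_round_half_down((m_lo + m_hi) / 2.0), lo), hi - 1)

    t = min(max(_round_half_down((lo + hi) / 2.0), lo), hi - 1)
    seen: list[int] = []
    while t not in seen:
        seen.append(t)
        t = step(t)
    t = min(seen[seen.index(t):])  # a rounding cycle resolves downward
    while t - 1 >= lo and step(t - 1) == t - 1:
        t -= 1
    return t


@dataclass
class BinaryMap:
    """Thresholded two-phase map of a chemical image."""

    mask: np.ndarray
    threshold: int
    source: ChemImage
    method: str = "isodata"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.source.shape:
            raise ValueError("mask shape must equal source image shape")
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")

    @property
    def pixel_size_um(self) -> float:
        return self.source.pixel_size_um

    @property
    def foreground_area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2


def binarize(image: ChemImage, threshold: int, method: str = "manual") -> BinaryMap:
    """Foreground = pixels strictly brighter than ``threshold``."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return BinaryMap(image.data > threshold, int(threshold), image, method=method)


def isodata_binarize(image: ChemImage) -> BinaryMap:
    """IsoData threshold followed by binarization."""
    t = isodata_threshold(image)
    bm = binarize(image, t, method="isodata")
    return bm


class Particle(NamedTuple):
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y), pixel-center convention
    equivalent_radius_um: float
    mean_intensity: float


@dataclass
class ParticleStats:
    """Aggregate particle statistics of one binary map (one table row)."""

    count: int
    total_area_um2: float
    mean_size_um2: float
    mean_intensity: float
    particles: list[Particle] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.count != len(self.particles):
            raise ValueError("count must equal the number of particles")
        if self.count:
            if abs(self.total_area_um2 - sum(p.area_um2 for p in self.particles)) > 1e-9:
                raise ValueError("total area must equal the sum of particle areas")
            if abs(self.mean_size_um2 - self.total_area_um2 / self.count) > 1e-9:
                raise ValueError("mean size must equal total area / count")


def label_particles(bmap: BinaryMap, min_size_um2: float = 0.0) -> ParticleStats:
    """Connected-component particle statistics under 8-connectivity.

    Per-particle area (µm²), centroid (µm, pixel centers), equivalent
    circular radius and mean source intensity; aggregates follow the
    ParticleStats invariants.  ``min_size_um2`` drops smaller particles
    (default: none dropped).
    """
    px = bmap.pixel_size_um
    px_area = px * px
    labels = measure.label(bmap.mask, connectivity=2)
    particles: list[Particle] = []
    for rp in measure.regionprops(labels, intensity_image=bmap.source.data):
        area = rp.area * px_area
        if area < min_size_um2:
            continue
        r, c = rp.centroid
        particles.append(
            Particle(
                area_um2=float(area),
                centroid_um=((c + 0.5) * px, (r + 0.5) * px),
                equivalent_radius_um=float(np.sqrt(area / np.pi)),
                mean_intensity=float(rp.intensity_mean),
            )
        )
    count = len(particles)
    total = float(sum(p.area_um2 for p in particles))
    return ParticleStats(
        count=count,
        total_area_um2=total,
        mean_size_um2=total / count if count else 0.0,
        mean_intensity=float(np.mean([p.mean_intensity for p in particles])) if count else 0.0,
        particles=particles,
    )


def _check_shapes(ion: BinaryMap, sites: BinaryMap) -> None:
    if ion.mask.shape != sites.mask.shape:
        raise ValueError("ion and site maps must share a grid shape")


def coverage_fraction(ion: BinaryMap, sites: BinaryMap) -> float:
    """Percent of site foreground pixels covered by the ion foreground."""
    _check_shapes(ion, sites)
    n_sites = int(sites.mask.sum())
    if n_sites == 0:
        raise EmptySitesError("site map has no foreground pixels")
    return 100.0 * int((ion.mask & sites.mask).sum()) / n_sites


def free_fraction(ion: BinaryMap, sites: BinaryMap) -> float:
    """Percent of site pixels free of the ion; exact complement of coverage."""
    return 100.0 - coverage_fraction(ion, sites)


def colocated_site_fraction(ion: BinaryMap, sites: BinaryMap) -> float:
    """Percent of site aggregates touched by at least one ion pixel."""
    _check_shapes(ion, sites)
    labels = measure.label(sites.mask, connectivity=2)
    n = labels.max()
    if n == 0:
        raise EmptySitesError("site map has no aggregates")
    touched = np.unique(labels[ion.mask & sites.mask])
    touched = touched[touched > 0]
    return 100.0 * touched.size / n
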