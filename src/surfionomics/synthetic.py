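"""Synthetic ion-map image suites and saccharification curves with known truth.

The generator emulates the structure of micrometer-scale ToF-SIMS chemical
images of pretreated sugarcane bagasse so that every downstream stage
(segmentation, surface metrics, discriminant analysis, curve comparison)
can be exercised and validated against planted ground truth:

* three aggregate point processes — homogeneous *random*, Thomas-process
  *clustered*, and *fibril_periodic* (aggregates strung along parallel,
  gently sinusoidal ridges, the fingerprint of intact fibril ordering);
* ion/(-OH) co-location pairs with a requested pixel-coverage fraction;
* a five-pretreatment image suite whose planted ionic signatures follow
  the field's reference particle table: Li⁺ aggregate counts ordered
  control > organosolv (EtOH:DMSO:AO) > steam explosion > microwave:acid,
  with alkali (NaOH) lowest, and whose non-lithium channels share
  signatures within the pretreatment groups {control, EtOH:DMSO:AO},
  {steam, microwave} while NaOH stands apart — lithium is therefore the
  planted discriminating channel group;
* reducing-sugar release curves with configurable fold effects at 10 h
  versus control (2.04, 1.74, 0.9 in the bundled study recipes) and an
  optional post-10 h decay.

All randomness flows from a single integer seed through counter-based
stream splitting; fixed seed means bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import child_rng
from .exceptions import InfeasibleCoverageError, OverlapPlacementError
from .imgio import ChemImage

__all__ = [
    "ImageRecipe",
    "CurveRecipe",
    "TreatmentSuite",
    "gen_ion_map",
    "gen_coloc_pair",
    "gen_treatment_suite",
    "gen_saccharification",
    "noise_free_curve",
    "study_curve_recipes",
    "TREATMENTS",
    "ION_CHANNELS",
    "ANATOMY_CHANNEL",
    "OH_CHANNEL",
]

_PATTERNS = ("random", "clustered", "fibril_periodic")

TREATMENTS = ["Control", "EtOH_DMSO_AO", "SteamExplosion", "Microwave_H2SO4", "NaOH"]
ION_CHANNELS = ["Li", "Na", "K", "Mg", "CaC3H4", "F", "Cl", "DDA"]
OH_CHANNEL = "OH"
ANATOMY_CHANNEL = "CHO"


@dataclass
class ImageRecipe:
    """Recipe for one synthetic ion-map image."""

    field_size_um: float = 100.0
    pixels_per_um: float = 2.56
    pattern: str = "random"
    n_aggregates: int = 50
    aggregate_radius_um: tuple[float, float] = (0.6, 0.15)  # (mean, sd)
    intensity_fg: int = 200
    intensity_bg: int = 30
    noise_sd: float = 6.0
    coloc_target: tuple[str, float] | None = None  # (site channel, coverage in [0,1])
    ridge_period_um: float = 4.0
    channel: str = "ion"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"pattern must be one of {_PATTERNS}")
        if self.n_aggregates < 0:
            raise ValueError("n_aggregates must be >= 0")
        if not self.intensity_fg > self.intensity_bg:
            raise ValueError("intensity_fg must exceed intensity_bg")
        if self.coloc_target is not None and not 0.0 <= self.coloc_target[1] <= 1.0:
            raise InfeasibleCoverageError("coverage_fraction must lie in [0, 1]")
        if self.field_size_um <= 0 or self.pixels_per_um <= 0:
            raise ValueError("field size and resolution must be positive")

    @property
    def n_pixels(self) -> int:
        return int(round(self.field_size_um * self.pixels_per_um))

    @property
    def pixel_size_um(self) -> float:
        return self.field_size_um / self.n_pixels


def _draw_radii(recipe: ImageRecipe, rng: np.random.Generator) -> np.ndarray:
    mean, sd = recipe.aggregate_radius_um
    r = np.abs(rng.normal(mean, sd, recipe.n_aggregates))
    lo = 0.5 * recipe.pixel_size_um
    return np.clip(r, lo, recipe.field_size_um / 8.0)


def _place_aggregates(
    recipe: ImageRecipe,
    rng: np.random.Generator,
    max_tries: int = 500,
    inside_mask_um: tuple[np.ndarray, float] | None = None,
    inside_prob: float = 0.0,
) -> pd.DataFrame:
    """Non-overlapping disc placement for the recipe's point process.

    ``inside_mask_um`` optionally provides (boolean mask, pixel size) of a
    region; each disc is seeded inside it with probability ``inside_prob``
    (used to plant ion/site co-location in the treatment suite).
    """
    n = recipe.n_aggregates
    field = recipe.field_size_um
    gap = 1.5 * recipe.pixel_size_um  # keep blurred discs separable
    radii = _draw_radii(recipe, rng)
    xs = np.empty(n)
    ys = np.empty(n)

    if recipe.pattern == "clustered":
        n_parents = max(1, int(round(n / 8)))
        parents = rng.uniform(0.0, field, size=(n_parents, 2))
        cluster_sd = field / 15.0
    elif recipe.pattern == "fibril_periodic":
        period = recipe.ridge_period_um
        n_ridges = max(1, int(field / period))
        ridge_idx = rng.integers(0, n_ridges, size=n)
        undulation = 0.15 * period
        wavelength = field / 2.0

    inside_pts = None
    if inside_mask_um is not None and inside_prob > 0.0:
        mask, px = inside_mask_um
        rr, cc = np.nonzero(mask)
        if rr.size:
            inside_pts = np.column_stack([(cc + 0.5) * px, (rr + 0.5) * px])

    for i in range(n):
        r = radii[i]
        lo, hi = r, field - r
        if lo >= hi:
            raise OverlapPlacementError("aggregate radius exceeds the field")
        # pattern-conditional attempts first; then uniform spill-over
        # attempts so dense clusters degrade gracefully before erroring
        for attempt in range(2 * max_tries):
            if attempt >= max_tries:
                x = rng.uniform(lo, hi)
                y = rng.uniform(lo, hi)
            elif inside_pts is not None and rng.random() < inside_prob:
                x, y = inside_pts[rng.integers(0, len(inside_pts))]
                x = float(np.clip(x, lo, hi))
                y = float(np.clip(y, lo, hi))
            elif recipe.pattern == "random":
                x = rng.uniform(lo, hi)
                y = rng.uniform(lo, hi)
            elif recipe.pattern == "clustered":
                px0, py0 = parents[rng.integers(0, n_parents)]
                x = px0 + rng.normal(0.0, cluster_sd)
                y = py0 + rng.normal(0.0, cluster_sd)
                if not (lo <= x <= hi and lo <= y <= hi):
                    continue
            else:  # fibril_periodic
                x = rng.uniform(lo, hi)
                y0 = (ridge_idx[i] + 0.5) * period
                y = y0 + undulation * np.sin(2.0 * np.pi * x / wavelength)
                if not (lo <= y <= hi):
                    continue
            d2 = (xs[:i] - x) ** 2 + (ys[:i] - y) ** 2
            if i == 0 or np.all(d2 > (radii[:i] + r + gap) ** 2):
                xs[i], ys[i] = x, y
                break
        else:
            raise OverlapPlacementError(
                f"could not place aggregate {i + 1}/{n} without overlap"
            )
    return pd.DataFrame({"center_x_um": xs, "center_y_um": ys, "radius_um": radii})


def _disc_mask(shape: tuple[int, int], truth: pd.DataFrame, px: float) -> np.ndarray:
    """Exact pixel-center disc mask for a ground-truth table."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for x, y, r in truth.itertuples(index=False):
        c0 = max(int((x - r) / px - 1), 0)
        c1 = min(int((x + r) / px + 2), w)
        r0 = max(int((y - r) / px - 1), 0)
        r1 = min(int((y + r) / px + 2), h)
        if c0 >= c1 or r0 >= r1:
            continue
        cc = (np.arange(c0, c1) + 0.5) * px
        rr = (np.arange(r0, r1) + 0.5) * px
        d2 = (cc[None, :] - x) ** 2 + (rr[:, None] - y) ** 2
        mask[r0:r1, c0:c1] |= d2 <= r * r
    return mask


def _render(
    recipe: ImageRecipe,
    fg_mask: np.ndarray,
    rng: np.random.Generator,
    blur: bool = True,
) -> np.ndarray:
    """Compose background, foreground, edge blur and noise.

    Images stay two-phase (background vs aggregate foreground) so the
    intermeans threshold model downstream is well posed; the fibril
    periodicity is carried by the aggregate *placement*, not by painted
    ridge lines.
    """
    n = recipe.n_pixels
    img = np.full((n, n), float(recipe.intensity_bg))
    img[fg_mask] = float(recipe.intensity_fg)
    if blur:
        img = ndimage.gaussian_filter(img, 0.5)  # diffuse sputter-spot edges
    if recipe.noise_sd > 0:
        img = img + rng.normal(0.0, recipe.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def gen_ion_map(
    recipe: ImageRecipe, _rng: np.random.Generator | None = None
) -> tuple[ChemImage, pd.DataFrame]:
    """Generate one ion map plus its ground-truth aggregate table.

    Ground truth columns: ``center_x_um, center_y_um, radius_um``; every
    disc lies fully inside the field and discs do not overlap.
    """
    rng = _rng if _rng is not None else child_rng(recipe.seed, "ion_map", recipe.channel)
    truth = _place_aggregates(recipe, rng)
    shape = (recipe.n_pixels, recipe.n_pixels)
    fg = _disc_mask(shape, truth, recipe.pixel_size_um)
    img = _render(recipe, fg, rng)
    chem = ChemImage(img, recipe.pixel_size_um, channel=recipe.channel)
    return chem, truth


def gen_coloc_pair(recipe: ImageRecipe) -> tuple[ChemImage, ChemImage]:
    """Generate an (ion, sites) image pair with a requested coverage fraction.

    The sites image carries the recipe's aggregates; the ion occupies the
    cores (by distance transform) of the site foreground so that exactly
    ``round(fraction * site_area_px)`` site pixels are covered.  Both
    images are rendered crisp (no edge blur) so the planted coverage is
    pixel-exact before noise.
    """
    if recipe.coloc_target is None:
        raise ValueError("recipe.coloc_target must be set for gen_coloc_pair")
    site_channel, frac = recipe.coloc_target
    rng = child_rng(recipe.seed, "coloc", site_channel)
    truth = _place_aggregates(recipe, rng)
    shape = (recipe.n_pixels, recipe.n_pixels)
    site_mask = _disc_mask(shape, truth, recipe.pixel_size_um)
    n_sites = int(site_mask.sum())
    if n_sites == 0:
        raise InfeasibleCoverageError("site image has no foreground area")
    k = int(round(frac * n_sites))
    if k > n_sites:
        raise InfeasibleCoverageError("requested coverage exceeds the site area")
    dist = ndimage.distance_transform_edt(site_mask)
    order = np.argsort(-dist.ravel(), kind="stable")
    ion_mask = np.zeros(site_mask.size, dtype=bool)
    ion_mask[order[:k]] = True
    ion_mask = ion_mask.reshape(shape)

    sites_img = _render(recipe, site_mask, rng, blur=False)
    ion_img = _render(recipe, ion_mask, rng, blur=False)
    px = recipe.pixel_size_um
    ion = ChemImage(ion_img, px, channel=recipe.channel)
    sites = ChemImage(sites_img, px, channel=site_channel)
    return ion, sites


# --- treatment suite -------------------------------------------------------

#: Planted aggregate counts per 100x100 um^2 field.  The Li row follows the
#: reference particle table of the five pretreatments; the other metal/anion
#: channels are treatment-independent background chemistry (identical
#: planted counts everywhere, only field-to-field placement noise), so the
#: lithium parameter group is the planted discriminating signal.  Two
#: qualitative signatures are kept: the alkali pretreatment enriches Na
#: and F 1.73-fold (impurity/side effect of the NaOH liquor), and DDA is
#: absent from the untreated control; -OH site exposure rises after the
#: delignifying pretreatments.
PLANTED_COUNTS: dict[str, dict[str, int]] = {
    "Li": {"Control": 353, "EtOH_DMSO_AO": 320, "SteamExplosion": 88, "Microwave_H2SO4": 63, "NaOH": 16},
    "Na": {"Control": 66, "EtOH_DMSO_AO": 66, "SteamExplosion": 66, "Microwave_H2SO4": 66, "NaOH": 114},
    "K": {"Control": 28, "EtOH_DMSO_AO": 28, "SteamExplosion": 28, "Microwave_H2SO4": 28, "NaOH": 28},
    "Mg": {"Control": 357, "EtOH_DMSO_AO": 357, "SteamExplosion": 357, "Microwave_H2SO4": 357, "NaOH": 357},
    "CaC3H4": {"Control": 63, "EtOH_DMSO_AO": 63, "SteamExplosion": 63, "Microwave_H2SO4": 63, "NaOH": 63},
    "F": {"Control": 248, "EtOH_DMSO_AO": 248, "SteamExplosion": 248, "Microwave_H2SO4": 248, "NaOH": 429},
    "Cl": {"Control": 143, "EtOH_DMSO_AO": 143, "SteamExplosion": 143, "Microwave_H2SO4": 143, "NaOH": 143},
    "DDA": {"Control": 0, "EtOH_DMSO_AO": 2, "SteamExplosion": 3, "Microwave_H2SO4": 2, "NaOH": 3},
    OH_CHANNEL: {"Control": 60, "EtOH_DMSO_AO": 60, "SteamExplosion": 120, "Microwave_H2SO4": 120, "NaOH": 150},
}

#: Mean aggregate radius (um) per channel (sd is 25% of the mean).
PLANTED_RADII: dict[str, float] = {
    "Li": 0.45, "Na": 1.6, "K": 2.0, "Mg": 0.5, "CaC3H4": 1.5,
    "F": 0.8, "Cl": 1.2, "DDA": 0.35, OH_CHANNEL: 1.5,
}

#: Li aggregate radii per treatment (um): alkali leaves few but large
#: aggregates, steam/microwave leave sparse minute ones (sub-pixel radii
#: render as single-pixel spots).
LI_RADII: dict[str, float] = {
    "Control": 0.22, "EtOH_DMSO_AO": 0.18,
    "SteamExplosion": 0.10, "Microwave_H2SO4": 0.10, "NaOH": 0.30,
}

#: Spatial pattern of Li aggregates per treatment (ridges on intact fibrils).
LI_PATTERN: dict[str, str] = {
    "Control": "fibril_periodic", "EtOH_DMSO_AO": "fibril_periodic",
    "SteamExplosion": "random", "Microwave_H2SO4": "random", "NaOH": "clustered",
}

#: Probability that a Li aggregate is seeded on an -OH site (co-location).
LI_ON_OH_PROB: dict[str, float] = {
    "Control": 0.6, "EtOH_DMSO_AO": 0.6,
    "SteamExplosion": 0.25, "Microwave_H2SO4": 0.25, "NaOH": 0.3,
}

#: Fraction of the anatomy (carbohydrate-fragment) field retaining periodic
#: fringe/lattice ordering.
PERIODIC_FRACTION: dict[str, float] = {
    "Control": 1.0, "EtOH_DMSO_AO": 0.90, "SteamExplosion": 0.47,
    "Microwave_H2SO4": 0.972, "NaOH": 0.087,
}

#: Circular excavations (count per 100x100 um^2, radius um) — microwave:acid only.
EXCAVATIONS: dict[str, tuple[int, float]] = {"Microwave_H2SO4": (72, 0.72)}


@dataclass
class TreatmentSuite:
    """Images and planted ground truth for the five-pretreatment study."""

    images: dict[str, dict[str, ChemImage]]
    truth_aggregates: dict[tuple[str, str], pd.DataFrame]
    planted_counts: pd.DataFrame  # channels x treatments
    periodic_fraction: dict[str, float]
    discriminating_group: str = "Li"
    seed: int = 0

    @property
    def treatments(self) -> list[str]:
        return list(self.images)

    def channels(self, treatment: str | None = None) -> list[str]:
        t = treatment or next(iter(self.images))
        return list(self.images[t])


def _gen_anatomy_image(
    treatment: str, field_um: float, ppu: float, rng: np.random.Generator
) -> ChemImage:
    """Carbohydrate-fragment texture image: periodic stripes over a fraction
    of the field, amorphous elsewhere, plus dark circular pits for the
    microwave:acid pretreatment.  All non-pit intensities stay >= 110 so
    pit segmentation is unambiguous."""
    n = int(round(field_um * ppu))
    px = field_um / n
    frac = PERIODIC_FRACTION[treatment]
    img = np.clip(rng.normal(170.0, 15.0, (n, n)), 110.0, 230.0)
    n_periodic = int(round(frac * n))
    if n_periodic > 0:
        period_um = 4.0
        y = (np.arange(n_periodic) + 0.5) * px
        stripes = 170.0 + 55.0 * np.sin(2.0 * np.pi * y / period_um)
        img[:n_periodic, :] = stripes[:, None] + rng.normal(0.0, 5.0, (n_periodic, n))
        img[:n_periodic, :] = np.clip(img[:n_periodic, :], 110.0, 230.0)
    if treatment in EXCAVATIONS:
        count_per_field, radius = EXCAVATIONS[treatment]
        n_pits = int(round(count_per_field * (field_um / 100.0) ** 2))
        pit_recipe = ImageRecipe(
            field_size_um=field_um,
            pixels_per_um=ppu,
            n_aggregates=n_pits,
            aggregate_radius_um=(radius, 0.0),
            intensity_fg=255,  # placement only; pits are rendered dark below
        )
        pits = _place_aggregates(pit_recipe, rng)
        img[_disc_mask((n, n), pits, px)] = 30.0
    return ChemImage(np.rint(img).astype(np.uint8), px, channel=ANATOMY_CHANNEL)


def gen_treatment_suite(
    seed: int, field_size_um: float = 100.0, pixels_per_um: float = 2.56
) -> TreatmentSuite:
    """Five pretreatments x (8 ion channels + -OH + anatomy) with ground truth.

    Counts scale with field area; lithium is the planted discriminating
    channel group (strong, group-structured differences), the non-lithium
    channels share within-group signatures.
    """
    scale = (field_size_um / 100.0) ** 2
    images: dict[str, dict[str, ChemImage]] = {}
    truths: dict[tuple[str, str], pd.DataFrame] = {}
    for treatment in TREATMENTS:
        images[treatment] = {}
        # -OH sites first: lithium placement references them
        oh_recipe = ImageRecipe(
            field_size_um=field_size_um,
            pixels_per_um=pixels_per_um,
            pattern="random",
            n_aggregates=max(1, int(round(PLANTED_COUNTS[OH_CHANNEL][treatment] * scale))),
            aggregate_radius_um=(PLANTED_RADII[OH_CHANNEL], 0.25 * PLANTED_RADII[OH_CHANNEL]),
            channel=OH_CHANNEL,
            seed=seed,
        )
        rng = child_rng(seed, "suite", treatment, OH_CHANNEL)
        oh_truth = _place_aggregates(oh_recipe, rng)
        shape = (oh_recipe.n_pixels, oh_recipe.n_pixels)
        oh_mask = _disc_mask(shape, oh_truth, oh_recipe.pixel_size_um)
        oh_img = _render(oh_recipe, oh_mask, rng)
        images[treatment][OH_CHANNEL] = ChemImage(
            oh_img, oh_recipe.pixel_size_um, channel=OH_CHANNEL, sample_id=treatment
        )
        truths[(treatment, OH_CHANNEL)] = oh_truth

        for channel in ION_CHANNELS:
            n_agg = int(round(PLANTED_COUNTS[channel][treatment] * scale))
            pattern = "random"
            inside_prob = 0.0
            radius = PLANTED_RADII[channel]
            if channel == "Li":
                pattern = LI_PATTERN[treatment]
                inside_prob = LI_ON_OH_PROB[treatment]
                radius = LI_RADII[treatment]
            elif channel == "Na":
                pattern = "clustered"
            recipe = ImageRecipe(
                field_size_um=field_size_um,
                pixels_per_um=pixels_per_um,
                pattern=pattern,
                n_aggregates=n_agg,
                aggregate_radius_um=(radius, 0.25 * radius),
                channel=channel,
                seed=seed,
            )
            rng = child_rng(seed, "suite", treatment, channel)
            truth = _place_aggregates(
                recipe,
                rng,
                inside_mask_um=(oh_mask, recipe.pixel_size_um) if inside_prob else None,
                inside_prob=inside_prob,
            )
            fg = _disc_mask(shape, truth, recipe.pixel_size_um)
            img = _render(recipe, fg, rng)
            images[treatment][channel] = ChemImage(
                img, recipe.pixel_size_um, channel=channel, sample_id=treatment
            )
            truths[(treatment, channel)] = truth

        rng = child_rng(seed, "suite", treatment, ANATOMY_CHANNEL)
        anat = _gen_anatomy_image(treatment, field_size_um, pixels_per_um, rng)
        anat = replace(anat, sample_id=treatment)
        images[treatment][ANATOMY_CHANNEL] = anat

    planted = pd.DataFrame(PLANTED_COUNTS).T[TREATMENTS] * scale
    return TreatmentSuite(
        images=images,
        truth_aggregates=truths,
        planted_counts=planted.round().astype(int),
        periodic_fraction=dict(PERIODIC_FRACTION),
        seed=seed,
    )


# --- saccharification curves -----------------------------------------------


@dataclass
class CurveRecipe:
    """Recipe for one treatment's reducing-sugar release curve."""

    fold_vs_control: float = 1.0
    decay_after_10h: bool = False
    noise_sd: float = 0.15  # mg/mL
    times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 49, 2))
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        if t.size and (t.min() < 0.0 or t.max() > 48.0):
            raise ValueError("times must lie within [0, 48] h")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.fold_vs_control <= 0:
            raise ValueError("fold_vs_control must be positive")


#: Saturating base release (mg/mL): plateau 6.0, half-saturation 6 h.
_PLATEAU, _HALF_SAT = 6.0, 6.0
_RS10 = _PLATEAU * 10.0 / (_HALF_SAT + 10.0)  # all curves anchored at 10 h


def noise_free_curve(recipe: CurveRecipe, t: np.ndarray) -> np.ndarray:
    """Deterministic mean curve; the 10 h value is exactly fold x control.

    Without decay: Michaelis-type saturating release.  With decay: a
    smooth gamma-shaped pulse that peaks exactly at 10 h and declines
    thereafter (non-increasing on (10, 48]); both shapes take the value
    ``fold * RS(10 h of the control)`` at 10 h, so fold ratios at 10 h
    are exact by construction.
    """
    t = np.asarray(t, dtype=float)
    f = recipe.fold_vs_control
    if not recipe.decay_after_10h:
        return f * _PLATEAU * t / (_HALF_SAT + t)
    return f * _RS10 * (t / 10.0) * np.exp(1.0 - t / 10.0)


def gen_saccharification(
    recipes: dict[str, CurveRecipe], control: str = "Control"
) -> pd.DataFrame:
    """Tidy replicate table (treatment, replicate, time_h, rs_mg_ml).

    The control recipe must have fold 1.0 so folds are anchored to it.
    """
    if control in recipes and recipes[control].fold_vs_control != 1.0:
        raise ValueError("the control recipe must have fold_vs_control == 1.0")
    rows = []
    for treatment, recipe in recipes.items():
        rng = child_rng(recipe.seed, "sacchar", treatment)
        t = np.asarray(recipe.times_h, dtype=float)
        mean = noise_free_curve(recipe, t)
        for rep in range(1, recipe.n_replicates + 1):
            rs = mean + (rng.normal(0.0, recipe.noise_sd, t.size) if recipe.noise_sd > 0 else 0.0)
            rows.append(
                pd.DataFrame(
                    {
                        "treatment": treatment,
                        "replicate": rep,
                        "time_h": t,
                        "rs_mg_ml": np.maximum(rs, 0.0),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def study_curve_recipes(seed: int, noise_sd: float = 0.15) -> dict[str, CurveRecipe]:
    """The five study conditions: folds at 10 h vs control and decay flags.

    NaOH 2.04x, steam explosion and microwave:acid 1.74x; the organosolv
    (EtOH:DMSO:AO) decrease is encoded as ratio 0.9; control and
    EtOH:DMSO:AO decay after 10 h.
    """
    return {
        "Control": CurveRecipe(1.0, decay_after_10h=True, noise_sd=noise_sd, seed=seed),
        "EtOH_DMSO_AO": CurveRecipe(0.9, decay_after_10h=True, noise_sd=noise_sd, seed=seed),
        "SteamExplosion": CurveRecipe(1.74, noise_sd=noise_sd, seed=seed),
        "Microwave_H2SO4": CurveRecipe(1.74, noise_sd=noise_sd, seed=seed),
        "NaOH": CurveRecipe(2.04, noise_sd=noise_sd, seed=seed),
    }
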