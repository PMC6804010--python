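"""End-to-end orchestration: images → features → discrimination → curves.

The pipeline sequences the study's analysis: generate (or read) one
chemical image per treatment and channel, standardize and threshold each
image, tile it into replicate fields, extract ionic particle/coverage
features and anatomical surface metrics per field, run the mixture
discriminant analysis with the neighbor-string machinery and column-wise
jackknife, and smooth/compare the saccharification curves.  Every output
table carries the seed and a config hash in a ``#`` header comment so runs
are auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curves as curves_mod
from . import synthetic
from .discriminant import (
    DendroTree,
    DiscriminationResult,
    FeatureMatrix,
    assemble_features,
    build_tree,
    discriminate,
    jackknife_importance,
    mda_fit,
)
from .exceptions import DegenerateImageError, StageError
from .imgio import ChemImage, write_image
from .segmentation import binarize, coverage_fraction, isodata_binarize, label_particles
from .surface import compute_surface_metrics

log = logging.getLogger("surfionomics")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "ionic_features", "anatomical_features"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    seed: int = 42
    outdir: str = "surfionomics_out"
    images_dir: str | None = None  # read <treatment>__<channel>.tif instead of simulating
    field_size_um: float = 100.0
    pixels_per_um: float = 2.56
    tiles_per_side: int = 4  # replicate fields per image (4 -> 16 25x25 um tiles)
    entropy_bins: int = 64
    cutoff_um: float = 8.0
    window_um: float = 12.5
    prominence: float = 0.3
    n_subclasses: int = 3
    n_permutations: int = 999
    alpha: float = 0.05
    curve_noise_sd: float = 0.15
    max_foreground_fraction: float = 0.25  # above this an ion map counts as spotless

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# surfionomics seed={cfg.seed} config_hash={cfg.hash()}\n")
        df.to_csv(fh, index=index)


def _tiles(img: ChemImage, per_side: int):
    h, w = img.shape
    th, tw = h // per_side, w // per_side
    for i in range(per_side):
        for j in range(per_side):
            sl = (slice(i * th, (i + 1) * th), slice(j * tw, (j + 1) * tw))
            yield f"t{i}{j}", sl


def ionic_features(
    suite: synthetic.TreatmentSuite, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Per-field ionic particle features and Li-on-(-OH) coverage.

    Each image is thresholded whole (IsoData), then split into
    ``tiles_per_side²`` replicate fields; per field and channel the
    aggregate count, total area and mean size are recorded.  Maps whose
    foreground exceeds ``max_foreground_fraction`` carry no distinct
    spots (the threshold landed inside a single intensity mode) and are
    scored as empty.  Returns (particle features, coverage features,
    channel → column-names grouping for the jackknife).
    """
    rows: dict[str, dict[str, float]] = {}
    cov_rows: dict[str, dict[str, float]] = {}
    groups: dict[str, list[str]] = {}
    for treatment in suite.treatments:
        masks = {}
        for channel in [*synthetic.ION_CHANNELS, synthetic.OH_CHANNEL]:
            img = suite.images[treatment][channel]
            try:
                bm = isodata_binarize(img)
            except DegenerateImageError:
                bm = binarize(img, 255)
            if bm.mask.mean() > cfg.max_foreground_fraction:
                bm = binarize(img, 255)  # spotless map
            masks[channel] = bm
        for tile_id, sl in _tiles(suite.images[treatment][synthetic.OH_CHANNEL], cfg.tiles_per_side):
            obs = f"{treatment}__{tile_id}"
            rows[obs] = {}
            cov_rows[obs] = {}
            for channel in synthetic.ION_CHANNELS:
                img = suite.images[treatment][channel]
                sub = ChemImage(img.data[sl], img.pixel_size_um, channel=channel)
                sub_map = binarize(sub, masks[channel].threshold, method=masks[channel].method)
                sub_map.mask &= masks[channel].mask[sl]
                stats = label_particles(sub_map)
                rows[obs][f"{channel}_count"] = stats.count
                rows[obs][f"{channel}_area_um2"] = stats.total_area_um2
                rows[obs][f"{channel}_mean_size_um2"] = stats.mean_size_um2
                groups.setdefault(channel, [])
            li = masks["Li"].mask[sl]
            oh = masks[synthetic.OH_CHANNEL].mask[sl]
            n_oh = int(oh.sum())
            cov_rows[obs]["Li_on_OH_cov_pct"] = (
                100.0 * int((li & oh).sum()) / n_oh if n_oh else 0.0
            )
    part = pd.DataFrame(rows).T.sort_index()
    cov = pd.DataFrame(cov_rows).T.sort_index()
    for channel in synthetic.ION_CHANNELS:
        groups[channel] = [
            f"ion__{channel}_count",
            f"ion__{channel}_area_um2",
            f"ion__{channel}_mean_size_um2",
        ]
    groups["Li"].append("ion__Li_on_OH_cov_pct")
    return part, cov, groups


def anatomical_features(suite: synthetic.TreatmentSuite, cfg: RunConfig) -> pd.DataFrame:
    """Per-field surface metrics of the carbohydrate-texture channel."""
    rows: dict[str, dict[str, float]] = {}
    for treatment in suite.treatments:
        img = suite.images[treatment][synthetic.ANATOMY_CHANNEL]
        for tile_id, sl in _tiles(img, cfg.tiles_per_side):
            sub = ChemImage(img.data[sl], img.pixel_size_um, channel=img.channel)
            m = compute_surface_metrics(
                sub,
                bins=cfg.entropy_bins,
                cutoff_um=cfg.cutoff_um,
                window_um=cfg.window_um,
                prominence=cfg.prominence,
            )
            rows[f"{treatment}__{tile_id}"] = {
                "entropy_nats": m.entropy_nats,
                "entropy_deficit_nats": m.entropy_deficit_nats,
                "roughness_Ra": m.roughness_Ra,
                "roughness_Rq": m.roughness_Rq,
                "waviness_Wa": m.waviness_Wa,
                "periodic_area_pct": m.periodic_area_pct,
                "excavation_count_per_field": m.excavations.count_per_field,
                "excavation_mean_radius_um": m.excavations.mean_radius_um,
                "excavation_depth_proxy": m.excavations.mean_depth_proxy,
            }
    return pd.DataFrame(rows).T.sort_index()


@dataclass
class PipelineResult:
    config: RunConfig
    suite: synthetic.TreatmentSuite
    features: FeatureMatrix
    labels: np.ndarray
    discrimination: DiscriminationResult
    tree: DendroTree
    jackknife: pd.DataFrame
    curve_table: pd.DataFrame
    fold_changes: dict[str, float]
    decay_flags: dict[str, bool]
    curve_comparisons: pd.DataFrame
    curve_partition: list[set[str]]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate → segment → metrics → discriminate → curves → report.

    All artifacts (images, feature tables, neighbor matrix, Newick tree,
    jackknife report, curve outputs, summary) are written under
    ``config.outdir``; identical config + seed reproduces them byte for
    byte.
    """
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    t0 = time.time()
    try:
        suite = synthetic.gen_treatment_suite(
            cfg.seed, field_size_um=cfg.field_size_um, pixels_per_um=cfg.pixels_per_um
        )
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for treatment, chans in suite.images.items():
            for channel, img in chans.items():
                write_image(img, img_dir / f"{treatment}__{channel}.tif", sidecar=False)
        for (treatment, channel), truth in suite.truth_aggregates.items():
            _write_csv(truth, img_dir / f"{treatment}__{channel}__truth.csv", cfg)
        curve_table = synthetic.gen_saccharification(
            synthetic.study_curve_recipes(cfg.seed, noise_sd=cfg.curve_noise_sd)
        )
        _write_csv(curve_table, out / "saccharification.csv", cfg)
        log.info("stage=simulate elapsed=%.2fs treatments=%d", time.time() - t0, len(suite.treatments))

        stage = "segment"
        t0 = time.time()
        part, cov, groups = ionic_features(suite, cfg)
        _write_csv(part, out / "particle_features.csv", cfg, index=True)
        _write_csv(cov, out / "coverage_features.csv", cfg, index=True)
        log.info("stage=segment elapsed=%.2fs observations=%d", time.time() - t0, len(part))

        stage = "metrics"
        t0 = time.time()
        anat = anatomical_features(suite, cfg)
        _write_csv(anat, out / "surface_metrics.csv", cfg, index=True)
        log.info("stage=metrics elapsed=%.2fs", time.time() - t0)

        stage = "discriminate"
        t0 = time.time()
        fm = assemble_features(part, anat, cov)
        labels = np.asarray([obs.split("__")[0] for obs in fm.X.index])
        _write_csv(fm.X, out / "feature_matrix.csv", cfg, index=True)
        # the similarity string / neighbor matrix / tree use the ionic block
        # (anatomical parameters cluster the pretreatments differently)
        ion_cols = fm.block_columns("ionic")
        fm_ion = fm.X[ion_cols]
        model = mda_fit(fm_ion, labels, n_subclasses=cfg.n_subclasses, seed=cfg.seed)
        result = discriminate(
            model, n_permutations=cfg.n_permutations, alpha=cfg.alpha, seed=cfg.seed
        )
        # jackknife over the ionic parameter groups (one group per channel)
        groups = {k: [c for c in v if c in fm.X.columns] for k, v in groups.items()}
        groups = {k: v for k, v in groups.items() if v}
        jk = jackknife_importance(
            fm_ion, labels, groups=groups, n_subclasses=cfg.n_subclasses,
            seed=cfg.seed, score="cv",
        )
        tree = build_tree([result.binary_matrix])
        _write_csv(result.binary_matrix, out / "neighbor_matrix.csv", cfg, index=True)
        _write_csv(jk, out / "jackknife.csv", cfg)
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        log.info(
            "stage=discriminate elapsed=%.2fs string=%s accuracy=%.3f",
            time.time() - t0, "-".join(result.string), result.accuracy,
        )

        stage = "curves"
        t0 = time.time()
        fits = {
            t: curves_mod.fit_curve(curve_table[curve_table.treatment == t])
            for t in curve_table.treatment.unique()
        }
        control = fits["Control"]
        folds = {t: curves_mod.fold_change(c, control) for t, c in fits.items()}
        decay = {t: curves_mod.detect_decay(c) for t, c in fits.items()}
        comp_rows = []
        names = list(fits)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                c = curves_mod.compare_curves(
                    curve_table[curve_table.treatment == a],
                    curve_table[curve_table.treatment == b],
                    alpha=cfg.alpha,
                )
                comp_rows.append({"a": a, "b": b, "F": c.F, "p": c.p, "same": c.same})
        comparisons = pd.DataFrame(comp_rows)
        partition = curves_mod.cluster_curves(
            {t: curve_table[curve_table.treatment == t] for t in names}, alpha=cfg.alpha
        )
        fold_df = pd.DataFrame(
            {"treatment": list(folds), "fold_vs_control_10h": list(folds.values()),
             "decay_after_10h": [decay[t] for t in folds]}
        )
        _write_csv(fold_df, out / "fold_changes.csv", cfg)
        _write_csv(comparisons, out / "curve_comparisons.csv", cfg)
        (out / "curve_partition.json").write_text(
            json.dumps({"seed": cfg.seed, "config_hash": cfg.hash(),
                        "partition": [sorted(g) for g in partition]}, indent=2)
        )
        log.info("stage=curves elapsed=%.2fs partition=%s", time.time() - t0, partition)

        stage = "report"
        summary = [
            f"surfionomics run (seed={cfg.seed}, config_hash={cfg.hash()})",
            f"similarity string : {' - '.join(result.string)}",
            f"merged groups     : {result.groups}",
            f"training accuracy : {result.accuracy:.3f}",
            f"tree              : {tree.newick()}",
            f"top jackknife     : {jk.iloc[0]['group']} ({jk.iloc[0]['importance_pct']:.1f}%)",
            "fold changes @10h : "
            + ", ".join(f"{t}={v:.3f}" for t, v in folds.items()),
            f"decay after 10h   : {[t for t, v in decay.items() if v]}",
            f"curve partition   : {[sorted(g) for g in partition]}",
        ]
        (out / "summary.txt").write_text("\n".join(summary) + "\n")
    except Exception as exc:  # noqa: BLE001 - surface the failing stage
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, cfg.outdir, exc) from exc

    return PipelineResult(
        config=cfg, suite=suite, features=fm, labels=labels, discrimination=result,
        tree=tree, jackknife=jk, curve_table=curve_table, fold_changes=folds,
        decay_flags=decay, curve_comparisons=comparisons, curve_partition=partition,
    )
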