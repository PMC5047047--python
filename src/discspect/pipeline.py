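"""End-to-end orchestration: simulate -> preprocess -> decompose -> maps ->
gradients -> correlate, with a reproducible run manifest.

The pipeline mirrors the cohort analysis design: a 10-row area of interest
is taken across each section, the AoIs of all samples are collated into one
matrix, a single MCR-ALS model resolves the collation, factors are assigned
against the reference library, per-sample component/tissue maps are reduced
to width-normalized gradients, and the regional parameters are correlated
with the covariate table. Two runs with the same config and seed produce
identical numerical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DiscspectError, InvalidParameterError, PipelineStageError
from .gradients import (
    default_aoi,
    extract_aoi,
    regional_table,
    width_normalized_profile,
)
from .mapping import (
    AMIDE_III_WINDOW,
    ComponentMap,
    TissueMap,
    assign_factors,
    cos_peak_position,
    ratio_map,
    tissue_map,
)
from .mcr import ConstraintSpec, resolve
from .phantom import (
    REGION_WINDOWS,
    PhantomConfig,
    default_library,
    generate_cohort,
    generate_phantom,
)
from .spectra import (
    HyperspectralImage,
    PixelMask,
    Spectrum,
    collate,
    compute_mask,
    second_derivative,
)
from . import io as dio

__all__ = ["AnalysisConfig", "RunManifest", "run_pipeline", "preprocess"]

log = logging.getLogger("discspect")

DEFAULT_PAIRS = [
    ("PG1", "grade", "NP"), ("PG1", "gag_ug_per_mg", "NP"),
    ("PG1", "t2star_ms", "NP"),
    ("PG2", "grade", "NP"), ("PG2", "gag_ug_per_mg", "NP"),
    ("PG2", "t2star_ms", "NP"),
]


@dataclass
class AnalysisConfig:
    """All printed analysis settings in one validated, serializable object."""

    # Savitzky-Golay second derivative
    sg_window: int = 15
    sg_poly_order: int = 3
    # working/normalization range and masking
    norm_range: tuple[float, float] = (950.0, 1800.0)
    mask_marker: float = 1554.0
    mask_threshold: float = 0.0
    # MCR-ALS
    mcr_region: tuple[float, float] = (950.0, 1300.0)
    k: int = 5
    init_method: str = "nipals"
    alpha_C: float = 0.5
    alpha_S: float = 0.0
    max_iter: int = 500
    tol: float = 1e-6
    # mapping and gradients
    amide_iii_window: tuple[float, float] = AMIDE_III_WINDOW
    aoi_rows: int = 10
    regional_windows: dict = field(
        default_factory=lambda: {k: list(v) for k, v in REGION_WINDOWS.items()})
    components: tuple[str, ...] = ("collagen_I", "collagen_II", "PG1", "PG2",
                                   "paraffin")
    # statistics
    alpha: float = 0.05
    pairs: list = field(default_factory=lambda: [list(p) for p in DEFAULT_PAIRS])
    # cohort simulation
    n_samples: int = 8
    phantom: dict = field(default_factory=dict)   # PhantomConfig overrides
    seed: int = 0

    def __post_init__(self):
        if self.sg_window % 2 == 0 or self.sg_window < self.sg_poly_order + 2:
            raise InvalidParameterError("invalid Savitzky-Golay window")
        if self.k < 1:
            raise InvalidParameterError("k must be positive")
        if self.aoi_rows < 1:
            raise InvalidParameterError("AoI height must be >= 1 row")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.n_samples < 2:
            raise InvalidParameterError("cohort needs >= 2 samples")

    def constraints(self) -> ConstraintSpec:
        return ConstraintSpec(self.alpha_C, self.alpha_S)

    def phantom_config(self, **overrides) -> PhantomConfig:
        merged = {"components": tuple(self.components), "seed": self.seed,
                  **self.phantom, **overrides}
        return PhantomConfig(**merged)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["norm_range"] = list(self.norm_range)
        d["mcr_region"] = list(self.mcr_region)
        d["amide_iii_window"] = list(self.amide_iii_window)
        d["components"] = list(self.components)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("norm_range", "mcr_region", "amide_iii_window",
                    "components"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    """Traceability record: config, version, seeds, stages, checksums."""

    config: dict
    version: str
    seed: int
    stages: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)    # path -> sha256
    started: float = 0.0
    finished: float = 0.0

    def record(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True))


def preprocess(image: HyperspectralImage, config: AnalysisConfig
               ) -> tuple[HyperspectralImage, PixelMask]:
    """Second derivative then amide II masking, with the configured settings."""
    deriv = second_derivative(image, config.sg_window, config.sg_poly_order)
    mask = compute_mask(deriv, config.mask_marker, config.mask_threshold)
    return deriv, mask


def _stage(manifest: RunManifest, name: str):
    manifest.stages.append(name)
    log.info("stage %s", name)


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> RunManifest:
    """Run the full cohort analysis and write all outputs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           seed=config.seed, started=time.time())

    # -- simulate ----------------------------------------------------------
    try:
        _stage(manifest, "simulate")
        cohort_cfgs, covariates, truth = generate_cohort(
            config.n_samples, seed=config.seed,
            base_config=config.phantom_config())
        sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
        phantoms = {}
        for sid, cfg in zip(sample_ids, cohort_cfgs):
            image, gt, _ = generate_phantom(cfg, sample_id=sid)
            phantoms[sid] = (image, gt)
        cov_path = out / "covariates.csv"
        covariates.to_csv(cov_path, index=False)
        truth.to_csv(out / "ground_truth_regional.csv", index=False)
    except DiscspectError as exc:
        raise PipelineStageError("simulate", str(exc)) from exc

    # -- preprocess --------------------------------------------------------
    try:
        _stage(manifest, "preprocess")
        derivs, masks, aois = {}, {}, {}
        for sid, (image, gt) in phantoms.items():
            deriv, mask = preprocess(image, config)
            derivs[sid], masks[sid] = deriv, mask
            aois[sid] = default_aoi(mask, config.aoi_rows)
            log.info("%s: %d/%d tissue pixels", sid, mask.n_included,
                     deriv.n_pixels)
    except DiscspectError as exc:
        raise PipelineStageError("preprocess", str(exc)) from exc

    # -- decompose (collated AoIs, one model) ------------------------------
    try:
        _stage(manifest, "decompose")
        aoi_images, aoi_masks = [], []
        for sid in sample_ids:
            a = aois[sid]
            im = derivs[sid]
            aoi_images.append(HyperspectralImage(
                im.axis, im.cube[a.row_start:a.row_stop], derivative_order=2))
            aoi_masks.append(masks[sid].included[a.row_start:a.row_stop])
        collated = collate(aoi_images)
        coll_mask = PixelMask(np.concatenate(aoi_masks, axis=0))
        model = resolve(collated, coll_mask, config.k,
                        region=tuple(config.mcr_region),
                        init_method=config.init_method,
                        constraints=config.constraints(),
                        max_iter=config.max_iter, tol=config.tol)
        log.info("k=%d lack of fit %.4f%% after %d iterations", model.k,
                 model.lack_of_fit, model.iterations_run)
        dio.write_model_archive(model, out / "model.h5")
        manifest.record(out / "model.h5")
    except DiscspectError as exc:
        raise PipelineStageError("decompose", str(exc)) from exc

    # -- maps (assignment, tissue, ratio) ----------------------------------
    try:
        _stage(manifest, "maps")
        axis = collated.axis
        library = default_library(
            axis, pg_shift=config.phantom_config().pg_shift)
        assignment = assign_factors(model, library,
                                    region=tuple(config.mcr_region))
        rows = []
        for fidx, comp in assignment.mapping.items():
            try:
                peak = cos_peak_position(
                    Spectrum(model.axis, model.S[:, fidx], derivative_order=2))
            except DiscspectError:
                peak = float("nan")
            ref_idx = (assignment.reference_names.index(comp)
                       if comp in assignment.reference_names else None)
            score = (assignment.scores[fidx, ref_idx]
                     if ref_idx is not None else float("nan"))
            rows.append({"factor": fidx, "component": comp,
                         "score": score, "cos_peak_cm1": peak})
        pd.DataFrame(rows).to_csv(out / "assignment.csv", index=False)
        manifest.record(out / "assignment.csv")

        tmaps = {sid: tissue_map(derivs[sid], masks[sid],
                                 *config.amide_iii_window)
                 for sid in sample_ids}
        grid = (config.aoi_rows, collated.n_cols)
        row0 = 0
        ratio_aois: dict[str, dict[str, np.ndarray]] = {}
        for sid in sample_ids:
            sl = slice(row0, row0 + config.aoi_rows)
            row0 += config.aoi_rows
            ratio_aois[sid] = {}
            a = aois[sid]
            t_aoi_map = TissueMap(extract_aoi(tmaps[sid].values, a),
                                  tmaps[sid].window)
            # this sample's block of collated C rows, back onto its AoI grid
            idx_block = coll_mask.included[sl]
            offset = int(coll_mask.included[:sl.start].sum())
            count = int(idx_block.sum())
            for fidx, comp in assignment.mapping.items():
                if comp not in config.components:
                    continue
                flat = np.full(grid, np.nan)
                flat[idx_block] = model.C[offset:offset + count, fidx]
                cmap = ComponentMap(flat, comp)
                ratio_aois[sid][comp] = ratio_map(cmap, t_aoi_map).values
    except DiscspectError as exc:
        raise PipelineStageError("maps", str(exc)) from exc

    # -- gradients ---------------------------------------------------------
    try:
        _stage(manifest, "gradients")
        profiles: dict[str, dict] = {}
        prof_rows = []
        for sid in sample_ids:
            a = aois[sid]
            tissue_aoi = extract_aoi(masks[sid].included, a)
            profiles[sid] = {}
            for comp, vals in ratio_aois[sid].items():
                prof = width_normalized_profile(vals, tissue_aoi,
                                                component=comp, sample_id=sid)
                profiles[sid][comp] = prof
                for pct, v in zip(prof.percent_axis, prof.values):
                    prof_rows.append({"sample_id": sid, "component": comp,
                                      "percent": pct, "value": v})
        pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
        windows = {k: tuple(v) for k, v in config.regional_windows.items()}
        regional = regional_table(profiles, windows)
        regional.to_csv(out / "regional_parameters.csv", index=False)
        manifest.record(out / "profiles.csv")
        manifest.record(out / "regional_parameters.csv")
    except DiscspectError as exc:
        raise PipelineStageError("gradients", str(exc)) from exc

    # -- correlate ---------------------------------------------------------
    try:
        _stage(manifest, "correlate")
        from .stats import correlate_cohort

        pairs = [tuple(p) for p in config.pairs]
        pairs = [p for p in pairs
                 if p[0] in regional.component.unique()]
        results = correlate_cohort(regional, covariates, pairs,
                                   alpha=config.alpha)
        assoc = pd.DataFrame([{
            "x": r.x_label, "y": r.y_label, "region": r.region, "n": r.n,
            "slope": r.slope, "intercept": r.intercept, "tau": r.kendall_tau,
            "p": r.p_value, "significant": r.significant,
        } for r in results])
        assoc.to_csv(out / "associations.csv", index=False)
        manifest.record(out / "associations.csv")
        manifest.record(cov_path)
    except DiscspectError as exc:
        raise PipelineStageError("correlate", str(exc)) from exc

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest
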