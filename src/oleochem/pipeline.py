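"""End-to-end orchestration: generate -> preprocess -> ratio -> PCA -> LDA -> PLSR.

``run_full`` executes the whole authentication workflow on a seeded
synthetic design and writes CSV tables plus one machine-readable JSON
summary stamped with the configuration hash and seed.  Identical
configurations produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import lda as _lda
from . import pca as _pca
from .preprocess import PreprocessConfig, preprocess_set
from .ratio import ratio_table
from .spectra import RegionSpec
from .synth import (BlendDesign, GeneratorConfig, SCREEN_LEVELS,
                    generate_design, generate_pure_set, generate_screen_set)
from .plsr import run_calibration_suite

__all__ = ["RunConfig", "run_full", "config_hash"]

#: The four spectral regions compared during PCA exploration.
PCA_REGIONS = (
    RegionSpec(((4000.0, 650.0),)),
    RegionSpec(((3050.0, 2750.0), (1800.0, 650.0))),
    RegionSpec(((3050.0, 2750.0),)),
    RegionSpec(((1800.0, 650.0),)),
)


@dataclass(frozen=True)
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(derivative_order=1))
    design: BlendDesign = field(default_factory=BlendDesign.table5)
    lda_wavenumbers: tuple = _pca.SELECTED_WAVENUMBERS
    lda_levels: tuple = SCREEN_LEVELS
    lda_replicates: int = 3
    plsr_factors: int = 4
    output_dir: str = "oleochem_run"


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, RegionSpec):
        return obj.label
    return obj


def config_hash(config: RunConfig) -> str:
    """Stable hash over the semantic configuration fields (where outputs are
    written does not change what is computed, so output_dir is excluded)."""
    payload = _to_jsonable(config)
    payload.pop("output_dir", None)
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode("utf-8")).hexdigest()[:16]


def _log(fh, stage: str, message: str) -> None:
    line = f"[{stage}] {message}"
    print(line, file=sys.stderr)
    fh.write(line + "\n")


def run_full(config: RunConfig) -> dict:
    """Run every stage and return the JSON-ready summary dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    summary: dict = {"seed": config.generator.seed, "config_hash": chash}

    with open(out / "run.log", "w") as log:
        def stage(name):
            t0 = time.perf_counter()

            def done(msg):
                _log(log, name, f"{msg} ({time.perf_counter() - t0:.2f}s)")
            return done

        # -- generate ------------------------------------------------------
        done = stage("generate")
        if not config.design.cao_brands or not config.design.rso_brands or not config.design.levels:
            raise ValueError("generate stage: blend design is empty")
        design_set = generate_design(config.design, config.generator)
        pure_set = generate_pure_set(config.generator)
        screen_set = generate_screen_set(config.generator, levels=config.lda_levels,
                                         replicates=config.lda_replicates)
        done(f"{len(design_set)} design + {len(pure_set)} pure + {len(screen_set)} screen spectra")
        summary["n_design_samples"] = len(design_set)
        summary["n_pure_samples"] = len(pure_set)

        # -- ratio screen (smoothed, non-derivative spectra) ---------------
        done = stage("ratio")
        smooth_cfg = PreprocessConfig(sg_window=config.preprocess.sg_window,
                                      sg_polyorder=config.preprocess.sg_polyorder,
                                      derivative_order=0, region=None)
        table = ratio_table(preprocess_set(pure_set, smooth_cfg))
        table.to_csv(out / "ratio_table.csv", index=False)
        digest = (table.groupby("oil_type")["ratio"]
                  .agg(["min", "max", "mean"]).round(6))
        summary["ratio_by_oil"] = {oil: {"min": row["min"], "max": row["max"], "mean": row["mean"]}
                                   for oil, row in digest.iterrows()}
        done(f"{len(table)} samples")

        # -- PCA region comparison (smoothed spectra, like the ratio screen) -
        done = stage("pca")
        prepped_pure = preprocess_set(pure_set, smooth_cfg)
        profile = _pca.explained_variance_profile(prepped_pure, PCA_REGIONS, 3)
        profile.to_csv(out / "pca_variance.csv", index=False)
        summary["pca_variance"] = [
            {k: (round(v, 6) if isinstance(v, float) else v) for k, v in row.items()}
            for row in profile.to_dict(orient="records")
        ]
        done(f"{len(PCA_REGIONS)} regions")

        # -- LDA screen (smoothed absorbances at selected wavenumbers) -----
        done = stage("lda")
        screen_smooth = preprocess_set(screen_set, smooth_cfg)
        features = _lda.extract_features(screen_smooth, config.lda_wavenumbers)
        cv_cm, resub_cm = _lda.loo_cross_validate(features)
        cv_cm.to_frame().to_csv(out / "lda_confusion_cv.csv")
        resub_cm.to_frame().to_csv(out / "lda_confusion_resub.csv")
        summary["lda"] = {
            "groups": list(cv_cm.groups),
            "cv_counts": cv_cm.counts.tolist(),
            "resub_counts": resub_cm.counts.tolist(),
            "cv_accuracy_pct": cv_cm.accuracy_pct,
            "resub_accuracy_pct": resub_cm.accuracy_pct,
        }
        done(f"LOO accuracy {cv_cm.accuracy_pct:.2f}%")

        # -- PLSR quantification -------------------------------------------
        done = stage("plsr")
        metrics = run_calibration_suite(design_set, config.design,
                                        a=config.plsr_factors, cfg=config.preprocess)
        metrics.to_csv(out / "plsr_metrics.csv", index=False)
        summary["plsr"] = {
            "n_models": int(len(metrics)),
            "n_factors": config.plsr_factors,
            "min_slope": float(metrics["slope"].min()),
            "min_r2": float(metrics["r2"].min()),
            "max_rmsec": float(metrics["rmsec"].max()),
            "max_rmsecv": float(metrics["rmsecv"].max()),
            "rows": [{k: (round(v, 6) if isinstance(v, float) else v) for k, v in row.items()}
                     for row in metrics.to_dict(orient="records")],
        }
        done(f"{len(metrics)} models, max RMSECV {metrics['rmsecv'].max():.3f} % v/v")

    with open(out / "summary.json", "w") as fh:
        json.dump(_to_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
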