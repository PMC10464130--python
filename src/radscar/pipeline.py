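"""End-to-end pipeline: phantom/ingest -> localize -> patches -> radon ->
features -> dissimilarity -> train.

Every stage writes its artifacts into the run directory before the next
stage starts, so the run can be audited file by file; a manifest with
checksums and a stage-granular log close the run. Re-running the same
config produces byte-identical masks, tables and metrics (the log carries
wall-clock timestamps and is excluded from checksumming).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, fields, asdict
from pathlib import Path

import numpy as np

from . import classify, features as feats, image_io, patches as patchmod, radon
from .errors import InsufficientOriginsError, RadscarError, StageError
from .phantom import PhantomSpec, generate_phantom
from .scar_map import (
    StructuringElement,
    dice,
    region_stats,
    robust_healthy_stats,
    scar_pipeline,
)

STAGES = (
    "phantom",
    "localize",
    "patches",
    "radon",
    "features",
    "dissimilarity",
    "train",
)

# distinct CLI exit code per failing stage
STAGE_EXIT_CODES = {name: i + 2 for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    """Flat, fully defaulted configuration of one pipeline run.

    When ``image_path``/``myocardium_path`` are set the phantom stage is
    replaced by file ingestion (and no ground-truth Dice is reported);
    otherwise a phantom is generated from the ``phantom_*`` fields.
    """

    # input: either files ...
    image_path: str = ""
    myocardium_path: str = ""
    # ... or a phantom
    phantom_size: int = 256
    phantom_inner_radius: float = 60.0
    phantom_outer_radius: float = 115.0
    phantom_myo_mean: float = 59.0
    phantom_myo_sd: float = 21.0
    phantom_scar_arcs: str = "30:90"  # semicolon-separated start:end degrees
    phantom_scar_mean: float = 0.0  # 0 -> auto: myo_mean + 4*myo_sd
    phantom_scar_sd: float = 21.0
    phantom_texture_scale: float = 3.0
    phantom_seed: int = 0
    # localization
    k: float = 3.0
    se: str = "square3"  # cross3 | square3
    morph_order: str = "open-close"
    healthy_stats: str = "robust"  # robust | plain
    # patches
    patch_size: int = 25
    n_per_class: int = 100
    patch_seed: int = 0
    overlap_policy: str = "any"
    # radon
    angle_step: float = 1.0
    save_sinograms: bool = True
    # cross-validation
    folds: int = 5
    cv_seed: int = 0
    models: str = "decision_tree,svm,logistic_regression"
    tree_max_depth: int = 0  # 0 -> unlimited
    tree_min_samples_split: int = 2
    tree_min_samples_leaf: int = 1
    tree_max_leaf_nodes: int = 0  # 0 -> unlimited
    # output
    out_dir: str = "radscar_run"

    def scar_arcs(self) -> tuple:
        text = self.phantom_scar_arcs.strip()
        if not text:
            return ()
        arcs = []
        for part in text.split(";"):
            a, b = part.split(":")
            arcs.append((float(a), float(b)))
        return tuple(arcs)

    def phantom_spec(self) -> PhantomSpec:
        scar_mean = self.phantom_scar_mean or None
        return PhantomSpec(
            image_size=self.phantom_size,
            inner_radius=self.phantom_inner_radius,
            outer_radius=self.phantom_outer_radius,
            myo_mean=self.phantom_myo_mean,
            myo_sd=self.phantom_myo_sd,
            scar_arcs=self.scar_arcs(),
            scar_mean=scar_mean,
            scar_sd=self.phantom_scar_sd,
            scar_texture_scale=self.phantom_texture_scale,
            seed=self.phantom_seed,
        )

    def tree_params(self) -> dict:
        return {
            "max_depth": self.tree_max_depth or None,
            "min_samples_split": self.tree_min_samples_split,
            "min_samples_leaf": self.tree_min_samples_leaf,
            "max_leaf_nodes": self.tree_max_leaf_nodes or None,
        }

    def model_names(self) -> tuple:
        return tuple(m.strip() for m in self.models.split(",") if m.strip())

    # -- flat key = value serialization --------------------------------

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        defaults = cls()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise RadscarError(f"config line {lineno}: expected key = value")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if not hasattr(defaults, key):
                raise RadscarError(f"config line {lineno}: unknown key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON).

    Raises
    ------
    StageError
        On any stage failure, naming the stage and the offending input.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    log = logging.getLogger("radscar.pipeline")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()

    def emit(path: Path):
        artifacts.append(path)
        log.info("wrote %s", path.name)

    try:
        cfg_path = out / "config.txt"
        cfg_path.write_text(config.to_text())
        emit(cfg_path)

        # --- stage: phantom / ingest -----------------------------------
        try:
            if config.image_path:
                image = image_io.read_image(config.image_path)
                myocardium = image_io.read_mask(config.myocardium_path)
                scar_truth = None
                log.info("ingested %s", config.image_path)
            else:
                spec = config.phantom_spec()
                image, myocardium, scar_truth = generate_phantom(spec)
                image_io.write_image(image, out / "image.png")
                image_io.write_mask(myocardium, out / "myocardium.png")
                image_io.write_mask(scar_truth, out / "scar_truth.png")
                with open(out / "phantom.json", "w") as fh:
                    json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)
                    fh.write("\n")
                for name in ("image.png", "myocardium.png", "scar_truth.png",
                             "phantom.json"):
                    emit(out / name)
        except StageError:
            raise
        except (RadscarError, OSError) as exc:
            raise StageError("phantom", str(exc)) from exc

        # --- stage: localize -------------------------------------------
        try:
            se = StructuringElement.named(config.se)
            plain = region_stats(image, myocardium)
            healthy = (
                robust_healthy_stats(image, myocardium)
                if config.healthy_stats == "robust"
                else plain
            )
            candidate = scar_pipeline(
                image, myocardium, healthy=healthy, k=config.k, se=se,
                order=config.morph_order,
            )
            image_io.write_mask(candidate, out / "scar_candidate.png")
            image_io.write_metrics(
                {
                    "myocardium": asdict(plain),
                    "healthy_estimate": asdict(healthy),
                    "k": config.k,
                    "cutoff_hu": healthy.mean + config.k * healthy.sd,
                    "n_candidate_pixels": int(candidate.sum()),
                },
                out / "region_stats.json",
            )
            emit(out / "scar_candidate.png")
            emit(out / "region_stats.json")
        except (RadscarError, ValueError) as exc:
            raise StageError("localize", str(exc)) from exc

        # --- stage: patches --------------------------------------------
        try:
            n_scar_origins = len(
                patchmod.eligible_origins(candidate, config.patch_size)
            )
            if n_scar_origins == 0:
                raise StageError(
                    "patches",
                    "no positive class: scar-candidate mask admits no "
                    f"{config.patch_size}x{config.patch_size} tile",
                )
            source_id = Path(config.image_path).stem if config.image_path else (
                f"phantom-seed{config.phantom_seed}"
            )
            scar_patches = patchmod.extract_patches(
                image, candidate, "scar", config.n_per_class,
                patch_size=config.patch_size, seed=config.patch_seed,
                overlap_policy=config.overlap_policy, source_id=source_id,
            )
            normal_patches = patchmod.extract_patches(
                image, myocardium & ~candidate, "normal", config.n_per_class,
                patch_size=config.patch_size, seed=config.patch_seed + 1,
                overlap_policy=config.overlap_policy, source_id=source_id,
            )
            patch_list = scar_patches + normal_patches
            manifest_csv = patchmod.save_patch_set(patch_list, out / "patches")
            emit(manifest_csv)
        except StageError:
            raise
        except InsufficientOriginsError as exc:
            raise StageError("patches", str(exc)) from exc
        except RadscarError as exc:
            raise StageError("patches", str(exc)) from exc

        # --- stage: radon ----------------------------------------------
        try:
            angles = np.arange(0.0, 180.0, config.angle_step)
            sinograms = [radon.radon_transform(p, angles=angles) for p in patch_list]
            if config.save_sinograms:
                for i, s in enumerate(sinograms):
                    radon.save_sinogram(s, out / "sinograms", f"{i:05d}")
                emit(out / "sinograms")
        except (RadscarError, OSError) as exc:
            raise StageError("radon", str(exc)) from exc

        # --- stage: features -------------------------------------------
        try:
            fvs = []
            for p, s in zip(patch_list, sinograms):
                img = radon.sinogram_to_image(s)
                fvs.append(
                    feats.lbp_feature(img, patch_id=p.patch_id, label=p.label)
                )
            image_io.write_feature_table(
                [
                    {"patch_id": f.patch_id, "label": f.label, "bins": f.bins}
                    for f in fvs
                ],
                out / "features.csv",
            )
            emit(out / "features.csv")
        except RadscarError as exc:
            raise StageError("features", str(exc)) from exc

        # --- stage: dissimilarity --------------------------------------
        try:
            w = feats.class_dissimilarity(fvs)
            image_io.write_metrics(
                {"scar_vs_normal_wasserstein": w}, out / "dissimilarity.json"
            )
            emit(out / "dissimilarity.json")
        except RadscarError as exc:
            raise StageError("dissimilarity", str(exc)) from exc

        # --- stage: train ----------------------------------------------
        try:
            reports = classify.run_models(
                fvs,
                k=config.folds,
                seed=config.cv_seed,
                models=config.model_names(),
                tree_params=config.tree_params(),
            )
            metrics = {r.model: r.to_dict() for r in reports}
            metrics["scar_vs_normal_wasserstein"] = w
            if scar_truth is not None:
                metrics["localization_dice"] = dice(candidate, scar_truth)
            image_io.write_metrics(metrics, out / "metrics.json")
            emit(out / "metrics.json")
        except RadscarError as exc:
            raise StageError("train", str(exc)) from exc

        manifest = {
            "artifacts": [
                {
                    "path": str(p.relative_to(out)),
                    "sha256": _sha256(p) if p.is_file() else None,
                }
                for p in artifacts
            ],
            "stages": list(STAGES),
            "elapsed_s": round(time.time() - t0, 3),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("pipeline complete: %d artifacts", len(artifacts))
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
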