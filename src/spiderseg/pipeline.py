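"""End-to-end wiring: manifest -> preprocess -> segment -> evaluate.

Segmentation thresholds are optimized per image (the search depends only
on the image, not on labels), so segmented images are computed once and
reused across evaluation splits; the SVD feature model and the ensemble
are refit inside every split.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import evaluate, preprocess, segment
from .config import PipelineConfig, stage_seed
from .errors import DataError

log = logging.getLogger("spiderseg")

LABEL_CODES = {"normal": 0, "tumor": 1}


def load_manifest(path) -> pd.DataFrame:
    path = Path(path)
    try:
        manifest = pd.read_csv(path)
    except OSError as exc:
        raise DataError(f"cannot read manifest {path}: {exc}") from exc
    missing = {"filename", "label"} - set(manifest.columns)
    if missing:
        raise DataError(f"manifest {path} lacks columns: {sorted(missing)}")
    bad = set(manifest["label"]) - set(LABEL_CODES)
    if bad:
        raise DataError(f"manifest {path} has unknown labels: {sorted(bad)}")
    return manifest


def load_image(path) -> np.ndarray:
    try:
        with Image.open(path) as img:
            return np.asarray(img.convert("L"))
    except OSError as exc:
        raise DataError(f"cannot read image {path}: {exc}") from exc


def segment_corpus(manifest: pd.DataFrame, image_dir, cfg: PipelineConfig,
                   out_dir=None) -> tuple[np.ndarray, np.ndarray, list[segment.SegmentedImage]]:
    """Preprocess + segment every manifest image; rows are flattened labels."""
    image_dir = Path(image_dir)
    seg_seed = stage_seed(cfg.seed, "segment")
    rows, labels, segmented = [], [], []
    m = cfg.segment.regions - 1
    for i, rec in enumerate(manifest.itertuples(index=False)):
        try:
            img = load_image(image_dir / rec.filename)
            pre = preprocess.preprocess_image(img, cfg.preprocess.threshold,
                                              cfg.preprocess.downsample)
            sso_cfg = _sso_config(cfg, m, seg_seed + i)
            seg = segment.segment_image(pre, C=cfg.segment.regions, q=cfg.segment.q,
                                        sso_config=sso_cfg)
        except Exception as exc:
            raise type(exc)(f"[segment stage, sample {rec.filename}] {exc}") from exc
        rows.append(seg.labels.ravel().astype(np.float64))
        labels.append(LABEL_CODES[rec.label])
        segmented.append(seg)
        if out_dir is not None:
            _write_segmented(Path(out_dir), rec.filename, seg)
        log.debug("segmented %s thresholds=%s fitness=%.6f",
                  rec.filename, seg.thresholds.thresholds, seg.fitness)
    shapes = {r.shape for r in rows}
    if len(shapes) > 1:
        raise DataError(f"images disagree in size after preprocessing: {shapes}")
    return np.vstack(rows), np.array(labels, dtype=int), segmented


def _sso_config(cfg: PipelineConfig, m: int, seed: int):
    from .sso import SSOConfig
    return SSOConfig(bounds=tuple((1.0, 254.0) for _ in range(m)),
                     population_size=cfg.sso.population_size,
                     max_iterations=cfg.sso.max_iterations,
                     attenuation_rate=cfg.sso.attenuation_rate,
                     mask_change_prob=cfg.sso.mask_change_prob,
                     mask_one_prob=cfg.sso.mask_one_prob,
                     seed=seed)


def _write_segmented(out_dir: Path, name: str, seg: segment.SegmentedImage) -> None:
    seg_dir = out_dir / "segmented"
    seg_dir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(seg.labels, mode="L").save(seg_dir / name)
    sidecar = {"thresholds": list(seg.thresholds.thresholds),
               "inclusive_uppers": list(seg.thresholds.to_inclusive()),
               "fitness": seg.fitness}
    (seg_dir / (Path(name).stem + ".json")).write_text(
        json.dumps(sidecar, sort_keys=True, indent=1))


def run_pipeline(cfg: PipelineConfig, manifest_path, out_dir) -> evaluate.EvalReport:
    """Run preprocessing, segmentation, feature extraction and evaluation.

    Writes segmented images + sidecars, the flattened feature corpus and
    the evaluation report under ``out_dir``. Deterministic given the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(manifest_path)
    image_dir = Path(manifest_path).parent
    log.info("segmenting %d images (C=%d, q=%g)", len(manifest),
             cfg.segment.regions, cfg.segment.q)
    X, y, _ = segment_corpus(manifest, image_dir, cfg, out_dir=out)
    np.savetxt(out / "segmented_flat.csv", X, fmt="%d", delimiter=",")

    eval_seed = stage_seed(cfg.seed, "evaluate")
    if cfg.evaluate.mode == "holdout":
        report = evaluate.repeated_holdout(
            X, y, reps=cfg.evaluate.reps, train_frac=cfg.evaluate.train_frac,
            energy_fraction=cfg.features.energy_fraction, seed=eval_seed,
            standardize=cfg.ensemble.standardize)
    else:
        report = evaluate.kfold_cv(
            X, y, k=cfg.evaluate.k, energy_fraction=cfg.features.energy_fraction,
            seed=eval_seed, standardize=cfg.ensemble.standardize)
    (out / "report.json").write_text(json.dumps(report.to_dict(), sort_keys=True, indent=1))
    log.info("mean accuracy %.2f%% (sens %.2f%%, spec %.2f%%)",
             report.mean_accuracy, report.sensitivity, report.specificity)
    return report
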