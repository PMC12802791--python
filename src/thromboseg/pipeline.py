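"""End-to-end pipeline: simulate -> preprocess -> train -> evaluate -> report.

Each stage writes its artifacts (plus a provenance record of seed and config
fingerprint) into its own subdirectory of ``out_dir`` and can be resumed:
with ``resume=True`` a stage whose outputs already exist is loaded instead of
recomputed.

Two test sets are produced: the regular one (with the microcatheter
distractor marker, like the training data) and a distractor-free twin built
from the same per-scene seeds, so the robustness of the model to the
distractor can be read off as a paired IOU difference.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .evaluation import evaluate_dataset
from .model import UNetConfig, load_params, save_params
from .preprocess import MaskPair, ThresholdConfig
from .simulate import SceneConfig, derive_seed, generate_dataset
from .stats import format_table, summarize
from .training import TrainConfig, train

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_pairs"]

logger = logging.getLogger(__name__)

PROCESSED_COLUMNS = ["id", "dot_mask_path", "clot_mask_path", "seed"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_train: int = 300
    n_test: int = 5
    seed: int = 0

    def validate(self) -> None:
        self.scene.validate()
        self.thresholds.validate()
        self.unet.validate()
        self.train.validate()
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        """Build from a YAML file with optional sections scene/thresholds/unet/train/pipeline."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"scene", "thresholds", "unet", "train", "pipeline"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
        sections = {}
        for name, typ in (
            ("scene", SceneConfig),
            ("thresholds", ThresholdConfig),
            ("unet", UNetConfig),
            ("train", TrainConfig),
        ):
            params = raw.get(name) or {}
            fields = {f.name for f in dataclasses.fields(typ)}
            bad = set(params) - fields
            if bad:
                raise ValueError(f"{path}: unknown keys {sorted(bad)} in section '{name}'")
            for key in ("clot_length_range", "clot_thickness_range"):
                if key in params:
                    params[key] = tuple(params[key])
            sections[name] = typ(**params)
        pl = raw.get("pipeline") or {}
        bad = set(pl) - {"n_train", "n_test", "seed"}
        if bad:
            raise ValueError(f"{path}: unknown keys {sorted(bad)} in section 'pipeline'")
        cfg = cls(**sections, **pl)
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed)
        return cfg


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def write_processed(out_dir: Path, pairs: list[MaskPair], seeds: list[int]) -> pd.DataFrame:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair, seed in zip(pairs, seeds):
        dot_p = f"{pair.source_id}_dot.png"
        clot_p = f"{pair.source_id}_clot.png"
        tio.write_mask_png(out_dir / dot_p, pair.dot_mask)
        tio.write_mask_png(out_dir / clot_p, pair.clot_mask)
        rows.append({"id": pair.source_id, "dot_mask_path": dot_p,
                     "clot_mask_path": clot_p, "seed": seed})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "manifest.csv", index=False)
    return df


def load_pairs(manifest_path: str | Path) -> list[MaskPair]:
    """Read a processed manifest (id, dot_mask_path, clot_mask_path, seed)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in PROCESSED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{manifest_path}: processed manifest missing columns {missing}")
    base = manifest_path.parent
    pairs = []
    for row in df.itertuples():
        for col in ("dot_mask_path", "clot_mask_path"):
            if not (base / getattr(row, col)).is_file():
                raise FileNotFoundError(
                    f"{manifest_path}: row id={row.id} references missing file "
                    f"{base / getattr(row, col)}"
                )
        pairs.append(
            MaskPair(
                dot_mask=tio.read_mask_png(base / row.dot_mask_path),
                clot_mask=tio.read_mask_png(base / row.clot_mask_path),
                source_id=str(row.id),
            )
        )
    return pairs


def preprocess_manifest(
    scene_dir: str | Path,
    thresholds: ThresholdConfig,
    out_dir: str | Path,
    clot_source: str = "auto",
) -> pd.DataFrame:
    """Turn a simulated dataset directory into model-resolution mask pairs.

    ``clot_source``: 'image' thresholds the radiopaque render, 'mask' uses the
    stored ground-truth mask, 'auto' tries the image first and falls back to
    the mask (the test-style case, where the clot is radiolucent).
    """
    from .preprocess import (
        ClotExtractionError,
        extract_clot_mask,
        extract_dot_mask,
        fill_marker_holes,
        normalize_dot_mask,
        resize_mask,
    )

    scene_dir = Path(scene_dir)
    manifest = tio.read_manifest(scene_dir / "manifest.csv")
    pairs, seeds = [], []
    for row in manifest.itertuples():
        image = tio.read_image_png(scene_dir / row.image_path)
        if clot_source == "mask":
            clot = tio.read_mask_png(scene_dir / row.clot_mask_path)
        else:
            try:
                clot = fill_marker_holes(extract_clot_mask(image, thresholds))
            except ClotExtractionError:
                if clot_source == "image":
                    raise
                clot = tio.read_mask_png(scene_dir / row.clot_mask_path)
        dot = normalize_dot_mask(extract_dot_mask(image, thresholds))
        pairs.append(
            MaskPair(
                dot_mask=resize_mask(dot, thresholds.target_size),
                clot_mask=resize_mask(clot, thresholds.target_size),
                source_id=str(row.id),
            )
        )
        seeds.append(int(row.seed))
    out_dir = Path(out_dir)
    write_processed(out_dir, pairs, seeds)
    tio.write_provenance(
        out_dir / "provenance.json", stage="preprocess", seed=None,
        config=dataclasses.asdict(thresholds),
    )
    return pairs


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path, resume: bool = False) -> dict:
    """Run all stages; returns (and writes) the summary report dict."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    train_seed = derive_seed(cfg.seed, 1_000_001)
    test_seed = derive_seed(cfg.seed, 2_000_002)

    @_stage("simulate")
    def do_simulate():
        train_cfg = dataclasses.replace(cfg.scene, radiopaque_clot=True)
        test_cfg = dataclasses.replace(cfg.scene, radiopaque_clot=False)
        test_nd_cfg = dataclasses.replace(test_cfg, distractor_enabled=False)
        for name, scfg, n, seed in (
            ("train", train_cfg, cfg.n_train, train_seed),
            ("test", test_cfg, cfg.n_test, test_seed),
            ("test_nodistractor", test_nd_cfg, cfg.n_test, test_seed),
        ):
            d = out / "scenes" / name
            if resume and (d / "manifest.csv").is_file():
                logger.info("simulate: reusing %s", d)
                continue
            logger.info("simulate: %d scenes -> %s", n, d)
            generate_dataset(scfg, n, seed, d)

    @_stage("preprocess")
    def do_preprocess():
        for name, source in (("train", "image"), ("test", "mask"),
                             ("test_nodistractor", "mask")):
            d = out / "processed" / name
            if resume and (d / "manifest.csv").is_file():
                logger.info("preprocess: reusing %s", d)
                continue
            preprocess_manifest(out / "scenes" / name, cfg.thresholds, d,
                                clot_source=source)

    @_stage("train")
    def do_train():
        weights = out / "model" / "weights.npz"
        if resume and weights.is_file():
            logger.info("train: reusing %s", weights)
            return load_params(weights)
        pairs = load_pairs(out / "processed" / "train" / "manifest.csv")
        params, log = train(pairs, cfg.train, cfg.unet)
        (out / "model").mkdir(parents=True, exist_ok=True)
        save_params(params, weights)
        pd.DataFrame([dataclasses.asdict(r) for r in log.records]).to_csv(
            out / "model" / "trainlog.csv", index=False
        )
        tio.write_provenance(
            out / "model" / "provenance.json", stage="train", seed=cfg.train.seed,
            config={"train": dataclasses.asdict(cfg.train),
                    "unet": dataclasses.asdict(cfg.unet)},
        )
        logger.info("train: best val mean IOU %.4f at epoch %d",
                    log.best_val_iou, log.best_epoch)
        return params

    @_stage("evaluate")
    def do_evaluate(params):
        (out / "metrics").mkdir(parents=True, exist_ok=True)
        results = {}
        for name in ("test", "test_nodistractor"):
            path = out / "metrics" / f"{name}.csv"
            if resume and path.is_file():
                results[name] = tio.read_metrics_csv(path)
                continue
            pairs = load_pairs(out / "processed" / name / "manifest.csv")
            metrics = evaluate_dataset(params, pairs, batch_size=cfg.train.batch_size)
            tio.write_metrics_csv(path, metrics)
            results[name] = tio.read_metrics_csv(path)
        return results

    @_stage("report")
    def do_report(results):
        from .evaluation import PerImageMetrics

        def records(df):
            return [PerImageMetrics(**row) for row in df.to_dict("records")]

        summaries = summarize(records(results["test"]))
        summaries_nd = summarize(records(results["test_nodistractor"]))
        gap = (results["test_nodistractor"]["mean_iou_2class"].mean()
               - results["test"]["mean_iou_2class"].mean())
        report = {
            "seed": cfg.seed,
            "n_train": cfg.n_train,
            "n_test": cfg.n_test,
            "config_fingerprint": tio.config_fingerprint(cfg),
            "test": [dataclasses.asdict(s) for s in summaries],
            "test_nodistractor": [dataclasses.asdict(s) for s in summaries_nd],
            "distractor_mean_iou_gap": float(gap),
            "table": format_table(summaries),
        }
        tio.write_summary_json(out / "summary.json", report)
        return report

    do_simulate()
    do_preprocess()
    params = do_train()
    results = do_evaluate(params)
    return do_report(results)
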