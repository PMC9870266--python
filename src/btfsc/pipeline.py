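"""End-to-end orchestration: denoise -> fuse -> segment -> features ->
feature selection -> bandwidth selection -> cross-validated classification.

A :class:`PipelineConfig` captures every stage parameter plus the master
seed; a run is fully reproducible from it (the manifest written next to
the outputs records config and seed).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .features import FeatureConfig, FEATURE_NAMES, GASettings, gaom_select, hybrid_features
from .fusion import FuseConfig, fuse
from .hfcmik import segment_tumor
from .hpwf import HPWFParams
from .io import LabeledSample, save_image, save_mask
from .metrics import ConfusionCounts, confusion_metrics, dice, mask_confusion, roc_auc
from .pnn import PNNClassifier, select_sigma

logger = logging.getLogger("btfsc.pipeline")

POSITIVE_LABEL = "malignant"


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    seed: int = 0
    fusion_mode: str = "activity"
    edge_gain: float = 0.25
    activity_window: int = 7
    rea_xi: float = 1.0
    rea_tol: float = 1e-4
    rea_max_iter: int = 100
    hpwf_windows: List[int] = field(default_factory=lambda: [3, 5])
    segmentation_k: int = 4
    fuzzifier: float = 2.0
    feature_use_mask: bool = True
    glcm_levels: int = 16
    wavelet: str = "db1"
    run_feature_selection: bool = True
    sigma_grid: List[float] = field(default_factory=lambda: [0.05, 0.1, 0.2, 0.5, 1.0, 2.0])
    cv_folds: int = 10
    classify: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load from a plain key-value YAML file; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def fuse_config(self) -> FuseConfig:
        return FuseConfig(
            mode=self.fusion_mode,
            edge_gain=self.edge_gain,
            activity_window=self.activity_window,
            rea_xi=self.rea_xi,
            rea_tol=self.rea_tol,
            rea_max_iter=self.rea_max_iter,
            hpwf=HPWFParams(windows=list(self.hpwf_windows)),
            cnn_seed=self.seed,
        )

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            levels=self.glcm_levels,
            use_mask=self.feature_use_mask,
            wavelet=self.wavelet,
        )


@dataclass
class PipelineResult:
    """Outputs of one run: per-sample artifacts and summary tables."""

    fused: List[np.ndarray]
    masks: List[np.ndarray]
    features: pd.DataFrame
    segmentation: Optional[pd.DataFrame]
    predictions: Optional[pd.DataFrame]
    classification: Optional[Dict[str, float]]
    selected_features: Optional[List[str]]
    sigma: Optional[float]


def _validate(dataset: List[LabeledSample], cfg: PipelineConfig) -> None:
    if not dataset:
        raise ValueError("empty dataset")
    if cfg.classify:
        labels = [s.label for s in dataset]
        if any(l is None for l in labels):
            raise ValueError("classification requires a label on every sample")
        _, counts = np.unique(labels, return_counts=True)
        if counts.size < 2:
            raise ValueError("classification requires at least two classes")
        if counts.min() < max(2, cfg.cv_folds):
            raise ValueError(
                f"each class needs at least {max(2, cfg.cv_folds)} samples "
                f"for {cfg.cv_folds}-fold cross-validation"
            )


def run_pipeline(
    dataset: List[LabeledSample],
    cfg: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run the full pipeline over a labeled dataset.

    Per sample: denoise both modalities, fuse, segment, extract the hybrid
    feature vector; then (when classification is enabled) select features
    with the genetic algorithm, pick the PNN bandwidth, and produce
    stratified cross-validated predictions and scores.
    """
    if cfg is None:
        cfg = PipelineConfig()
    _validate(dataset, cfg)
    fuse_cfg = cfg.fuse_config()
    feat_cfg = cfg.feature_config()

    fused_images: List[np.ndarray] = []
    masks: List[np.ndarray] = []
    rows = []
    seg_rows = []
    for i, sample in enumerate(dataset):
        t0 = time.perf_counter()
        fused = fuse(sample.mri, sample.ct, fuse_cfg)
        mask, _ = segment_tumor(
            fused, k=cfg.segmentation_k, m=cfg.fuzzifier
        )
        vec = hybrid_features(fused, mask, feat_cfg)
        fused_images.append(fused)
        masks.append(mask)
        rows.append(vec)
        if sample.mask is not None:
            cm = mask_confusion(mask, sample.mask)
            seg = confusion_metrics(cm)
            seg["dice"] = dice(mask, sample.mask)
            seg["sample"] = i
            seg_rows.append(seg)
        logger.info(
            "sample=%d stage=fuse+segment+features wall=%.2fs tumor_px=%d",
            i, time.perf_counter() - t0, int(mask.sum()),
        )

    features_df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    features_df.insert(0, "sample", range(len(dataset)))
    if any(s.label is not None for s in dataset):
        features_df["label"] = [s.label for s in dataset]

    segmentation = None
    if seg_rows:
        segmentation = pd.DataFrame(seg_rows).set_index("sample")

    predictions = None
    classification = None
    selected_names = None
    sigma = None
    if cfg.classify:
        F = features_df[FEATURE_NAMES].to_numpy()
        y = np.asarray([s.label for s in dataset])
        if cfg.run_feature_selection:
            idx = gaom_select(F, y, settings=GASettings(), seed=cfg.seed)
        else:
            idx = np.arange(F.shape[1])
        selected_names = [FEATURE_NAMES[i] for i in idx]
        Fs = F[:, idx]
        sigma = select_sigma(
            Fs, y, grid=list(cfg.sigma_grid), folds=cfg.cv_folds, seed=cfg.seed
        )
        skf = StratifiedKFold(
            n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed
        )
        pred = np.empty(len(y), dtype=object)
        score = np.empty(len(y))
        for train_idx, test_idx in skf.split(Fs, y):
            model = PNNClassifier(sigma=sigma).fit(Fs[train_idx], y[train_idx])
            proba = np.atleast_2d(model.predict_proba(Fs[test_idx]))
            pos_col = int(np.where(model.classes_ == POSITIVE_LABEL)[0][0])
            pred[test_idx] = model.classes_[np.argmax(proba, axis=1)]
            score[test_idx] = proba[:, pos_col]
        predictions = pd.DataFrame(
            {
                "sample": range(len(y)),
                "label": y,
                "predicted": pred.astype(str),
                "score_malignant": score,
            }
        )
        y_bin = (y == POSITIVE_LABEL).astype(int)
        p_bin = (pred.astype(str) == POSITIVE_LABEL).astype(int)
        cm = ConfusionCounts(
            tp=int(np.sum((p_bin == 1) & (y_bin == 1))),
            fp=int(np.sum((p_bin == 1) & (y_bin == 0))),
            tn=int(np.sum((p_bin == 0) & (y_bin == 0))),
            fn=int(np.sum((p_bin == 0) & (y_bin == 1))),
        )
        classification = confusion_metrics(cm)
        _, auc = roc_auc(score, y_bin)
        classification["auc"] = auc
        classification["sigma"] = sigma

    result = PipelineResult(
        fused=fused_images,
        masks=masks,
        features=features_df,
        segmentation=segmentation,
        predictions=predictions,
        classification=classification,
        selected_features=selected_names,
        sigma=sigma,
    )
    if out_dir is not None:
        _write_outputs(result, cfg, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for i, (fused, mask) in enumerate(zip(result.fused, result.masks)):
        save_image(fused, out / f"fused_{i:03d}.png", bit_depth=16)
        save_mask(mask, out / f"mask_{i:03d}.png")
    result.features.to_csv(out / "features.csv", index=False)
    if result.predictions is not None:
        result.predictions.to_csv(out / "preds.csv", index=False)
    metric_rows = []
    if result.segmentation is not None:
        mean_seg = result.segmentation.mean(numeric_only=True)
        metric_rows += [
            {"metric": f"seg_{k}", "value": v} for k, v in mean_seg.items()
        ]
    if result.classification is not None:
        metric_rows += [
            {"metric": f"cls_{k}", "value": v}
            for k, v in result.classification.items()
        ]
    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "selected_features": result.selected_features,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
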