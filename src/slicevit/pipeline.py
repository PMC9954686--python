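"""End-to-end experiment driver: synth -> decompose -> split -> train (xN
seeds) -> evaluate -> aggregate -> visualize, writing a self-describing
run directory."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attention import (extract_attention_maps, global_attention_feature_map,
                        save_attention_grid, save_global_attention_panel)
from .cohort import CohortSpec, generate_cohort, write_cohort
from .decompose import DecomposeParams, build_manifest, decompose_cohort
from .evaluate import (aggregate_repetitions, classification_report,
                       normalized_confusion, subject_report, vote_majority)
from .models import build_model, canonical_config
from .splits import apply_scheme, get_scheme, insert_hc_noise, stratified_split
from .train import (TrainConfig, predict_slices, select_best_checkpoint,
                    train_model)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_pipeline"]


@dataclass
class ExperimentConfig:
    """One experiment: a model variant on one modality under one scheme,
    repeated across seeds with fresh data splits."""

    model: str = "ovitad"
    modality: str = "smri"
    scheme: str = "AD_HC_MCI"
    seeds: tuple[int, ...] = (0, 1, 2)
    cohort: dict = field(default_factory=dict)
    decompose: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    model_overrides: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)  # {"n_to_ad": .., "n_to_mci": ..}
    attention_panels: bool = True

    @property
    def repetitions(self) -> int:
        return len(self.seeds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seeds" in raw:
            raw["seeds"] = tuple(raw["seeds"])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Execute all stages and return the populated run directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort_spec = CohortSpec(modality=config.modality, **config.cohort)
    volumes = _synth(cohort_spec, out_dir)
    records = _decompose(volumes, config, out_dir)

    subjects_by_class: dict[str, list[str]] = {}
    for vol in volumes:
        subjects_by_class.setdefault(vol.label, []).append(vol.subject_id)

    slice_reports, subj_reports = [], []
    for rep, seed in enumerate(config.seeds):
        rep_dir = out_dir / f"rep{rep}_seed{seed}"
        slice_rep, subj_rep = _run_repetition(
            config, records, subjects_by_class, seed, rep_dir)
        slice_reports.append(slice_rep)
        subj_reports.append(subj_rep)

    summary = aggregate_repetitions(subj_reports)
    slice_summary = aggregate_repetitions(slice_reports)
    pd.concat({"subject": summary.to_frame(), "slice": slice_summary.to_frame()}
              ).to_csv(out_dir / "repetition_summary.csv")
    rendered = {m: summary.render(m) for m in summary.means}
    logger.info("subject-level summary: %s", rendered)

    log = {
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "cohort_spec": asdict(cohort_spec),
        "summary_subject": {"means": summary.means, "stds": summary.stds,
                            "rendered": rendered},
        "summary_slice": {"means": slice_summary.means, "stds": slice_summary.stds},
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return out_dir


@_stage("synth")
def _synth(cohort_spec, out_dir):
    volumes = generate_cohort(cohort_spec)
    write_cohort(volumes, out_dir / "cohort")
    return volumes


@_stage("decompose")
def _decompose(volumes, config, out_dir):
    params = DecomposeParams(**config.decompose)
    return decompose_cohort(volumes, params, out_dir / "slices")


def _run_repetition(config, records, subjects_by_class, seed, rep_dir):
    rep_dir.mkdir(parents=True, exist_ok=True)
    split = stratified_split(subjects_by_class, seed=seed)
    split.to_frame().to_csv(rep_dir / "split.csv", index=False)

    manifest = build_manifest(records, split.assignment)
    manifest = apply_scheme(manifest, get_scheme(config.scheme))
    label_column = "label"
    if config.noise:
        manifest = insert_hc_noise(manifest, seed=seed, **config.noise)
        label_column = "train_label"
    manifest.to_csv(rep_dir / "manifest.csv", index=False)

    labels = tuple(sorted(manifest["label"].unique()))
    model_cfg = canonical_config(config.model, num_classes=len(labels),
                                 **config.model_overrides)
    model = build_model(model_cfg, seed=seed)
    train_cfg = TrainConfig(seed=seed, **config.train)

    history, checkpoints = _train(model, manifest, train_cfg, rep_dir, label_column)
    history.to_frame().to_csv(rep_dir / "history.csv", index=False)
    best = select_best_checkpoint(history, checkpoints)

    test_rows = manifest[manifest["split"] == "test"]
    slice_preds = predict_slices(best, test_rows)
    subject_preds = vote_majority(slice_preds)

    slice_rep = classification_report([p.predicted_label for p in slice_preds],
                                      [p.true_label for p in slice_preds])
    subj_rep = subject_report(subject_preds)
    slice_rep.to_frame().to_csv(rep_dir / "report_slice_test.csv")
    subj_rep.to_frame().to_csv(rep_dir / "report_subject_test.csv")

    confusion = normalized_confusion([p.predicted_label for p in subject_preds],
                                     [p.true_label for p in subject_preds],
                                     labels=list(labels))
    confusion.to_csv(rep_dir / "confusion_subject_test.csv")
    _save_confusion_heatmap(confusion, rep_dir / "confusion_subject_test.png")

    if config.attention_panels and len(test_rows):
        _attention_panels(best, test_rows, model_cfg, rep_dir)
    return slice_rep, subj_rep


@_stage("train")
def _train(model, manifest, train_cfg, rep_dir, label_column):
    return train_model(model, manifest, train_cfg, rep_dir / "checkpoints",
                       label_column=label_column, val_fallback_to_train=True)


@_stage("visualize")
def _attention_panels(best, test_rows, model_cfg, rep_dir):
    from .train import load_checkpoint, SliceDataset

    model, labels, _ = load_checkpoint(best)
    # first slice of the first test subject, as in the published figure
    first = test_rows.sort_values(["subject_id", "z", "t"]).iloc[0:1]
    ds = SliceDataset(first, model_cfg.image_size, labels)
    x, _ = ds.batch(np.arange(1))
    stack = extract_attention_maps(model, x[0])
    save_attention_grid(stack, rep_dir / "attention_grid.png")
    result = model.forward(x)
    gmap = global_attention_feature_map(ds.images[0, 0], result.features[0],
                                        size=model_cfg.image_size)
    save_global_attention_panel([gmap], rep_dir / "global_attention.png")


def _save_confusion_heatmap(confusion: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 2.8))
    im = ax.imshow(confusion.to_numpy(), cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(confusion.columns)), confusion.columns)
    ax.set_yticks(range(len(confusion.index)), confusion.index)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(confusion.shape[0]):
        for j in range(confusion.shape[1]):
            ax.text(j, i, f"{confusion.iat[i, j]:.2f}", ha="center", va="center")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
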