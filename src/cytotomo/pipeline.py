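"""End-to-end synthetic experiment: generate → (project → reconstruct) →
augment → featurize → train → evaluate.

`run_experiment` reproduces the full study design on seeded synthetic
cells: a class-stratified benchmark is generated, the training split is
augmented with the 9×/3×/3× multiplicities, 44-feature vectors are
extracted from the 3D tomograms (and optionally from the 0° phase maps
for the 2D baseline), a hierarchical classifier is trained per flavor,
and both are evaluated on the same untouched test cells.

Tomograms can be taken directly from the generator (``ideal`` mode,
isolating the feature/classification layers) or passed through the
physical loop (``reconstruct`` mode: rotate, project to a QPM sequence,
estimate rolling angles, invert by filtered back projection).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augment3d, classify, features, metrics, phantom, projection, tomography
from .core import DEFAULT_GRID, DEFAULT_PITCH_UM, DEFAULT_WAVELENGTH_UM, RITomogram


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment byte-for-byte."""

    counts: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in phantom.DEFAULT_COUNTS.items()}
    )
    multiplicity: dict = field(
        default_factory=lambda: dict(augment3d.DEFAULT_MULTIPLICITY)
    )
    seed: int = 0
    grid: int = DEFAULT_GRID
    voxel_pitch: float = DEFAULT_PITCH_UM
    radius_scale: float = 1.0
    tomogram_mode: str = "ideal"  # "ideal" or "reconstruct"
    angle_step_deg: float = 3.0
    n_frames: int = 130
    use_estimated_angles: bool = True
    include_2d: bool = True
    wavelength: float = DEFAULT_WAVELENGTH_UM
    alpha_ri: float = features.DEFAULT_ALPHA_RI
    nn_max_iter: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def benchmark_config(seed: int = 0) -> ExperimentConfig:
    """The default seeded benchmark used for release gating.

    Same class separations, augmentation multiplicities (9×/3×/3×) and
    test split (47/122/60) as the full-size experiment, with the phantom
    geometry scaled by half onto a 100³ grid and the training originals
    reduced to 30/40/40 so a complete run stays in the minutes range on
    one core.
    """
    return ExperimentConfig(
        counts={
            "train": {"MC": 30, "NB": 40, "OC": 40},
            "test": {"MC": 47, "NB": 122, "OC": 60},
        },
        multiplicity={"MC": 9, "NB": 3, "OC": 3},
        seed=seed,
        grid=100,
        radius_scale=0.5,
        tomogram_mode="ideal",
        include_2d=True,
    )


def _acquire(tomo: RITomogram, config: ExperimentConfig) -> RITomogram:
    """Pass a ground-truth tomogram through the imaging loop if requested."""
    if config.tomogram_mode == "ideal":
        return tomo
    if config.tomogram_mode != "reconstruct":
        raise ValueError(f"unknown tomogram_mode {config.tomogram_mode!r}")
    angles = [config.angle_step_deg * k for k in range(config.n_frames)]
    qpms = projection.project_sequence(tomo, angles, config.wavelength)
    if config.use_estimated_angles:
        try:
            track = tomography.estimate_angles(qpms)
        except tomography.PeriodNotFoundError:
            track = tomography.AngleTrack(np.asarray(angles), np.arange(len(angles)))
    else:
        track = tomography.AngleTrack(np.asarray(angles), np.arange(len(angles)))
    return tomography.reconstruct_fbp(qpms, track, n0=tomo.n0)


def _iter_split(config: ExperimentConfig, split: str, start_index: int):
    """Yield (label, ground-truth tomogram) pairs for one split."""
    dists = phantom.ClassDistributions(radius_scale=config.radius_scale)
    shape = (config.grid,) * 3
    index = start_index
    for label in phantom.CLASS_LABELS:
        for _ in range(config.counts[split].get(label, 0)):
            seed = phantom.cell_seed(config.seed, index)
            params = phantom.sample_class_params(
                label, seed, dists, shape=shape, voxel_pitch=config.voxel_pitch
            )
            tomo, _ = phantom.generate_phantom(params)
            yield label, tomo
            index += 1


def _split_size(config: ExperimentConfig, split: str) -> int:
    return sum(config.counts[split].get(c, 0) for c in phantom.CLASS_LABELS)


def _featurize(tomo: RITomogram, config: ExperimentConfig) -> tuple[np.ndarray, np.ndarray | None]:
    """3D feature row (and the 2D baseline row when enabled) for one cell."""
    row3d = features.features_3d(tomo, alpha_ri=config.alpha_ri).values
    row2d = None
    if config.include_2d:
        qpm = projection.project_qpm(tomo, 0.0, config.wavelength)
        row2d = features.features_2d(qpm, alpha_ri=config.alpha_ri).values
    return row3d, row2d


def _evaluate(
    model: classify.HierarchicalModel,
    test_features: np.ndarray,
    test_labels: np.ndarray,
) -> dict:
    """Confusion matrices and metric reports for both stages + hierarchy."""
    coarse_true = np.where(test_labels == "MC", "MC", "tumor")
    coarse_pred, _ = model.stage_a.predict(test_features)
    cm_a = metrics.confusion_matrix(coarse_true, coarse_pred, ("MC", "tumor"))

    tumor_rows = test_labels != "MC"
    fine_pred, _ = model.stage_b.predict(test_features[tumor_rows])
    cm_b = metrics.confusion_matrix(
        test_labels[tumor_rows], fine_pred, ("NB", "OC")
    )

    hier_pred = classify.predict_hierarchical(model, test_features)
    cm_h = metrics.confusion_matrix(test_labels, hier_pred, ("MC", "NB", "OC"))

    report_a = metrics.binary_metrics(cm_a)
    report_h = metrics.multiclass_metrics(cm_h)
    # routing identity: a cell exits as MC iff stage A said MC
    assert report_h.per_class["MC"]["recall"] == report_a.per_class["MC"]["recall"]

    return {
        "stage_A": {
            "confusion": cm_a.counts.tolist(),
            "classes": list(cm_a.classes),
            "report": report_a.as_dict(),
        },
        "stage_B": {
            "confusion": cm_b.counts.tolist(),
            "classes": list(cm_b.classes),
            "report": metrics.binary_metrics(cm_b).as_dict(),
        },
        "hierarchical": {
            "confusion": cm_h.counts.tolist(),
            "classes": list(cm_h.classes),
            "report": report_h.as_dict(),
        },
    }


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic experiment; returns the metric bundle.

    The bundle carries the stage-A/stage-B/hierarchical reports for the
    3D pipeline (and the 2D baseline when enabled) plus the 3D-vs-2D
    hierarchical accuracy gap, and is JSON-serializable.
    """
    # streamed: each volume is generated, (optionally) imaged and
    # reconstructed, augmented, featurized and immediately discarded, so
    # peak memory holds only a couple of tomograms at a time
    aug_labels: list[str] = []
    x_train_3d: list[np.ndarray] = []
    x_train_2d: list[np.ndarray] = []
    for k, (label, tomo) in enumerate(_iter_split(config, "train", 0)):
        acquired = _acquire(tomo, config)
        for record in (acquired,) + tuple(
            augment3d.augment(acquired, phantom.cell_seed(config.seed + 1, k * 64 + m))[0]
            for m in range(config.multiplicity.get(label, 0))
        ):
            row3d, row2d = _featurize(record, config)
            aug_labels.append(label)
            x_train_3d.append(row3d)
            if row2d is not None:
                x_train_2d.append(row2d)

    test_labels_list: list[str] = []
    x_test_3d: list[np.ndarray] = []
    x_test_2d: list[np.ndarray] = []
    for label, tomo in _iter_split(config, "test", _split_size(config, "train")):
        row3d, row2d = _featurize(_acquire(tomo, config), config)
        test_labels_list.append(label)
        x_test_3d.append(row3d)
        if row2d is not None:
            x_test_2d.append(row2d)

    aug_labels_arr = np.asarray(aug_labels)
    test_labels = np.asarray(test_labels_list)
    x_train_3d = np.stack(x_train_3d)
    x_test_3d = np.stack(x_test_3d)

    bundle: dict = {
        "config": asdict(config),
        "train_counts": {
            c: int((aug_labels_arr == c).sum()) for c in phantom.CLASS_LABELS
        },
        "test_counts": {
            c: int((test_labels == c).sum()) for c in phantom.CLASS_LABELS
        },
    }

    model_3d = classify.fit_hierarchical(
        x_train_3d,
        aug_labels_arr,
        classify.HierarchicalConfig(max_iter=config.nn_max_iter),
        seed=config.seed,
    )
    bundle["3D"] = _evaluate(model_3d, x_test_3d, test_labels)

    if config.include_2d:
        model_2d = classify.fit_hierarchical(
            np.stack(x_train_2d),
            aug_labels_arr,
            classify.HierarchicalConfig(kind_a="logistic", kind_b="lda"),
            seed=config.seed,
        )
        bundle["2D"] = _evaluate(model_2d, np.stack(x_test_2d), test_labels)
        bundle["accuracy_gap_3d_minus_2d"] = (
            bundle["3D"]["hierarchical"]["report"]["accuracy"]
            - bundle["2D"]["hierarchical"]["report"]["accuracy"]
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "metrics.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
        config.to_yaml(out_dir / "config.yaml")
        names = features.feature_names("3D")
        df = pd.DataFrame(x_test_3d, columns=list(names))
        df.insert(0, "class_label", test_labels)
        df.to_csv(out_dir / "test_features_3d.csv", index=False)
    return bundle
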