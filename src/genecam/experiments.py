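"""Standard desk-scale studies on the synthetic planted-marker cohorts.

These are the package's canonical verification experiments; each is a
deterministic function of one seed and returns plain measured quantities.

* default study - 4 well-separated unequal classes (60/40/30/20 samples,
  2,000 genes, 20 markers/class at +4 log2, noise sd 0.5): pooled 10-fold
  accuracy, confusion matrix, leader-gene recovery of the focal class's
  planted markers, and a marker-vs-non-marker rank-sum test on the
  aggregated attribution scores.
* permutation control - the same pipeline after permuting labels; pooled
  accuracy should collapse to chance, guarding against leakage.
* confusable study - classes 0 and 1 share their marker program except
  two subtle (2-fold) private genes each; measures the confusability
  index of the shared pair against the disjoint pairs.
* attribution study - a separable 2-class fixture on 256-pixel images;
  Spearman agreement between the upsampled CAM and the occlusion oracle,
  probed at the coarse map's own spatial resolution (window = the
  cumulative pooling stride) and averaged over the held-out focal-class
  samples.

Images are 128 pixels and training is 15 epochs in the pipeline studies:
with the default variance threshold only the planted markers survive
filtering, so a 128-pixel image holds the full retained gene set while
keeping a 10-fold run to a couple of minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, spearmanr

from .attribution import compute_cam, occlusion_importance, upsample_heatmap
from .classifier import CNNConfig, TrainConfig, build_model, cross_validate, predict, train_fold
from .evaluation import ConfusionMatrix, confusability_index, run_multiwise_experiment
from .preprocessing import PreprocessConfig, preprocess_dataset
from .synthetic import LabeledDataset, confusable_spec, default_spec, generate_dataset

__all__ = [
    "pipeline_configs",
    "run_default_study",
    "run_permutation_control",
    "run_confusable_study",
    "run_attribution_study",
]

PIPELINE_IMAGE_LENGTH = 128
PIPELINE_EPOCHS = 15
PIPELINE_FOLDS = 10


def pipeline_configs(
    n_classes: int,
    seed: int,
    image_length: int = PIPELINE_IMAGE_LENGTH,
    epochs: int = PIPELINE_EPOCHS,
    folds: int = PIPELINE_FOLDS,
) -> tuple[PreprocessConfig, CNNConfig, TrainConfig]:
    return (
        PreprocessConfig(image_length=image_length),
        CNNConfig(n_classes=n_classes, image_length=image_length),
        TrainConfig(epochs=epochs, folds=folds, seed=seed),
    )


@dataclass
class DefaultStudyResult:
    dataset: LabeledDataset
    cv: "object"
    confusion: ConfusionMatrix
    pooled_accuracy: float
    focal_class: str
    ranking_genes: list[str]
    marker_recovery: float  # fraction of the focal class's planted markers in its top-20
    ranksum_p: float  # marker vs non-marker aggregated attribution scores
    aggregated_scores: "object" = field(repr=False, default=None)


def run_default_study(seed: int, focal_class: str = "class0") -> DefaultStudyResult:
    """Full multiwise pipeline on the default 4-class planted-marker cohort."""
    dataset = generate_dataset(default_spec(seed))
    pconfig, cconfig, tconfig = pipeline_configs(4, seed)
    result = run_multiwise_experiment(
        dataset, pconfig, cconfig, tconfig, focal_class=focal_class
    )
    ranking = result.rankings[focal_class]
    markers = set(dataset.truth.genes_of(focal_class))
    top = set(ranking.genes[:20])
    from .attribution import aggregate_class_scores

    agg = aggregate_class_scores(result.cv, dataset, focal_class)
    marker_scores = [v for k, v in agg.items() if k in markers]
    other_scores = [v for k, v in agg.items() if k not in markers]
    p = float(mannwhitneyu(marker_scores, other_scores, alternative="greater").pvalue)
    return DefaultStudyResult(
        dataset=dataset,
        cv=result.cv,
        confusion=result.confusion,
        pooled_accuracy=result.cv.pooled_accuracy,
        focal_class=focal_class,
        ranking_genes=ranking.genes,
        marker_recovery=len(top & markers) / len(markers),
        ranksum_p=p,
        aggregated_scores=agg,
    )


def run_permutation_control(seed: int) -> float:
    """Pooled CV accuracy after permuting the labels: the leakage guard."""
    dataset = generate_dataset(default_spec(seed))
    rng = np.random.default_rng([seed, 99])
    permuted = dataset.labels.copy()
    permuted[:] = rng.permutation(permuted.values)
    shuffled = LabeledDataset(dataset.expression, permuted)
    pconfig, cconfig, tconfig = pipeline_configs(4, seed)
    return cross_validate(shuffled, pconfig, cconfig, tconfig).pooled_accuracy


@dataclass
class ConfusableStudyResult:
    confusion: ConfusionMatrix
    pooled_accuracy: float
    shared_confusability: float
    max_disjoint_confusability: float


def run_confusable_study(seed: int) -> ConfusableStudyResult:
    """Multiwise pipeline on the shared-marker cohort pair."""
    from .synthetic import make_confusable_dataset

    dataset = make_confusable_dataset(confusable_spec(seed))
    pconfig, cconfig, tconfig = pipeline_configs(4, seed)
    cv = cross_validate(dataset, pconfig, cconfig, tconfig)
    cm = cv.confusion()
    shared = confusability_index(cm, "class0", "class1")
    names = cm.class_names
    disjoint = [
        confusability_index(cm, a, b)
        for i, a in enumerate(names)
        for b in names[i + 1 :]
        if {a, b} != {"class0", "class1"}
    ]
    return ConfusableStudyResult(
        confusion=cm,
        pooled_accuracy=cv.pooled_accuracy,
        shared_confusability=shared,
        max_disjoint_confusability=max(disjoint),
    )


@dataclass
class AttributionStudyResult:
    spearman: float
    test_accuracy: float
    n_averaged: int
    cam: np.ndarray = field(repr=False, default=None)
    occlusion: np.ndarray = field(repr=False, default=None)


def run_attribution_study(seed: int, epochs: int = 12) -> AttributionStudyResult:
    """CAM vs occlusion-oracle agreement on a separable 2-class fixture.

    The occlusion window equals the cumulative pooling stride (8): a map
    pooled three times cannot represent structure finer than that, so the
    oracle perturbs at the resolution the map actually has. Window
    importances are averaged back onto pixels, and both attributions are
    averaged over all held-out focal-class samples before comparison.
    """
    spec = default_spec(
        seed, n_genes=400, n_classes=2, samples_per_class=(50, 50), n_markers_per_class=25
    )
    dataset = generate_dataset(spec)
    # low threshold so the 256-pixel image is fully gene-occupied
    pconfig = PreprocessConfig(image_length=256, variance_threshold=0.15)
    images, layout, _ = preprocess_dataset(dataset.expression, pconfig)
    classes = sorted(dataset.labels.unique())
    y = np.array([classes.index(dataset.labels[img.sample_id]) for img in images])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(images))
    train_idx, test_idx = order[:50], order[50:]
    cconfig = CNNConfig(n_classes=2, image_length=256)
    model = build_model(cconfig, seed=seed, layout=layout)
    train_fold(model, [images[i] for i in train_idx], y[train_idx],
               TrainConfig(epochs=epochs, seed=seed))
    probs = predict(model, [images[i] for i in test_idx])
    test_accuracy = float((probs.argmax(axis=1) == y[test_idx]).mean())

    window = cconfig.pool_width ** len(cconfig.conv_filters)
    length = layout.image_length
    focal = 0
    cams, occs = [], []
    for i in test_idx:
        if y[i] != focal:
            continue
        hm = upsample_heatmap(compute_cam(model, images[i], focal), length)
        cams.append(hm.upsampled)
        occ = occlusion_importance(model, images[i], focal, window=window)
        per_pixel = np.zeros(length)
        coverage = np.zeros(length)
        for j in range(len(occ)):
            per_pixel[j : j + window] += occ[j]
            coverage[j : j + window] += 1
        occs.append(per_pixel / coverage)
    nonpad = ~layout.is_padding()
    cam_mean = np.mean(cams, axis=0)
    occ_mean = np.mean(occs, axis=0)
    rho = float(spearmanr(cam_mean[nonpad], occ_mean[nonpad]).statistic)
    return AttributionStudyResult(
        spearman=rho, test_accuracy=test_accuracy, n_averaged=len(cams),
        cam=cam_mean, occlusion=occ_mean,
    )
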