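"""The 1-D CNN tumour classifier and its cross-validation protocol.

The network has three convolutional stages (64, 128, 256 filters by
default), each immediately followed by a max-pooling layer and a
batch-normalisation layer, a single 25% dropout before the fully
connected head, and four fully connected layers: flattened-input -> 1024
-> 512 -> 256 -> n_classes with softmax output. With the default image
length of 1152 the flattened input is 36,864 features. Training minimises
cross-entropy with Adam; evaluation uses stratified k-fold
cross-validation (10 folds by default) so every sample is scored exactly
once as held-out.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .network import Adam, ConvNet, flatten_size
from .preprocessing import (
    GeneImage,
    GeneLayout,
    PreprocessConfig,
    build_gene_layout,
    embed_samples,
    fit_intensity_scaler,
    log_transform,
    preprocess_dataset,
    variance_filter,
)
from .synthetic import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "ModelHandle",
    "FoldResult",
    "CVResult",
    "build_model",
    "flattened_feature_size",
    "train_fold",
    "predict",
    "cross_validate",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CNNConfig:
    n_classes: int
    image_length: int = 1152
    conv_filters: tuple[int, ...] = (64, 128, 256)
    conv_kernel: int = 7
    pool_width: int = 2
    fc_sizes: tuple[int, ...] = (1024, 512, 256)
    dropout_rate: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_filters", tuple(self.conv_filters))
        object.__setattr__(self, "fc_sizes", tuple(self.fc_sizes))
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.image_length <= 0 or self.pool_width < 1 or self.conv_kernel < 1:
            raise ConfigurationError("image_length, pool_width, conv_kernel must be positive")
        if flattened_feature_size(self) < 1:
            spatial = self.image_length
            sizes = [spatial]
            for _ in self.conv_filters:
                spatial //= self.pool_width
                sizes.append(spatial)
            raise ConfigurationError(
                f"image_length {self.image_length} collapses under pooling: spatial sizes {sizes}"
            )


def flattened_feature_size(config: CNNConfig) -> int:
    """Feature count entering the first fully connected layer.

    image_length floor-divided by pool_width once per conv stage, times the
    final filter count: 1152 -> 144 positions x 256 channels = 36,864.
    """
    return flatten_size(
        config.image_length, len(config.conv_filters), config.pool_width, config.conv_filters[-1]
    )


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "cross_entropy"
    optimiser: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss != "cross_entropy":
            raise ConfigurationError(f"unsupported loss {self.loss!r}")
        if self.optimiser != "adam":
            raise ConfigurationError(f"unsupported optimiser {self.optimiser!r}")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigurationError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class ModelHandle:
    """A (possibly trained) network plus the config and layout it belongs to."""

    net: ConvNet
    config: CNNConfig
    layout: GeneLayout | None = None
    class_names: list[str] | None = None
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.layout is not None and self.layout.image_length != self.config.image_length:
            raise ConfigurationError(
                f"layout length {self.layout.image_length} != config image_length "
                f"{self.config.image_length}"
            )


def build_model(
    config: CNNConfig,
    seed: int = 0,
    layout: GeneLayout | None = None,
    class_names: list[str] | None = None,
) -> ModelHandle:
    """Build an untrained network with seeded parameter initialization."""
    net = ConvNet(
        image_length=config.image_length,
        conv_filters=list(config.conv_filters),
        kernel=config.conv_kernel,
        pool_width=config.pool_width,
        fc_sizes=list(config.fc_sizes),
        n_classes=config.n_classes,
        dropout_rate=config.dropout_rate,
        seed=seed,
    )
    assert net.flat_size == flattened_feature_size(config)  # shape introspection must agree
    return ModelHandle(net, config, layout, class_names)


def _stack(images: list[GeneImage]) -> np.ndarray:
    return np.stack([img.intensities for img in images])


def train_fold(
    model: ModelHandle,
    images: list[GeneImage],
    labels: np.ndarray,
    tconfig: TrainConfig,
) -> ModelHandle:
    """Train the model in place on the given images; returns the same handle.

    `labels` are integer class indices. Per-epoch mean minibatch loss and
    accuracy are appended to the handle's history. Fixed seed and inputs
    give a bit-reproducible history.
    """
    x = _stack(images)
    y = np.asarray(labels, dtype=int)
    present = np.unique(y)
    if len(present) < model.config.n_classes:
        warnings.warn(
            f"training fold covers {len(present)} of {model.config.n_classes} classes",
            stacklevel=2,
        )
    rng = np.random.default_rng([tconfig.seed, 101])
    opt = Adam(model.net.params, lr=tconfig.learning_rate)
    n = len(y)
    for epoch in range(tconfig.epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, tconfig.batch_size):
            idx = order[start : start + tconfig.batch_size]
            model.net.zero_grads()
            loss, acc = model.net.loss_and_grads(x[idx], y[idx], rng=rng)
            opt.step()
            losses.append(loss)
            accs.append(acc)
        model.history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "train_accuracy": float(np.mean(accs))}
        )
    return model


def predict(model: ModelHandle, images: list[GeneImage]) -> np.ndarray:
    """Class-probability rows (softmax), one per image; rows sum to 1."""
    for img in images:
        if img.layout.image_length != model.config.image_length:
            raise ConfigurationError(
                f"image length {img.layout.image_length} does not match the model's "
                f"{model.config.image_length}"
            )
    return model.net.predict_proba(_stack(images))


@dataclass
class FoldResult:
    fold: int
    test_sample_ids: list[str]
    test_images: list[GeneImage]
    y_true: np.ndarray  # class indices
    y_pred: np.ndarray
    probabilities: np.ndarray
    model: ModelHandle


@dataclass
class CVResult:
    class_names: list[str]
    folds: list[FoldResult]
    layout: GeneLayout  # whole-dataset layout (all_samples scope) or fold 0's

    @property
    def pooled(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """(sample ids, true indices, predicted indices) pooled over folds."""
        ids, yt, yp = [], [], []
        for fr in self.folds:
            ids += fr.test_sample_ids
            yt.append(fr.y_true)
            yp.append(fr.y_pred)
        return ids, np.concatenate(yt), np.concatenate(yp)

    @property
    def pooled_accuracy(self) -> float:
        _, yt, yp = self.pooled
        return float((yt == yp).mean())

    @property
    def mean_training_accuracy(self) -> float:
        """Final-epoch training accuracy averaged over folds."""
        finals = [fr.model.history[-1]["train_accuracy"] for fr in self.folds if fr.model.history]
        return float(np.mean(finals)) if finals else float("nan")

    def confusion(self):
        from .evaluation import confusion_matrix

        _, yt, yp = self.pooled
        names = self.class_names
        return confusion_matrix([names[i] for i in yt], [names[i] for i in yp], names)


def cross_validate(
    dataset: LabeledDataset,
    pconfig: PreprocessConfig,
    cconfig: CNNConfig,
    tconfig: TrainConfig,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    With variance_scope="all_samples" preprocessing (filter, layout,
    intensity scaling) is fitted once on the whole dataset, mirroring
    whole-cohort preprocessing; with "train_only" it is refitted on each
    fold's training samples and applied to the held-out fold, which is the
    leakage-free variant.
    """
    class_names = dataset.class_names
    if cconfig.n_classes != len(class_names):
        raise ConfigurationError(
            f"config expects {cconfig.n_classes} classes, dataset has {len(class_names)}"
        )
    class_index = {c: i for i, c in enumerate(class_names)}
    sample_ids = list(dataset.expression.columns)
    y_all = np.array([class_index[dataset.labels[s]] for s in sample_ids])

    if tconfig.stratified:
        counts = np.bincount(y_all, minlength=len(class_names))
        if counts.min() < tconfig.folds:
            small = class_names[int(counts.argmin())]
            raise ConfigurationError(
                f"class {small!r} has {counts.min()} samples, fewer than {tconfig.folds} folds; "
                "use fewer folds"
            )
        splitter = StratifiedKFold(n_splits=tconfig.folds, shuffle=True, random_state=tconfig.seed)
    else:
        splitter = KFold(n_splits=tconfig.folds, shuffle=True, random_state=tconfig.seed)

    global_images = global_layout = None
    if pconfig.variance_scope == "all_samples":
        images, global_layout, info = preprocess_dataset(dataset.expression, pconfig)
        global_images = {img.sample_id: img for img in images}
        logger.info(
            "preprocessing: retained %d genes (%d dropped at embedding)",
            info["n_retained"],
            info["n_dropped_at_embedding"],
        )

    folds: list[FoldResult] = []
    for fold_idx, (train_pos, test_pos) in enumerate(splitter.split(np.zeros(len(y_all)), y_all)):
        train_ids = [sample_ids[i] for i in train_pos]
        test_ids = [sample_ids[i] for i in test_pos]
        if pconfig.variance_scope == "all_samples":
            layout = global_layout
            train_images = [global_images[s] for s in train_ids]
            test_images = [global_images[s] for s in test_ids]
        else:
            transformed = log_transform(dataset.expression)
            train_block = type(transformed)(transformed.values[train_ids])
            filtered, retained = variance_filter(train_block, pconfig)
            layout = build_gene_layout(filtered, retained, pconfig)
            scaler = fit_intensity_scaler(filtered, layout.genes, pconfig)
            full = type(transformed)(transformed.values.loc[filtered.genes])
            train_images = embed_samples(full, layout, pconfig, scaler, samples=train_ids)
            test_images = embed_samples(full, layout, pconfig, scaler, samples=test_ids)

        model = build_model(
            cconfig, seed=tconfig.seed * 1000 + fold_idx, layout=layout, class_names=class_names
        )
        fold_tconfig = replace(tconfig, seed=tconfig.seed * 1000 + fold_idx)
        train_fold(model, train_images, y_all[train_pos], fold_tconfig)
        probs = predict(model, test_images)
        # argmax ties (rare with float probabilities) resolve to the lower class index
        y_pred = probs.argmax(axis=1)
        folds.append(
            FoldResult(
                fold=fold_idx,
                test_sample_ids=test_ids,
                test_images=test_images,
                y_true=y_all[test_pos],
                y_pred=y_pred,
                probabilities=probs,
                model=model,
            )
        )
    layout0 = global_layout if global_layout is not None else folds[0].model.layout
    return CVResult(class_names=class_names, folds=folds, layout=layout0)
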