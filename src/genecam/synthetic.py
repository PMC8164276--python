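"""Synthetic multi-class RNA-seq expression datasets with planted markers.

Emulates the structure of normalized-count tumour cohorts (RSEM-style,
genes x samples) at desk scale: several cancer classes of unequal size,
heavy-tailed non-negative counts, a small set of class-specific marker
genes with large log2-scale shifts, and - optionally - a pair of classes
that share almost their whole marker program except a few distinguishing
genes (the situation of two squamous-cell carcinomas of neighbouring
anatomical sites).

The count model is log-normal: for gene g in sample s of class c,

    x_gs = 2**z - 1,   z ~ Normal(mu_g + shift_{g,c}, sigma),  z truncated at 0

with per-gene baseline means mu_g drawn uniformly over a configurable
log2 interval, shift_{g,c} equal to ``marker_log2_shift`` for planted
(gene, class) pairs and 0 otherwise. Everything is driven by one seed
through named sub-streams, so e.g. adding genes does not reshuffle the
sample noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "MarkerTruth",
    "LabeledDataset",
    "generate_dataset",
    "make_confusable_dataset",
    "write_fixture",
    "read_fixture",
    "default_spec",
    "confusable_spec",
]

# fixed sub-stream indices: adding a stage must not renumber existing ones
_STREAMS = {"means": 0, "markers": 1, "shifts": 2, "noise": 3}


class ConfigurationError(ValueError):
    """A SyntheticSpec field violates its invariants."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset; identical specs give identical data."""

    n_genes: int
    n_classes: int
    samples_per_class: tuple[int, ...]
    n_markers_per_class: int = 20
    marker_log2_shift: float = 4.0
    baseline_log2_mean_range: tuple[float, float] = (1.0, 8.0)
    log2_noise_sd: float = 0.5
    shared_pair: tuple[int, int] | None = None
    n_distinct_genes: int = 2
    distinct_log2_shift: float | None = None  # shift of the shared pair's private genes
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples_per_class", tuple(self.samples_per_class))
        if self.shared_pair is not None:
            object.__setattr__(self, "shared_pair", tuple(self.shared_pair))
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_classes", "n_markers_per_class"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if len(self.samples_per_class) != self.n_classes:
            raise ConfigurationError(
                f"samples_per_class has length {len(self.samples_per_class)}, "
                f"expected n_classes={self.n_classes}"
            )
        if any(n <= 0 for n in self.samples_per_class):
            raise ConfigurationError("samples_per_class entries must be positive")
        if self.n_markers_per_class * self.n_classes > self.n_genes:
            raise ConfigurationError(
                "n_markers_per_class x n_classes exceeds n_genes "
                f"({self.n_markers_per_class} x {self.n_classes} > {self.n_genes})"
            )
        if self.log2_noise_sd <= 0:
            raise ConfigurationError("log2_noise_sd must be positive")
        lo, hi = self.baseline_log2_mean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_log2_mean_range must be a (low, high) interval")
        if self.shared_pair is not None:
            a, b = self.shared_pair
            if a == b or not (0 <= a < self.n_classes and 0 <= b < self.n_classes):
                raise ConfigurationError(f"shared_pair {self.shared_pair} must name two distinct classes")
            if self.n_distinct_genes > self.n_markers_per_class:
                raise ConfigurationError(
                    f"n_distinct_genes ({self.n_distinct_genes}) exceeds "
                    f"n_markers_per_class ({self.n_markers_per_class})"
                )


@dataclass
class MarkerTruth:
    """Planted marker genes per class, with their signed log2 shifts."""

    markers: dict[str, dict[str, float]]  # class name -> {gene_id: log2_shift}

    def genes_of(self, class_name: str) -> list[str]:
        return sorted(self.markers[class_name])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "gene_id": g, "log2_shift": s}
            for c in self.markers
            for g, s in sorted(self.markers[c].items())
        ]
        return pd.DataFrame(rows, columns=["class", "gene_id", "log2_shift"])


@dataclass
class LabeledDataset:
    """Expression matrix (genes x samples) with sample labels and optional planted truth."""

    expression: pd.DataFrame
    labels: pd.Series  # sample_id -> class name
    truth: MarkerTruth | None = None
    spec: SyntheticSpec | None = None

    def __post_init__(self) -> None:
        missing = set(self.expression.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)[:5]}")

    @property
    def class_names(self) -> list[str]:
        return sorted(self.labels.unique())

    def restrict(self, classes: list[str]) -> "LabeledDataset":
        """Subset to the samples of the given classes (pairwise experiments)."""
        keep = self.labels[self.labels.isin(classes)]
        truth = None
        if self.truth is not None:
            truth = MarkerTruth({c: dict(self.truth.markers[c]) for c in classes if c in self.truth.markers})
        return LabeledDataset(self.expression[keep.index], keep, truth, self.spec)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _class_names(n: int) -> list[str]:
    return [f"class{i}" for i in range(n)]


def _plant_markers(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[dict[int, list[int]], dict[int, list[int]]]:
    """Assign marker gene indices per class index.

    Disjoint blocks of a random gene permutation; for a shared pair, both
    classes get the same block except n_distinct_genes private genes each.
    """
    perm = rng.permutation(spec.n_genes)
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        block = perm[cursor : cursor + k]
        cursor += k
        return list(block)

    markers: dict[int, list[int]] = {}
    distinct: dict[int, list[int]] = {}
    if spec.shared_pair is None:
        for c in range(spec.n_classes):
            markers[c] = take(spec.n_markers_per_class)
    else:
        a, b = spec.shared_pair
        shared = take(spec.n_markers_per_class - spec.n_distinct_genes)
        distinct[a] = take(spec.n_distinct_genes)
        distinct[b] = take(spec.n_distinct_genes)
        markers[a] = shared + distinct[a]
        markers[b] = shared + distinct[b]
        for c in range(spec.n_classes):
            if c not in (a, b):
                markers[c] = take(spec.n_markers_per_class)
    return markers, distinct


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw one dataset from the spec's log-normal planted-marker model."""
    spec.validate()
    streams = {
        name: np.random.default_rng([spec.seed, idx]) for name, idx in _STREAMS.items()
    }
    genes = _gene_ids(spec.n_genes)
    classes = _class_names(spec.n_classes)
    n_samples = sum(spec.samples_per_class)
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    label_values = np.repeat(classes, spec.samples_per_class)
    labels = pd.Series(label_values, index=sample_ids, name="class")

    lo, hi = spec.baseline_log2_mean_range
    mu = streams["means"].uniform(lo, hi, size=spec.n_genes)

    marker_idx, distinct_idx = _plant_markers(spec, streams["markers"])
    shift = np.zeros((spec.n_genes, spec.n_classes))
    for c, idxs in marker_idx.items():
        shift[idxs, c] = spec.marker_log2_shift
    if spec.distinct_log2_shift is not None:
        for c, idxs in distinct_idx.items():
            shift[idxs, c] = spec.distinct_log2_shift

    class_of_sample = np.repeat(np.arange(spec.n_classes), spec.samples_per_class)
    z_mean = mu[:, None] + shift[:, class_of_sample]
    z = streams["noise"].normal(z_mean, spec.log2_noise_sd)
    np.maximum(z, 0.0, out=z)
    x = np.exp2(z) - 1.0

    expression = pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    truth = MarkerTruth(
        {
            classes[c]: {genes[g]: float(shift[g, c]) for g in idxs}
            for c, idxs in marker_idx.items()
        }
    )
    return LabeledDataset(expression, labels, truth, spec)


def make_confusable_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Dataset in which the shared_pair classes differ only in a few marker genes."""
    if spec.shared_pair is None:
        raise ConfigurationError("shared_pair must be set for a confusable dataset")
    return generate_dataset(spec)


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Four well-separated classes of unequal size: the standard test-bed."""
    kwargs = dict(
        n_genes=2000,
        n_classes=4,
        samples_per_class=(60, 40, 30, 20),
        n_markers_per_class=20,
        marker_log2_shift=4.0,
        baseline_log2_mean_range=(1.0, 8.0),
        log2_noise_sd=0.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def confusable_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Like default_spec but classes 0 and 1 share all markers except two each.

    The private genes of the shared pair carry a subtle 2-fold shift rather
    than the 16-fold shift of cohort markers: two carcinomas of the same
    tissue origin differ in a handful of modestly expressed genes, which is
    what makes them hard to tell apart.
    """
    kwargs = dict(shared_pair=(0, 1), n_distinct_genes=2, distinct_log2_shift=1.0)
    kwargs.update(overrides)
    return default_spec(seed, **kwargs)


def write_fixture(dataset: LabeledDataset, directory: str | Path) -> dict[str, Path]:
    """Write expression/labels/truth TSVs; round-trips exactly via read_fixture."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "labels": directory / "labels.tsv",
    }
    dataset.expression.to_csv(paths["expression"], sep="\t")
    labels = dataset.labels.rename_axis("sample_id").reset_index()
    labels.columns = ["sample_id", "class"]
    labels.to_csv(paths["labels"], sep="\t", index=False)
    if dataset.truth is not None:
        paths["truth"] = directory / "truth.tsv"
        dataset.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_fixture(directory: str | Path) -> LabeledDataset:
    """Read a dataset written by write_fixture."""
    from .io import read_expression_tsv, read_labels_tsv  # local import: io depends on nothing here

    directory = Path(directory)
    expression = read_expression_tsv(directory / "expression.tsv")
    labels = read_labels_tsv(directory / "labels.tsv", expression)
    truth = None
    truth_path = directory / "truth.tsv"
    if truth_path.exists():
        frame = pd.read_csv(truth_path, sep="\t")
        markers: dict[str, dict[str, float]] = {}
        for row in frame.itertuples(index=False):
            markers.setdefault(str(row[0]), {})[str(row[1])] = float(row[2])
        truth = MarkerTruth(markers)
    return LabeledDataset(expression, labels, truth)
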