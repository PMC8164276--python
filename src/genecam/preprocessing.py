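"""Expression-matrix preprocessing and 1-D gene-image embedding.

The pipeline's working scale is y = log2(x + 1) applied to non-negative
normalized counts. Low-information genes are removed with a variance
threshold (population variance of y strictly greater than the threshold),
and the retained genes are laid out on a fixed-length 1-D "gene image":
one pixel per gene, ordered by descending variance with a lexicographic
gene-id tie-break, trailing pixels padded. Pixel intensities are the
y-values min-max scaled globally (one min and max over all in-scope
retained values, not per gene) to the configured intensity range; padding
pixels carry the scaled value of y = 0.

The default image length of 1152 makes the downstream network's flattened
feature count come out at 1152/2/2/2 x 256 = 36,864 with three pool-2
stages and 256 final channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessConfig",
    "TransformedMatrix",
    "GeneLayout",
    "GeneImage",
    "IntensityScaler",
    "log_transform",
    "variance_filter",
    "build_gene_layout",
    "fit_intensity_scaler",
    "embed_samples",
    "preprocess_dataset",
]

PAD = ""  # padding sentinel in layouts


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    variance_threshold: float = 1.0
    image_length: int = 1152
    intensity_range: tuple[float, float] = (0.0, 1.0)
    ordering: str = "variance_desc"
    variance_scope: str = "all_samples"  # or "train_only"

    def __post_init__(self) -> None:
        if self.variance_threshold < 0:
            raise ValidationError("variance_threshold must be >= 0")
        if self.image_length <= 0:
            raise ValidationError("image_length must be positive")
        if self.ordering != "variance_desc":
            raise ValidationError(f"unknown ordering {self.ordering!r}")
        if self.variance_scope not in ("all_samples", "train_only"):
            raise ValidationError(f"unknown variance_scope {self.variance_scope!r}")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValidationError("intensity_range must be (low, high) with low < high")


@dataclass
class TransformedMatrix:
    """Genes x samples matrix of y = log2(x+1) values."""

    values: pd.DataFrame
    provenance: str = "y = log2(x + 1)"

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneLayout:
    """Bijection between retained genes and pixel positions of the 1-D image."""

    pixels: list[str]  # gene id per pixel, PAD for padding
    gene_to_pixel: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.gene_to_pixel = {g: i for i, g in enumerate(self.pixels) if g != PAD}
        if len(self.gene_to_pixel) != sum(1 for g in self.pixels if g != PAD):
            raise ValidationError("layout assigns a gene to more than one pixel")

    @property
    def image_length(self) -> int:
        return len(self.pixels)

    @property
    def genes(self) -> list[str]:
        return [g for g in self.pixels if g != PAD]

    @property
    def n_padding(self) -> int:
        return self.image_length - len(self.gene_to_pixel)

    def is_padding(self) -> np.ndarray:
        return np.array([g == PAD for g in self.pixels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pixel_index": range(self.image_length), "gene_id": self.pixels})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneLayout":
        pixels = ["" if pd.isna(g) else str(g) for g in frame["gene_id"]]
        return cls(pixels)


@dataclass
class IntensityScaler:
    """Global min-max scaling of y-values onto the target intensity range."""

    y_min: float
    y_max: float
    intensity_range: tuple[float, float] = (0.0, 1.0)

    def transform(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.intensity_range
        if self.y_max <= self.y_min:  # degenerate: everything to the lower bound
            return np.full_like(np.asarray(y, dtype=float), lo)
        scaled = lo + (np.asarray(y, dtype=float) - self.y_min) * (hi - lo) / (self.y_max - self.y_min)
        return np.clip(scaled, lo, hi)

    @property
    def pad_value(self) -> float:
        return float(self.transform(np.array([0.0]))[0])


@dataclass
class GeneImage:
    """One sample embedded as a fixed-length 1-D intensity vector."""

    sample_id: str
    intensities: np.ndarray
    layout: GeneLayout
    pad_value: float


def log_transform(matrix: pd.DataFrame) -> TransformedMatrix:
    """Apply y = log2(x + 1) elementwise; shape and identifiers preserved."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative expression value for gene {matrix.index[g]!r} in sample {matrix.columns[s]!r}"
        )
    return TransformedMatrix(pd.DataFrame(np.log2(values + 1.0), index=matrix.index, columns=matrix.columns))


def variance_filter(
    matrix: TransformedMatrix, config: PreprocessConfig
) -> tuple[TransformedMatrix, list[str]]:
    """Keep genes whose population variance (ddof 0) strictly exceeds the threshold."""
    if matrix.values.shape[1] < 2:
        raise ValidationError("variance filtering needs at least 2 samples")
    variances = matrix.values.var(axis=1, ddof=0)
    keep = variances > config.variance_threshold
    retained = list(matrix.genes[keep])
    return TransformedMatrix(matrix.values.loc[retained]), retained


def build_gene_layout(
    matrix: TransformedMatrix, retained: list[str], config: PreprocessConfig
) -> GeneLayout:
    """Assign retained genes to pixels by descending variance (lexicographic ties)."""
    if not retained:
        raise ValidationError("no genes retained; lower the variance threshold")
    variances = matrix.values.loc[retained].var(axis=1, ddof=0)
    order = sorted(retained, key=lambda g: (-variances[g], g))
    if len(order) > config.image_length:
        order = order[: config.image_length]
    pixels = order + [PAD] * (config.image_length - len(order))
    return GeneLayout(pixels)


def fit_intensity_scaler(
    matrix: TransformedMatrix, genes: list[str], config: PreprocessConfig
) -> IntensityScaler:
    """Fit global min-max bounds over the in-scope y-values of the given genes."""
    block = matrix.values.loc[genes].to_numpy()
    return IntensityScaler(float(block.min()), float(block.max()), config.intensity_range)


def embed_samples(
    matrix: TransformedMatrix,
    layout: GeneLayout,
    config: PreprocessConfig,
    scaler: IntensityScaler | None = None,
    samples: list[str] | None = None,
) -> list[GeneImage]:
    """Embed samples as gene images under the layout.

    The scaler defaults to one fitted on `matrix` itself (whole-dataset
    scope); pass a train-fitted scaler for leakage-free embedding of test
    samples. Out-of-range values are clipped.
    """
    genes = layout.genes
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"layout gene {missing[0]!r} missing from matrix")
    if scaler is None:
        scaler = fit_intensity_scaler(matrix, genes, config)
    sample_ids = list(samples) if samples is not None else list(matrix.samples)
    pad_value = scaler.pad_value
    block = matrix.values.loc[genes, sample_ids].to_numpy()  # genes x samples
    scaled = scaler.transform(block)
    pixel_of_gene = np.array([layout.gene_to_pixel[g] for g in genes])
    images = []
    for j, sid in enumerate(sample_ids):
        intensities = np.full(layout.image_length, pad_value)
        intensities[pixel_of_gene] = scaled[:, j]
        images.append(GeneImage(sid, intensities, layout, pad_value))
    return images


def preprocess_dataset(
    matrix: pd.DataFrame, config: PreprocessConfig
) -> tuple[list[GeneImage], GeneLayout, dict]:
    """Full whole-dataset preprocessing: transform, filter, layout, embed.

    Returns the images, the layout and an info dict with the retained and
    dropped gene counts (observable, since real runs never report them).
    """
    transformed = log_transform(matrix)
    filtered, retained = variance_filter(transformed, config)
    layout = build_gene_layout(filtered, retained, config)
    scaler = fit_intensity_scaler(filtered, layout.genes, config)
    images = embed_samples(filtered, layout, config, scaler)
    info = {
        "n_genes_in": matrix.shape[0],
        "n_retained": len(retained),
        "n_embedded": len(layout.genes),
        "n_dropped_at_embedding": len(retained) - len(layout.genes),
        "scaler": scaler,
    }
    return images, layout, info
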