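"""Class-activation heatmaps over gene images and leader-gene extraction.

The network here has no global-average-pooling head, so the classic CAM
construction does not apply directly; a gradient-weighted generalization
is used instead: the coarse map is the rectified element-wise product of
the positive logit gradients with the final stage's rectified pooled
activations, summed over channels (see compute_cam for why element-wise
rather than spatially averaged channel weights). Each map is normalized
to [0, 1] before any averaging so that large-logit samples do not
dominate an aggregate.

Because every non-padding pixel represents one gene, an upsampled heatmap
converts directly into per-gene attribution scores; averaging those over
a class's held-out samples (each scored by the fold model that never saw
it) and ranking gives the class's leader genes. An occlusion oracle -
probability drop when pixels are blanked to the scaled-zero value - is
provided as a brute-force cross-check of the gradient maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import CVResult, ModelHandle
from .preprocessing import GeneImage, GeneLayout
from .synthetic import LabeledDataset

__all__ = [
    "Heatmap",
    "GeneScore",
    "GeneRanking",
    "compute_cam",
    "upsample_heatmap",
    "pixel_to_gene_scores",
    "aggregate_class_scores",
    "extract_leader_genes_multiwise",
    "extract_leader_genes_pairwise",
    "occlusion_importance",
]


@dataclass
class Heatmap:
    sample_id: str
    target_class: int
    coarse: np.ndarray
    upsampled: np.ndarray | None = None
    normalization: str = "per-map max scaled to 1 (all-zero maps stay zero)"


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    score: float
    pixel_index: int


@dataclass
class GeneRanking:
    class_name: str
    mode: str  # "multiwise" or "pairwise"
    scores: list[GeneScore]  # descending score, lexicographic gene-id tie-break
    provenance: str = ""

    @property
    def genes(self) -> list[str]:
        return [s.gene_id for s in self.scores]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.scores) + 1),
                "gene_id": [s.gene_id for s in self.scores],
                "score": [s.score for s in self.scores],
                "mode": self.mode,
                "class": self.class_name,
            }
        )


def _normalize(m: np.ndarray) -> np.ndarray:
    peak = m.max()
    return m / peak if peak > 0 else m


def compute_cam(model: ModelHandle, image: GeneImage, target_class: int) -> Heatmap:
    """Gradient-weighted class activation map at the final block's resolution.

    The map is built from the last convolutional stage's rectified pooled
    activations A (non-negative) and the gradient G of the target-class
    logit with respect to them, as the rectified element-wise weighting

        coarse[l] = relu( sum_c relu(G[c, l]) * A[c, l] ).

    Element-wise (rather than spatially pooled) gradient weights keep the
    map spatially specific, which matters because this architecture feeds
    the maps into a fully connected head rather than global average
    pooling: different spatial positions of one channel can carry
    oppositely signed evidence, and a single averaged channel weight
    cancels it. Validity is anchored by the occlusion oracle.
    """
    if not model.history:
        warnings.warn("computing a CAM for an untrained model", stacklevel=2)
    if not 0 <= target_class < model.config.n_classes:
        raise ValueError(f"invalid target class {target_class}")
    x = image.intensities[None, :]
    feats, grads = model.net.features_and_logit_grad(x, target_class)  # (1, C, Lp) each
    coarse = np.maximum((np.maximum(grads[0], 0.0) * feats[0]).sum(axis=0), 0.0)
    return Heatmap(image.sample_id, target_class, _normalize(coarse.astype(float)))


def upsample_heatmap(heatmap: Heatmap, image_length: int) -> Heatmap:
    """Linear interpolation from pooled-grid pixel centers to full resolution."""
    coarse = np.asarray(heatmap.coarse, dtype=float)
    if coarse.size == 0:
        raise ValueError("coarse map is empty")
    stride = image_length / coarse.size
    centers = (np.arange(coarse.size) + 0.5) * stride - 0.5
    heatmap.upsampled = np.interp(np.arange(image_length), centers, coarse)
    return heatmap


def pixel_to_gene_scores(heatmap: Heatmap, layout: GeneLayout) -> list[GeneScore]:
    """One score per non-padding pixel; padding pixels are skipped."""
    if heatmap.upsampled is None:
        raise ValueError("heatmap has no upsampled field; call upsample_heatmap first")
    if len(heatmap.upsampled) != layout.image_length:
        raise ValueError(
            f"heatmap length {len(heatmap.upsampled)} != layout length {layout.image_length}"
        )
    return [
        GeneScore(gene, float(heatmap.upsampled[i]), i)
        for i, gene in enumerate(layout.pixels)
        if gene
    ]


def _sample_gene_scores(model: ModelHandle, image: GeneImage, target_class: int) -> pd.Series:
    hm = compute_cam(model, image, target_class)
    upsample_heatmap(hm, image.layout.image_length)
    scores = pixel_to_gene_scores(hm, image.layout)
    return pd.Series({s.gene_id: s.score for s in scores})


def aggregate_class_scores(
    cv: CVResult, dataset: LabeledDataset, target_class: str
) -> pd.Series:
    """Mean per-gene CAM score over the class's held-out samples.

    Each sample is scored by the fold model that did not train on it, so
    the aggregate reflects generalized rather than memorized attributions.
    """
    if target_class not in cv.class_names:
        raise ValueError(f"unknown class {target_class!r}")
    class_idx = cv.class_names.index(target_class)
    per_sample: list[pd.Series] = []
    for fr in cv.folds:
        for img, y in zip(fr.test_images, fr.y_true):
            if y == class_idx:
                per_sample.append(_sample_gene_scores(fr.model, img, class_idx))
    if not per_sample:
        raise ValueError(f"class {target_class!r} has no held-out samples")
    return pd.concat(per_sample, axis=1).mean(axis=1)


def _rank_scores(scores: pd.Series, top_n: int) -> list[GeneScore]:
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return [GeneScore(g, float(s), -1) for g, s in ordered]


def extract_leader_genes_multiwise(
    cv: CVResult, dataset: LabeledDataset, target_class: str, top_n: int = 20
) -> GeneRanking:
    """Top genes by aggregated CAM score from a multi-class cross-validation."""
    if len(cv.class_names) < 3:
        raise ValueError("multiwise extraction needs a cross-validation over >= 3 classes")
    agg = aggregate_class_scores(cv, dataset, target_class)
    if top_n > len(agg):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(agg)} retained genes; truncating", stacklevel=2
        )
        top_n = len(agg)
    scores = _rank_scores(agg, top_n)
    pixmap = cv.layout.gene_to_pixel
    scores = [GeneScore(s.gene_id, s.score, pixmap.get(s.gene_id, -1)) for s in scores]
    return GeneRanking(
        target_class,
        "multiwise",
        scores,
        provenance=f"{len(cv.folds)} folds",
    )


def extract_leader_genes_pairwise(
    rankings: list[GeneRanking], top_n: int = 20, pool_depth: int = 500
) -> GeneRanking:
    """Intersect the focal class's pairwise rankings and order by mean rank.

    The candidate set is the intersection of each ranking's top
    `pool_depth` genes; candidates are ordered by mean rank across the
    rankings (ascending, lexicographic gene-id tie-break) and truncated to
    top_n. A smaller-than-top_n intersection is returned whole with a
    warning.
    """
    if len(rankings) < 2:
        raise ValueError("pairwise intersection needs at least 2 rankings")
    focal = {r.class_name for r in rankings}
    if len(focal) != 1:
        raise ValueError(f"rankings target different focal classes: {sorted(focal)}")
    pools = [r.genes[:pool_depth] for r in rankings]
    shared = set(pools[0]).intersection(*pools[1:])
    if len(shared) < top_n:
        warnings.warn(
            f"pairwise intersection has only {len(shared)} genes (< top_n={top_n})", stacklevel=2
        )
    rank_maps = [{g: i + 1 for i, g in enumerate(pool)} for pool in pools]
    mean_rank = {g: float(np.mean([rm[g] for rm in rank_maps])) for g in shared}
    ordered = sorted(shared, key=lambda g: (mean_rank[g], g))[:top_n]
    scores = [GeneScore(g, mean_rank[g], -1) for g in ordered]
    return GeneRanking(
        rankings[0].class_name,
        "pairwise",
        scores,
        provenance=f"intersection of {len(rankings)} rankings at depth {pool_depth}",
    )


def occlusion_importance(
    model: ModelHandle, image: GeneImage, target_class: int, window: int = 1
) -> np.ndarray:
    """Brute-force attribution: probability drop when a pixel window is blanked.

    importance[i] = p(target | intact) - p(target | pixels [i, i+window)
    set to the scaled-zero pad value). Length = image_length - window + 1.
    """
    length = image.layout.image_length
    n_pos = length - window + 1
    # the intact image rides in the same batch so the baseline sees the
    # exact same (batched) arithmetic as the occluded variants
    batch = np.repeat(image.intensities[None, :], n_pos + 1, axis=0)
    for i in range(n_pos):
        batch[i, i : i + window] = image.pad_value
    probs = model.net.predict_proba(batch)[:, target_class]
    return probs[-1] - probs[:-1]
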