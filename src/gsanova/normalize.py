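"""Library-size normalization, log transform, and sample-level QC.

Counts are normalized with median-of-ratios size factors and put on a
log2 scale (``log2(count / size_factor + pseudocount)``) to serve as
approximately homoscedastic expression estimates.  This is a simple
variance-stabilizing transform, not the shrinkage-based regularized log
of negative-binomial DE packages; downstream scoring only requires some
homoscedastic expression estimate, and the transform used is recorded in
``transform_tag``.

Sample QC computes pairwise Euclidean distances between transformed
samples, builds an average-linkage dendrogram, and flags samples whose
nearest-neighbour distance is far above the cohort's typical value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io_formats import CountMatrix

__all__ = [
    "ExpressionMatrix",
    "DistanceMatrix",
    "OutlierReport",
    "size_factors",
    "vst_log",
    "sample_distances",
    "detect_outliers",
]


@dataclass
class ExpressionMatrix:
    """Real-valued transformed expression, genes × samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    transform_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match identifiers")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


@dataclass
class OutlierReport:
    """Result of nearest-neighbour-distance outlier screening."""

    flagged: list[str]
    isolation_score: dict[str, float]  # nearest-neighbour distance per sample
    threshold: float
    multiplier: float
    linkage: str
    dendrogram: str  # Newick-like nested text for manual review

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "flagged": self.flagged,
                "isolation_score": self.isolation_score,
                "threshold": self.threshold,
                "multiplier": self.multiplier,
                "linkage": self.linkage,
                "dendrogram": self.dendrogram,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios library-size factors, one per sample.

    For each gene with a positive geometric mean across samples, the ratio
    of each sample's count to that geometric mean is formed; a sample's
    factor is the median of its ratios.  Requires at least one gene with
    nonzero counts in every sample.
    """
    counts = cm.counts.astype(float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "normalization needs at least one, or a pseudo-reference fallback"
        )
    log_counts = np.log(counts[all_pos])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    assert (factors > 0).all()
    return factors


def vst_log(cm: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(size-factor-normalized count + pseudocount) expression estimates."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    factors = size_factors(cm)
    values = np.log2(cm.counts / factors[np.newaxis, :] + pseudocount)
    tag = f"log2_norm_pseudocount={pseudocount:g}_median_of_ratios"
    return ExpressionMatrix(list(cm.gene_ids), list(cm.sample_ids), values, tag)


def sample_distances(em: ExpressionMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample columns."""
    if em.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(em.values.T, metric="euclidean"))
    return DistanceMatrix(list(em.sample_ids), d)


def _newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    return f"({left},{right}):{node.dist:.4g}"


def detect_outliers(dm: DistanceMatrix, multiplier: float = 2.0) -> OutlierReport:
    """Flag isolated samples from a distance matrix.

    A sample is flagged when its nearest-neighbour distance exceeds
    ``multiplier`` times the median nearest-neighbour distance over all
    samples.  An average-linkage dendrogram is included as text so the
    automatic call can be reviewed by eye, mirroring the usual practice of
    inspecting the clustering of samples before analysis.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    n = len(dm.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for outlier screening")
    off = dm.d + np.diag(np.full(n, np.inf))
    nn = off.min(axis=1)
    threshold = multiplier * float(np.median(nn))
    flagged = [s for s, score in zip(dm.sample_ids, nn) if score > threshold]
    link = hierarchy.linkage(squareform(dm.d, checks=False), method="average")
    tree = hierarchy.to_tree(link)
    newick = _newick(tree, dm.sample_ids) + ";"
    return OutlierReport(
        flagged=flagged,
        isolation_score={s: float(v) for s, v in zip(dm.sample_ids, nn)},
        threshold=threshold,
        multiplier=multiplier,
        linkage="average",
        dendrogram=newick,
    )
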