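"""From normalized element accessibility to per-gene activity probabilities.

The signal-to-noise reference is a per-cell *threshold accessibility vector*:
the expected number of background fragments in one counting window, estimated
from coverage of blacklist (centromeric/telomeric artefact) regions. To keep
threshold and signal on one scale the raw threshold is appended to the element
matrix as a pseudo-element and carried through the same normalization
transforms.

An element is *open* in a cell iff its normalized value strictly exceeds the
cell's threshold. A gene's accessibility is the max over its promoter and
linked-enhancer values, so the gene-level open call is the OR of its elements'
calls. The continuous gene *activity* (probability of expression) is a
sigmoid of the gap between gene accessibility and threshold; it crosses 0.5
exactly where the hard open call flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .atac_signal import ElementCountMatrix, PipelineConfig
from .formats_io import CellAnnotation, RegulatoryElement
from .normalization import (
    NormalizedAccessibility,
    gc_normalize,
    smooth_quantile_normalize,
)

logger = logging.getLogger("epi_impute")

THRESHOLD_PSEUDO_ID = "__threshold__"
_ACTIVITY_EPS = 1e-12  # keeps activities in the open interval (0, 1)


@dataclass
class GeneAccessibilityMatrix:
    """Genes x cells accessibility gaps (gene value minus cell threshold)."""

    genes: list[str]
    cells: list[str]
    gaps: np.ndarray

    def __post_init__(self) -> None:
        self.gaps = np.asarray(self.gaps, dtype=float)
        if self.gaps.shape != (len(self.genes), len(self.cells)):
            raise ValueError("gap matrix shape does not match id lists")


@dataclass
class GeneActivityMatrix:
    """Genes x cells probabilities of expression, strictly inside (0, 1)."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    sigmoid_k: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("activity matrix shape does not match id lists")
        if np.any(self.values <= 0) or np.any(self.values >= 1):
            raise ValueError("activities must lie strictly inside (0, 1)")


def build_threshold_vector(
    blacklist_per_bp, config: PipelineConfig
) -> np.ndarray:
    """Raw per-cell threshold: blacklist fragments/bp times the window length.

    This is the expected number of noise fragments in one counting window
    (``flank_up + flank_down`` bp). The caller normalizes it alongside the
    element matrix via :func:`normalize_with_threshold`.
    """
    theta = np.asarray(blacklist_per_bp, dtype=float) * config.window_length
    if np.any(theta < 0):
        raise ValueError("blacklist coverage must be non-negative")
    return theta


def normalize_with_threshold(
    matrix: ElementCountMatrix,
    theta_raw: np.ndarray,
    elements: Sequence[RegulatoryElement],
    config: PipelineConfig,
    groups: Optional[CellAnnotation] = None,
) -> tuple[NormalizedAccessibility, np.ndarray]:
    """Normalize an element matrix with the threshold riding along.

    The raw threshold vector is appended as a pseudo-element row (no GC
    annotation), the stack is smooth-quantile- and GC-normalized per the
    config, and the transformed threshold is split back off. Returns the
    normalized element matrix and the normalized per-cell threshold.

    A cell with zero observed blacklist coverage must still never call a
    zero-count element open, so the pseudo-element entry is floored at a tiny
    positive value: through rank-based transforms the threshold then sits
    strictly above exact-zero counts.
    """
    theta_raw = np.asarray(theta_raw, dtype=float)
    if theta_raw.shape != (len(matrix.cells),):
        raise ValueError("threshold vector length does not match cells")
    theta_entry = np.maximum(theta_raw, 1e-9)
    values = np.vstack([matrix.to_dense().astype(float), theta_entry[None, :]])
    stacked = NormalizedAccessibility(
        elements=list(matrix.elements) + [THRESHOLD_PSEUDO_ID],
        cells=list(matrix.cells),
        values=values,
    )
    if not config.skip_qsmooth:
        stacked = smooth_quantile_normalize(stacked, groups)
    if not config.skip_gc_norm:
        pseudo = RegulatoryElement(
            id=THRESHOLD_PSEUDO_ID,
            interval=elements[0].interval if elements else None,
            kind="enhancer",
            gene_ids=[],
            gc_fraction=None,
        )
        stacked = gc_normalize(
            stacked, list(elements) + [pseudo], gc_bins=config.gc_bins
        )
    out = NormalizedAccessibility(
        elements=stacked.elements[:-1],
        cells=stacked.cells,
        values=stacked.values[:-1],
    )
    theta_norm = stacked.values[-1].copy()
    return out, theta_norm


def call_open(value, theta) -> np.ndarray:
    """Open iff the normalized value strictly exceeds the threshold."""
    return np.asarray(value) > np.asarray(theta)


def gene_accessibility(
    matrix: NormalizedAccessibility,
    theta: np.ndarray,
    elements: Sequence[RegulatoryElement],
    genes: Sequence[str],
    agg: str = "max",
) -> GeneAccessibilityMatrix:
    """Aggregate element accessibility gaps to genes.

    Each element contributes its value minus the cell threshold; a gene takes
    the max over its promoter and linked enhancers (``agg="sum"`` is the
    logged alternative), so ``gap > 0`` iff any element is open. Genes without
    any element get a gap of ``-theta`` (value 0), with a warning.
    """
    if agg not in ("max", "sum"):
        raise ValueError(f"unknown gene aggregation {agg!r}")
    theta = np.asarray(theta, dtype=float)
    gene_index = {g: i for i, g in enumerate(genes)}
    excess = matrix.values - theta[None, :]

    n_cells = len(matrix.cells)
    if agg == "max":
        gaps = np.full((len(genes), n_cells), -np.inf)
    else:
        gaps = np.zeros((len(genes), n_cells))
    covered = np.zeros(len(genes), dtype=bool)
    for row, elem in enumerate(elements):
        if not elem.linked:
            continue
        for g in elem.gene_ids:
            gi = gene_index.get(g)
            if gi is None:
                continue
            covered[gi] = True
            if agg == "max":
                np.maximum(gaps[gi], excess[row], out=gaps[gi])
            else:
                gaps[gi] += excess[row]
    if not covered.all():
        logger.warning(
            "%d genes have no regulatory element; their accessibility is 0",
            int((~covered).sum()),
        )
        gaps[~covered] = -theta[None, :]
    return GeneAccessibilityMatrix(genes=list(genes), cells=list(matrix.cells), gaps=gaps)


def auto_sigmoid_k(gaps: np.ndarray) -> float:
    """Steepness calibrated to the data: 4 / median positive gap.

    Puts the median open entry at an activity of ~0.98 regardless of
    sequencing depth. Falls back to 1.0 when nothing is open.
    """
    pos = gaps[np.isfinite(gaps) & (gaps > 0)]
    if pos.size == 0:
        logger.warning("no open entries; sigmoid steepness defaults to 1.0")
        return 1.0
    return 4.0 / float(np.median(pos))


def sigmoid_activity(
    gene_value, theta, sigmoid_k: float
) -> np.ndarray:
    """Probability of expression: ``sigmoid(k * (value - threshold))``.

    Monotone increasing in the gene value, decreasing in the threshold;
    strictly above 0.5 exactly when the hard open call fires. Outputs are
    clipped infinitesimally inside (0, 1).
    """
    if sigmoid_k <= 0:
        raise ValueError("sigmoid_k must be > 0")
    gap = np.asarray(gene_value, dtype=float) - np.asarray(theta, dtype=float)
    act = expit(sigmoid_k * gap)
    return np.clip(act, _ACTIVITY_EPS, 1.0 - _ACTIVITY_EPS)


def gene_activity(
    accessibility: GeneAccessibilityMatrix, config: PipelineConfig
) -> GeneActivityMatrix:
    """Sigmoid-transform accessibility gaps into a gene activity matrix."""
    gaps = accessibility.gaps
    k = config.sigmoid_k if config.sigmoid_k is not None else auto_sigmoid_k(gaps)
    finite_gaps = np.where(np.isfinite(gaps), gaps, -np.inf)
    values = sigmoid_activity(finite_gaps, 0.0, k)
    return GeneActivityMatrix(
        genes=accessibility.genes,
        cells=accessibility.cells,
        values=values,
        sigmoid_k=k,
    )
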