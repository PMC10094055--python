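"""End-to-end orchestration: fragments -> gene activity -> imputed counts.

Promoter and enhancer count matrices are built and normalized separately
(each with the threshold vector riding along as a pseudo-element), converted
to accessibility gaps over the per-cell threshold, aggregated to genes by
max, merged across element classes, sigmoid-transformed into activities,
median-aggregated per cell type and added to the expression counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .accessibility import (
    GeneAccessibilityMatrix,
    GeneActivityMatrix,
    build_threshold_vector,
    gene_activity,
    gene_accessibility,
    normalize_with_threshold,
)
from .atac_signal import (
    ElementCountMatrix,
    PipelineConfig,
    blacklist_coverage,
    count_fragments,
)
from .formats_io import (
    CellAnnotation,
    ExpressionMatrix,
    GenomicInterval,
    RegulatoryElement,
)
from .imputation import aggregate_population_activity, impute

logger = logging.getLogger("epi_impute")


@dataclass
class PipelineResult:
    imputed: ExpressionMatrix
    accessibility: GeneAccessibilityMatrix
    activity: GeneActivityMatrix
    pop_activity: pd.DataFrame
    theta: dict                       # element class -> normalized threshold
    element_counts: dict              # element class -> ElementCountMatrix
    sigmoid_k: float
    stats: dict = field(default_factory=dict)


def _class_gaps(
    fragments,
    elements: Sequence[RegulatoryElement],
    theta_raw: np.ndarray,
    genes: Sequence[str],
    config: PipelineConfig,
    annotation: CellAnnotation,
):
    """Count, normalize and gene-aggregate one element class."""
    counts = count_fragments(fragments, elements, config, annotation=annotation)
    normed, theta_norm = normalize_with_threshold(
        counts, theta_raw, elements, config, groups=annotation
    )
    acc = gene_accessibility(normed, theta_norm, elements, genes, agg=config.gene_agg)
    return counts, theta_norm, acc


def run_pipeline(
    expression: ExpressionMatrix,
    fragments,
    elements: Sequence[RegulatoryElement],
    blacklist: Sequence[GenomicInterval],
    rna_annotation: CellAnnotation,
    atac_annotation: CellAnnotation,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full imputation pipeline on in-memory inputs.

    ``fragments`` may be a Fragment iterable or the DataFrame layout from
    :func:`epi_impute.formats_io.read_fragments_table`.
    """
    config = config or PipelineConfig()
    if not isinstance(fragments, pd.DataFrame):
        from .formats_io import fragments_to_table

        fragments = fragments_to_table(fragments)  # a stream is consumed once
    promoters = [e for e in elements if e.kind == "promoter"]
    enhancers = [e for e in elements if e.kind == "enhancer" and e.linked]
    n_unlinked = sum(1 for e in elements if e.kind == "enhancer" and not e.linked)
    if n_unlinked:
        logger.info("%d unlinked enhancers excluded from gene aggregation", n_unlinked)
    if not promoters and not enhancers:
        raise ValueError("no usable regulatory elements")

    # per-cell noise level from blacklist coverage, on the raw count scale
    per_bp = blacklist_coverage(
        fragments, blacklist, config, annotation=atac_annotation
    )
    theta_raw = build_threshold_vector(per_bp.to_numpy(), config)

    genes = sorted({g for e in elements for g in e.gene_ids})
    gaps = None
    thetas: dict[str, np.ndarray] = {}
    counts: dict[str, ElementCountMatrix] = {}
    cells = None
    for name, els in (("promoter", promoters), ("enhancer", enhancers)):
        if not els:
            continue
        cnt, theta_norm, acc = _class_gaps(
            fragments, els, theta_raw, genes, config, atac_annotation
        )
        counts[name] = cnt
        thetas[name] = theta_norm
        cells = acc.cells
        gaps = acc.gaps if gaps is None else np.maximum(gaps, acc.gaps)

    accessibility = GeneAccessibilityMatrix(genes=genes, cells=cells, gaps=gaps)
    activity = gene_activity(accessibility, config)
    pop = aggregate_population_activity(
        activity, atac_annotation, binarize=config.binarize_before_median
    )
    imputed = impute(
        expression, pop, rna_annotation, scale_activity=config.scale_activity
    )
    stats = {
        "n_promoters": len(promoters),
        "n_enhancers": len(enhancers),
        "n_unlinked_enhancers": n_unlinked,
        "n_genes_atac": len(genes),
        "n_atac_cells": len(activity.cells),
    }
    return PipelineResult(
        imputed=imputed,
        accessibility=accessibility,
        activity=activity,
        pop_activity=pop,
        theta=thetas,
        element_counts=counts,
        sigmoid_k=activity.sigmoid_k,
        stats=stats,
    )
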