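"""The imputation core: per-population gene activity added to raw counts.

Gene activity is aggregated over the ATAC cells of each cell type by the
median. By default the per-cell activities are first binarized at 0.5 (i.e.
at the hard open call), so the population value for a gene closed across a
population is exactly 0 and closed genes are never touched by imputation;
the continuous-median alternative is available via ``binarize=False``.

The additive term is the activity probability itself on its [0, 1] scale —
nothing is rescaled to the count distribution and nothing is ever
subtracted, so raw expression patterns within a cell type are preserved by
construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .accessibility import GeneActivityMatrix
from .formats_io import CellAnnotation, ExpressionMatrix

logger = logging.getLogger("epi_impute")


def aggregate_population_activity(
    activity: GeneActivityMatrix,
    atac_annotation: CellAnnotation,
    binarize: bool = True,
) -> pd.DataFrame:
    """Median gene activity per cell type (genes x labels DataFrame).

    With ``binarize=True`` (default) each cell's activity is first turned
    into its open call (activity > 0.5 -> 1.0, else 0.0) and the median is
    taken over the calls; with ``binarize=False`` the median is over the raw
    probabilities. Median of an even number of cells is the mean of the two
    middle values. Labels with no cells are dropped with a warning.
    """
    missing = [c for c in activity.cells if c not in atac_annotation]
    if missing:
        raise ValueError(
            f"{len(missing)} ATAC cells lack an annotation (first: {missing[0]!r})"
        )
    values = activity.values
    if binarize:
        values = (values > 0.5).astype(float)
    labels = pd.Series(
        [atac_annotation[c] for c in activity.cells], index=activity.cells
    )
    cols = {}
    for label in pd.unique(labels):
        mask = (labels == label).to_numpy()
        if not mask.any():
            logger.warning("cell type %r has no cells; dropped", label)
            continue
        cols[label] = np.median(values[:, mask], axis=1)
    return pd.DataFrame(cols, index=activity.genes)


def impute(
    expression: ExpressionMatrix,
    pop_activity: pd.DataFrame,
    rna_annotation: CellAnnotation,
    scale_activity: float = 1.0,
) -> ExpressionMatrix:
    """Add the population activity of each gene to every matching RNA cell.

    ``imputed(g, c) = raw(g, c) + scale * pop_activity(g, type(c))``. Genes
    absent from the activity table and cells whose label has no ATAC
    population pass through unchanged (counted and logged). The output is
    fractional; values are never decreased.
    """
    overlap = [g for g in expression.genes if g in pop_activity.index]
    if len(overlap) == 0:
        raise ValueError("no overlapping genes between expression and activity")
    n_gene_miss = len(expression.genes) - len(overlap)
    if n_gene_miss:
        logger.warning("%d expression genes have no activity entry", n_gene_miss)

    labels = []
    n_cell_miss = 0
    for c in expression.cells:
        lab = rna_annotation.get(c)
        if lab is None or lab not in pop_activity.columns:
            labels.append(None)
            n_cell_miss += 1
        else:
            labels.append(lab)
    if n_cell_miss:
        logger.warning(
            "%d RNA cells have no matching ATAC population; passed through",
            n_cell_miss,
        )

    add = np.zeros(expression.shape)
    act = pop_activity.reindex(expression.genes).fillna(0.0)
    for j, lab in enumerate(labels):
        if lab is not None:
            add[:, j] = act[lab].to_numpy()
    imputed = expression.to_dense().astype(float) + scale_activity * add
    return ExpressionMatrix(
        genes=list(expression.genes),
        cells=list(expression.cells),
        counts=sp.csr_matrix(imputed),
    )
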