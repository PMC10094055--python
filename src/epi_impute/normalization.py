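"""Accessibility normalization across cells and GC content.

Two transforms make raw element counts comparable across cells:

* :func:`smooth_quantile_normalize` — quantile normalization whose per-rank
  reference blends a cell-group-specific quantile with the global quantile,
  weighted by the fraction of that rank's across-cell variance explained by
  the groups. When groups are indistinguishable this collapses to classical
  quantile normalization; when groups differ strongly their distributions are
  preserved.
* :func:`gc_normalize` — a binned conditional correction: elements are split
  into equal-frequency GC bins and each bin is rescaled per cell so its mean
  matches the cell's global mean. This removes first-order GC bias while
  staying monotone within each bin.

Both operate on dense elements x cells arrays wrapped in
:class:`NormalizedAccessibility` and are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import CellAnnotation, RegulatoryElement
from .atac_signal import ElementCountMatrix

logger = logging.getLogger("epi_impute")


@dataclass
class NormalizedAccessibility:
    """Elements x cells accessibility values on a normalized scale."""

    elements: list[str]
    cells: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.elements), len(self.cells)):
            raise ValueError("values shape does not match id lists")
        if np.any(self.values < 0):
            raise ValueError("normalized accessibility must be non-negative")


def _as_values(matrix) -> tuple[list[str], list[str], np.ndarray]:
    if isinstance(matrix, ElementCountMatrix):
        return matrix.elements, matrix.cells, matrix.to_dense().astype(float)
    if isinstance(matrix, NormalizedAccessibility):
        return matrix.elements, matrix.cells, matrix.values.astype(float)
    raise TypeError(f"unsupported matrix type {type(matrix)!r}")


def smooth_quantile_normalize(
    matrix, groups: Optional[CellAnnotation] = None
) -> NormalizedAccessibility:
    """Quantile-normalize cells with a group-aware blended reference.

    For rank q the reference for group g is
    ``w(q) * Q_g(q) + (1 - w(q)) * Q(q)`` where ``Q_g`` / ``Q`` are the
    group/global mean sorted values and ``w(q)`` is the between-group share
    of the across-cell variance at that rank, clamped to [0, 1]. Each cell's
    values are replaced by its group reference at the cell's ranks, tied
    values receiving the mean reference over the tied rank positions.

    With a single group (or ``groups=None``) this is classical quantile
    normalization. Groups of one cell fall back to the global reference.
    """
    elements, cells, values = _as_values(matrix)
    n_el, n_cells = values.shape
    if n_cells < 2:
        raise ValueError("smooth quantile normalization needs >= 2 cells")
    if groups is None:
        labels = np.zeros(n_cells, dtype=int)
        label_names = ["_all"]
    else:
        missing = [c for c in cells if c not in groups]
        if missing:
            raise ValueError(
                f"{len(missing)} cells missing a group label (first: {missing[0]!r})"
            )
        label_names = sorted({groups[c] for c in cells})
        lab_idx = {l: i for i, l in enumerate(label_names)}
        labels = np.array([lab_idx[groups[c]] for c in cells])

    order = np.argsort(values, axis=0, kind="stable")
    Q = np.take_along_axis(values, order, axis=0)  # sorted per cell

    global_ref = Q.mean(axis=1)
    n_groups = len(label_names)
    group_ref = np.empty((n_el, n_groups))
    group_sizes = np.empty(n_groups)
    for gi in range(n_groups):
        mask = labels == gi
        group_sizes[gi] = mask.sum()
        group_ref[:, gi] = Q[:, mask].mean(axis=1)

    # variance decomposition per rank across cells
    sst = ((Q - global_ref[:, None]) ** 2).sum(axis=1)
    ssb = (group_sizes[None, :] * (group_ref - global_ref[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sst > 0, ssb / sst, 0.0)
    w = np.clip(w, 0.0, 1.0)

    blended = w[:, None] * group_ref + (1.0 - w[:, None]) * global_ref[:, None]
    singletons = group_sizes == 1
    if singletons.any():
        logger.warning(
            "%d group(s) with a single cell use the global reference",
            int(singletons.sum()),
        )
        blended[:, singletons] = global_ref[:, None]

    out = np.empty_like(values)
    for ci in range(n_cells):
        ref = blended[:, labels[ci]]
        col_sorted = Q[:, ci]
        # average the reference over runs of tied values
        boundaries = np.flatnonzero(np.diff(col_sorted)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_el]))
        csum = np.concatenate(([0.0], np.cumsum(ref)))
        run_means = (csum[ends] - csum[starts]) / (ends - starts)
        assigned = np.repeat(run_means, ends - starts)
        out[order[:, ci], ci] = assigned
    return NormalizedAccessibility(elements=list(elements), cells=list(cells), values=out)


def _gc_bin_assignments(
    gc: np.ndarray, n_bins: int, min_per_bin: int = 5
) -> np.ndarray:
    """Equal-frequency GC bins; missing GC (NaN) goes to a catch-all bin.

    Bins with fewer than ``min_per_bin`` elements are merged with the nearest
    neighbouring bin. Returns an integer bin id per element (catch-all = -1
    remapped to its own id at the end).
    """
    present = ~np.isnan(gc)
    n_present = int(present.sum())
    bins = np.full(gc.shape[0], -1, dtype=int)
    if n_present:
        n_eff = max(1, min(n_bins, n_present // max(min_per_bin, 1)))
        # bin on GC value quantiles; tied GC values always share a bin
        labels = np.asarray(
            pd.qcut(gc[present], q=n_eff, labels=False, duplicates="drop"),
            dtype=float,
        )
        labels[np.isnan(labels)] = 0  # all GC identical -> one bin
        bins[present] = labels.astype(int)
        # merge undersized bins with the nearest bin below (or above for bin 0)
        while True:
            ids, counts = np.unique(bins[present], return_counts=True)
            small = ids[(counts < min_per_bin)]
            if len(small) == 0 or len(ids) == 1:
                break
            b = small[0]
            pos = np.where(ids == b)[0][0]
            target = ids[pos - 1] if pos > 0 else ids[pos + 1]
            bins[bins == b] = target
    return bins


def gc_normalize(
    matrix,
    elements: Sequence[RegulatoryElement],
    gc_bins: int = 10,
) -> NormalizedAccessibility:
    """Binned GC-content correction of a normalized accessibility matrix.

    Elements are binned into ``gc_bins`` equal-frequency bins of GC fraction
    (bins with < 5 elements are merged with the nearest bin). Within each bin,
    values are rescaled per cell so the bin's mean equals the cell's mean over
    GC-annotated elements; ranks within a bin are preserved per cell. Elements
    with missing GC cannot be corrected and pass through unscaled. Identity
    (with a warning) when all GC is missing.
    """
    el_ids, cells, values = _as_values(matrix)
    if len(elements) != len(el_ids):
        raise ValueError("element annotation does not match matrix rows")
    gc = np.array(
        [np.nan if e.gc_fraction is None else float(e.gc_fraction) for e in elements]
    )
    if np.isnan(gc).all():
        logger.warning("all GC fractions missing; GC normalization is the identity")
        return NormalizedAccessibility(list(el_ids), list(cells), values.copy())
    n_missing = int(np.isnan(gc).sum())
    if n_missing > 0.1 * len(gc):
        logger.warning(
            "%d/%d elements missing GC fraction; they form a catch-all bin",
            n_missing, len(gc),
        )
    bins = _gc_bin_assignments(gc, gc_bins)

    out = values.copy()
    # the correction target is the per-cell mean over GC-annotated elements;
    # elements without GC cannot be corrected and pass through unscaled
    annotated = bins >= 0
    global_mean = values[annotated].mean(axis=0)  # per cell
    for b in np.unique(bins[annotated]):
        rows = bins == b
        bin_mean = values[rows].mean(axis=0)
        factor = np.where(bin_mean > 0, global_mean / np.where(bin_mean > 0, bin_mean, 1.0), 1.0)
        out[rows] = values[rows] * factor[None, :]
    return NormalizedAccessibility(list(el_ids), list(cells), out)
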