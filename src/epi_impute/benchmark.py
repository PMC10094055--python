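"""Evaluation protocols for imputation quality.

Four protocols are implemented, all scored against simulated dropouts with a
known pre-dropout ground truth:

* marker test — TPR/FPR from cell-type surface markers: positive-marker
  entries that are truly expressed must be non-zero after imputation; zero
  entries of negative markers must stay zero.
* bulk test — the same rates with classes derived from a per-type (pseudo-)
  bulk profile: top-fraction genes positive, zero-bulk genes negative.
* stratified imputation error — 1 - F1 of dropout recovery, within strata of
  the true expression value of the masked entries.
* correlation preservation — Pearson correlation of designated gene pairs in
  each matrix against an external reference correlation.

An entry counts as expressed after imputation iff it is strictly positive
(tolerance exactly 0): under the additive design any positive added activity
is an expression call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import CellAnnotation, ExpressionMatrix
from .synthetic_data import DropoutMask

logger = logging.getLogger("epi_impute")


@dataclass
class RateResult:
    """Pooled and per-type TPR/FPR; a rate is None when its class is empty."""

    tpr: Optional[float]
    fpr: Optional[float]
    per_type: pd.DataFrame  # columns: tpr, fpr, tp, fn, fp, tn


def _rate(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def marker_test(
    imputed: ExpressionMatrix,
    truth: ExpressionMatrix,
    markers: dict,
    annotation: CellAnnotation,
) -> RateResult:
    """Marker-based TPR/FPR of an imputed matrix.

    ``markers`` maps cell-type label -> ``{"positive": [...], "negative":
    [...]}``. Over entries (g, c) with g a positive marker for type(c) and
    ground truth non-zero: TP if imputed non-zero, FN otherwise. Over entries
    with g a negative marker for type(c) and ground truth zero: FP if imputed
    non-zero, TN otherwise. Ground truth should be the pre-dropout matrix
    when available, else the raw matrix. Markers absent from the matrix are
    logged and skipped; empty classes yield None, never 0-by-convention.
    """
    if imputed.genes != truth.genes or imputed.cells != truth.cells:
        raise ValueError("imputed and ground-truth matrices are not aligned")
    imp = imputed.to_dense()
    tru = truth.to_dense()
    gene_row = {g: i for i, g in enumerate(imputed.genes)}
    labels = np.array([annotation[c] for c in imputed.cells])

    rows = []
    totals = dict(tp=0, fn=0, fp=0, tn=0)
    for label, sets in markers.items():
        cell_mask = labels == label
        if not cell_mask.any():
            continue
        pos = [g for g in sets["positive"] if g in gene_row]
        neg = [g for g in sets["negative"] if g in gene_row]
        skipped = (len(sets["positive"]) - len(pos)) + (len(sets["negative"]) - len(neg))
        if skipped:
            logger.warning("%d markers of %r absent from the matrix, skipped", skipped, label)
        pr = [gene_row[g] for g in pos]
        nr = [gene_row[g] for g in neg]
        imp_p, tru_p = imp[np.ix_(pr, cell_mask)], tru[np.ix_(pr, cell_mask)]
        imp_n, tru_n = imp[np.ix_(nr, cell_mask)], tru[np.ix_(nr, cell_mask)]
        tp = int(((tru_p > 0) & (imp_p > 0)).sum())
        fn = int(((tru_p > 0) & (imp_p <= 0)).sum())
        fp = int(((tru_n == 0) & (imp_n > 0)).sum())
        tn = int(((tru_n == 0) & (imp_n <= 0)).sum())
        rows.append(
            dict(label=label, tpr=_rate(tp, tp + fn), fpr=_rate(fp, fp + tn),
                 tp=tp, fn=fn, fp=fp, tn=tn)
        )
        for k, v in zip(("tp", "fn", "fp", "tn"), (tp, fn, fp, tn)):
            totals[k] += v
    per_type = pd.DataFrame(rows).set_index("label") if rows else pd.DataFrame()
    return RateResult(
        tpr=_rate(totals["tp"], totals["tp"] + totals["fn"]),
        fpr=_rate(totals["fp"], totals["fp"] + totals["tn"]),
        per_type=per_type,
    )


def bulk_test(
    imputed: ExpressionMatrix,
    truth: ExpressionMatrix,
    bulk_profile: pd.DataFrame,
    annotation: CellAnnotation,
    top_fraction: float = 0.10,
) -> RateResult:
    """TPR/FPR with classes derived from a per-type bulk expression profile.

    Positive class per type: the top ``top_fraction`` genes by bulk value;
    negative class: genes with bulk value 0. Rates are then computed exactly
    as in :func:`marker_test` over all cells of the type.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    markers = {}
    n_top = max(1, int(round(top_fraction * len(bulk_profile))))
    for label in bulk_profile.columns:
        col = bulk_profile[label]
        top = col.sort_values(ascending=False, kind="stable").index[:n_top]
        markers[label] = {
            "positive": list(top),
            "negative": list(col.index[col == 0]),
        }
    return bulk_test_from_markers(imputed, truth, markers, annotation)


def bulk_test_from_markers(imputed, truth, markers, annotation) -> RateResult:
    return marker_test(imputed, truth, markers, annotation)


def stratified_error(
    imputed: ExpressionMatrix,
    truth: ExpressionMatrix,
    mask: DropoutMask,
    strata: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Imputation error (1 - F1) of dropout recovery by expression stratum.

    Every evaluated entry is assigned an expression level: masked entries
    carry their true (pre-dropout) value, and true-zero entries — the source
    of false positives — carry their gene's mean true expression (a zero has
    no entry-level value of its own), clamped into the outer strata. Recall
    per stratum is the fraction of its masked entries recovered (non-zero
    after imputation); precision is TP / (TP + FP) with FP the imputed
    non-zero true-zero entries assigned to the stratum. Default strata are
    the quartiles of the masked true values; a pooled "overall" row over all
    masked entries and all true zeros is appended. Empty strata report NaN.
    """
    if len(mask) == 0:
        raise ValueError("dropout mask is empty")
    imp = imputed.to_dense()
    tru = truth.to_dense()
    masked_vals = np.asarray(mask.values, dtype=float)
    if strata is None:
        qs = np.quantile(masked_vals, [0.25, 0.5, 0.75])
        bounds = np.concatenate(([masked_vals.min()], qs, [masked_vals.max()]))
        bounds = np.unique(bounds)
    else:
        bounds = np.asarray(strata, dtype=float)
    if len(bounds) < 2:
        bounds = np.array([masked_vals.min(), masked_vals.max()])

    recovered = imp[mask.gene_idx, mask.cell_idx] > 0
    # false positives: entries that are zero in truth but non-zero imputed,
    # located on the expression scale by their gene's mean true expression
    fp_gene, _ = np.nonzero((tru == 0) & (imp > 0))
    gene_mean = tru.mean(axis=1)
    fp_levels = gene_mean[fp_gene]
    fp_total = len(fp_gene)

    rows = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        last = i == len(bounds) - 2
        if last:
            sel = (masked_vals >= lo) & (masked_vals <= hi)
            fp_sel = fp_levels >= lo  # clamp high levels into the top stratum
        else:
            sel = (masked_vals >= lo) & (masked_vals < hi)
            fp_sel = (fp_levels >= lo) & (fp_levels < hi)
        if i == 0:
            fp_sel = fp_sel | (fp_levels < lo)  # clamp low levels into the bottom
        n_masked = int(sel.sum())
        if n_masked == 0:
            rows.append(dict(lo=lo, hi=hi, n_masked=0, recall=np.nan,
                             precision=np.nan, error=np.nan))
            continue
        tp = int(recovered[sel].sum())
        fp = int(fp_sel.sum())
        recall = tp / n_masked
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0 else 0.0
        )
        rows.append(dict(lo=lo, hi=hi, n_masked=n_masked,
                         recall=recall, precision=precision, error=1.0 - f1))
    tp_all = int(recovered.sum())
    recall_all = tp_all / len(mask)
    precision_all = tp_all / (tp_all + fp_total) if (tp_all + fp_total) else np.nan
    f1_all = (
        2 * precision_all * recall_all / (precision_all + recall_all)
        if (precision_all + recall_all) > 0 else 0.0
    )
    rows.append(dict(lo=masked_vals.min(), hi=masked_vals.max(),
                     n_masked=len(mask), recall=recall_all,
                     precision=precision_all, error=1.0 - f1_all))
    out = pd.DataFrame(rows)
    out.index = [f"stratum_{i}" for i in range(len(rows) - 1)] + ["overall"]
    return out


def correlation_preservation(
    matrices: dict[str, ExpressionMatrix],
    gene_pairs: Sequence[tuple[str, str]],
    reference_r: dict[tuple[str, str], float],
    pair_filter: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of gene pairs per matrix vs a reference.

    By default r is computed over all cells; with ``pair_filter=True`` only
    cells with at least one non-zero value in the pair are used. Pairs with a
    zero-variance gene report NaN. The preservation score is
    ``|r - reference_r|`` (lower is better).
    """
    rows = []
    for g1, g2 in gene_pairs:
        ref = reference_r.get((g1, g2), reference_r.get((g2, g1)))
        for name, mat in matrices.items():
            if g1 not in mat.genes or g2 not in mat.genes:
                logger.warning("pair (%s, %s) absent from matrix %r", g1, g2, name)
                continue
            x = mat.to_dense()[mat.genes.index(g1)].astype(float)
            y = mat.to_dense()[mat.genes.index(g2)].astype(float)
            if pair_filter:
                keep = (x != 0) | (y != 0)
                x, y = x[keep], y[keep]
            if len(x) < 3 or x.std() == 0 or y.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append(dict(gene_a=g1, gene_b=g2, matrix=name, r=r,
                             reference_r=ref,
                             abs_diff=abs(r - ref) if ref is not None and np.isfinite(r) else np.nan))
    return pd.DataFrame(rows)
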