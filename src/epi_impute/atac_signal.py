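"""From ATAC fragments to an elements x cells count matrix.

Read-processing rules applied here: fragments are Tn5-corrected (+4 bp on the
Watson-strand end, -5 bp on the Crick-strand end, unless the file is already
shifted), MAPQ-filtered (strictly > 30 when a MAPQ column is present), and
counted into strand-aware promoter windows (-500/+200 bp around the TSS) and
enhancer windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pyranges as pr
import scipy.sparse as sp

from .formats_io import (
    CellAnnotation,
    Fragment,
    GenomicInterval,
    RegulatoryElement,
    fragments_to_table,
)

logger = logging.getLogger("epi_impute")


@dataclass
class PipelineConfig:
    """Tunable constants of the pipeline.

    Defaults encode the method's printed constants: a -500/+200 bp promoter
    window, MAPQ strictly greater than 30, and Tn5 offsets of +4/-5 bp.
    """

    flank_up: int = 500
    flank_down: int = 200
    mapq_min: int = 30          # strict: kept iff mapq > mapq_min
    tn5_plus_offset: int = 4
    tn5_minus_offset: int = -5
    sigmoid_k: Optional[float] = None   # None -> auto-calibrated
    gc_bins: int = 10
    lhs_strata: int = 10
    seed: int = 0
    count_mode: str = "overlap"         # "overlap" | "insertion"
    fragments_shifted: bool = False
    fifth_column: str = "count"         # "count" | "mapq"
    gene_agg: str = "max"               # "max" | "sum"
    binarize_before_median: bool = True
    skip_qsmooth: bool = False
    skip_gc_norm: bool = False
    scale_activity: float = 1.0

    def __post_init__(self) -> None:
        if self.flank_up < 0 or self.flank_down < 0:
            raise ValueError("flanks must be >= 0")
        if self.count_mode not in ("overlap", "insertion"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        if self.gene_agg not in ("max", "sum"):
            raise ValueError(f"unknown gene_agg {self.gene_agg!r}")
        if self.sigmoid_k is not None and self.sigmoid_k <= 0:
            raise ValueError("sigmoid_k must be > 0")

    @property
    def window_length(self) -> int:
        return self.flank_up + self.flank_down

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ElementCountMatrix:
    """Elements x cells raw fragment counts."""

    elements: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.elements), len(self.cells)):
            raise ValueError("count matrix shape does not match id lists")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative fragment count")

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


# ---------------------------------------------------------------------------
# Tn5 correction
# ---------------------------------------------------------------------------


def tn5_shift(fragment: Fragment, config: PipelineConfig) -> Optional[Fragment]:
    """Apply the Tn5 dimer correction to one fragment.

    The fragment start is the Watson-strand insertion (shifted by +4 bp) and
    the end the Crick-strand insertion (shifted by -5 bp). Returns ``None``
    (drop, with a warning) when the corrected interval collapses.
    """
    start = fragment.interval.start + config.tn5_plus_offset
    end = fragment.interval.end + config.tn5_minus_offset
    if start >= end:
        logger.warning(
            "dropping fragment %s:%d-%d (%s): collapsed by Tn5 correction",
            fragment.interval.chrom, fragment.interval.start,
            fragment.interval.end, fragment.barcode,
        )
        return None
    return Fragment(
        interval=GenomicInterval(fragment.interval.chrom, start, end),
        barcode=fragment.barcode,
        mapq=fragment.mapq,
        count=fragment.count,
    )


def tn5_shift_table(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Vectorised Tn5 correction of a fragments table.

    Already-shifted tables (``df.attrs['shifted']``) pass through unchanged.
    Collapsed fragments are dropped with a warning.
    """
    if df.attrs.get("shifted", False):
        return df
    out = df.copy()
    out["start"] = out["start"] + config.tn5_plus_offset
    out["end"] = out["end"] + config.tn5_minus_offset
    bad = out["start"] >= out["end"]
    if bad.any():
        logger.warning("dropped %d fragments collapsed by Tn5 correction", int(bad.sum()))
        out = out[~bad].reset_index(drop=True)
    out.attrs["shifted"] = True
    out.attrs["malformed"] = df.attrs.get("malformed", 0)
    return out


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def promoter_window(tss_record: RegulatoryElement, config: PipelineConfig) -> GenomicInterval:
    """Strand-aware -flank_up/+flank_down window around a TSS, clamped at 0.

    The TSS of a "+" record is its ``start``; of a "-" record ``end - 1``.
    """
    strand = tss_record.interval.strand
    if strand == "+":
        tss = tss_record.interval.start
        start = tss - config.flank_up
        end = tss + config.flank_down
    elif strand == "-":
        tss = tss_record.interval.end - 1
        start = tss - config.flank_down + 1
        end = tss + config.flank_up + 1
    else:
        raise ValueError(
            f"promoter record {tss_record.id!r} has strand '.'; "
            "the window is strand-dependent"
        )
    return GenomicInterval(tss_record.interval.chrom, max(0, start), end)


def enhancer_window(element: RegulatoryElement, config: PipelineConfig) -> GenomicInterval:
    """Window of an enhancer: the annotated interval itself when it is at
    least ``flank_up + flank_down`` bp long, else the same-size window centred
    on its midpoint (enhancers have no strand, so the flanks are laid out
    upstream-up/downstream-down of the midpoint)."""
    iv = element.interval
    if len(iv) >= config.window_length:
        return iv
    mid = (iv.start + iv.end) // 2
    return GenomicInterval(iv.chrom, max(0, mid - config.flank_up), mid + config.flank_down)


def materialize_windows(
    elements: Sequence[RegulatoryElement], config: PipelineConfig
) -> list[GenomicInterval]:
    """Counting window for each element, promoter or enhancer."""
    out = []
    for e in elements:
        if e.kind == "promoter":
            out.append(promoter_window(e, config))
        else:
            out.append(enhancer_window(e, config))
    return out


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def _as_table(fragments: Union[pd.DataFrame, Iterable[Fragment]]) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        return fragments
    return fragments_to_table(fragments)


def _prepare_fragments(
    fragments, config: PipelineConfig, annotation: Optional[CellAnnotation]
) -> tuple[pd.DataFrame, dict]:
    """Shift, MAPQ-filter and annotation-filter a fragments table."""
    df = _as_table(fragments)
    stats = {"input": len(df), "mapq_failed": 0, "unannotated": 0}
    df = tn5_shift_table(df, config)
    if "mapq" in df.columns:
        keep = df["mapq"].fillna(config.mapq_min + 1) > config.mapq_min
        stats["mapq_failed"] = int((~keep).sum())
        df = df[keep]
    elif config.fifth_column == "count":
        logger.info("fragments carry duplicate counts, MAPQ filter skipped")
    if annotation is not None:
        keep = df["barcode"].isin(set(annotation.barcodes))
        stats["unannotated"] = int((~keep).sum())
        if stats["unannotated"]:
            logger.warning(
                "dropped %d fragments from barcodes absent from the ATAC annotation",
                stats["unannotated"],
            )
        df = df[keep]
    return df.reset_index(drop=True), stats


def count_fragments(
    fragments: Union[pd.DataFrame, Iterable[Fragment]],
    elements: Sequence[RegulatoryElement],
    config: PipelineConfig,
    annotation: Optional[CellAnnotation] = None,
    windows: Optional[Sequence[GenomicInterval]] = None,
) -> ElementCountMatrix:
    """Count Tn5-corrected fragments into element windows.

    In ``overlap`` mode a fragment contributes its duplicate count to every
    window its corrected interval overlaps by >= 1 bp; in ``insertion`` mode
    each of its two insertion sites (corrected start and end - 1) is counted
    separately. Barcodes absent from the ATAC annotation are dropped and
    tallied. Cells are ordered by the annotation when given, else by sorted
    barcode.
    """
    if len(elements) == 0:
        raise ValueError("no regulatory elements to count into")
    df, stats = _prepare_fragments(fragments, config, annotation)
    if len(df) == 0:
        raise ValueError(
            f"no fragments retained (input={stats['input']}, "
            f"mapq_failed={stats['mapq_failed']}, unannotated={stats['unannotated']})"
        )
    if windows is None:
        windows = materialize_windows(elements, config)

    cells = annotation.barcodes if annotation is not None else sorted(df["barcode"].unique())
    cell_index = {c: i for i, c in enumerate(cells)}

    win_df = pd.DataFrame(
        {
            "Chromosome": [w.chrom for w in windows],
            "Start": [w.start for w in windows],
            "End": [w.end for w in windows],
            "elem_idx": np.arange(len(windows)),
        }
    )
    frag = pd.DataFrame(
        {
            "Chromosome": df["chrom"].to_numpy(),
            "Start": df["start"].to_numpy(),
            "End": df["end"].to_numpy(),
            "cell_idx": df["barcode"].map(cell_index).to_numpy(),
            "weight": df["count"].to_numpy() if "count" in df.columns else 1,
        }
    )
    if config.count_mode == "insertion":
        # count each corrected endpoint (insertion site) separately
        left = frag.copy()
        left["End"] = left["Start"] + 1
        right = frag.copy()
        right["Start"] = right["End"] - 1
        frag = pd.concat([left, right], ignore_index=True)

    joined = pr.PyRanges(win_df).join(pr.PyRanges(frag)).df
    if len(joined):
        grouped = (
            joined.groupby(["elem_idx", "cell_idx"], sort=False)["weight"].sum()
        )
        rows = grouped.index.get_level_values(0).to_numpy()
        cols = grouped.index.get_level_values(1).to_numpy()
        vals = grouped.to_numpy()
    else:
        rows = cols = vals = np.array([], dtype=int)
    counts = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(elements), len(cells))
    ).tocsr()
    return ElementCountMatrix(
        elements=[e.id for e in elements], cells=list(cells), counts=counts
    )


def blacklist_coverage(
    fragments: Union[pd.DataFrame, Iterable[Fragment]],
    blacklist: Sequence[GenomicInterval],
    config: PipelineConfig,
    annotation: Optional[CellAnnotation] = None,
    cells: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Per-cell blacklist coverage in fragments per bp.

    For each cell: number of Tn5-corrected, MAPQ-passing fragments overlapping
    any blacklist region (each fragment counted once however many regions it
    touches), divided by the total blacklist length.
    """
    if len(blacklist) == 0:
        raise ValueError("blacklist is empty")
    total_len = sum(len(iv) for iv in blacklist)
    if total_len <= 0:
        raise ValueError("blacklist has zero total length")
    df, _ = _prepare_fragments(fragments, config, annotation)
    if cells is None:
        cells = annotation.barcodes if annotation is not None else sorted(df["barcode"].unique())

    frag = pd.DataFrame(
        {
            "Chromosome": df["chrom"].to_numpy(),
            "Start": df["start"].to_numpy(),
            "End": df["end"].to_numpy(),
            "frag_id": np.arange(len(df)),
            "barcode": df["barcode"].to_numpy(),
            "weight": df["count"].to_numpy() if "count" in df.columns else 1,
        }
    )
    bl = pd.DataFrame(
        {
            "Chromosome": [iv.chrom for iv in blacklist],
            "Start": [iv.start for iv in blacklist],
            "End": [iv.end for iv in blacklist],
        }
    )
    joined = pr.PyRanges(frag).join(pr.PyRanges(bl)).df
    per_cell = pd.Series(0.0, index=list(cells))
    if len(joined):
        hits = joined.drop_duplicates("frag_id")
        sums = hits.groupby("barcode")["weight"].sum()
        sums = sums[sums.index.isin(per_cell.index)]
        per_cell.loc[sums.index] = sums.to_numpy(dtype=float)
    return per_cell / float(total_len)
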