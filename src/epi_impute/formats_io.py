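"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are BED-native: 0-based, half-open ``[start, end)``.
The TSS of a ``+`` promoter record is ``start``; of a ``-`` record ``end - 1``.

Supported formats
-----------------
* expression matrices: MatrixMarket coordinate triplets with ``genes.tsv`` /
  ``barcodes.tsv`` sidecars (10x style), or dense TSV (genes x cells, first
  column gene id, header row barcodes)
* ATAC fragments: 4+ column TSV (chrom, start, end, barcode[, count-or-MAPQ]),
  plain or gzip-compressed
* regulatory elements: BED6 promoter TSS records (strand required, optional
  7th column GC fraction); BED3+ enhancers (optional name, optional GC column)
  with a 2-column enhancer-id -> gene-id link TSV
* blacklist regions: BED3
* cell annotations: 2-column TSV, barcode -> cell-type label
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("epi_impute")

VALID_STRANDS = {"+", "-", "."}

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Fragment:
    """A sequenced ATAC fragment assigned to a cell barcode.

    ``count`` carries the duplicate count when the fragments file has a
    count-style 5th column; ``mapq`` when it is a MAPQ-style file.
    """

    interval: GenomicInterval
    barcode: str
    mapq: Optional[int] = None
    count: int = 1

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("fragment barcode must be non-empty")


@dataclass
class RegulatoryElement:
    """A promoter TSS record or enhancer interval linked to >= 1 gene.

    Promoters carry exactly one gene id; enhancers may be linked to several
    genes or to none (unlinked enhancers are kept but excluded from gene
    aggregation).
    """

    id: str
    interval: GenomicInterval
    kind: str  # "promoter" | "enhancer"
    gene_ids: list[str] = field(default_factory=list)
    gc_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("promoter", "enhancer"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "promoter" and len(self.gene_ids) != 1:
            raise ValueError(
                f"promoter element {self.id!r} must have exactly one gene id"
            )
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction of {self.id!r} outside [0, 1]")

    @property
    def linked(self) -> bool:
        return len(self.gene_ids) > 0


@dataclass
class ExpressionMatrix:
    """Gene x cell count matrix with ordered identifier lists."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative expression entry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


class CellAnnotation:
    """Mapping barcode -> cell-type label, preserving file order."""

    def __init__(self, mapping: dict[str, str]):
        for bc, label in mapping.items():
            if not label:
                raise ValueError(f"empty label for barcode {bc!r}")
        self._map = dict(mapping)

    def __getitem__(self, barcode: str) -> str:
        return self._map[barcode]

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def barcodes(self) -> list[str]:
        return list(self._map)

    @property
    def labels(self) -> list[str]:
        """Unique labels in order of first appearance."""
        seen: dict[str, None] = {}
        for v in self._map.values():
            seen.setdefault(v)
        return list(seen)

    def get(self, barcode: str, default=None):
        return self._map.get(barcode, default)

    def items(self):
        return self._map.items()

    def as_series(self) -> pd.Series:
        return pd.Series(self._map, name="label")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _open_text(path) -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _mtx_paths(path) -> tuple[Path, Path, Path]:
    """Resolve an MTX path or directory to (matrix, genes, barcodes) files."""
    p = Path(path)
    if p.is_dir():
        return p / "matrix.mtx", p / "genes.tsv", p / "barcodes.tsv"
    return p, p.parent / "genes.tsv", p.parent / "barcodes.tsv"


def read_expression(path, format: str = "mtx_triplet") -> ExpressionMatrix:
    """Read a gene x cell count matrix.

    ``mtx_triplet`` expects a MatrixMarket coordinate file with ``genes.tsv``
    and ``barcodes.tsv`` sidecars (one id per line) next to it, or a directory
    containing all three. ``dense_tsv`` expects genes in rows, a header row of
    barcodes and the gene id in the first column.
    """
    if format == "mtx_triplet":
        mtx, genes_f, bc_f = _mtx_paths(path)
        for f in (mtx, genes_f, bc_f):
            if not Path(f).exists():
                raise FileNotFoundError(f"missing expression input {f}")
        try:
            mat = scipy.io.mmread(os.fspath(mtx))
        except Exception as exc:  # malformed header / truncated triplets
            raise ValueError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
        genes = [ln.split("\t")[0] for ln in _read_lines(genes_f)]
        cells = [ln.split("\t")[0] for ln in _read_lines(bc_f)]
        counts = sp.csr_matrix(mat)
        if counts.shape != (len(genes), len(cells)):
            raise ValueError(
                f"dimension mismatch: {mtx} declares {counts.shape}, sidecars "
                f"give {len(genes)} genes x {len(cells)} cells"
            )
        if counts.nnz and counts.data.min() < 0:
            _raise_negative_mtx(mtx)
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = np.argwhere(df.values < 0)
        if bad.size:
            r, _ = bad[0]
            raise ValueError(f"negative entry at line {r + 2} of {path}")
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        counts = sp.csr_matrix(df.values)
    else:
        raise ValueError(f"unknown expression format {format!r}")

    if len(cells) == 0:
        raise ValueError(f"no cells in expression matrix {path}")
    if len(genes) == 0:
        raise ValueError(f"no genes in expression matrix {path}")
    return ExpressionMatrix(genes=genes, cells=cells, counts=counts)


def _read_lines(path) -> list[str]:
    with _open_text(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def _raise_negative_mtx(mtx_path) -> None:
    """Locate the first negative triplet to name its line number."""
    with _open_text(mtx_path) as fh:
        for i, ln in enumerate(fh, start=1):
            if ln.startswith("%") or not ln.strip():
                continue
            parts = ln.split()
            if len(parts) == 3 and i > 1:
                try:
                    if float(parts[2]) < 0:
                        raise ValueError(
                            f"negative entry at line {i} of {mtx_path}"
                        )
                except ValueError as exc:
                    if "negative entry" in str(exc):
                        raise
    raise ValueError(f"negative entry in {mtx_path}")


def write_expression(matrix: ExpressionMatrix, path, format: str = "mtx_triplet") -> None:
    """Write a matrix such that ``read_expression`` round-trips it."""
    if len(matrix.genes) == 0:
        raise ValueError("refusing to write a 0-gene matrix")
    if len(matrix.cells) == 0:
        raise ValueError("refusing to write a 0-cell matrix")
    if format == "mtx_triplet":
        p = Path(path)
        p.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(os.fspath(p / "matrix.mtx"), sp.coo_matrix(matrix.counts))
        (p / "genes.tsv").write_text("".join(g + "\n" for g in matrix.genes))
        (p / "barcodes.tsv").write_text("".join(c + "\n" for c in matrix.cells))
    elif format == "dense_tsv":
        df = pd.DataFrame(matrix.to_dense(), index=matrix.genes, columns=matrix.cells)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode"]


def read_fragments(
    path,
    shifted: bool = False,
    fifth_column: str = "count",
    stats: Optional[dict] = None,
) -> Iterator[Fragment]:
    """Stream fragments from a (possibly gzipped) BED-like TSV in file order.

    ``fifth_column`` selects the dialect of the optional 5th column:
    ``"count"`` (10x duplicate count, the default) or ``"mapq"``. Records with
    ``start >= end`` are skipped with a warning and counted in
    ``stats["malformed"]``; unparseable lines are a hard error.
    """
    if stats is not None:
        stats.setdefault("malformed", 0)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            chrom, barcode = parts[0], parts[3]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            if start >= end:
                logger.warning(
                    "%s:%d: skipping malformed fragment with start >= end", path, lineno
                )
                if stats is not None:
                    stats["malformed"] += 1
                continue
            mapq = None
            count = 1
            if len(parts) >= 5:
                try:
                    fifth = int(parts[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable 5th column") from exc
                if fifth_column == "mapq":
                    mapq = fifth
                elif fifth_column == "count":
                    count = fifth
                else:
                    raise ValueError(f"unknown fifth_column dialect {fifth_column!r}")
            yield Fragment(
                interval=GenomicInterval(chrom, start, end),
                barcode=barcode,
                mapq=mapq,
                count=count,
            )


def read_fragments_table(
    path, shifted: bool = False, fifth_column: str = "count"
) -> pd.DataFrame:
    """Vectorised fragments reader returning a DataFrame.

    Equivalent content to :func:`read_fragments` but parsed in one pass with
    pandas; used by the pipeline for large files. The ``shifted`` flag and the
    malformed-record count are carried in ``df.attrs``.
    """
    probe = pd.read_csv(path, sep="\t", comment="#", header=None, nrows=1)
    n_cols = probe.shape[1]
    if n_cols < 4:
        raise ValueError(f"{path}: expected >=4 columns, found {n_cols}")
    names = (FRAGMENT_COLUMNS + ["fifth"])[: min(n_cols, 5)]
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=names,
        usecols=range(len(names)),
        dtype={"chrom": str, "barcode": str},
        on_bad_lines="error",
    )
    if "fifth" not in df.columns:
        df["fifth"] = np.nan
    bad = df["start"] >= df["end"]
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: skipped %d fragments with start >= end", path, n_bad)
        df = df[~bad]
    if df["fifth"].notna().any():
        if fifth_column == "mapq":
            df = df.rename(columns={"fifth": "mapq"})
        else:
            df = df.rename(columns={"fifth": "count"})
            df["count"] = df["count"].fillna(1).astype(np.int64)
    else:
        df = df.drop(columns=["fifth"])
    df = df.reset_index(drop=True)
    df.attrs["shifted"] = bool(shifted)
    df.attrs["malformed"] = n_bad
    return df


def fragments_to_table(fragments: Iterable[Fragment], shifted: bool = False) -> pd.DataFrame:
    """Materialize a Fragment stream into the pipeline's DataFrame layout."""
    rows = {"chrom": [], "start": [], "end": [], "barcode": [], "mapq": [], "count": []}
    for f in fragments:
        rows["chrom"].append(f.interval.chrom)
        rows["start"].append(f.interval.start)
        rows["end"].append(f.interval.end)
        rows["barcode"].append(f.barcode)
        rows["mapq"].append(f.mapq)
        rows["count"].append(f.count)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "barcode", "mapq", "count"])
    if df["mapq"].isna().all():
        df = df.drop(columns=["mapq"])
    df.attrs["shifted"] = bool(shifted)
    df.attrs["malformed"] = 0
    return df


def write_fragments(df: pd.DataFrame, path) -> None:
    """Write a fragments table as a (gzip if *.gz) 4/5-column TSV."""
    cols = [c for c in ("chrom", "start", "end", "barcode", "count", "mapq") if c in df.columns]
    extra = [c for c in ("count", "mapq") if c in cols]
    if len(extra) > 1:  # one optional 5th column only
        cols.remove("mapq")
    out = df[cols]
    path = os.fspath(path)
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED elements, blacklist, annotations
# ---------------------------------------------------------------------------


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read a BED3+ file (e.g. the blacklist) into intervals."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def read_bed_elements(
    path, kind: str, links: Optional[object] = None
) -> list[RegulatoryElement]:
    """Read regulatory elements from BED.

    Promoters: BED6 TSS records (strand required; name column = gene id;
    optional 7th column = GC fraction). Enhancers: BED3+ (optional name,
    optional GC fraction column after the name) plus an optional 2-column
    enhancer-id -> gene-id links TSV. Enhancers without any link are retained
    but flagged unlinked.
    """
    if kind not in ("promoter", "enhancer"):
        raise ValueError(f"unknown element kind {kind!r}")
    elements: list[RegulatoryElement] = []
    by_id: dict[str, RegulatoryElement] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if kind == "promoter":
                if len(parts) < 6:
                    raise ValueError(
                        f"{path}:{lineno}: promoter records need BED6 with strand"
                    )
                name, strand = parts[3], parts[5]
                if strand not in ("+", "-"):
                    raise ValueError(
                        f"{path}:{lineno}: promoter record without strand "
                        "(the TSS window is strand-dependent)"
                    )
                gc = float(parts[6]) if len(parts) > 6 and parts[6] != "." else None
                elem = RegulatoryElement(
                    id=f"prom:{name}",
                    interval=GenomicInterval(chrom, start, end, strand),
                    kind="promoter",
                    gene_ids=[name],
                    gc_fraction=gc,
                )
            else:
                name = parts[3] if len(parts) > 3 and parts[3] else f"enh:{chrom}:{start}-{end}"
                gc = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
                elem = RegulatoryElement(
                    id=name,
                    interval=GenomicInterval(chrom, start, end),
                    kind="enhancer",
                    gene_ids=[],
                    gc_fraction=gc,
                )
            if elem.id in by_id:
                raise ValueError(f"{path}:{lineno}: duplicate element id {elem.id!r}")
            by_id[elem.id] = elem
            elements.append(elem)

    if kind == "enhancer" and links is not None:
        n_dropped = 0
        with _open_text(links) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{links}:{lineno}: expected 2 columns")
                enh_id, gene_id = parts[0], parts[1]
                elem = by_id.get(enh_id)
                if elem is None:
                    logger.warning(
                        "%s:%d: link references unknown enhancer %r, dropped",
                        links, lineno, enh_id,
                    )
                    n_dropped += 1
                    continue
                if gene_id not in elem.gene_ids:
                    elem.gene_ids.append(gene_id)
        if n_dropped:
            logger.warning("%s: dropped %d links to unknown enhancers", links, n_dropped)
    return elements


def write_bed_elements(elements: list[RegulatoryElement], path, links_path=None) -> None:
    """Write elements back to BED (and enhancer links when requested)."""
    lines = []
    link_lines = []
    for e in elements:
        iv = e.interval
        if e.kind == "promoter":
            gc = "." if e.gc_fraction is None else f"{e.gc_fraction:.6g}"
            lines.append(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{e.gene_ids[0]}\t0\t{iv.strand}\t{gc}"
            )
        else:
            gc = "." if e.gc_fraction is None else f"{e.gc_fraction:.6g}"
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{e.id}\t{gc}")
            for g in e.gene_ids:
                link_lines.append(f"{e.id}\t{g}")
    Path(path).write_text("".join(ln + "\n" for ln in lines))
    if links_path is not None:
        Path(links_path).write_text("".join(ln + "\n" for ln in link_lines))


def write_bed_intervals(intervals: list[GenomicInterval], path) -> None:
    Path(path).write_text(
        "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in intervals)
    )


def read_annotation(path) -> CellAnnotation:
    """Read a 2-column barcode -> label TSV (no header)."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            bc, label = parts[0], parts[1]
            if bc in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate barcode {bc!r}")
            mapping[bc] = label
    return CellAnnotation(mapping)


def write_annotation(annotation: CellAnnotation, path) -> None:
    Path(path).write_text(
        "".join(f"{bc}\t{label}\n" for bc, label in annotation.items())
    )
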