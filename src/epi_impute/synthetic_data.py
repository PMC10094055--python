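"""Matched synthetic scRNA-seq + scATAC-seq data with known ground truth.

The generator emulates FACS-sorted cell populations: each cell type carries
positive marker genes (negative-binomial expression in that type, zero
elsewhere) and negative markers (zero in that type; by construction the
negative markers of a type are positive markers of the next type, mirroring
surface markers that distinguish sibling populations). Non-marker background
genes are expressed in every type. Chromatin accessibility is concordant:
every regulatory element of a gene expressed in a type receives a Poisson
pileup of fragments in the cells of that type, on top of a uniform Poisson
background covering the whole synthetic genome including blacklist regions.

A designated housekeeping gene pair with a known population Pearson
correlation can be embedded for correlation-preservation benchmarks; the
pair is expressed in a subset of types and its within-type correlation is
solved in closed form so that the correlation over *all* cells equals the
requested target exactly (shared-component Poisson construction).

Dropout injection follows a Latin-hypercube scheme: within each cell type an
equal share of non-zero entries is zeroed, spread evenly over value-rank
strata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atac_signal import PipelineConfig, materialize_windows
from .formats_io import (
    CellAnnotation,
    ExpressionMatrix,
    GenomicInterval,
    RegulatoryElement,
    write_annotation,
    write_bed_elements,
    write_bed_intervals,
    write_expression,
    write_fragments,
)

logger = logging.getLogger("epi_impute")


@dataclass
class SyntheticDesign:
    """Study design of the synthetic matched dataset.

    Expression is negative-binomial with variance ``mu + mu^2/nb_dispersion``.
    ATAC depth is ``atac_signal_fragments`` expected fragments per open
    element per cell plus ``atac_noise_rate`` background fragments per kb per
    cell over the whole genome.
    """

    n_cell_types: int = 3
    cells_per_type: int = 200
    n_genes: int = 1500
    markers_per_type_pos: int = 20
    markers_per_type_neg: int = 20
    marker_mean: float = 5.0
    background_mean: float = 3.0
    nb_dispersion: float = 3.0
    atac_signal_fragments: float = 2.0
    atac_noise_rate: float = 0.02        # fragments / kb / cell
    fragment_length: int = 50
    genes_per_chrom: int = 500
    gene_spacing: int = 10_000
    enhancer_offset: int = 3_000
    enhancer_length: int = 400
    embed_pair: bool = True
    pair_target_r: float = 0.7
    pair_mean: float = 4.0
    pair_expressed_types: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("need >= 2 cell types (negative markers cross types)")
        reserved = self.markers_per_type_pos * self.n_cell_types + 2 * self.embed_pair
        if reserved > self.n_genes:
            raise ValueError(
                f"markers_per_type x n_cell_types (+pair) = {reserved} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if self.markers_per_type_neg > self.markers_per_type_pos:
            raise ValueError(
                "markers_per_type_neg cannot exceed markers_per_type_pos "
                "(negative markers are drawn from the next type's positives)"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.atac_noise_rate < 0 or self.atac_signal_fragments < 0:
            raise ValueError("ATAC rates must be >= 0")
        if not (1 <= self.pair_expressed_types <= self.n_cell_types):
            raise ValueError("pair_expressed_types out of range")

    @property
    def n_chroms(self) -> int:
        return int(np.ceil(self.n_genes / self.genes_per_chrom))

    @property
    def chrom_head(self) -> int:
        return 50_000

    @property
    def chrom_tail(self) -> int:
        return 50_000

    @property
    def chrom_length(self) -> int:
        return self.chrom_head + self.genes_per_chrom * self.gene_spacing + self.chrom_tail

    def labels(self) -> list[str]:
        return [f"type{t}" for t in range(self.n_cell_types)]


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside a generated dataset."""

    design: SyntheticDesign
    true_expression: ExpressionMatrix
    mean_expression: np.ndarray          # genes x types
    marker_sets: dict                    # label -> {"positive": [...], "negative": [...]}
    open_elements: dict                  # label -> set of element ids
    pair_genes: Optional[tuple[str, str]] = None
    pair_reference_r: Optional[float] = None

    def pseudobulk(self) -> pd.DataFrame:
        """Per-type mean of the true (pre-dropout) expression, genes x labels."""
        dense = self.true_expression.to_dense()
        labels = self.design.labels()
        n = self.design.cells_per_type
        cols = {
            lab: dense[:, t * n:(t + 1) * n].mean(axis=1)
            for t, lab in enumerate(labels)
        }
        return pd.DataFrame(cols, index=self.true_expression.genes)


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    fragments: pd.DataFrame
    elements: list[RegulatoryElement]
    blacklist: list[GenomicInterval]
    rna_annotation: CellAnnotation
    atac_annotation: CellAnnotation
    truth: SyntheticTruth


def pair_within_correlation(design: SyntheticDesign) -> float:
    """Within-type correlation that yields the target population correlation.

    With the pair expressed (Poisson, mean mu) in k of T types and zero in
    the rest, the Pearson correlation over all cells decomposes into a
    within-type and a between-type part; solving for the within-type
    correlation gives ``rho = r (1 + (1-p) mu) - (1-p) mu`` with ``p = k/T``.
    """
    p = design.pair_expressed_types / design.n_cell_types
    mu = design.pair_mean
    rho = design.pair_target_r * (1.0 + (1.0 - p) * mu) - (1.0 - p) * mu
    if not (0.0 <= rho <= 1.0):
        raise ValueError(
            f"pair construction infeasible: within-type correlation {rho:.3f} "
            "outside [0, 1]; lower pair_mean or change pair_expressed_types"
        )
    return rho


def _gene_ids(design: SyntheticDesign) -> list[str]:
    return [f"g{i:05d}" for i in range(design.n_genes)]


def _build_elements(
    design: SyntheticDesign, rng: np.random.Generator
) -> tuple[list[RegulatoryElement], list[GenomicInterval]]:
    """Synthetic regulatory annotation: a promoter TSS record (1 bp,
    alternating strand) and one linked enhancer per gene, tiled at fixed
    spacing; two blacklist regions in the tail of each chromosome."""
    genes = _gene_ids(design)
    elements: list[RegulatoryElement] = []
    gcs = rng.uniform(0.3, 0.7, size=2 * design.n_genes)
    for i, gene in enumerate(genes):
        chrom = f"synth{i // design.genes_per_chrom}"
        idx = i % design.genes_per_chrom
        tss = design.chrom_head + idx * design.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        elements.append(
            RegulatoryElement(
                id=f"prom:{gene}",
                interval=GenomicInterval(chrom, tss, tss + 1, strand),
                kind="promoter",
                gene_ids=[gene],
                gc_fraction=float(gcs[2 * i]),
            )
        )
        estart = tss + design.enhancer_offset
        elements.append(
            RegulatoryElement(
                id=f"enh:{gene}",
                interval=GenomicInterval(chrom, estart, estart + design.enhancer_length),
                kind="enhancer",
                gene_ids=[gene],
                gc_fraction=float(gcs[2 * i + 1]),
            )
        )
    blacklist = []
    L = design.chrom_length
    for k in range(design.n_chroms):
        chrom = f"synth{k}"
        blacklist.append(GenomicInterval(chrom, L - 45_000, L - 35_000))
        blacklist.append(GenomicInterval(chrom, L - 25_000, L - 15_000))
    return elements, blacklist


def _mean_expression(design: SyntheticDesign) -> tuple[np.ndarray, dict, Optional[tuple[str, str]]]:
    """Genes x types mean matrix plus marker sets and the embedded pair."""
    genes = _gene_ids(design)
    T, P = design.n_cell_types, design.markers_per_type_pos
    mu = np.zeros((design.n_genes, T))
    marker_sets: dict[str, dict[str, list[str]]] = {}
    pos_of_type = {}
    for t in range(T):
        rows = np.arange(t * P, (t + 1) * P)
        mu[rows, t] = design.marker_mean
        pos_of_type[t] = [genes[r] for r in rows]
    for t, lab in enumerate(design.labels()):
        neg_src = (t + 1) % T
        marker_sets[lab] = {
            "positive": pos_of_type[t],
            "negative": pos_of_type[neg_src][: design.markers_per_type_neg],
        }
    next_free = T * P
    pair: Optional[tuple[str, str]] = None
    if design.embed_pair:
        pair = (genes[next_free], genes[next_free + 1])
        for g in (next_free, next_free + 1):
            mu[g, : design.pair_expressed_types] = design.pair_mean
        next_free += 2
    mu[next_free:, :] = design.background_mean
    return mu, marker_sets, pair


def _sample_expression(
    design: SyntheticDesign, mu: np.ndarray, pair_rows: Optional[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """NB counts per gene x cell; the embedded pair uses a shared-component
    Poisson construction with exact marginal means and within-type
    correlation."""
    T, n = design.n_cell_types, design.cells_per_type
    disp = design.nb_dispersion
    counts = np.zeros((design.n_genes, T * n), dtype=np.int64)
    for t in range(T):
        m = mu[:, t][:, None]
        p = disp / (disp + np.where(m > 0, m, 1.0))
        block = rng.negative_binomial(disp, p, size=(design.n_genes, n))
        block[np.broadcast_to(m == 0, block.shape)] = 0
        counts[:, t * n:(t + 1) * n] = block
    if pair_rows is not None:
        rho = pair_within_correlation(design)
        lam = design.pair_mean
        for t in range(design.pair_expressed_types):
            shared = rng.poisson(rho * lam, size=n)
            a = shared + rng.poisson((1 - rho) * lam, size=n)
            b = shared + rng.poisson((1 - rho) * lam, size=n)
            counts[pair_rows[0], t * n:(t + 1) * n] = a
            counts[pair_rows[1], t * n:(t + 1) * n] = b
        for t in range(design.pair_expressed_types, T):
            counts[pair_rows[0], t * n:(t + 1) * n] = 0
            counts[pair_rows[1], t * n:(t + 1) * n] = 0
    return counts


def _sample_fragments(
    design: SyntheticDesign,
    elements: list[RegulatoryElement],
    open_rows_per_type: list[np.ndarray],
    atac_barcodes: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Signal pileups at open element windows plus uniform genome background."""
    config = PipelineConfig()
    windows = materialize_windows(elements, config)
    w_chrom = np.array([w.chrom for w in windows])
    w_start = np.array([w.start for w in windows])
    w_end = np.array([w.end for w in windows])
    L = design.fragment_length
    T, n = design.n_cell_types, design.cells_per_type

    chroms, starts, barcodes = [], [], []
    bc_arr = np.array(atac_barcodes)
    for t in range(T):
        rows = open_rows_per_type[t]
        cells_t = np.arange(t * n, (t + 1) * n)
        if len(rows) and design.atac_signal_fragments > 0:
            k = rng.poisson(design.atac_signal_fragments, size=(len(rows), n))
            el_rep = np.repeat(np.repeat(rows, n), k.ravel())
            cell_rep = np.repeat(np.tile(cells_t, len(rows)), k.ravel())
            span = w_end[el_rep] - w_start[el_rep] - L
            offs = rng.integers(0, np.maximum(span, 1))
            starts.append(w_start[el_rep] + offs)
            chroms.append(w_chrom[el_rep])
            barcodes.append(bc_arr[cell_rep])
    # uniform background over the whole genome, blacklist included
    genome_kb = design.n_chroms * design.chrom_length / 1000.0
    lam_noise = design.atac_noise_rate * genome_kb
    if lam_noise > 0:
        n_noise = rng.poisson(lam_noise, size=T * n)
        total = int(n_noise.sum())
        if total:
            cell_rep = np.repeat(np.arange(T * n), n_noise)
            chrom_idx = rng.integers(0, design.n_chroms, size=total)
            pos = rng.integers(0, design.chrom_length - L, size=total)
            chroms.append(np.array([f"synth{c}" for c in chrom_idx]))
            starts.append(pos)
            barcodes.append(bc_arr[cell_rep])
    if chroms:
        chrom_all = np.concatenate(chroms)
        start_all = np.concatenate(starts).astype(np.int64)
        bc_all = np.concatenate(barcodes)
    else:
        chrom_all = np.array([], dtype=str)
        start_all = np.array([], dtype=np.int64)
        bc_all = np.array([], dtype=str)
    df = pd.DataFrame(
        {
            "chrom": chrom_all,
            "start": start_all,
            "end": start_all + L,
            "barcode": bc_all,
        }
    )
    df.attrs["shifted"] = False
    df.attrs["malformed"] = 0
    return df


def generate(design: SyntheticDesign) -> SyntheticDataset:
    """Generate a matched synthetic dataset, fully reproducible from the seed."""
    ss = np.random.SeedSequence(design.seed)
    rng_elem, rng_expr, rng_atac = (np.random.default_rng(s) for s in ss.spawn(3))

    elements, blacklist = _build_elements(design, rng_elem)
    mu, marker_sets, pair = _mean_expression(design)
    genes = _gene_ids(design)
    gene_row = {g: i for i, g in enumerate(genes)}
    pair_rows = (gene_row[pair[0]], gene_row[pair[1]]) if pair else None

    counts = _sample_expression(design, mu, pair_rows, rng_expr)
    labels = design.labels()
    n = design.cells_per_type
    rna_barcodes = [f"rna_t{t}_{i:04d}" for t in range(design.n_cell_types) for i in range(n)]
    atac_barcodes = [f"atac_t{t}_{i:04d}" for t in range(design.n_cell_types) for i in range(n)]
    rna_ann = CellAnnotation({bc: labels[t] for t in range(design.n_cell_types)
                              for bc in rna_barcodes[t * n:(t + 1) * n]})
    atac_ann = CellAnnotation({bc: labels[t] for t in range(design.n_cell_types)
                               for bc in atac_barcodes[t * n:(t + 1) * n]})

    expression = ExpressionMatrix(genes=genes, cells=rna_barcodes, counts=sp.csr_matrix(counts))

    # open elements: every element of a gene with non-zero mean in the type
    elem_gene_row = np.array([gene_row[e.gene_ids[0]] for e in elements])
    open_rows_per_type = []
    open_elements: dict[str, set] = {}
    for t, lab in enumerate(labels):
        rows = np.flatnonzero(mu[elem_gene_row, t] > 0)
        open_rows_per_type.append(rows)
        open_elements[lab] = {elements[r].id for r in rows}

    fragments = _sample_fragments(design, elements, open_rows_per_type, atac_barcodes, rng_atac)

    truth = SyntheticTruth(
        design=design,
        true_expression=expression,
        mean_expression=mu,
        marker_sets=marker_sets,
        open_elements=open_elements,
        pair_genes=pair,
        pair_reference_r=design.pair_target_r if pair else None,
    )
    return SyntheticDataset(
        expression=expression,
        fragments=fragments,
        elements=elements,
        blacklist=blacklist,
        rna_annotation=rna_ann,
        atac_annotation=atac_ann,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# dropout injection
# ---------------------------------------------------------------------------


@dataclass
class DropoutMask:
    """Positions and original values of simulated dropouts."""

    gene_idx: np.ndarray
    cell_idx: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def restore(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        """Put the masked values back; inverse of the injection."""
        dense = matrix.to_dense().astype(float)
        dense[self.gene_idx, self.cell_idx] = self.values
        return ExpressionMatrix(
            genes=list(matrix.genes), cells=list(matrix.cells),
            counts=sp.csr_matrix(dense),
        )


def inject_dropouts(
    matrix: ExpressionMatrix,
    rate: float,
    annotation: CellAnnotation,
    seed: int,
    strata: int = 10,
) -> tuple[ExpressionMatrix, DropoutMask]:
    """Zero a fraction of non-zero entries, balanced across cell types and
    expression strata.

    Per cell type exactly ``round(rate * nnz_type)`` non-zero entries are
    zeroed. Within a type, entries are ranked by value, split into ``strata``
    equal-rank strata, and each stratum loses an equal share of the quota
    (Latin-hypercube rank sampling; the per-stratum count is within +-1 of
    ``quota / strata``). The mask records every zeroed position with its
    original value so the injection is exactly invertible.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("dropout rate must be in [0, 1)")
    missing = [c for c in matrix.cells if c not in annotation]
    if missing:
        raise ValueError(f"{len(missing)} cells lack an annotation")
    coo = sp.coo_matrix(matrix.counts)
    rows, cols, data = coo.row, coo.col, coo.data
    cell_labels = np.array([annotation[c] for c in matrix.cells])
    entry_labels = cell_labels[cols]

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    drop = np.zeros(len(data), dtype=bool)
    for label in pd.unique(cell_labels):
        idx = np.flatnonzero(entry_labels == label)
        nnz = len(idx)
        n_zero = int(np.floor(rate * nnz + 0.5))
        if n_zero == 0:
            continue
        # rank by value with deterministic tie-breaks, then stratify
        order = idx[np.lexsort((cols[idx], rows[idx], data[idx]))]
        strata_bins = np.array_split(order, strata)
        quota = np.full(strata, n_zero // strata)
        rem = n_zero - quota.sum()
        if rem:
            quota[rng.choice(strata, size=rem, replace=False)] += 1
        # cap quotas at stratum size, pushing overflow to strata with room
        for _ in range(strata):
            over = quota - np.array([len(b) for b in strata_bins])
            if (over <= 0).all():
                break
            excess = int(over[over > 0].sum())
            quota = np.minimum(quota, [len(b) for b in strata_bins])
            room = np.array([len(b) for b in strata_bins]) - quota
            for s in np.argsort(-room):
                take = min(excess, room[s])
                quota[s] += take
                excess -= take
                if excess == 0:
                    break
        for s, bin_idx in enumerate(strata_bins):
            if quota[s] == 0 or len(bin_idx) == 0:
                continue
            chosen = rng.choice(bin_idx, size=quota[s], replace=False)
            drop[chosen] = True

    mask = DropoutMask(
        gene_idx=rows[drop].copy(), cell_idx=cols[drop].copy(), values=data[drop].copy()
    )
    new_data = data.copy()
    new_data[drop] = 0
    out = sp.coo_matrix((new_data, (rows, cols)), shape=matrix.shape).tocsr()
    out.eliminate_zeros()
    dropped = ExpressionMatrix(
        genes=list(matrix.genes), cells=list(matrix.cells), counts=out
    )
    return dropped, mask


# ---------------------------------------------------------------------------
# on-disk layout (consumed by the CLI and acceptance workflows)
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write every file of a synthetic dataset in the formats the readers
    understand: counts/ (MTX + sidecars), fragments.tsv.gz, promoters.bed,
    enhancers.bed + links.tsv, blacklist.bed, annotations, truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.expression, out / "counts", format="mtx_triplet")
    write_fragments(dataset.fragments, out / "fragments.tsv.gz")
    promoters = [e for e in dataset.elements if e.kind == "promoter"]
    enhancers = [e for e in dataset.elements if e.kind == "enhancer"]
    write_bed_elements(promoters, out / "promoters.bed")
    write_bed_elements(enhancers, out / "enhancers.bed", out / "links.tsv")
    write_bed_intervals(dataset.blacklist, out / "blacklist.bed")
    write_annotation(dataset.rna_annotation, out / "rna_annotation.tsv")
    write_annotation(dataset.atac_annotation, out / "atac_annotation.tsv")
    truth = dataset.truth
    payload = {
        "design": asdict(truth.design),
        "marker_sets": truth.marker_sets,
        "open_elements": {k: sorted(v) for k, v in truth.open_elements.items()},
        "pair_genes": list(truth.pair_genes) if truth.pair_genes else None,
        "pair_reference_r": truth.pair_reference_r,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
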