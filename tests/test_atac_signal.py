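"""Tn5 correction, window arithmetic and fragment counting."""

import numpy as np
import pandas as pd
import pytest

from epi_impute import (
    Fragment,
    GenomicInterval,
    PipelineConfig,
    RegulatoryElement,
    blacklist_coverage,
    count_fragments,
    enhancer_window,
    promoter_window,
    tn5_shift,
    tn5_shift_table,
)

CFG = PipelineConfig()


def frag(chrom, start, end, barcode="bc", mapq=None, count=1):
    return Fragment(GenomicInterval(chrom, start, end), barcode, mapq=mapq, count=count)


def prom(gene, chrom, tss, strand):
    return RegulatoryElement(
        id=f"prom:{gene}", interval=GenomicInterval(chrom, tss, tss + 1, strand),
        kind="promoter", gene_ids=[gene],
    )


def table(frags, shifted=True):
    df = pd.DataFrame(
        {
            "chrom": [f.interval.chrom for f in frags],
            "start": [f.interval.start for f in frags],
            "end": [f.interval.end for f in frags],
            "barcode": [f.barcode for f in frags],
        }
    )
    if any(f.mapq is not None for f in frags):
        df["mapq"] = [f.mapq for f in frags]
    if any(f.count != 1 for f in frags):
        df["count"] = [f.count for f in frags]
    df.attrs["shifted"] = shifted
    return df


class TestTn5Shift:
    def test_plus4_minus5(self):
        out = tn5_shift(frag("chr1", 100, 250), CFG)
        assert (out.interval.start, out.interval.end) == (104, 245)

    def test_preserves_identity_fields(self):
        out = tn5_shift(frag("chr7", 10, 300, barcode="AACG", mapq=60), CFG)
        assert out.interval.chrom == "chr7"
        assert out.barcode == "AACG"
        assert out.mapq == 60

    def test_collapsed_fragment_dropped(self):
        assert tn5_shift(frag("chr1", 100, 108), CFG) is None

    def test_table_applied_once(self):
        df = table([frag("chr1", 100, 250)], shifted=False)
        once = tn5_shift_table(df, CFG)
        twice = tn5_shift_table(once, CFG)  # identity on already-shifted input
        assert once.loc[0, "start"] == 104 and once.loc[0, "end"] == 245
        assert twice.equals(once)


class TestPromoterWindow:
    def test_plus_strand(self):
        w = promoter_window(prom("g", "chr1", 10_000, "+"), CFG)
        assert (w.start, w.end) == (9_500, 10_200)

    def test_minus_strand_reflected(self):
        w = promoter_window(prom("g", "chr1", 10_000, "-"), CFG)
        assert (w.start, w.end) == (9_801, 10_501)

    def test_clamped_at_zero(self):
        w = promoter_window(prom("g", "chr1", 300, "+"), CFG)
        assert (w.start, w.end) == (0, 500)

    def test_unstranded_record_rejected(self):
        rec = RegulatoryElement(
            id="prom:g", interval=GenomicInterval("chr1", 100, 101),
            kind="promoter", gene_ids=["g"],
        )
        with pytest.raises(ValueError, match="strand"):
            promoter_window(rec, CFG)


class TestEnhancerWindow:
    def test_short_enhancer_recentred(self):
        e = RegulatoryElement(
            id="e", interval=GenomicInterval("chr1", 10_000, 10_400), kind="enhancer"
        )
        w = enhancer_window(e, CFG)
        assert (w.start, w.end) == (10_200 - 500, 10_200 + 200)

    def test_long_enhancer_kept_as_is(self):
        e = RegulatoryElement(
            id="e", interval=GenomicInterval("chr1", 10_000, 11_000), kind="enhancer"
        )
        w = enhancer_window(e, CFG)
        assert (w.start, w.end) == (10_000, 11_000)


def brute_force_counts(frags, windows, mapq_min=30):
    """Independent all-pairs overlap scan (already-shifted fragments)."""
    cells = sorted({f.barcode for f in frags})
    cell_idx = {c: i for i, c in enumerate(cells)}
    out = np.zeros((len(windows), len(cells)), dtype=int)
    for f in frags:
        if f.mapq is not None and not (f.mapq > mapq_min):
            continue
        for wi, w in enumerate(windows):
            if w.chrom == f.interval.chrom and f.interval.start < w.end and w.start < f.interval.end:
                out[wi, cell_idx[f.barcode]] += f.count
    return cells, out


class TestCountFragments:
    def setup_method(self):
        self.elements = [prom(f"g{i}", "chr1", 10_000 + 2_000 * i, "+") for i in range(3)]
        # windows: [9500,10200), [11500,12200), [13500,14200)

    def test_containment_counts_one(self):
        m = count_fragments(table([frag("chr1", 9_600, 9_700)]), self.elements, CFG)
        assert m.to_dense()[0, 0] == 1 and m.to_dense().sum() == 1

    def test_low_mapq_excluded(self):
        frags = [frag("chr1", 9_600, 9_700, mapq=20), frag("chr1", 9_600, 9_700, mapq=31)]
        m = count_fragments(table(frags), self.elements, CFG)
        assert m.to_dense().sum() == 1

    def test_mapq_30_exactly_excluded(self):
        with pytest.raises(ValueError, match="no fragments retained"):
            count_fragments(table([frag("chr1", 9_600, 9_700, mapq=30)]),
                            self.elements, CFG)

    def test_fragment_spanning_two_windows_counts_in_both(self):
        m = count_fragments(table([frag("chr1", 10_100, 11_600)]), self.elements, CFG)
        col = m.to_dense()[:, 0]
        assert col[0] == 1 and col[1] == 1 and col[2] == 0

    def test_zero_elements_errors(self):
        with pytest.raises(ValueError, match="elements"):
            count_fragments(table([frag("chr1", 1, 2)]), [], CFG)

    def test_insertion_mode_counts_endpoints(self):
        cfg = PipelineConfig(count_mode="insertion")
        # both corrected insertion sites inside window 0
        m = count_fragments(table([frag("chr1", 9_600, 9_700)]), self.elements, cfg)
        assert m.to_dense()[0, 0] == 2
        # one endpoint in window 0, the other outside any window
        m2 = count_fragments(table([frag("chr1", 10_100, 10_900)]), self.elements, cfg)
        assert m2.to_dense()[0, 0] == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1234)
        windows = []
        elements = []
        for i in range(10):
            chrom = "chr1" if i < 7 else "chr2"
            start = int(rng.integers(0, 50_000))
            e = RegulatoryElement(
                id=f"e{i}", interval=GenomicInterval(chrom, start, start + int(rng.integers(100, 2_000))),
                kind="enhancer", gene_ids=[f"g{i}"],
            )
            elements.append(e)
            windows.append(enhancer_window(e, CFG))
        frags = []
        for j in range(50):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            start = int(rng.integers(0, 52_000))
            frags.append(frag(chrom, start, start + int(rng.integers(20, 800)),
                              barcode=f"bc{int(rng.integers(0, 6))}",
                              count=int(rng.integers(1, 3))))
        cells, expected = brute_force_counts(frags, windows)
        got = count_fragments(table(frags), elements, CFG)
        assert got.cells == cells
        np.testing.assert_array_equal(got.to_dense(), expected)

    def test_total_mass_bound(self):
        frags = [frag("chr1", 9_000 + 100 * i, 9_000 + 100 * i + 3_000) for i in range(20)]
        m = count_fragments(table(frags), self.elements, CFG)
        assert m.to_dense().sum() <= len(frags) * len(self.elements)


class TestBlacklistCoverage:
    BL = [GenomicInterval("chrB", 0, 7_000)]

    def test_no_blacklist_fragments_is_zero(self):
        cov = blacklist_coverage(table([frag("chr1", 10, 60)]), self.BL, CFG)
        assert (cov == 0).all()

    def test_seven_over_7000(self):
        frags = [frag("chrB", 100 * i, 100 * i + 50) for i in range(7)]
        cov = blacklist_coverage(table(frags), self.BL, CFG)
        assert cov.loc["bc"] == pytest.approx(0.001)

    def test_linearity(self):
        frags = [frag("chrB", 100 * i, 100 * i + 50, count=1) for i in range(5)]
        doubled = [frag("chrB", 100 * i, 100 * i + 50, count=2) for i in range(5)]
        a = blacklist_coverage(table(frags), self.BL, CFG).loc["bc"]
        b = blacklist_coverage(table(doubled), self.BL, CFG).loc["bc"]
        assert b == pytest.approx(2 * a)

    def test_fragment_counted_once_across_regions(self):
        bl = [GenomicInterval("chrB", 0, 1_000), GenomicInterval("chrB", 1_000, 2_000)]
        cov = blacklist_coverage(table([frag("chrB", 900, 1_100)]), bl, CFG)
        assert cov.loc["bc"] == pytest.approx(1 / 2_000)

    def test_empty_blacklist_errors(self):
        with pytest.raises(ValueError):
            blacklist_coverage(table([frag("chr1", 1, 2)]), [], CFG)
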