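"""Smooth quantile normalization and GC-content correction."""

import numpy as np
import pytest

from epi_impute import (
    CellAnnotation,
    GenomicInterval,
    NormalizedAccessibility,
    RegulatoryElement,
    gc_normalize,
    smooth_quantile_normalize,
)


def acc(values, prefix="e"):
    values = np.asarray(values, dtype=float)
    return NormalizedAccessibility(
        elements=[f"{prefix}{i}" for i in range(values.shape[0])],
        cells=[f"c{i}" for i in range(values.shape[1])],
        values=values,
    )


def classical_quantile_norm(values):
    """Sort-and-average oracle: every cell gets the mean sorted profile at
    its own ranks, ties averaged."""
    values = np.asarray(values, dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for c in range(values.shape[1]):
        order = np.argsort(values[:, c], kind="stable")
        col = np.empty(values.shape[0])
        col[order] = ref
        # average over ties
        for v in np.unique(values[:, c]):
            tie = values[:, c] == v
            col[tie] = col[tie].mean()
        out[:, c] = col
    return out


def qsmooth_oracle(values, labels):
    """Explicit per-rank variance-decomposition oracle (loops, no tricks)."""
    values = np.asarray(values, dtype=float)
    n_el, n_cells = values.shape
    Q = np.sort(values, axis=0)
    uniq = sorted(set(labels))
    out = np.empty_like(values)
    refs = {}
    for g in uniq:
        cols = [i for i, l in enumerate(labels) if l == g]
        ref = np.empty(n_el)
        for q in range(n_el):
            row = Q[q]
            grand = row.mean()
            ssb = sum(
                len([i for i, l in enumerate(labels) if l == h])
                * (row[[i for i, l in enumerate(labels) if l == h]].mean() - grand) ** 2
                for h in uniq
            )
            sst = ((row - grand) ** 2).sum()
            w = min(1.0, max(0.0, ssb / sst)) if sst > 0 else 0.0
            ref[q] = w * row[cols].mean() + (1 - w) * grand
        refs[g] = ref
    for c in range(n_cells):
        ref = refs[labels[c]]
        order = np.argsort(values[:, c], kind="stable")
        col = np.empty(n_el)
        col[order] = ref
        for v in np.unique(values[:, c]):
            tie = values[:, c] == v
            col[tie] = col[tie].mean()
        out[:, c] = col
    return out


class TestSmoothQuantile:
    def test_single_group_equals_classical(self):
        rng = np.random.default_rng(3)
        values = rng.poisson(4, size=(5, 4)).astype(float)
        got = smooth_quantile_normalize(acc(values))
        np.testing.assert_allclose(got.values, classical_quantile_norm(values))

    def test_identical_group_distributions_equal_classical(self):
        # both groups hold the same per-cell sorted profiles
        values = np.array(
            [[1, 2, 1, 2], [3, 5, 3, 5], [7, 9, 7, 9], [0, 0, 0, 0]], dtype=float
        )
        groups = CellAnnotation({"c0": "A", "c1": "A", "c2": "B", "c3": "B"})
        got = smooth_quantile_normalize(acc(values), groups)
        np.testing.assert_allclose(got.values, classical_quantile_norm(values))

    def test_disjoint_groups_preserve_group_quantiles(self):
        """With zero within-group variance the blend weight is 1 and each
        group keeps its own distribution exactly."""
        values = np.column_stack([[1, 2, 3]] * 3 + [[10, 20, 30]] * 3).astype(float)
        cells = {f"c{i}": ("A" if i < 3 else "B") for i in range(6)}
        got = smooth_quantile_normalize(acc(values), CellAnnotation(cells))
        np.testing.assert_allclose(got.values, values)

    def test_matches_explicit_oracle_mixed_groups(self):
        rng = np.random.default_rng(17)
        values = rng.poisson(3, size=(4, 6)).astype(float)
        values[:, 3:] += rng.poisson(5, size=(4, 3))
        labels = ["A", "A", "A", "B", "B", "B"]
        groups = CellAnnotation({f"c{i}": labels[i] for i in range(6)})
        got = smooth_quantile_normalize(acc(values), groups)
        np.testing.assert_allclose(got.values, qsmooth_oracle(values, labels))

    def test_rank_preservation_within_cell(self):
        rng = np.random.default_rng(23)
        values = rng.poisson(2, size=(30, 8)).astype(float)
        groups = CellAnnotation({f"c{i}": f"G{i % 2}" for i in range(8)})
        got = smooth_quantile_normalize(acc(values), groups)
        for c in range(8):
            raw_order = np.argsort(values[:, c], kind="stable")
            assert (np.diff(got.values[raw_order, c]) >= -1e-12).all()

    def test_idempotent(self):
        # tie-free values: tie-averaging trades exact idempotency for the
        # stated ties-get-the-mean-reference convention
        rng = np.random.default_rng(5)
        values = rng.gamma(3.0, 1.0, size=(12, 6))
        groups = CellAnnotation({f"c{i}": f"G{i % 3}" for i in range(6)})
        once = smooth_quantile_normalize(acc(values), groups)
        twice = smooth_quantile_normalize(once, groups)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_singleton_group_uses_global_reference(self, caplog):
        values = np.array([[1, 5, 9], [2, 6, 10], [3, 7, 11]], dtype=float)
        groups = CellAnnotation({"c0": "A", "c1": "A", "c2": "B"})
        with caplog.at_level("WARNING", logger="epi_impute"):
            got = smooth_quantile_normalize(acc(values), groups)
        global_ref = np.sort(values, axis=0).mean(axis=1)
        np.testing.assert_allclose(got.values[:, 2], global_ref)


def elem(i, gc):
    return RegulatoryElement(
        id=f"e{i}", interval=GenomicInterval("chr1", 100 * i + 1, 100 * i + 50),
        kind="enhancer", gene_ids=["g"], gc_fraction=gc,
    )


class TestGCNormalize:
    def test_uniform_gc_is_identity(self):
        rng = np.random.default_rng(7)
        values = rng.poisson(4, size=(8, 3)).astype(float)
        elements = [elem(i, 0.5) for i in range(8)]
        got = gc_normalize(acc(values), elements, gc_bins=4)
        np.testing.assert_allclose(got.values, values)

    def test_two_bins_doubled_values_equalized(self):
        """Elements in the high-GC bin carry doubled signal; after the
        correction both bins share each cell's mean."""
        base = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0], [2.0, 3.0]])
        values = np.vstack([base, 2 * base])
        elements = [elem(i, 0.35) for i in range(5)] + [elem(i + 5, 0.65) for i in range(5)]
        got = gc_normalize(acc(values), elements, gc_bins=2)
        lo = got.values[:5].mean(axis=0)
        hi = got.values[5:].mean(axis=0)
        np.testing.assert_allclose(lo, hi)
        np.testing.assert_allclose(lo, values.mean(axis=0))

    def test_rank_order_within_bin_preserved(self):
        rng = np.random.default_rng(9)
        values = rng.gamma(2, 2, size=(20, 4))
        elements = [elem(i, float(g)) for i, g in enumerate(rng.uniform(0.3, 0.7, 20))]
        got = gc_normalize(acc(values), elements, gc_bins=2)
        from epi_impute.normalization import _gc_bin_assignments

        gc = np.array([e.gc_fraction for e in elements])
        bins = _gc_bin_assignments(gc, 2)
        for b in np.unique(bins):
            rows = np.flatnonzero(bins == b)
            for c in range(4):
                order = np.argsort(values[rows, c], kind="stable")
                assert (np.diff(got.values[rows[order], c]) >= -1e-12).all()

    def test_all_gc_missing_is_identity(self, caplog):
        values = np.arange(12, dtype=float).reshape(4, 3)
        elements = [elem(i, None) for i in range(4)]
        with caplog.at_level("WARNING", logger="epi_impute"):
            got = gc_normalize(acc(values), elements)
        np.testing.assert_allclose(got.values, values)

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        values = rng.poisson(5, size=(30, 4)).astype(float)
        elements = [elem(i, float(g)) for i, g in enumerate(rng.uniform(0.2, 0.8, 30))]
        once = gc_normalize(acc(values), elements, gc_bins=3)
        twice = gc_normalize(once, elements, gc_bins=3)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(13)
        values = rng.poisson(1, size=(25, 5)).astype(float)
        elements = [elem(i, float(g)) for i, g in enumerate(rng.uniform(0.2, 0.8, 25))]
        got = gc_normalize(acc(values), elements)
        assert (got.values >= 0).all()
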