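import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from podmap import (
    binarize_region,
    correlate_all,
    partition_regions,
    weighted_map_correlation,
)
from podmap.errors import ShapeError

GRID = (50, 50)


def _grid(fill=0.0):
    return np.full(GRID, fill, dtype=float)


class TestPartitionRegions:
    def test_identical_masks(self):
        mask = np.zeros(GRID, bool)
        mask[25:, :] = True
        part = partition_regions(mask, mask)
        np.testing.assert_array_equal(part.region_a, mask)
        assert not part.region_b.any()
        np.testing.assert_array_equal(part.region_c, ~mask)

    def test_disjoint_and_empty_masks(self):
        a = np.zeros(GRID, bool)
        b = np.zeros(GRID, bool)
        a[:10], b[40:] = True, True
        part = partition_regions(a, b)
        assert not part.region_a.any()
        assert part.region_b.sum() == 20 * 50
        part = partition_regions(np.zeros(GRID, bool), np.zeros(GRID, bool))
        assert part.region_c.all()

    def test_partition_covers_grid_disjointly(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(GRID) < 0.3, rng.random(GRID) < 0.6
        part = partition_regions(a, b)
        total = part.region_a.astype(int) + part.region_b.astype(int) + part.region_c.astype(int)
        assert (total == 1).all()

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            partition_regions(np.zeros((50, 50), bool), np.zeros((50, 49), bool))


class TestBinarizeRegion:
    def test_threshold_at_regional_mean(self):
        grid = _grid()
        region = np.zeros(GRID, bool)
        region[0, :4] = True
        grid[0, :4] = [1.0, 2.0, 3.0, 4.0]  # mean 2.5
        np.testing.assert_array_equal(binarize_region(grid, region), [0, 0, 1, 1])

    def test_constant_region_is_all_zero(self):
        region = np.zeros(GRID, bool)
        region[:5] = True
        assert not binarize_region(_grid(3.3), region).any()

    def test_negation_complements_bits(self):
        rng = np.random.default_rng(1)
        grid = rng.random(GRID)
        region = rng.random(GRID) < 0.4
        bits = binarize_region(grid, region)
        flipped = binarize_region(-grid, region)
        # no value equals the mean almost surely, so bits complement
        np.testing.assert_array_equal(flipped, 1 - bits)


class TestWeightedMapCorrelation:
    def _gene_setup(self):
        rng = np.random.default_rng(2)
        grid = rng.normal(size=GRID)
        mask = np.zeros(GRID, bool)
        mask[20:, :] = True
        return grid, mask

    def test_self_correlation_is_one(self):
        grid, mask = self._gene_setup()
        res = weighted_map_correlation(grid, grid, mask, mask)
        assert res.r_a == pytest.approx(1.0)
        assert res.r_b is None  # XOR region empty for identical masks
        assert res.r_c == pytest.approx(1.0)
        assert res.combined == pytest.approx(1.0)
        assert res.passes

    def test_negated_map_gives_minus_one(self):
        grid, mask = self._gene_setup()
        res = weighted_map_correlation(grid, -grid, mask, mask)
        assert res.combined == pytest.approx(-1.0)
        assert res.passes

    def test_hand_computed_phi_on_four_cells(self):
        # region A = 4 cells; gene values 1,2,3,4 -> bits 0011;
        # cell values 10,20,30,40 -> bits 0011; phi = 1 on the 2x2 table
        gene, cell = _grid(), _grid()
        gene_mask, cell_mask = np.zeros(GRID, bool), np.zeros(GRID, bool)
        gene_mask[0, :4] = cell_mask[0, :4] = True
        gene[0, :4] = [1, 2, 3, 4]
        cell[0, :4] = [10, 20, 30, 40]
        res = weighted_map_correlation(gene, cell, gene_mask, cell_mask)
        assert res.r_a == pytest.approx(1.0)
        assert res.r_b is None and res.r_c is None  # constant outside region A
        assert res.combined == pytest.approx(1.0)

    def test_single_defined_region_equals_its_correlation(self):
        # only region B defined: combined = r_b regardless of its 0.2 weight
        rng = np.random.default_rng(3)
        gene, cell = rng.normal(size=GRID), rng.normal(size=GRID)
        gene_mask = np.zeros(GRID, bool)
        gene_mask[:25] = True
        cell_mask = ~gene_mask  # XOR covers everything: A and C empty
        res = weighted_map_correlation(gene, cell, gene_mask, cell_mask)
        assert res.r_a is None and res.r_c is None
        assert res.combined == pytest.approx(res.r_b)

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(4)
        gene, cell = rng.normal(size=GRID), rng.normal(size=GRID)
        gmask, cmask = rng.random(GRID) < 0.4, rng.random(GRID) < 0.5
        a = weighted_map_correlation(gene, cell, gmask, cmask)
        b = weighted_map_correlation(cell, gene, cmask, gmask)
        for attr in ("r_a", "r_c", "combined"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))
        assert a.r_b == pytest.approx(b.r_b)

    def test_identical_permutation_within_region_preserves_phi(self):
        rng = np.random.default_rng(5)
        gene, cell = rng.normal(size=GRID), rng.normal(size=GRID)
        mask = np.ones(GRID, bool)
        base = weighted_map_correlation(gene, cell, mask, mask)
        perm = rng.permutation(GRID[0] * GRID[1])
        gene_p = gene.ravel()[perm].reshape(GRID)
        cell_p = cell.ravel()[perm].reshape(GRID)
        permuted = weighted_map_correlation(gene_p, cell_p, mask, mask)
        assert permuted.r_a == pytest.approx(base.r_a)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_combined_lies_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        gene, cell = rng.normal(size=GRID), rng.normal(size=GRID)
        gmask = rng.random(GRID) < rng.random()
        cmask = rng.random(GRID) < rng.random()
        res = weighted_map_correlation(gene, cell, gmask, cmask)
        if res.combined is not None:
            assert -1.0 - 1e-12 <= res.combined <= 1.0 + 1e-12

    def test_zero_policy_does_not_renormalize(self):
        grid, mask = self._gene_setup()
        res = weighted_map_correlation(grid, grid, mask, mask, undefined_region_policy="zero")
        # defined regions A and C each correlate 1.0; B contributes 0
        assert res.combined == pytest.approx(0.7 + 0.1)


class TestCorrelateAll:
    def test_empty_gene_set(self):
        cell_maps = {"neu": _grid(1.0)}
        cell_masks = {"neu": np.ones(GRID, bool)}
        table, summary = correlate_all({}, {}, cell_maps, cell_masks)
        assert len(table) == 0
        assert (summary["n_passing"] == 0).all()

    def test_single_gene_matches_single_cell(self):
        rng = np.random.default_rng(6)
        grid = rng.normal(size=GRID)
        mask = np.zeros(GRID, bool)
        mask[10:, :] = True
        gene_maps, gene_masks = {"g1": grid}, {"g1": mask}
        cell_maps = {"match": grid, "other": rng.normal(size=GRID)}
        cell_masks = {"match": mask, "other": rng.random(GRID) < 0.5}
        table, summary = correlate_all(gene_maps, gene_masks, cell_maps, cell_masks)
        assert len(table) == 2
        s = summary.set_index("cell_type")
        assert s.loc["match", "proportion_passing"] == 1.0
        assert s.loc["match", "n_passing"] == 1

    def test_planted_shared_structure_beats_independent_cell(self):
        # gene maps derived from one cell trend correlate with that cell far
        # more often than with an unrelated one
        rng = np.random.default_rng(7)
        base = np.add.outer(np.linspace(0, 2, 50), np.linspace(0, 0.5, 50))
        cell_mask = base >= np.log2(1.5)
        gene_maps, gene_masks = {}, {}
        for i in range(20):
            gene_maps[f"g{i}"] = base + rng.normal(0, 0.05, size=GRID)
            gene_masks[f"g{i}"] = cell_mask.copy()
        cell_maps = {"matched": base, "independent": rng.normal(size=GRID)}
        cell_masks = {"matched": cell_mask, "independent": rng.random(GRID) < 0.5}
        _, summary = correlate_all(gene_maps, gene_masks, cell_maps, cell_masks)
        s = summary.set_index("cell_type")
        assert s.loc["matched", "proportion_passing"] > s.loc["independent", "proportion_passing"]
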