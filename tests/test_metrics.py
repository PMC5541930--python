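import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from patchtraits import (
    DegenerateInputError,
    PatchRecord,
    distribution_summary,
    label_patches,
    metric_correlations,
    plot_metrics,
    shape_index,
    species_metrics,
)

from .conftest import make_grid

# ---------------------------------------------------------------------------
# independent oracle: exhaustive BFS flood fill + face-by-face edge counting


def bfs_patches(values):
    """Brute-force patch extraction: BFS flood fill under the 4-neighbour
    rule and perimeter by enumerating all four faces of every cell."""
    values = np.asarray(values)
    nrows, ncols = values.shape
    seen = np.zeros_like(values, dtype=bool)
    patches = []
    for r0 in range(nrows):
        for c0 in range(ncols):
            if values[r0, c0] == 0 or seen[r0, c0]:
                continue
            code = values[r0, c0]
            stack, cells = [(r0, c0)], set()
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                cells.add((r, c))
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols:
                        if not seen[rr, cc] and values[rr, cc] == code:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            perim = 0
            for r, c in cells:
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    outside = not (0 <= rr < nrows and 0 <= cc < ncols)
                    if outside or (rr, cc) not in cells:
                        perim += 1
            patches.append((int(code), len(cells), perim))
    return patches


def as_multiset(records):
    return sorted((p.species_code, p.area, p.perimeter) for p in records)


class TestLabelPatches:
    def test_single_cell_patch(self):
        recs = label_patches(make_grid([[0, 0], [0, 1]]))
        assert len(recs) == 1
        p = recs[0]
        assert (p.area, p.perimeter, p.shape_index) == (1.0, 4.0, 1.0)

    def test_diagonal_cells_are_two_patches_under_four_neighbour_rule(self):
        recs = label_patches(make_grid([[1, 0], [0, 1]]))
        assert len(recs) == 2
        recs8 = label_patches(make_grid([[1, 0], [0, 1]]), connectivity=8)
        assert len(recs8) == 1

    def test_bar_1x3(self):
        recs = label_patches(make_grid([[1, 1, 1]]))
        assert len(recs) == 1
        assert recs[0].area == 3.0
        assert recs[0].perimeter == 8.0
        assert recs[0].shape_index == pytest.approx(8 / (4 * math.sqrt(3)))

    def test_touching_patches_of_different_species_stay_separate(self):
        recs = label_patches(make_grid([[1, 2], [1, 2]]))
        assert as_multiset(recs) == [(1, 2.0, 6.0), (2, 2.0, 6.0)]

    def test_empty_grid_gives_empty_list(self):
        assert label_patches(make_grid([[0, 0], [0, 0]])) == []

    @settings(max_examples=60, deadline=None)
    @given(arrays(np.int64, (12, 12), elements=st.integers(0, 3)))
    def test_matches_brute_force_oracle_on_random_grids(self, values):
        got = as_multiset(label_patches(make_grid(values)))
        want = sorted((c, float(a), float(p)) for c, a, p in bfs_patches(values))
        assert got == want

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.int64, (9, 7), elements=st.integers(0, 3)))
    def test_invariant_under_rotation_and_mirroring(self, values):
        base = as_multiset(label_patches(make_grid(values)))
        for transform in (np.rot90, np.fliplr, np.flipud):
            assert as_multiset(label_patches(make_grid(transform(values)))) == base

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.int64, (10, 10), elements=st.integers(0, 4)))
    def test_total_patch_area_equals_nonzero_cell_count(self, values):
        recs = label_patches(make_grid(values))
        assert sum(p.area for p in recs) == float((values != 0).sum())


class TestShapeIndex:
    @pytest.mark.parametrize(
        "area, perimeter, expected",
        [(4, 8, 1.0), (3, 8, 8 / (4 * math.sqrt(3))), (25, 20, 1.0), (100, 40, 1.0)],
    )
    def test_known_shapes(self, area, perimeter, expected):
        assert shape_index(area, perimeter) == pytest.approx(expected)

    def test_scale_free_in_cell_size(self):
        # a 2x2-cell square of 0.5 cm cells: area 1 cm^2, perimeter 4 cm
        assert shape_index(1.0, 4.0, cell_size=0.5) == pytest.approx(1.0)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(DegenerateInputError):
            shape_index(0, 8)
        with pytest.raises(DegenerateInputError):
            shape_index(4, -1)


def _patch(species, area, perimeter, plot="p1"):
    return PatchRecord(plot, species, float(area), float(perimeter),
                       shape_index(area, perimeter))


class TestPlotMetrics:
    def test_single_patch_has_zero_pscv(self):
        rec = plot_metrics([_patch(1, 9, 12)])
        assert rec.PSCV == 0.0
        assert rec.NP == 1 and rec.PR == 1

    def test_single_species_has_zero_shdi(self):
        rec = plot_metrics([_patch(1, 4, 8), _patch(1, 16, 16)])
        assert rec.SHDI == 0.0

    def test_two_species_equal_areas_give_ln2(self):
        rec = plot_metrics([_patch(1, 10, 14), _patch(2, 10, 14)])
        assert rec.SHDI == pytest.approx(math.log(2))

    def test_mps_times_np_is_total_vegetated_area(self):
        patches = [_patch(1, 4, 8), _patch(2, 9, 12), _patch(1, 1, 4)]
        rec = plot_metrics(patches)
        assert rec.MPS * rec.NP == pytest.approx(sum(p.area for p in patches))
        assert rec.TE == pytest.approx(sum(p.perimeter for p in patches))

    def test_shdi_bounded_by_log_richness(self, rng):
        for _ in range(20):
            patches = [
                _patch(int(s), int(a), 4 * int(math.ceil(math.sqrt(a))) * 2)
                for s, a in zip(rng.integers(1, 5, 8), rng.integers(1, 50, 8))
            ]
            rec = plot_metrics(patches)
            assert rec.SHDI <= math.log(rec.PR) + 1e-12

    def test_empty_plot_is_a_defined_record(self):
        rec = plot_metrics([], plot_id="empty")
        assert rec.NP == 0 and rec.PR == 0
        assert math.isnan(rec.MPS) and math.isnan(rec.SHDI)


class TestSpeciesMetrics:
    def test_identical_patches_aggregate_exactly(self):
        patches = [_patch(1, 7, 16, plot=f"p{i}") for i in range(3)]
        out = species_metrics(patches, n_plots=4)
        row = out.loc[1]
        assert row["MPS"] == 7.0
        assert row["MPS_sd"] == 0.0
        assert row["CA"] == 21.0
        assert row["NP"] == 3
        assert row["frequency"] == pytest.approx(75.0)

    def test_single_patch_species(self):
        out = species_metrics([_patch(2, 11, 14)], n_plots=46)
        row = out.loc[2]
        assert row["MPS"] == 11.0 and row["CA"] == 11.0 and row["NP"] == 1
        assert math.isnan(row["MPS_sd"])


class TestDistributionSummary:
    def test_symmetric_sample_has_zero_skewness(self):
        out = distribution_summary([1.0, 2.0, 3.0])
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert out["median"] == 2.0 and out["max"] == 3.0

    def test_lognormal_sample_is_positively_skewed(self, rng):
        x = rng.lognormal(3.0, 1.0, size=2000)
        assert distribution_summary(x)["skewness"] > 0.5

    def test_type7_quartiles(self):
        out = distribution_summary([1.0, 2.0, 3.0, 4.0])
        assert out["q1"] == pytest.approx(1.75)
        assert out["q3"] == pytest.approx(3.25)

    def test_tiny_sample_flags_sd_and_skewness(self):
        out = distribution_summary([5.0])
        assert math.isnan(out["sd"]) and math.isnan(out["skewness"])


class TestMetricCorrelations:
    def test_duplicated_and_anticorrelated_columns(self):
        import pandas as pd

        R = pd.DataFrame({"a": [1.0, 2, 3, 4, 7], "b": [1.0, 2, 3, 4, 7]})
        R["c"] = -R["a"]
        r, p = metric_correlations(R)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)
        assert np.allclose(np.diag(r), 1.0)

    def test_matches_direct_formula_on_fixture(self, rng):
        import pandas as pd

        R = pd.DataFrame(rng.normal(size=(5, 3)), columns=["x", "y", "z"])
        r, _ = metric_correlations(R)
        for a in R.columns:
            for b in R.columns:
                xa, xb = R[a] - R[a].mean(), R[b] - R[b].mean()
                direct = (xa * xb).sum() / math.sqrt((xa**2).sum() * (xb**2).sum())
                assert r.loc[a, b] == pytest.approx(direct)

    def test_constant_column_is_flagged_missing(self):
        import pandas as pd

        R = pd.DataFrame({"a": [1.0, 2, 3], "k": [5.0, 5, 5]})
        r, p = metric_correlations(R)
        assert math.isnan(r.loc["a", "k"]) and math.isnan(p.loc["a", "k"])
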