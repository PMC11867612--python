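import itertools

import numpy as np
import pandas as pd
import pytest

from boutonmap.ephys import (
    compare_density_distributions,
    local_density,
    probability_vs_density,
    region_response_stats,
    validate_cells,
)
from boutonmap.quantify import VoxelGrid


def make_cells(responded, amplitudes=None, region="LC", sections=None, xy=None):
    responded = np.asarray(responded, dtype=bool)
    n = responded.size
    if amplitudes is None:
        amplitudes = np.where(responded, 100.0, 0.0)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "section_id": sections if sections is not None else 0,
            "x_um": xy[:, 0] if xy is not None else 10.0,
            "y_um": xy[:, 1] if xy is not None else 10.0,
            "region_id": region,
            "responded": responded,
            "amplitude_pa": np.asarray(amplitudes, dtype=float),
        }
    )
    return df


class TestRegionResponseStats:
    def test_lc_pooled_fraction_rounds_to_three_percent(self):
        # per-section counts: 0/27 anterior, 2/40 posterior
        responded = np.zeros(67, dtype=bool)
        responded[27:29] = True
        sections = np.array([0] * 27 + [1] * 40)
        cells = make_cells(responded, sections=sections)
        stats = region_response_stats(cells, by="region_id")
        frac = stats.loc[0, "fraction_responding"]
        assert round(100.0 * frac) == 3

    def test_mean_amplitude_conventions(self):
        cells = make_cells([False, False, True, True], amplitudes=[0, 0, 100, 300])
        s = region_response_stats(cells).iloc[0]
        assert s["mean_amplitude_all_pa"] == pytest.approx(100.0)
        assert s["mean_amplitude_responders_pa"] == pytest.approx(200.0)

    def test_no_responders_undefined_mean(self):
        cells = make_cells([False] * 23)
        s = region_response_stats(cells).iloc[0]
        assert s["fraction_responding"] == 0.0
        assert np.isnan(s["mean_amplitude_responders_pa"])

    def test_amplitude_identity(self):
        # mean_all = fraction × mean_responders when nonresponders are 0 pA
        rng = np.random.default_rng(0)
        responded = rng.random(50) < 0.4
        amps = np.where(responded, rng.lognormal(5, 1, 50), 0.0)
        s = region_response_stats(make_cells(responded, amps)).iloc[0]
        assert s["mean_amplitude_all_pa"] == pytest.approx(
            s["fraction_responding"] * s["mean_amplitude_responders_pa"]
        )

    def test_pooled_fraction_weighted_identity(self):
        responded = np.zeros(67, dtype=bool)
        responded[27:29] = True
        sections = np.array([0] * 27 + [1] * 40)
        cells = make_cells(responded, sections=sections)
        pooled = region_response_stats(cells, by=None).iloc[0]
        per_sec = region_response_stats(cells, by="section_id")
        weighted = (per_sec["fraction_responding"] * per_sec["n"]).sum() / per_sec["n"].sum()
        assert pooled["fraction_responding"] == pytest.approx(weighted)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_response_stats(make_cells([]).iloc[0:0])

    def test_validate_rejects_responder_mismatch(self):
        cells = make_cells([False], amplitudes=[5.0])
        with pytest.raises(ValueError, match="amplitude_pa"):
            validate_cells(cells)


class TestLocalDensity:
    GRID = VoxelGrid((0.0, 0.0, 0.0), (144.0, 144.0, 4.0),
                     np.arange(9, dtype=float).reshape(3, 3, 1) * 144 * 144)

    def test_voxel_center_lookup(self):
        cells = make_cells([True], xy=np.array([[72.0, 72.0]]))
        assert local_density(cells, self.GRID)[0] == pytest.approx(0.0)
        cells = make_cells([True], xy=np.array([[360.0, 216.0]]))
        # bin (2, 1) -> counts index [2,1,0] = 7 counts/bin-area
        assert local_density(cells, self.GRID)[0] == pytest.approx(7.0)

    def test_bin_edge_belongs_to_higher_bin(self):
        cells = make_cells([True], xy=np.array([[144.0, 0.0]]))
        # bin (1, 0) -> value 3
        assert local_density(cells, self.GRID)[0] == pytest.approx(3.0)

    def test_outside_grid_is_nan(self):
        cells = make_cells([True], xy=np.array([[-1.0, 0.0]]))
        assert np.isnan(local_density(cells, self.GRID)[0])

    def test_synthetic_cells_match_direct_lookup(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 3 * 144.0 - 1e-6, size=(200, 2))
        cells = make_cells(np.ones(200, bool), xy=xy)
        got = local_density(cells, self.GRID)
        idx = np.floor(xy / 144.0).astype(int)
        expected = self.GRID.density[idx[:, 0], idx[:, 1], 0]
        np.testing.assert_allclose(got, expected)


class TestProbabilityVsDensity:
    def test_all_responding_probability_one(self):
        cells = make_cells(np.ones(40, bool))
        dens = np.linspace(0, 1, 40)
        curve = probability_vs_density(cells, dens, n_bins=4)
        np.testing.assert_allclose(curve.probability, 1.0)
        assert (curve.ci_low <= curve.probability).all()
        assert (curve.probability <= curve.ci_high).all()

    def test_single_bin_reduces_to_fraction(self):
        responded = np.array([True] * 3 + [False] * 7)
        cells = make_cells(responded)
        dens = np.full(10, 0.5)
        curve = probability_vs_density(cells, dens, bin_edges=np.array([0.0, 1.0]))
        assert curve.probability.tolist() == [0.3]
        frac = region_response_stats(cells).iloc[0]["fraction_responding"]
        assert curve.probability[0] == pytest.approx(frac)

    def test_empty_bins_dropped(self):
        cells = make_cells([True, False])
        dens = np.array([0.05, 0.95])
        curve = probability_vs_density(
            cells, dens, bin_edges=np.array([0.0, 0.1, 0.5, 0.9, 1.0])
        )
        assert len(curve.n_cells) == 2

    def test_no_finite_densities_rejected(self):
        cells = make_cells([True])
        with pytest.raises(ValueError, match="finite"):
            probability_vs_density(cells, np.array([np.nan]))


class TestCompareDensityDistributions:
    def test_complete_separation_exhaustive_oracle(self):
        x = np.array([6.0, 7.0, 8.0, 9.0, 10.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        u, p = compare_density_distributions(x, y)
        assert u == 25.0
        # oracle: enumerate all C(10,5) label assignments of the pooled data;
        # no assignment attains a smaller two-sided p than complete separation
        pooled = np.concatenate([x, y])
        ps = []
        for combo in itertools.combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(combo)] = True
            ps.append(compare_density_distributions(pooled[mask], pooled[~mask])[1])
        assert p == pytest.approx(min(ps))

    def test_identical_multisets_p_one(self):
        vals = np.array([3.0, 3.0, 3.0, 3.0])
        u, p = compare_density_distributions(vals, vals)
        assert p == 1.0

    def test_shift_alternative_power(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(1.0, 1.0, size=100)
            b = rng.normal(0.0, 1.0, size=100)
            _, p = compare_density_distributions(a, b)
            hits += p < 0.05
        assert hits >= 90

    def test_permutation_agrees_with_normal_on_clear_effect(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.5, 1.0, size=40)
        b = rng.normal(0.0, 1.0, size=40)
        u_n, p_n = compare_density_distributions(a, b, method="normal")
        u_p, p_p = compare_density_distributions(a, b, method="permutation",
                                                 n_permutations=2000, seed=1)
        assert u_n == u_p
        assert p_n < 0.01 and p_p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_density_distributions(np.array([]), np.array([1.0]))
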