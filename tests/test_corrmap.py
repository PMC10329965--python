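"""Band-difference correlation maps: oracle equivalence, masking, hotspots."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from nicospec import (
    CorrelationMap,
    SpectraSet,
    Spectrum,
    apply_mask,
    band_difference_matrix,
    brute_force_map,
    correlation_map,
    critical_r,
    find_hotspot,
    per_group_maps,
    pvalues,
)
from nicospec.grid import WavelengthGrid


def _random_instance(seed, n=30, grid=None):
    g = grid or WavelengthGrid(400, 890, 10)
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.05, 0.95, size=(n, g.n_channels))
    conc = rng.lognormal(np.log(10_000), 0.7, size=n)
    return SpectraSet([f"s{i}" for i in range(n)], values, g), conc


class TestDifferenceMatrix:
    def test_hand_computed_entries(self):
        g = WavelengthGrid(400, 420, 10)
        d = band_difference_matrix(Spectrum("a", [0.10, 0.20, 0.40], g))
        assert d[0, 2] == pytest.approx(0.30)
        assert d[2, 0] == pytest.approx(-0.30)

    @given(seed=st.integers(0, 1000))
    def test_zero_diagonal_and_antisymmetry(self, seed):
        g = WavelengthGrid(400, 590, 10)
        rng = np.random.default_rng(seed)
        d = band_difference_matrix(Spectrum("a", rng.uniform(0, 1, 20), g))
        np.testing.assert_array_equal(np.diag(d), 0.0)
        np.testing.assert_array_equal(d, -d.T)


class TestPvalues:
    def test_limits(self):
        assert pvalues(0.0, 10) == pytest.approx(1.0)
        assert pvalues(1.0, 10) == 0.0
        assert pvalues(-1.0, 10) == 0.0

    def test_significance_boundary_at_n24(self):
        # two-sided t boundary at df=22 corresponds to |r| ~ 0.404
        assert pvalues(0.4044, 24) == pytest.approx(0.05, abs=2e-3)
        assert critical_r(24) == pytest.approx(0.4044, abs=2e-3)

    def test_critical_r_matches_t_quantile_oracle(self):
        for n in (10, 24, 69):
            r = critical_r(n)
            t = r * np.sqrt((n - 2) / (1 - r**2))
            assert 2 * stats.t.sf(t, n - 2) == pytest.approx(0.05, abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pvalues(0.5, 2)


class TestStreamingVsOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_on_seeded_instances(self, seed):
        spectra, conc = _random_instance(seed)
        fast = correlation_map(spectra, conc)
        slow = brute_force_map(spectra, conc)
        np.testing.assert_allclose(fast.r, slow.r, atol=1e-10, equal_nan=True)
        np.testing.assert_allclose(fast.p, slow.p, atol=1e-10, equal_nan=True)
        np.testing.assert_array_equal(fast.mask, slow.mask)

    def test_three_sample_hand_case(self):
        g = WavelengthGrid(400, 410, 10)
        spectra = SpectraSet(
            ["a", "b", "c"], np.array([[0.1, 0.2], [0.2, 0.4], [0.3, 0.6]]), g
        )
        m = brute_force_map(spectra, np.array([1.0, 2.0, 3.0]))
        assert m.r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_guard_refuses_large_grids(self):
        g = WavelengthGrid(350, 649, 1)  # 300 channels
        spectra = SpectraSet(
            ["a", "b", "c"], np.random.default_rng(0).uniform(0, 1, (3, 300)), g
        )
        with pytest.raises(ValueError, match="guard"):
            brute_force_map(spectra, np.array([1.0, 2.0, 3.0]))

    def test_spearman_matches_scipy(self):
        spectra, conc = _random_instance(3, n=12, grid=WavelengthGrid(400, 490, 10))
        m = correlation_map(spectra, conc, method="spearman")
        a, b = 2, 7
        d = spectra.values[:, b] - spectra.values[:, a]
        rho, p = stats.spearmanr(d, conc)
        assert m.r[a, b] == pytest.approx(rho, abs=1e-12)
        assert m.p[a, b] == pytest.approx(p, abs=1e-12)


class TestCorrelationMapProperties:
    def test_perfect_linear_dependence(self):
        g = WavelengthGrid(400, 420, 10)
        conc = np.array([1.0, 5.0, 9.0, 13.0])
        values = np.column_stack(
            [np.full(4, 0.3), 0.1 + 0.02 * conc, 0.9 - 0.01 * conc]
        )
        spectra = SpectraSet(["a", "b", "c", "d"], values, g)
        m = correlation_map(spectra, conc)
        assert m.r[0, 1] == pytest.approx(1.0, abs=1e-8)
        assert m.r[0, 2] == pytest.approx(-1.0, abs=1e-8)

    @given(seed=st.integers(0, 500))
    def test_exact_antisymmetry(self, seed):
        spectra, conc = _random_instance(seed, n=10, grid=WavelengthGrid(400, 590, 10))
        m = correlation_map(spectra, conc)
        defined = np.isfinite(m.r) & np.isfinite(m.r.T)
        np.testing.assert_array_equal(m.r[defined], -m.r.T[defined])

    @given(scale=st.floats(0.1, 1000.0), offset=st.floats(-0.2, 0.2))
    def test_scale_and_offset_invariance(self, scale, offset):
        spectra, conc = _random_instance(7, n=12, grid=WavelengthGrid(400, 490, 10))
        base = correlation_map(spectra, conc)
        scaled = correlation_map(spectra, conc * scale)
        np.testing.assert_allclose(scaled.r, base.r, atol=1e-10, equal_nan=True)
        shifted = SpectraSet(
            spectra.sample_ids, spectra.values + offset, spectra.grid
        )
        m2 = correlation_map(shifted, conc)
        np.testing.assert_allclose(m2.r, base.r, atol=1e-7, equal_nan=True)

    def test_constant_difference_cells_are_nan_and_masked(self):
        g = WavelengthGrid(400, 420, 10)
        rng = np.random.default_rng(1)
        col = rng.uniform(0, 1, 5)
        values = np.column_stack([col, col + 0.1, rng.uniform(0, 1, 5)])
        spectra = SpectraSet([f"s{i}" for i in range(5)], values, g)
        m = correlation_map(spectra, np.arange(5.0))
        assert np.isnan(m.r[0, 1]) and m.mask[0, 1]
        assert np.isnan(np.diag(m.r)).all() and m.mask.diagonal().all()

    def test_input_validation(self):
        spectra, conc = _random_instance(0, n=5, grid=WavelengthGrid(400, 440, 10))
        with pytest.raises(ValueError, match="concentrations"):
            correlation_map(spectra, conc[:-1])
        with pytest.raises(ValueError, match="constant"):
            correlation_map(spectra, np.full(5, 3.0))
        tiny = SpectraSet(spectra.sample_ids[:2], spectra.values[:2], spectra.grid)
        with pytest.raises(ValueError, match=">= 3"):
            correlation_map(tiny, conc[:2])


class TestMasking:
    def _map(self, p):
        p = np.asarray(p, dtype=float)
        g = WavelengthGrid(400, 400 + 10 * (p.shape[0] - 1), 10)
        r = np.where(np.isfinite(p), 0.5, np.nan)
        return CorrelationMap(
            r=r, p=p, mask=np.zeros_like(p, dtype=bool), n=10, grid=g
        )

    def test_all_insignificant_all_masked(self):
        m = apply_mask(self._map(np.ones((4, 4))))
        assert m.mask.all()

    def test_single_significant_pair_survives(self):
        p = np.ones((4, 4))
        p[1, 2] = p[2, 1] = 0.01
        m = apply_mask(self._map(p), alpha_level=0.05)
        expected = np.ones((4, 4), dtype=bool)
        expected[1, 2] = expected[2, 1] = False
        np.testing.assert_array_equal(m.mask, expected)

    def test_boundary_p_is_masked(self):
        p = np.full((3, 3), 0.05)  # p >= alpha is suppressed
        m = apply_mask(self._map(p), alpha_level=0.05)
        assert m.mask.all()

    def test_fdr_is_more_conservative(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.0, 0.2, (20, 20))
        p = (p + p.T) / 2
        per_cell = apply_mask(self._map(p), fdr=False)
        fdr = apply_mask(self._map(p), fdr=True)
        assert fdr.mask.sum() >= per_cell.mask.sum()
        # FDR mask stays symmetric
        np.testing.assert_array_equal(fdr.mask, fdr.mask.T)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            apply_mask(self._map(np.ones((3, 3))), alpha_level=1.5)


class TestHotspot:
    def test_single_unmasked_cell(self):
        g = WavelengthGrid(400, 420, 10)
        r = np.array([[np.nan, 0.9, 0.2], [-0.9, np.nan, 0.1], [-0.2, -0.1, np.nan]])
        p = np.where(np.isnan(r), np.nan, 0.01)
        mask = np.ones((3, 3), dtype=bool)
        mask[0, 1] = False
        m = CorrelationMap(r=r, p=p, mask=mask, n=10, grid=g)
        hs = find_hotspot(m)
        assert (hs.alpha_nm, hs.beta_nm, hs.r_value) == (400.0, 410.0, 0.9)

    def test_tie_broken_by_smaller_beta_then_alpha(self):
        g = WavelengthGrid(400, 420, 10)
        r = np.zeros((3, 3))
        r[2, 0] = 0.8   # beta=400
        r[0, 2] = -0.8  # beta=420
        p = np.full((3, 3), 0.01)
        mask = np.zeros((3, 3), dtype=bool)
        np.fill_diagonal(mask, True)
        m = CorrelationMap(r=r, p=p, mask=mask, n=10, grid=g)
        hs = find_hotspot(m)
        assert hs.beta_nm == 400.0 and hs.alpha_nm == 420.0

    def test_fully_masked_map_rejected(self):
        g = WavelengthGrid(400, 410, 10)
        m = CorrelationMap(
            r=np.zeros((2, 2)),
            p=np.ones((2, 2)),
            mask=np.ones((2, 2), dtype=bool),
            n=5,
            grid=g,
        )
        with pytest.raises(ValueError, match="masked"):
            find_hotspot(m)

    def test_noise_free_ni_band_cells_reach_unit_correlation(self, noise_free_hyper):
        """Linear dip depth, no noise: in-band vs out-of-band cells hit |r|=1."""
        spectra, meta = noise_free_hyper
        conc = meta["ni_conc"].to_numpy()
        m = correlation_map(spectra, conc)
        a = spectra.grid.nearest_channel(1600)  # out of every band's support
        b = spectra.grid.nearest_channel(1000)  # Ni band centre
        assert abs(m.r[a, b]) == pytest.approx(1.0, abs=1e-8)
        assert not m.mask[a, b]
        # with zero noise the global maximum |r| saturates at exactly 1
        hs = find_hotspot(m)
        assert abs(hs.r_value) == 1.0 and hs.p_value == 0.0


class TestPerGroupMaps:
    def _dataset(self):
        g = WavelengthGrid(400, 490, 10)
        rng = np.random.default_rng(5)
        n = 14
        spectra = SpectraSet(
            [f"s{i}" for i in range(n)], rng.uniform(0, 1, (n, 10)), g
        )
        meta = pd.DataFrame(
            {
                "sample_id": spectra.sample_ids,
                "species": ["sp1"] * 6 + ["sp2"] * 6 + ["sp3"] * 2,
                "state": ["hydrated"] * n,
                "ni_conc": rng.lognormal(8, 0.5, n),
                "method": ["synthetic"] * n,
            }
        )
        return spectra, meta

    def test_one_map_per_viable_group(self, caplog):
        spectra, meta = self._dataset()
        with caplog.at_level("WARNING"):
            maps = per_group_maps(spectra, meta)
        assert len(maps) == 2  # sp3 skipped: only 2 samples
        assert any("skipped" in r.message for r in caplog.records)
        for m in maps.values():
            assert m.n == 6

    def test_constant_conc_group_skipped(self, caplog):
        spectra, meta = self._dataset()
        meta.loc[meta["species"] == "sp1", "ni_conc"] = 500.0
        with caplog.at_level("WARNING"):
            maps = per_group_maps(spectra, meta)
        assert len(maps) == 1

    def test_small_group_uses_correct_unmask_boundary(self):
        """n=24 group: cells unmask exactly where |r| exceeds ~0.404."""
        g = WavelengthGrid(400, 490, 10)
        rng = np.random.default_rng(8)
        spectra = SpectraSet(
            [f"s{i}" for i in range(24)], rng.uniform(0, 1, (24, 10)), g
        )
        conc = rng.lognormal(8, 0.6, 24)
        m = correlation_map(spectra, conc)
        rc = critical_r(24)
        off_diag = ~np.eye(10, dtype=bool)
        unmasked = ~m.mask & off_diag
        assert np.all(np.abs(m.r[unmasked]) > rc - 1e-12)
        masked_defined = m.mask & off_diag & np.isfinite(m.r)
        assert np.all(np.abs(m.r[masked_defined]) < rc + 1e-12)
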