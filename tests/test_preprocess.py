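"""Referencing, bucketing, water exclusion and Pareto scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrstrat.preprocess import (BucketGrid, BucketTable, bucket,
                                 bucket_spectra, exclude_water, pareto_scale,
                                 reference_to_alanine)
from nmrstrat.spectra import Spectrum
from nmrstrat.synth import generate_spectrum


def _flat_spectrum(value=0.0, n=12000, ppm_max=9.2, ppm_min=0.3):
    ppm = np.linspace(ppm_max, ppm_min, n)
    return Spectrum(ppm, np.full(n, float(value)))


class TestReferencing:
    def _doublet_spectrum(self, center):
        ppm = np.linspace(2.0, 1.0, 8000)
        j = 7.0 / 400.0
        y = np.exp(-0.5 * ((ppm - center + j / 2) / 0.002) ** 2)
        y += np.exp(-0.5 * ((ppm - center - j / 2) / 0.002) ** 2)
        return Spectrum(ppm, y)

    @pytest.mark.parametrize("planted,expected_shift", [
        (1.52, -0.02),
        (1.50, 0.00),
    ])
    def test_doublet_shifted_to_target(self, planted, expected_shift):
        s = self._doublet_spectrum(planted)
        out = reference_to_alanine(s, (1.3, 1.7), target=1.50)
        assert out.referenced
        np.testing.assert_allclose(out.ppm - s.ppm, expected_shift, atol=3e-4)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_flat_spectrum_flagged_and_unshifted(self):
        s = _flat_spectrum(1.0)
        with pytest.warns(UserWarning, match="flat"):
            out = reference_to_alanine(s, (1.3, 1.7))
        assert out.reference_failed and not out.referenced
        np.testing.assert_array_equal(out.ppm, s.ppm)

    def test_competing_lactate_doublet_does_not_hijack(self):
        # strong doublet at 1.33 (lactate-like) + weaker one at 1.49
        ppm = np.linspace(2.0, 1.0, 8000)
        j = 7.0 / 400.0

        def doublet(center, amp):
            return amp * (np.exp(-0.5 * ((ppm - center + j / 2) / 0.002) ** 2)
                          + np.exp(-0.5 * ((ppm - center - j / 2) / 0.002) ** 2))

        s = Spectrum(ppm, doublet(1.33, 10.0) + doublet(1.49, 1.0))
        out = reference_to_alanine(s, (1.3, 1.7), target=1.48)
        np.testing.assert_allclose(out.ppm - s.ppm, -0.01, atol=3e-4)


class TestBucketing:
    def test_default_grid_has_4250_buckets(self):
        assert BucketGrid().n_buckets == 4250

    def test_constant_spectrum_buckets_equal_count_times_value(self):
        # 4 points per bucket exactly: points at bucket centers +- offsets
        grid = BucketGrid(upper=2.0, lower=1.0, width=0.01, exclusions=())
        edges = grid.edges
        pts = []
        for i in range(grid.n_buckets):
            hi, lo = edges[i], edges[i + 1]
            pts.extend(np.linspace(hi - 1e-4, lo + 1e-4, 4))
        ppm = np.array(sorted(set(pts), reverse=True))
        s = Spectrum(np.concatenate([[2.5], ppm, [0.5]]),
                     np.concatenate([[0.0], np.full(ppm.size, 3.0), [0.0]]))
        vals = bucket(s, grid)
        np.testing.assert_allclose(vals, 12.0)

    def test_single_point_lands_in_exactly_one_bucket(self):
        # brute-force interval membership oracle over all buckets
        grid = BucketGrid(exclusions=())
        rng = np.random.default_rng(4)
        for ppm0 in rng.uniform(0.51, 8.99, 25):
            ppm = np.array([9.25, ppm0, 0.25])
            s = Spectrum(ppm, np.array([0.0, 5.0, 0.0]))
            vals = bucket(s, grid)
            nz = np.flatnonzero(vals)
            assert nz.size == 1
            edges = grid.edges
            expected = [i for i in range(grid.n_buckets)
                        if edges[i + 1] < ppm0 <= edges[i]]
            assert nz.tolist() == expected

    def test_spectrum_not_covering_grid_rejected(self):
        s = _flat_spectrum(1.0, ppm_max=8.0)
        with pytest.raises(ValueError, match="cover"):
            bucket(s, BucketGrid())

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_bucket_sum_conserves_total_intensity(self, seed):
        """Sum over an unmasked grid equals the raw sum inside (0.5, 9.0]."""
        rng = np.random.default_rng(seed)
        ppm = np.sort(rng.uniform(0.3, 9.2, 3000))[::-1]
        y = rng.normal(size=3000)
        s = Spectrum(ppm, y)
        grid = BucketGrid(exclusions=())
        inside = (ppm > 0.5) & (ppm <= 9.0)
        np.testing.assert_allclose(bucket(s, grid).sum(), y[inside].sum(),
                                   rtol=1e-9, atol=1e-9)

    def test_exclusion_commutes_with_bucketing_for_aligned_windows(self):
        # zeroing raw points inside an edge-aligned window, then bucketing,
        # equals bucketing then masking those buckets
        rng = np.random.default_rng(8)
        ppm = np.linspace(9.25, 0.25, 9000)
        y = rng.normal(size=9000) ** 2
        s = Spectrum(ppm, y)
        grid = BucketGrid(exclusions=())
        window = (4.38, 5.15)  # aligned: both are multiples of 0.002 from 9.0
        table = exclude_water(bucket_spectra([s], grid), window)
        y2 = y.copy()
        y2[(ppm > window[0]) & (ppm <= window[1])] = 0.0
        vals2 = bucket(Spectrum(ppm, y2), grid)
        keep = table.mask
        np.testing.assert_allclose(table.matrix[0][keep], vals2[keep])
        assert np.all(vals2[~keep] == 0.0)


class TestWaterExclusion:
    def test_default_window_removes_385_of_4250(self):
        s = _flat_spectrum(1.0)
        table = bucket_spectra([s], BucketGrid(exclusions=()))
        out = exclude_water(table, (4.38, 5.15))
        # brute-force count oracle over bucket centers
        centers = table.centers
        expected = int(((centers >= 4.38) & (centers <= 5.15)).sum())
        assert expected == 385
        assert out.n_retained == 4250 - 385 == 3865
        assert not np.any((out.retained_centers >= 4.38)
                          & (out.retained_centers <= 5.15))

    def test_window_outside_grid_is_noop(self):
        s = _flat_spectrum(1.0, ppm_max=9.6)
        table = bucket_spectra([s], BucketGrid(exclusions=()))
        out = exclude_water(table, (9.2, 9.4))
        assert out.n_retained == table.n_retained

    def test_whole_grid_window_leaves_nothing_and_fit_refuses(self):
        from nmrstrat.oplsda import fit_oplsda

        s = _flat_spectrum(1.0)
        table = exclude_water(bucket_spectra([s, s], BucketGrid(exclusions=())),
                              (0.5, 9.0))
        assert table.n_retained == 0
        with pytest.raises(ValueError):
            fit_oplsda(table.values, np.array(["pre", "post"]), n_orth=0)


class TestParetoScaling:
    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.ones(3), np.array([1.0, 2.0, 3.0])])
        out = pareto_scale(X)
        np.testing.assert_array_equal(out[:, 0], 0.0)

    def test_scaling_divides_by_sqrt_of_sd(self):
        col = np.array([0.0, 8.0])  # sd (ddof=1) = sqrt(32) -> no; use known
        X = np.array([[0.0], [4.0], [8.0]])  # sd = 4
        out = pareto_scale(X)
        np.testing.assert_allclose(out[:, 0], np.array([-4.0, 0.0, 4.0]) / 2.0)

    def test_column_means_are_zero(self):
        rng = np.random.default_rng(0)
        out = pareto_scale(rng.normal(size=(20, 7)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            pareto_scale(np.ones((1, 5)))
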