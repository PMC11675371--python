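"""Kernel, density curves, edge correction, delta and region calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senscan._errors import ConfigError, RangeError
from senscan.io import VariantTable
from senscan.tolerance import (
    KernelConfig,
    call_sensitive_regions,
    delta_profile,
    density_curve,
    gaussian_window_kernel,
    normalize_pair,
    tolerance_profile,
)
from senscan.variant_model import SourceLabel

from conftest import brute_force_curve, make_missense, table_at


class TestKernel:
    def test_default_window_sums_to_one(self):
        k = gaussian_window_kernel(KernelConfig())
        assert len(k) == 31
        assert abs(k.sum() - 1.0) < 1e-12

    def test_window_one_is_identity(self):
        assert gaussian_window_kernel(KernelConfig(window=1)).tolist() == [1.0]

    def test_symmetric_and_unimodal(self):
        k = gaussian_window_kernel(KernelConfig(window=31))
        center = 15
        for off in range(1, 16):
            assert k[center + off] == pytest.approx(k[center - off], abs=1e-15)
        assert k.argmax() == center
        assert all(k[i] >= k[i + 1] for i in range(center, 30))

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            KernelConfig(window=30)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ConfigError):
            KernelConfig(window=31, sigma=0.0)


class TestDensityCurve:
    def test_no_variants_gives_zero_curve(self):
        curve = density_curve(table_at([]), 100)
        assert not curve.values.any()

    def test_single_interior_impulse_peaks_at_variant(self):
        cfg = KernelConfig()
        curve = density_curve(table_at([100]), 200, cfg)
        kernel = gaussian_window_kernel(cfg)
        assert curve.values.argmax() == 99
        assert curve.values[99] == pytest.approx(kernel[cfg.half_width], abs=1e-12)

    def test_uniform_density_is_flat_after_edge_correction(self):
        curve = density_curve(table_at(range(1, 201)), 200)
        assert curve.values.max() - curve.values.min() < 1e-10

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            L = int(rng.integers(40, 2000))
            n = int(rng.integers(0, min(L, 500)))
            positions = sorted(set(rng.integers(1, L + 1, size=n).tolist()))
            curve = density_curve(table_at(positions), L)
            expected = brute_force_curve(positions, L)
            assert np.abs(curve.values - np.array(expected)).max() < 1e-10

    def test_shift_equivariance_away_from_edges(self):
        positions = [80, 85, 90]
        shift = 20
        a = density_curve(table_at(positions), 300).values
        b = density_curve(table_at([p + shift for p in positions]), 300).values
        interior = slice(40, 200)
        assert np.allclose(a[interior], b[interior.start + shift : interior.stop + shift], atol=1e-12)

    def test_edge_flags_cover_half_window(self):
        curve = density_curve(table_at([]), 100, KernelConfig(window=31))
        assert curve.edge_flag[:15].all() and curve.edge_flag[-15:].all()
        assert not curve.edge_flag[15:-15].any()

    def test_out_of_range_variant_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="beyond protein length"):
            curve = density_curve(table_at([50, 500]), 100)
        assert list(curve.positions) == [50]

    def test_mask_drops_variants_and_flags_residues(self):
        curve = density_curve(table_at([50, 170]), 300, mask=[(160, 180)])
        assert list(curve.positions) == [50]
        assert curve.masked[159:180].all()
        assert not curve.masked[:159].any()

    def test_non_missense_filtered_out(self):
        from senscan.variant_model import parse_hgvs_p

        records = [parse_hgvs_p("p.L25*", gene="G"), parse_hgvs_p("p.A50C", gene="G")]
        curve = density_curve(VariantTable(records, SourceLabel.CLINICAL), 100)
        assert list(curve.positions) == [50]


class TestNormalizeAndDelta:
    def test_both_maxima_scaled_to_one(self):
        c = density_curve(table_at([50] * 1), 200)
        p = density_curve(table_at([150, 151, 152], SourceLabel.POPULATION), 200)
        cn, pn = normalize_pair(c, p)
        assert cn.max() == pytest.approx(1.0)
        assert pn.max() == pytest.approx(1.0)

    def test_zero_clinical_curve_passes_through(self):
        c = density_curve(table_at([]), 200)
        p = density_curve(table_at([100], SourceLabel.POPULATION), 200)
        cn, pn = normalize_pair(c, p)
        assert not cn.any()
        assert pn.max() == pytest.approx(1.0)

    def test_normalization_idempotent(self):
        c = density_curve(table_at([50]), 200)
        p = density_curve(table_at([150], SourceLabel.POPULATION), 200)
        cn, pn = normalize_pair(c, p)
        c.values, p.values = cn, pn
        cn2, pn2 = normalize_pair(c, p)
        assert np.array_equal(cn, cn2) and np.array_equal(pn, pn2)

    def test_length_mismatch_is_error(self):
        c = density_curve(table_at([]), 100)
        p = density_curve(table_at([], SourceLabel.POPULATION), 101)
        with pytest.raises(ValueError):
            normalize_pair(c, p)
        with pytest.raises(ValueError):
            delta_profile(np.zeros(100), np.zeros(101))

    def test_identical_variant_sets_cancel(self):
        positions = [30, 60, 90]
        prof = tolerance_profile(
            table_at(positions), table_at(positions, SourceLabel.POPULATION), 150
        )
        assert np.abs(prof.delta).max() < 1e-12
        assert prof.regions == []

    def test_empty_clinical_gives_nonnegative_delta(self):
        prof = tolerance_profile(
            table_at([]), table_at([75], SourceLabel.POPULATION), 150
        )
        assert (prof.delta >= 0).all()
        assert np.array_equal(prof.delta, prof.population_norm)

    def test_two_impulse_toy_signs(self):
        """Clinical at 50 and population at 150 give delta < 0 around 50
        and > 0 around 150 (oracle-confirmed window behaviour)."""
        prof = tolerance_profile(
            table_at([50]), table_at([150], SourceLabel.POPULATION), 200
        )
        assert (prof.delta[50 - 15 - 1 : 50 + 15] < 0).all()
        assert (prof.delta[150 - 15 - 1 : 150 + 15] > 0).all()
        expected_c = np.array(brute_force_curve([50], 200))
        expected_p = np.array(brute_force_curve([150], 200))
        expected = expected_p / expected_p.max() - expected_c / expected_c.max()
        assert np.abs(prof.delta - expected).max() < 1e-10

    def test_antisymmetry_under_source_swap(self):
        a_pos, b_pos = [40, 45, 200], [90, 140, 141]
        fwd = tolerance_profile(table_at(a_pos), table_at(b_pos, SourceLabel.POPULATION), 250)
        rev = tolerance_profile(table_at(b_pos), table_at(a_pos, SourceLabel.POPULATION), 250)
        assert np.abs(fwd.delta + rev.delta).max() < 1e-12


class TestRegionCalling:
    def test_zero_delta_calls_nothing(self):
        prof = tolerance_profile(table_at([]), table_at([], SourceLabel.POPULATION), 100)
        assert call_sensitive_regions(prof) == []

    def test_single_cluster_yields_one_region_containing_center(self):
        prof = tolerance_profile(
            table_at([98, 100, 100, 102]), table_at([], SourceLabel.POPULATION), 400
        )
        regions = prof.regions
        assert len(regions) == 1
        assert regions[0].contains(100)
        assert regions[0].n_clinical == 3  # dedup: two A→C at 100 collapse
        assert regions[0].min_delta < 0

    def test_two_far_clusters_yield_two_regions(self):
        prof = tolerance_profile(
            table_at([100, 300]), table_at([], SourceLabel.POPULATION), 400
        )
        regions = prof.regions
        assert len(regions) == 2
        assert regions[0].contains(100) and regions[1].contains(300)
        assert regions[0].end < regions[1].start

    def test_regions_are_maximal_negative_runs(self):
        prof = tolerance_profile(
            table_at([100]), table_at([160], SourceLabel.POPULATION), 300
        )
        for r in prof.regions:
            assert (prof.delta[r.start - 1 : r.end] < 0).all()
            if r.start > 1:
                assert prof.delta[r.start - 2] >= 0
            if r.end < len(prof.delta):
                assert prof.delta[r.end] >= 0

    def test_min_length_filters_short_runs(self):
        prof = tolerance_profile(
            table_at([100]), table_at([115], SourceLabel.POPULATION), 300
        )
        all_regions = call_sensitive_regions(prof, min_length=1)
        long_regions = call_sensitive_regions(prof, min_length=10)
        assert len(long_regions) <= len(all_regions)
        assert all(r.length >= 10 for r in long_regions)

    def test_edge_region_annotated_low_confidence_not_removed(self):
        # a protein shorter than the window is edge-flagged end to end,
        # so any region called on it rests entirely on partial windows
        prof = tolerance_profile(
            table_at([10]), table_at([], SourceLabel.POPULATION), 20
        )
        assert prof.edge_flag.all()
        regions = call_sensitive_regions(prof, ignore_edges=True)
        assert regions, "the cluster must still be called, not dropped"
        assert all(r.low_confidence for r in regions)
        # without the flag the same regions come back full-confidence
        assert all(not r.low_confidence for r in call_sensitive_regions(prof))

    def test_per_source_mask_excludes_population_only(self):
        mask = {"population": [(160, 205)]}
        prof = tolerance_profile(
            table_at([170]), table_at([170, 300], SourceLabel.POPULATION), 400, mask=mask
        )
        assert 170 in prof.clinical_positions
        assert 170 not in prof.population_positions
        assert prof.masked[169]


@given(
    st.lists(st.integers(min_value=1, max_value=300), max_size=12),
    st.lists(st.integers(min_value=1, max_value=300), max_size=12),
)
@settings(max_examples=25, deadline=None)
def test_antisymmetry_property(a_pos, b_pos):
    fwd = tolerance_profile(table_at(a_pos), table_at(b_pos, SourceLabel.POPULATION), 300)
    rev = tolerance_profile(table_at(b_pos), table_at(a_pos, SourceLabel.POPULATION), 300)
    assert np.abs(fwd.delta + rev.delta).max() < 1e-12
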