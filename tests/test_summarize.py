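"""Hierarchical order summaries, rho variability, profiles, group tests."""

import numpy as np
import pytest

from actinorder.masking import ActinMask
from actinorder.polarimetry import OrderMaps
from actinorder.summarize import (
    axial_circular_sd,
    compare_groups,
    image_mean_psi,
    longitudinal_order_profile,
    rho_variability,
    summarize_order,
)


def order_from(psi, rho=None, pixel_size=154.0):
    psi = np.asarray(psi, dtype=float)
    rho = np.zeros_like(psi) if rho is None else np.asarray(rho, dtype=float)
    return OrderMaps(
        rho=rho, psi=psi, valid=np.ones(psi.shape, bool),
        clipped=np.zeros(psi.shape, bool), pixel_size=pixel_size,
    )


def full_mask(shape):
    return ActinMask(mask=np.ones(shape, bool), smoothing_scale=2.0, threshold=1.0)


class TestSummarizeOrder:
    def test_constant_field_propagates_through_hierarchy(self):
        shape = (16, 16)
        images = [(order_from(np.full(shape, 129.0)), full_mask(shape))] * 4
        s = summarize_order(images, ["h0", "h0", "h1", "h1"], psi_ref=129.0)
        assert np.allclose(s.per_image["psi"], 129.0)
        assert np.allclose(s.per_hemithorax["psi"], 129.0)
        assert s.population_mean == pytest.approx(129.0)
        assert s.delta_psi == pytest.approx(0.0)

    def test_population_mean_is_mean_of_hemithorax_means(self):
        shape = (8, 8)
        images = [
            (order_from(np.full(shape, 130.0)), full_mask(shape)),
            (order_from(np.full(shape, 140.0)), full_mask(shape)),
        ]
        s = summarize_order(images, ["a", "b"])
        assert s.population_mean == pytest.approx(135.0)

    def test_delta_psi_arithmetic_for_early_myotubes(self):
        """Population mean 163 deg against the 129-deg mature reference -> 34."""
        shape = (8, 8)
        images = [(order_from(np.full(shape, 163.0)), full_mask(shape))]
        s = summarize_order(images, ["h0"], psi_ref=129.0)
        assert s.delta_psi == pytest.approx(34.0)

    def test_delta_psi_linear_in_reference(self):
        shape = (8, 8)
        images = [(order_from(np.full(shape, 150.0)), full_mask(shape))]
        a = summarize_order(images, ["h"], psi_ref=129.0)
        b = summarize_order(images, ["h"], psi_ref=139.0)
        assert a.delta_psi - b.delta_psi == pytest.approx(10.0)

    def test_empty_mask_image_excluded_with_warning(self, caplog):
        shape = (8, 8)
        empty = ActinMask(mask=np.zeros(shape, bool), smoothing_scale=2.0, threshold=1.0)
        images = [
            (order_from(np.full(shape, 140.0)), full_mask(shape)),
            (order_from(np.full(shape, 100.0)), empty),
        ]
        with caplog.at_level("WARNING"):
            s = summarize_order(images, ["h0", "h0"])
        assert len(s.per_image) == 1
        assert "empty mask" in caplog.text

    def test_intensity_weighted_option(self):
        shape = (2, 2)
        order = order_from(np.array([[100.0, 200.0], [100.0, 200.0]]))
        w = np.array([[1.0, 3.0], [1.0, 3.0]])
        assert image_mean_psi(order, full_mask(shape)) == pytest.approx(150.0)
        assert image_mean_psi(order, full_mask(shape), intensity=w) == pytest.approx(175.0)


class TestRhoVariability:
    def test_constant_field_has_zero_sd(self):
        order = order_from(np.full((64, 64), 130.0), rho=np.full((64, 64), 42.0))
        res = rho_variability(order, full_mask((64, 64)), window=9)
        assert res.per_image_mean == pytest.approx(0.0, abs=1e-9)

    def test_wrap_safety_under_global_rotation(self):
        rng = np.random.default_rng(8)
        rho = np.mod(rng.normal(0.0, 10.0, (80, 80)), 180.0)  # straddles 0/180
        o1 = order_from(np.full(rho.shape, 130.0), rho=rho)
        o2 = order_from(np.full(rho.shape, 130.0), rho=np.mod(rho + 90.0, 180.0))
        r1 = rho_variability(o1, full_mask(rho.shape), window=65)
        r2 = rho_variability(o2, full_mask(rho.shape), window=65)
        assert abs(r1.per_image_mean - r2.per_image_mean) < 1e-6

    def test_axial_mixture_of_1_and_179_is_tight(self):
        rho = np.where(np.arange(64 * 64).reshape(64, 64) % 2 == 0, 1.0, 179.0)
        sd = axial_circular_sd(rho)
        assert sd < 1.5  # same axis, not ~89 deg apart

    def test_matches_analytic_circular_sd_of_wrapped_normal(self):
        """i.i.d. axial angles with doubled-angle dispersion sigma2 have
        expected axial circular SD sigma2/2 (E[Rbar] = exp(-sigma2^2/2))."""
        rng = np.random.default_rng(12)
        sigma2 = np.deg2rad(20.0)
        rho = np.mod(np.rad2deg(0.5 * rng.normal(0.3, sigma2, (120, 120))), 180.0)
        order = order_from(np.full(rho.shape, 130.0), rho=rho)
        res = rho_variability(order, full_mask(rho.shape), window=65)
        expected = np.rad2deg(sigma2) / 2.0
        assert res.per_image_mean == pytest.approx(expected, rel=0.05)

    def test_even_window_rejected(self):
        order = order_from(np.full((8, 8), 130.0))
        with pytest.raises(ValueError):
            rho_variability(order, full_mask((8, 8)), window=8)


class TestLongitudinalProfile:
    def _line(self, shape, px=0.154):
        y = shape[0] / 2 * px
        return np.array([[0.5, y], [(shape[1] - 1) * px - 0.5, y]])

    def test_uniform_field_yields_flat_profile(self):
        rng = np.random.default_rng(4)
        shape = (64, 256)
        psi = 140.0 + rng.normal(0, 0.8, shape)  # acquisition-level noise
        order = order_from(psi)
        tables = longitudinal_order_profile(order, full_mask(shape), [self._line(shape)])
        prof = tables[0]["psi_rel"].to_numpy()
        assert np.ptp(prof[np.isfinite(prof)]) < 4.0

    def test_gradient_recovered(self):
        shape = (64, 256)
        ramp = np.linspace(130.0, 140.0, shape[1])
        order = order_from(np.tile(ramp, (shape[0], 1)))
        tables = longitudinal_order_profile(order, full_mask(shape), [self._line(shape)])
        psi = tables[0]["psi"].to_numpy()
        assert psi[-1] - psi[0] == pytest.approx(10.0, abs=1.0)

    def test_relative_profile_averages_to_zero(self):
        shape = (32, 128)
        rng = np.random.default_rng(9)
        order = order_from(135 + rng.normal(0, 2, shape))
        tables = longitudinal_order_profile(order, full_mask(shape), [self._line(shape)])
        rel = tables[0]["psi_rel"].to_numpy()
        assert np.nanmean(rel) == pytest.approx(0.0, abs=1e-9)

    def test_empty_bins_interpolated_and_flagged(self):
        shape = (32, 128)
        mask = np.ones(shape, bool)
        mask[:, 40:60] = False  # hole along the line
        am = ActinMask(mask=mask, smoothing_scale=2.0, threshold=1.0)
        order = order_from(np.full(shape, 135.0))
        tables = longitudinal_order_profile(order, am, [self._line(shape)], bin_um=1.0)
        t = tables[0]
        assert t["interpolated"].any()
        assert np.isfinite(t["psi"]).all()


class TestCompareGroups:
    def test_identical_groups_no_evidence(self):
        rep = compare_groups({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]})
        assert rep["p_value"] > 0.5

    def test_separated_groups_exact_u_distribution(self):
        """Complete separation of 3 vs 3: U = 0 and exact two-sided p = 2/20."""
        rep = compare_groups({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        assert rep["statistic"] == 0.0
        assert rep["p_value"] == pytest.approx(0.1)

    def test_paired_zero_differences_convention(self):
        rep = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, paired=True)
        assert rep["p_value"] == 1.0
        assert rep.get("zero_differences")

    def test_paired_wilcoxon_runs(self):
        rep = compare_groups(
            {"a": [1.0, 2.0, 3.0, 4.0, 6.0], "b": [2.0, 3.0, 5.0, 6.0, 7.0]}, paired=True
        )
        assert rep["test"] == "wilcoxon_signed_rank"
        assert 0.0 < rep["p_value"] <= 1.0

    def test_underpowered_groups_report_no_p(self):
        rep = compare_groups({"a": [1.0, 2.0], "b": [4.0, 5.0, 6.0]})
        assert rep["underpowered"] and rep["p_value"] is None

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0]}, paired=True)
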