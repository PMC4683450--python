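"""Density-of-states thermodynamics: reweighting, transition location,
landscapes, confinement free energy, unit mapping."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slitperm import (
    ConventionMismatchError,
    ModelParams,
    WindowError,
    barrier,
    confinement_free_energy,
    critical_slit_height,
    find_critical_epsilon,
    fluctuation_curve,
    landscape,
    phase_map,
    reweight,
    transition_summary,
    two_state_table,
    unit_mapping,
)
from slitperm.dos import DoSTable
from slitperm.thermo import ThermoCurve, probabilities

from conftest import exact_table

TWO_STATE_FWHM_10 = 2.0 * math.log(3.0 + 2.0 * math.sqrt(2.0)) / 10.0


def make_table(nc, log_g, nm=64, **kwargs):
    return DoSTable(
        params=ModelParams(nm),
        nc=np.asarray(nc, dtype=np.int64),
        log_g=np.asarray(log_g, dtype=np.float64),
        provenance="analytic",
        **kwargs,
    )


@st.composite
def random_tables(draw):
    n = draw(st.integers(2, 12))
    nc = np.sort(
        np.asarray(
            draw(
                st.lists(
                    st.integers(0, 40), min_size=n, max_size=n, unique=True
                )
            )
        )
    )
    log_g = np.asarray(
        draw(
            st.lists(
                st.floats(-20, 20, allow_nan=False), min_size=n, max_size=n
            )
        )
    )
    return make_table(nc, log_g)


class TestReweight:
    def test_symmetric_two_level_system(self):
        toy = two_state_table(0.0, 1)
        mean, var = reweight(toy, 0.0)
        assert (mean, var) == pytest.approx((0.5, 0.25))

    def test_strong_attraction_saturates_the_contact_bin(self):
        toy = two_state_table(0.0, 1)
        mean, var = reweight(toy, 60.0)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_exact_four_monomer_mean(self, nm4_bulk):
        mean, _ = reweight(nm4_bulk, 0.0)
        assert mean == pytest.approx(24.0 / 150.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(random_tables(), st.floats(-3, 3, allow_nan=False))
    def test_probabilities_normalize_and_variance_nonnegative(self, table, eps):
        p = probabilities(table, eps)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        _, var = reweight(table, eps)
        assert var >= 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(random_tables(), st.floats(-5, 5, allow_nan=False))
    def test_every_output_is_invariant_under_log_g_shifts(self, table, shift):
        """g is only defined up to normalization; nothing downstream may care."""
        shifted = replace(table, log_g=table.log_g + shift)
        assert reweight(shifted, 0.7) == pytest.approx(reweight(table, 0.7))
        np.testing.assert_allclose(
            landscape(shifted, 0.7).y, landscape(table, 0.7).y, atol=1e-9
        )

    def test_susceptibility_identity(self):
        """Variance equals the epsilon-derivative of the mean contact number."""
        nc = np.arange(0, 21)
        table = make_table(nc, -0.05 * (nc - 8.0) ** 2)
        h = 3e-4
        for eps in (0.0, 0.4, 1.1):
            _, var = reweight(table, eps)
            dmean = (reweight(table, eps + h)[0] - reweight(table, eps - h)[0]) / (2 * h)
            assert var == pytest.approx(dmean, abs=1e-6)


class TestTransitionLocation:
    def test_two_state_critical_point_and_width(self, toy_two_state):
        s = find_critical_epsilon(toy_two_state)
        assert s.eps_star == pytest.approx(1.0, abs=1e-6)
        assert s.fwhm == pytest.approx(TWO_STATE_FWHM_10, abs=1e-6)

    def test_doubling_the_contact_gap_halves_location_and_width(self):
        s = find_critical_epsilon(two_state_table(10.0, 20))
        assert s.eps_star == pytest.approx(0.5, abs=1e-6)
        assert s.fwhm == pytest.approx(TWO_STATE_FWHM_10 / 2.0, abs=1e-6)

    def test_fluctuation_curve_peaks_at_the_analytic_crossover(self, toy_two_state):
        grid = np.arange(0.0, 2.0, 1e-3)
        curve = fluctuation_curve(toy_two_state, grid)
        assert np.all(curve.y >= 0.0)
        assert grid[np.argmax(curve.y)] == pytest.approx(1.0, abs=2e-3)

    def test_per_monomer_normalization_scales_the_curve(self, toy_two_state):
        grid = np.linspace(0.5, 1.5, 11)
        raw = fluctuation_curve(toy_two_state, grid)
        per = fluctuation_curve(toy_two_state, grid, per_monomer=True)
        np.testing.assert_allclose(
            per.y, raw.y / toy_two_state.params.n_monomers, rtol=1e-12
        )

    def test_missing_interior_peak_raises_window_error(self, toy_two_state):
        with pytest.raises(WindowError):
            find_critical_epsilon(toy_two_state, window=(1.5, 2.0))

    def test_double_well_coexistence_recovered(self):
        """A table built from a known double-well landscape at coexistence
        eps0 must put the fluctuation peak back at eps0."""
        eps0 = 0.8
        nc = np.arange(0, 41)
        f0 = 6.0 * (((nc - 20.0) / 20.0) ** 2 - 1.0) ** 2  # equal minima at 0 and 40
        table = make_table(nc, -f0 - eps0 * nc)
        s = find_critical_epsilon(table)
        assert s.eps_star == pytest.approx(eps0, abs=2e-3)


class TestLandscape:
    def test_two_state_minima_are_degenerate_at_coexistence(self, toy_two_state):
        curve = landscape(toy_two_state, 1.0)
        np.testing.assert_allclose(curve.y, [0.0, 0.0], atol=1e-12)

    def test_free_energy_inverts_to_probability(self, nm4_bulk):
        curve = landscape(nm4_bulk, 0.3)
        p = np.exp(-curve.y)
        np.testing.assert_allclose(p / p.sum(), probabilities(nm4_bulk, 0.3), rtol=1e-12)

    def test_exact_four_monomer_gap(self, nm4_bulk):
        curve = landscape(nm4_bulk, 0.0)
        assert curve.y[1] - curve.y[0] == pytest.approx(math.log(126.0 / 24.0))

    def test_barrier_of_piecewise_curve(self):
        c = ThermoCurve("free_energy", "Nc", [0, 1, 2], [0.0, 2.0, 1.0], ModelParams(4))
        b = barrier(c)
        assert b.height == pytest.approx(2.0)
        assert b.first_order and (b.coil_min_nc, b.globule_min_nc) == (0, 2)

    def test_monotone_curve_has_no_barrier(self):
        c = ThermoCurve("free_energy", "Nc", [0, 1, 2, 3], [0.0, 1.0, 2.0, 3.0], ModelParams(5))
        b = barrier(c)
        assert b.height == 0.0 and not b.first_order

    def test_two_state_support_has_no_interior_barrier(self, toy_two_state):
        b = barrier(landscape(toy_two_state, 1.0))
        assert b.height == 0.0 and not b.first_order

    def test_sampling_ripple_and_deep_tail_dips_are_not_basins(self):
        nc = np.arange(0, 9)
        f = np.array([0.0, 1.5, 0.1, 1.6, 0.05, 1.55, 12.0, 11.5, 13.0])
        c = ThermoCurve("free_energy", "Nc", nc, f, ModelParams(16))
        b = barrier(c)
        assert b.first_order
        assert b.globule_min_nc == 4  # the 11.5 kBT dip at Nc=7 is tail noise
        assert b.height == pytest.approx(1.6)


class TestConfinement:
    def test_identical_tables_give_the_zero_curve(self):
        bulk = exact_table(6, 1.5, None)
        tall = exact_table(6, 1.5, 8)
        curve = confinement_free_energy(tall, bulk)
        np.testing.assert_allclose(curve.y, 0.0, atol=1e-12)

    def test_matches_exact_enumeration_ratio(self):
        """Anchored -ln ratio of the Nm=4 monolayer and bulk tables."""
        slit = exact_table(4, 0.0, 1)
        bulk = exact_table(4, 0.0, None)
        curve = confinement_free_energy(slit, bulk)
        # g_2D = (28, 8), g_bulk = (126, 24); anchored at Nc=0
        expected = -(math.log(8.0 / 24.0) - math.log(28.0 / 126.0))
        assert curve.y[0] == 0.0
        assert curve.y[1] == pytest.approx(expected)

    def test_independent_of_attraction_reweighting(self):
        """Boltzmann factors e^{eps Nc} cancel in the slit/bulk ratio."""
        slit = exact_table(7, 1.5, 2)
        bulk = exact_table(7, 1.5, None)
        raw = confinement_free_energy(slit, bulk)
        eps = 0.9
        rw = lambda t: replace(t, log_g=t.log_g + eps * t.nc)
        reweighted = confinement_free_energy(rw(slit), rw(bulk))
        np.testing.assert_allclose(reweighted.y, raw.y, atol=1e-10)

    def test_convention_or_chain_mismatch_is_refused(self):
        bulk = exact_table(6)
        with pytest.raises(ConventionMismatchError):
            confinement_free_energy(exact_table(5, 0.0, 2), bulk)
        other = replace(exact_table(6, 0.0, 2), convention="z0-sum")
        with pytest.raises(ConventionMismatchError):
            confinement_free_energy(other, bulk)


class TestPhaseMap:
    def test_single_bulk_table_yields_one_row(self, toy_two_state):
        df = phase_map([toy_two_state])
        assert len(df) == 1
        assert math.isinf(df.loc[0, "slit_height"])
        assert df.loc[0, "eps_star"] == pytest.approx(1.0, abs=1e-6)

    def test_identical_tables_yield_identical_rows(self, toy_two_state):
        df = phase_map([toy_two_state, toy_two_state])
        assert df.loc[0, "eps_star"] == df.loc[1, "eps_star"]
        assert df.loc[0, "fwhm"] == df.loc[1, "fwhm"]

    def test_errors_are_recorded_without_stopping_the_rest(self, toy_two_state):
        single = make_table([0], [1.0])
        df = phase_map([single, toy_two_state])
        assert df.loc[0, "error"] is not None
        assert df.loc[1, "eps_star"] == pytest.approx(1.0, abs=1e-6)

    def test_slit_series_from_enumeration_has_finite_positive_critical_points(self):
        tables = [exact_table(10, 3.0, h) for h in (1, 2, 3, None)]
        df = phase_map(tables, window=(0.0, 4.0))
        assert df["error"].isna().all() or (df["error"] == None).all()  # noqa: E711
        assert np.all(np.isfinite(df["eps_star"])) and np.all(df["eps_star"] > 0)
        assert np.all(df["fwhm"] > 0)

    def test_critical_slit_height_crossing_construction(self):
        h = [1, 2, 3, 4, 6]
        e = [0.9, 0.5, 0.6, 0.74, 0.8]  # V-shape with discrete minimum at H=2
        hstar, how = critical_slit_height(h, e, method="crossing")
        assert how == "crossing"
        # segment through (1,.9)-(2,.5) meets segment (3,.6)-(4,.74) at H=56/27
        assert hstar == pytest.approx(56.0 / 27.0, abs=1e-6)
        hmin, how = critical_slit_height(h, e, method="argmin")
        assert (hmin, how) == (2.0, "argmin")


class TestUnitMapping:
    def test_dna_scale_mapping(self):
        m = unit_mapping(ModelParams(1024, 3.0), physical_lp_nm=50.0)
        assert round(m.contour_um, 1) == 9.3
        assert round(m.chain_width_nm) == 9
        assert not m.lp_below_spacing

    def test_linearity_in_the_physical_persistence_length(self):
        a = unit_mapping(ModelParams(512, 1.5), 25.0)
        b = unit_mapping(ModelParams(512, 1.5), 50.0)
        assert b.contour_um == pytest.approx(2 * a.contour_um)
        assert b.chain_width_nm == pytest.approx(2 * a.chain_width_nm)

    def test_flexible_chain_is_flagged(self):
        assert unit_mapping(ModelParams(64, 0.0), 50.0).lp_below_spacing


class TestCurveSerialization:
    def test_curve_tsv_and_summary_json_round_trip(self, tmp_path, toy_two_state):
        import json

        curve = fluctuation_curve(toy_two_state, np.linspace(0.5, 1.5, 21))
        path = tmp_path / "curve.tsv"
        curve.write_tsv(path)
        text = path.read_text()
        assert "# kind=fluctuation" in text
        assert f"# source_checksum={toy_two_state.checksum()}" in text
        summ = transition_summary(toy_two_state)
        data = json.loads(summ.to_json())
        assert data["eps_star"] == pytest.approx(1.0, abs=1e-6)
        assert data["barrier"] == 0.0
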