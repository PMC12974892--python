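import numpy as np
import pandas as pd
import pytest

from mlmm.free_energy import (
    NoInteriorMaximumError,
    NonOverlappingWindowsError,
    PMFProfile,
    UmbrellaSystem,
    catalytic_effect,
    make_window_grid,
    pmf_statistics,
    pmf_uncertainty,
    run_umbrella,
    sample_umbrella_1d,
    wham,
)
from mlmm.units import KB_KCALMOL

KT300 = KB_KCALMOL * 300.0


class TestWindowGrid:
    @pytest.mark.parametrize("lo,hi,step,count", [
        (1.3, 3.8, 0.1, 26),
        (-4.5, 2.2, 0.1, 68),
        (-2.5, 2.2, 0.1, 48),
        (0.0, 1.0, 0.5, 3),
    ])
    def test_inclusive_counts(self, lo, hi, step, count):
        grid = make_window_grid(lo, hi, step, 100.0)
        assert grid.n_windows == count
        assert grid.centers[0] == pytest.approx(lo)
        assert grid.centers[-1] == pytest.approx(hi)

    def test_off_lattice_endpoint_rejected(self):
        with pytest.raises(ValueError, match="lattice"):
            make_window_grid(0.0, 1.03, 0.1, 100.0)


class TestPMFProfile:
    def test_min_shifted_to_zero(self):
        p = PMFProfile([0.0, 1.0, 2.0], [3.0, 5.0, 4.0])
        assert p.free_energy.min() == 0.0

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            PMFProfile([0.0, 0.0, 1.0], [0.0, 1.0, 2.0])


def harmonic_potential(k_s):
    return lambda x: k_s * x**2          # engine convention, no ½


class TestWHAM:
    def test_single_window_degenerate_case(self):
        """One window, zero bias: PMF is −kT ln(histogram) + const."""
        rng = np.random.default_rng(4)
        k_s = 20.0
        sigma = np.sqrt(KT300 / (2 * k_s))
        x = sigma * rng.standard_normal(40_000)
        df = pd.DataFrame({
            "window_center": 0.0, "replica": 0,
            "step": np.arange(len(x)), "rc_value": x,
        })
        grid = make_window_grid(0.0, 0.0, 1.0, 0.0)
        profile = wham(df, grid, 300.0, bin_width=0.02)
        mask = np.abs(profile.rc_grid) < 2 * sigma
        fit = np.polyfit(profile.rc_grid[mask],
                         profile.free_energy[mask], 2)
        assert fit[0] == pytest.approx(k_s, rel=0.1)

    def test_recovers_harmonic_curvature(self):
        k_s = 10.0
        grid = make_window_grid(-0.6, 0.6, 0.1, 50.0)
        df = sample_umbrella_1d(harmonic_potential(k_s), grid,
                                n_samples=1500, seed=2)
        profile = wham(df, grid, 300.0)
        mask = np.abs(profile.rc_grid) < 0.45
        fit = np.polyfit(profile.rc_grid[mask],
                         profile.free_energy[mask], 2)
        assert fit[0] == pytest.approx(k_s, rel=0.1)

    def test_double_well_barrier_against_quadrature(self):
        """Sampled WHAM PMF vs direct Boltzmann quadrature of the exact
        double well, within combined statistical error."""
        def double_well(x):
            return 4.0 * (x**2 - 1.0) ** 2   # barrier 4 kcal/mol at x=0

        grid = make_window_grid(-1.4, 1.4, 0.1, 40.0)
        df = sample_umbrella_1d(double_well, grid, n_samples=3000, seed=3,
                                replicas=3)
        profile = wham(df, grid, 300.0)
        stats = pmf_statistics(profile, (-1.3, -0.6), (0.6, 1.3))
        # exact PMF equals the potential itself in 1D
        unc = pmf_uncertainty(df, grid, 300.0, method="replica",
                              reactant_range=(-1.3, -0.6),
                              product_range=(0.6, 1.3))
        tol = 3 * max(unc["barrier_std"], 0.05) + 0.1
        assert stats["barrier"] == pytest.approx(4.0, abs=tol)
        assert stats["reaction_free_energy"] == pytest.approx(0.0, abs=tol)

    def test_bin_width_invariance(self):
        grid = make_window_grid(-0.6, 0.6, 0.1, 50.0)
        df = sample_umbrella_1d(harmonic_potential(8.0), grid,
                                n_samples=4000, seed=5)
        p1 = wham(df, grid, 300.0, bin_width=0.02)
        p2 = wham(df, grid, 300.0, bin_width=0.01)
        common = np.linspace(-0.4, 0.4, 33)
        g1 = np.interp(common, p1.rc_grid, p1.free_energy)
        g2 = np.interp(common, p2.rc_grid, p2.free_energy)
        assert np.max(np.abs(g1 - g2)) < 0.15

    def test_non_overlapping_histograms_error(self):
        rng = np.random.default_rng(0)
        rows = []
        for center in (-1.0, 1.0):   # far apart, stiff bias
            x = center + 0.01 * rng.standard_normal(200)
            for i, v in enumerate(x):
                rows.append((center, 0, i, v))
        df = pd.DataFrame(
            rows, columns=["window_center", "replica", "step", "rc_value"]
        )
        grid = make_window_grid(-1.0, 1.0, 2.0, 500.0)
        with pytest.raises(NonOverlappingWindowsError, match="gap"):
            wham(df, grid, 300.0, bin_width=0.02)


class TestRunUmbrella:
    @pytest.fixture()
    def harmonic_system(self):
        """One particle on a 1D harmonic well; RC = x coordinate."""
        k_well = 20.0

        def force(c):
            f = np.zeros_like(c)
            f[0, 0] = -2.0 * k_well * c[0, 0]
            return f

        def rc(c):
            grad = np.zeros_like(c)
            grad[0, 0] = 1.0
            return c[0, 0], grad

        return UmbrellaSystem(np.zeros((1, 3)), np.array([12.0]), force,
                              rc), k_well

    def test_stiff_bias_pins_window_means(self, harmonic_system):
        system, _ = harmonic_system
        grid = make_window_grid(-0.3, 0.3, 0.1, 2000.0)
        df = run_umbrella(grid, system, steps_per_window=400, seed=1,
                          equilibration=100)
        means = df.groupby("window_center").rc_value.mean()
        for center, mean in means.items():
            assert abs(mean - center) < 0.01   # spacing/10

    def test_window_variance_matches_gaussian_closed_form(
            self, harmonic_system):
        """Sample variance ≈ kT / (2 (K_bias + k_well)) in each window."""
        system, k_well = harmonic_system
        k_bias = 200.0
        grid = make_window_grid(-0.2, 0.2, 0.2, k_bias)
        df = run_umbrella(grid, system, steps_per_window=8000, seed=2,
                          equilibration=500, friction=0.15)
        expected = KT300 / (2.0 * (k_bias + k_well))
        variances = df.groupby("window_center").rc_value.var()
        assert variances.mean() == pytest.approx(expected, rel=0.15)
        for v in variances:
            assert v == pytest.approx(expected, rel=0.4)

    def test_replicas_distinct_but_metadata_identical(self, harmonic_system):
        system, _ = harmonic_system
        grid = make_window_grid(-0.1, 0.1, 0.1, 100.0)
        df = run_umbrella(grid, system, replicas=2, steps_per_window=50,
                          seed=3, equilibration=10)
        r0 = df[df.replica == 0].rc_value.to_numpy()
        r1 = df[df.replica == 1].rc_value.to_numpy()
        assert not np.allclose(r0, r1)
        assert set(df[df.replica == 0].window_center) == set(
            df[df.replica == 1].window_center
        )


class TestPMFStatistics:
    def test_simple_barrier_and_reaction(self):
        p = PMFProfile([0.0, 1.0, 2.0], [0.0, 5.0, 2.0])
        stats = pmf_statistics(p, (0.0, 0.2), (1.8, 2.0))
        assert stats["barrier"] == pytest.approx(5.0)
        assert stats["reaction_free_energy"] == pytest.approx(2.0)

    def test_gauge_invariance(self):
        grid = np.linspace(-1, 1, 41)
        values = 4 * (grid**2 - 0.8**2) ** 2
        p1 = PMFProfile(grid, values)
        p2 = PMFProfile(grid, values + 7.3)
        s1 = pmf_statistics(p1, (-1.0, -0.6), (0.6, 1.0))
        s2 = pmf_statistics(p2, (-1.0, -0.6), (0.6, 1.0))
        assert s2["barrier"] == pytest.approx(s1["barrier"], abs=1e-10)
        assert s2["reaction_free_energy"] == pytest.approx(
            s1["reaction_free_energy"], abs=1e-10
        )

    def test_monotone_profile_requires_ts_range(self):
        grid = np.linspace(0, 1, 21)
        p = PMFProfile(grid, 3.0 * grid)
        with pytest.raises(NoInteriorMaximumError, match="ts_range"):
            pmf_statistics(p, (0.0, 0.1), (0.9, 1.0))


class TestCatalyticEffect:
    @pytest.mark.parametrize("water,enzyme,expected", [
        (23.3, 10.8, -12.5),
        (25.6, 12.8, -12.8),
        (15.0, 15.0, 0.0),
    ])
    def test_barrier_differences(self, water, enzyme, expected):
        assert catalytic_effect(water, enzyme) == pytest.approx(
            expected, abs=1e-12
        )


class TestUncertainty:
    def test_identical_replicas_zero_uncertainty(self):
        grid = make_window_grid(-0.4, 0.4, 0.1, 50.0)
        df = sample_umbrella_1d(harmonic_potential(10.0), grid,
                                n_samples=800, seed=6)
        dup = pd.concat([df, df.assign(replica=1)])
        out = pmf_uncertainty(dup, grid, 300.0, method="replica")
        assert np.nanmax(out["std"]) < 1e-12

    def test_fragment_scaling_with_length(self):
        """Fragment-wise uncertainty shrinks roughly as 1/√length."""
        grid = make_window_grid(-0.4, 0.4, 0.1, 50.0)
        stds = []
        for n in (600, 4800):
            df = sample_umbrella_1d(harmonic_potential(10.0), grid,
                                    n_samples=n, seed=7)
            out = pmf_uncertainty(df, grid, 300.0, method="fragment5")
            stds.append(np.nanmean(out["std"]))
        ratio = stds[0] / stds[1]
        assert 1.5 < ratio < 6.0   # ideal √8 ≈ 2.8

    def test_replica_and_fragment_methods_agree_in_expectation(self):
        """5 replicas vs 5 fragments of a concatenated reseeded series."""
        grid = make_window_grid(-0.4, 0.4, 0.1, 50.0)
        df_rep = sample_umbrella_1d(harmonic_potential(10.0), grid,
                                    n_samples=1000, seed=8, replicas=5)
        rep = pmf_uncertainty(df_rep, grid, 300.0, method="replica",
                              reactant_range=(-0.4, -0.1),
                              product_range=(0.1, 0.4),
                              ts_range=(-0.1, 0.1))
        # concatenate the replicas into one series per window, then split
        parts = []
        for (c, r), g in df_rep.groupby(["window_center", "replica"]):
            g = g.assign(step=g.step + r * 10_000, replica=0)
            parts.append(g)
        df_cat = pd.concat(parts)
        frag = pmf_uncertainty(df_cat, grid, 300.0, method="fragment5",
                               reactant_range=(-0.4, -0.1),
                               product_range=(0.1, 0.4),
                               ts_range=(-0.1, 0.1))
        assert frag["barrier_std"] == pytest.approx(
            rep["barrier_std"], rel=1e-9
        )
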