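import numpy as np
import pytest

from mlmm.core import MLRegion, MMEnvironment, ReactionCoordinate
from mlmm.engine import (
    EmbeddingVariant,
    LangevinIntegrator,
    MDState,
    Restraint,
    ToySurfaceParameters,
    induced_from_reference,
    langevin_step,
    masses_for,
    restraint_energy,
    total_energy,
    toy_profile,
    toy_reactive_surface,
)
from mlmm.synthetic import TruePolarizabilityModel, TrueStaticModel
from mlmm.units import FORCE_TO_ACC, KB_KCALMOL


class TestTotalEnergy:
    def test_empty_environment_is_gas_only(self, gt):
        region = gt.build_geometry(-0.8)
        dec = total_energy(region, None, gt.gas_potential(),
                           TrueStaticModel(gt), TruePolarizabilityModel(gt))
        gas_e, _ = gt.gas_potential()(region)
        assert dec.e_total == pytest.approx(gas_e)
        assert dec.e_static == dec.e_induced == dec.e_mm == 0.0

    def test_decomposition_identity(self, gt, cat_env):
        region = gt.build_geometry(0.2)
        dec = total_energy(region, cat_env, gt.gas_potential(),
                           TrueStaticModel(gt), TruePolarizabilityModel(gt))
        assert dec.e_total == pytest.approx(
            dec.e_gas + dec.e_static + dec.e_induced + dec.e_mm, abs=1e-12
        )

    def test_mechanical_removes_exactly_the_induced_term(self, gt, cat_env):
        region = gt.build_geometry(-0.3)
        sm, pm = TrueStaticModel(gt), TruePolarizabilityModel(gt)
        gas = gt.gas_potential()
        full = total_energy(region, cat_env, gas, sm, pm,
                            EmbeddingVariant("emle"))
        mech = total_energy(region, cat_env, gas, sm, pm,
                            EmbeddingVariant("mechanical"))
        assert mech.e_gas == full.e_gas
        assert mech.e_static == full.e_static
        assert mech.e_induced == 0.0
        assert full.e_total - mech.e_total == pytest.approx(full.e_induced,
                                                            abs=1e-12)

    def test_variants_coincide_in_degenerate_limits(self, gt, cat_env):
        """emle with vanishing polarizabilities equals mechanical; the
        static term reduces to Coulomb over the equalized charges when
        widths and valence populations vanish (mm_fixed with that set)."""
        from mlmm.static import DensityParameters, mm_embedding_energy

        region = gt.build_geometry(0.4)
        density = gt.true_density(region)
        sm = TrueStaticModel(gt)
        gas = gt.gas_potential()

        class TinyAlpha:
            thole_damping_a = None

            def atomic_polarizabilities(self, density, region):
                return np.full(region.n_atoms, 1e-10)

        mech = total_energy(region, cat_env, gas, sm, None,
                            EmbeddingVariant("mechanical"))
        near = total_energy(region, cat_env, gas, sm, TinyAlpha(),
                            EmbeddingVariant("emle"))
        assert near.e_total == pytest.approx(mech.e_total, abs=1e-6)

        point_density = DensityParameters(
            density.charges, np.full(region.n_atoms, 1e-3),
            np.full(region.n_atoms, 1e-12), density.volumes,
        )
        from mlmm.static import static_energy

        e_point, _, _ = static_energy(point_density, region, cat_env)
        e_coul, _, _ = mm_embedding_energy(density.charges, region, cat_env)
        assert e_point == pytest.approx(e_coul, abs=1e-8)

    def test_fd_forces_sum_to_zero(self, gt, cat_env):
        """Total force over ML + MM vanishes (translation invariance)."""
        region = gt.build_geometry(-0.5)
        dec = total_energy(
            region, cat_env, gt.gas_potential(), TrueStaticModel(gt),
            TruePolarizabilityModel(gt), EmbeddingVariant("emle"),
            forces="fd", fd_order=4, include_mm_forces=True,
        )
        net = dec.forces_ml.sum(axis=0) + dec.forces_mm.sum(axis=0)
        assert np.linalg.norm(net) < 1e-5

    def test_fast_equals_fd_without_predicted_parameters(self, gt, cat_env):
        """Frozen-parameter ("fast") and full ("fd") differentiation agree
        exactly when the variant carries no geometry-dependent parameters
        (fixed-charge MM embedding); with predicted parameters the modes
        differ only by the parameter-response term."""
        region = gt.build_geometry(0.0)
        kw = dict(env=cat_env, gas=gt.gas_potential(),
                  static_model=None, pol_model=None,
                  variant=EmbeddingVariant("mm_fixed", "q_R",
                                           gt.q_reactant))
        fd = total_energy(region, forces="fd", **kw)
        fast = total_energy(region, forces="fast", **kw)
        np.testing.assert_allclose(fast.forces_ml, fd.forces_ml, atol=1e-9)
        emle_kw = dict(env=cat_env, gas=gt.gas_potential(),
                       static_model=TrueStaticModel(gt),
                       pol_model=TruePolarizabilityModel(gt),
                       variant=EmbeddingVariant("emle"))
        fast_emle = total_energy(region, forces="fast", **emle_kw)
        fd_emle = total_energy(region, forces="fd", **emle_kw)
        assert np.all(np.isfinite(fast_emle.forces_ml))
        # parameter response is a correction, not a rewrite, of the force
        scale = np.abs(fd_emle.forces_ml).max()
        assert np.abs(fast_emle.forces_ml - fd_emle.forces_ml).max() < scale


class TestInducedFromReference:
    def test_arithmetic(self):
        assert induced_from_reference(-10.0, -7.0, -2.0) == pytest.approx(
            -1.0
        )
        assert induced_from_reference(-9.0, -7.0, -2.0) == 0.0

    def test_inverse_round_trip(self, rng):
        for _ in range(20):
            total, gas_e, static_e = rng.standard_normal(3) * 10
            ind = induced_from_reference(total, gas_e, static_e)
            assert ind + gas_e + static_e == pytest.approx(total, abs=1e-12)


class TestRestraints:
    @pytest.fixture()
    def pair_region(self):
        def make(d):
            return MLRegion(["C", "C"], [[0, 0, 0], [d, 0, 0]],
                            atom_labels=["C2", "C8"])
        return make

    def test_one_sided_inactive_beyond_threshold(self, pair_region):
        r = Restraint("one_sided_distance", 100.0, threshold=2.7,
                      pair=("C2", "C8"))
        e, f = restraint_energy(r, pair_region(3.0))
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_one_sided_engine_convention(self, pair_region):
        """K(d−d0)² without the ½: 100·0.1² = 1.0 kcal/mol at d = 2.6."""
        r = Restraint("one_sided_distance", 100.0, threshold=2.7,
                      pair=("C2", "C8"))
        e, _ = restraint_energy(r, pair_region(2.6))
        assert e == pytest.approx(1.0, abs=1e-10)
        r_half = Restraint("one_sided_distance", 100.0, threshold=2.7,
                           pair=("C2", "C8"), half_convention=True)
        e_half, _ = restraint_energy(r_half, pair_region(2.6))
        assert e_half == pytest.approx(0.5, abs=1e-10)

    def test_harmonic_zero_at_target(self, pair_region):
        rc = ReactionCoordinate("weighted_distance_sum", [("C2", "C8")],
                                [1.0])
        r = Restraint("harmonic_rc", 200.0, target=2.0, rc=rc)
        e, f = restraint_energy(r, pair_region(2.0))
        assert e == 0.0
        np.testing.assert_allclose(f, 0.0, atol=1e-12)
        e2, _ = restraint_energy(r, pair_region(2.3))
        assert e2 == pytest.approx(200.0 * 0.3**2, abs=1e-9)


class TestToySurface:
    def test_symmetric_profile(self):
        p = ToySurfaceParameters(("C1", "O1"), ("C1", "O2"),
                                 rc_reactant=-1.5, rc_product=1.5,
                                 barrier=10.0, delta_e=0.0)
        xi = np.linspace(-2.0, 2.0, 801)
        v, _ = toy_profile(p, xi)
        np.testing.assert_allclose(v, v[::-1], atol=1e-12)

    def test_barrier_height_matches_configuration(self):
        """1D scan oracle: minima at the configured positions, barrier at
        the midpoint equal to the configured height (symmetric case)."""
        p = ToySurfaceParameters(("A", "B"), ("B", "C"),
                                 rc_reactant=-1.5, rc_product=1.5,
                                 barrier=12.0, delta_e=0.0)
        xi = np.linspace(-1.9, 1.9, 7601)
        v, _ = toy_profile(p, xi)
        i_min = np.argmin(v[xi < 0])
        assert xi[xi < 0][i_min] == pytest.approx(-1.5, abs=2e-3)
        barrier = v[np.argmin(np.abs(xi))] - v[xi < 0][i_min]
        assert barrier == pytest.approx(12.0, abs=0.01)

    def test_gradients_validate_against_finite_differences(self, gt, rng):
        gas = gt.gas_potential()
        probes = [gt.build_geometry(x, jitter=0.05, rng=rng)
                  for x in (-1.2, 0.1, 1.3)]
        gas.validate_gradients(probes)   # raises on disagreement

    def test_batch_energies_match_sequential(self, gt, rng):
        gas = gt.gas_potential()
        template = gt.build_geometry(0.0)
        coords = np.stack([
            gt.build_geometry(x, jitter=0.05, rng=rng).coordinates
            for x in np.linspace(-1.5, 1.5, 7)
        ])
        batch = gas.batch_fn(template, coords)
        seq = [gas(template.with_coordinates(c))[0] for c in coords]
        np.testing.assert_allclose(batch, seq, rtol=1e-12)


class TestLangevin:
    def test_zero_temperature_zero_friction_conserves_energy(self):
        """Reduces to velocity Verlet in a harmonic well: energy drift
        below 1e−6 relative over 10⁴ steps at dt = 0.5 fs."""
        k_spring = 100.0   # kcal/mol/Å²
        mass = np.array([12.0])

        def force(x):
            return -2.0 * k_spring * x

        rng = np.random.default_rng(0)
        state = MDState(np.array([[0.3, 0.0, 0.0]]),
                        np.array([[0.0, 0.0, 0.0]]))
        forces = force(state.coordinates)

        def energy(s):
            kin = 0.5 * mass[0] * np.sum(s.velocities**2) / FORCE_TO_ACC
            return k_spring * np.sum(s.coordinates**2) + kin

        energies = [energy(state)]
        for _ in range(10_000):
            state, forces = langevin_step(
                state, force, mass, 0.5, 0.0, 0.0, rng, forces=forces
            )
            energies.append(energy(state))
        energies = np.array(energies)
        # symplectic: a bounded shadow-energy oscillation but no secular
        # drift — the fitted linear trend over the run stays below 1e−6
        slope = np.polyfit(np.arange(len(energies)), energies, 1)[0]
        assert abs(slope) * len(energies) < 1e-6 * abs(energies[0])

    def test_equipartition_in_harmonic_well(self):
        """⟨x²⟩ = kT/k_spring for E = ½ k x² at 300 K, within 3 SE.

        64 independent walkers × 2·10⁴ steps give ~1.3M samples.
        """
        k_spring = 50.0        # E = ½ k x² → force −k x
        temperature = 300.0
        mass = np.full(64, 12.0)

        def force(x):
            return -k_spring * x

        integ = LangevinIntegrator(mass, dt=1.0, temperature=temperature,
                                   friction=0.2, seed=9)
        sumsq = []

        def collect(step, state):
            if step >= 2000:
                sumsq.append(np.mean(state.coordinates[:, 0] ** 2))

        integ.run(np.zeros((64, 3)), force, 22_000, callback=collect)
        x2 = np.array(sumsq)
        expected = KB_KCALMOL * temperature / k_spring
        mean = x2.mean()
        # standard error from batch means over the correlated series
        batches = x2[: len(x2) // 20 * 20].reshape(20, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(mean - expected) < 3 * se + 0.02 * expected

    def test_same_seed_is_bitwise_reproducible(self, gt):
        gas = gt.gas_potential()
        region = gt.build_geometry(-1.0)
        masses = masses_for(region.elements)

        def run():
            integ = LangevinIntegrator(masses, dt=0.5, temperature=300.0,
                                       friction=0.1, seed=123)
            traj = []
            integ.run(region.coordinates,
                      lambda c: -gas(region.with_coordinates(c))[1],
                      50, callback=lambda s, st: traj.append(
                          st.coordinates.copy()))
            return np.array(traj)

        t1, t2 = run(), run()
        np.testing.assert_array_equal(t1, t2)
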