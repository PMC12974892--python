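import numpy as np
import pytest

from mlmm.core import MLRegion, MMEnvironment
from mlmm.descriptors import DescriptorSettings
from mlmm.gpr import SparseGPRModel
from mlmm.static import DensityParameters
from mlmm.thole import (
    OverpolarizationError,
    PolarizabilityModel,
    atomic_polarizabilities,
    fit_flexible_alpha,
    fit_kz,
    molecular_polarizability,
    solve_induction,
)
from mlmm.units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL

from conftest import random_rigid_motion


def single_atom(element="O"):
    return MLRegion([element], [[0.0, 0.0, 0.0]])


def constant_k_alpha_model(value, n_features):
    """A GPR stub with no inducing contribution: k_α ≡ value."""
    return SparseGPRModel(
        inducing_points=np.zeros((1, n_features)),
        weights=np.zeros(1),
        kernel_lengthscale=1.0,
        kernel_variance=1.0,
        noise_variance=0.0,
        prior_mean=value,
    )


class TestAtomicPolarizabilities:
    def test_fixed_mode_arithmetic(self):
        model = PolarizabilityModel({"O": 1.0}, "fixed")
        density = DensityParameters([0.0], [0.4], [6.0], [2.0])
        alpha = atomic_polarizabilities(model, density, single_atom())
        assert alpha[0] == pytest.approx(2.0, abs=1e-15)

    def test_flexible_with_unit_correction_equals_fixed(self, gt):
        region = gt.build_geometry(-0.5)
        density = gt.true_density(region)
        settings = DescriptorSettings()
        fixed = PolarizabilityModel(gt.k_z_true, "fixed")
        flex = PolarizabilityModel(
            gt.k_z_true, "flexible",
            k_alpha_model=constant_k_alpha_model(1.0, settings.n_features),
            settings=settings,
        )
        a_fixed = atomic_polarizabilities(fixed, density, region)
        a_flex = atomic_polarizabilities(flex, density, region)
        np.testing.assert_array_equal(a_fixed, a_flex)

    def test_missing_element_is_named(self):
        model = PolarizabilityModel({"C": 1.0}, "fixed")
        density = DensityParameters([0.0], [0.4], [6.0], [2.0])
        with pytest.raises(KeyError, match="O"):
            atomic_polarizabilities(model, density, single_atom("O"))


class TestSolveInduction:
    def test_zero_charges_give_zero(self, gt):
        region = gt.build_geometry(0.0)
        env = MMEnvironment([[8.0, 0, 0]], [0.0])
        res = solve_induction(gt.true_alphas(region), region, env)
        assert res.e_induced == 0.0
        assert np.all(res.induced_dipoles == 0.0)

    def test_single_atom_closed_form(self):
        """μ = αE and E_ind = −½αE² for one atom in a point-charge field."""
        alpha = 5.0
        region = single_atom()
        d_ang = 12.0
        env = MMEnvironment([[d_ang, 0, 0]], [1.0])
        d = d_ang * ANGSTROM_TO_BOHR
        e_field = 1.0 / d**2
        res = solve_induction(np.array([alpha]), region, env)
        assert res.induced_dipoles[0, 0] == pytest.approx(
            -alpha * e_field, rel=1e-12
        )
        assert res.e_induced == pytest.approx(
            -0.5 * alpha * e_field**2 * HARTREE_TO_KCALMOL, rel=1e-12
        )

    def test_two_atom_closed_form_no_damping(self):
        """Effective polarizability along the bond matches the analytic
        two-site relay solution (and hence the dense 6×6 solve)."""
        a1, a2, d = 4.0, 6.0, 4.0      # bohr³, bohr³, bohr
        region = MLRegion(
            ["C", "C"], [[0, 0, 0], [d * BOHR_TO_ANGSTROM, 0, 0]]
        )
        tensor, _ = molecular_polarizability(
            np.array([a1, a2]), region, damping_a=None
        )
        expect = (a1 + a2 + 4 * a1 * a2 / d**3) / (1 - 4 * a1 * a2 / d**6)
        assert tensor[0, 0] == pytest.approx(expect, rel=1e-10)

    def test_induction_energy_never_positive(self, gt, rng, droplet):
        for _ in range(10):
            region = gt.build_geometry(
                rng.uniform(-1.6, 1.6), jitter=0.05, rng=rng
            )
            res = solve_induction(gt.true_alphas(region), region, droplet)
            assert res.e_induced <= 0.0

    def test_jacobi_agrees_with_direct(self, gt, droplet):
        region = gt.build_geometry(0.3)
        alphas = gt.true_alphas(region)
        direct = solve_induction(alphas, region, droplet, method="direct")
        jacobi = solve_induction(alphas, region, droplet, method="jacobi",
                                 tol=1e-13)
        np.testing.assert_allclose(
            jacobi.induced_dipoles, direct.induced_dipoles, atol=1e-8
        )

    def test_dipoles_rotate_equivariantly(self, gt, rng, droplet):
        region = gt.build_geometry(-0.2)
        alphas = gt.true_alphas(region)
        res = solve_induction(alphas, region, droplet)
        q, t = random_rigid_motion(rng)
        moved = region.with_coordinates(region.coordinates @ q.T + t)
        env2 = MMEnvironment(droplet.positions @ q.T + t, droplet.charges,
                             droplet.lj_sigma, droplet.lj_epsilon)
        res2 = solve_induction(alphas, moved, env2)
        np.testing.assert_allclose(
            res2.induced_dipoles, res.induced_dipoles @ q.T, atol=1e-10
        )
        assert res2.e_induced == pytest.approx(res.e_induced, rel=1e-10)

    def test_overpolarization_reports_pair(self):
        region = MLRegion(["C", "C"], [[0, 0, 0], [0.4, 0, 0]])
        with pytest.raises(OverpolarizationError, match=r"\(0, 1\)"):
            solve_induction(np.array([12.0, 12.0]), region,
                            MMEnvironment([[5.0, 0, 0]], [1.0]),
                            damping_a=None)


class TestMolecularPolarizability:
    def test_single_atom_isotropic(self):
        tensor, iso = molecular_polarizability(np.array([3.5]),
                                               single_atom())
        np.testing.assert_allclose(tensor, 3.5 * np.eye(3), atol=1e-12)
        assert iso == pytest.approx(3.5)

    def test_far_apart_atoms_add(self):
        region = MLRegion(["C", "C"], [[0, 0, 0], [400.0, 0, 0]])
        _, iso = molecular_polarizability(np.array([4.0, 6.0]), region)
        assert iso == pytest.approx(10.0, rel=1e-6)

    def test_symmetric_positive_definite(self, gt):
        region = gt.build_geometry(0.1)
        tensor, _ = molecular_polarizability(gt.true_alphas(region), region,
                                             gt.thole_damping_a)
        np.testing.assert_allclose(tensor, tensor.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(tensor) > 0)

    def test_finite_field_oracle(self, gt):
        """α_mol from the relay inverse vs numerical differentiation of the
        total induced dipole in a uniform field."""
        region = gt.build_geometry(-0.7)
        alphas = gt.true_alphas(region)
        a_damp = gt.thole_damping_a
        tensor, _ = molecular_polarizability(alphas, region, a_damp)
        from mlmm.thole import _relay_matrix

        coords = region.coordinates * ANGSTROM_TO_BOHR
        relay, _ = _relay_matrix(alphas, coords, a_damp)
        h = 1e-4
        num = np.zeros((3, 3))
        n = region.n_atoms
        for k in range(3):
            for sign in (+1, -1):
                field = np.zeros(3)
                field[k] = sign * h
                b = np.tile(field, n)
                mu = np.linalg.solve(relay, b).reshape(n, 3)
                num[:, k] += sign * mu.sum(axis=0)
        num /= 2 * h
        np.testing.assert_allclose(tensor, num, atol=1e-6)


class TestFitKz:
    def make_fixed_alpha_data(self, gt, n=20):
        gt_fixed = type(gt)()
        gt_fixed.k_alpha_amp = {"O": 0.0, "C": 0.0, "H": 0.0}
        from mlmm.synthetic import emit_reference_tables, generate_conformers

        regions, _ = generate_conformers(gt_fixed, n, seed=21)
        tables = emit_reference_tables(gt_fixed, regions, [None] * n)
        pol = tables["polarizabilities"]
        tensors = np.array([
            [[r.axx, r.axy, r.axz], [r.axy, r.ayy, r.ayz],
             [r.axz, r.ayz, r.azz]]
            for r in pol.itertuples()
        ])
        props = tables["properties"]
        volumes = [
            props[props.frame_id == i].sort_values("atom_index")["v"]
            .to_numpy()
            for i in range(n)
        ]
        # a diverse fit set pins every element: add isolated-atom frames
        # whose tensors are exactly k_Z·v·I
        for el, v in (("O", 23.0), ("C", 35.0), ("H", 7.0)):
            regions.append(single_atom(el))
            volumes.append(np.array([v]))
            tensors = np.concatenate([
                tensors,
                [gt_fixed.k_z_true[el] * v * np.eye(3)],
            ])
        return gt_fixed, regions, tensors, volumes

    def test_recovers_true_ratios(self, gt):
        gt_fixed, regions, tensors, volumes = self.make_fixed_alpha_data(gt)
        k_z = fit_kz(tensors, regions, volumes, gt.thole_damping_a)
        for el, true in gt_fixed.k_z_true.items():
            assert k_z[el] == pytest.approx(true, rel=1e-3)

    def test_single_atom_closed_form(self):
        region = single_atom("O")
        v = 20.0
        alpha_ref = 7.5
        tensors = np.array([alpha_ref * np.eye(3)])
        k_z = fit_kz(tensors, [region], [np.array([v])], damping_a=None)
        assert k_z["O"] == pytest.approx(alpha_ref / v, rel=1e-9)

    def test_duplicated_conformers_idempotent(self, gt):
        gt_fixed, regions, tensors, volumes = self.make_fixed_alpha_data(
            gt, n=8
        )
        k1 = fit_kz(tensors, regions, volumes, gt.thole_damping_a)
        k2 = fit_kz(
            np.concatenate([tensors, tensors]),
            regions + regions, volumes + volumes, gt.thole_damping_a,
        )
        for el in k1:
            assert k2[el] == pytest.approx(k1[el], rel=1e-6)


@pytest.fixture(scope="module")
def flex_data(gt):
    from mlmm.synthetic import emit_reference_tables, generate_conformers

    regions, _ = generate_conformers(gt, 60, seed=31)
    tables = emit_reference_tables(gt, regions, [None] * 60)
    pol = tables["polarizabilities"]
    tensors = np.array([
        [[r.axx, r.axy, r.axz], [r.axy, r.ayy, r.ayz],
         [r.axz, r.ayz, r.azz]]
        for r in pol.itertuples()
    ])
    props = tables["properties"]
    volumes = [
        props[props.frame_id == i].sort_values("atom_index")["v"]
        .to_numpy()
        for i in range(60)
    ]
    base = PolarizabilityModel(
        dict(gt.k_z_true), "fixed", settings=DescriptorSettings(),
        thole_damping_a=gt.thole_damping_a,
    )
    return regions, tensors, volumes, base


class TestFlexibleAlpha:

    def test_strong_regularization_pins_k_alpha_to_unity(self, gt,
                                                         flex_data):
        regions, tensors, volumes, base = flex_data
        model = fit_flexible_alpha(
            tensors, regions, volumes, base, base.settings,
            regularization=1e8, n_inducing=16, seed=0,
        )
        from mlmm.descriptors import compute_descriptors
        from mlmm.gpr import predict

        feats = compute_descriptors(regions[0], base.settings)
        k_alpha = predict(model.k_alpha_model, feats)
        np.testing.assert_allclose(k_alpha, 1.0, atol=1e-4)

    def test_recovers_k_alpha_field(self, gt, flex_data):
        """Held-out per-atom k_α within 5% on noise-free synthetic data."""
        regions, tensors, volumes, base = flex_data
        model = fit_flexible_alpha(
            tensors, regions, volumes, base, base.settings,
            regularization=1e-3, seed=0,
        )
        from mlmm.descriptors import compute_descriptors
        from mlmm.gpr import predict
        from mlmm.synthetic import generate_conformers

        held, _ = generate_conformers(gt, 25, seed=77)
        errs = []
        for region in held:
            feats = compute_descriptors(region, base.settings)
            k_pred = predict(model.k_alpha_model, feats)
            k_true = gt.true_k_alpha(region)
            errs.append((k_pred - k_true) / k_true)
        rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        assert rmse < 0.05

    def test_unregularized_fit_beats_fixed_on_training_misfit(self, gt,
                                                              flex_data):
        regions, tensors, volumes, base = flex_data
        from mlmm.thole import predicted_tensors

        elements = [r.elements for r in regions]
        fixed_pred = predicted_tensors(base.k_z, elements, volumes, regions,
                                       base.thole_damping_a)
        fixed_misfit = np.sum((fixed_pred - tensors) ** 2)
        model = fit_flexible_alpha(
            tensors, regions, volumes, base, base.settings,
            regularization=0.0, n_inducing=24, seed=0,
        )
        from mlmm.descriptors import compute_descriptors
        from mlmm.gpr import predict

        k_alpha_list = [
            predict(model.k_alpha_model,
                    compute_descriptors(r, base.settings))
            for r in regions
        ]
        flex_pred = predicted_tensors(base.k_z, elements, volumes, regions,
                                      base.thole_damping_a, k_alpha_list)
        flex_misfit = np.sum((flex_pred - tensors) ** 2)
        assert flex_misfit < fixed_misfit
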