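"""Static ML↔MM electrostatics with charge penetration.

The unperturbed charge density of the ML region is modelled as a sum of
spherical atomic contributions: a point core of charge (q_i + N_i) plus a
normalised Slater valence cloud of charge −N_i,

    ρ_i(r) = N_i · exp(−r/s_i) / (8 π s_i³),

so the electrostatic potential of atom i at distance d (atomic units) is

    V_i(d) = (q_i + N_i)/d − N_i/d · [1 − e^{−d/s_i}(1 + d/(2 s_i))]
           = q_i/d + N_i e^{−d/s_i} (1/d + 1/(2 s_i)).

V_i → q_i/d at long range; the second form makes the (always positive)
charge-penetration correction explicit.  The static interaction energy is
the sum of MM point charges times this potential.

Atomic charges are conformation-dependent: per-atom electronegativities χ,
valence widths s and volumes v are predicted from local-environment
descriptors by sparse GPR, and charges follow from electronegativity
equalization under a total-charge constraint, with hardness η = 1/(2s)
(the documented hardness rule tying equalization to the predicted width).

The fixed-charge "MM embedding" ablation replaces all of this by a plain
Coulomb sum over static point charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MLRegion, MMEnvironment
from .descriptors import DescriptorSettings, compute_descriptors
from .gpr import PerElementGPR
from .units import (
    ANGSTROM_TO_BOHR,
    BOHR_TO_ANGSTROM,
    HARTREE_TO_KCALMOL,
    VALENCE_POPULATIONS,
)

#: softplus-style positivity floors (atomic units)
WIDTH_FLOOR = 0.05     # bohr
VOLUME_FLOOR = 0.5     # bohr³

#: ML/MM contact distance below which the static energy is refused
MIN_CONTACT_BOHR = 0.1


class OverlappingAtomsError(ValueError):
    """ML and MM atoms closer than the minimum contact distance."""


class SingularEqualizationError(np.linalg.LinAlgError):
    """Electronegativity-equalization matrix is singular (coincident atoms)."""


@dataclass
class DensityParameters:
    """Per-atom Slater-density parameters (atomic units).

    charges q (e), valence widths s (bohr), valence populations N (e),
    density-derived volumes v (bohr³).
    """

    charges: np.ndarray
    widths: np.ndarray
    valence_populations: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        self.widths = np.atleast_1d(np.asarray(self.widths, float))
        self.valence_populations = np.atleast_1d(
            np.asarray(self.valence_populations, float)
        )
        self.volumes = np.atleast_1d(np.asarray(self.volumes, float))
        n = len(self.charges)
        for arr, name in (
            (self.widths, "widths"),
            (self.valence_populations, "valence_populations"),
            (self.volumes, "volumes"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.widths <= 0):
            raise ValueError("all Slater widths must be positive")
        if np.any(self.volumes <= 0):
            raise ValueError("all atomic volumes must be positive")


@dataclass
class StaticModel:
    """GPR models for electronegativity, width and volume, sharing one
    descriptor configuration."""

    electronegativity_model: PerElementGPR
    width_model: PerElementGPR
    volume_model: PerElementGPR
    settings: DescriptorSettings
    hardness_rule: str = "inverse_width"   # η = 1/(2 s)
    meta: dict = field(default_factory=dict)


def softplus_floor(x: np.ndarray, floor: float,
                   sharpness: float | None = None) -> np.ndarray:
    """Smooth positivity clamp: ≈ identity for x ≳ floor + sharpness,
    asymptote ``floor`` below.  Default sharpness is floor/4."""
    beta = floor / 4.0 if sharpness is None else sharpness
    z = (np.asarray(x, float) - floor) / beta
    soft = np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30.0))))
    return floor + beta * soft


def hardness_from_width(widths: np.ndarray) -> np.ndarray:
    return 1.0 / (2.0 * np.asarray(widths, float))


def equalize_charges(
    chi: np.ndarray,
    eta: np.ndarray,
    coords_bohr: np.ndarray,
    total_charge: float,
) -> np.ndarray:
    """Minimise Σ(χ_i q_i + ½η_i q_i²) + ½Σ_{i≠j} q_i q_j/d_ij s.t. Σq = Q.

    Solved as the (N+1) symmetric linear system with a Lagrange multiplier.
    """
    n = len(chi)
    if n == 1:
        return np.array([float(total_charge)])
    diff = coords_bohr[:, None, :] - coords_bohr[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    if np.any(d[~np.eye(n, dtype=bool)] < 1e-10):
        raise SingularEqualizationError("coincident atoms in ML region")
    with np.errstate(divide="ignore"):
        inv_d = np.where(np.eye(n, dtype=bool), 0.0, 1.0 / d)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = inv_d
    a[np.arange(n), np.arange(n)] = eta
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    b = np.concatenate([-chi, [float(total_charge)]])
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as err:
        raise SingularEqualizationError(str(err)) from err
    return sol[:n]


def chi_targets_from_charges(
    charges: np.ndarray, widths: np.ndarray, coords_bohr: np.ndarray
) -> np.ndarray:
    """Electronegativities that make equalization reproduce given charges.

    Inverts the stationarity condition χ_i + η_i q_i + Σ_{j≠i} q_j/d_ij = λ
    at gauge λ = 0 (a per-conformer constant shift of χ does not change the
    constrained solution).  Used to build GPR training targets from
    reference charge tables.
    """
    n = len(charges)
    eta = hardness_from_width(widths)
    if n == 1:
        return -eta * charges
    diff = coords_bohr[:, None, :] - coords_bohr[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    with np.errstate(divide="ignore"):
        inv_d = np.where(np.eye(n, dtype=bool), 0.0, 1.0 / d)
    return -(eta * charges + inv_d @ charges)


def predict_density(model: StaticModel, region: MLRegion) -> DensityParameters:
    """Conformation-dependent charges/widths/volumes for a geometry."""
    feats = compute_descriptors(region, model.settings)
    chi = model.electronegativity_model.predict(region.elements, feats)
    widths = softplus_floor(
        model.width_model.predict(region.elements, feats), WIDTH_FLOOR
    )
    volumes = softplus_floor(
        model.volume_model.predict(region.elements, feats), VOLUME_FLOOR
    )
    eta = hardness_from_width(widths)
    coords_bohr = region.coordinates * ANGSTROM_TO_BOHR
    charges = equalize_charges(chi, eta, coords_bohr, region.total_charge)
    pops = np.array([VALENCE_POPULATIONS[el] for el in region.elements])
    return DensityParameters(charges, widths, pops, volumes)


def fit_static_model(
    regions: list[MLRegion],
    properties,
    settings: DescriptorSettings | None = None,
    n_inducing: int = 32,
    kernel_lengthscale: float | None = None,
    kernel_variance: float = 1.0,
    noise_variance: float = 1e-8,
    seed: int = 0,
) -> StaticModel:
    """Train the three per-element GPR property models from reference tables.

    ``properties`` is the per-atom table (columns frame_id, atom_index,
    element, q, s, v in atomic units), with rows grouped per frame in the
    order of ``regions``.  Widths and volumes are regressed directly;
    electronegativity targets are obtained by inverting the equalization
    stationarity condition with the reference charges and widths
    (:func:`chi_targets_from_charges`), so that equalization under the
    trained model reproduces the reference charges.
    """
    import pandas as pd

    from .gpr import fit_per_element

    properties = pd.DataFrame(properties)
    if settings is None:
        settings = DescriptorSettings()
    feats, elements = [], []
    s_t, v_t, chi_t = [], [], []
    for fid, region in enumerate(regions):
        sub = properties[properties["frame_id"] == fid].sort_values(
            "atom_index"
        )
        if len(sub) != region.n_atoms:
            raise ValueError(f"frame {fid}: property rows != atom count")
        feats.append(compute_descriptors(region, settings))
        elements.extend(region.elements)
        q = sub["q"].to_numpy()
        s = sub["s"].to_numpy()
        v = sub["v"].to_numpy()
        s_t.append(s)
        v_t.append(v)
        coords_bohr = region.coordinates * ANGSTROM_TO_BOHR
        chi_t.append(chi_targets_from_charges(q, s, coords_bohr))
    feats = np.vstack(feats)
    if kernel_lengthscale is None:
        sub = feats[:: max(1, len(feats) // 400)]
        d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
        kernel_lengthscale = float(np.median(d[d > 0])) or 1.0
    kw = dict(
        n_inducing=n_inducing,
        kernel_lengthscale=kernel_lengthscale,
        kernel_variance=kernel_variance,
        noise_variance=noise_variance,
        seed=seed,
    )
    chi_model = fit_per_element(elements, feats, np.concatenate(chi_t), **kw)
    width_model = fit_per_element(elements, feats, np.concatenate(s_t), **kw)
    volume_model = fit_per_element(elements, feats, np.concatenate(v_t), **kw)
    return StaticModel(chi_model, width_model, volume_model, settings)


def slater_potential(q, n_val, s, d, derivative: bool = False):
    """Electrostatic potential (a.u.) of one Slater atom at distance d (bohr).

    ``derivative=True`` additionally returns dV/dd.
    """
    d = np.asarray(d, float)
    if np.any(d <= 0):
        raise ValueError("slater_potential requires d > 0 "
                         "(self-interaction is not defined here)")
    if np.any(np.asarray(s, float) <= 0):
        raise ValueError("Slater width s must be positive")
    expo = np.exp(-d / s)
    v = q / d + n_val * expo * (1.0 / d + 1.0 / (2.0 * s))
    if not derivative:
        return v
    dv = (
        -q / d**2
        + n_val * expo * (-(1.0 / s) * (1.0 / d + 1.0 / (2.0 * s)) - 1.0 / d**2)
    )
    return v, dv


def _pairwise(region: MLRegion, env: MMEnvironment):
    r_ml = region.coordinates * ANGSTROM_TO_BOHR
    r_mm = env.positions * ANGSTROM_TO_BOHR
    diff = r_ml[:, None, :] - r_mm[None, :, :]       # (n_ml, n_mm, 3)
    dist = np.linalg.norm(diff, axis=-1)
    if np.any(dist < MIN_CONTACT_BOHR):
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        raise OverlappingAtomsError(
            f"ML atom {i} and MM atom {j} are {dist[i, j]:.4f} bohr apart "
            f"(< {MIN_CONTACT_BOHR} bohr)"
        )
    return diff, dist


def static_energy(
    density: DensityParameters, region: MLRegion, env: MMEnvironment
):
    """E_static = Σ_j q_j^MM Σ_i V_i(d_ij), with analytic gradients.

    Density parameters are held fixed for the force contract (the
    geometry-dependence of the predicted parameters is handled by the
    finite-difference force mode of the embedding engine).

    Returns ``(energy kcal/mol, forces_ml, forces_mm)`` with forces in
    kcal/mol/Å; Newton's third law holds exactly.
    """
    if len(density.charges) != region.n_atoms:
        raise ValueError("density/region size mismatch")
    diff, dist = _pairwise(region, env)
    v, dv = slater_potential(
        density.charges[:, None],
        density.valence_populations[:, None],
        density.widths[:, None],
        dist,
        derivative=True,
    )
    qmm = env.charges[None, :]
    e_au = float(np.sum(qmm * v))
    # dE/dR_i = Σ_j q_j V'(d_ij) û_ij ; force = −dE/dR
    unit = diff / dist[:, :, None]
    grad_ml = np.sum((qmm * dv)[:, :, None] * unit, axis=1)
    f_scale = HARTREE_TO_KCALMOL * ANGSTROM_TO_BOHR  # hartree/bohr→kcal/mol/Å
    forces_ml = -grad_ml * f_scale
    forces_mm = np.sum((qmm * dv)[:, :, None] * unit, axis=0) * f_scale
    return e_au * HARTREE_TO_KCALMOL, forces_ml, forces_mm


def mm_embedding_energy(
    fixed_charges: np.ndarray, region: MLRegion, env: MMEnvironment
):
    """Plain Coulomb between fixed ML point charges and MM charges.

    No penetration, no conformational response.  Same return contract as
    :func:`static_energy`.
    """
    fixed_charges = np.atleast_1d(np.asarray(fixed_charges, float))
    if len(fixed_charges) != region.n_atoms:
        raise ValueError("fixed_charges length must equal ML atom count")
    diff, dist = _pairwise(region, env)
    qq = fixed_charges[:, None] * env.charges[None, :]
    e_au = float(np.sum(qq / dist))
    unit = diff / dist[:, :, None]
    grad_ml = np.sum((-qq / dist**2)[:, :, None] * unit, axis=1)
    f_scale = HARTREE_TO_KCALMOL * ANGSTROM_TO_BOHR
    forces_ml = -grad_ml * f_scale
    forces_mm = np.sum((-qq / dist**2)[:, :, None] * unit, axis=0) * f_scale
    return e_au * HARTREE_TO_KCALMOL, forces_ml, forces_mm


def slater_potential_quadrature(q, n_val, s, d, r_max_factor: float = 60.0,
                                n_points: int = 200_000) -> float:
    """Independent radial-quadrature evaluation of the Slater potential.

    Integrates the spherically symmetric valence density directly:
    V_cloud(d) = −[Q_enc(d)/d + ∫_d^∞ 4πr ρ(r) dr], plus the point core.
    Slow; intended as a numerical oracle, not for production use.
    """
    from scipy.integrate import simpson

    def rho(r):
        return n_val * np.exp(-r / s) / (8.0 * np.pi * s**3)

    r_in = np.linspace(1e-8, d, n_points)
    q_enc = simpson(4.0 * np.pi * r_in**2 * rho(r_in), x=r_in)
    r_out = np.linspace(d, r_max_factor * s + d, n_points)
    outer = simpson(4.0 * np.pi * r_out * rho(r_out), x=r_out)
    v_cloud = -(q_enc / d + outer)
    return (q + n_val) / d + v_cloud


__all__ = [
    "DensityParameters",
    "StaticModel",
    "predict_density",
    "slater_potential",
    "slater_potential_quadrature",
    "static_energy",
    "mm_embedding_energy",
    "equalize_charges",
    "chi_targets_from_charges",
    "hardness_from_width",
    "softplus_floor",
    "OverlappingAtomsError",
    "SingularEqualizationError",
    "BOHR_TO_ANGSTROM",
]
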