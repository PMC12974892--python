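"""Assembly of the four-term ML/MM energy and desk-scale dynamics.

    E_ML/MM = E_gas(R_ML) + E_static(R_ML, R_MM) + E_induced(R_ML, R_MM)
              + E_MM(R_ML, R_MM)

Three embedding variants are supported:

* ``emle``       — all four terms (Slater static + Thole induction);
* ``mechanical`` — induction removed, static kept conformation-dependent;
* ``mm_fixed``   — induction removed and static replaced by plain Coulomb
  over a named fixed ML charge set (e.g. reactant-derived ``q_R`` or
  product-derived ``q_P``).

E_MM here is the ML–MM 12-6 Lennard-Jones interaction (Lorentz–Berthelot
combining); MM-internal nonbonded energy is excluded while the environment
is frozen (it is a constant) — the ``mm_internal`` metadata flag records
this.

Forces: the component kernels expose analytic frozen-parameter gradients,
but the geometry dependence of the *predicted* density parameters has no
closed form, so the correctness-defining force mode is central finite
differences of the full energy ("fd"); "fast" differentiates with the
density parameters and polarizabilities frozen at the evaluation geometry.

Restraint convention: the bias energy is K·(Δξ)² *without* the factor ½,
matching the restraint format of the MD engines whose force constants
(100, 200 kcal/mol/Å²) these workflows quote.  Set ``half_convention=True``
on a restraint for ½K(Δξ)².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import (
    EnergyDecomposition,
    MLRegion,
    MMEnvironment,
    ReactionCoordinate,
    evaluate_rc,
)
from .static import (
    StaticModel,
    mm_embedding_energy,
    predict_density,
    static_energy,
)
from .thole import PolarizabilityModel, atomic_polarizabilities, solve_induction
from .units import ATOMIC_MASSES, BOHR_TO_ANGSTROM, FORCE_TO_ACC, KB_KCALMOL

#: per-element 12-6 Lennard-Jones parameters for ML atoms
#: (sigma Å, epsilon kcal/mol); generic force-field-like values
ML_LJ_PARAMS = {
    "H": (2.50, 0.0157),
    "C": (3.40, 0.0860),
    "N": (3.25, 0.1700),
    "O": (3.00, 0.2100),
    "S": (3.56, 0.2500),
}

FD_STEP_BOHR = 1e-3


@dataclass
class GasPhasePotential:
    """Pluggable gas-phase potential: (MLRegion) → (kcal/mol, kcal/mol/Å).

    Stands in for any machine-learned potential trained on gas-phase data;
    gradients are validated against finite differences at registration.
    ``batch_fn``, when provided, evaluates energies for a whole batch of
    geometries at once: (template region, (B, n, 3) coords) → (B,).
    """

    fn: Callable[[MLRegion], tuple[float, np.ndarray]]
    name: str = "anonymous"
    elements: tuple[str, ...] = ()
    notes: str = ""
    batch_fn: Callable | None = None

    def __call__(self, region: MLRegion):
        e, g = self.fn(region)
        return float(e), np.asarray(g, float)

    def validate_gradients(self, probes: list[MLRegion], h: float = 1e-5,
                           rtol: float = 1e-6) -> None:
        for region in probes:
            _, grad = self(region)
            num = np.zeros_like(grad)
            for i in range(region.n_atoms):
                for k in range(3):
                    for sgn in (+1, -1):
                        c = region.coordinates.copy()
                        c[i, k] += sgn * h
                        e, _ = self(region.with_coordinates(c))
                        num[i, k] += sgn * e
            num /= 2 * h
            scale = np.max(np.abs(num)) + 1.0
            if np.max(np.abs(num - grad)) > rtol * scale:
                raise ValueError(
                    f"gas-phase potential {self.name!r}: analytic gradient "
                    "disagrees with finite differences"
                )


@dataclass
class EmbeddingVariant:
    """Which embedding terms are active."""

    kind: str = "emle"                       # {emle, mechanical, mm_fixed}
    charge_set_name: str | None = None       # e.g. "q_R", "q_P"
    fixed_charges: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("emle", "mechanical", "mm_fixed"):
            raise ValueError(f"unknown embedding variant {self.kind!r}")
        if self.kind == "mm_fixed":
            if self.fixed_charges is None:
                raise ValueError("mm_fixed variant requires a charge set")
            self.fixed_charges = np.atleast_1d(
                np.asarray(self.fixed_charges, float)
            )


@dataclass
class Restraint:
    """Harmonic bias on an RC, or a one-sided harmonic on a distance."""

    kind: str                                 # {harmonic_rc, one_sided_distance}
    force_constant: float                     # kcal/mol/Å²
    target: float | None = None               # ξ0, Å (harmonic_rc)
    threshold: float | None = None            # Å (one_sided_distance)
    rc: ReactionCoordinate | None = None
    pair: tuple[str, str] | None = None
    half_convention: bool = False

    def __post_init__(self):
        if self.kind not in ("harmonic_rc", "one_sided_distance"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")
        if self.kind == "harmonic_rc" and (self.rc is None
                                           or self.target is None):
            raise ValueError("harmonic_rc needs an rc and a target")
        if self.kind == "one_sided_distance" and (self.pair is None
                                                  or self.threshold is None):
            raise ValueError("one_sided_distance needs a pair and threshold")


def restraint_energy(restraint: Restraint, region: MLRegion):
    """Bias energy (kcal/mol) and forces on ML atoms (kcal/mol/Å)."""
    k = restraint.force_constant
    pref = 0.5 * k if restraint.half_convention else k
    if restraint.kind == "harmonic_rc":
        xi, grad = evaluate_rc(restraint.rc, region, gradient=True)
        delta = xi - restraint.target
        return pref * delta**2, -2.0 * pref * delta * grad
    rc = ReactionCoordinate("weighted_distance_sum", [restraint.pair], [1.0])
    d, grad = evaluate_rc(rc, region, gradient=True)
    if d >= restraint.threshold:
        return 0.0, np.zeros_like(region.coordinates)
    delta = d - restraint.threshold
    return pref * delta**2, -2.0 * pref * delta * grad


def lj_interaction(region: MLRegion, env: MMEnvironment):
    """ML–MM 12-6 Lennard-Jones with Lorentz–Berthelot combining."""
    sig_ml = np.array([ML_LJ_PARAMS[el][0] for el in region.elements])
    eps_ml = np.array([ML_LJ_PARAMS[el][1] for el in region.elements])
    sig = 0.5 * (sig_ml[:, None] + env.lj_sigma[None, :])
    eps = np.sqrt(eps_ml[:, None] * env.lj_epsilon[None, :])
    diff = region.coordinates[:, None, :] - env.positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(eps > 0, (sig / dist) ** 6, 0.0)
    e = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    # dE/dd = 4 eps (−12 sr12 + 6 sr6)/d
    dedd = np.where(
        eps > 0, 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / dist, 0.0
    )
    unit = diff / dist[:, :, None]
    forces_ml = -np.sum(dedd[:, :, None] * unit, axis=1)
    forces_mm = np.sum(dedd[:, :, None] * unit, axis=0)
    return e, forces_ml, forces_mm


def _energy_terms(region, env, gas, static_model, pol_model, variant,
                  frozen=None):
    """The four components at one geometry; ``frozen`` reuses parameters."""
    e_gas, _ = gas(region)
    if env is None or env.n_atoms == 0 or not np.any(env.charges) and not np.any(env.lj_epsilon):
        return e_gas, 0.0, 0.0, 0.0, None
    if variant.kind == "mm_fixed":
        e_static, _, _ = mm_embedding_energy(
            variant.fixed_charges, region, env
        )
        e_induced = 0.0
        density = None
    else:
        if frozen is not None:
            density = frozen[0]
        elif hasattr(static_model, "predict_density"):
            density = static_model.predict_density(region)
        else:
            density = predict_density(static_model, region)
        e_static, _, _ = static_energy(density, region, env)
        if variant.kind == "mechanical":
            e_induced = 0.0
        else:
            if frozen is not None:
                alphas = frozen[1]
            elif hasattr(pol_model, "atomic_polarizabilities"):
                alphas = pol_model.atomic_polarizabilities(density, region)
            else:
                alphas = atomic_polarizabilities(pol_model, density, region)
            result = solve_induction(
                alphas, region, env, pol_model.thole_damping_a
            )
            e_induced = result.e_induced
    e_mm, _, _ = lj_interaction(region, env)
    return e_gas, e_static, e_induced, e_mm, density


def total_energy(
    region: MLRegion,
    env: MMEnvironment | None,
    gas: GasPhasePotential,
    static_model: StaticModel | None = None,
    pol_model: PolarizabilityModel | None = None,
    variant: EmbeddingVariant | None = None,
    forces: str = "none",                  # {none, fd, fast}
    fd_step_bohr: float = FD_STEP_BOHR,
    fd_order: int = 2,
    include_mm_forces: bool = False,
) -> EnergyDecomposition:
    """Evaluate the four-term decomposition for one configuration.

    ``forces="fd"`` differentiates the full energy (density parameters
    re-predicted at each displaced geometry — the correctness-defining
    mode); ``"fast"`` freezes density parameters and polarizabilities at
    the evaluation geometry.  ``include_mm_forces`` additionally
    differentiates with respect to MM positions.
    """
    if variant is None:
        variant = EmbeddingVariant("emle")
    if variant.kind in ("emle", "mechanical") and static_model is None:
        raise ValueError(f"{variant.kind} embedding requires a StaticModel")
    if variant.kind == "emle" and pol_model is None:
        raise ValueError("emle embedding requires a PolarizabilityModel")

    e_gas, e_static, e_induced, e_mm, density = _energy_terms(
        region, env, gas, static_model, pol_model, variant
    )
    forces_ml = forces_mm = None
    if forces in ("fd", "fast"):
        frozen = None
        if forces == "fast" and density is not None:
            if variant.kind != "emle":
                alphas = None
            elif hasattr(pol_model, "atomic_polarizabilities"):
                alphas = pol_model.atomic_polarizabilities(density, region)
            else:
                alphas = atomic_polarizabilities(pol_model, density, region)
            frozen = (density, alphas)

        def etot(coords_ml, coords_mm):
            r = region.with_coordinates(coords_ml)
            e = (env if coords_mm is None
                 else MMEnvironment(coords_mm, env.charges,
                                    env.lj_sigma, env.lj_epsilon))
            g, s, i, m, _ = _energy_terms(
                r, e, gas, static_model, pol_model, variant, frozen=frozen
            )
            return g + s + i + m

        h = fd_step_bohr * BOHR_TO_ANGSTROM
        forces_ml = None
        if forces == "fd" and fd_order == 2:
            forces_ml = _fd_forces_batched(
                region, env, gas, static_model, pol_model, variant, h
            )
        if forces_ml is None:
            forces_ml = _fd_forces(
                lambda c: etot(c, None), region.coordinates, h, fd_order
            )
        if include_mm_forces and env is not None and env.n_atoms:
            forces_mm = _fd_forces(
                lambda c: etot(region.coordinates, c), env.positions, h,
                fd_order,
            )
    return EnergyDecomposition(
        e_gas=e_gas, e_static=e_static, e_induced=e_induced, e_mm=e_mm,
        forces_ml=forces_ml, forces_mm=forces_mm,
        meta={
            "variant": variant.kind,
            "charge_set": variant.charge_set_name,
            "force_mode": forces,
            "mm_internal": "excluded(frozen environment)",
        },
    )


def _fd_forces_batched(region, env, gas, static_model, pol_model, variant, h):
    """Central-difference ML forces via the vectorised batch evaluator.

    Returns None when the batch path does not apply (it then falls back to
    the sequential evaluator with identical numerics).
    """
    from .batched import decomposition_energies

    coords = region.coordinates
    n = coords.shape[0]
    batch = np.repeat(coords[None, :, :], 6 * n, axis=0)
    k = 0
    for i in range(n):
        for c in range(3):
            batch[k, i, c] += h
            batch[k + 1, i, c] -= h
            k += 2
    try:
        energies = decomposition_energies(
            region, batch, env, gas, static_model, pol_model, variant
        )
    except (np.linalg.LinAlgError, NotImplementedError):
        return None
    grad = (energies[0::2] - energies[1::2]).reshape(n, 3) / (2 * h)
    return -grad


def _fd_forces(efun, coords, h, order):
    coords = np.asarray(coords, float)
    grad = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for k in range(3):
            if order == 2:
                stencil = ((h, 0.5), (-h, -0.5))
            elif order == 4:
                stencil = (
                    (2 * h, -1 / 12), (h, 8 / 12), (-h, -8 / 12),
                    (-2 * h, 1 / 12),
                )
            else:
                raise ValueError("fd_order must be 2 or 4")
            acc = 0.0
            for dx, w in stencil:
                c = coords.copy()
                c[i, k] += dx
                acc += w * efun(c)
            grad[i, k] = acc / h
    return -grad


def induced_from_reference(e_ref_total, e_gas, e_static):
    """Back out the induction component from a reference total energy."""
    return e_ref_total - (e_gas + e_static)


# ---------------------------------------------------------------------------
# toy reactive gas-phase surface
# ---------------------------------------------------------------------------

@dataclass
class ToySurfaceParameters:
    """Analytic double-well reactive surface over a small molecule.

    Two Morse wells in the distance-difference coordinate
    ξ = d(break) − d(form), coupled through a smooth tanh switching
    function, plus harmonic scaffold bonds that keep the remaining degrees
    of freedom near a reference geometry.  The construction places the
    reactant minimum at ``rc_reactant`` (profile value ≈ 0), the product
    minimum at ``rc_product`` (≈ ``delta_e``) and the barrier top at the
    midpoint with height ``barrier`` above the reactant well (exact when
    ``delta_e = 0`` by symmetry; tanh tails contribute < 1e−3 kcal/mol at
    the default switch width).
    """

    breaking_pair: tuple[str, str]
    forming_pair: tuple[str, str]
    rc_reactant: float = -1.6        # Å
    rc_product: float = 1.6          # Å
    barrier: float = 15.0            # kcal/mol
    delta_e: float = 0.0             # product − reactant, kcal/mol
    morse_depth: float = 16.0        # kcal/mol
    morse_a: float = 1.5             # 1/Å
    switch_width: float = 0.35       # Å
    scaffold: list[tuple[str, str, float, float]] = field(
        default_factory=list
    )                                 # (label_a, label_b, k, d0)
    linear_bends: list[tuple[str, str, str, float]] = field(
        default_factory=list
    )                                 # (A, B, C, k): E = k·(1 + cos θ_ABC)
    perp_bends: list[tuple[str, str, str, float]] = field(
        default_factory=list
    )                                 # (A, B, C, k): E = k·cos²θ_ABC

    @property
    def rc(self) -> ReactionCoordinate:
        return ReactionCoordinate(
            "distance_difference", [self.breaking_pair, self.forming_pair]
        )


def toy_profile(p: ToySurfaceParameters, xi):
    """1D gas-phase profile V(ξ) and dV/dξ."""
    xi = np.asarray(xi, float)
    mid = 0.5 * (p.rc_reactant + p.rc_product)
    d_half = mid - p.rc_reactant
    crossing = p.morse_depth * (1 - np.exp(-p.morse_a * d_half)) ** 2
    bump = p.barrier - crossing - 0.5 * p.delta_e

    em_r = np.exp(-p.morse_a * (xi - p.rc_reactant))
    em_p = np.exp(-p.morse_a * (p.rc_product - xi))
    m_r = p.morse_depth * (1 - em_r) ** 2
    m_p = p.morse_depth * (1 - em_p) ** 2
    dm_r = 2 * p.morse_depth * (1 - em_r) * p.morse_a * em_r
    dm_p = -2 * p.morse_depth * (1 - em_p) * p.morse_a * em_p

    t = np.tanh((xi - mid) / p.switch_width)
    s = 0.5 * (1 + t)
    ds = 0.5 * (1 - t**2) / p.switch_width

    v = (1 - s) * m_r + s * (m_p + p.delta_e) + bump * 4 * s * (1 - s)
    dv = (
        (1 - s) * dm_r + s * dm_p
        + ds * (m_p + p.delta_e - m_r)
        + bump * 4 * (1 - 2 * s) * ds
    )
    return v, dv


def _cos_angle_grad(coords, ia, ib, ic):
    """cos of the A–B–C angle and its gradient w.r.t. the three atoms."""
    u = coords[ia] - coords[ib]
    v = coords[ic] - coords[ib]
    cu = np.linalg.norm(u)
    cv = np.linalg.norm(v)
    c = float(u @ v / (cu * cv))
    da = v / (cu * cv) - c * u / cu**2
    dc = u / (cu * cv) - c * v / cv**2
    return c, da, dc


def toy_reactive_surface(params: ToySurfaceParameters) -> GasPhasePotential:
    """Wrap the analytic surface as a :class:`GasPhasePotential`."""

    def fn(region: MLRegion):
        xi, grad_xi = evaluate_rc(params.rc, region, gradient=True)
        v, dv = toy_profile(params, xi)
        e = float(v)
        grad = dv * grad_xi
        coords = region.coordinates
        for la, lb, k, d0 in params.scaffold:
            ia, ib = region.index_of(la), region.index_of(lb)
            rij = coords[ia] - coords[ib]
            d = float(np.linalg.norm(rij))
            e += k * (d - d0) ** 2
            g = 2 * k * (d - d0) * rij / d
            grad[ia] += g
            grad[ib] -= g
        for la, lb, lc, k in params.linear_bends:
            ia, ib, ic = (region.index_of(x) for x in (la, lb, lc))
            c, da, dc = _cos_angle_grad(coords, ia, ib, ic)
            e += k * (1.0 + c)
            grad[ia] += k * da
            grad[ic] += k * dc
            grad[ib] -= k * (da + dc)
        for la, lb, lc, k in params.perp_bends:
            ia, ib, ic = (region.index_of(x) for x in (la, lb, lc))
            c, da, dc = _cos_angle_grad(coords, ia, ib, ic)
            e += k * c**2
            grad[ia] += 2 * k * c * da
            grad[ic] += 2 * k * c * dc
            grad[ib] -= 2 * k * c * (da + dc)
        return e, grad

    def batch_fn(template: MLRegion, coords: np.ndarray) -> np.ndarray:
        idx = [
            [template.index_of(l) for l in pair]
            for pair in (params.breaking_pair, params.forming_pair)
        ]
        d_b = np.linalg.norm(
            coords[:, idx[0][0]] - coords[:, idx[0][1]], axis=1
        )
        d_f = np.linalg.norm(
            coords[:, idx[1][0]] - coords[:, idx[1][1]], axis=1
        )
        e, _ = toy_profile(params, d_b - d_f)
        for la, lb, k, d0 in params.scaffold:
            ia, ib = template.index_of(la), template.index_of(lb)
            d = np.linalg.norm(coords[:, ia] - coords[:, ib], axis=1)
            e = e + k * (d - d0) ** 2
        for bends, form in ((params.linear_bends, "linear"),
                            (params.perp_bends, "perp")):
            for la, lb, lc, k in bends:
                ia, ib, ic = (template.index_of(x) for x in (la, lb, lc))
                u = coords[:, ia] - coords[:, ib]
                v = coords[:, ic] - coords[:, ib]
                c = np.sum(u * v, axis=1) / (
                    np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
                )
                e = e + (k * (1.0 + c) if form == "linear" else k * c**2)
        return e

    return GasPhasePotential(
        fn=fn,
        name="toy-reactive-surface",
        notes=(
            "analytic double-well over a distance-difference coordinate; "
            "stands in for a gas-phase machine-learned potential"
        ),
        batch_fn=batch_fn,
    )


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB)
# ---------------------------------------------------------------------------

@dataclass
class MDState:
    coordinates: np.ndarray     # Å
    velocities: np.ndarray      # Å/fs


def initial_velocities(masses, temperature, rng):
    """Maxwell–Boltzmann draw, Å/fs."""
    masses = np.asarray(masses, float)
    sigma = np.sqrt(KB_KCALMOL * temperature * FORCE_TO_ACC / masses)
    return sigma[:, None] * rng.standard_normal((len(masses), 3))


def langevin_step(
    state: MDState,
    force_fn: Callable[[np.ndarray], np.ndarray],
    masses: np.ndarray,
    dt: float,
    temperature: float,
    friction: float,
    rng: np.random.Generator,
    forces: np.ndarray | None = None,
) -> tuple[MDState, np.ndarray]:
    """One BAOAB update.  dt in fs, friction in 1/fs, forces kcal/mol/Å.

    At zero temperature and friction this reduces to velocity Verlet.
    Returns the new state and the forces at the new coordinates (reusable
    for the next step).
    """
    masses = np.asarray(masses, float)[:, None]
    if forces is None:
        forces = force_fn(state.coordinates)
    v = state.velocities + 0.5 * dt * forces * FORCE_TO_ACC / masses
    x = state.coordinates + 0.5 * dt * v
    if friction > 0:
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt(max(0.0, 1.0 - c1**2))
    else:
        c1, c2 = 1.0, 0.0
    sigma = np.sqrt(KB_KCALMOL * temperature * FORCE_TO_ACC / masses)
    v = c1 * v + c2 * sigma * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    new_forces = force_fn(x)
    v = v + 0.5 * dt * new_forces * FORCE_TO_ACC / masses
    return MDState(x, v), new_forces


@dataclass
class LangevinIntegrator:
    """Seeded BAOAB integrator over an arbitrary force callable."""

    masses: np.ndarray
    dt: float = 0.5                # fs
    temperature: float = 300.0     # K
    friction: float = 0.01         # 1/fs
    seed: int = 0

    def __post_init__(self):
        self.masses = np.asarray(self.masses, float)
        self.rng = np.random.default_rng(self.seed)

    def run(self, coordinates, force_fn, n_steps,
            velocities=None, callback=None):
        if velocities is None:
            velocities = initial_velocities(
                self.masses, self.temperature, self.rng
            )
        state = MDState(
            np.asarray(coordinates, float).copy(),
            np.asarray(velocities, float).copy(),
        )
        forces = force_fn(state.coordinates)
        for step in range(n_steps):
            state, forces = langevin_step(
                state, force_fn, self.masses, self.dt, self.temperature,
                self.friction, self.rng, forces=forces,
            )
            if callback is not None:
                callback(step, state)
        return state


def masses_for(elements: list[str]) -> np.ndarray:
    return np.array([ATOMIC_MASSES[el] for el in elements])
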