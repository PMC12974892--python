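"""Synthetic ground truth standing in for gas-phase QM reference data.

A small reactive toy molecule — a collinear O1–C1(–H1)–O2 anion in which
the C1–O1 bond breaks while C1–O2 forms, net charge −1 — is equipped with
an analytic double-well gas-phase surface and *exactly known* atomic
properties that vary smoothly with the reaction coordinate
ξ = d(C1–O1) − d(C1–O2):

* each oxygen's charge follows its own logistic detachment variable —
  half an elementary charge moves onto the leaving oxygen as its C–O bond
  cleaves (an oxyanion-like rearrangement); the rules are local, so
  mirror-equivalent atoms carry identical properties;
* Slater widths and volumes swell smoothly with detachment (oxygens) or
  through the transition state (carbon);
* true polarizabilities follow α = k_α · k_Z · v with a k_α field that is
  a stated smooth function of the local coordination number
  c_i = Σ_j 1/(1 + exp((d_ij − r₀)/w)): a Gaussian bump centred at each
  element's mid-reaction coordination, so the reactive pair roughly
  doubles its polarizability through the transition-state region.

Everything downstream (GPR property models, k_Z/k_α fits, embedding
variants, umbrella sampling) can therefore be trained and validated
against exact reference tables without any quantum chemistry.  All
randomness flows from a single top-level seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MLRegion, MMEnvironment
from .engine import (
    GasPhasePotential,
    ToySurfaceParameters,
    toy_reactive_surface,
)
from .static import DensityParameters, static_energy
from .thole import molecular_polarizability, solve_induction
from .units import VALENCE_POPULATIONS


def _substream(seed: int, name: str) -> np.random.Generator:
    import zlib

    child = np.random.SeedSequence(
        [seed % 2**31, zlib.crc32(name.encode()) % 2**31]
    )
    return np.random.default_rng(child)


@dataclass
class GroundTruthModel:
    """The study conditions: toy molecule, surface and true properties."""

    elements: list[str] = field(
        default_factory=lambda: ["O", "C", "O", "H"]
    )
    atom_labels: list[str] = field(
        default_factory=lambda: ["O1", "C1", "O2", "H1"]
    )
    total_charge: int = -1
    surface: ToySurfaceParameters = None
    # local property rules, per element: a bound oxygen carries −0.30 e
    # and gains another −0.50 e as it detaches (oxyanion formation); its
    # valence width and volume swell with detachment; the carbon's
    # density swells symmetrically through the transition state.  All
    # rules are functions of each atom's OWN local state, so mirror-
    # equivalent atoms get identical properties.
    q_bound: dict = field(default_factory=lambda: {
        "O": -0.30, "C": 0.15, "H": -0.05})
    q_detach_shift: dict = field(default_factory=lambda: {
        "O": -0.50, "C": 0.0, "H": 0.0})
    width_base: dict = field(default_factory=lambda: {
        "O": 0.42, "C": 0.46, "H": 0.31})               # bohr
    width_amp: dict = field(default_factory=lambda: {
        "O": 0.10, "C": 0.0, "H": 0.0})                 # relative
    volume_base: dict = field(default_factory=lambda: {
        "O": 23.0, "C": 35.0, "H": 7.0})                # bohr³
    volume_amp: dict = field(default_factory=lambda: {
        "O": 0.30, "C": 0.05, "H": 0.0})                # relative
    prop_switch_width: float = 0.4                      # Å along ξ
    k_z_true: dict = field(default_factory=lambda: {
        "H": 0.25, "C": 0.25, "O": 0.40})
    # k_α bump: amplitude and centre per element, shared width (in
    # coordination units).  Oxygen peaks at zero coordination (a free
    # oxyanion is far more polarizable than a bound oxygen), carbon at its
    # mid-reaction coordination dip; H unaffected.
    k_alpha_amp: dict = field(default_factory=lambda: {
        "O": 1.0, "C": 0.4, "H": 0.0})
    k_alpha_center: dict = field(default_factory=lambda: {
        "O": 0.0, "C": 1.3, "H": 1.0})
    k_alpha_sigma: float = 0.45
    coord_r0: float = 1.8                               # Å
    coord_w: float = 0.2                                # Å
    thole_damping_a: float = 0.39
    bond_ch: float = 1.09
    bond_sum: float = 4.3        # d(C1–O1) + d(C1–O2) at generation, Å

    def __post_init__(self):
        if self.surface is None:
            # collinear O1–C1–O2 oxygen-anion transfer: every soft mode is
            # either an exact isometry (H1 azimuth), energetically free
            # (H1 tilt), or restrained (chain bend via the O1–O2 term), so
            # umbrella windows equilibrate within tens of femtoseconds
            self.surface = ToySurfaceParameters(
                breaking_pair=("C1", "O1"),
                forming_pair=("C1", "O2"),
                rc_reactant=-1.6,
                rc_product=1.6,
                barrier=20.0,
                delta_e=-4.0,
                scaffold=[
                    ("C1", "H1", 300.0, 1.09),
                    ("O1", "O2", 60.0, 4.3),
                ],
                linear_bends=[("O1", "C1", "O2", 100.0)],
                perp_bends=[("O1", "C1", "H1", 50.0)],
            )

    # -- analytic property fields ------------------------------------------

    @property
    def rc(self):
        return self.surface.rc

    @property
    def q_reactant(self) -> np.ndarray:
        """Reactant-state charges (the fixed q_R set for MM embedding)."""
        return self.true_density(
            self.build_geometry(self.surface.rc_reactant)
        ).charges

    @property
    def q_product(self) -> np.ndarray:
        """Product-state charges (the fixed q_P set for MM embedding)."""
        return self.true_density(
            self.build_geometry(self.surface.rc_product)
        ).charges

    def gas_potential(self) -> GasPhasePotential:
        return toy_reactive_surface(self.surface)

    def switch(self, xi: float) -> float:
        mid = 0.5 * (self.surface.rc_reactant + self.surface.rc_product)
        return 1.0 / (1.0 + np.exp(-(xi - mid) / self.prop_switch_width))

    def coordination(self, region: MLRegion) -> np.ndarray:
        coords = region.coordinates
        d = np.linalg.norm(
            coords[:, None, :] - coords[None, :, :], axis=-1
        )
        s = 1.0 / (1.0 + np.exp((d - self.coord_r0) / self.coord_w))
        np.fill_diagonal(s, 0.0)
        return s.sum(axis=1)

    def detachment(self, region: MLRegion) -> np.ndarray:
        """Per-atom reaction progress, 0 = bound, 1 = detached.

        Oxygens use their own C1 distance (a local variable, so the two
        mirror-related oxygens with identical environments get identical
        properties); carbon and hydrogen use the symmetric mid-reaction
        bump 4σ(1−σ) of the global switch.  On the ideal path the oxygen
        variables reduce to σ(ξ) and σ(−ξ) exactly.
        """
        from .core import UnresolvedLabelError, evaluate_rc

        try:
            c1 = region.index_of("C1")
            xi = evaluate_rc(self.rc, region)
        except UnresolvedLabelError:
            # fragment without the reactive carbon: every oxygen counts as
            # fully detached, nothing is mid-reaction
            rho = np.zeros(region.n_atoms)
            rho[[el == "O" for el in region.elements]] = 1.0
            return rho
        sig = self.switch(xi)
        bump = 4.0 * sig * (1.0 - sig)
        w_d = self.prop_switch_width / 2.0
        mid = self.bond_sum / 2.0
        rho = np.empty(region.n_atoms)
        for i, el in enumerate(region.elements):
            if el == "O":
                d = float(np.linalg.norm(
                    region.coordinates[i] - region.coordinates[c1]
                ))
                rho[i] = 1.0 / (1.0 + np.exp(-(d - mid) / w_d))
            else:
                rho[i] = bump
        return rho

    def true_density(self, region: MLRegion) -> DensityParameters:
        rho = self.detachment(region)
        els = region.elements
        q = np.array([self.q_bound[el] for el in els]) + np.array(
            [self.q_detach_shift[el] for el in els]) * rho
        # exact total charge: spread the (small, jitter-induced) residual
        q = q + (self.total_charge - q.sum()) / len(q)
        s = np.array([self.width_base[el] for el in els]) * (
            1.0 + np.array([self.width_amp[el] for el in els]) * rho
        )
        v = np.array([self.volume_base[el] for el in els]) * (
            1.0 + np.array([self.volume_amp[el] for el in els]) * rho
        )
        pops = np.array([VALENCE_POPULATIONS[el] for el in els])
        return DensityParameters(q, s, pops, v)

    def true_k_alpha(self, region: MLRegion) -> np.ndarray:
        c = self.coordination(region)
        amp = np.array([self.k_alpha_amp[el] for el in region.elements])
        c0 = np.array([self.k_alpha_center[el] for el in region.elements])
        return 1.0 + amp * np.exp(
            -((c - c0) ** 2) / (2.0 * self.k_alpha_sigma**2)
        )

    def true_alphas(self, region: MLRegion,
                    flexible: bool = True) -> np.ndarray:
        density = self.true_density(region)
        kz = np.array([self.k_z_true[el] for el in region.elements])
        alpha = kz * density.volumes
        if flexible:
            alpha = self.true_k_alpha(region) * alpha
        return alpha

    # -- geometry ----------------------------------------------------------

    def build_geometry(self, xi: float, jitter: float = 0.0,
                       rng: np.random.Generator | None = None) -> MLRegion:
        """Place the toy molecule at reaction progress ξ (Å)."""
        d1 = 0.5 * (self.bond_sum + xi)    # C1–O1 (breaking)
        d2 = 0.5 * (self.bond_sum - xi)    # C1–O2 (forming)
        c1 = np.zeros(3)
        o1 = np.array([d1, 0.0, 0.0])
        o2 = np.array([-d2, 0.0, 0.0])
        h1 = c1 + self.bond_ch * np.array([0.0, 1.0, 0.0])
        coords = np.array([o1, c1, o2, h1])
        if jitter > 0:
            if rng is None:
                raise ValueError("jitter needs an rng")
            coords = coords + jitter * rng.standard_normal(coords.shape)
        return MLRegion(
            list(self.elements), coords, self.total_charge,
            list(self.atom_labels),
        )


def default_ground_truth() -> GroundTruthModel:
    return GroundTruthModel()


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_conformers(
    model: GroundTruthModel,
    n: int,
    seed: int = 0,
    rc_min: float | None = None,
    rc_max: float | None = None,
    jitter: float = 0.02,
    thermal: bool = False,
    temperature: float = 300.0,
    bias_k: float = 100.0,
    md_steps: int = 120,
) -> tuple[list[MLRegion], np.ndarray]:
    """``n`` frames stratified across the reaction-coordinate range.

    With ``thermal=False`` each frame is the ideal geometry at its RC
    stratum plus a small Gaussian coordinate jitter — a smooth, noise-free
    surface for parameter-recovery studies.  With ``thermal=True`` each
    frame is drawn by short RC-restrained Langevin dynamics on the
    gas-phase surface, the way training structures are harvested from
    umbrella windows in practice; this samples the soft angular modes a
    simulation will actually visit.  Deterministic given ``seed``; RC
    values are re-measured from the final geometries.
    """
    from .core import evaluate_rc

    if rc_min is None:
        rc_min = model.surface.rc_reactant - 0.2
    if rc_max is None:
        rc_max = model.surface.rc_product + 0.2
    rng = _substream(seed, "conformers")
    span = rc_max - rc_min
    targets = rc_min + span * (
        (np.arange(n) + 0.25 + 0.5 * rng.random(n)) / n
    )
    regions = []
    rc_values = np.empty(n)
    if thermal:
        from .engine import LangevinIntegrator, masses_for

        gas = model.gas_potential()
        template = model.build_geometry(0.0)
        masses = masses_for(template.elements)
        for i, t in enumerate(targets):
            region = model.build_geometry(float(t))

            def force_fn(coords, t=t):
                r = template.with_coordinates(coords)
                _, grad = gas(r)
                xi, gxi = evaluate_rc(model.rc, r, gradient=True)
                return -grad - 2.0 * bias_k * (xi - t) * gxi

            integ = LangevinIntegrator(
                masses=masses, dt=0.5, temperature=temperature,
                friction=0.2, seed=int(rng.integers(2**31)),
            )
            final = integ.run(region.coordinates, force_fn, md_steps)
            regions.append(template.with_coordinates(final.coordinates))
            rc_values[i] = evaluate_rc(model.rc, regions[-1])
    else:
        width = span / n
        for i, t in enumerate(targets):
            # resample the jitter until the measured RC stays inside its
            # stratum, so the frames tile the RC range without gaps
            lo_i, hi_i = rc_min + i * width, rc_min + (i + 1) * width
            for _ in range(200):
                region = model.build_geometry(float(t), jitter=jitter,
                                              rng=rng)
                rc = evaluate_rc(model.rc, region)
                if lo_i <= rc <= hi_i:
                    break
            regions.append(region)
            rc_values[i] = rc
    return regions, rc_values


def generate_environment(
    style: str = "droplet",
    n_charges: int = 80,
    radius: float = 7.0,
    charge_scale: float = 0.7,
    seed: int = 0,
    region: MLRegion | None = None,
    exclusion_coordinates: np.ndarray | None = None,
    min_approach: float = 2.7,
    net_neutral: bool = True,
    dipoles: bool = True,
    dipole_separation: float = 0.7,
    lj_sigma: float = 3.15,
    lj_epsilon: float = 0.152,
) -> MMEnvironment:
    """Random point-charge environment around the ML region.

    ``droplet`` fills a sphere of the given radius (centred on the ML
    centroid); ``shell`` places sites on its surface.  By default each
    site is a randomly oriented ±``charge_scale`` pair separated by
    ``dipole_separation`` Å — a water-like dipole (≈2.4 D at the default
    0.7 e / 0.7 Å), which exerts strong local fields without the runaway
    monopole coupling of isolated random charges.  With ``dipoles=False``
    single charges uniform in (−scale, scale) are placed instead.  No
    charge comes closer than ``min_approach`` Å to any ML atom;
    ``net_neutral`` enforces Σq = 0 exactly (automatic for dipoles).
    """
    if style not in ("droplet", "shell"):
        raise ValueError(f"unknown environment style {style!r}")
    rng = _substream(seed, f"environment-{style}")
    if exclusion_coordinates is not None:
        ml = np.atleast_2d(np.asarray(exclusion_coordinates, float))
    elif region is not None:
        ml = region.coordinates
    else:
        ml = np.zeros((1, 3))
    center = ml.mean(axis=0)
    n_sites = n_charges // 2 if dipoles else n_charges
    positions, charges = [], []
    attempts = 0
    while len(charges) < (2 * n_sites if dipoles else n_sites):
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place environment charges")
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        r = radius if style == "shell" else radius * rng.random() ** (1 / 3)
        p = center + r * u
        if dipoles:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            p_plus = p + 0.5 * dipole_separation * axis
            p_minus = p - 0.5 * dipole_separation * axis
            # minus end is the LJ-carrying (O-like) site and keeps the full
            # approach distance; the plus (H-like) end may come closer,
            # like a hydrogen-bond donor
            if np.min(np.linalg.norm(ml - p_minus, axis=1)) < min_approach:
                continue
            if np.min(np.linalg.norm(ml - p_plus, axis=1)) < 0.7 * min_approach:
                continue
            positions.extend([p_plus, p_minus])
            charges.extend([charge_scale, -charge_scale])
        else:
            if np.min(np.linalg.norm(ml - p, axis=1)) < min_approach:
                continue
            positions.append(p)
            charges.append(charge_scale * (2.0 * rng.random() - 1.0))
    positions = np.array(positions)
    charges = np.array(charges)
    if net_neutral:
        charges -= charges.mean()
    n = len(charges)
    return MMEnvironment(
        positions, charges,
        np.full(n, lj_sigma), np.full(n, lj_epsilon),
    )


def catalytic_environment(
    model: GroundTruthModel,
    seed: int = 0,
    distance: float = 2.2,
    separation: float = 1.2,
    charge: float = 0.8,
    rc_span: tuple[float, float] = (-1.8, 1.8),
    **env_kwargs,
) -> MMEnvironment:
    """Solvent-like droplet plus one fixed "catalytic" dipole near O1.

    The dipole sits perpendicular to the reaction axis at the oxygen's
    transition-state position, positive end toward the oxygen — the
    analogue of a positively charged active-site residue next to a
    nascent oxyanion.  Because the oxygen's polarizability grows through
    the transition state, this near field makes the induced component a
    substantial, RC-dependent part of the embedding energy.
    """
    lo, hi = rc_span
    path = np.vstack([
        model.build_geometry(x).coordinates
        for x in np.linspace(lo, hi, 5)
    ])
    env = generate_environment(
        seed=seed, exclusion_coordinates=path, **env_kwargs
    )
    o1_ts = model.build_geometry(0.0).coordinates[0]
    direction = np.array([0.0, -1.0, 0.0])   # opposite side from H1
    p_plus = o1_ts + distance * direction
    p_minus = o1_ts + (distance + separation) * direction
    positions = np.vstack([env.positions, p_plus, p_minus])
    charges = np.concatenate([env.charges, [charge, -charge]])
    # small LJ site on the positive end keeps the oxygen from collapsing
    # onto the bare charge during dynamics
    lj_sigma = np.concatenate([env.lj_sigma, [1.8, env.lj_sigma[0]]])
    lj_eps = np.concatenate([env.lj_epsilon, [0.1, env.lj_epsilon[0]]])
    return MMEnvironment(positions, charges, lj_sigma, lj_eps)


class DuplicateFrameError(ValueError):
    pass


def assemble_training_set(
    seed_structures: list,
    windows: dict | None = None,
    per_window: int = 0,
    extra: dict | None = None,
) -> tuple[list, dict]:
    """Concatenate seed structures, per-window subsamples and extras.

    ``windows`` maps a window key to its candidate frames; ``per_window``
    frames are taken from each window (evenly strided), and ``extra`` maps
    window keys to additional counts drawn from the remaining frames.
    Returns the dataset and a manifest of counts; duplicate frames are
    rejected.
    """
    windows = windows or {}
    extra = extra or {}
    dataset = list(seed_structures)
    manifest = {
        "n_seed": len(seed_structures),
        "per_window": {},
        "extra": {},
    }
    taken: dict = {}
    for key in sorted(windows, key=str):
        frames = list(windows[key])
        if per_window > len(frames):
            raise ValueError(
                f"window {key!r} has {len(frames)} frames < {per_window}"
            )
        stride_idx = np.linspace(0, len(frames) - 1, per_window).astype(int) \
            if per_window else np.array([], dtype=int)
        chosen = [frames[i] for i in dict.fromkeys(stride_idx.tolist())]
        if per_window and len(chosen) != per_window:
            raise DuplicateFrameError(
                f"window {key!r}: subsample stride produced duplicates"
            )
        dataset.extend(chosen)
        taken[key] = set(stride_idx.tolist())
        manifest["per_window"][key] = len(chosen)
    for key, count in extra.items():
        frames = list(windows[key])
        remaining = [i for i in range(len(frames))
                     if i not in taken.get(key, set())]
        if count > len(remaining):
            raise ValueError(f"window {key!r}: not enough frames for extras")
        dataset.extend(frames[i] for i in remaining[:count])
        manifest["extra"][key] = count
    ids = [id(f) if isinstance(f, np.ndarray) else f for f in dataset]
    if len(set(map(str, ids))) != len(ids):
        raise DuplicateFrameError("duplicate frames in assembled dataset")
    manifest["n_total"] = len(dataset)
    return dataset, manifest


# ---------------------------------------------------------------------------
# ground-truth adapters for the embedding engine
# ---------------------------------------------------------------------------

def _rc_batch(model: GroundTruthModel, template: MLRegion,
              coords: np.ndarray) -> np.ndarray:
    i_b = [template.index_of(l) for l in model.surface.breaking_pair]
    i_f = [template.index_of(l) for l in model.surface.forming_pair]
    d_b = np.linalg.norm(coords[:, i_b[0]] - coords[:, i_b[1]], axis=1)
    d_f = np.linalg.norm(coords[:, i_f[0]] - coords[:, i_f[1]], axis=1)
    return d_b - d_f


@dataclass
class TrueStaticModel:
    """Drives the embedding engine with the exact synthetic density."""

    ground_truth: GroundTruthModel

    def predict_density(self, region: MLRegion) -> DensityParameters:
        return self.ground_truth.true_density(region)

    def true_density_batch(self, elements, coords, template):
        gt = self.ground_truth
        b = coords.shape[0]
        xi = _rc_batch(gt, template, coords)
        mid = 0.5 * (gt.surface.rc_reactant + gt.surface.rc_product)
        sig = 1.0 / (1.0 + np.exp(-(xi - mid) / gt.prop_switch_width))
        bump = 4.0 * sig * (1.0 - sig)
        c1 = template.index_of("C1")
        w_d = gt.prop_switch_width / 2.0
        d_mid = gt.bond_sum / 2.0
        rho = np.empty((b, len(elements)))
        for i, el in enumerate(elements):
            if el == "O":
                d = np.linalg.norm(coords[:, i] - coords[:, c1], axis=1)
                rho[:, i] = 1.0 / (1.0 + np.exp(-(d - d_mid) / w_d))
            else:
                rho[:, i] = bump
        q0 = np.array([gt.q_bound[el] for el in elements])
        dq = np.array([gt.q_detach_shift[el] for el in elements])
        q = q0 + dq * rho
        q = q + (gt.total_charge - q.sum(axis=1))[:, None] / len(elements)
        s0 = np.array([gt.width_base[el] for el in elements])
        sa = np.array([gt.width_amp[el] for el in elements])
        v0 = np.array([gt.volume_base[el] for el in elements])
        va = np.array([gt.volume_amp[el] for el in elements])
        s = s0 * (1.0 + sa * rho)
        v = v0 * (1.0 + va * rho)
        pops = np.tile(
            np.array([VALENCE_POPULATIONS[el] for el in elements]),
            (b, 1),
        )
        return q, s, pops, v


@dataclass
class TruePolarizabilityModel:
    """Exact synthetic polarizabilities (fixed or flexible α/v)."""

    ground_truth: GroundTruthModel
    flexible: bool = True

    @property
    def thole_damping_a(self) -> float:
        return self.ground_truth.thole_damping_a

    def atomic_polarizabilities(self, density, region: MLRegion):
        return self.ground_truth.true_alphas(region, flexible=self.flexible)

    def true_alphas_batch(self, elements, coords, template):
        gt = self.ground_truth
        _, _, _, v = TrueStaticModel(gt).true_density_batch(
            elements, coords, template
        )
        kz = np.array([gt.k_z_true[el] for el in elements])
        alpha = kz * v
        if self.flexible:
            dist = np.linalg.norm(
                coords[:, :, None, :] - coords[:, None, :, :], axis=-1
            )
            s = 1.0 / (1.0 + np.exp((dist - gt.coord_r0) / gt.coord_w))
            idx = np.arange(coords.shape[1])
            s[:, idx, idx] = 0.0
            c = s.sum(axis=2)
            amp = np.array([gt.k_alpha_amp[el] for el in elements])
            c0 = np.array([gt.k_alpha_center[el] for el in elements])
            k_alpha = 1.0 + amp * np.exp(
                -((c - c0) ** 2) / (2.0 * gt.k_alpha_sigma**2)
            )
            alpha = k_alpha * alpha
        return alpha


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

def emit_reference_tables(
    model: GroundTruthModel,
    regions: list[MLRegion],
    environments: list[MMEnvironment],
    flexible: bool = True,
) -> dict[str, pd.DataFrame]:
    """Exact reference tables for a set of (conformer, environment) pairs.

    Returns ``properties`` (per-atom q/s/v, a.u.), ``energies`` (the four
    components and their sum, kcal/mol) and ``polarizabilities`` (gas-phase
    molecular tensors, bohr³).
    """
    from .core import evaluate_rc
    from .engine import lj_interaction

    prop_rows, energy_rows, pol_rows = [], [], []
    for fid, (region, env) in enumerate(zip(regions, environments)):
        density = model.true_density(region)
        for a in range(region.n_atoms):
            prop_rows.append({
                "frame_id": fid,
                "atom_index": a,
                "element": region.elements[a],
                "q": density.charges[a],
                "s": density.widths[a],
                "v": density.volumes[a],
            })
        e_gas, _ = model.gas_potential()(region)
        alphas = model.true_alphas(region, flexible=flexible)
        tensor, iso = molecular_polarizability(
            alphas, region, model.thole_damping_a
        )
        pol_rows.append({
            "frame_id": fid,
            "axx": tensor[0, 0], "axy": tensor[0, 1], "axz": tensor[0, 2],
            "ayy": tensor[1, 1], "ayz": tensor[1, 2], "azz": tensor[2, 2],
            "iso": iso,
        })
        if env is not None and env.n_atoms:
            e_static, _, _ = static_energy(density, region, env)
            e_induced = solve_induction(
                alphas, region, env, model.thole_damping_a
            ).e_induced
            e_mm, _, _ = lj_interaction(region, env)
        else:
            e_static = e_induced = e_mm = 0.0
        energy_rows.append({
            "frame_id": fid,
            "rc": evaluate_rc(model.rc, region),
            "e_gas_ref": e_gas,
            "e_static_ref": e_static,
            "e_induced_ref": e_induced,
            "e_mm_ref": e_mm,
            "e_total_ref": e_gas + e_static + e_induced + e_mm,
        })
    return {
        "properties": pd.DataFrame(prop_rows),
        "energies": pd.DataFrame(energy_rows),
        "polarizabilities": pd.DataFrame(pol_rows),
    }
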