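"""Umbrella sampling, WHAM and PMF statistics.

Umbrella windows place harmonic biases U_w(ξ) = K (ξ − c_w)² (no factor ½,
matching the engine's restraint convention) on an inclusive arithmetic grid
of centers.  The weighted histogram analysis method (WHAM) recombines the
biased histograms by self-consistent iteration

    P(b) = Σ_w n_w(b) / Σ_w N_w e^{β f_w} e^{−β U_w(x_b)},
    e^{−β f_w} = Σ_b P(b) e^{−β U_w(x_b)},

converged when the largest change of any window free-energy constant f_w
falls below a tolerance.  The PMF is −kT ln P, shifted so its minimum is
zero.  Uncertainties come either from independent replicas or from
splitting each window's time series into five contiguous fragments and
recomputing the PMF per fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import KB_KCALMOL


class NonOverlappingWindowsError(ValueError):
    """Umbrella histograms do not form a connected chain."""


class WHAMConvergenceError(RuntimeError):
    pass


class NoInteriorMaximumError(ValueError):
    """Profile is monotone between the basins; give an explicit TS range."""


@dataclass
class WindowGrid:
    """Inclusive arithmetic grid of umbrella-window centers."""

    rc_min: float
    rc_max: float
    spacing: float
    force_constant: float    # kcal/mol/Å², engine convention K(Δξ)²

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        n_span = (self.rc_max - self.rc_min) / self.spacing
        if abs(n_span - round(n_span)) > 1e-9 * max(1.0, abs(n_span)):
            raise ValueError(
                f"rc_max {self.rc_max} is not on the lattice "
                f"{self.rc_min} + k·{self.spacing}"
            )

    @property
    def centers(self) -> np.ndarray:
        n = int(round((self.rc_max - self.rc_min) / self.spacing)) + 1
        return self.rc_min + self.spacing * np.arange(n)

    @property
    def n_windows(self) -> int:
        return len(self.centers)


def make_window_grid(rc_min, rc_max, spacing, force_constant) -> WindowGrid:
    return WindowGrid(rc_min, rc_max, spacing, force_constant)


@dataclass
class PMFProfile:
    """Free-energy profile along the reaction coordinate.

    ``free_energy`` is min-shifted to zero (kcal/mol); ``std`` is the
    per-point standard deviation when an uncertainty method was applied.
    """

    rc_grid: np.ndarray
    free_energy: np.ndarray
    std: np.ndarray | None = None
    temperature: float = 300.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rc_grid = np.asarray(self.rc_grid, float)
        self.free_energy = np.asarray(self.free_energy, float)
        if np.any(np.diff(self.rc_grid) <= 0):
            raise ValueError("rc grid must be strictly increasing")
        finite = self.free_energy[np.isfinite(self.free_energy)]
        if len(finite) == 0:
            raise ValueError("profile has no finite values")
        shift = finite.min()
        self.free_energy = self.free_energy - shift
        if self.std is not None:
            self.std = np.asarray(self.std, float)

    def to_frame(self) -> pd.DataFrame:
        d = {"rc": self.rc_grid, "free_energy": self.free_energy}
        d["std"] = (self.std if self.std is not None
                    else np.zeros_like(self.rc_grid))
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaSystem:
    """What umbrella sampling needs to run: coordinates, masses, a force
    callable and the reaction coordinate (value + gradient)."""

    coordinates: np.ndarray
    masses: np.ndarray
    force_fn: object          # coords -> forces (kcal/mol/Å)
    rc_fn: object             # coords -> (value Å, gradient)


def run_umbrella(
    windows: WindowGrid,
    system: UmbrellaSystem,
    replicas: int = 1,
    steps_per_window: int = 500,
    seed: int = 0,
    equilibration: int = 100,
    sample_stride: int = 1,
    dt: float = 0.5,
    temperature: float = 300.0,
    friction: float = 0.15,
    start_fn=None,
) -> pd.DataFrame:
    """Umbrella sweep; each replica uses an independent seed substream.

    ``start_fn(center) -> coords`` provides per-window starting
    geometries (the recommended mode: it avoids the systematic lag a
    chained sweep accumulates when equilibration is short).  Without it,
    windows are chained — each starts from the previous window's final
    configuration.

    Returns a tidy frame (window_center, replica, step, rc_value); windows
    whose samples never enter ±3σ of their center (σ from the stiff-bias
    estimate √(kT/2K)) are listed in ``df.attrs["non_overlapping"]``.
    """
    from .engine import LangevinIntegrator

    k_bias = windows.force_constant
    rows = []
    flagged = []
    sigma_bias = np.sqrt(KB_KCALMOL * temperature / (2.0 * k_bias))
    for rep in range(replicas):
        coords = np.asarray(system.coordinates, float).copy()
        for w_i, center in enumerate(windows.centers):
            if start_fn is not None:
                coords = np.asarray(start_fn(center), float).copy()

            def biased_force(c, center=center):
                f = np.asarray(system.force_fn(c), float)
                xi, grad = system.rc_fn(c)
                return f - 2.0 * k_bias * (xi - center) * grad

            integ = LangevinIntegrator(
                masses=system.masses, dt=dt, temperature=temperature,
                friction=friction,
                seed=int((seed * 100_003 + rep * 1009 + w_i) % 2**31),
            )
            samples = []

            def record(step, state):
                if step >= equilibration and (step - equilibration) % sample_stride == 0:
                    xi, _ = system.rc_fn(state.coordinates)
                    samples.append((step, xi))

            final = integ.run(
                coords, biased_force, equilibration + steps_per_window,
                callback=record,
            )
            coords = final.coordinates
            rc_vals = np.array([s[1] for s in samples])
            if not np.any(np.abs(rc_vals - center) < 3 * sigma_bias):
                flagged.append((rep, float(center)))
            for step, xi in samples:
                rows.append((float(center), rep, step, float(xi)))
    df = pd.DataFrame(
        rows, columns=["window_center", "replica", "step", "rc_value"]
    )
    df.attrs["non_overlapping"] = flagged
    df.attrs["temperature"] = temperature
    df.attrs["force_constant"] = k_bias
    return df


def sample_umbrella_1d(
    potential_fn,
    windows: WindowGrid,
    temperature: float = 300.0,
    n_samples: int = 2000,
    seed: int = 0,
    replicas: int = 1,
    proposal_width: float | None = None,
    burn_in: int = 200,
) -> pd.DataFrame:
    """Metropolis umbrella sampler for scalar potentials (oracle tests).

    The coordinate itself is the reaction coordinate; exact canonical
    sampling of U(x) + K(x−c)² per window.
    """
    beta = 1.0 / (KB_KCALMOL * temperature)
    k = windows.force_constant
    if proposal_width is None:
        proposal_width = 2.0 * np.sqrt(1.0 / (2.0 * beta * k))
    rows = []
    for rep in range(replicas):
        rng = np.random.default_rng((seed * 9176 + rep) % 2**31)
        for center in windows.centers:
            x = float(center)
            e = potential_fn(x) + k * (x - center) ** 2
            t = 0
            for i in range(burn_in + n_samples):
                prop = x + proposal_width * rng.standard_normal()
                e_new = potential_fn(prop) + k * (prop - center) ** 2
                if rng.random() < np.exp(-beta * (e_new - e)):
                    x, e = prop, e_new
                if i >= burn_in:
                    rows.append((float(center), rep, t, x))
                    t += 1
    df = pd.DataFrame(
        rows, columns=["window_center", "replica", "step", "rc_value"]
    )
    df.attrs["temperature"] = temperature
    df.attrs["force_constant"] = k
    return df


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def _check_overlap(occupied: np.ndarray, centers: np.ndarray) -> None:
    """Windows must chain through shared occupied bins (union-find).

    Occupancy is dilated by one bin so that histograms touching at a bin
    boundary count as overlapping.
    """
    occupied = (
        occupied
        | np.roll(occupied, 1, axis=1)
        | np.roll(occupied, -1, axis=1)
    )
    n_w = occupied.shape[0]
    parent = list(range(n_w))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_w):
        for j in range(i + 1, n_w):
            if np.any(occupied[i] & occupied[j]):
                parent[find(i)] = find(j)
    roots = {find(i) for i in range(n_w)}
    if len(roots) > 1:
        groups = {}
        for i in range(n_w):
            groups.setdefault(find(i), []).append(centers[i])
        edges = sorted(max(g) for g in groups.values())[:-1]
        raise NonOverlappingWindowsError(
            "umbrella histograms do not overlap; gaps after window "
            f"centers {edges}"
        )


def wham(
    samples: pd.DataFrame,
    windows: WindowGrid,
    temperature: float = 300.0,
    bin_width: float | None = None,
    tolerance: float = 1e-6,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Self-consistent WHAM over binned umbrella histograms.

    ``samples`` is the tidy frame from the samplers above.  Default bin
    width is a fifth of the window spacing.  Convergence: the largest
    change of any window offset f_w below ``tolerance`` kcal/mol.
    """
    if bin_width is None:
        bin_width = windows.spacing / 5.0
    beta = 1.0 / (KB_KCALMOL * temperature)
    k = windows.force_constant
    centers = windows.centers
    x = samples["rc_value"].to_numpy()
    lo = min(x.min(), centers.min()) - bin_width
    hi = max(x.max(), centers.max()) + bin_width
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])

    counts = np.zeros((windows.n_windows, n_bins))
    wc = samples["window_center"].to_numpy()
    for w_i, c in enumerate(centers):
        # tolerant match: centers may have passed through text round-trips
        sel = samples.loc[
            np.isclose(wc, c, atol=1e-6 * windows.spacing), "rc_value"
        ]
        counts[w_i], _ = np.histogram(sel, bins=edges)
    n_w = counts.sum(axis=1)
    if np.any(n_w == 0):
        missing = centers[n_w == 0]
        raise ValueError(f"no samples for windows at {missing}")
    if windows.n_windows >= 2:
        _check_overlap(counts > 0, centers)

    bias = k * (mids[None, :] - centers[:, None]) ** 2    # (n_w, n_bins)
    boltz = np.exp(-beta * bias)
    total = counts.sum(axis=0)
    f = np.zeros(windows.n_windows)                        # kcal/mol offsets
    for _ in range(max_iter):
        denom = (n_w[:, None] * np.exp(beta * f)[:, None] * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total > 0, total / denom, 0.0)
        z = boltz @ p
        f_new = -np.log(z) / beta
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            break
    else:
        raise WHAMConvergenceError(
            f"WHAM not converged after {max_iter} iterations "
            f"(residual {delta:.3e} kcal/mol)"
        )
    with np.errstate(divide="ignore"):
        pmf = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)) / beta, np.nan)
    keep = np.isfinite(pmf)
    return PMFProfile(
        rc_grid=mids[keep],
        free_energy=pmf[keep],
        temperature=temperature,
        meta={
            "bin_width": bin_width,
            "force_constant": k,
            "window_centers": centers.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _range_min(profile: PMFProfile, rng):
    lo, hi = sorted(rng)
    mask = (profile.rc_grid >= lo) & (profile.rc_grid <= hi)
    if not mask.any():
        raise ValueError(f"no PMF points inside range {rng}")
    return float(np.nanmin(profile.free_energy[mask]))


def pmf_statistics(
    profile: PMFProfile,
    reactant_range: tuple[float, float],
    product_range: tuple[float, float],
    ts_range: tuple[float, float] | None = None,
) -> dict:
    """Barrier Δ‡G and reaction free energy ΔrG from explicit basin ranges.

    The barrier region is the grid between the two basins unless
    ``ts_range`` is given.  A profile with no interior maximum there is
    rejected (give an explicit TS range for monotone profiles).  Both
    statistics are invariant to constant shifts of the profile.
    """
    g_react = _range_min(profile, reactant_range)
    g_prod = _range_min(profile, product_range)
    if ts_range is None:
        inner_lo = min(max(reactant_range), max(product_range))
        inner_hi = max(min(reactant_range), min(product_range))
        lo, hi = sorted((inner_lo, inner_hi))
        mask = (profile.rc_grid > lo) & (profile.rc_grid < hi)
        if not mask.any():
            raise ValueError("no PMF points between the basins")
        vals = profile.free_energy[mask]
        i_max = int(np.nanargmax(vals))
        if i_max in (0, len(vals) - 1) and len(vals) > 2:
            raise NoInteriorMaximumError(
                "profile is monotone between the basins; pass ts_range "
                "explicitly"
            )
        g_ts = float(vals[i_max])
    else:
        lo, hi = sorted(ts_range)
        mask = (profile.rc_grid >= lo) & (profile.rc_grid <= hi)
        if not mask.any():
            raise ValueError(f"no PMF points inside ts_range {ts_range}")
        g_ts = float(np.nanmax(profile.free_energy[mask]))
    return {
        "barrier": g_ts - g_react,
        "reaction_free_energy": g_prod - g_react,
    }


def catalytic_effect(barrier_env_a: float, barrier_env_b: float) -> float:
    """ΔΔ‡G = Δ‡G(B) − Δ‡G(A); negative means environment B catalyses
    relative to A (e.g. enzyme vs water)."""
    return barrier_env_b - barrier_env_a


def pmf_uncertainty(
    samples: pd.DataFrame,
    windows: WindowGrid,
    temperature: float = 300.0,
    method: str = "replica",
    n_fragments: int = 5,
    bin_width: float | None = None,
    reactant_range: tuple[float, float] | None = None,
    product_range: tuple[float, float] | None = None,
    ts_range: tuple[float, float] | None = None,
    tolerance: float = 1e-6,
) -> dict:
    """Per-point PMF standard deviation and propagated Δ‡G/ΔrG errors.

    ``method="replica"`` recomputes one PMF per replica; ``"fragment5"``
    splits each window's time series into ``n_fragments`` contiguous
    fragments and recomputes one PMF per fragment index.  Derived-quantity
    errors are the standard deviation of that quantity across the
    recomputations.
    """
    if method == "replica":
        groups = [g for _, g in samples.groupby("replica")]
    elif method == "fragment5":
        parts = []
        for _, g in samples.groupby(["window_center", "replica"]):
            g = g.sort_values("step").reset_index(drop=True)
            frag = np.minimum(
                (np.arange(len(g)) * n_fragments) // len(g), n_fragments - 1
            )
            parts.append(g.assign(_frag=frag))
        allf = pd.concat(parts)
        groups = [g for _, g in allf.groupby("_frag")]
    else:
        raise ValueError(f"unknown uncertainty method {method!r}")

    profiles = [
        wham(g, windows, temperature, bin_width, tolerance=tolerance)
        for g in groups
    ]
    grid = profiles[0].rc_grid
    values = np.full((len(profiles), len(grid)), np.nan)
    values[0] = profiles[0].free_energy
    for i, p in enumerate(profiles[1:], start=1):
        values[i] = np.interp(grid, p.rc_grid, p.free_energy,
                              left=np.nan, right=np.nan)
    counts = np.sum(np.isfinite(values), axis=0)
    std = np.full(len(grid), np.nan)
    enough = counts > 1
    if len(profiles) > 1 and enough.any():
        std[enough] = np.nanstd(values[:, enough], axis=0, ddof=1)
    elif len(profiles) == 1:
        std = np.zeros(len(grid))
    out = {"rc_grid": grid, "std": std, "profiles": profiles}
    if reactant_range is not None and product_range is not None:
        stats = [
            pmf_statistics(p, reactant_range, product_range, ts_range)
            for p in profiles
        ]
        barriers = np.array([s["barrier"] for s in stats])
        rxn = np.array([s["reaction_free_energy"] for s in stats])
        ddof = 1 if len(profiles) > 1 else 0
        out["barrier_std"] = float(np.std(barriers, ddof=ddof))
        out["reaction_std"] = float(np.std(rxn, ddof=ddof))
        out["barriers"] = barriers
        out["reaction_free_energies"] = rxn
    return out
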