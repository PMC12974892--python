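"""Per-structure decomposition of model error into energy components.

Given reference tables of embedded energies (the interface to whatever
produced them — this module never computes quantum chemistry), the model's
gas, static and induced components are evaluated for each structure and
differenced against the reference.  The reference induced component, when
not tabulated, is reconstructed as

    e_induced_ref = e_total_ref − e_gas_ref − e_static_ref [− e_mm_ref]

(the MM Lennard-Jones term is shared between model and reference, so the
three embedding-component errors sum exactly to the total-energy error).

Also provides the presentation helpers used alongside: smoothing cubic
splines for error-vs-window curves (raw data always retained) and a
radial distribution function with droplet (non-periodic) normalisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MLRegion, MMEnvironment
from .engine import EmbeddingVariant, GasPhasePotential, total_energy
from .static import StaticModel
from .thole import PolarizabilityModel


def component_errors(
    regions: list[MLRegion],
    environments: list[MMEnvironment],
    reference: pd.DataFrame,
    gas: GasPhasePotential,
    static_model: StaticModel,
    pol_model: PolarizabilityModel,
    variant: EmbeddingVariant | None = None,
    windows: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-structure (Δe_gas, Δe_static, Δe_induced), model − reference.

    ``reference`` needs columns frame_id, e_gas_ref, e_static_ref,
    e_total_ref and optionally e_induced_ref / e_mm_ref.  ``windows``
    optionally tags each structure for window-mean aggregation.
    """
    if variant is None:
        variant = EmbeddingVariant("emle")
    if len(reference) != len(regions):
        raise ValueError("reference table and structure list misaligned")
    rows = []
    for i, (region, env) in enumerate(zip(regions, environments)):
        dec = total_energy(region, env, gas, static_model, pol_model, variant)
        r = reference.iloc[i]
        if "e_induced_ref" in reference.columns:
            e_ind_ref = float(r["e_induced_ref"])
        else:
            e_mm_ref = float(r.get("e_mm_ref", 0.0))
            e_ind_ref = (
                float(r["e_total_ref"]) - float(r["e_gas_ref"])
                - float(r["e_static_ref"]) - e_mm_ref
            )
        rows.append({
            "frame_id": r["frame_id"],
            "window": windows[i] if windows is not None else np.nan,
            "d_e_gas": dec.e_gas - float(r["e_gas_ref"]),
            "d_e_static": dec.e_static - float(r["e_static_ref"]),
            "d_e_induced": dec.e_induced - e_ind_ref,
        })
    df = pd.DataFrame(rows)
    df["d_e_total"] = df[["d_e_gas", "d_e_static", "d_e_induced"]].sum(axis=1)
    return df


def window_mean_errors(errors: pd.DataFrame) -> pd.DataFrame:
    """Mean component error per window (order-invariant within windows)."""
    cols = ["d_e_gas", "d_e_static", "d_e_induced", "d_e_total"]
    return errors.groupby("window", sort=True)[cols].mean().reset_index()


def smooth_curve(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "cubic_spline",
    smoothing: float | None = None,
    n_out: int | None = None,
) -> pd.DataFrame:
    """Smoothing cubic spline through (x, y); raw data kept alongside.

    ``smoothing`` is the spline regularisation λ (0 → interpolating
    spline through all points; None → generalised cross-validation).
    Returns a frame with columns x, raw, smooth (evaluated at the input
    abscissae, or at ``n_out`` evenly spaced points).
    """
    if method != "cubic_spline":
        raise ValueError(f"unknown smoothing method {method!r}")
    from scipy.interpolate import make_smoothing_spline

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = np.argsort(x)
    spline = make_smoothing_spline(x[order], y[order], lam=smoothing)
    if n_out is None:
        xs = x
        raw = y
    else:
        xs = np.linspace(x.min(), x.max(), n_out)
        raw = np.interp(xs, x[order], y[order])
    return pd.DataFrame({"x": xs, "raw": raw, "smooth": spline(xs)})


def rdf(
    center_frames: list[np.ndarray],
    partner_frames: list[np.ndarray],
    bin_width: float,
    r_max: float,
    mode: str = "all_pairs",
) -> pd.DataFrame:
    """Radial distribution function for finite (non-periodic) droplets.

    ``mode="all_pairs"`` histograms every center–partner distance;
    ``"min_distance"`` histograms each partner's minimum distance to any
    center (the around-the-substrate variant).  Counts are normalised by
    the shell volume 4πr²Δr and a droplet density estimated from the
    outermost 20% of sampled shells (so g → 1 at the edge of the sampled
    range by construction); there is no periodic-image convention.
    """
    if mode not in ("all_pairs", "min_distance"):
        raise ValueError(f"unknown rdf mode {mode!r}")
    if not center_frames:
        raise ValueError("need at least one frame")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    n_norm = 0
    for centers, partners in zip(center_frames, partner_frames):
        centers = np.atleast_2d(centers)
        partners = np.atleast_2d(partners)
        d = np.linalg.norm(
            centers[:, None, :] - partners[None, :, :], axis=-1
        )
        if mode == "min_distance":
            d = d.min(axis=0)
            n_norm += 1
        else:
            d = d.ravel()
            n_norm += len(centers)
        h, _ = np.histogram(d, bins=edges)
        counts += h
    mids = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * mids**2 * bin_width
    outer = mids >= 0.8 * r_max
    outer_counts = counts[outer].sum()
    outer_vol = shell_vol[outer].sum()
    if outer_counts > 0:
        rho = outer_counts / (n_norm * outer_vol)
    else:
        rho = counts.sum() / (n_norm * (4.0 / 3.0) * np.pi * r_max**3)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = counts / (n_norm * shell_vol * rho)
    return pd.DataFrame({"r": mids, "g": g, "counts": counts})
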