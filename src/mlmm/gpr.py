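"""Sparse Gaussian-process regression for scalar atomic properties.

A subset-of-regressors (SoR/Nyström) sparse GP with an RBF kernel

    k(x, x') = σ² exp(−‖x − x'‖² / (2 ℓ²))

and inducing points chosen by deterministic farthest-point sampling.
Hyperparameters are fixed by configuration rather than optimised:
reproducibility of the training pipeline is valued over marginal-likelihood
tuning, and the fitted weights admit a dense-GP oracle check when
``n_inducing = n_samples``.

Predictions take the form  f(x) = prior_mean + Σ_m w_m k(x, x_m),  so the
same container also serves models whose weights were obtained by other
penalised least-squares fits (the flexible polarizability correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateFeaturesError(ValueError):
    """All training features identical — no signal to regress on.

    Usually means the descriptor cutoff is too small for the system; try a
    larger ``cutoff_radius``.
    """


@dataclass
class SparseGPRModel:
    inducing_points: np.ndarray      # (m, n_features)
    weights: np.ndarray              # (m,)
    kernel_lengthscale: float
    kernel_variance: float
    noise_variance: float
    prior_mean: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inducing_points = np.atleast_2d(
            np.asarray(self.inducing_points, float)
        )
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        if len(self.weights) != len(self.inducing_points):
            raise ValueError("weights length != number of inducing points")
        if self.kernel_lengthscale <= 0 or self.kernel_variance <= 0:
            raise ValueError("kernel hyperparameters must be positive")

    def to_arrays(self) -> dict:
        return {
            "inducing_points": self.inducing_points,
            "weights": self.weights,
            "hyper": np.array([
                self.kernel_lengthscale,
                self.kernel_variance,
                self.noise_variance,
                self.prior_mean,
            ]),
        }

    @classmethod
    def from_arrays(cls, d: dict) -> "SparseGPRModel":
        ell, var, noise, mean = np.asarray(d["hyper"], float)
        return cls(d["inducing_points"], d["weights"], ell, var, noise, mean)


def rbf_kernel(x: np.ndarray, y: np.ndarray,
               lengthscale: float, variance: float) -> np.ndarray:
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    d2 = (
        np.sum(x**2, axis=1)[:, None]
        + np.sum(y**2, axis=1)[None, :]
        - 2.0 * x @ y.T
    )
    return variance * np.exp(-np.maximum(d2, 0.0) / (2.0 * lengthscale**2))


def farthest_point_indices(x: np.ndarray, m: int, seed: int = 0) -> np.ndarray:
    """Greedy max-min selection of ``m`` rows.

    The first pick is the point farthest from the data mean, making the
    whole selection deterministic and independent of sample ordering (the
    ``seed`` argument is kept for interface stability; the selection does
    not consume randomness).
    """
    center = x.mean(axis=0)
    chosen = [int(np.argmax(np.linalg.norm(x - center, axis=1)))]
    d = np.linalg.norm(x - x[chosen[0]], axis=1)
    while len(chosen) < m:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(x - x[nxt], axis=1))
    return np.array(sorted(chosen))


def fit_sparse_gpr(
    features: np.ndarray,
    targets: np.ndarray,
    n_inducing: int,
    kernel_lengthscale: float,
    kernel_variance: float = 1.0,
    noise_variance: float = 1e-8,
    seed: int = 0,
    prior_mean: float | None = None,
) -> SparseGPRModel:
    """Fit the SoR weights for the regularised projected system.

    Solves  (σ_n² K_mm + K_mn K_nm) w = K_mn (y − ȳ)  with a small jitter,
    the standard subset-of-regressors normal equations.
    """
    x = np.atleast_2d(np.asarray(features, float))
    y = np.atleast_1d(np.asarray(targets, float))
    if len(x) != len(y):
        raise ValueError("features/targets misaligned")
    if n_inducing > len(x):
        raise ValueError("n_inducing exceeds number of samples")
    spread = np.ptp(x, axis=0).max() if len(x) > 1 else 0.0
    if len(x) > 1 and spread < 1e-12:
        raise DegenerateFeaturesError(
            "all training features are identical; increase the descriptor "
            "cutoff radius so atoms see their neighbourhoods"
        )
    if prior_mean is None:
        prior_mean = float(np.mean(y))
    idx = farthest_point_indices(x, n_inducing, seed)
    xm = x[idx]
    kmm = rbf_kernel(xm, xm, kernel_lengthscale, kernel_variance)
    kmn = rbf_kernel(xm, x, kernel_lengthscale, kernel_variance)
    resid = y - prior_mean
    # solve the SoR system  (σ² K_mm + K_mn K_nm) w = K_mn (y − ȳ)  in its
    # stacked least-squares form: QR keeps the conditioning at √κ of the
    # normal equations
    jitter = 1e-10 * kernel_variance
    ell_chol = np.linalg.cholesky(kmm + jitter * np.eye(len(xm)))
    stacked = np.vstack([kmn.T, np.sqrt(noise_variance) * ell_chol.T])
    rhs = np.concatenate([resid, np.zeros(len(xm))])
    w = np.linalg.lstsq(stacked, rhs, rcond=None)[0]
    return SparseGPRModel(
        xm, w, kernel_lengthscale, kernel_variance, noise_variance,
        prior_mean,
    )


def predict(model: SparseGPRModel, features: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, float))
    k = rbf_kernel(
        x, model.inducing_points,
        model.kernel_lengthscale, model.kernel_variance,
    )
    return model.prior_mean + k @ model.weights


@dataclass
class PerElementGPR:
    """One independent :class:`SparseGPRModel` per chemical element."""

    models: dict[str, SparseGPRModel]

    def predict(self, elements: list[str], features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        out = np.empty(len(elements))
        els = np.asarray(elements)
        for el in set(elements):
            if el not in self.models:
                raise KeyError(f"no model trained for element {el!r}")
            mask = els == el
            out[mask] = predict(self.models[el], features[mask])
        return out


def fit_per_element(
    elements: list[str],
    features: np.ndarray,
    targets: np.ndarray,
    n_inducing: int,
    kernel_lengthscale: float,
    kernel_variance: float = 1.0,
    noise_variance: float = 1e-8,
    seed: int = 0,
) -> PerElementGPR:
    """Group samples by element and fit one sparse GP each."""
    elements = list(elements)
    features = np.atleast_2d(features)
    targets = np.asarray(targets, float)
    models = {}
    for el in sorted(set(elements)):
        mask = np.array([e == el for e in elements])
        m = min(n_inducing, int(mask.sum()))
        models[el] = fit_sparse_gpr(
            features[mask], targets[mask], m,
            kernel_lengthscale, kernel_variance, noise_variance, seed,
        )
    return PerElementGPR(models)
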