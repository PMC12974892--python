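"""Invariant per-atom local-environment descriptors.

Each atom is described by element-resolved radial Gaussian sums

    G_{i,(Z,k)} = Σ_{j≠i, Z_j=Z} exp(−(d_ij − μ_k)² / (2 w²)) · f_c(d_ij)

with centers μ_k evenly spaced on (0, cutoff] and the smooth cutoff
f_c(d) = ½(cos(π d / r_c) + 1) for d ≤ r_c, zero beyond.  The features are
invariant to rotation, translation and same-element permutation, and see
only the ML region — the MM environment is never visible to them.

Every scalar atomic property predicted in this package (electronegativity,
valence width, volume, the flexible polarizability correction k_α) is a
function of these descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MLRegion


class UnknownElementError(KeyError):
    """An element of the region is missing from the descriptor vocabulary."""


@dataclass
class DescriptorSettings:
    """Radial-basis layout; defaults suit small reactive molecules."""

    cutoff_radius: float = 5.0      # Å
    n_radial: int = 16
    gaussian_width: float = 0.5     # Å
    element_vocabulary: list[str] = field(
        default_factory=lambda: ["H", "C", "N", "O", "S"]
    )

    def __post_init__(self):
        if self.cutoff_radius <= 0:
            raise ValueError("cutoff_radius must be positive")
        if self.n_radial < 1:
            raise ValueError("n_radial must be >= 1")
        if not self.element_vocabulary:
            raise ValueError("element vocabulary must be non-empty")
        if len(set(self.element_vocabulary)) != len(self.element_vocabulary):
            raise ValueError("element vocabulary must be duplicate-free")

    @property
    def n_features(self) -> int:
        return len(self.element_vocabulary) * self.n_radial

    @property
    def centers(self) -> np.ndarray:
        k = np.arange(1, self.n_radial + 1)
        return self.cutoff_radius * k / self.n_radial

    def to_dict(self) -> dict:
        return {
            "cutoff_radius": self.cutoff_radius,
            "n_radial": self.n_radial,
            "gaussian_width": self.gaussian_width,
            "element_vocabulary": list(self.element_vocabulary),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorSettings":
        return cls(**d)


def smooth_cutoff(d: np.ndarray, r_c: float) -> np.ndarray:
    d = np.asarray(d, float)
    out = 0.5 * (np.cos(np.pi * d / r_c) + 1.0)
    return np.where(d <= r_c, out, 0.0)


def compute_descriptors(
    region: MLRegion, settings: DescriptorSettings
) -> np.ndarray:
    """Feature matrix of shape (n_atoms, |vocabulary| × n_radial)."""
    vocab = settings.element_vocabulary
    for el in region.elements:
        if el not in vocab:
            raise UnknownElementError(
                f"element {el!r} not in descriptor vocabulary {vocab}"
            )
    n = region.n_atoms
    coords = region.coordinates
    mu = settings.centers
    w2 = 2.0 * settings.gaussian_width**2
    r_c = settings.cutoff_radius
    z_index = np.array([vocab.index(el) for el in region.elements])

    feats = np.zeros((n, len(vocab), settings.n_radial))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    fc = smooth_cutoff(dist, r_c)
    np.fill_diagonal(fc, 0.0)
    # radial Gaussians: (n, n, n_radial)
    g = np.exp(-((dist[:, :, None] - mu[None, None, :]) ** 2) / w2)
    contrib = g * fc[:, :, None]
    for zi in range(len(vocab)):
        mask = z_index == zi
        if mask.any():
            feats[:, zi, :] = contrib[:, mask, :].sum(axis=1)
    return feats.reshape(n, settings.n_features)
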