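"""Domain types shared across the toolkit.

An ML/MM system is split into a reactive *ML region* (treated by a
machine-learned gas-phase potential plus the embedding model) and a fixed
point-charge *MM environment*.  All coordinates held by these types are in
Å and energies in kcal/mol; energy kernels convert to atomic units
internally.  Distances are Euclidean — there are no periodic boundary
conditions anywhere in the package (finite droplet/toy systems only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class UnresolvedLabelError(KeyError):
    """An atom label referenced by a reaction coordinate does not exist."""


@dataclass
class MLRegion:
    """The reactive subsystem.

    Parameters
    ----------
    elements
        Chemical element symbols, one per atom.
    coordinates
        (n, 3) array, Å.
    total_charge
        Total formal charge in elementary units (integer).
    atom_labels
        Optional per-atom names (e.g. ``"C10"``) used by reaction
        coordinates.  Defaults to ``element + 1-based index``.
    """

    elements: list[str]
    coordinates: np.ndarray
    total_charge: int = 0
    atom_labels: list[str] | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.elements), 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if self.total_charge != int(self.total_charge):
            raise ValueError("total_charge must be an integer")
        self.total_charge = int(self.total_charge)
        if self.atom_labels is None:
            self.atom_labels = [
                f"{el}{i + 1}" for i, el in enumerate(self.elements)
            ]
        if len(self.atom_labels) != len(self.elements):
            raise ValueError("atom_labels length mismatch")
        if len(set(self.atom_labels)) != len(self.atom_labels):
            raise ValueError("atom_labels must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def index_of(self, label: str) -> int:
        try:
            return self.atom_labels.index(label)
        except ValueError:
            raise UnresolvedLabelError(
                f"atom label {label!r} not found in ML region "
                f"(have {self.atom_labels})"
            ) from None

    def with_coordinates(self, coordinates: np.ndarray) -> "MLRegion":
        return MLRegion(
            elements=list(self.elements),
            coordinates=np.asarray(coordinates, dtype=float),
            total_charge=self.total_charge,
            atom_labels=list(self.atom_labels),
        )


@dataclass
class MMEnvironment:
    """Fixed point-charge environment with Lennard-Jones parameters.

    positions in Å, charges in elementary units, ``lj_sigma`` in Å and
    ``lj_epsilon`` in kcal/mol.
    """

    positions: np.ndarray
    charges: np.ndarray
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        n = len(self.charges)
        if self.positions.shape != (n, 3):
            raise ValueError("positions/charges length mismatch")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("charges must be finite")
        if self.lj_sigma is None:
            self.lj_sigma = np.zeros(n)
        if self.lj_epsilon is None:
            self.lj_epsilon = np.zeros(n)
        self.lj_sigma = np.atleast_1d(np.asarray(self.lj_sigma, float))
        self.lj_epsilon = np.atleast_1d(np.asarray(self.lj_epsilon, float))
        if len(self.lj_sigma) != n or len(self.lj_epsilon) != n:
            raise ValueError("Lennard-Jones array length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


@dataclass
class EnergyDecomposition:
    """Four-term ML/MM energy split: gas + static + induced + MM (kcal/mol).

    ``e_total`` always equals the sum of the four components; the class
    recomputes it on construction and refuses inconsistent input.
    """

    e_gas: float
    e_static: float
    e_induced: float
    e_mm: float
    e_total: float | None = None
    forces_ml: np.ndarray | None = None
    forces_mm: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        total = self.e_gas + self.e_static + self.e_induced + self.e_mm
        if self.e_total is None:
            self.e_total = total
        else:
            scale = max(
                abs(self.e_gas), abs(self.e_static), abs(self.e_induced),
                abs(self.e_mm), 1.0,
            )
            if abs(self.e_total - total) > 1e-10 * scale:
                raise ValueError(
                    "e_total inconsistent with components: "
                    f"{self.e_total} != {total}"
                )

    def components(self) -> dict[str, float]:
        return {
            "e_gas": self.e_gas,
            "e_static": self.e_static,
            "e_induced": self.e_induced,
            "e_mm": self.e_mm,
            "e_total": self.e_total,
        }


@dataclass
class ReactionCoordinate:
    """Scalar collective variable: a weighted sum of interatomic distances.

    ``kind="weighted_distance_sum"`` covers coordinates such as the
    Diels–Alder forming-bond combination 0.3·d(C10–C15) + 0.7·d(C13–C14);
    ``kind="distance_difference"`` is the breaking-minus-forming
    bond-distance difference used for Claisen-type rearrangements, with
    weights fixed to (+1, −1).
    """

    kind: str
    pairs: list[tuple[str, str]]
    weights: list[float] | None = None

    def __post_init__(self):
        if self.kind not in ("weighted_distance_sum", "distance_difference"):
            raise ValueError(f"unknown reaction-coordinate kind {self.kind!r}")
        if self.kind == "distance_difference":
            if len(self.pairs) != 2:
                raise ValueError("distance_difference needs exactly 2 pairs")
            self.weights = [1.0, -1.0]
        if self.weights is None:
            raise ValueError("weights required for weighted_distance_sum")
        if len(self.weights) != len(self.pairs):
            raise ValueError("weights and pairs must have equal length")


def evaluate_rc(
    rc: ReactionCoordinate, region: MLRegion, gradient: bool = False
):
    """Evaluate ``Σ_k w_k · d(pair_k)`` in Å.

    With ``gradient=True`` returns ``(value, grad)`` where ``grad`` is the
    (n, 3) analytic derivative with respect to all ML coordinates
    (dimensionless, Å per Å).
    """
    coords = region.coordinates
    value = 0.0
    grad = np.zeros_like(coords)
    for w, (a, b) in zip(rc.weights, rc.pairs):
        ia, ib = region.index_of(a), region.index_of(b)
        rij = coords[ia] - coords[ib]
        d = float(np.linalg.norm(rij))
        if d == 0.0:
            raise ValueError(f"coincident atoms in RC pair ({a}, {b})")
        value += w * d
        if gradient:
            g = w * rij / d
            grad[ia] += g
            grad[ib] -= g
    if gradient:
        return value, grad
    return value
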