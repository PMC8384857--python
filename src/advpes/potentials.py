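"""Analytic ground-truth potentials and seeded initial-dataset generation.

These oracles stand in for the expensive reference calculations (electronic
structure or force fields) that label configurations in a real active-learning
campaign.  Each potential exposes an energy function and its analytic negative
gradient (the forces); agreement between the two is property-tested against
central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .data import Configuration, Dataset, LabeledSample
from .cv import DihedralCV, dihedral_and_gradient

__all__ = [
    "GroundTruthPotential",
    "DoubleWell",
    "ToyTorsionalSurface",
    "TorsionalMolecule",
    "make_two_torsion_molecule",
    "sample_initial_dataset",
    "evaluate_oracle",
]


class GroundTruthPotential:
    """Interface: energy and forces (negative energy gradient) of a configuration."""

    kind = "vector"

    def energy(self, config: Configuration) -> float:
        raise NotImplementedError

    def forces(self, config: Configuration) -> np.ndarray:
        raise NotImplementedError

    def label(self, config: Configuration) -> LabeledSample:
        if config.kind != self.kind:
            raise TypeError(f"{type(self).__name__} expects {self.kind}-kind configurations")
        return LabeledSample(config, self.energy(config), self.forces(config))

    # vectorized energy over an (N, d) coordinate matrix; default loops
    def energy_batch(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.energy(Configuration(x)) for x in np.atleast_2d(X)])


class DoubleWell(GroundTruthPotential):
    """Two-dimensional double-well polynomial ``E(x, y) = 10x^4 - 10x^2 + 2x + 4y^2``.

    The linear tilt makes the left basin (global minimum near x = -0.75,
    E = -3.96) deeper than the right one, so an energy filter E < -2 isolates
    the left basin and leaves the right basin unseen by the initial data.
    """

    kind = "vector"
    dof = 2

    def _check(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float).ravel()
        if p.shape != (2,):
            raise ValueError("double well expects a 2-vector")
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite input")
        return p

    def energy(self, config) -> float:
        x, y = self._check(np.asarray(config.coords if isinstance(config, Configuration) else config))
        return float(10 * x**4 - 10 * x**2 + 2 * x + 4 * y**2)

    def forces(self, config) -> np.ndarray:
        x, y = self._check(np.asarray(config.coords if isinstance(config, Configuration) else config))
        return -np.array([40 * x**3 - 20 * x + 2, 8 * y])

    def energy_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        x, y = X[:, 0], X[:, 1]
        return 10 * x**4 - 10 * x**2 + 2 * x + 4 * y**2


@dataclass(frozen=True)
class ToyTorsionalSurface:
    """Smooth 2pi-periodic two-angle surface with multiple minima and one bump.

    Closed form (angles in radians)::

        E(phi, psi) = cos(phi) + 0.8 cos(2 phi) + 0.6 cos(psi) + 0.7 cos(2 psi)
                      + 0.25 sin(phi) sin(psi)
                      + A exp(kappa (cos(phi) - 1) + kappa (cos(psi) - 1))

    The cosine series creates distinct minima away from the origin; the
    von-Mises-style bump (A = 4, kappa = 4) puts a localized high-energy
    region around (0, 0), mimicking a sterically forbidden zone.  The form is
    versioned by its coefficients; changing them is an API change.
    """

    amplitude: float = 4.0
    kappa: float = 4.0

    def energy_angles(self, phi, psi):
        phi = np.asarray(phi, float)
        psi = np.asarray(psi, float)
        bump = self.amplitude * np.exp(
            self.kappa * (np.cos(phi) - 1.0) + self.kappa * (np.cos(psi) - 1.0)
        )
        return (
            np.cos(phi) + 0.8 * np.cos(2 * phi)
            + 0.6 * np.cos(psi) + 0.7 * np.cos(2 * psi)
            + 0.25 * np.sin(phi) * np.sin(psi)
            + bump
        )

    def gradient_angles(self, phi, psi):
        phi = np.asarray(phi, float)
        psi = np.asarray(psi, float)
        bump = self.amplitude * np.exp(
            self.kappa * (np.cos(phi) - 1.0) + self.kappa * (np.cos(psi) - 1.0)
        )
        dphi = (
            -np.sin(phi) - 1.6 * np.sin(2 * phi)
            + 0.25 * np.cos(phi) * np.sin(psi)
            - self.kappa * np.sin(phi) * bump
        )
        dpsi = (
            -0.6 * np.sin(psi) - 1.4 * np.sin(2 * psi)
            + 0.25 * np.sin(phi) * np.cos(psi)
            - self.kappa * np.sin(psi) * bump
        )
        return np.array([dphi, dpsi])


class TorsionalMolecule(GroundTruthPotential):
    """Molecular oracle whose energy depends on two torsion angles.

    Energy is ``surface(phi, psi)`` with the angles measured on the geometry;
    forces follow from the chain rule through the analytic torsion gradient.
    Degrees of freedom other than the two torsions carry zero force, which is
    exactly the regime where collective-variable attacks are the right tool.
    """

    kind = "molecule"

    def __init__(self, cvs: Sequence[DihedralCV], surface: ToyTorsionalSurface | None = None):
        if len(cvs) != 2:
            raise ValueError("TorsionalMolecule uses exactly two torsional CVs")
        self.cvs = list(cvs)
        self.surface = surface or ToyTorsionalSurface()

    def angles(self, config: Configuration) -> np.ndarray:
        return np.array([cv.measure(config.coords) for cv in self.cvs])

    def energy(self, config: Configuration) -> float:
        phi, psi = self.angles(config)
        return float(self.surface.energy_angles(phi, psi))

    def forces(self, config: Configuration) -> np.ndarray:
        R = config.coords
        grads = []
        angles = []
        for cv in self.cvs:
            ang, g = dihedral_and_gradient(R, cv.indices)
            angles.append(ang)
            grads.append(g)
        dE = self.surface.gradient_angles(*angles)
        dE_dR = dE[0] * grads[0] + dE[1] * grads[1]
        return -dE_dR


def make_two_torsion_molecule(bond_graph: bool = False):
    """Reference geometry and CVs of the synthetic two-torsion chain molecule.

    A six-heavy-atom zigzag chain (butane-like backbone extended by one bond on
    each side) with torsions phi = (0,1,2,3) about bond 1-2 and
    psi = (2,3,4,5) about bond 3-4.  Returns ``(config, cvs)`` or additionally
    the bond list when ``bond_graph`` is true.
    """
    # zigzag carbon chain, ~1.5 A bonds, staggered out-of-plane kicks so no
    # three consecutive atoms are collinear
    R = np.array(
        [
            [0.00, 0.00, 0.30],
            [1.45, 0.00, -0.20],
            [2.20, 1.25, 0.25],
            [3.65, 1.25, -0.25],
            [4.40, 2.50, 0.30],
            [5.85, 2.50, -0.20],
        ]
    )
    Z = np.array([6, 6, 6, 6, 6, 6])
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
    config = Configuration(R, Z)
    cvs = [
        DihedralCV((0, 1, 2, 3), bonds),
        DihedralCV((2, 3, 4, 5), bonds),
    ]
    if bond_graph:
        return config, cvs, bonds
    return config, cvs


def sample_initial_dataset(
    potential: GroundTruthPotential,
    n_max: int = 800,
    filter_max_energy: float = -2.0,
    region=((-1.5, 1.5), (-1.5, 1.5)),
    seed: int = 0,
) -> Dataset:
    """Draw up to ``n_max`` uniform points in ``region``, label them with the
    oracle and keep only those with energy strictly below ``filter_max_energy``.

    Reproducible from ``seed``; raises if the filter leaves nothing.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in region], dtype=float)
    hi = np.array([b[1] for b in region], dtype=float)
    pts = rng.uniform(lo, hi, size=(n_max, lo.size))
    samples = []
    for p in pts:
        sample = potential.label(Configuration(p))
        if sample.energy < filter_max_energy:
            samples.append(sample)
    if not samples:
        raise ValueError(
            f"energy filter E < {filter_max_energy} left no samples out of {n_max}"
        )
    return Dataset(samples, ["initial"] * len(samples))


def evaluate_oracle(potential: GroundTruthPotential, configs: Sequence[Configuration]) -> List[LabeledSample]:
    """Label each configuration with oracle energy and forces, order preserved."""
    return [potential.label(c) for c in configs]
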