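"""Synthetic test systems: two-center molecules, chains, rings, random Hamiltonians.

These generators define the study conditions for every validation
experiment in the package.  The two-center ("diatomic") fixture emulates a
first-row diatomic such as CO: two heavy centers, each carrying a small
stack of basis sites so that several valence and conduction orbitals --
and hence several low-lying excitons -- exist, with a ground-state
bond-length minimum between 2 and 3 Bohr.  All fixtures are deterministic
given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry
from .model import MeanFieldState, ModelParams

__all__ = [
    "fixture",
    "diatomic_geometry",
    "chain_geometry",
    "ring_geometry",
    "RandomHamiltonianFamily",
    "mean_field_from_matrix",
    "DIATOMIC_BOND_DEFAULT",
    "DIATOMIC_STACK_SPACING",
]

# Frozen fixture constants (Bohr).
DIATOMIC_BOND_DEFAULT = 2.4       # default inter-center distance
DIATOMIC_STACK_SPACING = 2.2      # spacing of the left center's transverse stack
DIATOMIC_CHAIN_SPACING = 2.0      # spacing of the right center's axial sites

# Conduction-orbital quasiparticle shift that places an exact crossing of the
# two lowest (opposite-parity) excitons inside the bond scan window of the
# default two-center fixture; used by the level-crossing experiments.
CROSSING_CONDUCTION_SHIFTS = {2: 0.2}


def diatomic_geometry(n_sites: int = 4, bond_length: float = DIATOMIC_BOND_DEFAULT) -> Geometry:
    """Two-center molecule with ``n_sites/2`` basis sites per center.

    The left ("C") center is a stack of sites at x = 0 placed symmetrically
    about the bond (x) axis with spacing :data:`DIATOMIC_STACK_SPACING`,
    standing in for transverse valence orbitals; the right ("O") center is
    a chain of sites on the axis starting at x = ``bond_length`` with
    spacing :data:`DIATOMIC_CHAIN_SPACING`.  ``bond_length`` is the bond
    being scanned or relaxed.

    Two properties of this arrangement matter for the validation
    experiments.  The triangle of hoppings between the transverse pair and
    the first axial site breaks the particle-hole symmetry of a bipartite
    half-filled chain, so the low excitons are well separated in energy.
    And the geometry is mirror-symmetric about the bond axis, so excitons
    carry an exact parity label that is conserved under axial
    displacements: crossings between opposite-parity states are exact, as
    between states of different angular momentum in a real diatomic.  With
    the default four sites at half filling there are two valence and two
    conduction orbitals and four singlet excitons, and the ground state
    binds with a bond-length minimum between 2 and 3 Bohr.
    """
    if n_sites < 2 or n_sites % 2 != 0:
        raise ValueError("diatomic fixture needs an even n_sites >= 2")
    per = n_sites // 2
    ys = (np.arange(per) - (per - 1) / 2.0) * DIATOMIC_STACK_SPACING
    pos = [[0.0, y, 0.0] for y in ys]
    pos += [[bond_length + k * DIATOMIC_CHAIN_SPACING, 0.0, 0.0] for k in range(per)]
    labels = ("C",) * per + ("O",) * per
    return Geometry(labels=labels, positions=np.asarray(pos))


def chain_geometry(n_sites: int, spacing: float | None = None) -> Geometry:
    if n_sites < 2:
        raise ValueError("chain needs at least 2 sites")
    a = ModelParams().r_ref if spacing is None else spacing
    pos = np.zeros((n_sites, 3))
    pos[:, 0] = a * np.arange(n_sites)
    return Geometry(labels=("C",) * n_sites, positions=pos)


def ring_geometry(n_sites: int, bond: float | None = None) -> Geometry:
    """Regular polygon with all nearest-neighbor distances equal to ``bond``."""
    if n_sites < 3:
        raise ValueError("ring needs at least 3 sites")
    a = ModelParams().r_ref if bond is None else bond
    radius = a / (2.0 * np.sin(np.pi / n_sites))
    ang = 2.0 * np.pi * np.arange(n_sites) / n_sites
    pos = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_sites)])
    return Geometry(labels=("C",) * n_sites, positions=pos)


@dataclass(frozen=True)
class RandomHamiltonianFamily:
    """Smooth one-parameter family H(lam) = H0 + lam*H1 of symmetric matrices.

    Used to exercise the manifold projector on orbital sets without any
    self-consistency, including cases small enough for brute-force
    many-body oracles.
    """

    h0: np.ndarray
    h1: np.ndarray
    n_valence: int

    def at(self, lam: float) -> np.ndarray:
        return self.h0 + lam * self.h1

    def mean_field(self, lam: float) -> MeanFieldState:
        return mean_field_from_matrix(self.at(lam), self.n_valence)


def mean_field_from_matrix(h: np.ndarray, n_valence: int) -> MeanFieldState:
    """Wrap the spectrum of an arbitrary symmetric matrix as a mean field.

    The associated geometry is a placeholder chain; ``e0`` is the band sum
    of the occupied eigenvalues.  Intended for projector and solver tests
    that need orbital manifolds but no self-consistent model behind them.
    """
    h = np.asarray(h, dtype=float)
    if not np.allclose(h, h.T, atol=1e-12):
        raise ValueError("Hamiltonian matrix must be symmetric")
    n = h.shape[0]
    eps, c = np.linalg.eigh(h)
    params = ModelParams(n_electrons=2 * n_valence)
    return MeanFieldState(
        orbitals=c,
        energies=eps,
        n_valence=n_valence,
        e0=float(2.0 * np.sum(eps[:n_valence])),
        geometry=chain_geometry(max(n, 2)) if n >= 2 else chain_geometry(2),
        params=params,
        converged=True,
    )


def fixture(kind: str, n_sites: int, seed: int = 0):
    """Build a named test system.

    Returns ``(Geometry, ModelParams)`` for the geometric kinds
    (``diatomic``, ``chain``, ``ring``) and a
    :class:`RandomHamiltonianFamily` for ``random_h``.  Deterministic
    given ``seed``.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    rng = np.random.default_rng(seed)
    if kind == "diatomic":
        geom = diatomic_geometry(n_sites)
        return geom, ModelParams(n_electrons=n_sites)
    if kind == "chain":
        return chain_geometry(n_sites), ModelParams(n_electrons=n_sites)
    if kind == "ring":
        return ring_geometry(n_sites), ModelParams(n_electrons=n_sites)
    if kind == "random_h":
        a = rng.standard_normal((n_sites, n_sites))
        b = rng.standard_normal((n_sites, n_sites))
        h0 = (a + a.T) / 2.0
        h1 = (b + b.T) / 2.0
        return RandomHamiltonianFamily(h0=h0, h1=h1, n_valence=max(1, n_sites // 2))
    raise ValueError(f"unknown fixture kind {kind!r}")
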