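"""Bare and statically screened Coulomb interactions.

The exchange kernel of the excitonic Hamiltonian uses the bare repulsion
``v`` (the Ohno matrix of the model); the direct kernel uses the static
screened interaction ``W``.  Screening is computed in the random-phase
approximation from the mean-field orbitals:

    chi0_rs = 4 * sum_{v,c} phi_v(r) phi_c(r) phi_v(s) phi_c(s) / (eps_v - eps_c)
    W       = (I - v chi0)^(-1) v

The factor 4 is the spin factor 2 times the double counting of each
(occupied, empty) pair in the symmetric sum.  ``chi0`` is negative
semidefinite, so screening always weakens the interaction.  A ``bare``
mode (W = v) is also provided; it makes the excitonic Hamiltonian
coincide with configuration-interaction singles and is used as an exact
oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry
from .model import MeanFieldState, ModelParams, ohno_potential

__all__ = [
    "InteractionKernels",
    "ScreeningError",
    "bare_coulomb",
    "static_polarizability",
    "screened_from_chi0",
    "rpa_static_w",
    "build_kernels",
]

MIN_GAP = 1e-10


class ScreeningError(RuntimeError):
    """Raised when the static dielectric problem is singular or gapless."""


@dataclass(frozen=True)
class InteractionKernels:
    """Bare (``v``) and screened (``w``) site-basis interaction matrices, Ry."""

    v: np.ndarray
    w: np.ndarray
    screening_mode: str  # "bare" | "rpa"

    def __post_init__(self) -> None:
        for name in ("v", "w"):
            m = np.asarray(getattr(self, name), dtype=float)
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} matrix not symmetric")
            m.setflags(write=False)
            object.__setattr__(self, name, m)
        if self.screening_mode not in ("bare", "rpa"):
            raise ValueError(f"unknown screening mode {self.screening_mode!r}")
        if self.screening_mode == "bare" and not np.array_equal(self.v, self.w):
            raise ValueError("bare mode requires w == v")


def bare_coulomb(geometry: Geometry, params: ModelParams) -> np.ndarray:
    """Ohno repulsion matrix V(R_ij); diagonal is the on-site U."""
    return ohno_potential(geometry.distance_matrix(), params.u_onsite, params.ohno_a)


def static_polarizability(mf: MeanFieldState) -> np.ndarray:
    """Independent-particle static polarizability chi0 in the site basis."""
    if not mf.converged:
        raise ValueError("mean field not converged")
    if mf.n_conduction < 1:
        raise ValueError("no empty orbitals: cannot screen")
    occ = mf.occupied                      # (n, Nv)
    vir = mf.virtual                       # (n, Nc)
    de = mf.energies[: mf.n_valence, None] - mf.energies[None, mf.n_valence:]
    if np.max(de) > -MIN_GAP:
        raise ScreeningError("gapless system: occupied/empty degeneracy across the gap")
    # pair densities phi_v(r) phi_c(r): (n, Nv, Nc)
    pair = occ[:, :, None] * vir[:, None, :]
    # spin factor 2 x (v,c)/(c,v) double counting
    return 4.0 * np.einsum("rvc,svc,vc->rs", pair, pair, 1.0 / de, optimize=True)


def screened_from_chi0(v: np.ndarray, chi0: np.ndarray) -> np.ndarray:
    """W = (I - v chi0)^(-1) v, explicitly symmetrized."""
    n = v.shape[0]
    eps_mat = np.eye(n) - v @ chi0
    cond = np.linalg.cond(eps_mat)
    if not np.isfinite(cond) or cond > 1e12:
        raise ScreeningError(f"singular static dielectric matrix (condition number {cond:.3e})")
    w = np.linalg.solve(eps_mat, v)
    asym = np.max(np.abs(w - w.T))
    if asym > 1e-8:
        raise ScreeningError(f"screened interaction asymmetry {asym:.3e} exceeds tolerance")
    return (w + w.T) / 2.0


def rpa_static_w(mf: MeanFieldState, v: np.ndarray) -> np.ndarray:
    """Static RPA screened interaction from the mean-field spectrum."""
    return screened_from_chi0(v, static_polarizability(mf))


def build_kernels(mf: MeanFieldState, screening: str = "rpa") -> InteractionKernels:
    """Convenience constructor: bare Ohno v, plus W per the screening mode."""
    v = bare_coulomb(mf.geometry, mf.params)
    if screening == "bare":
        return InteractionKernels(v=v, w=v.copy(), screening_mode="bare")
    if screening == "rpa":
        return InteractionKernels(v=v, w=rpa_static_w(mf, v), screening_mode="rpa")
    raise ValueError(f"unknown screening mode {screening!r}")
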