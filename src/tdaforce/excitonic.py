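"""The excitonic Hamiltonian in batch representation.

A Tamm-Dancoff excited state is a sum of single promotions from valence
orbital v to conduction orbital c with amplitudes A_{v,c}.  Instead of
enumerating conduction orbitals, each valence channel is represented by a
single *batch* vector

    |xi_v> = sum_c A_{v,c} |phi_c>,

which lives in the conduction subspace.  The excitonic Hamiltonian

    H_exc = D + K_x + K_d

acts channel-wise on batches:

* diagonal:  D|xi_v> = (H_mf - eps_v + Delta)|xi_v>, with the scissor
  Delta and optional per-orbital quasiparticle shifts standing in for a
  self-energy correction of the mean-field gap;
* exchange:  (K_x xi)_v(r) = s * P_c[ phi_v(r) * sum_v' (v (phi_v' xi_v'))(r) ],
  with the spin factor s = 2 for singlets and 0 for triplets;
* direct:    (K_d xi)_v(r) = -P_c[ sum_v' xi_v'(r) * (W (phi_v' phi_v))(r) ].

Pointwise products over sites realize the real-space orbital products of
the kernels under the zero-differential-overlap convention; all orbitals
are real.  A dense matrix over (v, c) pairs is provided as the reference
oracle for the batch algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import InteractionKernels
from .model import MeanFieldState

__all__ = [
    "QPCorrections",
    "ExcitonState",
    "ExcitonicContext",
    "project_conduction",
    "apply_diagonal",
    "apply_exchange",
    "apply_direct",
    "apply_hexc",
    "dense_matrix",
    "batches_from_amplitudes",
    "amplitudes_from_batches",
]

SPIN_FACTORS = {"singlet": 2.0, "triplet": 0.0}


@dataclass(frozen=True)
class QPCorrections:
    """Scissor shift plus optional per-orbital quasiparticle corrections (Ry).

    ``valence_shifts`` and ``conduction_shifts`` map absolute orbital
    indices (0-based, in the mean-field energy ordering) to additive
    energy corrections for the explicitly corrected orbitals; everything
    not listed is covered by the rigid ``scissor`` opening of the gap.
    """

    scissor: float = 0.0
    valence_shifts: dict[int, float] = field(default_factory=dict)
    conduction_shifts: dict[int, float] = field(default_factory=dict)

    def check_indices(self, n_valence: int, n_orbitals: int) -> None:
        for i in self.valence_shifts:
            if not 0 <= i < n_valence:
                raise IndexError(f"valence shift index {i} outside [0, {n_valence})")
        for i in self.conduction_shifts:
            if not n_valence <= i < n_orbitals:
                raise IndexError(
                    f"conduction shift index {i} outside [{n_valence}, {n_orbitals})"
                )


@dataclass
class ExcitonState:
    """Batch representation of one Tamm-Dancoff excitation.

    ``batches`` has shape (n_valence, n_sites); row v is xi_v in the site
    basis and must lie in the conduction subspace of ``mf_ref``.  For a
    solved eigenstate, sum_v <xi_v|xi_v> = 1 and ``omega`` is its
    excitation energy in Ry.
    """

    batches: np.ndarray
    mf_ref: MeanFieldState
    omega: float | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.batches, dtype=float)
        if b.ndim != 2 or b.shape != (self.mf_ref.n_valence, self.mf_ref.n_sites):
            raise ValueError(
                f"batches must be (n_valence, n_sites) = "
                f"({self.mf_ref.n_valence}, {self.mf_ref.n_sites}), got {b.shape}"
            )
        self.batches = b

    def norm2(self) -> float:
        return float(np.sum(self.batches * self.batches))


@dataclass(frozen=True)
class ExcitonicContext:
    """Everything needed to apply H_exc at one geometry."""

    mf: MeanFieldState
    kernels: InteractionKernels
    qp: QPCorrections = field(default_factory=QPCorrections)
    spin_channel: str = "singlet"

    def __post_init__(self) -> None:
        if not self.mf.converged:
            raise ValueError("mean field not converged")
        if self.spin_channel not in SPIN_FACTORS:
            raise ValueError(f"unknown spin channel {self.spin_channel!r}")
        if self.kernels.v.shape[0] != self.mf.n_sites:
            raise ValueError("kernels and mean field disagree in basis size")
        self.qp.check_indices(self.mf.n_valence, self.mf.orbitals.shape[1])

    @property
    def n_valence(self) -> int:
        return self.mf.n_valence

    @property
    def n_conduction(self) -> int:
        return self.mf.n_conduction

    def corrected_energies(self) -> np.ndarray:
        """Orbital energies with scissor and explicit QP shifts folded in.

        Valence energies gain their explicit shifts; conduction energies
        gain the scissor plus their explicit shifts.
        """
        eps = self.mf.energies.copy()
        for i, s in self.qp.valence_shifts.items():
            eps[i] += s
        eps[self.mf.n_valence:] += self.qp.scissor
        for i, s in self.qp.conduction_shifts.items():
            eps[i] += s
        return eps


def batches_from_amplitudes(mf: MeanFieldState, amplitudes: np.ndarray) -> np.ndarray:
    """xi_v = sum_c A_{v,c} phi_c; amplitudes (Nv, Nc) -> batches (Nv, n)."""
    return np.asarray(amplitudes, dtype=float) @ mf.virtual.T


def amplitudes_from_batches(mf: MeanFieldState, batches: np.ndarray) -> np.ndarray:
    """A_{v,c} = <phi_c|xi_v>; batches (Nv, n) -> amplitudes (Nv, Nc)."""
    return np.asarray(batches, dtype=float) @ mf.virtual


def project_conduction(ctx: ExcitonicContext, vector: np.ndarray) -> np.ndarray:
    """Apply P_c = I - sum_v |phi_v><phi_v| (idempotent)."""
    occ = ctx.mf.occupied
    vector = np.asarray(vector, dtype=float)
    return vector - (vector @ occ) @ occ.T


def _project_rows(ctx: ExcitonicContext, batches: np.ndarray) -> np.ndarray:
    occ = ctx.mf.occupied
    return batches - (batches @ occ) @ occ.T


def apply_diagonal(ctx: ExcitonicContext, batches: np.ndarray) -> np.ndarray:
    """(H_mf - eps_v^QP + Delta)|xi_v> channel-wise, re-projected onto conduction.

    The scissor and conduction shifts are realized by adding
    sum_c shift_c |phi_c><phi_c| on top of the mean-field Hamiltonian; the
    per-valence subtraction uses the QP-corrected valence energy.
    """
    eps = ctx.corrected_energies()
    nv = ctx.n_valence
    f = ctx.mf.fock_matrix()
    out = batches @ f.T
    out += ctx.qp.scissor * batches
    for i, s in ctx.qp.conduction_shifts.items():
        phi = ctx.mf.orbitals[:, i]
        out += s * np.outer(batches @ phi, phi)
    out -= eps[:nv, None] * batches
    return _project_rows(ctx, out)


def apply_exchange(ctx: ExcitonicContext, batches: np.ndarray) -> np.ndarray:
    """Exchange kernel K_x in batch form (spin factor 2 singlet / 0 triplet)."""
    s = SPIN_FACTORS[ctx.spin_channel]
    if s == 0.0:
        return np.zeros_like(batches)
    occ = ctx.mf.occupied                       # (n, Nv)
    codensity = np.einsum("rv,vr->r", occ, batches)   # sum_v' phi_v'(r) xi_v'(r)
    t = ctx.kernels.v @ codensity
    out = s * (occ.T * t[None, :])              # row v: phi_v(r) * t(r)
    return _project_rows(ctx, out)


def apply_direct(ctx: ExcitonicContext, batches: np.ndarray) -> np.ndarray:
    """Direct kernel K_d in batch form (screened interaction, attractive)."""
    occ = ctx.mf.occupied                        # (n, Nv)
    # pair densities phi_v'(r) phi_v(r): (n, Nv, Nv)
    pair = occ[:, :, None] * occ[:, None, :]
    wp = np.einsum("rs,sab->rab", ctx.kernels.w, pair, optimize=True)
    out = -np.einsum("ar,rab->br", batches, wp, optimize=True)
    return _project_rows(ctx, out)


def apply_hexc(ctx: ExcitonicContext, batches: np.ndarray) -> np.ndarray:
    """Full excitonic Hamiltonian: diagonal + exchange + direct."""
    return (
        apply_diagonal(ctx, batches)
        + apply_exchange(ctx, batches)
        + apply_direct(ctx, batches)
    )


def dense_matrix(ctx: ExcitonicContext) -> np.ndarray:
    """Explicit H_exc over (v, c) pairs, v-major c-minor; reference oracle.

    Entry ((v,c),(v',c')) = delta delta (eps_c^QP - eps_v^QP)
    + s (vc|v'c')_v - (cc'|v'v)_W with the two-electron integrals taken in
    the zero-differential-overlap convention.
    """
    mf = ctx.mf
    nv, nc = ctx.n_valence, ctx.n_conduction
    occ, vir = mf.occupied, mf.virtual
    eps = ctx.corrected_energies()
    diag = (eps[nv:][None, :] - eps[:nv][:, None]).reshape(-1)  # (nv*nc,)
    h = np.diag(diag)

    s = SPIN_FACTORS[ctx.spin_channel]
    # pair densities phi_v(r) phi_c(r): (n, Nv, Nc)
    pvc = occ[:, :, None] * vir[:, None, :]
    if s != 0.0:
        kx = s * np.einsum("rvc,rs,swd->vcwd", pvc, ctx.kernels.v, pvc, optimize=True)
        h += kx.reshape(nv * nc, nv * nc)
    pcc = vir[:, :, None] * vir[:, None, :]      # (n, Nc, Nc)
    pvv = occ[:, :, None] * occ[:, None, :]      # (n, Nv, Nv)
    kd = -np.einsum("rcd,rs,swv->vcwd", pcc, ctx.kernels.w, pvv, optimize=True)
    h += kd.reshape(nv * nc, nv * nc)
    return h
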