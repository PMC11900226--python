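"""Projection of Tamm-Dancoff excitations between orbital manifolds.

A Tamm-Dancoff state built on the orbitals of one geometry (lambda = 0)
does not belong to the Tamm-Dancoff manifold of a displaced geometry
(lambda).  The projector implemented here maps it there by expanding the
many-body overlaps between the nonorthogonal Slater determinants of the
two manifolds.  The projected coefficients are

    A~_{v',c'}(lam) = sum_v det < phi_1(lam) ... phi_{c' in slot v'}(lam) ...
                                 | phi_1 ... xi_v in slot v ... phi_Nv >,

i.e. determinants of Nv x Nv mixed orbital-overlap matrices in which one
displaced occupied orbital is replaced by a displaced conduction orbital
and one reference occupied orbital is replaced by a batch.  Two
equivalent evaluations are provided:

* :func:`project_determinant` -- the reference form, looping explicitly
  over displaced conduction orbitals c';
* :func:`project_batches` -- the conduction-sum-free form, obtained by
  cofactor expansion along the substituted row: each signed (Nv-1)-minor
  multiplies a conduction-projected orbital or batch, so only the
  projector P_c(lam) and never an enumeration of empty states appears.

The overlap of the reference excited state with the displaced ground
state, g(lam), is computed from the same determinant machinery; it
vanishes at lam = 0 and is antisymmetric in lam at linear order.

All formulas are determinant-based and therefore insensitive to
per-orbital sign flips; a global sign on the projected state can appear
and consumers must compare magnitudes or quadratic forms (as the force
expressions do).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .excitonic import ExcitonState
from .model import MeanFieldState

__all__ = [
    "ProjectedState",
    "occupied_overlap",
    "project_determinant",
    "project_batches",
    "ground_state_overlap",
    "projected_norm2",
    "align_orbital_signs",
]

NEAR_SINGULAR_DET = 1e-12


@dataclass
class ProjectedState:
    """Unnormalized batches on the displaced manifold plus ground overlap g."""

    batches_tilde: np.ndarray        # (Nv, n_sites), in the lambda conduction subspace
    g: float
    mf_lambda_ref: MeanFieldState
    mf_zero_ref: MeanFieldState
    warning: str | None = None

    def norm2(self) -> float:
        """Squared norm of the projected excited-state component."""
        return float(np.sum(self.batches_tilde * self.batches_tilde))


def projected_norm2(ps: ProjectedState) -> float:
    return ps.norm2()


def occupied_overlap(mf_lambda: MeanFieldState, mf_zero: MeanFieldState) -> np.ndarray:
    """S_ij = <phi_i(lambda) | phi_j(0)> over the occupied orbitals."""
    if mf_lambda.n_valence != mf_zero.n_valence:
        raise ValueError("occupied manifolds have different sizes")
    if mf_lambda.n_sites != mf_zero.n_sites:
        raise ValueError("basis dimension mismatch")
    return mf_lambda.occupied.T @ mf_zero.occupied


def _check_inputs(exciton: ExcitonState, mf_zero: MeanFieldState, mf_lambda: MeanFieldState):
    if exciton.mf_ref is not mf_zero:
        raise ValueError("exciton was not built on mf_zero")
    if mf_lambda.n_valence != mf_zero.n_valence or mf_lambda.n_sites != mf_zero.n_sites:
        raise ValueError("incompatible mean fields")


def _mixed_overlaps(exciton, mf_zero, mf_lambda):
    """S (occ-occ), X (occ_lam x batches), and the singularity warning."""
    s = occupied_overlap(mf_lambda, mf_zero)
    x = mf_lambda.occupied.T @ exciton.batches.T      # X[i, v] = <phi_i(lam)|xi_v>
    warning = None
    det_s = float(np.linalg.det(s))
    if abs(det_s) < NEAR_SINGULAR_DET:
        warning = (
            f"occupied manifolds nearly orthogonal: |det S| = {abs(det_s):.3e}"
        )
    return s, x, warning


def _column_replaced(s: np.ndarray, col: int, new_col: np.ndarray) -> np.ndarray:
    m = s.copy()
    m[:, col] = new_col
    return m


def ground_state_overlap(
    exciton: ExcitonState, mf_zero: MeanFieldState, mf_lambda: MeanFieldState
) -> float:
    """g(lambda) = sum_v det of S with column v replaced by <phi_i(lam)|xi_v>."""
    _check_inputs(exciton, mf_zero, mf_lambda)
    s, x, _ = _mixed_overlaps(exciton, mf_zero, mf_lambda)
    nv = mf_zero.n_valence
    return float(sum(np.linalg.det(_column_replaced(s, v, x[:, v])) for v in range(nv)))


def project_determinant(
    exciton: ExcitonState, mf_zero: MeanFieldState, mf_lambda: MeanFieldState
) -> ProjectedState:
    """Reference projector: explicit loop over displaced conduction orbitals."""
    _check_inputs(exciton, mf_zero, mf_lambda)
    s, x, warning = _mixed_overlaps(exciton, mf_zero, mf_lambda)
    nv = mf_zero.n_valence
    nc = mf_lambda.n_conduction
    vir = mf_lambda.virtual                              # (n, Nc)
    sc = vir.T @ mf_zero.occupied                        # Sc[c', j] = <phi_c'(lam)|phi_j>
    xc = vir.T @ exciton.batches.T                       # Xc[c', v] = <phi_c'(lam)|xi_v>

    amp = np.zeros((nv, nc))
    for v in range(nv):
        n_v = _column_replaced(s, v, x[:, v])            # rows: lam occ, cols: 0-set(v)
        row_v = _column_replaced(sc, v, xc[:, v])        # rows: lam cond, same cols
        for vp in range(nv):
            for cp in range(nc):
                m = n_v.copy()
                m[vp, :] = row_v[cp, :]
                amp[vp, cp] += np.linalg.det(m)
    batches_tilde = amp @ vir.T
    g = float(sum(
        np.linalg.det(_column_replaced(s, v, x[:, v])) for v in range(nv)
    ))
    return ProjectedState(
        batches_tilde=batches_tilde,
        g=g,
        mf_lambda_ref=mf_lambda,
        mf_zero_ref=mf_zero,
        warning=warning,
    )


def _minor_dets(m: np.ndarray, row: int) -> np.ndarray:
    """Determinants of m with `row` and each column removed, in column order."""
    nv = m.shape[0]
    if nv == 1:
        return np.ones(1)
    sub = np.delete(m, row, axis=0)
    return np.array([np.linalg.det(np.delete(sub, j, axis=1)) for j in range(nv)])


def project_batches(
    exciton: ExcitonState, mf_zero: MeanFieldState, mf_lambda: MeanFieldState
) -> ProjectedState:
    """Conduction-sum-free projector via cofactor expansion.

    Expanding each Nv x Nv determinant along the row carrying the
    displaced conduction orbital turns the sum over c' into the projector
    P_c(lambda) acting on the reference orbitals and batches:

        xi~_{v'} = sum_v sum_j (-1)^(v'+j) minor_{v',j}[N(v)] P_c(lam) |y_j(v)>

    where N(v) is the occupied overlap matrix with column v replaced by
    <phi_i(lam)|xi_v>, and y_j(v) is the j-th column vector of the
    reference set (phi_j, or xi_v in slot v).  Agrees with
    :func:`project_determinant` to numerical precision.
    """
    _check_inputs(exciton, mf_zero, mf_lambda)
    s, x, warning = _mixed_overlaps(exciton, mf_zero, mf_lambda)
    nv = mf_zero.n_valence
    n = mf_zero.n_sites
    pc = mf_lambda.conduction_projector()

    # conduction-projected column vectors: P_c(lam) phi_j and P_c(lam) xi_v
    pc_occ = pc @ mf_zero.occupied                      # (n, Nv)
    pc_xi = exciton.batches @ pc.T                      # (Nv, n)

    g = 0.0
    batches_tilde = np.zeros((nv, n))
    for v in range(nv):
        n_v = _column_replaced(s, v, x[:, v])
        g += float(np.linalg.det(n_v))
        for vp in range(nv):
            minors = _minor_dets(n_v, vp)
            signs = (-1.0) ** (vp + np.arange(nv))
            coeff = signs * minors
            for j in range(nv):
                y = pc_xi[v] if j == v else pc_occ[:, j]
                batches_tilde[vp] += coeff[j] * y
    return ProjectedState(
        batches_tilde=batches_tilde,
        g=g,
        mf_lambda_ref=mf_lambda,
        mf_zero_ref=mf_zero,
        warning=warning,
    )


def align_orbital_signs(mf: MeanFieldState, reference: MeanFieldState) -> MeanFieldState:
    """Flip orbital signs so each column overlaps positively with the reference.

    Determinant-based quantities are insensitive to these flips except for
    an overall sign; aligning makes scalar diagnostics such as g(lambda)
    vary smoothly along a geometric path.  Orbitals are matched by index,
    so this is only meaningful away from degeneracies.
    """
    diag = np.einsum("ni,ni->i", mf.orbitals, reference.orbitals)
    flips = np.where(diag < 0.0, -1.0, 1.0)
    return replace(mf, orbitals=mf.orbitals * flips[None, :])
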