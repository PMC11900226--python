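"""Independent reference implementations used as test oracles.

Everything here deliberately avoids the package's production code paths:
pair interactions are accumulated with explicit Python loops, the
configuration-interaction-singles matrix is assembled from molecular-
orbital two-electron integrals via the Slater-Condon rules, and
many-body determinant overlaps are expanded over permutations (Leibniz
rule) instead of calling a determinant routine.
"""

from __future__ import annotations

import itertools

import numpy as np


def pair_loop_core(geometry, params):
    """Element-by-element recomputation of the core and pair matrices."""
    n = geometry.n_atoms
    pos = geometry.positions
    h = np.zeros((n, n))
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            r = float(np.sqrt(sum((pos[i, k] - pos[j, k]) ** 2 for k in range(3))))
            v[i, j] = params.u_onsite / np.sqrt(1.0 + (r / params.ohno_a) ** 2)
            if i != j and r <= params.hop_cutoff:
                h[i, j] = -params.t0 * np.exp(-(r - params.r_ref) / params.zeta)
    for i in range(n):
        h[i, i] = -sum(v[i, j] for j in range(n) if j != i)
    return h, v


def mo_eri_zdo(orbitals, gamma):
    """(pq|rs) in the molecular-orbital basis from ZDO site integrals."""
    n = orbitals.shape[1]
    eri = np.zeros((n, n, n, n))
    for p in range(n):
        for q in range(n):
            dpq = orbitals[:, p] * orbitals[:, q]
            for r in range(n):
                for s in range(n):
                    drs = orbitals[:, r] * orbitals[:, s]
                    eri[p, q, r, s] = dpq @ gamma @ drs
    return eri


def cis_singlet_matrix(mf, gamma):
    """Singlet CI-singles matrix over (occupied, virtual) pairs, v-major.

    H_{ia,jb} = delta_ij delta_ab (eps_a - eps_i) + 2 (ia|jb) - (ij|ab),
    the Slater-Condon result for spin-adapted singlet single excitations.
    """
    nv = mf.n_valence
    nc = mf.n_conduction
    eps = mf.energies
    eri = mo_eri_zdo(mf.orbitals, gamma)
    h = np.zeros((nv * nc, nv * nc))
    for i in range(nv):
        for a in range(nc):
            for j in range(nv):
                for b in range(nc):
                    val = 2.0 * eri[i, nv + a, j, nv + b] - eri[i, j, nv + a, nv + b]
                    if i == j and a == b:
                        val += eps[nv + a] - eps[i]
                    h[i * nc + a, j * nc + b] = val
    return h


def perm_sign(perm) -> int:
    s = 1
    p = list(perm)
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            if p[i] > p[j]:
                s = -s
    return s


def leibniz_overlap(rows_a: np.ndarray, rows_b: np.ndarray) -> float:
    """Overlap of two Slater determinants by full permutation expansion.

    ``rows_a`` and ``rows_b`` hold the single-particle orbitals row-wise in
    a common orthonormal basis.
    """
    ne = rows_a.shape[0]
    total = 0.0
    for perm in itertools.permutations(range(ne)):
        term = perm_sign(perm)
        for i in range(ne):
            term *= float(rows_a[i] @ rows_b[perm[i]])
        total += term
    return total


def project_by_enumeration(exciton_batches, mf_zero, mf_lambda):
    """Projected amplitudes and ground overlap via Leibniz-rule overlaps.

    Enumerates every displaced (v', c') pair and evaluates the many-body
    determinant overlaps by permutation expansion; feasible for up to ~6
    basis functions.
    """
    nv = mf_zero.n_valence
    nc = mf_lambda.n_conduction
    occ0 = mf_zero.occupied.T
    occl = mf_lambda.occupied.T
    virl = mf_lambda.virtual.T
    amp = np.zeros((nv, nc))
    g = 0.0
    for v in range(nv):
        cols0 = occ0.copy()
        cols0[v] = exciton_batches[v]
        g += leibniz_overlap(occl, cols0)
        for vp in range(nv):
            for cp in range(nc):
                rows = occl.copy()
                rows[vp] = virl[cp]
                amp[vp, cp] += leibniz_overlap(rows, cols0)
    return amp, g
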