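"""Diagonalization of the excitonic Hamiltonian and exciton bookkeeping.

Two routes are provided: a dense reference diagonalization over explicit
(valence, conduction) pairs, and a block-Davidson iteration that touches
the Hamiltonian only through its batch application -- the representation
that scales to systems where conduction states cannot be enumerated.
Their agreement is the correctness claim of the batch formalism and is
asserted across the test suite.

State tracking matches excitons computed at neighboring geometries by
their mutual overlaps, which is what makes finite differences of
excitation energies well defined through level crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .excitonic import (
    ExcitonState,
    ExcitonicContext,
    amplitudes_from_batches,
    apply_hexc,
    batches_from_amplitudes,
    dense_matrix,
)

__all__ = [
    "ExcitonSet",
    "SolverError",
    "inner",
    "solve_dense",
    "solve_iterative",
    "track_states",
    "TrackingResult",
]


class SolverError(RuntimeError):
    """Eigensolver failure (non-convergence or invalid request)."""


@dataclass
class ExcitonSet:
    """Solved excitons in ascending-energy order, mutually orthonormal."""

    states: list[ExcitonState]
    ctx_ref: ExcitonicContext
    n_cycles: int = 0

    def __post_init__(self) -> None:
        omegas = [s.omega for s in self.states]
        if any(o is None for o in omegas):
            raise ValueError("all states in an ExcitonSet must carry omega")
        if any(b > a + 1e-12 for a, b in zip(omegas[1:], omegas)):
            raise ValueError("omegas must be ascending")

    @property
    def omegas(self) -> np.ndarray:
        return np.array([s.omega for s in self.states])

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> ExcitonState:
        return self.states[i]


def inner(a: ExcitonState, b: ExcitonState) -> float:
    """Batch inner product sum_v <xi_v^a | xi_v^b>.

    Equals the amplitude dot product sum_{v,c} A^a_{v,c} A^b_{v,c} for
    states on the same mean field; states on different mean fields are
    rejected (compare via :func:`track_states` instead).
    """
    if a.mf_ref is not b.mf_ref:
        raise ValueError("inner product requires a common mean-field reference")
    return float(np.sum(a.batches * b.batches))


def solve_dense(ctx: ExcitonicContext, n_states: int) -> ExcitonSet:
    """Lowest eigenpairs by explicit diagonalization over (v, c) pairs."""
    nv, nc = ctx.n_valence, ctx.n_conduction
    dim = nv * nc
    if not 1 <= n_states <= dim:
        raise SolverError(f"n_states must be in [1, {dim}], got {n_states}")
    h = dense_matrix(ctx)
    evals, evecs = np.linalg.eigh(h)
    states = []
    for k in range(n_states):
        amp = evecs[:, k].reshape(nv, nc)
        states.append(
            ExcitonState(
                batches=batches_from_amplitudes(ctx.mf, amp),
                mf_ref=ctx.mf,
                omega=float(evals[k]),
            )
        )
    return ExcitonSet(states=states, ctx_ref=ctx)


def _davidson_guess(ctx: ExcitonicContext, n_guess: int) -> np.ndarray:
    """Unit amplitudes on the lowest diagonal (v, c) gaps."""
    nv, nc = ctx.n_valence, ctx.n_conduction
    eps = ctx.corrected_energies()
    diag = (eps[nv:][None, :] - eps[:nv][:, None]).reshape(-1)
    order = np.argsort(diag)[:n_guess]
    amps = np.zeros((n_guess, nv * nc))
    amps[np.arange(n_guess), order] = 1.0
    return amps.reshape(n_guess, nv, nc)


def solve_iterative(
    ctx: ExcitonicContext,
    n_states: int,
    tol: float = 1e-10,
    max_space: int | None = None,
    max_cycles: int = 200,
) -> ExcitonSet:
    """Block Davidson using only batch applications of H_exc.

    Trial vectors are batch arrays; the Hamiltonian enters exclusively via
    :func:`apply_hexc`.  The preconditioner divides residual amplitudes by
    the diagonal orbital-energy differences.  Raises :class:`SolverError`
    with a residual report if the requested states do not converge.
    """
    mf = ctx.mf
    nv, nc = ctx.n_valence, ctx.n_conduction
    dim = nv * nc
    if not 1 <= n_states <= dim:
        raise SolverError(f"n_states must be in [1, {dim}], got {n_states}")
    if max_space is None:
        max_space = min(dim, 12 * n_states)
    max_space = min(max(max_space, 2 * n_states), dim)

    eps = ctx.corrected_energies()
    diag = (eps[nv:][None, :] - eps[:nv][:, None])   # (nv, nc)

    def flat(b):  # batches (nv, n) -> amplitude vector (dim,)
        return amplitudes_from_batches(mf, b).reshape(-1)

    def unflat(x):
        return batches_from_amplitudes(mf, x.reshape(nv, nc))

    # subspace bases stored as amplitude vectors for cheap orthogonalization
    basis: list[np.ndarray] = []
    sigma: list[np.ndarray] = []
    for g in _davidson_guess(ctx, min(n_states + 1, dim)):
        basis.append(g.reshape(-1) / np.linalg.norm(g))

    theta = np.zeros(n_states)
    last_resid = np.full(n_states, np.inf)
    for cycle in range(max_cycles):
        while len(sigma) < len(basis):
            b = basis[len(sigma)]
            sigma.append(flat(apply_hexc(ctx, unflat(b))))
        bmat = np.array(basis)            # (m, dim)
        smat = np.array(sigma)            # (m, dim)
        hsub = bmat @ smat.T
        hsub = (hsub + hsub.T) / 2.0
        evals, evecs = np.linalg.eigh(hsub)
        theta = evals[:n_states]
        ritz = evecs[:, :n_states].T @ bmat          # (n_states, dim)
        ritz_sigma = evecs[:, :n_states].T @ smat
        resid = ritz_sigma - theta[:, None] * ritz
        last_resid = np.linalg.norm(resid, axis=1)
        if np.all(last_resid < tol) or len(basis) >= dim:
            break

        if len(basis) + n_states > max_space:
            # restart: keep the current Ritz vectors
            basis = [r / np.linalg.norm(r) for r in ritz]
            sigma = []
            continue

        added = 0
        for k in range(n_states):
            if last_resid[k] < tol:
                continue
            denom = diag.reshape(-1) - theta[k]
            denom = np.where(np.abs(denom) < 1e-8, np.sign(denom + 1e-30) * 1e-8, denom)
            new = resid[k] / denom
            for b in basis:
                new -= (b @ new) * b
            for b in basis:
                new -= (b @ new) * b
            nrm = np.linalg.norm(new)
            if nrm > 1e-10:
                basis.append(new / nrm)
                added += 1
        if added == 0 and np.any(last_resid >= tol):
            # subspace saturated without convergence
            break

    if np.any(last_resid >= tol) and not len(basis) >= dim:
        raise SolverError(
            "Davidson did not converge: residual norms "
            + np.array2string(last_resid, precision=3)
        )
    if len(basis) >= dim and np.any(last_resid >= tol):
        # full space reached: the Rayleigh-Ritz solution is exact
        pass

    order = np.argsort(theta)
    states = []
    for k in order:
        x = ritz[k]
        x = x / np.linalg.norm(x)
        states.append(ExcitonState(batches=unflat(x), mf_ref=mf, omega=float(theta[k])))
    return ExcitonSet(states=states, ctx_ref=ctx, n_cycles=cycle + 1)


@dataclass
class TrackingResult:
    """Greedy overlap assignment between two exciton sets.

    ``mapping[i]`` is the candidate index matched to reference state ``i``;
    ``overlaps[i]`` the corresponding |overlap|; ``ambiguous[i]`` flags
    matches below 0.5, where a crossing cannot be resolved confidently.
    """

    mapping: list[int]
    overlaps: list[float]
    ambiguous: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ambiguous:
            self.ambiguous = [o < 0.5 for o in self.overlaps]


AMBIGUITY_THRESHOLD = 0.5


def overlap_matrix(reference: ExcitonSet, candidate: ExcitonSet) -> np.ndarray:
    """O_ij = sum_v <xi_v^ref,i | P_c(ref) xi_v^cand,j>.

    Candidate batches are projected onto the reference conduction subspace
    before taking inner products, so sets built on different (e.g.
    displaced) mean fields are comparable.
    """
    pc = reference.ctx_ref.mf.conduction_projector()
    ref = np.array([s.batches for s in reference.states])       # (nr, nv, n)
    cand = np.array([s.batches @ pc.T for s in candidate.states])
    if ref.shape[1:] != cand.shape[1:]:
        raise ValueError("exciton sets have incompatible shapes")
    return np.einsum("ivn,jvn->ij", ref, cand, optimize=True)


def track_states(reference: ExcitonSet, candidate: ExcitonSet) -> TrackingResult:
    """Match each reference state to a distinct candidate by |overlap|.

    Greedy descending-|overlap| assignment; adequate for the small state
    counts targeted here.  Matches with |overlap| < 0.5 are flagged
    ambiguous but still returned.
    """
    o = overlap_matrix(reference, candidate)
    nr, ncand = o.shape
    if ncand < nr:
        raise ValueError("candidate set has fewer states than reference")
    mapping = [-1] * nr
    used = set()
    pairs = sorted(
        ((abs(o[i, j]), i, j) for i in range(nr) for j in range(ncand)),
        reverse=True,
    )
    for mag, i, j in pairs:
        if mapping[i] == -1 and j not in used:
            mapping[i] = j
            used.add(j)
    overlaps = [float(abs(o[i, mapping[i]])) for i in range(nr)]
    return TrackingResult(mapping=mapping, overlaps=overlaps)
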