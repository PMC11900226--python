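"""Excited-state atomic forces and geometry relaxation.

The total energy of excited state S is E_S = E0 + Omega_S.  Its
derivative along a nuclear coordinate lambda is taken as

    dE_S/dlam ~= [ <Psi_S| P+(dl) H_exc(+dl) P(+dl) |Psi_S>
                 - <Psi_S| P+(-dl) H_exc(-dl) P(-dl) |Psi_S> ] / (2 dl)
                 + dE0/dlam,

a Hellmann-Feynman expectation of the finite-difference derivative of
the excitonic Hamiltonian, evaluated with the eigenstate of the
undisplaced geometry projected (unnormalized) onto the Tamm-Dancoff
manifolds of the displaced geometries.  Only one excited-state solve is
needed per geometry, and the expression stays well defined through level
crossings because no eigenstate of a displaced geometry is ever needed.

The brute-force alternative -- central differences of E0 + Omega_S with
the displaced eigenstates identified by exciton overlaps -- is provided
for validation and for exhibiting the crossing bookkeeping it requires.

The mean field, both interaction kernels, and the screening are
recomputed at every displaced geometry; the scissor and quasiparticle
shifts are held fixed during differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .excitonic import ExcitonState, ExcitonicContext, QPCorrections, apply_hexc
from .geometry import AXES, Geometry
from .kernels import build_kernels
from .model import MeanFieldState, ModelParams, ScfError, scf_ground_state
from .projector import ProjectedState, project_batches
from .solver import ExcitonSet, solve_dense, solve_iterative, track_states

__all__ = [
    "BseSettings",
    "ForceRecord",
    "OptimizationTrace",
    "OptimizationStep",
    "make_context",
    "displaced_context",
    "omega_derivative_hf",
    "e0_derivative",
    "excited_force",
    "brute_force_force",
    "optimize",
    "all_coordinates",
]

DEFAULT_DELTA_LAMBDA = 0.1   # Bohr; operator-derivative step
DEFAULT_FMAX = 1e-2          # Ry/Bohr; relaxation convergence criterion


@dataclass(frozen=True)
class BseSettings:
    """Solver-facing excited-state options (one geometry-independent bundle)."""

    screening: str = "rpa"           # "rpa" | "bare"
    scissor: float = 0.0             # Ry
    spin: str = "singlet"            # "singlet" | "triplet"
    n_states: int = 3
    solver: str = "dense"            # "dense" | "davidson"
    davidson_tol: float = 1e-10
    valence_shifts: dict[int, float] = field(default_factory=dict)
    conduction_shifts: dict[int, float] = field(default_factory=dict)

    def qp(self) -> QPCorrections:
        return QPCorrections(
            scissor=self.scissor,
            valence_shifts=dict(self.valence_shifts),
            conduction_shifts=dict(self.conduction_shifts),
        )


def make_context(geometry: Geometry, params: ModelParams, bse: BseSettings) -> ExcitonicContext:
    """Mean field + kernels + corrections at one geometry."""
    mf = scf_ground_state(geometry, params)
    return ExcitonicContext(
        mf=mf, kernels=build_kernels(mf, bse.screening), qp=bse.qp(), spin_channel=bse.spin
    )


def displaced_context(ctx0: ExcitonicContext, geometry: Geometry) -> ExcitonicContext:
    """Rebuild the full context (mean field, v, W) at another geometry."""
    mf = scf_ground_state(geometry, ctx0.mf.params)
    return ExcitonicContext(
        mf=mf,
        kernels=build_kernels(mf, ctx0.kernels.screening_mode),
        qp=ctx0.qp,
        spin_channel=ctx0.spin_channel,
    )


def solve_excitons(ctx: ExcitonicContext, bse: BseSettings, n_states: int) -> ExcitonSet:
    if bse.solver == "davidson":
        return solve_iterative(ctx, n_states, tol=bse.davidson_tol)
    return solve_dense(ctx, n_states)


def all_coordinates(geometry: Geometry) -> list[tuple[int, int]]:
    return [(a, ax) for a in range(geometry.n_atoms) for ax in range(3)]


@dataclass
class ForceRecord:
    """Per-atom Cartesian forces in Ry/Bohr, with their energy derivatives.

    Entries outside ``coordinates`` were not computed and are zero.
    ``forces = -(omega_derivatives + e0_derivatives)`` on every computed
    coordinate.
    """

    forces: np.ndarray               # (n_atoms, 3)
    omega_derivatives: np.ndarray    # (n_atoms, 3)
    e0_derivatives: np.ndarray       # (n_atoms, 3)
    coordinates: list[tuple[int, int]]
    method: str                      # "hellmann_feynman" | "finite_difference"
    delta_lambda: float
    state_index: int | None = None
    ambiguous: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("non-finite forces")
        recomputed = -(self.omega_derivatives + self.e0_derivatives)
        for a, ax in self.coordinates:
            if abs(recomputed[a, ax] - self.forces[a, ax]) > 1e-12:
                raise ValueError("forces inconsistent with energy derivatives")

    def max_force(self) -> float:
        return max(abs(self.forces[a, ax]) for a, ax in self.coordinates)


def _check_step(delta_lambda: float) -> None:
    if not delta_lambda > 0:
        raise ValueError(f"delta_lambda must be positive, got {delta_lambda}")


def _projected_expectation(ps: ProjectedState, ctx: ExcitonicContext) -> float:
    """<P Psi | H_exc | P Psi> with the unnormalized projected batches."""
    return float(np.sum(ps.batches_tilde * apply_hexc(ctx, ps.batches_tilde)))


def _displaced_pair(ctx0, coordinate, delta_lambda):
    atom, axis = coordinate[0], AXES[coordinate[1]]
    out = []
    for sign in (+1.0, -1.0):
        geom = ctx0.mf.geometry.displace(atom, axis, sign * delta_lambda)
        try:
            out.append(displaced_context(ctx0, geom))
        except ScfError as exc:
            raise ScfError(
                f"SCF failed at displacement {sign * delta_lambda:+.4f} Bohr of "
                f"atom {atom} axis {axis}: {exc}"
            ) from exc
    return out


def omega_derivative_hf(
    exciton: ExcitonState,
    ctx0: ExcitonicContext,
    coordinate: tuple[int, int | str],
    delta_lambda: float = DEFAULT_DELTA_LAMBDA,
) -> float:
    """dOmega_S/dlambda by the projected Hellmann-Feynman estimator."""
    _check_step(delta_lambda)
    ctx_p, ctx_m = _displaced_pair(ctx0, coordinate, delta_lambda)
    ps_p = project_batches(exciton, ctx0.mf, ctx_p.mf)
    ps_m = project_batches(exciton, ctx0.mf, ctx_m.mf)
    return (_projected_expectation(ps_p, ctx_p) - _projected_expectation(ps_m, ctx_m)) / (
        2.0 * delta_lambda
    )


def e0_derivative(
    geometry: Geometry,
    params: ModelParams,
    coordinate: tuple[int, int | str],
    delta_lambda: float = DEFAULT_DELTA_LAMBDA,
) -> float:
    """dE0/dlambda by central finite difference of the mean-field energy."""
    _check_step(delta_lambda)
    atom, axis = coordinate[0], AXES[coordinate[1]]
    ep = scf_ground_state(geometry.displace(atom, axis, +delta_lambda), params).e0
    em = scf_ground_state(geometry.displace(atom, axis, -delta_lambda), params).e0
    return (ep - em) / (2.0 * delta_lambda)


def excited_force(
    exciton: ExcitonState,
    ctx0: ExcitonicContext,
    delta_lambda: float = DEFAULT_DELTA_LAMBDA,
    coordinates: list[tuple[int, int]] | None = None,
    state_index: int | None = None,
) -> ForceRecord:
    """Hellmann-Feynman forces: -(dOmega + dE0) over the chosen coordinates.

    Coordinates default to all 3N; a restricted subset exploits symmetry
    (e.g. only the internuclear axis of a linear molecule).  Both
    derivatives share the same displaced self-consistent fields.
    """
    _check_step(delta_lambda)
    geom = ctx0.mf.geometry
    coords = coordinates if coordinates is not None else all_coordinates(geom)
    domega = np.zeros((geom.n_atoms, 3))
    de0 = np.zeros((geom.n_atoms, 3))
    for atom, axis in coords:
        ax = AXES[axis]
        ctx_p, ctx_m = _displaced_pair(ctx0, (atom, ax), delta_lambda)
        ps_p = project_batches(exciton, ctx0.mf, ctx_p.mf)
        ps_m = project_batches(exciton, ctx0.mf, ctx_m.mf)
        domega[atom, ax] = (
            _projected_expectation(ps_p, ctx_p) - _projected_expectation(ps_m, ctx_m)
        ) / (2.0 * delta_lambda)
        de0[atom, ax] = (ctx_p.mf.e0 - ctx_m.mf.e0) / (2.0 * delta_lambda)
    coords_ax = [(a, AXES[x]) for a, x in coords]
    return ForceRecord(
        forces=-(domega + de0),
        omega_derivatives=domega,
        e0_derivatives=de0,
        coordinates=coords_ax,
        method="hellmann_feynman",
        delta_lambda=delta_lambda,
        state_index=state_index,
    )


def brute_force_force(
    state_index: int,
    geometry: Geometry,
    params: ModelParams,
    bse: BseSettings,
    delta_lambda: float = DEFAULT_DELTA_LAMBDA,
    coordinates: list[tuple[int, int]] | None = None,
    tracking: bool = True,
) -> ForceRecord:
    """Forces by central differences of E0 + Omega_S at displaced geometries.

    ``state_index`` is 1-based over excitons (index 0 would be the ground
    state, which has no excitation energy to difference and is rejected).
    The displaced eigenstate belonging to the followed exciton is
    identified by maximum overlap against the undisplaced set; matches
    with |overlap| < 0.5 are flagged in ``ambiguous``.  With
    ``tracking=False`` the energy-ordered state of the same index is
    differenced instead -- the naive bookkeeping that fails through level
    crossings, kept as a comparator for the crossing experiments.
    """
    if state_index < 1:
        raise ValueError("state_index is 1-based over excitons; use the mean field for the ground state")
    _check_step(delta_lambda)
    ctx0 = make_context(geometry, params, bse)
    dim = ctx0.n_valence * ctx0.n_conduction
    if state_index > dim:
        raise ValueError(f"state_index {state_index} exceeds {dim} excitations")
    n_solve = min(dim, max(bse.n_states, state_index + 2))
    set0 = solve_excitons(ctx0, bse, n_solve)

    coords = coordinates if coordinates is not None else all_coordinates(geometry)
    domega = np.zeros((geometry.n_atoms, 3))
    de0 = np.zeros((geometry.n_atoms, 3))
    ambiguous: list[tuple[int, int]] = []
    k = state_index - 1
    for atom, axis in coords:
        ax = AXES[axis]
        vals = {}
        amb = False
        for sign in (+1.0, -1.0):
            geom_d = geometry.displace(atom, ax, sign * delta_lambda)
            ctx_d = displaced_context(ctx0, geom_d)
            set_d = solve_excitons(ctx_d, bse, n_solve)
            if tracking:
                tr = track_states(set0, set_d)
                j = tr.mapping[k]
                amb = amb or tr.ambiguous[k]
            else:
                j = k
            vals[sign] = (ctx_d.mf.e0, set_d.omegas[j])
        de0[atom, ax] = (vals[1.0][0] - vals[-1.0][0]) / (2.0 * delta_lambda)
        domega[atom, ax] = (vals[1.0][1] - vals[-1.0][1]) / (2.0 * delta_lambda)
        if amb:
            ambiguous.append((atom, ax))
    coords_ax = [(a, AXES[x]) for a, x in coords]
    return ForceRecord(
        forces=-(domega + de0),
        omega_derivatives=domega,
        e0_derivatives=de0,
        coordinates=coords_ax,
        method="finite_difference",
        delta_lambda=delta_lambda,
        state_index=state_index,
        ambiguous=ambiguous,
    )


@dataclass
class OptimizationStep:
    geometry: Geometry
    energy: float                   # E_S = E0 + Omega, Ry
    max_force: float                # Ry/Bohr over the active coordinates
    state_index: int                # 0-based index of the followed state at this geometry
    tracking_overlap: float
    ambiguous: bool


@dataclass
class OptimizationTrace:
    steps: list[OptimizationStep]
    algorithm: str
    converged: bool
    fmax_threshold: float

    @property
    def final_geometry(self) -> Geometry:
        return self.steps[-1].geometry

    @property
    def final_energy(self) -> float:
        return self.steps[-1].energy


class _Surface:
    """E_S evaluations with overlap-based state following along the path."""

    def __init__(self, state_index, params, bse, n_solve):
        self.params = params
        self.bse = bse
        self.n_solve = n_solve
        self.k = state_index - 1

    def solve(self, geometry, ref_set=None, ref_k=None):
        ctx = make_context(geometry, self.params, self.bse)
        eset = solve_excitons(ctx, self.bse, self.n_solve)
        if ref_set is None:
            k, ov, amb = self.k, 1.0, False
        else:
            tr = track_states(ref_set, eset)
            k, ov, amb = tr.mapping[ref_k], tr.overlaps[ref_k], tr.ambiguous[ref_k]
        return ctx, eset, k, ctx.mf.e0 + eset.omegas[k], ov, amb


def optimize(
    state_index: int,
    geometry: Geometry,
    params: ModelParams,
    bse: BseSettings,
    algorithm: str = "bfgs",
    fmax: float = DEFAULT_FMAX,
    max_steps: int = 60,
    step_init: float = 0.5,
    delta_lambda: float = DEFAULT_DELTA_LAMBDA,
    coordinates: list[tuple[int, int]] | None = None,
) -> OptimizationTrace:
    """Relax the geometry on excited surface ``state_index`` (1-based).

    Steepest descent or BFGS on E_S = E0 + Omega_S with the
    Hellmann-Feynman forces as the gradient; any trial step that raises
    E_S is halved (both algorithms), so the energy is non-increasing over
    accepted steps.  The followed state is re-identified after every
    geometry change by exciton overlaps.  Converged when every active
    force component is below ``fmax`` (default 0.01 Ry/Bohr).
    """
    if algorithm not in ("sd", "steepest_descent", "bfgs"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if not fmax > 0:
        raise ValueError("fmax must be positive")
    if state_index < 1:
        raise ValueError("state_index is 1-based over excitons")

    probe = make_context(geometry, params, bse)
    dim = probe.n_valence * probe.n_conduction
    if state_index > dim:
        raise ValueError(f"state_index {state_index} exceeds {dim} excitations")
    n_solve = min(dim, max(bse.n_states, state_index + 2))
    surface = _Surface(state_index, params, bse, n_solve)

    coords = coordinates if coordinates is not None else all_coordinates(geometry)
    coords = [(a, AXES[x]) for a, x in coords]
    m = len(coords)

    ctx, eset, k, energy, ov, amb = surface.solve(geometry)
    hinv = step_init * np.eye(m)
    steps: list[OptimizationStep] = []
    converged = False
    sd_step = step_init
    prev_grad = None
    prev_x = None

    def grad_vector(rec: ForceRecord) -> np.ndarray:
        return np.array([-rec.forces[a, ax] for a, ax in coords])

    x = np.array([geometry.positions[a, ax] for a, ax in coords])

    for _ in range(max_steps):
        rec = excited_force(eset[k], ctx, delta_lambda, coords, state_index=state_index)
        g = grad_vector(rec)
        fmax_now = rec.max_force()
        steps.append(OptimizationStep(geometry, energy, fmax_now, k, ov, amb))
        if fmax_now < fmax:
            converged = True
            break

        if algorithm == "bfgs":
            if prev_grad is not None:
                s = x - prev_x
                y = g - prev_grad
                sy = float(s @ y)
                if sy > 1e-12:
                    rho = 1.0 / sy
                    eye = np.eye(m)
                    v = eye - rho * np.outer(s, y)
                    hinv = v @ hinv @ v.T + rho * np.outer(s, s)
            direction = -hinv @ g
        else:
            direction = -sd_step * g

        prev_grad, prev_x = g, x

        # safeguarded line step: halve on energy increase
        alpha = 1.0
        accepted = None
        for _try in range(12):
            x_new = x + alpha * direction
            pos = geometry.positions.copy()
            for (a, ax), val in zip(coords, x_new):
                pos[a, ax] = val
            geom_new = Geometry(labels=geometry.labels, positions=pos)
            ctx_n, eset_n, k_n, e_n, ov_n, amb_n = surface.solve(geom_new, eset, k)
            if e_n <= energy + 1e-12:
                accepted = (geom_new, ctx_n, eset_n, k_n, e_n, ov_n, amb_n, x_new)
                break
            alpha *= 0.5
        if accepted is None:
            if algorithm != "bfgs":
                sd_step *= 0.5
                if sd_step < 1e-6:
                    break
                continue
            # reset curvature information and fall back to a small descent step
            hinv = step_init * np.eye(m)
            prev_grad = None
            continue
        geometry, ctx, eset, k, energy, ov, amb = accepted[:7]
        x = accepted[7]
        if algorithm != "bfgs" and alpha == 1.0:
            sd_step = min(sd_step * 1.2, 4.0 * step_init)

    else:
        # loop exhausted max_steps without convergence check on last point
        rec = excited_force(eset[k], ctx, delta_lambda, coords, state_index=state_index)
        fmax_now = rec.max_force()
        steps.append(OptimizationStep(geometry, energy, fmax_now, k, ov, amb))
        converged = fmax_now < fmax

    return OptimizationTrace(
        steps=steps,
        algorithm="bfgs" if algorithm == "bfgs" else "steepest_descent",
        converged=converged,
        fmax_threshold=fmax,
    )
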