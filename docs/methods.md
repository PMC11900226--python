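# Methods

This note documents the model, the algorithms, the numerical choices, and
what the synthetic test systems do and do not establish.  Units are
Rydberg (energy) and Bohr (length) everywhere; the thresholds quoted
below (0.01 Ry/Bohr, Δλ = 0.1 Bohr) are therefore literal.

## Mean-field backend

The one-particle layer is a Pariser–Parr–Pople-style π-electron model:
one orbital per site in an orthonormal basis (zero-differential-overlap,
ZDO, convention), with

* hopping `t(R) = t0·exp(−(R − r_ref)/ζ)` between sites within the
  neighbor cutoff (default `1.6·r_ref`), zero beyond;
* electron–electron repulsion `V(R) = U/√(1 + (R/a)²)` (Ohno
  interpolation between the on-site U and a screened `U·a/R` tail);
* electron–core attraction `−Σ_j V(R_ij)` on the site diagonal, one
  positive core charge per site, so the half-filled molecule is neutral
  and size-consistent;
* a classical core–core term `Σ_{i<j} [V(R_ij) + A·exp(−R_ij/ρ)]` whose
  short-range exponential provides the repulsive wall of the
  potential-energy surface.

The restricted closed-shell self-consistent field starts from the
core-Hamiltonian guess and uses linear density mixing (factor 0.5),
density tolerance 1e-10, at most 500 iterations — robustness on tiny
systems matters more than speed here.  Open shells (frontier degeneracy
at the Fermi level) are rejected rather than fractionally occupied,
because the whole excited-state formalism assumes a single closed-shell
reference determinant.  The mean-field operator, its orbitals φ_i,
energies ε_i, and total energy E0 are the only things the excited-state
layer consumes, which is exactly the interface a first-principles
density-functional backend would present.

Default model parameters (frozen once for all experiments): t0 = 0.2 Ry,
r_ref = 2.4 Bohr, ζ = 1 Bohr, U = 0.8 Ry, a = 2 Bohr, A = 40 Ry,
ρ = 0.35 Bohr.  The hopping scale and on-site repulsion are of the
magnitude customary for π-electron models (≈2.7 eV and ≈11 eV); the core
wall was chosen so the two-center fixture binds with a bond minimum
between 2 and 3 Bohr, like a first-row diatomic.

## Excitonic Hamiltonian in batch form

A Tamm–Dancoff excitation is Σ_{v,c} A_{v,c} a†_c a_v |Ψ0⟩.  All
amplitudes of one valence channel are carried by a single batch vector
ξ_v = Σ_c A_{v,c} φ_c in the conduction subspace, so sums over empty
orbitals are replaced by applications of the mean-field Hamiltonian and
of the conduction projector P_c = I − Σ_v |φ_v⟩⟨φ_v|.  The three terms
act channel-wise:

* **diagonal**: (H_mf − ε_v + Δ)|ξ_v⟩, with the scissor Δ and optional
  explicit per-orbital quasiparticle shifts (applied through
  Σ_c shift_c |φ_c⟩⟨φ_c| and corrected valence energies) standing in for
  a many-body self-energy; shifts beyond the explicitly corrected
  orbitals are absorbed into Δ;
* **exchange**: `ξ''_v(r) = s·P_c[φ_v(r)·(v·Σ_{v'} φ_{v'}∘ξ_{v'})(r)]`,
  with spin factor s = 2 (singlet) or 0 (triplet) — the spin factor is
  placed on the exchange kernel, which is the only spin-dependent choice
  that matters at Tamm–Dancoff level;
* **direct**: `ξ'''_v(r) = −P_c[Σ_{v'} ξ_{v'}(r)·(W·(φ_{v'}∘φ_v))(r)]`.

Site-pointwise products implement the real-space orbital products of the
kernels under the ZDO convention; all orbitals are real.  A dense matrix
over explicit (v, c) pairs is kept as a reference oracle; tests assert
batch ≡ dense to 1e-10 on every fixture, and that with bare screening and
zero scissor the dense matrix equals an independently coded Slater–Condon
configuration-interaction-singles matrix.

## Screening

W is the static random-phase-approximation screened interaction,
`W = (I − v·χ0)⁻¹·v`, with the independent-particle polarizability
`χ0_rs = 4·Σ_{v,c} φ_v(r)φ_c(r)φ_v(s)φ_c(s)/(ε_v − ε_c)` (factor 4 =
spin 2 × the (v,c)/(c,v) double counting).  χ0 is negative semidefinite,
so `I − v·χ0` has spectrum ≥ 1 and the solve is well conditioned for any
physical input; W is explicitly symmetrized after asserting the raw
asymmetry is below 1e-8.  Screening weakens the interaction in the
operator sense (W ⪯ v in the positive-semidefinite order) — note this
does **not** force every exciton energy to rise: on lattices, site-local
field effects can anti-screen individual matrix elements, and the frozen
two-center fixture indeed shows a 7·10⁻⁴ Ry *drop* of the lowest exciton
under screening while the six-site chain shows the expected rise.  A
`bare` mode (W = v) is provided; it makes the Hamiltonian exactly the
singlet CIS matrix and powers that oracle.

## Solvers and state tracking

Dense diagonalization is the reference.  The production path is a block
Davidson iteration whose matrix–vector product is the batch application
only; the preconditioner divides residual amplitudes by
`ε_c − ε_v + Δ − θ`, the subspace restarts at 12·n_states vectors, and
non-convergence raises with a residual report.  Agreement with the dense
route to 1e-8 Ry on every fixture is the correctness claim of the
conduction-sum-free algebra.

Excitons at neighboring geometries are matched by the overlap
`Σ_v ⟨ξ_v^ref | P_c(ref) | ξ_v^cand⟩` (candidate batches projected onto
the reference conduction subspace), with greedy assignment by descending
magnitude — adequate for the handful of states targeted here; matches
below |overlap| = 0.5 are flagged ambiguous rather than rejected.  Within
numerically degenerate blocks only subspaces, not individual vectors, are
meaningful, and the tests compare them accordingly.

## Manifold projector

A Tamm–Dancoff state built at geometry 0 is carried to the manifold of a
displaced geometry λ by expanding many-body overlaps of nonorthogonal
Slater determinants.  The projected amplitude Ã_{v',c'} is a sum over v
of Nv×Nv determinants of the mixed overlap matrix in which displaced
occupied orbital v' is replaced by displaced conduction orbital c' and
reference occupied orbital v is replaced by the batch ξ_v.  Two
implementations are kept deliberately:

* a **determinant** reference that enumerates (v', c') explicitly;
* a **cofactor (batch)** form derived by expanding each determinant along
  the substituted row: the sum over c' collapses into P_c(λ) acting on
  the reference orbitals and batches, weighted by signed (Nv−1)-minors of
  the mixed overlap matrix.  This form never enumerates conduction
  states.

The two agree to 1e-15 in practice (asserted ≤1e-9), and both agree with
a brute-force oracle that expands the Slater determinants over all
orbital permutations (feasible to six basis functions).  Minors are
evaluated as determinants of submatrices — Nv is small at desk scale, so
no LU/cofactor caching is needed.  The overlap of the projected state
with the displaced *ground* determinant, g(λ), comes from the same
machinery; g(0) = 0 and g is odd in λ at linear order, which the tests
verify by a Richardson ratio (halving λ shrinks g(λ)+g(−λ) fourfold).
No orbital-sign convention is imposed between geometries: everything is
determinant-based and thus consistent under per-orbital sign flips, up to
a global sign that quadratic forms (all force expressions) cancel; only
scalar diagnostics of g along a path use an explicit sign-alignment
helper, which is meaningful away from degeneracies.

## Forces

The force along coordinate λ on excited surface S is
−(∂Ω_S/∂λ + ∂E0/∂λ) with

* ∂Ω_S/∂λ from the Hellmann–Feynman expectation of the symmetric
  finite-difference operator derivative: displace by ±Δλ (default
  0.1 Bohr), re-solve the mean field **and both interaction kernels** at
  each displaced geometry (the faithful reading of "the Hamiltonian at
  the displaced geometry"; the scissor and quasiparticle shifts are held
  fixed), project the undisplaced eigenstate with the cofactor projector,
  and evaluate the two quadratic forms with the projected states entering
  **unnormalized** — their O(λ²) norm deficit cancels to the order of the
  central difference;
* ∂E0/∂λ by a central difference of the mean-field energy with the same
  Δλ, so both terms carry error of the same order in Δλ.

The estimator is second-order in Δλ (Richardson ratio ≈ 4 when halving,
asserted against a Δλ = 10⁻³ reference).  The brute-force comparator
re-solves the full excited-state problem at every displaced geometry and
identifies the followed state by overlap tracking; an untracked
(energy-ordered) mode is kept only to demonstrate how naive differencing
fails through crossings.  Agreement between the two routes within
0.01 Ry/Bohr over the two-center bond scan (2.2–2.6 Bohr, three lowest
singlets) is the package's headline validation; measured maximum
discrepancy ≈ 3·10⁻³ Ry/Bohr at Δλ = 0.1 Bohr, tightening as Δλ shrinks.

Two finite-step caveats the test suite makes explicit: per-atom central
differences carry an O(Δλ²) third-derivative bias, so sums of per-atom
derivatives obey the translational sum rule only to that bias (the
collective-translation derivative is exactly zero); and at a scan-grid
minimum the residual slope is limited by grid × curvature, which on this
stiff-walled fixture requires a 10⁻³ Bohr grid to reach the 2·10⁻³
Ry/Bohr level.

## Geometry relaxation

`optimize` minimizes E_S = E0 + Ω_S with the Hellmann–Feynman forces as
the gradient, by steepest descent or BFGS (inverse-Hessian update,
initialized to `step_init·I`).  Both algorithms share a step-halving
safeguard — any trial step that raises E_S is halved, so the energy is
non-increasing over accepted steps and the BFGS curvature information is
reset if a whole line search fails.  The followed state is re-identified
after every geometry change by exciton overlaps; per-step records keep
the energy, maximum force, tracked index, and the tracking overlap.
Convergence: every active force component below `fmax` (default
10⁻² Ry/Bohr).  Coordinates can be restricted to a subset to exploit
symmetry (the diatomic experiments relax only the bond coordinate).

## Synthetic test systems and what they show

`fixtures` provides chains, rings, smooth random one-parameter
Hamiltonian families H(λ) = H0 + λH1 (for projector tests with no
self-consistency in the way), and the central **two-center ("diatomic")
fixture**: a left center made of a transverse pair of sites mirror-placed
about the bond axis, and a right center made of axial sites.  Two
deliberate design features:

* the hopping triangle between the transverse pair and the first axial
  site breaks the particle–hole symmetry that otherwise keeps two of the
  four excitons of a bipartite half-filled four-site model nearly
  degenerate at every geometry (collinear layouts failed this way:
  near-degenerate states mix strongly over a ±0.1 Bohr window and no
  finite-difference route is then well conditioned);
* the exact mirror symmetry about the bond axis gives every exciton a
  parity label conserved under axial displacements, so crossings between
  opposite-parity states are exact — the desk-scale analogue of
  symmetry-protected crossings between states of different angular
  momentum in a linear molecule.  A frozen conduction-orbital shift
  (+0.2 Ry on the odd lowest conduction orbital) places such a crossing
  at bond coordinate ≈ 2.675 Bohr, where the level-crossing experiments
  run: tracked differencing agrees with Hellmann–Feynman to ≲3·10⁻³
  Ry/Bohr while energy-ordered differencing errs by up to ≈0.2 Ry/Bohr.

What passing on these fixtures does **not** show: anything about
plane-wave or Gaussian-basis first-principles backends (pseudopotentials,
basis incompleteness, self-consistent screening quality), about systems
with dense spectra where greedy tracking can misassign, or about
spin-unrestricted or open-shell references, all of which are outside this
model's reach by construction.

## Problem sizes

All experiments run on 2–7 basis functions; the validation scan is 15
force evaluations (5 bond lengths × 3 states), each involving two
self-consistent fields, two screening builds, two projections, and — for
the comparator route — two dense excited-state solves.  The whole test
suite plus the acceptance experiment completes in well under a minute on
one CPU core; these sizes were chosen because every claim here is about
exactness of dual routes, which small dense references certify best.

## Known limitations

* The Hellmann–Feynman estimator evaluates per-branch derivatives; at an
  *avoided* crossing with gap comparable to (slope difference)·Δλ, both
  it and any finite-difference route describe a mixture — only
  symmetry-exact crossings are fully clean, as the crossing fixture
  demonstrates.
* Greedy (non-optimal) assignment in tracking can in principle cascade
  misassignments in dense spectra; the ambiguity flag (overlap < 0.5) is
  the guardrail.
* Quasiparticle shifts and the scissor are frozen during displacement;
  a geometry-dependent self-energy correction would add a term the model
  cannot estimate.
* ∂E0/∂λ is a finite difference, not an analytic mean-field gradient;
  this is deliberate (matched error orders) but makes machine-precision
  force zeros unattainable.
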