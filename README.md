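# tdaforce

Atomic forces on molecules in **excited states**, computed from a
Tamm–Dancoff excitonic Hamiltonian by a finite-difference
Hellmann–Feynman scheme with determinant-based manifold projectors, plus
overlap-tracked level-crossing bookkeeping and excited-state geometry
relaxation.

## The problem and the method

Optical excitation energies Ω_S come from diagonalizing an excitonic
(electron–hole) Hamiltonian built on a mean-field reference,

    H_exc = D + K_x + K_d,        H_exc |Ψ_S⟩ = Ω_S |Ψ_S⟩,

with a diagonal term D = H_mf − ε_v + Δ (scissor Δ and optional
per-orbital quasiparticle shifts open the mean-field gap), an exchange
kernel K_x built from the bare Coulomb interaction v, and a direct kernel
K_d built from the statically screened interaction W.  The total energy
of the S-th excited state is E_S = E0 + Ω_S, and the force on atom
coordinate λ is −∂E_S/∂λ.

Differentiating Ω_S by brute force means one full excited-state solve per
displaced geometry — 6N of them — and through level crossings the "same"
state must be re-identified at every displacement.  Instead, this package
evaluates the Hellmann–Feynman expectation of a *finite-difference
operator derivative*:

    ∂Ω_S/∂λ ≈ [⟨Ψ_S|P†(+Δλ) H_exc(+Δλ) P(+Δλ)|Ψ_S⟩
             − ⟨Ψ_S|P†(−Δλ) H_exc(−Δλ) P(−Δλ)|Ψ_S⟩] / 2Δλ.

Because a Tamm–Dancoff state built on the orbitals of one geometry does
not live in the Tamm–Dancoff manifold of a displaced geometry, the
eigenstate is first carried there by the projector P(λ), evaluated as
determinants of mixed orbital-overlap matrices — either by explicit
enumeration of displaced conduction orbitals, or in a conduction-sum-free
*batch* form obtained by cofactor expansion.  The batch representation
(one conduction-subspace vector ξ_v per valence orbital, encoding all
amplitudes A_{v,c} = ⟨φ_c|ξ_v⟩) is used throughout, so no sum over empty
orbitals ever appears in the Hamiltonian application or in the projector.

The mean-field layer is a self-contained Pariser–Parr–Pople-style
π-electron model (geometry-dependent hoppings, Ohno repulsion, restricted
closed-shell self-consistent field), so every equation is testable at
desk scale.  Units are Rydberg and Bohr throughout.

## Worked example

Generate the standard two-center test molecule, compute its spectrum, and
compare the two force routes for the lowest exciton:

```sh
tdaforce fixture --kind diatomic --n-sites 4 -o dia
tdaforce spectrum dia.xyz -c dia.toml -o spectrum.json
tdaforce forces dia.xyz -c dia.toml -s 1 --compare-fd -o forces
```

The spectrum run prints (and `spectrum.json` records):

```
INFO tdaforce: spectrum: E0 = -0.65736737 Ry, lowest Omega = 0.49211565 Ry
```

i.e. a ground-state energy of −0.657 Ry and a first singlet excitation of
0.492 Ry, so E_1 = E0 + Ω_1 = −0.165 Ry.  The force comparison prints

```
INFO tdaforce: forces: max |F_hf - F_fd| = 3.204e-03 Ry/Bohr
```

— over all 3N coordinates, the projector-based Hellmann–Feynman forces
and brute-force central differences of E0 + Ω agree to about
3·10⁻³ Ry/Bohr at the default
operator step Δλ = 0.1 Bohr, well inside the 0.01 Ry/Bohr validation
band.  `forces.csv` lists per-coordinate F_hf, F_fd and their deviation.

Excited-state relaxation on the third singlet surface:

```sh
tdaforce optimize dia.xyz -c dia.toml -s 3 -o relaxed
```

converges when every force component drops below 10⁻² Ry/Bohr and writes
the relaxed geometry (`relaxed.xyz`) plus a step-by-step trace with
energies, forces, and the overlap used to re-identify the followed state
after each move.  `tdaforce validate` runs the internal dual-route
consistency suite (batch vs dense Hamiltonian, determinant vs cofactor
projector, iterative vs dense eigenvalues, force-route agreement) and
prints a pass/fail table.

## Layout

| module | contents |
|---|---|
| `tdaforce.model` | π-electron model, restricted mean field (orbitals, ε_i, E0) |
| `tdaforce.kernels` | bare Ohno interaction v, static RPA screened W |
| `tdaforce.excitonic` | batch algebra of D, K_x, K_d; dense reference matrix |
| `tdaforce.solver` | dense and block-Davidson eigensolvers, exciton overlaps, state tracking |
| `tdaforce.projector` | determinant / cofactor manifold projectors, ground-state overlap g(λ) |
| `tdaforce.forces` | Hellmann–Feynman and brute-force forces, steepest-descent / BFGS relaxation |
| `tdaforce.fixtures` | synthetic test systems (two-center, chain, ring, random Hamiltonian families) |
| `tdaforce.cli`, `tdaforce.config`, `tdaforce.validate` | command-line surface, TOML configuration, self-checks |

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
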