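# Methods

Modeling choices, numerical parameters, and limitations of the
`nofpair` package.

## Functionals

All three functionals operate on real natural orbitals with occupation
numbers n_p ∈ [0, 1] (spatial convention, 2 Σ n_p = N) and an
electron-pairing partition of the orbital window: pair subspaces with
one strongly occupied reference and N_g weak partners (Σ n = 1 per
subspace), plus singleton subspaces pinned at n = 1/2 for unpaired
electrons.  Integrals used are H_pp (one-electron), J_pq = (pp|qq),
K_pq = (pq|qp), and L_pq = (pq|pq); for real orbitals K = L, which the
code asserts at 1e-10 and exploits.

Shared intrapair term (per subspace, including the q = p diagonal,
whose Π(n_p, n_p) = n_p contribution is required for the exact
Hartree–Fock reduction):

    E_intra = Σ_g [ Σ_{p∈Ω_g} 2 n_p H_pp + Σ_{q,p∈Ω_g} c_q c_p L_pq ]

with c_p = +√n_p for orbitals in the strongly occupied window (the
first N_II/2 orbitals) and −√n_p otherwise.  Singleton subspaces
contribute H_gg only.

Interpair terms (all sums restricted to orbital pairs in different
subspaces):

- PNOF5: E_HF = Σ' n_q n_p (2 J_pq − K_pq).
- GNOF static: −Σ Φ_q Φ_p weights, Φ_p = √(n_p h_p), h_p = 1 − n_p;
  three unit-weight L-blocks where at least one index lies above
  N_Ω = N_II/2 + N_I, two half-weight L-blocks across the
  strong/single-window boundary, and one K-block inside the singles
  window.
- GNOFm static: −Σ' Φ_q Φ_p K_pq over all interpair index pairs — the
  compact form that restores strong–strong couplings.
- GNOF/GNOFm dynamic: Σ'' (c^d_q c^d_p + n^d_q n^d_p) L_pq with
  n^d_p = n_p exp[−(h_g/h_c)²] (h_g the hole of the subspace's strong
  reference; singles have zero dynamic occupancy), the same sign rule
  applied to the damped occupancies, and the double prime excluding
  index pairs that are both inside the strongly occupied window.

### The damping constant h_c

The default is h_c = 0.02·√2 ≈ 0.0283.  With this value the dynamic
occupancy of a weak orbital whose occupancy equals its subspace hole
peaks at (h_c/√2)·e^{−1/2} ≈ 0.0121 — the ≈ 0.012 ceiling used as the
package's quantitative acceptance target.  The frequently quoted
rounded constant 0.022 would give a ceiling of ≈ 0.0094 instead; the
package standardizes on 0.02·√2 precisely because it reproduces the
0.012 ceiling.  `SolverSettings.h_c` and the CLI flag `--h-c` override
the default.

## Occupancy parametrization and gradients

Occupancies are parametrized per subspace by a softmax over
unconstrained real parameters (strong orbital first), so the pairing
sums, the [0, 1] bounds, and the trace hold *by construction* at every
iterate — constraint conservation is structural, not enforced by
penalties.  Initial occupancies put 0.98 on each strong reference with
the remainder spread evenly over its weak partners.

The occupancy gradient is fully analytic: dE/dn is assembled per term
(including the chain rules through the signed amplitudes c_p, through
Φ_p, and through the shared damping factor's dependence on the strong
reference's occupancy) and chained through the softmax Jacobian
diag(n) − n nᵀ per block.  It is verified against central finite
differences at ~1e-9 in the tests.

## Energy evaluation and orbital gradient

All terms are also expressible through coefficient matrices (n, A, B):

    E_elec = 2 Σ_p n_p H_pp + Σ_pq A_pq (pp|qq) + Σ_pq B_pq (pq|pq)

This second evaluation route is tested against the per-term route and
drives the analytic orbital gradient G = 2(Λ − Λᵀ) with
Λ_rs = 2 n_s h_rs + 2 Σ_q A_qs (rs|qq) + 2 Σ_q B_qs (rq|sq),
verified against finite differences of exponentially parametrized
rotations.

## Optimizer

`solve` alternates two stages until the total energy changes by less
than `tol_energy` (default 1e-6 Eh) on two consecutive sweeps, up to
`max_outer` (50) sweeps:

1. Occupancies at fixed orbitals: ADAM (rate 0.05, β₁ 0.9, β₂ 0.999,
   30 steps) on the softmax parameters, followed by an L-BFGS-B polish
   on the same parameters (gtol = tol_gradient/10).
2. Orbitals at fixed occupancies: damped Newton steps on the
   antisymmetric rotation generator X (orbitals updated through
   exp(X)).  The Hessian is built by finite differences of the
   analytic gradient (step 1e-5), symmetrized, with an
   absolute-eigenvalue floor to handle indefiniteness, plus
   backtracking line search and QR re-orthonormalization on drift.

Starting orbitals diagonalize the one-electron Hamiltonian with a
deterministic sign convention (largest-magnitude coefficient positive),
so repeated runs are bitwise identical.  Every sweep re-validates the
pairing constraints at 1e-10 and raises on violation.

`rhf_reference` runs the same machinery with occupancies pinned at 1/0,
where every functional is exactly restricted Hartree–Fock; correlation
energies are reported against this internal reference in millihartree.

## Oracles

Two independent reference implementations live in `oracle.py` and are
used only for testing and diagnostics:

- `fci_ground_energy`: full determinant enumeration in spin orbitals
  with Slater–Condon rules and dense diagonalization, guarded at
  100 000 determinants.
- `rhf_energy`: closed-shell SCF with a core-Hamiltonian guess and
  0.7/0.3 density damping, converged to 1e-12.

## Fixtures

`src/nofpair/data/` carries three small FCIDUMP fixtures (H2/STO-3G at
0.7414 Å, He/6-31G, LiH/STO-3G at 1.5949 Å) in the RHF molecular
orbital basis, with reference RHF and exact-diagonalization energies
recorded in `fixtures.json`.  They were generated once with an
established integral program (see `scripts/make_fixtures.py`); the
tests recompute both reference energies from the FCIDUMP files with
this package's own oracles, so the fixtures are self-validating and no
external backend is needed.

## Synthetic systems

The Hubbard chain builder (`build_hubbard`) is the primary desk-scale
test generator: the two-site half-filled model is exactly solvable
(E = (U − √(U² + 16t²))/2, natural occupancies cos²θ/sin²θ with
tan 2θ = U/(4t)), and longer chains exercise multi-pair schemes.
Hubbard models have diagonal-only two-electron integrals and no
geometry, so they probe the functional and optimizer logic, not
basis-set or integral-handling realism — that is what the molecular
fixtures are for.

## CBS extrapolation

`cbs_extrapolate` supports three laws: E_∞ + bX⁻³ (linear least
squares; modes "all" points or "last2"), E_∞ + b·exp(−γX), and
E_∞ + bX^(−γ) (both via `scipy.optimize.least_squares` with starting
values derived from the last increments and tolerances at 1e-15).
Model-generated series are recovered to ≥ 8 digits and the power3 fit
is exactly affine-equivariant.

## Tolerances (defaults)

| quantity | value |
| --- | --- |
| energy convergence (`tol_energy`) | 1e-6 Eh |
| gradient threshold (`tol_gradient`) | 1e-5 |
| pairing/trace validation | 1e-10 (solver), 1e-8 (reporting) |
| K = L symmetry assertion | 1e-10 |
| rotation orthogonality | 1e-8 |
| SCF oracle convergence | 1e-12 |

## Known limitations

- Closed-shell and high-spin pinned singles only; no general open-shell
  spin coupling.
- The exact solver is brute-force and limited to ~100 000 determinants;
  the package targets desk-scale systems (≲ 10 orbitals) for exact
  comparisons.
- The orbital Hessian is built by finite differences, which is
  O(n_rot²) energy-gradient evaluations per Newton step — fine at desk
  scale, not tuned for large bases.
- No point-group symmetry handling; FCIDUMP orbital symmetry labels are
  read and ignored.
- NOF energies are not variational with respect to the exact ground
  state: GNOFm in particular can overshoot the exact correlation energy
  (e.g. LiH/STO-3G, −23.1 mEh vs the exact −20.4 mEh).
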