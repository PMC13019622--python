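# nofpair

Electron-pairing natural orbital functionals — PNOF5, GNOF, and GNOFm —
with full occupancy and orbital optimization, exact-diagonalization and
mean-field oracles, and complete-basis-set (CBS) extrapolation tools.

## Science

Natural orbital functional (NOF) theory expresses the electronic energy
as a functional of the natural orbitals {φ_p} and their occupation
numbers n_p ∈ [0, 1] (spatial-orbital convention; the 1-RDM trace is
2 Σ_p n_p = N).  The functionals implemented here are built on an
electron-pairing scheme: the orbital window splits into subspaces Ω_g,
each holding one strongly occupied reference orbital and N_g weakly
occupied partners, with the spin-summed occupancy of every subspace
pinned to exactly one electron pair (Σ_{p∈Ω_g} n_p = 1).  Unpaired
electrons occupy singleton subspaces pinned at n = 1/2.

Three functionals share the intrapair energy

    E_intra = Σ_g [ Σ_{p∈Ω_g} 2 n_p H_pp + Σ_{q,p∈Ω_g} c(n_q) c(n_p) L_pq ]

with the signed amplitudes c(n_p) = +√n_p for strong references and
−√n_p for weak partners, and L_pq = ⟨pp|qq⟩ (equal to the exchange
integral K_pq for real orbitals).  They differ in the interpair part:

- **PNOF5** — interpair interaction is pure Hartree–Fock,
  E_inter = Σ'_{pq} n_q n_p (2 J_pq − K_pq).
- **GNOF** — adds a static term built from Φ_p = √(n_p h_p)
  (h_p = 1 − n_p), with full weight when at least one index lies above
  the correlated window and half weight across the strong/single
  boundary, plus a dynamic term built from Gaussian-damped occupancies
  n_p^d = n_p exp[−(h_g/h_c)²], where h_g is the hole of the subspace's
  strong reference.
- **GNOFm** — replaces GNOF's multi-block static term by the compact
  form −Σ'_{pq} Φ_q Φ_p K_pq, which reintroduces the coupling between
  strongly occupied orbitals.

With occupancies pinned at 1/0 all three reduce exactly to restricted
Hartree–Fock; for two-electron systems all three are exact.

The default damping constant is h_c = 0.02·√2, which caps the dynamic
occupancy of a weak orbital at ≈ 0.012 — the package's single
quantitative acceptance target (see below).

## Worked example

Build the half-filled two-site Hubbard model (U = 4, t = 1), get the
exact answer from the brute-force diagnostic solver, then optimize GNOF:

```sh
$ nofpair hubbard --sites 2 -t 1 -u 4 --electrons 2 --out dimer.fcidump
wrote dimer.fcidump

$ nofpair fci dimer.fcidump
E_FCI = -0.828427125 Eh  (4 determinants)

$ nofpair run dimer.fcidump --functional gnof --out dimer_gnof -v
functional     gnof
E_intra        -0.828427124746
E_HF_inter     0
E_sta_inter    -0
E_dyn_inter    0
E_core         0
E_electronic   -0.828427124746
E_total        -0.828427124746

E_HF           -0.000000000
E_total        -0.828427125 hartree
E_corr         -828.427 mEh
converged      True
outer sweeps   3

$ cat dimer_gnof.occ.txt
orbital  occupation
      1  0.853553391631
      2  0.146446608369
```

The optimized energy matches the closed-form exact ground state
(U − √(U² + 16t²))/2 = −0.8284271 Eh, and the occupancies match the
analytic natural occupancies cos²θ, sin²θ with tan 2θ = U/(4t).

The same machinery runs on the packaged molecular fixtures from the
Python API:

```python
from importlib.resources import files
from nofpair import (read_fcidump, build_scheme, SolverSettings,
                     solve, rhf_reference, correlation_energy)

ints = read_fcidump(files("nofpair.data") / "lih_sto3g.fcidump")
scheme = build_scheme(ints.n_electrons, 1, ints.n_basis, "max")
for fid in ("pnof5", "gnof", "gnofm"):
    s = SolverSettings(functional_id=fid)
    res = solve(ints, scheme, s)
    hf = rhf_reference(ints, scheme, s)
    print(fid, f"{res.breakdown.e_total:.9f}",
          f"{correlation_energy(res.breakdown.e_total, hf.breakdown.e_total):.3f} mEh")
```

prints (LiH, STO-3G, E_RHF = −7.862026959 Eh, exact −7.882403410 Eh):

```
pnof5 -7.881716153 -19.689 mEh
gnof  -7.868805878 -6.779 mEh
gnofm -7.885151858 -23.125 mEh
```

CBS extrapolation works on any two-column (cardinal, energy) series:

```sh
$ nofpair extrapolate series.txt --scheme power3 --both-modes
```

## Layout

- `src/nofpair/integrals.py` — FCIDUMP I/O, Hubbard builder, basis
  transformations, J/K/L matrices.
- `src/nofpair/pairing.py` — pairing-scheme construction and validation.
- `src/nofpair/occupancies.py` — softmax occupancy parametrization,
  phases, Φ amplitudes, dynamic occupancies.
- `src/nofpair/functionals.py` — PNOF5/GNOF/GNOFm energy terms,
  coefficient matrices, analytic occupancy gradient.
- `src/nofpair/optimizer.py` — alternating occupancy (ADAM + polish)
  and orbital (damped Newton on the rotation generator) optimization.
- `src/nofpair/oracle.py` — determinant-enumeration exact solver and
  RHF SCF, used as independent references in the tests.
- `src/nofpair/analysis.py` — correlation energies, CBS extrapolation,
  dipole moments, RMS deviations.
- `src/nofpair/cli.py` — the `nofpair` command line (`run`, `hubbard`,
  `extrapolate`, `fci`, `validate`).

See `docs/methods.md` for modeling choices, tolerances, and known
limitations.
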