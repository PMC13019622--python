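"""Brute-force exact solvers used as test references.

* :func:`fci_ground_energy` — full configuration interaction by explicit
  determinant enumeration in the fixed-Sz spin-orbital basis and dense
  diagonalization (bitmask occupation lists, Slater-Condon rules).
* :func:`rhf_energy` — closed-shell restricted Hartree-Fock by repeated
  Fock-matrix diagonalization with DIIS-free damping.

Both favour transparency over speed; a hard guard keeps the determinant
dimension at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import scipy.linalg

from .integrals import IntegralSet

__all__ = ["FCISolution", "fci_ground_energy", "rhf_energy"]

MAX_DETERMINANTS = 100_000


@dataclass
class FCISolution:
    energy: float           # total ground-state energy incl. core constant
    n_determinants: int
    ground_vector_norm: float


def _spin_orbital_integrals(ints: IntegralSet):
    """Spin-orbital h and antisymmetrized <ij||kl> tensors; spin orbital
    2p is alpha-p, 2p+1 is beta-p."""
    nb = ints.n_basis
    nso = 2 * nb
    h_so = np.zeros((nso, nso))
    h_so[0::2, 0::2] = ints.h_one
    h_so[1::2, 1::2] = ints.h_one
    phys = ints.eri_physicist()  # <ij|kl> spatial
    g = np.zeros((nso,) * 4)
    # <IJ|KL> = <ij|kl> delta(sI,sK) delta(sJ,sL)
    for si in (0, 1):
        for sj in (0, 1):
            g[si::2, sj::2, si::2, sj::2] = phys
    g_anti = g - g.transpose(0, 1, 3, 2)
    return h_so, g_anti


def _excitation(det_a: tuple, det_b: tuple):
    """Spin orbitals removed/added going from det_a to det_b."""
    sa, sb = set(det_a), set(det_b)
    return sorted(sa - sb), sorted(sb - sa)


def _single_sign(det: list, h: int, p: int) -> float:
    """Phase of the single excitation h -> p on a sorted determinant:
    (-1) to the number of occupied spin orbitals strictly between them."""
    lo, hi = (h, p) if h < p else (p, h)
    return (-1.0) ** sum(1 for x in det if lo < x < hi)


def _sign(det: tuple, holes: list, parts: list) -> float:
    """Fermionic phase of the excitation holes -> parts applied to det,
    one substitution at a time (sorted holes paired with sorted parts)."""
    det = list(det)
    sign = 1.0
    for h, p in zip(holes, parts):
        sign *= _single_sign(det, h, p)
        det[det.index(h)] = p
        det.sort()
    return sign


def fci_ground_energy(
    ints: IntegralSet, n_electrons: int | None = None, ms2: int | None = None
) -> FCISolution:
    """Exact lowest eigenvalue in the fixed-Sz determinant basis.

    Raises if the determinant count exceeds ``MAX_DETERMINANTS``.
    """
    if n_electrons is None:
        n_electrons = ints.n_electrons
    if ms2 is None:
        ms2 = ints.ms2
    nb = ints.n_basis
    n_alpha = (n_electrons + ms2) // 2
    n_beta = n_electrons - n_alpha
    if n_alpha < 0 or n_beta < 0 or n_alpha > nb or n_beta > nb:
        raise ValueError("invalid electron/spin counts for this basis")
    dim = comb(nb, n_alpha) * comb(nb, n_beta)
    if dim > MAX_DETERMINANTS:
        raise ValueError(f"determinant dimension {dim} exceeds guard")

    h_so, g = _spin_orbital_integrals(ints)
    alpha_orbs = [2 * p for p in range(nb)]
    beta_orbs = [2 * p + 1 for p in range(nb)]
    dets = []
    for occ_a in combinations(alpha_orbs, n_alpha):
        for occ_b in combinations(beta_orbs, n_beta):
            dets.append(tuple(sorted(occ_a + occ_b)))

    n_det = len(dets)
    ham = np.zeros((n_det, n_det))
    for a in range(n_det):
        da = dets[a]
        occ = list(da)
        # diagonal
        e = sum(h_so[p, p] for p in occ)
        e += 0.5 * sum(g[p, q, p, q] for p in occ for q in occ)
        ham[a, a] = e
        for b in range(a + 1, n_det):
            db = dets[b]
            holes, parts = _excitation(da, db)
            if len(holes) == 1:
                (h,), (p,) = holes, parts
                sgn = _sign(da, holes, parts)
                val = h_so[h, p] + sum(g[h, q, p, q] for q in da if q != h)
                ham[a, b] = ham[b, a] = sgn * val
            elif len(holes) == 2:
                (h1, h2), (p1, p2) = holes, parts
                sgn = _sign(da, holes, parts)
                ham[a, b] = ham[b, a] = sgn * g[h1, h2, p1, p2]
    evals, evecs = scipy.linalg.eigh(ham)
    vec = evecs[:, 0]
    return FCISolution(
        energy=float(evals[0] + ints.core_constant),
        n_determinants=n_det,
        ground_vector_norm=float(np.linalg.norm(vec)),
    )


def rhf_energy(
    ints: IntegralSet,
    n_electrons: int | None = None,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> float:
    """Closed-shell SCF energy by repeated Fock diagonalization.

    The orbital basis is orthonormal by construction (the integrals are
    already in an orthogonal basis), so no overlap handling is needed.
    """
    if n_electrons is None:
        n_electrons = ints.n_electrons
    if n_electrons % 2:
        raise ValueError("rhf_energy requires a closed shell")
    nocc = n_electrons // 2
    nb = ints.n_basis
    chem = ints.eri_chemist()
    h = ints.h_one

    # core guess
    _, cmat = scipy.linalg.eigh(h)
    e_old = None
    dm = 2.0 * cmat[:, :nocc] @ cmat[:, :nocc].T
    for it in range(max_iter):
        jmat = np.einsum("pqrs,rs->pq", chem, dm)
        kmat = np.einsum("prqs,rs->pq", chem, dm)
        fock = h + jmat - 0.5 * kmat
        e_elec = 0.5 * float(np.sum(dm * (h + fock)))
        if e_old is not None and abs(e_elec - e_old) < tol:
            return e_elec + ints.core_constant
        e_old = e_elec
        _, cmat = scipy.linalg.eigh(fock)
        dm_new = 2.0 * cmat[:, :nocc] @ cmat[:, :nocc].T
        dm = 0.7 * dm_new + 0.3 * dm  # damping for stubborn cases
    raise RuntimeError("SCF did not converge")
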