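"""Spin-free Hamiltonian integrals: FCIDUMP I/O, model generators, basis
transformations, and the Coulomb/exchange/exchange-time-inversion matrices
(J, K, L) that pairing functionals consume.

Conventions
-----------
Two-electron integrals are stored internally in *chemist* notation,
``(ij|kl) = ∫∫ φ_i(1)φ_j(1) r_12^{-1} φ_k(2)φ_l(2)``, which is the FCIDUMP
native layout.  Physicist brackets relate to it by ``<ij|kl> = (ik|jl)``;
the conversion happens only at the :func:`jkl_matrices` boundary.  All
orbitals are real, so the exchange-time-inversion integral
``L_pq = <pp|qq>`` coincides with the exchange integral ``K_pq = <pq|qp>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "IntegralSet",
    "OrbitalRotation",
    "read_fcidump",
    "write_fcidump",
    "build_hubbard",
    "transform_basis",
    "jkl_matrices",
]

_SYM_TOL = 1e-10
_ORTHO_TOL = 1e-8


class FCIDumpError(ValueError):
    """Raised for malformed FCIDUMP headers or out-of-range indices."""


@dataclass
class IntegralSet:
    """Spin-free molecular or lattice-model Hamiltonian data.

    Parameters
    ----------
    n_basis
        Number of spatial orbitals.
    n_electrons
        Total electron count.
    ms2
        Twice the spin projection (``2*Ms``), non-negative.
    core_constant
        Scalar energy offset (nuclear repulsion), hartree.
    h_one
        Symmetric ``(n_basis, n_basis)`` one-electron matrix, hartree.
    eri
        Rank-4 two-electron tensor, hartree, in ``convention`` layout.
    convention
        Either ``"chemist"`` (``(ij|kl)``) or ``"physicist"``
        (``<ij|kl>``).
    dipole_ints
        Optional ``(3, n_basis, n_basis)`` position-operator matrices
        (atomic units) in the same orbital basis.
    nuclear_dipole
        Optional length-3 nuclear dipole vector, atomic units.
    """

    n_basis: int
    n_electrons: int
    ms2: int
    core_constant: float
    h_one: np.ndarray
    eri: np.ndarray
    convention: str = "chemist"
    dipole_ints: np.ndarray | None = None
    nuclear_dipole: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.h_one = np.asarray(self.h_one, dtype=float)
        self.eri = np.asarray(self.eri, dtype=float)
        nb = self.n_basis
        if self.h_one.shape != (nb, nb):
            raise ValueError("h_one shape mismatch")
        if self.eri.shape != (nb, nb, nb, nb):
            raise ValueError("eri shape mismatch")
        if self.convention not in ("chemist", "physicist"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if not np.allclose(self.h_one, self.h_one.T, atol=_SYM_TOL):
            raise ValueError("h_one is not symmetric")
        if self.n_electrons > 2 * nb:
            raise ValueError("more electrons than spin orbitals")
        if self.ms2 < 0:
            raise ValueError("ms2 must be non-negative")

    def copy(self) -> "IntegralSet":
        return replace(
            self,
            h_one=self.h_one.copy(),
            eri=self.eri.copy(),
            dipole_ints=None if self.dipole_ints is None else self.dipole_ints.copy(),
            nuclear_dipole=None
            if self.nuclear_dipole is None
            else np.array(self.nuclear_dipole, dtype=float),
        )

    def eri_physicist(self) -> np.ndarray:
        """Two-electron tensor in physicist notation ``<ij|kl>``."""
        if self.convention == "physicist":
            return self.eri
        # <ij|kl> = (ik|jl)
        return self.eri.transpose(0, 2, 1, 3)

    def eri_chemist(self) -> np.ndarray:
        """Two-electron tensor in chemist notation ``(ij|kl)``."""
        if self.convention == "chemist":
            return self.eri
        return self.eri.transpose(0, 2, 1, 3)


@dataclass
class OrbitalRotation:
    """Real orthogonal map from the stored integral basis to the current
    natural-orbital basis; column ``p`` holds orbital ``p`` in the stored
    basis."""

    coeff: np.ndarray

    def __post_init__(self) -> None:
        self.coeff = np.asarray(self.coeff, dtype=float)
        n = self.coeff.shape[0]
        if self.coeff.shape != (n, n):
            raise ValueError("rotation must be square")
        if not np.allclose(self.coeff.T @ self.coeff, np.eye(n), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthogonal within 1e-8")

    @classmethod
    def identity(cls, n: int) -> "OrbitalRotation":
        return cls(np.eye(n))

    def compose(self, other: "OrbitalRotation") -> "OrbitalRotation":
        """Rotation equivalent to applying ``self`` then ``other``."""
        return OrbitalRotation(self.coeff @ other.coeff)


def symmetrize_eri(eri: np.ndarray) -> np.ndarray:
    """Project a rank-4 tensor onto 8-fold permutational symmetry
    (real-orbital chemist layout)."""
    e = np.asarray(eri, dtype=float)
    e = e + e.transpose(1, 0, 2, 3)
    e = e + e.transpose(0, 1, 3, 2)
    e = e + e.transpose(2, 3, 0, 1)
    return e / 8.0


def read_fcidump(path: str | Path) -> IntegralSet:
    """Parse an FCIDUMP file into an :class:`IntegralSet`.

    Accepts Fortran-namelist headers terminated by ``&END`` or ``/``;
    ``ORBSYM`` and other symmetry keys are read and ignored.  The returned
    set is symmetry-completed (8-fold) and tagged chemist.
    """
    path = Path(path)
    text = path.read_text()
    m = re.search(r"(&END|/|\$END)", text, flags=re.IGNORECASE)
    if m is None:
        raise FCIDumpError(f"{path}: no namelist terminator found")
    header, body = text[: m.start()], text[m.end() :]

    def _header_int(key: str) -> int:
        hm = re.search(rf"\b{key}\s*=\s*(-?\d+)", header, flags=re.IGNORECASE)
        if hm is None:
            raise FCIDumpError(f"{path}: header missing {key}")
        return int(hm.group(1))

    norb = _header_int("NORB")
    nelec = _header_int("NELEC")
    ms2_m = re.search(r"\bMS2\s*=\s*(-?\d+)", header, flags=re.IGNORECASE)
    ms2 = int(ms2_m.group(1)) if ms2_m else 0

    h_one = np.zeros((norb, norb))
    eri = np.zeros((norb, norb, norb, norb))
    core = 0.0
    for line in body.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FCIDumpError(f"{path}: malformed record {line!r}")
        val = float(parts[0].replace("D", "E").replace("d", "e"))
        i, j, k, l = (int(x) for x in parts[1:])
        for idx in (i, j, k, l):
            if idx < 0 or idx > norb:
                raise FCIDumpError(f"{path}: orbital index {idx} out of range")
        if i == j == k == l == 0:
            core = val
        elif k == l == 0:
            h_one[i - 1, j - 1] = val
            h_one[j - 1, i - 1] = val
        elif k != 0 and l != 0 and i != 0 and j != 0:
            a, b, c, d = i - 1, j - 1, k - 1, l - 1
            for p, q, r, s in (
                (a, b, c, d), (b, a, c, d), (a, b, d, c), (b, a, d, c),
                (c, d, a, b), (d, c, a, b), (c, d, b, a), (d, c, b, a),
            ):
                eri[p, q, r, s] = val
        else:
            raise FCIDumpError(f"{path}: inconsistent zero indices in {line!r}")

    return IntegralSet(
        n_basis=norb,
        n_electrons=nelec,
        ms2=ms2,
        core_constant=core,
        h_one=h_one,
        eri=eri,
        convention="chemist",
    )


def write_fcidump(ints: IntegralSet, path: str | Path, threshold: float = 1e-12) -> Path:
    """Write ``ints`` to a standard FCIDUMP file (chemist convention,
    symmetry-unique records only, magnitudes above ``threshold``)."""
    path = Path(path)
    nb = ints.n_basis
    eri = ints.eri_chemist()
    lines = [
        f"&FCI NORB={nb},NELEC={ints.n_electrons},MS2={ints.ms2},",
        " ORBSYM=" + ",".join(["1"] * nb) + ",",
        " ISYM=1,",
        "&END",
    ]
    # unique (ij|kl): i>=j, k>=l, (i,j) >= (k,l) lexicographically
    for i in range(nb):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    v = eri[i, j, k, l]
                    if abs(v) > threshold:
                        lines.append(
                            f"{v:23.16E} {i + 1:4d} {j + 1:4d} {k + 1:4d} {l + 1:4d}"
                        )
    for i in range(nb):
        for j in range(i + 1):
            v = ints.h_one[i, j]
            if abs(v) > threshold:
                lines.append(f"{v:23.16E} {i + 1:4d} {j + 1:4d} {0:4d} {0:4d}")
    lines.append(f"{ints.core_constant:23.16E} {0:4d} {0:4d} {0:4d} {0:4d}")
    path.write_text("\n".join(lines) + "\n")
    return path


def build_hubbard(
    n_sites: int,
    t: float,
    u: float,
    n_electrons: int,
    periodic: bool = False,
) -> IntegralSet:
    """Hubbard-chain Hamiltonian in the site basis.

    ``h_one`` carries ``-t`` on nearest-neighbour bonds (with the wrap
    bond iff ``periodic``); the only nonzero two-electron elements are the
    on-site repulsions ``(ii|ii) = u``; the core constant is zero.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if n_electrons > 2 * n_sites:
        raise ValueError("more electrons than spin orbitals")
    h = np.zeros((n_sites, n_sites))
    for i in range(n_sites - 1):
        h[i, i + 1] = h[i + 1, i] = -t
    if periodic and n_sites > 2:
        h[0, n_sites - 1] = h[n_sites - 1, 0] = -t
    eri = np.zeros((n_sites,) * 4)
    for i in range(n_sites):
        eri[i, i, i, i] = u
    return IntegralSet(
        n_basis=n_sites,
        n_electrons=n_electrons,
        ms2=n_electrons % 2,
        core_constant=0.0,
        h_one=h,
        eri=eri,
        convention="chemist",
    )


def transform_basis(ints: IntegralSet, rot: OrbitalRotation) -> IntegralSet:
    """Four-index-transform ``ints`` into the basis defined by ``rot``.

    Column ``p`` of ``rot.coeff`` expresses new orbital ``p`` in the
    stored basis; convention and core constant are preserved.
    """
    c = rot.coeff
    if c.shape[0] != ints.n_basis:
        raise ValueError("rotation dimension mismatch")
    h_new = c.T @ ints.h_one @ c
    eri_new = np.einsum("pi,qj,rk,sl,pqrs->ijkl", c, c, c, c, ints.eri, optimize=True)
    dip = None
    if ints.dipole_ints is not None:
        dip = np.einsum("pi,xpq,qj->xij", c, ints.dipole_ints, c)
    return replace(ints, h_one=h_new, eri=eri_new, dipole_ints=dip)


def jkl_matrices(ints: IntegralSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coulomb ``J_pq = <pq|pq>``, exchange ``K_pq = <pq|qp>``, and
    exchange-time-inversion ``L_pq = <pp|qq>`` matrices.

    For real orbitals K equals L; this is asserted to 1e-10.
    """
    chem = ints.eri_chemist()
    j = np.einsum("ppqq->pq", chem)        # <pq|pq> = (pp|qq)
    k = np.einsum("pqqp->pq", chem)        # <pq|qp> = (pq|qp)
    l = np.einsum("pqpq->pq", chem)        # <pp|qq> = (pq|pq)
    if not np.allclose(k, l, atol=_SYM_TOL):
        raise ValueError("K != L: integrals are not real-orbital symmetric")
    return j, k, l
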