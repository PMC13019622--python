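"""Partition of the orbital space into electron-pair subspaces.

The correlated orbital window splits as Ω = Ω_I ⊕ Ω_II.  Ω_II holds
N_II/2 disjoint subspaces, each with one strongly occupied reference
orbital ``g`` and ``N_g`` weakly occupied partners; the spin-summed
occupancy of each such subspace is one pair.  Ω_I holds N_I singleton
subspaces, one per unpaired electron, pinned at occupancy 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PairingScheme", "build_scheme", "validate_occupancies", "MAX_COUPLING"]

MAX_COUPLING = "max"

STRONG, WEAK, SINGLE, INACTIVE = "strong", "weak", "single", "inactive"


@dataclass(frozen=True)
class PairingScheme:
    """Immutable orbital-to-subspace assignment.

    Orbitals are 0-indexed.  Orbitals ``0 .. n_pairs-1`` are the strong
    references, ``n_pairs .. n_subspaces-1`` the singles; weak orbitals
    live above ``n_subspaces``.  ``subspace_of[p] == -1`` marks an orbital
    outside every subspace (possible only with finite coupling).
    """

    n_electrons: int
    n_unpaired: int
    n_basis: int
    coupling: tuple[int, ...]          # N_g per pair subspace
    subspace_of: tuple[int, ...]       # orbital -> subspace index, -1 if none
    role_of: tuple[str, ...]           # orbital -> strong/weak/single/inactive
    ordering: str = "stacked"

    @property
    def n_paired(self) -> int:
        return self.n_electrons - self.n_unpaired

    @property
    def n_pairs(self) -> int:
        return self.n_paired // 2

    @property
    def n_subspaces(self) -> int:
        """N_Ω = N_II/2 + N_I."""
        return self.n_pairs + self.n_unpaired

    def members(self, g: int) -> list[int]:
        """Orbitals belonging to subspace ``g`` (strong/single first)."""
        out = [p for p, s in enumerate(self.subspace_of) if s == g]
        return sorted(out)

    def pair_subspaces(self) -> list[list[int]]:
        return [self.members(g) for g in range(self.n_pairs)]

    def singles(self) -> list[int]:
        return list(range(self.n_pairs, self.n_subspaces))

    def same_subspace_mask(self) -> np.ndarray:
        """Boolean matrix: True where p and q share an assigned subspace
        (diagonal of assigned orbitals included)."""
        s = np.array(self.subspace_of)
        mask = (s[:, None] == s[None, :]) & (s[:, None] >= 0)
        return mask

    def strong_mask(self) -> np.ndarray:
        return np.array([r == STRONG for r in self.role_of])

    def as_table(self) -> str:
        """Plain-text orbital -> subspace table."""
        lines = ["orbital  subspace  role"]
        for p in range(self.n_basis):
            lines.append(f"{p + 1:7d}  {self.subspace_of[p] + 1:8d}  {self.role_of[p]}")
        return "\n".join(lines)


def build_scheme(
    n_electrons: int,
    multiplicity: int,
    n_basis: int,
    coupling: int | str = MAX_COUPLING,
    ordering: str = "stacked",
) -> PairingScheme:
    """Construct the pairing partition.

    Parameters
    ----------
    n_electrons, multiplicity
        Electron count and spin multiplicity 2S+1; ``N_I = multiplicity-1``
        electrons are unpaired, the rest pair up.
    n_basis
        Size of the orbital window being partitioned.
    coupling
        Number of weak partners per pair (``N_g``), or ``"max"`` to deal
        every remaining orbital out as evenly as possible (earlier pairs
        receive the extras).
    ordering
        ``"stacked"``: pair g takes a contiguous weak block counting down
        from the top of the basis (pair 1 couples to the highest
        virtuals).  ``"interleaved"``: weak orbitals are dealt round-robin
        upward from N_Ω.
    """
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    n_unpaired = multiplicity - 1
    n_paired = n_electrons - n_unpaired
    if n_paired < 0 or n_paired % 2:
        raise ValueError(
            f"multiplicity {multiplicity} incompatible with {n_electrons} electrons"
        )
    n_pairs = n_paired // 2
    n_sub = n_pairs + n_unpaired
    if n_basis < n_sub:
        raise ValueError("basis smaller than the number of subspaces")
    if ordering not in ("stacked", "interleaved"):
        raise ValueError(f"unknown ordering {ordering!r}")

    n_weak_avail = n_basis - n_sub
    if coupling == MAX_COUPLING:
        if n_pairs:
            base, extra = divmod(n_weak_avail, n_pairs)
            ng = [base + (1 if g < extra else 0) for g in range(n_pairs)]
        else:
            ng = []
    else:
        c = int(coupling)
        if c < 1:
            raise ValueError("coupling must be >= 1 or 'max'")
        if c * n_pairs > n_weak_avail:
            raise ValueError("not enough virtual orbitals for requested coupling")
        ng = [c] * n_pairs

    subspace_of = [-1] * n_basis
    role_of = [INACTIVE] * n_basis
    for g in range(n_pairs):
        subspace_of[g] = g
        role_of[g] = STRONG
    for i, p in enumerate(range(n_pairs, n_sub)):
        subspace_of[p] = n_pairs + i
        role_of[p] = SINGLE

    if ordering == "stacked":
        # pair 0 (deepest) takes the highest-index block, counting down
        top = n_basis
        for g in range(n_pairs):
            block = list(range(top - ng[g], top))
            for p in block:
                subspace_of[p] = g
                role_of[p] = WEAK
            top -= ng[g]
    else:
        pool = list(range(n_sub, n_basis))
        remaining = list(ng)
        g = 0
        for p in pool:
            # round-robin over pairs that still need partners
            tries = 0
            while remaining and remaining[g % n_pairs] == 0 and tries <= n_pairs:
                g += 1
                tries += 1
            if not n_pairs or all(r == 0 for r in remaining):
                break
            gi = g % n_pairs
            subspace_of[p] = gi
            role_of[p] = WEAK
            remaining[gi] -= 1
            g += 1

    return PairingScheme(
        n_electrons=n_electrons,
        n_unpaired=n_unpaired,
        n_basis=n_basis,
        coupling=tuple(ng),
        subspace_of=tuple(subspace_of),
        role_of=tuple(role_of),
        ordering=ordering,
    )


@dataclass
class OccupancyReport:
    """Per-subspace pairing-sum defects and the 1RDM trace defect."""

    pair_defects: list[float]
    single_defects: list[float]
    trace_defect: float
    tol: float = 1e-8

    @property
    def passed(self) -> bool:
        worst = max(
            [0.0] + [abs(d) for d in self.pair_defects + self.single_defects]
            + [abs(self.trace_defect)]
        )
        return worst < self.tol

    def __str__(self) -> str:
        lines = []
        for g, d in enumerate(self.pair_defects):
            lines.append(f"pair subspace {g + 1}: |sum n - 1| = {abs(d):.3e}")
        for g, d in enumerate(self.single_defects):
            lines.append(f"single {g + 1}: |n - 1/2| = {abs(d):.3e}")
        lines.append(f"trace: |2*sum n - N| = {abs(self.trace_defect):.3e}")
        lines.append("PASS" if self.passed else "FAIL")
        return "\n".join(lines)


def validate_occupancies(
    scheme: PairingScheme, occ: np.ndarray, tol: float = 1e-8
) -> OccupancyReport:
    """Check the pairing sums (each pair subspace holds one pair), the
    singles pinning at 1/2, and the 1RDM trace against the electron count.
    Report-only; never raises on defects."""
    occ = np.asarray(occ, dtype=float)
    if occ.shape != (scheme.n_basis,):
        raise ValueError("occupancy length mismatch")
    if occ.min() < -1e-12 or occ.max() > 1 + 1e-12:
        raise ValueError("occupancies must lie in [0, 1]")
    pair_defects = [
        float(sum(occ[p] for p in members) - 1.0)
        for members in scheme.pair_subspaces()
    ]
    single_defects = [float(occ[p] - 0.5) for p in scheme.singles()]
    trace_defect = float(2.0 * occ.sum() - scheme.n_electrons)
    return OccupancyReport(pair_defects, single_defects, trace_defect, tol)
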