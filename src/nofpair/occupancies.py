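"""Occupation numbers on the pairing-constraint manifold.

Each pair subspace carries one unconstrained parameter per member
orbital; the occupancies of the subspace are the softmax (normalized
exponentials) of that block, so the pairing sum ``Σ_{p∈Ω_g} n_p = 1``
holds exactly for any parameter values.  Singles are pinned at 1/2 and
orbitals outside every subspace at 0.

The module also provides the phase coefficients ``c(n_p) = ±√n_p`` (plus
for strong references, minus otherwise), the occupancy-hole amplitudes
``Φ_p = √(n_p h_p)``, and the Gaussian-damped dynamic occupancies
``n_p^d = n_p exp(-(h_g/h_c)^2)`` that isolate the dynamic-correlation
channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairing import PairingScheme, SINGLE, STRONG

__all__ = [
    "DEFAULT_HC",
    "OccupancyState",
    "params_to_occupancies",
    "phase_coefficients",
    "dynamic_occupancies",
    "occupancy_jacobian",
    "initial_params",
]

# Hole scale of the dynamic-occupancy damping.  The value 0.02*sqrt(2)
# makes the maximum attainable dynamic occupancy (h_c/sqrt(2))*exp(-1/2)
# ≈ 0.0121, consistent with Pulay's 0.01-deviation criterion for a
# natural orbital to contribute dynamic correlation.
DEFAULT_HC = 0.02 * np.sqrt(2.0)


@dataclass
class OccupancyState:
    """Occupancies and every derived occupancy quantity the functionals
    need, together with the unconstrained parameters that generated them."""

    occ: np.ndarray       # n_p
    holes: np.ndarray     # h_p = 1 - n_p
    phases: np.ndarray    # c(n_p), signed sqrt
    phi: np.ndarray       # sqrt(n_p h_p)
    dyn_occ: np.ndarray   # n_p^d
    params: np.ndarray
    h_c: float = DEFAULT_HC


def params_to_occupancies(
    scheme: PairingScheme, params: np.ndarray, h_c: float = DEFAULT_HC
) -> OccupancyState:
    """Map unconstrained parameters to a full :class:`OccupancyState`.

    ``params`` concatenates one block per pair subspace, in subspace
    order, each block holding one entry per member orbital (strong
    reference first, then weak partners in ascending orbital index).
    Within a block the occupancies are ``softmax(block)``; the map is
    smooth, shift-invariant per block, and surjective onto the open
    feasible set.
    """
    params = np.asarray(params, dtype=float)
    sizes = [1 + ng for ng in scheme.coupling]
    if params.size != sum(sizes):
        raise ValueError(
            f"expected {sum(sizes)} parameters, got {params.size}"
        )
    occ = np.zeros(scheme.n_basis)
    pos = 0
    for g, members in enumerate(scheme.pair_subspaces()):
        block = params[pos : pos + sizes[g]]
        pos += sizes[g]
        z = np.exp(block - block.max())
        occ[members] = z / z.sum()
    for p in scheme.singles():
        occ[p] = 0.5
    return occupancy_state_from_occ(scheme, occ, params=params, h_c=h_c)


def occupancy_state_from_occ(
    scheme: PairingScheme,
    occ: np.ndarray,
    params: np.ndarray | None = None,
    h_c: float = DEFAULT_HC,
) -> OccupancyState:
    """Build the derived quantities from an explicit occupancy vector
    (used for pinned and hand-set occupancies)."""
    occ = np.asarray(occ, dtype=float)
    holes = 1.0 - occ
    phases = phase_coefficients(scheme, occ)
    phi = np.sqrt(np.clip(occ * holes, 0.0, None))
    dyn = dynamic_occupancies(scheme, occ, h_c)
    if params is None:
        params = np.zeros(0)
    return OccupancyState(
        occ=occ, holes=holes, phases=phases, phi=phi, dyn_occ=dyn,
        params=np.asarray(params, dtype=float), h_c=h_c,
    )


def phase_coefficients(scheme: PairingScheme, occ: np.ndarray) -> np.ndarray:
    """Signed square roots ``c(n_p)``: ``+√n_p`` for the strongly occupied
    reference orbitals (p ≤ N_II/2), ``-√n_p`` for every other orbital."""
    occ = np.asarray(occ, dtype=float)
    if occ.min() < 0:
        raise ValueError("negative occupancy")
    root = np.sqrt(occ)
    sign = np.where(scheme.strong_mask(), 1.0, -1.0)
    return sign * root


def dynamic_occupancies(
    scheme: PairingScheme, occ: np.ndarray, h_c: float = DEFAULT_HC
) -> np.ndarray:
    """Gaussian-damped occupancies ``n_p^d = n_p exp(-(h_g/h_c)^2)``.

    ``h_g = 1 - n_g`` is the hole of the subspace's strong reference; the
    damping is shared by every orbital of that subspace.  Singles carry no
    dynamic occupancy (their 1/2 is pinned), nor do orbitals outside every
    subspace.
    """
    if h_c <= 0:
        raise ValueError("h_c must be positive")
    occ = np.asarray(occ, dtype=float)
    dyn = np.zeros_like(occ)
    for g, members in enumerate(scheme.pair_subspaces()):
        h_g = 1.0 - occ[members[0]] if members else 0.0
        # members[0] is the strong reference (lowest index in subspace)
        damp = np.exp(-((h_g / h_c) ** 2))
        for p in members:
            dyn[p] = occ[p] * damp
    return dyn


def occupancy_jacobian(scheme: PairingScheme, state: OccupancyState) -> np.ndarray:
    """Jacobian ``d n_p / d param_j`` of the softmax parametrization,
    shape ``(n_basis, n_params)``; rows of singles and inactive orbitals
    are zero."""
    jac = np.zeros((scheme.n_basis, state.params.size))
    pos = 0
    for g, members in enumerate(scheme.pair_subspaces()):
        k = len(members)
        n_blk = state.occ[members]
        block_jac = np.diag(n_blk) - np.outer(n_blk, n_blk)
        for a, p in enumerate(members):
            jac[p, pos : pos + k] = block_jac[a]
        pos += k
    return jac


def initial_params(scheme: PairingScheme, delta: float = 0.02) -> np.ndarray:
    """Seeded start near the Hartree-Fock solution: each strong reference
    at occupancy ``1 - delta`` with ``delta`` spread evenly over its weak
    partners.  Pinned starts (delta=0) are stationary traps, so delta is
    kept strictly positive."""
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    blocks = []
    for ng in scheme.coupling:
        if ng == 0:
            blocks.append(np.zeros(1))
            continue
        strong = np.log((1.0 - delta) * ng / delta)
        blocks.append(np.concatenate([[strong], np.zeros(ng)]))
    if not blocks:
        return np.zeros(0)
    return np.concatenate(blocks)


def pinned_occupancies(scheme: PairingScheme) -> np.ndarray:
    """Occupancy vector of the Hartree-Fock limit: strong references at 1,
    singles at 1/2, everything else at 0."""
    occ = np.zeros(scheme.n_basis)
    for p, role in enumerate(scheme.role_of):
        if role == STRONG:
            occ[p] = 1.0
        elif role == SINGLE:
            occ[p] = 0.5
    return occ
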