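"""Energy expressions of the electron-pairing natural orbital functionals.

Three functionals share the same building blocks:

* **PNOF5** — independent electron pairs:
  ``E = E_intra + E_HF^inter``.
* **GNOF** — adds intersubspace static and dynamic correlation:
  ``E = E_intra + E_HF^inter + E_sta^inter + E_dyn^inter`` with the
  static term assembled from five index blocks of ``Φ_q Φ_p`` couplings.
* **GNOFm** — same as GNOF but with the compact static term
  ``E_sta^inter = -Σ' Φ_q Φ_p K_pq`` over *all* intersubspace pairs,
  which reintroduces the couplings between strongly occupied orbitals
  that GNOF omits.

All double sums run over ordered orbital pairs exactly as written; a
prime excludes pairs sharing a subspace, and the dynamic term's double
prime additionally excludes pairs with both orbitals in the strongly
occupied window.

Internally every term is also expressible through symmetric coefficient
matrices ``A`` (on Coulomb integrals ``(pp|qq)``) and ``B`` (on exchange
integrals ``(pq|pq)``), so the electronic energy reads
``E = 2 Σ_p n_p H_pp + Σ_pq A_pq (pp|qq) + Σ_pq B_pq (pq|pq)``; the
orbital-rotation gradient in :mod:`nofpair.optimizer` is built from the
same matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import IntegralSet, jkl_matrices
from .occupancies import OccupancyState, occupancy_jacobian
from .pairing import PairingScheme

__all__ = [
    "FUNCTIONALS",
    "EnergyBreakdown",
    "energy_intra",
    "energy_hf_inter",
    "energy_static_gnof",
    "energy_static_gnofm",
    "energy_dynamic",
    "total_energy",
    "occupation_gradient",
    "coefficient_matrices",
]

FUNCTIONALS = ("pnof5", "gnof", "gnofm")


@dataclass
class EnergyBreakdown:
    """Term-by-term energy decomposition, hartree."""

    functional_id: str
    e_intra: float
    e_hf_inter: float
    e_sta_inter: float
    e_dyn_inter: float
    e_core: float

    @property
    def e_electronic(self) -> float:
        return self.e_intra + self.e_hf_inter + self.e_sta_inter + self.e_dyn_inter

    @property
    def e_total(self) -> float:
        return self.e_electronic + self.e_core

    def report(self) -> str:
        fields = [
            ("functional", self.functional_id),
            ("E_intra", self.e_intra),
            ("E_HF_inter", self.e_hf_inter),
            ("E_sta_inter", self.e_sta_inter),
            ("E_dyn_inter", self.e_dyn_inter),
            ("E_core", self.e_core),
            ("E_electronic", self.e_electronic),
            ("E_total", self.e_total),
        ]
        lines = []
        for name, v in fields:
            if isinstance(v, str):
                lines.append(f"{name:14s} {v}")
            else:
                lines.append(f"{name:14s} {v:.12g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# masks


def _inter_mask(scheme: PairingScheme) -> np.ndarray:
    """True where p and q do NOT share an assigned subspace (the prime)."""
    return ~scheme.same_subspace_mask()


def _window_masks(scheme: PairingScheme):
    nb = scheme.n_basis
    f = scheme.n_pairs            # N_II/2
    nw = scheme.n_subspaces       # N_Omega
    idx = np.arange(nb)
    below_f = idx < f                       # strongly occupied window
    singles_win = (idx >= f) & (idx < nw)   # (N_II/2, N_Omega]
    above_nw = idx >= nw                    # weak window
    return below_f, singles_win, above_nw


# ---------------------------------------------------------------------------
# energy terms


def energy_intra(
    ints: IntegralSet, scheme: PairingScheme, occ_state: OccupancyState
) -> float:
    """Intrapair energy: for each pair subspace
    ``E_g = 2 Σ_p n_p H_pp + Σ_{q,p∈Ω_g} Π(n_q,n_p) L_pq`` (the q=p
    diagonal contributes ``n_p L_pp``), plus one ``H_gg`` per single
    (n=1/2, one electron)."""
    h = ints.h_one
    _, _, l = jkl_matrices(ints)
    c = occ_state.phases
    n = occ_state.occ
    e = 0.0
    for members in scheme.pair_subspaces():
        m = np.array(members)
        e += 2.0 * float(n[m] @ np.diag(h)[m])
        cm = c[m]
        e += float(cm @ l[np.ix_(m, m)] @ cm)
    for p in scheme.singles():
        e += h[p, p]
    return e


def energy_hf_inter(
    ints: IntegralSet, scheme: PairingScheme, occ_state: OccupancyState
) -> float:
    """Intersubspace mean-field term ``Σ' n_q n_p (2J_pq - K_pq)`` over
    ordered orbital pairs in different subspaces."""
    j, k, _ = jkl_matrices(ints)
    n = occ_state.occ
    w = np.outer(n, n) * (2.0 * j - k)
    return float(w[_inter_mask(scheme)].sum())


def _static_weight_gnof(scheme: PairingScheme) -> tuple[np.ndarray, np.ndarray]:
    """Block weights of the GNOF static term: (W_L, W_K) such that
    ``E_sta = -Σ_pq [W_L ΦΦᵀ]_pq L_pq - Σ_pq [W_K ΦΦᵀ]_pq K_pq``."""
    below_f, singles_win, above_nw = _window_masks(scheme)
    inter = _inter_mask(scheme)
    in_nw = ~above_nw  # orbitals 1..N_Omega
    wl = np.zeros((scheme.n_basis,) * 2)
    # blocks 1-3: at least one index above N_Omega
    wl += np.outer(in_nw, above_nw) + np.outer(above_nw, in_nw)
    wl += np.outer(above_nw, above_nw)
    # block 4 (weight 1/2): strong window against singles window, both ways
    wl += 0.5 * (np.outer(below_f, singles_win) + np.outer(singles_win, below_f))
    # block 5 (K): both inside the singles window
    wk = np.outer(singles_win, singles_win).astype(float)
    return wl * inter, wk * inter


def energy_static_gnof(
    ints: IntegralSet, scheme: PairingScheme, occ_state: OccupancyState
) -> float:
    """GNOF static intersubspace correlation: five ``Φ_q Φ_p`` index
    blocks (three on L split at N_Ω, a half-weighted pair split at
    N_II/2, and a K block inside the singles window), all with negative
    sign and intersubspace pairs only."""
    _, k, l = jkl_matrices(ints)
    wl, wk = _static_weight_gnof(scheme)
    pp = np.outer(occ_state.phi, occ_state.phi)
    return float(-(wl * pp * l).sum() - (wk * pp * k).sum())


def energy_static_gnofm(
    ints: IntegralSet, scheme: PairingScheme, occ_state: OccupancyState
) -> float:
    """GNOFm static term ``-Σ' Φ_q Φ_p K_pq`` over every intersubspace
    ordered pair (strong-strong couplings included)."""
    _, k, _ = jkl_matrices(ints)
    pp = np.outer(occ_state.phi, occ_state.phi)
    return float(-(pp * k)[_inter_mask(scheme)].sum())


def _dynamic_mask(scheme: PairingScheme) -> np.ndarray:
    """Double-prime mask: intersubspace pairs excluding those with BOTH
    orbitals in the strongly occupied window (p,q ≤ N_II/2)."""
    below_f, _, _ = _window_masks(scheme)
    return _inter_mask(scheme) & ~np.outer(below_f, below_f)


def _dynamic_phases(scheme: PairingScheme, dyn: np.ndarray) -> np.ndarray:
    sign = np.where(scheme.strong_mask(), 1.0, -1.0)
    return sign * np.sqrt(np.clip(dyn, 0.0, None))


def energy_dynamic(
    ints: IntegralSet, scheme: PairingScheme, occ_state: OccupancyState
) -> float:
    """Dynamic intersubspace correlation
    ``Σ'' [Π(n_q^d, n_p^d) + n_q^d n_p^d] L_pq`` with Π built from the
    damped occupancies under the same sign rule as the static Π."""
    _, _, l = jkl_matrices(ints)
    nd = occ_state.dyn_occ
    cd = _dynamic_phases(scheme, nd)
    w = np.outer(cd, cd) + np.outer(nd, nd)
    return float((w * l)[_dynamic_mask(scheme)].sum())


def total_energy(
    ints: IntegralSet,
    scheme: PairingScheme,
    occ_state: OccupancyState,
    functional_id: str,
) -> EnergyBreakdown:
    """Assemble the per-functional breakdown; ``e_total`` includes the
    core constant."""
    if functional_id not in FUNCTIONALS:
        raise ValueError(f"unknown functional {functional_id!r}")
    e_intra = energy_intra(ints, scheme, occ_state)
    e_hf = energy_hf_inter(ints, scheme, occ_state)
    e_sta = 0.0
    e_dyn = 0.0
    if functional_id == "gnof":
        e_sta = energy_static_gnof(ints, scheme, occ_state)
        e_dyn = energy_dynamic(ints, scheme, occ_state)
    elif functional_id == "gnofm":
        e_sta = energy_static_gnofm(ints, scheme, occ_state)
        e_dyn = energy_dynamic(ints, scheme, occ_state)
    return EnergyBreakdown(
        functional_id=functional_id,
        e_intra=e_intra,
        e_hf_inter=e_hf,
        e_sta_inter=e_sta,
        e_dyn_inter=e_dyn,
        e_core=ints.core_constant,
    )


# ---------------------------------------------------------------------------
# coefficient matrices (shared with the orbital gradient)


def coefficient_matrices(
    scheme: PairingScheme, occ_state: OccupancyState, functional_id: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(n, A, B)`` with the electronic energy equal to
    ``2 Σ_p n_p H_pp + Σ_pq A_pq (pp|qq) + Σ_pq B_pq (pq|pq)``.

    ``n`` includes the pinned 1/2 of singles, so their one-electron
    ``H_gg`` is carried by the ``2 n H`` term.  ``A`` collects Coulomb
    couplings, ``B`` exchange/exchange-time-inversion couplings (K = L
    for real orbitals); both are symmetric.
    """
    if functional_id not in FUNCTIONALS:
        raise ValueError(f"unknown functional {functional_id!r}")
    nb = scheme.n_basis
    n = occ_state.occ
    inter = _inter_mask(scheme)
    a = 2.0 * np.outer(n, n) * inter
    b = -np.outer(n, n) * inter
    # intrapair Pi couplings (diagonal included)
    c = occ_state.phases
    same_pair = np.zeros((nb, nb), dtype=bool)
    for members in scheme.pair_subspaces():
        same_pair[np.ix_(members, members)] = True
    b = b + np.outer(c, c) * same_pair
    if functional_id in ("gnof", "gnofm"):
        pp = np.outer(occ_state.phi, occ_state.phi)
        if functional_id == "gnof":
            wl, wk = _static_weight_gnof(scheme)
            b = b - (wl + wk) * pp
        else:
            b = b - pp * inter
        nd = occ_state.dyn_occ
        cd = _dynamic_phases(scheme, nd)
        b = b + (np.outer(cd, cd) + np.outer(nd, nd)) * _dynamic_mask(scheme)
    return n, a, b


# ---------------------------------------------------------------------------
# occupation-number gradient


def _denergy_doccupancy(
    ints: IntegralSet,
    scheme: PairingScheme,
    occ_state: OccupancyState,
    functional_id: str,
) -> np.ndarray:
    """Analytic ``dE_electronic / dn_p`` for orbitals inside pair
    subspaces (entries elsewhere are irrelevant and left at zero).

    Requires strictly interior occupancies (0 < n < 1) for the signed
    square roots; the softmax parametrization guarantees this.
    """
    h = ints.h_one
    j, k, l = jkl_matrices(ints)
    n = occ_state.occ
    nb = scheme.n_basis
    grad = np.zeros(nb)
    strong = scheme.strong_mask()
    sign = np.where(strong, 1.0, -1.0)

    pair_orbs = [p for members in scheme.pair_subspaces() for p in members]
    pair_orbs = np.array(sorted(pair_orbs), dtype=int)
    if pair_orbs.size == 0:
        return grad

    # intrapair: 2 H_pp + 2 c'_p sum_{q in same pair} c_q L_pq
    c = occ_state.phases
    with np.errstate(divide="ignore"):
        cprime = sign / (2.0 * np.sqrt(n, where=n > 0, out=np.full(nb, np.inf)))
    for members in scheme.pair_subspaces():
        m = np.array(members)
        lv = l[np.ix_(m, m)] @ c[m]
        grad[m] += 2.0 * np.diag(h)[m] + 2.0 * cprime[m] * lv

    # intersubspace HF: 2 sum_{q not in subspace(p)} n_q (2J - K)
    inter = _inter_mask(scheme)
    grad[pair_orbs] += 2.0 * ((2.0 * j - k) * inter @ n)[pair_orbs]

    if functional_id in ("gnof", "gnofm"):
        phi = occ_state.phi
        with np.errstate(divide="ignore", invalid="ignore"):
            phiprime = np.where(phi > 0, (1.0 - 2.0 * n) / (2.0 * phi), 0.0)
        if functional_id == "gnof":
            wl, wk = _static_weight_gnof(scheme)
            coupling = wl * l + wk * k
        else:
            coupling = inter * k
        grad[pair_orbs] += (-2.0 * phiprime * (coupling @ phi))[pair_orbs]

        # dynamic term, via d/d n^d then the damping chain rule
        nd = occ_state.dyn_occ
        cd = _dynamic_phases(scheme, nd)
        with np.errstate(divide="ignore"):
            cdprime = np.where(
                nd > 0, sign / (2.0 * np.sqrt(np.clip(nd, 1e-300, None))), 0.0
            )
        mask = _dynamic_mask(scheme)
        ml = mask * l
        de_dnd = 2.0 * (cdprime * (ml @ cd) + (ml @ nd))
        h_c = occ_state.h_c
        for members in scheme.pair_subspaces():
            m = np.array(members)
            g_orb = members[0]
            h_g = 1.0 - n[g_orb]
            damp = np.exp(-((h_g / h_c) ** 2))
            grad[m] += de_dnd[m] * damp
            # dependence of the shared damping factor on the reference ON
            ddamp_dng = damp * 2.0 * h_g / h_c**2
            grad[g_orb] += float(de_dnd[m] @ (n[m] * ddamp_dng))
    return grad


def occupation_gradient(
    ints: IntegralSet,
    scheme: PairingScheme,
    occ_state: OccupancyState,
    functional_id: str,
) -> np.ndarray:
    """Gradient of the total energy with respect to the unconstrained
    softmax parameters (chain rule through the occupancy Jacobian)."""
    de_dn = _denergy_doccupancy(ints, scheme, occ_state, functional_id)
    jac = occupancy_jacobian(scheme, occ_state)
    return de_dn @ jac
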