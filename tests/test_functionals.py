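"""Functional energy terms against literal index-by-index transcriptions.

The reference implementations below spell out every double sum with
explicit Python loops and 1-based window logic, independently of the
vectorized production code.
"""

import numpy as np
import pytest

from nofpair.functionals import (
    coefficient_matrices,
    energy_dynamic,
    energy_hf_inter,
    energy_intra,
    energy_static_gnof,
    energy_static_gnofm,
    occupation_gradient,
    total_energy,
)
from nofpair.integrals import jkl_matrices, transform_basis, OrbitalRotation
from nofpair.occupancies import (
    occupancy_state_from_occ,
    params_to_occupancies,
    pinned_occupancies,
)
from nofpair.oracle import rhf_energy
from nofpair.pairing import build_scheme

from conftest import DIMER_E_FCI, dimer_natural_occupancies, random_integral_set


# ---------------------------------------------------------------------------
# literal loop transcriptions (test oracles)


def _c(scheme, occ, p):
    return np.sqrt(occ[p]) if p < scheme.n_pairs else -np.sqrt(occ[p])


def loop_intra(ints, scheme, occ):
    h = ints.h_one
    _, _, l = jkl_matrices(ints)
    e = 0.0
    for members in scheme.pair_subspaces():
        for p in members:
            e += 2.0 * occ[p] * h[p, p]
        for q in members:
            for p in members:
                e += _c(scheme, occ, q) * _c(scheme, occ, p) * l[p, q]
    for g in scheme.singles():
        e += h[g, g]
    return e


def loop_hf_inter(ints, scheme, occ):
    j, k, _ = jkl_matrices(ints)
    nb = scheme.n_basis
    sub = scheme.subspace_of
    e = 0.0
    for p in range(nb):
        for q in range(nb):
            if sub[p] == sub[q] and sub[p] >= 0:
                continue
            if p == q:
                continue
            e += occ[q] * occ[p] * (2.0 * j[p, q] - k[p, q])
    return e


def loop_static_gnof(ints, scheme, occ):
    _, k, l = jkl_matrices(ints)
    phi = np.sqrt(occ * (1.0 - occ))
    f = scheme.n_pairs
    nw = scheme.n_subspaces
    nb = scheme.n_basis
    sub = scheme.subspace_of

    def inter(p, q):
        return not (sub[p] == sub[q] and sub[p] >= 0)

    e = 0.0
    # three blocks split at N_Omega, on L
    for p in range(nw):
        for q in range(nw, nb):
            if inter(p, q):
                e -= phi[q] * phi[p] * l[p, q]
    for p in range(nw, nb):
        for q in range(nw):
            if inter(p, q):
                e -= phi[q] * phi[p] * l[p, q]
    for p in range(nw, nb):
        for q in range(nw, nb):
            if inter(p, q):
                e -= phi[q] * phi[p] * l[p, q]
    # half-weighted pair of blocks split at N_II/2, on L
    for p in range(f):
        for q in range(f, nw):
            if inter(p, q):
                e -= 0.5 * phi[q] * phi[p] * l[p, q]
    for p in range(f, nw):
        for q in range(f):
            if inter(p, q):
                e -= 0.5 * phi[q] * phi[p] * l[p, q]
    # singles-window block on K
    for p in range(f, nw):
        for q in range(f, nw):
            if inter(p, q):
                e -= phi[q] * phi[p] * k[p, q]
    return e


def loop_static_gnofm(ints, scheme, occ):
    _, k, _ = jkl_matrices(ints)
    phi = np.sqrt(occ * (1.0 - occ))
    sub = scheme.subspace_of
    e = 0.0
    for p in range(scheme.n_basis):
        for q in range(scheme.n_basis):
            if sub[p] == sub[q] and sub[p] >= 0:
                continue
            e -= phi[q] * phi[p] * k[p, q]
    return e


def loop_dynamic(ints, scheme, occ, h_c):
    _, _, l = jkl_matrices(ints)
    nb = scheme.n_basis
    sub = scheme.subspace_of
    f = scheme.n_pairs
    nd = np.zeros(nb)
    for members in scheme.pair_subspaces():
        h_g = 1.0 - occ[members[0]]
        for p in members:
            nd[p] = occ[p] * np.exp(-((h_g / h_c) ** 2))
    cd = np.array(
        [np.sqrt(nd[p]) if p < f else -np.sqrt(nd[p]) for p in range(nb)]
    )
    e = 0.0
    for p in range(nb):
        for q in range(nb):
            if sub[p] == sub[q] and sub[p] >= 0:
                continue
            if p < f and q < f:
                continue  # both in the strongly occupied window
            e += (cd[q] * cd[p] + nd[q] * nd[p]) * l[p, q]
    return e


def _random_instance(rng):
    """Random 4-8 orbital instance: integrals, a valid scheme, and a
    feasible fractional occupancy vector."""
    nb = int(rng.integers(4, 9))
    n_pairs = int(rng.integers(1, min(3, nb // 2) + 1))
    n_unpaired = int(rng.integers(0, 2)) if nb > n_pairs + 1 else 0
    n_electrons = 2 * n_pairs + n_unpaired
    ints = random_integral_set(rng, nb, n_electrons)
    scheme = build_scheme(n_electrons, n_unpaired + 1, nb, "max")
    n_params = sum(1 + c for c in scheme.coupling)
    state = params_to_occupancies(scheme, rng.normal(scale=1.0, size=n_params))
    return ints, scheme, state


TERMS = [
    (energy_intra, loop_intra),
    (energy_hf_inter, loop_hf_inter),
    (energy_static_gnof, loop_static_gnof),
    (energy_static_gnofm, loop_static_gnofm),
    (energy_dynamic, loop_dynamic),
]


class TestLoopOracleEquivalence:
    @pytest.mark.parametrize("term,oracle", TERMS, ids=lambda f: f.__name__)
    def test_twenty_random_instances(self, term, oracle):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            ints, scheme, state = _random_instance(rng)
            got = term(ints, scheme, state)
            if oracle is loop_dynamic:
                want = oracle(ints, scheme, state.occ, state.h_c)
            else:
                want = oracle(ints, scheme, state.occ)
            assert got == pytest.approx(want, abs=1e-12)


class TestIntrapair:
    def test_pinned_dimer_is_hartree_fock(self, dimer_mo, dimer_scheme):
        state = occupancy_state_from_occ(dimer_scheme, np.array([1.0, 0.0]))
        e = energy_intra(dimer_mo, dimer_scheme, state)
        assert e == pytest.approx(2.0 * (-1.0) + 2.0, abs=1e-12)

    def test_exact_occupancies_reach_fci(self, dimer_mo, dimer_scheme):
        n1, n2 = dimer_natural_occupancies()
        state = occupancy_state_from_occ(dimer_scheme, np.array([n1, n2]))
        e = energy_intra(dimer_mo, dimer_scheme, state)
        assert e == pytest.approx(DIMER_E_FCI, abs=1e-10)

    def test_one_electron_limit(self):
        rng = np.random.default_rng(1)
        ints = random_integral_set(rng, 4)
        ints.eri[:] = 0.0
        scheme = build_scheme(4, 1, 4, "max")
        state = params_to_occupancies(scheme, rng.normal(size=4))
        e = energy_intra(ints, scheme, state)
        assert e == pytest.approx(
            2.0 * float(state.occ @ np.diag(ints.h_one)), abs=1e-12
        )


class TestInterTerms:
    def test_single_pair_has_no_inter_terms(self, dimer_mo, dimer_scheme):
        state = occupancy_state_from_occ(dimer_scheme, np.array([0.8, 0.2]))
        assert energy_hf_inter(dimer_mo, dimer_scheme, state) == 0.0
        assert energy_static_gnof(dimer_mo, dimer_scheme, state) == 0.0
        assert energy_static_gnofm(dimer_mo, dimer_scheme, state) == 0.0
        assert energy_dynamic(dimer_mo, dimer_scheme, state) == 0.0

    def test_two_singleton_subspaces_hf(self):
        # 4 electrons in 2 orbitals: two pair subspaces with no partners
        rng = np.random.default_rng(9)
        ints = random_integral_set(rng, 2, 4)
        scheme = build_scheme(4, 1, 2, "max")
        state = occupancy_state_from_occ(scheme, np.array([1.0, 1.0]))
        j, k, _ = jkl_matrices(ints)
        e = energy_hf_inter(ints, scheme, state)
        assert e == pytest.approx(2.0 * (2.0 * j[0, 1] - k[0, 1]), abs=1e-12)

    def test_zero_occupancy_terms_vanish(self):
        rng = np.random.default_rng(10)
        ints = random_integral_set(rng, 2, 4)
        scheme = build_scheme(4, 1, 2, "max")
        state = occupancy_state_from_occ(scheme, np.array([1.0, 0.0]))
        j, _, _ = jkl_matrices(ints)
        assert energy_hf_inter(ints, scheme, state) == 0.0

    def test_gnofm_two_singletons_half_occupied(self):
        rng = np.random.default_rng(12)
        ints = random_integral_set(rng, 2, 4)
        scheme = build_scheme(4, 1, 2, "max")
        state = occupancy_state_from_occ(scheme, np.array([0.5, 0.5]))
        _, k, _ = jkl_matrices(ints)
        e = energy_static_gnofm(ints, scheme, state)
        assert e == pytest.approx(-0.5 * k[0, 1], abs=1e-12)

    def test_pinned_static_and_dynamic_vanish(self, scheme4, hubbard4):
        state = occupancy_state_from_occ(scheme4, pinned_occupancies(scheme4))
        assert energy_static_gnof(hubbard4, scheme4, state) == pytest.approx(0.0, abs=1e-14)
        assert energy_static_gnofm(hubbard4, scheme4, state) == pytest.approx(0.0, abs=1e-14)
        assert energy_dynamic(hubbard4, scheme4, state) == pytest.approx(0.0, abs=1e-14)


class TestTotalEnergy:
    def test_dimer_exact_for_every_functional(self, dimer_mo, dimer_scheme):
        n1, n2 = dimer_natural_occupancies()
        state = occupancy_state_from_occ(dimer_scheme, np.array([n1, n2]))
        for fid in ("pnof5", "gnof", "gnofm"):
            bd = total_energy(dimer_mo, dimer_scheme, state, fid)
            assert bd.e_total == pytest.approx(DIMER_E_FCI, abs=1e-10)
            assert bd.e_sta_inter == 0.0 and bd.e_dyn_inter == 0.0

    def test_pnof5_never_has_static_or_dynamic_terms(self):
        rng = np.random.default_rng(21)
        ints, scheme, state = _random_instance(rng)
        bd = total_energy(ints, scheme, state, "pnof5")
        assert bd.e_sta_inter == 0.0 and bd.e_dyn_inter == 0.0

    def test_hf_reduction_on_random_integrals(self):
        # pinned occupancies collapse every functional to restricted HF
        # evaluated in the same (non-self-consistent) orbital basis
        rng = np.random.default_rng(33)
        nb = 5
        ints = random_integral_set(rng, nb, 4)
        scheme = build_scheme(4, 1, nb, "max")
        state = occupancy_state_from_occ(scheme, pinned_occupancies(scheme))
        h = ints.h_one
        j, k, _ = jkl_matrices(ints)
        occ_idx = range(scheme.n_pairs)
        e_hf = sum(2.0 * h[i, i] + j[i, i] for i in occ_idx)
        e_hf += sum(
            2.0 * j[i, m] - k[i, m] if i != m else 0.0
            for i in occ_idx
            for m in occ_idx
        ) * 2.0 / 2.0
        for fid in ("pnof5", "gnof", "gnofm"):
            bd = total_energy(ints, scheme, state, fid)
            assert bd.e_electronic == pytest.approx(e_hf, abs=1e-10)

    def test_unknown_functional_rejected(self, dimer_mo, dimer_scheme):
        state = occupancy_state_from_occ(dimer_scheme, np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            total_energy(dimer_mo, dimer_scheme, state, "pnof9")

    def test_gnof_gnofm_differ_only_in_static_term(self):
        rng = np.random.default_rng(17)
        ints, scheme, state = _random_instance(rng)
        a = total_energy(ints, scheme, state, "gnof")
        b = total_energy(ints, scheme, state, "gnofm")
        assert a.e_intra == b.e_intra
        assert a.e_hf_inter == b.e_hf_inter
        assert a.e_dyn_inter == b.e_dyn_inter

    def test_weak_orbital_relabeling_invariance(self):
        # swapping two weak partners of the same subspace, together with
        # their occupancies, leaves every term unchanged
        rng = np.random.default_rng(41)
        nb = 6
        ints = random_integral_set(rng, nb, 2)
        scheme = build_scheme(2, 1, nb, "max")  # one pair, 5 weak partners
        state = params_to_occupancies(scheme, rng.normal(size=6))
        perm = np.eye(nb)
        p, q = 3, 5  # two weak orbitals of the same subspace
        perm[[p, q]] = perm[[q, p]]
        ints_p = transform_basis(ints, OrbitalRotation(perm))
        occ_p = state.occ.copy()
        occ_p[[p, q]] = occ_p[[q, p]]
        state_p = occupancy_state_from_occ(scheme, occ_p, h_c=state.h_c)
        for fid in ("pnof5", "gnof", "gnofm"):
            a = total_energy(ints, scheme, state, fid)
            b = total_energy(ints_p, scheme, state_p, fid)
            assert a.e_total == pytest.approx(b.e_total, abs=1e-10)

    def test_coefficient_matrix_identity(self):
        # the electronic energy equals the A/B coefficient contraction
        # used by the orbital gradient
        rng = np.random.default_rng(55)
        for _ in range(5):
            ints, scheme, state = _random_instance(rng)
            chem = ints.eri_chemist()
            j_t = np.einsum("ppqq->pq", chem)
            k_t = np.einsum("pqpq->pq", chem)
            for fid in ("pnof5", "gnof", "gnofm"):
                n, a, b = coefficient_matrices(scheme, state, fid)
                e = (
                    2.0 * float(n @ np.diag(ints.h_one))
                    + float((a * j_t).sum())
                    + float((b * k_t).sum())
                )
                bd = total_energy(ints, scheme, state, fid)
                assert e == pytest.approx(bd.e_electronic, abs=1e-10)


class TestOccupationGradient:
    @pytest.mark.parametrize("fid", ["pnof5", "gnof", "gnofm"])
    def test_matches_central_differences(self, fid):
        rng = np.random.default_rng(77)
        ints, scheme, state = _random_instance(rng)
        params = state.params
        g = occupation_gradient(ints, scheme, state, fid)
        eps = 1e-6
        for i in range(params.size):
            pp, pm = params.copy(), params.copy()
            pp[i] += eps
            pm[i] -= eps
            ep = total_energy(ints, scheme, params_to_occupancies(scheme, pp), fid).e_total
            em = total_energy(ints, scheme, params_to_occupancies(scheme, pm), fid).e_total
            fd = (ep - em) / (2 * eps)
            scale = max(1.0, abs(fd))
            assert g[i] == pytest.approx(fd, abs=1e-6 * scale)

    def test_stationary_at_dimer_optimum(self, dimer_mo, dimer_scheme):
        n1, n2 = dimer_natural_occupancies()
        params = np.array([np.log(n1), np.log(n2)])
        state = params_to_occupancies(dimer_scheme, params)
        for fid in ("pnof5", "gnof", "gnofm"):
            g = occupation_gradient(dimer_mo, dimer_scheme, state, fid)
            assert np.linalg.norm(g) < 1e-6

    def test_symmetric_point_gradient_sums_to_zero(self, dimer_mo, dimer_scheme):
        # softmax shift invariance forces the block gradient onto the
        # constraint tangent space
        state = params_to_occupancies(dimer_scheme, np.array([0.4, -0.7]))
        for fid in ("pnof5", "gnof", "gnofm"):
            g = occupation_gradient(dimer_mo, dimer_scheme, state, fid)
            assert g.sum() == pytest.approx(0.0, abs=1e-12)
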