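"""Alternating occupation-number / orbital-rotation minimization.

The total energy is stationary in two coupled variable sets and is
optimized for each in turn, holding the other fixed:

* **Occupancies** live on the pairing-constraint manifold through the
  softmax parametrization; the inner solver takes ADAM momentum steps on
  the unconstrained parameters with the analytic gradient, followed by an
  L-BFGS polish when the momentum loop exits above tolerance.
* **Orbitals** are updated multiplicatively through exponentials of
  skew-symmetric generators, which preserves orthogonality exactly (up
  to roundoff; the accumulated rotation is re-orthonormalized when drift
  exceeds 1e-8).  The energy gradient with respect to a generator
  element X_rs is the antisymmetric part of a generalized Lagrangian
  matrix ``Λ_rs = 2 n_s H_rs + 2 Σ_q A_qs (rs|qq) + 2 Σ_q B_qs (rq|sq)``
  (``G = 2(Λ - Λᵀ)``); inner steps are damped Newton with a
  finite-difference Hessian of that analytic gradient.

The outer loop alternates the two inner solvers until the energy change
stays below tolerance on two consecutive sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.optimize

from .functionals import coefficient_matrices, total_energy, occupation_gradient, EnergyBreakdown
from .integrals import IntegralSet, OrbitalRotation, transform_basis
from .occupancies import (
    DEFAULT_HC,
    OccupancyState,
    initial_params,
    occupancy_state_from_occ,
    params_to_occupancies,
    pinned_occupancies,
)
from .pairing import PairingScheme, validate_occupancies

__all__ = [
    "SolverSettings",
    "SolverResult",
    "optimize_occupancies",
    "optimize_orbitals",
    "orbital_gradient",
    "solve",
    "rhf_reference",
]


@dataclass
class SolverSettings:
    """Tunable knobs of the alternating solver.

    ``tol_energy`` (hartree) controls the outer loop, ``tol_gradient``
    both inner loops.  The ADAM scalars drive the occupancy steps; the
    orbital Newton steps use ``orb_fd_step`` for the finite-difference
    Hessian.  ``seed`` feeds only optional random-perturbation tests;
    the default path is deterministic.
    """

    functional_id: str = "gnof"
    max_outer: int = 50
    tol_energy: float = 1e-6
    tol_gradient: float = 1e-5
    adam_rate: float = 0.05
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    max_occ_steps: int = 30
    max_orb_steps: int = 30
    h_c: float = DEFAULT_HC
    pinned: bool = False
    orb_fd_step: float = 1e-5
    occ_polish: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_energy <= 0 or self.tol_gradient <= 0:
            raise ValueError("tolerances must be positive")
        for r in (self.adam_rate, self.adam_beta1, self.adam_beta2):
            if not 0 < r < 1:
                raise ValueError("ADAM scalars must lie in (0, 1)")


@dataclass
class SolverResult:
    breakdown: EnergyBreakdown
    occ_state: OccupancyState
    rotation: OrbitalRotation
    converged: bool
    outer_iterations: int
    energy_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# occupancies


def optimize_occupancies(
    ints: IntegralSet,
    scheme: PairingScheme,
    start: OccupancyState,
    settings: SolverSettings,
) -> OccupancyState:
    """Minimize the energy over occupancies at a fixed orbital basis.

    ADAM momentum steps on the unconstrained parameters until the
    gradient norm drops under ``tol_gradient`` or the step cap; if the
    cap is hit first and ``occ_polish`` is set, an L-BFGS refinement with
    the same analytic gradient finishes the job.  The pairing constraint
    holds by construction at every iterate.
    """
    fid = settings.functional_id
    params = start.params.copy()
    if params.size == 0:
        return start

    def value_grad(p):
        st = params_to_occupancies(scheme, p, h_c=settings.h_c)
        e = total_energy(ints, scheme, st, fid).e_total
        g = occupation_gradient(ints, scheme, st, fid)
        if not np.isfinite(e):
            raise RuntimeError("non-finite energy during occupancy optimization")
        return e, g

    m = np.zeros_like(params)
    v = np.zeros_like(params)
    b1, b2 = settings.adam_beta1, settings.adam_beta2
    eps = 1e-8
    converged = False
    for t in range(1, settings.max_occ_steps + 1):
        _, g = value_grad(params)
        if np.linalg.norm(g) < settings.tol_gradient:
            converged = True
            break
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        params = params - settings.adam_rate * mhat / (np.sqrt(vhat) + eps)

    if not converged and settings.occ_polish:
        res = scipy.optimize.minimize(
            value_grad, params, jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-15, "gtol": settings.tol_gradient / 10},
        )
        params = res.x
    return params_to_occupancies(scheme, params, h_c=settings.h_c)


# ---------------------------------------------------------------------------
# orbitals


def orbital_gradient(
    ints: IntegralSet,
    scheme: PairingScheme,
    occ_state: OccupancyState,
    functional_id: str,
) -> np.ndarray:
    """Antisymmetric energy gradient ``dE/dX_rs`` with respect to the
    skew-symmetric rotation generator, evaluated at the current basis."""
    n, a, b = coefficient_matrices(scheme, occ_state, functional_id)
    chem = ints.eri_chemist()
    h = ints.h_one
    jt = np.einsum("rsqq->rsq", chem)   # (rs|qq)
    kt = np.einsum("rqsq->rqs", chem)   # (rq|sq)
    lam = (
        2.0 * h * n[None, :]
        + 2.0 * np.einsum("rsq,qs->rs", jt, a, optimize=True)
        + 2.0 * np.einsum("rqs,qs->rs", kt, b, optimize=True)
    )
    return 2.0 * (lam - lam.T)


def _triu_indices(nb: int):
    return np.triu_indices(nb, k=1)


def _skew_from_vector(x: np.ndarray, nb: int) -> np.ndarray:
    xm = np.zeros((nb, nb))
    iu = _triu_indices(nb)
    xm[iu] = x
    return xm - xm.T


def optimize_orbitals(
    ints: IntegralSet,
    scheme: PairingScheme,
    occ_state: OccupancyState,
    start: OrbitalRotation,
    settings: SolverSettings,
) -> OrbitalRotation:
    """Minimize the energy over orbital rotations at fixed occupancies.

    Damped Newton steps on the generator: the Hessian is assembled by
    forward differences of the analytic gradient along each generator
    direction, made positive definite through an absolute-value
    eigenvalue floor, and the step is backtracked on the actual energy.
    ``ints`` must be in the *stored* basis; ``start`` maps it to the
    current orbitals.
    """
    fid = settings.functional_id
    nb = ints.n_basis
    iu = _triu_indices(nb)
    nvar = len(iu[0])
    if nvar == 0:
        return start

    coeff = start.coeff.copy()

    def current():
        return transform_basis(ints, OrbitalRotation(coeff))

    cur = current()

    def energy_of(its):
        return total_energy(its, scheme, occ_state, fid).e_total

    e_cur = energy_of(cur)
    fd = settings.orb_fd_step
    for _ in range(settings.max_orb_steps):
        g_mat = orbital_gradient(cur, scheme, occ_state, fid)
        g = g_mat[iu]
        if np.linalg.norm(g) < settings.tol_gradient:
            break
        # finite-difference Hessian of the analytic gradient
        hess = np.zeros((nvar, nvar))
        for i in range(nvar):
            x = np.zeros(nvar)
            x[i] = fd
            step = scipy.linalg.expm(_skew_from_vector(x, nb))
            pert = transform_basis(cur, OrbitalRotation(step))
            gp = orbital_gradient(pert, scheme, occ_state, fid)[iu]
            hess[:, i] = (gp - g) / fd
        hess = 0.5 * (hess + hess.T)
        evals, evecs = scipy.linalg.eigh(hess)
        floor = max(1e-8, 1e-8 * np.abs(evals).max())
        evals = np.maximum(np.abs(evals), floor)
        step_vec = -evecs @ ((evecs.T @ g) / evals)
        # backtracking line search on the energy
        alpha = 1.0
        accepted = False
        for _bt in range(30):
            rot_step = scipy.linalg.expm(_skew_from_vector(alpha * step_vec, nb))
            trial_coeff = coeff @ rot_step
            trial = transform_basis(ints, OrbitalRotation(trial_coeff))
            e_trial = energy_of(trial)
            if e_trial < e_cur + 1e-14:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        coeff = trial_coeff
        # re-orthonormalize on drift
        if not np.allclose(coeff.T @ coeff, np.eye(nb), atol=1e-10):
            q, r = np.linalg.qr(coeff)
            coeff = q * np.sign(np.diag(r))
        cur = trial
        e_cur = e_trial
    return OrbitalRotation(coeff)


# ---------------------------------------------------------------------------
# outer loop


def _start_state(
    ints: IntegralSet, scheme: PairingScheme, settings: SolverSettings
) -> OccupancyState:
    if settings.pinned:
        return occupancy_state_from_occ(
            scheme, pinned_occupancies(scheme), h_c=settings.h_c
        )
    return params_to_occupancies(
        scheme, initial_params(scheme), h_c=settings.h_c
    )


def _core_guess(ints: IntegralSet) -> OrbitalRotation:
    """Eigenvectors of h_one, ascending eigenvalue, deterministic column
    signs (largest-magnitude entry positive)."""
    _, c = scipy.linalg.eigh(ints.h_one)
    for j in range(c.shape[1]):
        k = np.argmax(np.abs(c[:, j]))
        if c[k, j] < 0:
            c[:, j] = -c[:, j]
    return OrbitalRotation(c)


def solve(
    ints: IntegralSet,
    scheme: PairingScheme,
    settings: SolverSettings | None = None,
    check_constraints: bool = True,
) -> SolverResult:
    """Alternate occupancy and orbital optimization to a stationary
    total energy.

    Starts from the core-guess orbitals (eigenvectors of ``h_one``) and
    the seeded near-pinned occupancies; declares convergence when the
    outer energy change stays below ``tol_energy`` on two consecutive
    sweeps.  A result is returned (flagged unconverged) even when the
    sweep cap is hit.
    """
    if settings is None:
        settings = SolverSettings()
    rotation = _core_guess(ints)
    occ_state = _start_state(ints, scheme, settings)
    trace = []
    cur = transform_basis(ints, rotation)
    e_prev = total_energy(cur, scheme, occ_state, settings.functional_id).e_total
    trace.append(e_prev)
    small_changes = 0
    converged = False
    outer = 0
    for outer in range(1, settings.max_outer + 1):
        if not settings.pinned:
            occ_state = optimize_occupancies(cur, scheme, occ_state, settings)
        if check_constraints:
            rep = validate_occupancies(scheme, occ_state.occ, tol=1e-10)
            if not rep.passed:
                raise RuntimeError(f"pairing constraint violated:\n{rep}")
        rotation = optimize_orbitals(ints, scheme, occ_state, rotation, settings)
        cur = transform_basis(ints, rotation)
        e_now = total_energy(cur, scheme, occ_state, settings.functional_id).e_total
        trace.append(e_now)
        if abs(e_now - e_prev) < settings.tol_energy:
            small_changes += 1
            if small_changes >= 2:
                converged = True
                break
        else:
            small_changes = 0
        e_prev = e_now
    breakdown = total_energy(cur, scheme, occ_state, settings.functional_id)
    return SolverResult(
        breakdown=breakdown,
        occ_state=occ_state,
        rotation=rotation,
        converged=converged,
        outer_iterations=outer,
        energy_trace=trace,
    )


def rhf_reference(
    ints: IntegralSet,
    scheme: PairingScheme,
    settings: SolverSettings | None = None,
) -> SolverResult:
    """Hartree-Fock baseline: orbital-only optimization at pinned
    occupancies (strong orbitals at 1, singles at 1/2, rest at 0); the
    static and dynamic terms vanish identically there."""
    if settings is None:
        settings = SolverSettings()
    settings = replace(
        settings, pinned=True, tol_gradient=min(settings.tol_gradient, 1e-7)
    )
    return solve(ints, scheme, settings)
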