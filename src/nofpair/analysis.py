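"""Correlation-energy bookkeeping, complete-basis-set extrapolation, and
dipole moments from the one-particle density matrix.

Correlation energies are differences ``E_corr = E_method - E_HF``
reported in millihartree.  Three extrapolation laws in the basis-set
cardinal number X are supported:

* ``power3`` (inverse-cubic): ``E(X) = E_inf + b X^-3`` — linear least
  squares, exact interpolation with two points;
* ``exponential``: ``E(X) = E_inf + A exp(-gamma X)``;
* ``power``: ``E(X) = E_inf + A X^-gamma``;

the latter two by nonlinear least squares with documented starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .integrals import IntegralSet, OrbitalRotation
from .occupancies import OccupancyState

__all__ = [
    "CBSSeries",
    "DipoleResult",
    "correlation_energy",
    "cbs_extrapolate",
    "dipole_moment",
    "rms_deviation",
]

SCHEMES = ("power3", "exponential", "power")


@dataclass
class CBSSeries:
    """A (cardinal, energy) series plus the fitted extrapolation."""

    points: list            # [(X, energy)]
    scheme: str = "power3"
    e_inf: float | None = None
    b: float | None = None          # prefactor A / A' / b
    gamma: float | None = None      # decay exponent; fixed 3 for power3
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        xs = [p[0] for p in self.points]
        if any(x2 <= x1 for x1, x2 in zip(xs, xs[1:])):
            raise ValueError("cardinal numbers must be strictly increasing")
        if any(x < 2 for x in xs):
            raise ValueError("cardinal numbers must be >= 2")
        n_min = 2 if self.scheme == "power3" else 3
        if len(self.points) < n_min:
            raise ValueError(f"{self.scheme} needs at least {n_min} points")


def correlation_energy(e_method: float, e_hf: float) -> float:
    """``(E_method - E_HF) * 1000`` — millihartree."""
    return (e_method - e_hf) * 1000.0


def _model(scheme: str, x: np.ndarray, p: np.ndarray) -> np.ndarray:
    if scheme == "power3":
        return p[0] + p[1] * x**-3.0
    if scheme == "exponential":
        return p[0] + p[1] * np.exp(-p[2] * x)
    return p[0] + p[1] * x ** -p[2]


def cbs_extrapolate(series: CBSSeries, points: str = "all") -> CBSSeries:
    """Fit the extrapolation law of ``series.scheme`` and return a new
    series with ``e_inf``, ``b``, ``gamma`` and residuals populated.

    ``points="all"`` fits every cardinal by least squares; ``points=
    "last2"`` (power3 only) restricts to the two largest cardinals, the
    common two-point inverse-cubic practice.
    """
    pts = list(series.points)
    if points == "last2":
        if series.scheme != "power3":
            raise ValueError("last2 mode applies to the power3 scheme only")
        pts = pts[-2:]
    elif points != "all":
        raise ValueError(f"unknown points mode {points!r}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)

    if series.scheme == "power3":
        design = np.stack([np.ones_like(x), x**-3.0], axis=1)
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        p = np.array([sol[0], sol[1], 3.0])
    else:
        # starts: E_inf from the largest cardinal, decay from the last
        # two increments (falls back to 1 when degenerate)
        e_inf0 = y[-1]
        d1, d2 = y[-2] - y[-1], y[-3] - y[-2]
        if series.scheme == "exponential":
            gamma0 = np.log(abs(d2 / d1)) if d1 != 0 and d2 != 0 else 1.0
            gamma0 = float(np.clip(gamma0, 0.1, 10.0))
            a0 = (y[0] - e_inf0) / np.exp(-gamma0 * x[0])
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                gamma0 = (
                    np.log(abs(d2 / d1)) / np.log(x[-2] / x[-3])
                    if d1 and d2
                    else 3.0
                )
            gamma0 = float(np.clip(abs(gamma0), 0.5, 10.0))
            a0 = (y[0] - e_inf0) * x[0] ** gamma0
        p0 = np.array([e_inf0, a0 if a0 else 1.0, gamma0])
        res = scipy.optimize.least_squares(
            lambda p: _model(series.scheme, x, p) - y, p0, xtol=1e-15, ftol=1e-15,
            gtol=1e-15,
        )
        if not res.success:
            raise RuntimeError(f"nonlinear CBS fit did not converge: {res.message}")
        p = res.x
    residuals = _model(series.scheme, x, p) - y
    return CBSSeries(
        points=list(series.points),
        scheme=series.scheme,
        e_inf=float(p[0]),
        b=float(p[1]),
        gamma=float(p[2]),
        residuals=residuals,
    )


@dataclass
class DipoleResult:
    """Dipole vector and magnitude in atomic units, with an optional
    experimental reference magnitude."""

    vector: np.ndarray
    reference: float | None = None

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))

    @property
    def deviation(self) -> float | None:
        if self.reference is None:
            return None
        return self.magnitude - self.reference


def dipole_moment(
    ints: IntegralSet,
    rotation: OrbitalRotation,
    occ_state: OccupancyState,
    reference: float | None = None,
) -> DipoleResult:
    """Dipole from the (diagonal) 1RDM in the converged natural-orbital
    basis: electronic part ``-2 Σ_p n_p <φ_p|r|φ_p>`` plus the nuclear
    dipole."""
    if ints.dipole_ints is None:
        raise ValueError("IntegralSet carries no dipole integrals")
    c = rotation.coeff
    dip_no = np.einsum("pi,xpq,qj->xij", c, ints.dipole_ints, c)
    elec = -2.0 * np.einsum("xpp,p->x", dip_no, occ_state.occ)
    nuc = (
        np.zeros(3)
        if ints.nuclear_dipole is None
        else np.asarray(ints.nuclear_dipole, dtype=float)
    )
    return DipoleResult(vector=elec + nuc, reference=reference)


def rms_deviation(values, references) -> float:
    """Root-mean-square deviation between paired value lists."""
    values = np.asarray(values, dtype=float)
    references = np.asarray(references, dtype=float)
    if values.shape != references.shape or values.size == 0:
        raise ValueError("value and reference lists must be equal-length, nonempty")
    return float(np.sqrt(np.mean((values - references) ** 2)))
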