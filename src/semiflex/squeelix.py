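"""Ground states of a helical filament squeezed onto a plane ("squeelix").

A helical worm-like chain carries intrinsic curvature ``omega1`` and
intrinsic torsion ``omega3`` with bending and torsional moduli ``B`` and
``C``.  Squeezed flat, its projected curvature becomes slaved to the twist
angle ``psi``:

    kappa(s) = omega1 * sin(psi(s)),

and ``psi`` obeys a pendulum equation

    psi'' + (B omega1^2 / 2C) sin(2 psi) = 0.

The revolving-pendulum solutions ``psi(s) = am(s / lambda | m)`` (Jacobi
amplitude, parameter convention: ``E(0) = pi/2``, ``E(1) = 1``) with kink
width ``lambda = sqrt(m C / B) / omega1`` describe ground states whose
elliptic parameter minimizes the energy density, giving the selection rule

    m E(m) = gamma,     gamma = 4 omega1^2 B / (pi^2 omega3^2 C).

``gamma`` is the twist-expulsion parameter: for ``gamma > 1`` no revolving
solution minimizes the energy and the ground state is a circle of radius
``1/omega1``; for ``gamma <= 1`` the ground state carries a finite density
of twist-kinks, localized curvature-reversal points of width ``lambda``
and self-energy ``pi C omega3 (gamma - 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.special import ellipe, ellipj, ellipk

from semiflex.wlc import Chain2D

__all__ = [
    "SqueelixSystem",
    "GroundState",
    "twist_expulsion_gamma",
    "ground_state_m",
    "kink_width",
    "twist_and_curvature_profile",
    "reconstruct_shape",
    "kink_energetics",
    "classify_regime",
    "dense_dilute_threshold",
    "pendulum_residual",
]


@dataclass(frozen=True)
class SqueelixSystem:
    """Material parameters of a squeezed helical filament.

    ``B``/``C`` are bending/torsional moduli (energy x length), ``omega1``
    and ``omega3`` intrinsic curvature and torsion (1/length), ``L`` the
    contour length.  The second principal curvature is set to zero by a
    proper choice of the material frame.
    """

    B: float
    C: float
    omega1: float
    omega3: float
    L: float = 1.0

    def __post_init__(self) -> None:
        for name in ("B", "C", "omega1", "omega3", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GroundState:
    """Selected ground state of a squeelix.

    ``m`` is the elliptic parameter (``nan`` in the circular phase),
    ``lam`` the twist-kink width, ``regime`` one of ``circle``,
    ``dilute_kinks`` or ``dense_kinks``.
    """

    gamma: float
    m: float
    lam: float
    regime: str


def twist_expulsion_gamma(sys: SqueelixSystem) -> float:
    """Twist-expulsion parameter ``gamma = 4 omega1^2 B / (pi^2 omega3^2 C)``."""
    return 4.0 * sys.omega1**2 * sys.B / (np.pi**2 * sys.omega3**2 * sys.C)


def _mE(m: float) -> float:
    return m * ellipe(m)


def ground_state_m(gamma: float, tol: float = 1e-12):
    """Solve the ground-state selection rule ``m E(m) = gamma``.

    For ``gamma <= 1`` returns the root ``m`` in ``(0, 1]`` found by
    bracketed bisection; for ``gamma > 1`` no revolving minimum exists and
    the string ``"circle"`` is returned.

    Notes
    -----
    ``m E(m)`` rises from 0 but is not strictly monotone up to ``m = 1``:
    it peaks slightly above 1 (about 1.0087 near ``m = 0.966``) before
    returning to ``m E(1) = 1``.  For ``gamma < 1`` the crossing on the
    rising branch is unique; the boundary case ``gamma = 1`` is pinned to
    the homoclinic solution ``m = 1`` (single twist-kink), consistent with
    the energy-density selection.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if gamma > 1.0:
        return "circle"
    if abs(gamma - 1.0) <= tol:
        return 1.0
    lo = 1e-15
    # bracket the first crossing of the rising branch
    hi = 1.0
    # shrink hi below the non-monotone cap so brentq sees a sign change
    grid = np.linspace(1e-6, 1.0, 2001)
    vals = np.array([_mE(g) for g in grid]) - gamma
    idx = np.nonzero(vals > 0)[0]
    if idx.size:
        hi = grid[idx[0]]
        lo = grid[max(idx[0] - 1, 0)] if idx[0] > 0 else lo
    return float(brentq(lambda m: _mE(m) - gamma, lo, hi, xtol=tol))


def kink_width(sys: SqueelixSystem, m: float) -> float:
    """Twist-kink width ``lambda = sqrt(m C / B) / omega1``.

    Fixed (given ``m``) by requiring ``psi(s) = am(s/lambda | m)`` to solve
    the pendulum equation ``psi'' + (B omega1^2 / 2C) sin(2 psi) = 0``.
    """
    return np.sqrt(m * sys.C / sys.B) / sys.omega1


def twist_and_curvature_profile(
    sys: SqueelixSystem, m: float, n_points: int = 1001, s=None
):
    """Twist angle and slaved curvature of the bulk ground-state solution.

    Returns ``(s, psi, kappa)`` with ``psi(s) = am(s / lambda | m)``
    (so ``psi(0) = 0``) and ``kappa = omega1 sin(psi)``.  The profile is
    the bulk (infinite-chain) solution truncated to ``[-L/2, L/2]``; the
    finite-length boundary condition is not solved.

    For ``m = 1`` the amplitude degenerates to the homoclinic kink
    ``psi(s) = 2 arctan(exp(s / lambda)) - pi/2`` interpolating between
    ``-pi/2`` and ``+pi/2``.
    """
    if not (0.0 < m <= 1.0):
        raise ValueError("elliptic parameter m must lie in (0, 1]")
    if s is None:
        if n_points < 100:
            raise ValueError("n_points must be >= 100")
        s = np.linspace(-sys.L / 2.0, sys.L / 2.0, n_points)
    else:
        s = np.asarray(s, dtype=float)
    lam = kink_width(sys, m)
    u = s / lam
    if m == 1.0:
        psi = 2.0 * np.arctan(np.exp(u)) - np.pi / 2.0
    else:
        _, _, _, psi = ellipj(u, m)
    kappa = sys.omega1 * np.sin(psi)
    return s, psi, kappa


def reconstruct_shape(s, kappa, x0: float = 0.0, y0: float = 0.0) -> Chain2D:
    """Planar shape from a curvature profile.

    Cumulative trapezoidal integration: ``phi = int kappa ds`` then
    ``(x, y) = int (cos phi, sin phi) ds``.  A non-uniform grid is
    resampled (with a warning) onto a uniform one of the same size.
    """
    s = np.asarray(s, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    ds = np.diff(s)
    if not np.allclose(ds, ds[0], rtol=1e-9, atol=1e-12):
        warnings.warn("non-uniform grid; resampling")
        su = np.linspace(s[0], s[-1], len(s))
        kappa = np.interp(su, s, kappa)
        s = su
    phi = cumulative_trapezoid(kappa, s, initial=0.0)
    x = x0 + cumulative_trapezoid(np.cos(phi), s, initial=0.0)
    y = y0 + cumulative_trapezoid(np.sin(phi), s, initial=0.0)
    return Chain2D(s=s, theta=phi, xy=np.column_stack([x, y]))


def kink_energetics(sys: SqueelixSystem):
    """Circle energy density, kink self-energy, and kink width.

    Returns ``(E0_per_L, DeltaE, lam)``: the circular-state energy density
    ``C omega3^2 / 2``, the single twist-kink self-energy
    ``pi C omega3 (gamma - 1)`` (positive for ``gamma > 1``: kinks are
    expelled), and the homoclinic kink width ``sqrt(C/B)/omega1``.
    """
    gamma = twist_expulsion_gamma(sys)
    E0 = sys.C * sys.omega3**2 / 2.0
    dE = np.pi * sys.C * sys.omega3 * (gamma - 1.0)
    lam = np.sqrt(sys.C / sys.B) / sys.omega1
    return E0, dE, lam


def dense_dilute_threshold() -> float:
    """Twist-expulsion parameter below which kinks lose their identity.

    In the revolving ground state the curvature flips every half period
    ``d = 2 K(m) lambda`` of the Jacobi amplitude while an individual kink
    core spans about ``2 lambda`` on either side of the flip.  Plateaus of
    nearly constant curvature -- the signature of well-separated kinks --
    survive while ``2 K(m) > 4``; below that the twist advances nearly
    uniformly and the shape is sinus-like.  The returned value is
    ``gamma = m_c E(m_c)`` with ``K(m_c) = 2``.
    """
    m_c = brentq(lambda m: ellipk(m) - 2.0, 1e-9, 1 - 1e-12, xtol=1e-14)
    return float(m_c * ellipe(m_c))


def classify_regime(sys: SqueelixSystem) -> GroundState:
    """Ground-state regime of a squeelix.

    ``gamma > 1``: circular ground state (twist-kinks expelled).
    ``gamma_dense < gamma <= 1``: dilute twist-kinks separating arcs of
    nearly constant curvature.  ``gamma <= gamma_dense``: dense kinks,
    sinus-like shape.
    """
    gamma = twist_expulsion_gamma(sys)
    if gamma > 1.0:
        return GroundState(gamma, np.nan, np.nan, "circle")
    m = ground_state_m(gamma)
    lam = kink_width(sys, m)
    regime = "dilute_kinks" if gamma > dense_dilute_threshold() else "dense_kinks"
    return GroundState(gamma, m, lam, regime)


def pendulum_residual(sys: SqueelixSystem, m: float, n: int = 512) -> float:
    """Max residual of the pendulum equation for the amplitude profile.

    For ``m < 1`` the profile is linear-plus-periodic,
    ``psi(u) = pi u / (2K) + periodic``; the periodic part is
    differentiated spectrally over exactly one period and the residual of
    ``psi'' + (m / 2 lambda^2) sin(2 psi) = 0`` is returned.  For
    ``m = 1`` the homoclinic closed form is differentiated analytically.
    """
    lam = kink_width(sys, m)
    coef = sys.B * sys.omega1**2 / (2.0 * sys.C)  # = m / (2 lam^2)
    if m == 1.0:
        u = np.linspace(-8.0, 8.0, n)
        s = u * lam
        psi = 2.0 * np.arctan(np.exp(u)) - np.pi / 2.0
        # psi'' = -sech(u) tanh(u) / lam^2 analytically
        psi_ss = -(1.0 / np.cosh(u)) * np.tanh(u) / lam**2
        return float(np.max(np.abs(psi_ss + coef * np.sin(2.0 * psi))))
    K = ellipk(m)
    period = 2.0 * K  # am advances by pi per period in u
    u = np.arange(n) * (period / n)
    _, _, _, psi = ellipj(u, m)
    slope = np.pi / period
    per = psi - slope * u
    k = 2.0 * np.pi * np.fft.rfftfreq(n, d=period / n)
    per_hat = np.fft.rfft(per)
    psi_ss = np.fft.irfft(-(k**2) * per_hat, n)
    resid = psi_ss / lam**2 + coef * np.sin(2.0 * psi)
    return float(np.max(np.abs(resid)))
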