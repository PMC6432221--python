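"""Shear-coupled bundles and tail-induced bistable filaments.

Two stiff filaments cross-linked by soft springs (a "railway-track"
bundle) carry, besides the bending energy ``(B/2) int theta'^2``, a shear
energy ``(K/2) int tau^2`` with ``tau(s) = theta(s) - theta_bar`` acting
like an internal self-tension.  Curvature imposed on a region of length
``l`` is screened over the length ``lambda = sqrt(B/K)``: counter-arcs of
opposite curvature decay as ``exp(-|s - s0| / lambda)``, and the energy of
an imposed arc grows as ``sqrt(B K) kappa0^2 l^2`` for ``l << lambda`` and
as ``K kappa0^2 l^3`` beyond -- faster than the linear growth of a plain
worm-like chain.

A semiflexible filament dressed with prestressed elastic tails (span
``d``, spring constant ``k``) buckles into curved sections once
``k > k_crit = 12 B / d^3``.  Near threshold the energy has the Landau
form

    E = (k d^3 / 2) int [ C1 (k_crit/k - 1) kappa^2 + C2 d^2 kappa^4 ] ds

with bistable curvature ``kappa ~ +/- sqrt(1 - k_crit/k) / d``.
Overlapping tail intervals add a "hyper-stiffness" penalty
``(H/2) int kappa'^2`` (``H ~ k d^5``) which makes curvature -- not the
tangent -- persistent and widens the domain walls between curvature
states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "BundleSystem",
    "TailSystem",
    "screening_length",
    "shear_constant",
    "arc_energy",
    "imposed_arc_response",
    "buckling",
    "landau_energy",
    "landau_minimizer",
    "domain_wall_profile",
]


@dataclass(frozen=True)
class BundleSystem:
    """Two-filament bundle coupled by shear springs.

    ``B``: bending constant of the bundle (twice the single-filament
    value); ``K``: shear constant; ``rho_ch``, ``w``, ``k_spring``:
    cross-link line density, lateral width and spring constant entering
    the estimate ``K ~ rho_ch w^2 k_spring``; ``L``: length.
    """

    B: float
    K: float
    rho_ch: float = 1.0
    w: float = 1.0
    k_spring: float = 1.0
    L: float = 100.0

    def __post_init__(self) -> None:
        for name in ("B", "K", "rho_ch", "w", "k_spring", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TailSystem:
    """Filament with prestressed elastic tails of span ``d``."""

    B: float
    d: float
    k: float

    def __post_init__(self) -> None:
        for name in ("B", "d", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k_crit(self) -> float:
        return 12.0 * self.B / self.d**3


def shear_constant(rho_ch: float, w: float, k_spring: float) -> float:
    """Shear-constant estimate ``K ~ rho_ch w^2 k_spring`` (unit prefactor)."""
    return rho_ch * w**2 * k_spring


def screening_length(sys: BundleSystem) -> float:
    """Elastic screening length ``lambda = sqrt(B / K)``."""
    return np.sqrt(sys.B / sys.K)


def arc_energy(sys: BundleSystem, kappa0: float, l_arc):
    """Energy of an arc of curvature ``kappa0`` imposed over length ``l``.

    ``sqrt(B K) kappa0^2 l^2`` for ``l <= lambda`` and
    ``K kappa0^2 l^3`` beyond (continuous at ``l = lambda`` with unit
    prefactors).
    """
    lam = screening_length(sys)
    l = np.asarray(l_arc, dtype=float)
    below = np.sqrt(sys.B * sys.K) * kappa0**2 * l**2
    above = sys.K * kappa0**2 * l**3
    out = np.where(l <= lam, below, above)
    return out if out.ndim else float(out)


def imposed_arc_response(
    sys: BundleSystem, kappa0: float, l_arc: float, s0: float = 0.0, n: int = 1024
):
    """Deformation of a bundle with curvature imposed on a region.

    Minimizes ``(1/2) int [B theta'^2 + K (theta - theta_bar)^2] ds``
    exactly (sparse-free KKT solve on an ``n``-node grid) subject to
    ``theta' = kappa0`` on the arc ``|s - s0| < l_arc / 2`` and to the
    gauge ``theta_bar = 0``.  Returns ``(s, theta, tau)`` with
    ``tau = theta - theta_bar``; away from the arc ``tau`` decays as
    ``exp(-|s - s0| / lambda)`` with ``lambda = sqrt(B/K)``.
    """
    if l_arc >= sys.L:
        raise ValueError("arc longer than the bundle")
    s = np.linspace(-sys.L / 2.0, sys.L / 2.0, n)
    ds = s[1] - s[0]
    # difference operator: (n-1) x n
    D = (np.diff(np.eye(n), axis=0)) / ds
    A = sys.B * ds * (D.T @ D)
    P = np.eye(n) - np.full((n, n), 1.0 / n)
    A += sys.K * ds * P  # P idempotent: P^T P = P
    mids = 0.5 * (s[:-1] + s[1:])
    arc_rows = np.nonzero(np.abs(mids - s0) < l_arc / 2.0)[0]
    Cmat = np.vstack([D[arc_rows], np.full((1, n), 1.0 / n)])
    rhs = np.concatenate([np.full(len(arc_rows), kappa0), [0.0]])
    nc = Cmat.shape[0]
    KKT = np.block([[A, Cmat.T], [Cmat, np.zeros((nc, nc))]])
    sol = np.linalg.solve(KKT, np.concatenate([np.zeros(n), rhs]))
    theta = sol[:n]
    tau = theta - theta.mean()
    return s, theta, tau


def buckling(sys: TailSystem):
    """Buckling threshold and bistable curvature amplitude.

    Returns ``(k_crit, kappa)`` with ``k_crit = 12 B / d^3`` and, for
    ``k > k_crit``, ``|kappa| = sqrt(1 - k_crit/k) / d`` (unit
    prefactor); zero below threshold.
    """
    kc = sys.k_crit
    if sys.k <= kc:
        return kc, 0.0
    return kc, np.sqrt(1.0 - kc / sys.k) / sys.d


def landau_energy(sys: TailSystem, kappa, C1: float = 1.0, C2: float = 1.0):
    """Landau energy density of the buckled filament (per unit length).

    ``(k d^3 / 2) [C1 (k_crit/k - 1) kappa^2 + C2 d^2 kappa^4]``.
    """
    kappa = np.asarray(kappa, dtype=float)
    pref = sys.k * sys.d**3 / 2.0
    return pref * (
        C1 * (sys.k_crit / sys.k - 1.0) * kappa**2 + C2 * sys.d**2 * kappa**4
    )


def landau_minimizer(sys: TailSystem, C1: float = 1.0, C2: float = 1.0) -> float:
    """Curvature minimizing the Landau energy density.

    ``kappa* = sqrt(C1 (1 - k_crit/k) / (2 C2)) / d`` for ``k > k_crit``,
    zero otherwise.
    """
    if sys.k <= sys.k_crit:
        return 0.0
    return np.sqrt(C1 * (1.0 - sys.k_crit / sys.k) / (2.0 * C2)) / sys.d


def default_hyperstiffness(sys: TailSystem) -> float:
    """Default hyper-stiffness constant ``H = k d^5`` (unit prefactor)."""
    return sys.k * sys.d**5


def domain_wall_profile(
    sys: TailSystem,
    H: float | None = None,
    C1: float = 1.0,
    C2: float = 1.0,
    L: float | None = None,
    n: int = 257,
):
    """Curvature domain wall between the two buckled states.

    Minimizes ``int [f_Landau(kappa) + (H/2) kappa'^2] ds`` with ends
    pinned at ``-/+ kappa*`` (L-BFGS with analytic gradient).  Returns
    ``(s, kappa, width)`` where the width is the distance between the
    ``-/+ kappa* tanh(1)`` crossings of the wall; it grows with ``H``.
    """
    if sys.k <= sys.k_crit:
        raise ValueError("no bistability below the buckling threshold")
    if H is None:
        H = default_hyperstiffness(sys)
    kstar = landau_minimizer(sys, C1, C2)
    pref = sys.k * sys.d**3 / 2.0
    a = pref * C1 * (sys.k_crit / sys.k - 1.0)  # < 0
    c = pref * C2 * sys.d**2
    if L is None:
        # analytic phi^4 wall width sqrt(H / (4 c kstar^2)); keep 30x margin
        L = 30.0 * np.sqrt(H / (4.0 * c * kstar**2))
    s = np.linspace(-L / 2.0, L / 2.0, n)
    ds = s[1] - s[0]

    def split(x):
        kap = np.empty(n)
        kap[0], kap[-1] = -kstar, kstar
        kap[1:-1] = x
        return kap

    def fun(x):
        kap = split(x)
        grad_k = np.diff(kap) / ds
        e = np.sum((a * kap**2 + c * kap**4) * ds) + 0.5 * H * np.sum(
            grad_k**2
        ) * ds
        g = 2.0 * a * kap * ds + 4.0 * c * kap**3 * ds
        lap = np.zeros(n)
        lap[1:] += grad_k
        lap[:-1] -= grad_k
        g += H * lap
        return e, g[1:-1]

    x0 = kstar * np.tanh(s[1:-1] / max(np.sqrt(H / (4 * c * kstar**2)), ds))
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
    kap = split(res.x)
    thresh = kstar * np.tanh(1.0)
    inside = np.abs(kap) < thresh
    width = float(inside.sum() * ds)
    return s, kap, width
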