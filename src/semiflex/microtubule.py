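"""Polymorphic cross-section model of microtubules.

A microtubule cross-section of ``N`` protofilaments (typically 13) is a
two-layer annulus ``Ri < rho < Ro`` with layer boundary ``Rm``.  Each
tubulin dimer can switch (``sigma_n = 1``) from the straight to a curved
conformation, gaining switching free energy ``DeltaG`` per dimer but
acquiring preferred strains: tensile ``eps_i > 0`` in the inner layer and
compressive ``eps_o < 0`` in the outer layer (outward curving).  With the
axial strain field ``eps(rho, phi) = -kappa . rho + eps_bar`` the elastic
energy per unit length is

    e_el = (Y/2) int rho drho dphi (eps - eps_pref)^2,

and the total energy adds ``e_switch = (DeltaG / b) sum_n sigma_n`` plus
work terms ``F eps_bar + M kappa`` of external loads.  Switched dimers
effectively attract within the lattice, so the energetically relevant
states are single contiguous blocks parameterized by the block angle
``phi_p = 2 pi p / N``.  Minimizing over curvature and stretch yields the
polymorphic potential over ``phi_p`` whose competing minima are the
straight-long (``phi_p = 0``), curved (interior ``phi_p``) and
straight-short (``phi_p = 2 pi``) states; the curved state carries a
curvature close to the characteristic value

    kappa_1 = (8 / 3 pi) [eps_i (Rm^3 - Ri^3) + eps_o (Ro^3 - Rm^3)]
              / (Ro^4 - Ri^4).

In rescaled load variables (generalized force ``f``, torque ``m``) the
potential takes the form

    V(phi_p) = -(c_p / 2) phi_p^2 + f phi_p - m sin(phi_p / 2)
               - (1/2) sin^2(phi_p / 2)

in units of ``B kappa_1^2`` (``B = Y I_kappa`` the bending stiffness of
the annulus); the generalized force absorbs the external force, the
lattice strain constraints, and a contribution linear in ``DeltaG``.  The
potential here is *constructed* by the explicit minimization, and the
structural form above is verified against it in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "MTCrossSection",
    "PolymorphicState",
    "demo_cross_section",
    "characteristic_curvature",
    "cross_section_energy",
    "minimize_cross_section",
    "block_sigma",
    "polymorphic_cp",
    "polymorphic_potential",
    "phase_diagram",
    "hysteresis_sweep",
]


@dataclass(frozen=True)
class MTCrossSection:
    """Geometry, strains and energies of a microtubule cross-section.

    Radii in any consistent length unit; ``Y`` an elastic modulus per
    area (energy / length^4 in reduced units); ``DeltaG`` the switching
    free energy per dimer (thermal units); ``b`` the dimer length.
    """

    Ri: float
    Rm: float
    Ro: float
    eps_i: float
    eps_o: float
    N: int = 13
    b: float = 8.0
    Y: float = 1.0
    DeltaG: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.Ri < self.Rm < self.Ro):
            raise ValueError("need 0 < Ri < Rm < Ro")
        if not (self.eps_i > 0 > self.eps_o):
            raise ValueError("need tensile eps_i > 0 and compressive eps_o < 0")
        if self.N < 9:
            raise ValueError("protofilament count N must be >= 9")

    # --- geometric moments -------------------------------------------------
    @property
    def area(self) -> float:
        return np.pi * (self.Ro**2 - self.Ri**2)

    @property
    def I_kappa(self) -> float:
        """Second area moment: ``int rho_x^2 dA = (pi/4)(Ro^4 - Ri^4)``."""
        return np.pi * (self.Ro**4 - self.Ri**4) / 4.0

    @property
    def bending_stiffness(self) -> float:
        return self.Y * self.I_kappa

    def _layer_m0(self):
        """Per-radian areas of (inner, outer) layer."""
        return (
            (self.Rm**2 - self.Ri**2) / 2.0,
            (self.Ro**2 - self.Rm**2) / 2.0,
        )

    def _layer_m1(self):
        """Per-radian first radial moments of (inner, outer) layer."""
        return (
            (self.Rm**3 - self.Ri**3) / 3.0,
            (self.Ro**3 - self.Rm**3) / 3.0,
        )

    def sector_edges(self) -> np.ndarray:
        """Angular edges of the N dimer sectors."""
        return np.linspace(0.0, 2.0 * np.pi, self.N + 1)


@dataclass
class PolymorphicState:
    """A candidate state of the polymorphic potential."""

    phi_p: float
    f: float
    m: float
    energy: float
    label: str = ""


def demo_cross_section() -> MTCrossSection:
    """Synthetic illustrative geometry (not a fitted structure).

    Radii roughly microtubule-like (inner ~8.4, outer ~12.5 nm, layer
    boundary midway) with strains chosen so the fully switched state is
    2% shorter and the characteristic curvature is of order (1 um)^-1.
    """
    return MTCrossSection(
        Ri=8.4, Rm=10.45, Ro=12.5, eps_i=0.04, eps_o=-0.0692, N=13, b=8.0
    )


def characteristic_curvature(cs: MTCrossSection) -> float:
    """Characteristic polymorphic curvature ``kappa_1``.

    ``(8 / 3 pi) [eps_i (Rm^3 - Ri^3) + eps_o (Ro^3 - Rm^3)] /
    (Ro^4 - Ri^4)``; equals (up to sign convention) the optimal curvature
    of the half-switched (``phi_p = pi``) single-block state.
    """
    num = cs.eps_i * (cs.Rm**3 - cs.Ri**3) + cs.eps_o * (cs.Ro**3 - cs.Rm**3)
    return (8.0 / (3.0 * np.pi)) * num / (cs.Ro**4 - cs.Ri**4)


def block_sigma(cs: MTCrossSection, p: int) -> np.ndarray:
    """State vector with a single contiguous block of ``p`` switched dimers."""
    sigma = np.zeros(cs.N, dtype=int)
    sigma[:p] = 1
    return sigma


def _sector_trig(cs: MTCrossSection, sigma):
    """Angular integrals over switched sectors: (sum dphi, sum cos, sum sin)."""
    edges = cs.sector_edges()
    sigma = np.asarray(sigma)
    lo, hi = edges[:-1][sigma == 1], edges[1:][sigma == 1]
    return (
        float(np.sum(hi - lo)),
        float(np.sum(np.sin(hi) - np.sin(lo))),
        float(np.sum(-np.cos(hi) + np.cos(lo))),
    )


def _moments(cs: MTCrossSection, sigma=None, phi_p: float | None = None):
    """Strain moments S0 = int eps_pref dA, b_vec = int rho_vec eps_pref dA,
    P2 = int eps_pref^2 dA, and the switched angle."""
    m0i, m0o = cs._layer_m0()
    m1i, m1o = cs._layer_m1()
    if phi_p is not None:
        # contiguous block of angle phi_p centered at angle 0
        ang, csum, ssum = phi_p, 2.0 * np.sin(phi_p / 2.0), 0.0
    else:
        ang, csum, ssum = _sector_trig(cs, sigma)
    S0 = (cs.eps_i * m0i + cs.eps_o * m0o) * ang
    P2 = (cs.eps_i**2 * m0i + cs.eps_o**2 * m0o) * ang
    bx = (cs.eps_i * m1i + cs.eps_o * m1o) * csum
    by = (cs.eps_i * m1i + cs.eps_o * m1o) * ssum
    return S0, np.array([bx, by]), P2, ang


def cross_section_energy(
    cs: MTCrossSection,
    kappa_vec,
    eps_bar: float,
    sigma=None,
    phi_p: float | None = None,
    n_r: int = 64,
    n_phi: int = 256,
    quadrature: bool = False,
):
    """Total cross-section energy per unit length at fixed strains.

    Elastic part ``(Y/2) int (eps - eps_pref)^2 rho drho dphi`` with
    ``eps = -kappa . rho + eps_bar`` plus the switching part
    ``(DeltaG / b) sum sigma``.  By default the (exact) moment-based
    closed form is used; ``quadrature=True`` forces tensor Gauss-Legendre
    integration (``n_r`` radial points per layer, ``n_phi`` angular) as an
    independent numerical route.
    """
    kx, ky = float(kappa_vec[0]), float(kappa_vec[1])
    if quadrature:
        return _energy_quadrature(cs, kx, ky, eps_bar, sigma, phi_p, n_r, n_phi)
    S0, bvec, P2, ang = _moments(cs, sigma, phi_p)
    el = (cs.Y / 2.0) * (
        (kx**2 + ky**2) * cs.I_kappa
        + cs.area * eps_bar**2
        + 2.0 * (kx * bvec[0] + ky * bvec[1])
        - 2.0 * eps_bar * S0
        + P2
    )
    n_switched = ang * cs.N / (2.0 * np.pi)
    return el + (cs.DeltaG / cs.b) * n_switched


def _energy_quadrature(cs, kx, ky, eps_bar, sigma, phi_p, n_r, n_phi):
    from numpy.polynomial.legendre import leggauss

    xr, wr = leggauss(n_r)
    xp, wp = leggauss(n_phi)

    if phi_p is not None:
        edges_sw = [(-phi_p / 2.0, phi_p / 2.0)] if phi_p > 0 else []
        full = (-np.pi, np.pi)
    else:
        e = cs.sector_edges()
        sig = np.asarray(sigma)
        edges_sw = list(zip(e[:-1][sig == 1], e[1:][sig == 1]))
        full = (0.0, 2.0 * np.pi)

    def integrate(r1, r2, p1, p2, eps_pref):
        r = 0.5 * (r2 - r1) * xr + 0.5 * (r1 + r2)
        ph = 0.5 * (p2 - p1) * xp + 0.5 * (p1 + p2)
        R, PH = np.meshgrid(r, ph, indexing="ij")
        eps = -(kx * R * np.cos(PH) + ky * R * np.sin(PH)) + eps_bar
        integ = (eps - eps_pref) ** 2 * R
        w = np.outer(wr, wp) * (0.25 * (r2 - r1) * (p2 - p1))
        return float(np.sum(integ * w))

    total = 0.0
    # straight background (eps_pref = 0) over the full annulus...
    total += integrate(cs.Ri, cs.Ro, *full, 0.0)
    # ...then correct the switched sectors layer by layer
    for p1, p2 in edges_sw:
        for (r1, r2, ep) in ((cs.Ri, cs.Rm, cs.eps_i), (cs.Rm, cs.Ro, cs.eps_o)):
            total += integrate(r1, r2, p1, p2, ep) - integrate(r1, r2, p1, p2, 0.0)
    el = (cs.Y / 2.0) * total
    ang = phi_p if phi_p is not None else _sector_trig(cs, sigma)[0]
    return el + (cs.DeltaG / cs.b) * ang * cs.N / (2.0 * np.pi)


def minimize_cross_section(
    cs: MTCrossSection,
    sigma=None,
    phi_p: float | None = None,
    F: float = 0.0,
    M: float = 0.0,
):
    """Optimal strains and energy of a switching pattern under loads.

    Minimizes ``e_el + e_switch + F eps_bar + M kappa_x`` over
    ``(kappa_x, kappa_y, eps_bar)`` -- a linear solve, since the elastic
    energy is a positive-definite quadratic form (the curvature and
    stretch sectors decouple because ``int rho_vec dA = 0``).  Returns a
    dict with ``kappa``, ``eps_bar`` and ``energy``.
    """
    S0, bvec, _, _ = _moments(cs, sigma, phi_p)
    kx = -(cs.Y * bvec[0] + M) / (cs.Y * cs.I_kappa)
    ky = -bvec[1] / cs.I_kappa
    eb = (cs.Y * S0 - F) / (cs.Y * cs.area)
    e = cross_section_energy(cs, (kx, ky), eb, sigma=sigma, phi_p=phi_p)
    return {
        "kappa": np.array([kx, ky]),
        "eps_bar": eb,
        "energy": e + F * eb + M * kx,
    }


def polymorphic_cp(cs: MTCrossSection) -> float:
    """Coefficient ``c_p`` of the quadratic term of the potential.

    ``c_p = Y S0'^2 / (A B kappa_1^2)`` with ``S0' = d S0 / d phi_p`` the
    mean-preferred-strain slope; it stems from the stretch-frustration of
    partially switched rings.
    """
    m0i, m0o = cs._layer_m0()
    S0p = cs.eps_i * m0i + cs.eps_o * m0o
    k1 = characteristic_curvature(cs)
    return cs.Y * S0p**2 / (cs.area * cs.bending_stiffness * k1**2)


def _load_mapping(cs: MTCrossSection, f: float, m: float):
    """Physical loads (F, M) realizing rescaled (f, m).

    ``M = m * B kappa_1`` (so the torque term is ``-m sin(phi_p/2)`` in
    units of ``B kappa_1^2``); ``F`` is set so that the total linear
    coefficient of ``phi_p`` -- switching energy, strain frustration and
    external force combined -- equals ``f B kappa_1^2``.
    """
    k1 = characteristic_curvature(cs)
    B = cs.bending_stiffness
    m0i, m0o = cs._layer_m0()
    m1i, m1o = cs._layer_m1()
    S0p = cs.eps_i * m0i + cs.eps_o * m0o
    P2p = cs.eps_i**2 * m0i + cs.eps_o**2 * m0o
    if abs(S0p) < 1e-300:
        raise ValueError("degenerate geometry: d S0/d phi_p = 0")
    M = m * B * k1
    F = (f * B * k1**2 - 0.5 * cs.Y * P2p - cs.DeltaG * cs.N / (2.0 * np.pi * cs.b)) \
        * cs.area / S0p
    return F, M


def polymorphic_potential(cs: MTCrossSection, phi_p, f: float = 0.0, m: float = 0.0):
    """Polymorphic potential ``V(phi_p; f, m)`` in units of ``B kappa_1^2``.

    Constructed from first principles: for each block angle the energy
    ``e_el + e_switch + F eps_bar + M kappa`` is minimized over strain and
    curvature with the physical loads realizing the rescaled ``(f, m)``,
    and the result is referenced to the straight state ``phi_p = 0``.
    """
    k1 = characteristic_curvature(cs)
    B = cs.bending_stiffness
    F, M = _load_mapping(cs, f, m)
    phi = np.atleast_1d(np.asarray(phi_p, dtype=float))
    if np.any((phi < 0) | (phi > 2.0 * np.pi)):
        raise ValueError("phi_p must lie in [0, 2 pi]")
    e0 = minimize_cross_section(cs, phi_p=0.0, F=F, M=M)["energy"]
    out = np.array(
        [
            minimize_cross_section(cs, phi_p=p, F=F, M=M)["energy"] - e0
            for p in phi
        ]
    ) / (B * k1**2)
    return out if np.ndim(phi_p) else float(out[0])


def _potential_closed(cs: MTCrossSection, phi, f, m):
    """Vectorized structural form of the potential (equal to the
    first-principles construction; the equality is asserted in tests)."""
    cp = polymorphic_cp(cs)
    phi = np.asarray(phi, dtype=float)
    return (
        -(cp / 2.0) * phi**2
        + f * phi
        - m * np.sin(phi / 2.0)
        - 0.5 * np.sin(phi / 2.0) ** 2
    )


def _candidate_states(cs, f, m, n_phi=721):
    """Energies of the L (phi=0), C (interior minimum) and S (phi=2pi)
    states; C is NaN when no interior local minimum exists."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi)
    V = _potential_closed(cs, phi, f, m)
    EL, ES = V[0], V[-1]
    interior = None
    Vin = V[1:-1]
    loc = (Vin < V[:-2]) & (Vin <= V[2:])
    if loc.any():
        i = 1 + int(np.argmin(np.where(loc, Vin, np.inf)))
        lo, hi = phi[max(i - 1, 0)], phi[min(i + 1, n_phi - 1)]
        res = minimize_scalar(
            lambda p: _potential_closed(cs, p, f, m), bounds=(lo, hi),
            method="bounded", options={"xatol": 1e-10},
        )
        interior = (float(res.x), float(res.fun))
    EC = interior[1] if interior else np.nan
    phiC = interior[0] if interior else np.nan
    return EL, EC, ES, phiC


def phase_diagram(cs: MTCrossSection, f_grid, m_grid, n_phi: int = 721):
    """Energy ordering of the L/C/S states over an ``(f, m)`` grid.

    Returns a dict of arrays: ``label`` (ordering string such as
    ``"C<L<S"``, states ranked lowest first, absent C omitted),
    ``E_L``, ``E_C``, ``E_S`` and ``phi_C`` (location of the interior
    minimum, NaN when absent).
    """
    f_grid = np.asarray(f_grid, dtype=float)
    m_grid = np.asarray(m_grid, dtype=float)
    if f_grid.size < 20 or m_grid.size < 20:
        raise ValueError("need at least 20 grid points per axis")
    shape = (m_grid.size, f_grid.size)
    EL = np.empty(shape)
    EC = np.empty(shape)
    ES = np.empty(shape)
    PC = np.empty(shape)
    labels = np.empty(shape, dtype=object)
    for i, m in enumerate(m_grid):
        for j, f in enumerate(f_grid):
            el, ec, es, pc = _candidate_states(cs, f, m, n_phi)
            EL[i, j], EC[i, j], ES[i, j], PC[i, j] = el, ec, es, pc
            states = [("L", el), ("S", es)]
            if np.isfinite(ec):
                states.append(("C", ec))
            states.sort(key=lambda t: t[1])
            labels[i, j] = "<".join(name for name, _ in states)
    return {
        "f": f_grid, "m": m_grid, "label": labels,
        "E_L": EL, "E_C": EC, "E_S": ES, "phi_C": PC,
    }


def hysteresis_sweep(
    cs: MTCrossSection, m: float, f_values, n_phi: int = 1441, jump_threshold: float = 0.5
):
    """Quasi-static sweep of the generalized force at fixed torque.

    Follows the local minimum of the potential by continuation (nearest
    local minimum of the dense-grid potential to the previous state) for
    the given ``f_values`` and again in reverse.  Returns a dict with the
    two branches and the ``f`` locations of discontinuous jumps of the
    equilibrium ``phi_p``; differing jump locations up versus down signal
    hysteresis.
    """
    f_values = np.asarray(f_values, dtype=float)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi)

    def local_minima(V):
        idx = [0] if V[0] < V[1] else []
        interior = np.nonzero((V[1:-1] < V[:-2]) & (V[1:-1] <= V[2:]))[0] + 1
        idx.extend(interior.tolist())
        if V[-1] < V[-2]:
            idx.append(len(V) - 1)
        return np.asarray(idx)

    def sweep(fs):
        path = np.empty(len(fs))
        jumps = []
        current = None
        for j, f in enumerate(fs):
            V = _potential_closed(cs, phi, f, m)
            mins = local_minima(V)
            if current is None:
                current = phi[mins[np.argmin(V[mins])]]
            cand = phi[mins]
            new = cand[np.argmin(np.abs(cand - current))]
            if abs(new - current) > jump_threshold:
                jumps.append(f)
            current = new
            path[j] = current
        return path, jumps

    up_path, up_jumps = sweep(f_values)
    down_path, down_jumps = sweep(f_values[::-1])
    hysteretic = bool(
        up_jumps and down_jumps and any(
            min(abs(a - b) for b in down_jumps) > 0 for a in up_jumps
        )
    ) or (bool(up_jumps) != bool(down_jumps))
    return {
        "f_up": f_values, "phi_up": up_path, "jumps_up": up_jumps,
        "f_down": f_values[::-1], "phi_down": down_path,
        "jumps_down": down_jumps, "hysteretic": hysteretic,
    }
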