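"""Exact statistics of the arc/arc twist-kink gas.

In the twist-expulsion regime of a squeezed helical filament the ground
state is a circular arc and twist-kinks appear only as localized thermal
excitations with Boltzmann weight ``exp(-E)``.  Neglecting their width and
interactions, the chain is an ideal gas of ``k`` kinks separating arcs of
alternating signed curvature ``+/- omega``; ``k`` is Poisson distributed
with mean ``<k> = (S/b) exp(-E)``.  Gaussian flexural fluctuations
(persistence length ``ell``) factor out of the partition function and
enter as a convolution in the deflection angle.

The module evaluates, in closed form:

* the deflection-angle distribution ``P(theta)``: a Bessel-function bulk
  with compact support ``|theta| <= omega S`` plus two delta atoms of
  weight ``exp(-<k>)/2`` at ``theta = +/- omega S`` (the kink-free ground
  state), optionally convolved with the flexural Gaussian of variance
  ``S / ell``;
* the tangent correlation ``C(s)``, a sum of two (generally complex)
  exponentials with rates ``1/(2 ell_{1,2}) = (exp(-E)/b)(1 -/+
  sqrt(1 - omega^2 b^2 exp(2E))) + 1/(2 ell)``; ``C`` oscillates when a
  full turn survives between kinks (``omega b exp(E) > 1``);
* chain dimensions ``Re^2``/``Rg^2`` as the corresponding combinations of
  the 2D worm-like-chain closed forms evaluated at ``ell_1`` and
  ``ell_2`` (complex arithmetic retained, reality asserted at the end);
* the linear force response ``<x> = Re^2 f / 2`` (thermal units).

A kink-resolved Monte-Carlo sampler provides the brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import i0, i1
from scipy.stats import poisson

from semiflex.wlc import WLCEnsemble, _re2_closed, _rg2_closed

__all__ = [
    "ArcArcSystem",
    "DeflectionDistribution",
    "kink_statistics",
    "deflection_pdf",
    "correlation_and_moments",
    "partition_function_laplace",
    "sample_chain",
    "sample_deflection_angles",
    "linear_extension",
]


@dataclass(frozen=True)
class ArcArcSystem:
    """Parameters of the arc/arc model.

    ``S``: contour length; ``b``: microscopic step; ``omega``: arc
    curvature magnitude (1/length); ``ell``: flexural persistence length;
    ``E_kink``: kink energy in thermal units.
    """

    S: float
    b: float
    omega: float
    ell: float
    E_kink: float

    def __post_init__(self) -> None:
        for name in ("S", "b", "omega", "ell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.S / self.b < 1:
            raise ValueError("need S/b >= 1")

    @property
    def mean_kinks(self) -> float:
        """Mean kink number ``<k> = (S/b) exp(-E)``."""
        return (self.S / self.b) * np.exp(-self.E_kink)


@dataclass
class DeflectionDistribution:
    """Deflection-angle distribution on a uniform grid.

    ``theta_grid`` holds cell midpoints of a uniform partition and
    ``density`` the cell-averaged continuous part (the square-root edge
    behavior at ``|theta| = omega S`` makes point values converge slowly,
    cell averages are exact to quadrature accuracy).  ``atom_weight`` is
    the mass of each delta component at ``theta = +/- omega S`` (zero once
    the flexural convolution has smeared the atoms into the continuous
    part).
    """

    theta_grid: np.ndarray
    density: np.ndarray
    atom_weight: float
    support: float  # omega * S

    @property
    def cell_width(self) -> float:
        return float(self.theta_grid[1] - self.theta_grid[0])

    def total_mass(self) -> float:
        return 2.0 * self.atom_weight + float(self.density.sum()) * self.cell_width

    def cdf(self, theta):
        """Cumulative distribution, atoms included as steps."""
        h = self.cell_width
        edges = np.concatenate(
            [self.theta_grid - h / 2.0, [self.theta_grid[-1] + h / 2.0]]
        )
        cums = np.concatenate([[0.0], np.cumsum(self.density) * h])
        out = np.interp(theta, edges, cums)
        th = np.asarray(theta, dtype=float)
        out = out + self.atom_weight * (
            (th >= -self.support).astype(float) + (th >= self.support)
        )
        return out

    def moment(self, order: int) -> float:
        m = float(np.sum(self.density * self.theta_grid**order)) * self.cell_width
        if self.atom_weight:
            m += self.atom_weight * (
                self.support**order + (-self.support) ** order
            )
        return m


def kink_statistics(sys: ArcArcSystem, tail: float = 1e-12):
    """Mean kink number and its Poisson pmf.

    Returns ``(mean_k, k_values, pmf)`` with the pmf truncated where the
    upper tail drops below ``tail``.
    """
    mean_k = sys.mean_kinks
    kmax = max(int(poisson.isf(tail, mean_k)) + 1, 2) if mean_k > 0 else 2
    k = np.arange(kmax + 1)
    return mean_k, k, poisson.pmf(k, mean_k)


def _bulk_density(theta, sys: ArcArcSystem):
    """Continuous part of the kink-gas deflection distribution.

    ``(a / 2 Theta) e^{-a} [I0(a w) + I1(a w) / w]`` with ``a = <k>``,
    ``Theta = omega S``, ``w = sqrt(1 - (theta/Theta)^2)``; the removable
    ``w -> 0`` singularity of the ``I1`` term has the finite limit
    ``a / 2``.
    """
    a = sys.mean_kinks
    Theta = sys.omega * sys.S
    th_hat = np.asarray(theta, dtype=float) / Theta
    inside = np.abs(th_hat) < 1.0
    w = np.sqrt(np.clip(1.0 - th_hat**2, 0.0, None))
    z = a * w
    # I1(z)/w = a * I1(z)/z -> a/2 as z -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(z > 1e-8, i1(z) / np.where(w > 0, w, 1.0), a / 2.0)
    dens = (a / (2.0 * Theta)) * np.exp(-a) * (i0(z) + ratio)
    return np.where(inside, dens, 0.0)


def _cell_averaged_bulk(edges, sys: ArcArcSystem, n_gauss: int = 8):
    """Cell averages of the bulk density, integrated in the arcsine
    variable ``theta = Theta sin(alpha)`` where the integrand is smooth
    through the support edges."""
    from numpy.polynomial.legendre import leggauss

    Theta = sys.omega * sys.S
    lo = np.clip(edges[:-1], -Theta, Theta)
    hi = np.clip(edges[1:], -Theta, Theta)
    a_lo = np.arcsin(lo / Theta)
    a_hi = np.arcsin(hi / Theta)
    x, w = leggauss(n_gauss)
    mid = 0.5 * (a_hi + a_lo)
    half = 0.5 * (a_hi - a_lo)
    alpha = mid[:, None] + half[:, None] * x[None, :]
    theta = Theta * np.sin(alpha)
    vals = _bulk_density(theta.ravel(), sys).reshape(theta.shape)
    integ = Theta * np.sum(vals * np.cos(alpha) * w[None, :], axis=1) * half
    return integ / np.diff(edges)


def deflection_pdf(
    sys: ArcArcSystem,
    with_flexure: bool = False,
    n_grid: int = 8000,
    pad_sigmas: float = 8.0,
) -> DeflectionDistribution:
    """Deflection-angle distribution of the arc/arc chain.

    Without flexure the result is the compact-support Bessel bulk plus two
    atoms ``exp(-<k>)/2`` at ``+/- omega S``.  With flexure the bulk is
    convolved (FFT) with the Gaussian ``G(theta)`` of variance ``S/ell``
    and the atoms are convolved analytically into shifted Gaussians; the
    grid is refined automatically until ``sigma_G`` spans at least 4 grid
    steps.  Densities are cell averages on a uniform grid; see
    :class:`DeflectionDistribution`.
    """
    Theta = sys.omega * sys.S
    atom = np.exp(-sys.mean_kinks) / 2.0
    if not with_flexure:
        edges = np.linspace(-Theta, Theta, n_grid + 1)
        dens = _cell_averaged_bulk(edges, sys)
        mids = 0.5 * (edges[:-1] + edges[1:])
        return DeflectionDistribution(mids, dens, atom, Theta)
    from scipy.special import erf

    sigma = np.sqrt(sys.S / sys.ell)
    lo, hi = -Theta - pad_sigmas * sigma, Theta + pad_sigmas * sigma
    n = n_grid
    while (hi - lo) / n > sigma / 4.0:
        n *= 2
    edges = np.linspace(lo, hi, n + 1)
    d = edges[1] - edges[0]
    mids = 0.5 * (edges[:-1] + edges[1:])
    bulk = _cell_averaged_bulk(edges, sys)
    half_k = int(np.ceil(pad_sigmas * sigma / d))
    kern_edges = (np.arange(-half_k, half_k + 2) - 0.5) * d
    kern = np.diff(erf(kern_edges / (np.sqrt(2.0) * sigma))) / 2.0
    kern /= kern.sum()  # discrete mass exactly 1
    dens = fftconvolve(bulk, kern / d, mode="same") * d
    for center in (-Theta, Theta):
        cell_mass = np.diff(
            erf((edges - center) / (np.sqrt(2.0) * sigma))
        ) / 2.0
        dens += atom * cell_mass / d
    return DeflectionDistribution(mids, dens, 0.0, Theta)


def _complex_rates(sys: ArcArcSystem):
    """Decay rates ``1/(2 ell_1)``, ``1/(2 ell_2)`` and the discriminant root."""
    a = np.exp(-sys.E_kink) / sys.b  # kink flip rate per unit length
    disc = 1.0 - (sys.omega * sys.b) ** 2 * np.exp(2.0 * sys.E_kink)
    root = np.sqrt(complex(disc))
    r1 = a * (1.0 - root) + 1.0 / (2.0 * sys.ell)
    r2 = a * (1.0 + root) + 1.0 / (2.0 * sys.ell)
    return r1, r2, root


def correlation_and_moments(sys: ArcArcSystem, s=None, imag_tol: float = 1e-9):
    """Tangent correlation and chain dimensions of the arc/arc chain.

    Returns ``(s, C, Re2, Rg2)``.  ``C(s)`` is the two-exponential closed
    form; ``Re2``/``Rg2`` are the matching combinations of the 2D WLC
    closed forms at the complex persistence lengths ``ell_1``, ``ell_2``.
    Imaginary parts must vanish to within ``imag_tol`` (relative); they
    are then discarded.
    """
    if s is None:
        s = np.linspace(0.0, sys.S, 513)
    s = np.asarray(s, dtype=float)
    r1, r2, root = _complex_rates(sys)
    A1 = 0.5 + 0.5 / root
    A2 = 0.5 - 0.5 / root
    C = A1 * np.exp(-r1 * s) + A2 * np.exp(-r2 * s)
    ell1, ell2 = 1.0 / (2.0 * r1), 1.0 / (2.0 * r2)
    Re2 = A1 * _re2_closed(2.0 * ell1, sys.S) + A2 * _re2_closed(2.0 * ell2, sys.S)
    Rg2 = A1 * _rg2_closed(2.0 * ell1, sys.S) + A2 * _rg2_closed(2.0 * ell2, sys.S)
    for val, name in ((C, "C"), (np.atleast_1d(Re2), "Re2"),
                      (np.atleast_1d(Rg2), "Rg2")):
        scale = np.maximum(np.abs(val), 1.0)
        if np.any(np.abs(np.imag(val)) / scale > imag_tol):
            raise FloatingPointError(f"imaginary part of {name} too large")
    return s, np.real(C), float(np.real(Re2)), float(np.real(Rg2))


def partition_function_laplace(sys: ArcArcSystem, q, p):
    """Fourier-Laplace partition function of the bare kink gas.

    ``Z(q, p) = (p + e^-E) / (p^2 + q^2 omega^2 b^2 - e^-2E)`` with ``p``
    conjugate to ``n = s / b`` (flexural fluctuations excluded -- they
    factor out).  Serves as the transform-domain cross-check of the
    deflection statistics.
    """
    e = np.exp(-sys.E_kink)
    q = np.asarray(q, dtype=complex)
    p = np.asarray(p, dtype=complex)
    return (p + e) / (p**2 + q**2 * sys.omega**2 * sys.b**2 - e**2)


def partition_function_s(sys: ArcArcSystem, q, n):
    """Unnormalized kink-gas partition sum in the arc-length domain.

    Inverse Laplace of ``Z(q, p)`` by residues:
    ``Z(q, n) = [(r+a) e^{rn} + (r-a) e^{-rn}] / (2r)`` with
    ``a = e^{-E}`` and ``r = sqrt(a^2 - q^2 omega^2 b^2)``.
    ``Z(0, n) = e^{a n}`` counts kink configurations; the normalized
    characteristic function of the deflection angle is ``Z(q,n)/Z(0,n)``.
    """
    a = np.exp(-sys.E_kink)
    q = np.asarray(q, dtype=complex)
    r = np.sqrt(a**2 - q**2 * sys.omega**2 * sys.b**2)
    n = np.asarray(n, dtype=float)
    return ((r + a) * np.exp(r * n) + (r - a) * np.exp(-r * n)) / (2.0 * r)


def _signed_arc_sums(k_counts, S, rng):
    """Signed time integral of the alternating curvature sign per chain.

    For a chain with kinks at sorted positions ``s_1 < ... < s_k``:
    ``T = (-1)^k S + 2 sum_j (-1)^{j+1} s_j`` (starting sign +1).
    """
    T = np.empty(len(k_counts))
    for k in np.unique(k_counts):
        idx = np.nonzero(k_counts == k)[0]
        if k == 0:
            T[idx] = S
            continue
        pos = np.sort(rng.uniform(0.0, S, size=(len(idx), k)), axis=1)
        signs = np.where(np.arange(1, k + 1) % 2 == 1, 1.0, -1.0)
        T[idx] = (-1.0) ** k * S + 2.0 * pos @ signs
    return T


def sample_deflection_angles(
    sys: ArcArcSystem, n_samples: int, seed: int, with_flexure: bool = True
):
    """Fast sampler of the end-deflection angle ``theta(S)``.

    Exactly equivalent in law to integrating full chains: kink count
    Poisson, positions uniform, initial curvature sign ``+/- omega`` with
    probability 1/2, plus (optionally) the flexural Gaussian of variance
    ``S / ell``.
    """
    rng = np.random.default_rng(seed)
    k = rng.poisson(sys.mean_kinks, size=n_samples)
    T = _signed_arc_sums(k, sys.S, rng)
    sign0 = rng.choice([-1.0, 1.0], size=n_samples)
    theta = sign0 * sys.omega * T
    if with_flexure:
        theta = theta + rng.normal(0.0, np.sqrt(sys.S / sys.ell), size=n_samples)
    return theta


def sample_chain(
    sys: ArcArcSystem, n_chains: int, seed: int, with_flexure: bool = True
) -> WLCEnsemble:
    """Sample full arc/arc chains as discrete planar chains.

    Per chain the kink count is Poisson(``<k>``), kink positions uniform
    on ``(0, S)``, the initial curvature sign ``+/- omega`` equiprobable
    and flipped at every kink; the tangent angle integrates the signed
    curvature plus Gaussian flexural increments of variance ``b / ell``.
    """
    if n_chains < 1:
        raise ValueError("need n_chains >= 1")
    rng = np.random.default_rng(seed)
    n_steps = int(round(sys.S / sys.b))
    mids = (np.arange(n_steps) + 0.5) * sys.b
    theta = np.empty((n_chains, n_steps))
    k_counts = rng.poisson(sys.mean_kinks, size=n_chains)
    sign0 = rng.choice([-1.0, 1.0], size=n_chains)
    for i in range(n_chains):
        k = k_counts[i]
        if k:
            pos = np.sort(rng.uniform(0.0, sys.S, size=k))
            flips = np.searchsorted(pos, mids)
            sign = sign0[i] * (-1.0) ** flips
        else:
            sign = np.full(n_steps, sign0[i])
        det = sign * sys.omega * sys.b
        # bond angles at segment midpoints (second-order accurate positions)
        bond = np.cumsum(det) - det / 2.0
        if with_flexure:
            bond = bond + np.cumsum(
                rng.normal(0.0, np.sqrt(sys.b / sys.ell), size=n_steps)
            )
        theta[i] = bond
    return WLCEnsemble(theta, b=sys.b, seed=seed)


def linear_extension(sys: ArcArcSystem, f: float) -> float:
    """Linear-response extension ``<x> = Re^2 f / 2`` (thermal units)."""
    _, _, Re2, _ = correlation_and_moments(sys, s=np.array([0.0]))
    return Re2 * f / 2.0
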