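"""Worm-like chains at an adsorbing flat wall.

Loops (wall-to-wall fragments) and tails (end fragments) govern the
structure of both reversible adsorption layers and irreversibly
chemisorbed layers.  For an ideal semiflexible chain the fragment
statistical weights are power laws,

    Z_loop ~ s^(-5/2)  (stiff, s < ~2 ell),   ~ s^(-3/2)  (flexible)
    Z_tail ~ s^(-1/4)  (stiff, s < ~ell),     ~ s^(-1/2)  (flexible)

the stiff exponents reflecting the extra orientational constraint at the
wall.  Superposing stiff loops yields the proximal concentration profile
``c(z) ~ z^(-4/3)`` for ``b < z < ell``.

Chemisorption (irreversible, reaction-limited binding with intrinsic
frequency ``q``) proceeds by zipping in steps of the minimal-loop size
``s0 = (ell b^2)^(1/3)`` at rate ``q s0 / b``, competing with the
nucleation of large adsorption loops whose rate integrates the
equilibrium wall-contact probability

    P(s) ~ 1                              (s < s0)
    P(s) ~ (s/s0)^(-5/2)                  (s0 < s < ell)
    P(s) ~ (ell/s0)^(-5/2) (s/ell)^(-3/2) (s > ell).

Zipping of a single front is preempted by large-loop nucleation beyond
the chain length ``S* = ell^(5/3) b^(-2/3)``.  All scaling relations here
carry unit prefactors and are order-of-magnitude statements; tests treat
them as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AdsorptionSystem",
    "fragment_weight",
    "sample_loop_statistics",
    "LoopStatistics",
    "proximal_profile",
    "loop_height",
    "sample_proximal_heights",
    "adsorption_thresholds",
    "chemisorption_scales",
    "contact_probability",
    "contact_probability_integral",
    "simulate_zipping",
    "zipping_crossover",
    "crossing_statistics",
    "layered_profile",
]


@dataclass(frozen=True)
class AdsorptionSystem:
    """Chain and wall parameters for adsorption problems.

    ``ell``: persistence length; ``b``: monomer size (also the reaction
    distance for chemisorption); ``S``: chain length; ``Delta``: range of
    the adsorption potential; ``u``: adsorption strength (thermal units);
    ``q``: intrinsic reaction frequency; ``c2inf``: final 2D monomer
    concentration of the irreversible layer.
    """

    ell: float
    b: float = 1.0
    S: float = 100.0
    Delta: float = 0.1
    u: float = 1.0
    q: float = 1.0
    c2inf: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ell", "b", "S", "Delta", "u", "q", "c2inf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.b > self.ell:
            raise ValueError("semiflexible regime requires b <= ell")

    @property
    def s0(self) -> float:
        return (self.ell * self.b**2) ** (1.0 / 3.0)

    @property
    def S_star(self) -> float:
        return self.ell ** (5.0 / 3.0) * self.b ** (-2.0 / 3.0)


# ---------------------------------------------------------------------------
# fragment weights and contact probability (piecewise power laws)

_EXPONENTS = {
    "loop": (-2.5, -1.5),  # stiff, flexible
    "tail": (-0.25, -0.5),
}
_CROSSOVER_FACTOR = {"loop": 2.0, "tail": 1.0}  # crossover at 2*ell / ell


def fragment_weight(s, sys: AdsorptionSystem, kind: str = "loop"):
    """Relative statistical weight of a loop or tail of size ``s``.

    Piecewise power law with continuous matching at the stiff/flexible
    crossover (``2 ell`` for loops, ``ell`` for tails); normalized to 1 at
    the crossover.  Vectorized in ``s``.
    """
    if kind not in _EXPONENTS:
        raise ValueError("kind must be 'loop' or 'tail'")
    a_stiff, a_flex = _EXPONENTS[kind]
    sc = _CROSSOVER_FACTOR[kind] * sys.ell
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("fragment size must be positive")
    return np.where(s <= sc, (s / sc) ** a_stiff, (s / sc) ** a_flex)


def contact_probability(s, sys: AdsorptionSystem):
    """Equilibrium wall-contact probability ``P(s)`` (relative units).

    Three regimes continuous at ``s0`` and ``ell``:
    ``1``; ``(s/s0)^(-5/2)``; ``(ell/s0)^(-5/2) (s/ell)^(-3/2)``.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("s must be positive")
    s0, ell = sys.s0, sys.ell
    A = (ell / s0) ** -2.5
    out = np.ones_like(s)
    mid = (s > s0) & (s <= ell)
    out[mid] = (s[mid] / s0) ** -2.5
    far = s > ell
    out[far] = A * (s[far] / ell) ** -1.5
    return out if out.ndim else float(out)


def contact_probability_integral(s, sys: AdsorptionSystem):
    """Closed-form ``int_0^s P(u) du`` for the three-regime contact law."""
    s0, ell = sys.s0, sys.ell
    A = (ell / s0) ** -2.5
    s = np.asarray(s, dtype=float)
    I1 = np.minimum(s, s0)
    u = np.clip(s, s0, ell)
    I2 = s0 * (1.0 - (u / s0) ** -1.5) / 1.5
    v = np.maximum(s, ell)
    I3 = A * ell * (1.0 - (v / ell) ** -0.5) / 0.5
    return I1 + I2 + I3


# ---------------------------------------------------------------------------
# Monte-Carlo loop statistics

@dataclass
class LoopStatistics:
    """Result of the wall-contact Monte Carlo.

    ``s``: node arc lengths; ``P``: equilibrium contact probability of a
    wall-avoiding grafted chain (contact = node height < b), corrected for
    the finite remainder-tail weight; ``stiff_slope``/``flex_slope``:
    fitted log-log exponents with their fit windows; ``n_survivors``:
    chains that avoided the wall over the full length.
    """

    s: np.ndarray
    P: np.ndarray
    stiff_slope: float
    flex_slope: float
    stiff_window: tuple
    flex_window: tuple
    n_survivors: int


def _fit_loglog(s, y, lo, hi, what=""):
    mask = (s >= lo) & (s <= hi) & (y > 0)
    if mask.sum() < 4:
        warnings.warn(f"too few points in {what} window [{lo}, {hi}]; widening")
        order = np.argsort(np.abs(s - 0.5 * (lo + hi)))
        mask = np.zeros_like(mask)
        mask[order[:6]] = True
        mask &= y > 0
    return float(np.polyfit(np.log(s[mask]), np.log(y[mask]), 1)[0])


def sample_loop_statistics(
    sys: AdsorptionSystem,
    n_chains: int = 2_000_000,
    seed: int = 0,
    launch_angle: float = 0.0,
    chunk: int | None = None,
) -> LoopStatistics:
    """Monte-Carlo loop statistics of a grafted semiflexible chain.

    Discrete 2D worm-like chains are launched from the wall (first node at
    height 0, initial tangent in-plane plus an optional ``launch_angle``)
    and the hard wall is enforced by rejection: only chains with all node
    heights positive contribute.  The equilibrium contact probability
    ``P(s) = Prob(height(s) < b | wall avoided)`` is then proportional to
    ``Z_loop(s) Z_tail(S - s)``; dividing out the known flexible-tail
    weight ``(S - s)^(-1/2)`` isolates the loop exponent.  Log-log slopes
    are fitted in the stiff window ``[4 b, ell]`` and the flexible window
    ``[8 ell, 0.8 S]`` -- the flexible-loop asymptote requires ``s >> ell``
    (crossover tails bias shallower fits at ``s`` of a few ``ell``).

    Note: conditioning on the chain's future survival is essential -- it
    selects near-grazing returns, which is exactly the orientational
    constraint in the stiff-loop weight.  An unconditioned first-passage
    count decays with a different (first-passage) exponent.
    """
    if sys.S < 20 * sys.b:
        raise ValueError("need S >= 20 b")
    n_steps = int(round(sys.S / sys.b))
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(sys.b / sys.ell)
    if chunk is None:
        chunk = max(10_000, int(3.0e7 / n_steps))  # keep working set ~ hundreds of MB
    num = np.zeros(n_steps + 1)
    den = 0
    for start in range(0, n_chains, chunk):
        m = min(chunk, n_chains - start)
        th = rng.normal(0.0, sigma, size=(m, n_steps)).astype(np.float32)
        np.cumsum(th, axis=1, out=th)
        if launch_angle:
            th += np.float32(launch_angle)
        np.sin(th, out=th)
        y = np.cumsum(th, axis=1)  # heights in units of b
        del th
        survived = np.min(y, axis=1) > 0.0
        den += int(survived.sum())
        num[1:] += (y[survived] < 1.0).sum(axis=0)
        del y
    if den == 0:
        raise RuntimeError("no surviving chains; increase n_chains")
    s = np.arange(n_steps + 1) * sys.b
    P = num / den
    # finite-chain correction: divide out the remainder-tail weight
    Pc = P.copy()
    Pc[1:-1] /= (sys.S - s[1:-1]) ** -0.5
    stiff_w = (4.0 * sys.b, sys.ell)
    flex_w = (8.0 * sys.ell, 0.8 * sys.S)
    stiff = _fit_loglog(s[1:], P[1:], *stiff_w, what="stiff")
    flex = _fit_loglog(s[1:-1], Pc[1:-1], *flex_w, what="flexible")
    return LoopStatistics(s, P, stiff, flex, stiff_w, flex_w, den)


# ---------------------------------------------------------------------------
# proximal profile

def loop_height(s, sys: AdsorptionSystem):
    """Typical height reached by a stiff loop: ``z = s^(3/2) / ell^(1/2)``."""
    s = np.asarray(s, dtype=float)
    return s**1.5 / np.sqrt(sys.ell)


def proximal_profile(z, sys: AdsorptionSystem):
    """Proximal-layer concentration ``c(z) ~ z^(-4/3)``.

    Normalized to unit integral over ``[b, ell]``.  Heights outside the
    proximal range return NaN (flagged).
    """
    z = np.asarray(z, dtype=float)
    lo, hi = sys.b, sys.ell
    # normalization: int_b^ell z^(-4/3) dz = 3 (b^(-1/3) - ell^(-1/3))
    norm = 3.0 * (lo ** (-1.0 / 3.0) - hi ** (-1.0 / 3.0))
    c = z ** (-4.0 / 3.0) / norm
    out = np.where((z >= lo) & (z <= hi), c, np.nan)
    return out if out.ndim else float(out)


def sample_proximal_heights(
    sys: AdsorptionSystem, n: int = 100_000, seed: int = 0
):
    """Monte-Carlo superposition of stiff loops.

    Loop sizes are drawn on ``[b, ell]`` with density proportional to
    ``Z_loop(s) * s ~ s^(-3/2)`` (each loop of size ``s`` holds ``~s``
    monomers) and mapped to heights ``z = s^(3/2) / ell^(1/2)``; the
    histogram of ``z`` realizes the proximal profile and its log-log slope
    approximates -4/3.
    """
    rng = np.random.default_rng(seed)
    a, c = sys.b, sys.ell
    # inverse CDF for density ~ s^(-3/2) on [a, c]
    u = rng.uniform(size=n)
    Fa, Fc = a ** -0.5, c ** -0.5
    sizes = (Fa - u * (Fa - Fc)) ** -2.0
    return loop_height(sizes, sys)


# ---------------------------------------------------------------------------
# thresholds and chemisorption scales

def adsorption_thresholds(sys: AdsorptionSystem):
    """Critical strength, reduced distance and layer thickness.

    ``uc = (Delta^2 ell)^(-1/3)`` (unit prefactor), ``tau = (u - uc)/uc``;
    strong adsorption (``h = Delta / tau^(3/2) < ell``) requires
    ``tau > (Delta/ell)^(2/3)``.  Returns a dict with ``uc``, ``tau``,
    ``h`` (NaN unless strongly adsorbed) and a ``regime`` label.
    """
    if sys.Delta >= sys.ell:
        raise ValueError("potential range Delta must be < ell")
    uc = (sys.Delta**2 * sys.ell) ** (-1.0 / 3.0)
    tau = (sys.u - uc) / uc
    if sys.u <= uc:
        return {"uc": uc, "tau": tau, "h": np.nan, "regime": "not adsorbed"}
    strong = tau > (sys.Delta / sys.ell) ** (2.0 / 3.0)
    h = sys.Delta / tau**1.5 if strong else np.nan
    return {
        "uc": uc,
        "tau": tau,
        "h": h,
        "regime": "strong" if strong else "weak",
    }


def chemisorption_scales(ell: float, b: float):
    """Chemisorption length scales (unit prefactors).

    ``s0 = (ell b^2)^(1/3)``: minimal zipping-loop size;
    ``S* = ell^(5/3) b^(-2/3)``: chain length beyond which large-loop
    nucleation preempts single-front zipping.
    """
    if ell <= 0 or b <= 0:
        raise ValueError("ell and b must be positive")
    return (ell * b**2) ** (1.0 / 3.0), ell ** (5.0 / 3.0) * b ** (-2.0 / 3.0)


# ---------------------------------------------------------------------------
# zipping kinetic Monte Carlo

@dataclass
class ZippingResult:
    """Outcome statistics of the zipping/nucleation competition."""

    n_runs: int
    n_preempted: int
    preempt_fraction: float
    nucleation_sizes: np.ndarray  # sizes of the preempting loops


def _preempt_step_probs(sys: AdsorptionSystem, S: float):
    """Per-zip-step preemption probabilities along the front ladder.

    The front descends ``R = S, S - s0, ...``; between zip events (rate
    ``q s0 / b``) a *large* loop may nucleate with rate
    ``Q_n(R) = (q / b) int P(s) ds`` over flexible-scale loops spanning at
    least half the unzipped remainder (``max(ell, R/2) < s < R``).
    Smaller nucleation events merely create extra local zipping centers
    and do not preempt completion.
    """
    s0 = sys.s0
    r_zip = sys.q * s0 / sys.b
    R = np.arange(S, s0, -s0)
    lo = np.maximum(sys.ell, R / 2.0)
    Qn = np.where(
        R > lo,
        (sys.q / sys.b)
        * (contact_probability_integral(R, sys)
           - contact_probability_integral(lo, sys)),
        0.0,
    )
    return R, Qn / (r_zip + Qn)


def simulate_zipping(
    sys: AdsorptionSystem, n_runs: int = 400, seed: int = 0, S: float | None = None
) -> ZippingResult:
    """Gillespie competition between zipping and large-loop nucleation.

    Each run starts from a single bond and zips in steps of size ``s0``.
    With rates frozen between events, the embedded ladder of front
    positions is deterministic, so the first preemption event is sampled
    exactly from the per-step probabilities (inverse-CDF on the cumulative
    hazard); the preempting loop size is then drawn from the contact law
    ``P(s)`` restricted to ``(max(ell, R/2), R)``.  Returns the fraction
    of runs in which a distant nucleation precedes zip completion.
    """
    if S is None:
        S = sys.S
    if S <= sys.s0:
        raise ValueError("chain shorter than one zipping step")
    rng = np.random.default_rng(seed)
    R, p = _preempt_step_probs(sys, S)
    log_surv = np.cumsum(np.log1p(-p))
    surv = np.exp(log_surv[-1])
    u = rng.uniform(size=n_runs)
    preempted = u > surv
    sizes = []
    if preempted.any():
        # step index at which preemption happened
        targets = np.log(u[preempted])
        idx = np.searchsorted(-log_surv, -targets)
        idx = np.clip(idx, 0, len(R) - 1)
        for i in idx:
            lo = max(sys.ell, R[i] / 2.0)
            sizes.append(_draw_loop_size(sys, lo, R[i], rng))
    n_pre = int(preempted.sum())
    return ZippingResult(n_runs, n_pre, n_pre / n_runs, np.asarray(sizes))


def _draw_loop_size(sys: AdsorptionSystem, lo: float, hi: float, rng):
    """Inverse-CDF draw from ``P(s)`` restricted to ``(lo, hi)``.

    In the preemption range ``lo >= ell`` so only the flexible branch
    ``~ s^(-3/2)`` contributes.
    """
    u = rng.uniform()
    Fa, Fb = lo**-0.5, hi**-0.5
    return float((Fa - u * (Fa - Fb)) ** -2.0)


def zipping_crossover(
    sys: AdsorptionSystem,
    n_runs: int = 400,
    seed: int = 0,
    span: float = 1.2,
    n_S: int = 13,
):
    """Chain length at which nucleation preempts half the zipping runs.

    Sweeps ``S`` logarithmically around ``S*`` and interpolates the 50%
    point of the preempted fraction.  Returns ``(S_cross, S_grid,
    fractions)``.
    """
    Ss = sys.S_star * np.logspace(-span, span, n_S)
    fr = np.array(
        [
            simulate_zipping(sys, n_runs=n_runs, seed=seed + j, S=S).preempt_fraction
            for j, S in enumerate(Ss)
        ]
    )
    i = int(np.argmax(fr >= 0.5))
    if i == 0 or not (fr >= 0.5).any():
        return float("nan"), Ss, fr
    x = np.interp(0.5, fr[i - 1 : i + 1], np.log(Ss[i - 1 : i + 1]))
    return float(np.exp(x)), Ss, fr


# ---------------------------------------------------------------------------
# crossing statistics and layered profile

def crossing_statistics(theta, sys: AdsorptionSystem):
    """Crossing-angle statistics of sequentially chemisorbed stiff chains.

    Two straight adsorbed lines that cross do so with angle distribution
    ``P(theta) = sin(theta) / 2`` on ``(0, pi)`` (parallel lines never
    cross); the most likely crossing angle is ``pi/2``.  Bending over to
    align instead of crossing is only favorable for incidence angles below
    ``theta_max = (b / ell)^(1/3)``; doubling the small-angle cumulative
    ``theta^2 / 4`` by symmetry gives the alignment probability.

    Returns a dict with ``pdf``, ``cdf``, ``theta_max`` and
    ``alignment_probability``.
    """
    th = np.asarray(theta, dtype=float)
    if np.any((th <= 0) | (th >= np.pi)):
        raise ValueError("crossing angle must lie in (0, pi)")
    pdf = np.sin(th) / 2.0
    cdf = (1.0 - np.cos(th)) / 2.0
    theta_max = (sys.b / sys.ell) ** (1.0 / 3.0)
    align = 1.0 - np.cos(min(theta_max, np.pi))  # 2 * cumulative, ~ theta_max^2/2
    return {
        "pdf": pdf if pdf.ndim else float(pdf),
        "cdf": cdf if cdf.ndim else float(cdf),
        "theta_max": theta_max,
        "alignment_probability": float(align),
    }


def layered_profile(z, sys: AdsorptionSystem):
    """Concentration profile of the irreversibly built layer.

    Three regimes with continuity enforced at the interior boundaries:
    linear growth ``c ~ c2inf z`` for ``z < 1/(c2inf b)`` (dense stiff
    lines), ``c ~ z^(-2)`` for ``1/(c2inf b) < z < ell`` (larger stiff
    loops), and ``c ~ z^(-1)`` for ``ell < z < sqrt(S ell)`` (flexible
    loops).  Beyond ``sqrt(S ell)`` the profile is controlled by grafted
    tails and NaN is returned (flag).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("height z must be positive")
    z1 = 1.0 / (sys.c2inf * sys.b)
    z2 = sys.ell
    z_out = np.sqrt(sys.S * sys.ell)
    c1 = sys.c2inf * np.minimum(z, z1)
    A2 = sys.c2inf * z1 * z1**2  # continuity at z1
    c2 = A2 / np.clip(z, z1, z2) ** 2
    A3 = A2 / z2  # continuity at z2
    c3 = A3 / np.clip(z, z2, None)
    out = np.where(z <= z1, c1, np.where(z <= z2, c2, c3))
    out = np.where(z > z_out, np.nan, out)
    return out if out.ndim else float(out)
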