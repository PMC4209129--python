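"""Steady states of the starved system, stability, and fate regimes.

With the external supply removed (``x7 = 0``) the normalized system
always admits the extinction state ``x3 = 0``.  Every positive steady
state satisfies the scalar balance

    f_left(x3)  = C * (1 + k13)/(sigma + k13) * (sigma*x3**g13 + k13)/(x3**g13 + k13)
    f_right(x3) = (1 + k23)**(2m - n) * (x3/(x3 + k23))**(2m - n)
    f_left(x3)  = f_right(x3)

obtained by eliminating ``x1`` and ``x2`` at equilibrium.  ``f_left`` is
monotone decreasing (repression relaxes as the amino acid disappears);
``f_right`` is monotone increasing precisely when the critical bias
``n - 2m`` is negative.  The intersection pattern therefore yields three
regimes:

* safe (``n <= 2m``): one positive root, stable; extinction unstable;
* bistable (``2m < n < m_c``): two positive roots — the upper stable, the
  lower unstable — with extinction also stable;
* fatal (``n > m_c``): no positive root; extinction is the only outcome.

``m_c`` is the saddle-node value of ``n`` at which the two positive roots
coalesce; :func:`find_critical_n` locates it by bisection in a continuous
``n``.

Stability of interior roots is read off the eigenvalues of the numerical
Jacobian of the full three-variable system.  At the origin that
linearization is structurally degenerate (every ``x3``-dependent term
vanishes faster than linearly when ``m, n, g13 > 1``, leaving eigenvalues
``{-A, 0, 0}``), so the extinction state is classified on the slow
manifold instead: the sign of ``f_left - f_right`` as ``x3 -> 0+`` gives
the direction of the reduced flow, positive meaning net production (zero
root repelling), negative meaning net demand (zero root attracting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .dynamics import NormalizedParameters, growth_rate, jacobian, rhs, _transcription, _saturation

__all__ = [
    "SteadyRoot",
    "SteadyStateReport",
    "f_left",
    "f_right",
    "find_steady_states",
    "classify_stability",
    "find_critical_n",
    "regime_map",
]

#: bounds of the root scan: below the floor a root is indistinguishable
#: from extinction at solver precision; above x3 = 1 no root can exist
#: once the external supply is gone.
X3_FLOOR = 1e-8
X3_CEIL = 10.0


def f_left(x3: float, p: NormalizedParameters) -> float:
    """Left side of the steady-state balance: repressible supply curve."""
    if x3 <= 0:
        raise ValueError("f_left is defined for x3 > 0 (x3 = 0 is the trivial root)")
    u = x3 ** p.g13
    return p.C * (1.0 + p.k13) / (p.sigma + p.k13) * (p.sigma * u + p.k13) / (u + p.k13)


def f_right(x3: float, p: NormalizedParameters) -> float:
    """Right side of the steady-state balance: demand curve, exponent 2m - n."""
    if x3 <= 0:
        raise ValueError("f_right is defined for x3 > 0 (x3 = 0 is the trivial root)")
    e = 2.0 * p.m - p.n
    return ((1.0 + p.k23) * x3 / (x3 + p.k23)) ** e


def _log_gap(x3: float, p: NormalizedParameters) -> float:
    """log f_left - log f_right; same zeros as the balance, overflow-safe."""
    u = x3 ** p.g13
    logL = (np.log(p.C) + np.log1p(p.k13) - np.log(p.sigma + p.k13)
            + np.log(p.sigma * u + p.k13) - np.log(u + p.k13))
    e = 2.0 * p.m - p.n
    logR = e * (np.log1p(p.k23) + np.log(x3) - np.log(x3 + p.k23))
    return logL - logR


@dataclass(frozen=True)
class SteadyRoot:
    """One steady state of the starved system."""

    x3: float
    x1: float
    x2: float
    stability: str            # 'stable' | 'unstable' | 'marginal'
    degenerate: bool = False  # tangential (saddle-node) double root
    growth: float = 0.0       # normalized growth rate mu/muM at the root


@dataclass
class SteadyStateReport:
    """All steady states at one parameter set, with the fate regime."""

    params: NormalizedParameters
    roots: list = field(default_factory=list)  # SteadyRoot, ascending in x3
    regime: str = ""                           # 'safe' | 'bistable' | 'fatal' | 'degenerate'

    @property
    def positive_roots(self) -> list:
        return [r for r in self.roots if r.x3 > 0 and not r.degenerate]

    @property
    def stable_positive(self) -> list:
        return [r for r in self.positive_roots if r.stability == "stable"]


def _full_state(x3: float, p: NormalizedParameters) -> tuple[float, float]:
    """Reconstruct (x1, x2) at a positive root from the equilibrium relations."""
    x1 = _transcription(x3, p)
    x2 = _saturation(x3, p) ** p.m / p.C
    return x1, x2


def classify_stability(state, p: NormalizedParameters, tol: float = 1e-9) -> str:
    """Stability of a full steady state by linearization.

    Central-difference numerical Jacobian of the starved vector field
    (step ``1e-7 * max(|xi|, 1)`` per coordinate); ``stable`` iff every
    eigenvalue real part is below ``-tol``, ``unstable`` iff any exceeds
    ``+tol``, otherwise ``marginal`` — reported, never silently binned.
    """
    state = np.asarray(state, dtype=float)
    J = np.empty((3, 3))
    for j in range(3):
        step = 1e-7 * max(abs(state[j]), 1.0)
        hi = state.copy(); hi[j] += step
        lo = state.copy(); lo[j] = max(lo[j] - step, 0.0)
        J[:, j] = (rhs(hi, p, 0.0) - rhs(lo, p, 0.0)) / (hi[j] - lo[j])
    eig = np.linalg.eigvals(J)
    if np.all(eig.real < -tol):
        return "stable"
    if np.any(eig.real > tol):
        return "unstable"
    return "marginal"


def _zero_root_stability(p: NormalizedParameters) -> str:
    """Stability of the extinction state via the reduced flow near 0+.

    The linearization at the origin is degenerate for m, n, g13 > 1, so the
    sign of f_left - f_right just above the scan floor decides: net
    production (positive gap) repels trajectories from extinction; net
    demand attracts them.
    """
    gap = _log_gap(X3_FLOOR, p)
    if gap > 1e-9:
        return "unstable"
    if gap < -1e-9:
        return "stable"
    return "marginal"


def find_steady_states(
    p: NormalizedParameters,
    n_grid: int = 4000,
    x3_min: float = X3_FLOOR,
    x3_max: float = X3_CEIL,
) -> SteadyStateReport:
    """Locate and classify every steady state of the starved system.

    Scans the log gap of the scalar balance for sign changes on a
    log-spaced grid over ``[x3_min, x3_max]``, polishes each bracket with
    Brent's method to 1e-12, de-duplicates at relative tolerance 1e-6,
    reconstructs the full state at each root, appends the extinction root
    and classifies stability.  Tangential (double) roots — detected by a
    vanishing derivative of the gap — are flagged degenerate and excluded
    from regime counting.
    """
    grid = np.logspace(np.log10(x3_min), np.log10(x3_max), n_grid)
    gap = np.array([_log_gap(x, p) for x in grid])
    roots: list[float] = []
    for i in np.flatnonzero(np.sign(gap[:-1]) * np.sign(gap[1:]) < 0):
        r = brentq(_log_gap, grid[i], grid[i + 1], args=(p,), xtol=1e-12, rtol=8.9e-16)
        roots.append(float(r))
    # points where the gap is numerically zero on the grid (tangencies)
    for i in np.flatnonzero(gap == 0.0):
        roots.append(float(grid[i]))
    roots.sort()
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-6 * max(abs(r), 1e-30):
            dedup.append(r)

    out: list[SteadyRoot] = []
    for r in dedup:
        # tangency check: derivative of the gap at the root
        eps = 1e-6 * r
        dgap = (_log_gap(r + eps, p) - _log_gap(r - eps, p)) / (2 * eps)
        degenerate = abs(dgap) < 1e-8
        x1, x2 = _full_state(r, p)
        stab = classify_stability((x1, x2, r), p) if not degenerate else "marginal"
        if stab == "marginal" and not degenerate:
            # the slow eigenvalue scales like h(x3)**m and can sit far below
            # any fixed numerical band while its sign is still well defined;
            # resolve it on the slow manifold: the reduced flow moves x3 up
            # where production exceeds demand, so a root is stable iff the
            # gap crosses from + to - (negative slope).
            stab = "unstable" if dgap > 0 else "stable"
        out.append(SteadyRoot(x3=r, x1=x1, x2=x2, stability=stab,
                              degenerate=degenerate, growth=growth_rate(r, p)))

    zero = SteadyRoot(x3=0.0, x1=_transcription(0.0, p), x2=0.0,
                      stability=_zero_root_stability(p), degenerate=False, growth=0.0)
    report = SteadyStateReport(params=p, roots=[zero] + out)
    report.regime = _classify_regime(report)
    return report


def _classify_regime(report: SteadyStateReport) -> str:
    pos = report.positive_roots
    zero = report.roots[0]
    if len(pos) == 1 and pos[0].stability == "stable" and zero.stability == "unstable":
        return "safe"
    if (len(pos) == 2 and pos[1].stability == "stable"
            and pos[0].stability == "unstable" and zero.stability == "stable"):
        return "bistable"
    if len(pos) == 0 and zero.stability == "stable":
        return "fatal"
    return "degenerate"


def find_critical_n(
    p: NormalizedParameters,
    n_lo: float | None = None,
    n_hi: float | None = None,
    tol: float = 1e-3,
) -> float:
    """Saddle-node threshold m_c of the critical-enzyme cognate count.

    Treats ``n`` as continuous and bisects between a lower bracket where
    positive roots exist (default ``n = 2m``) and an upper bracket where
    none do (default ``n = 3m``) for the point where the two positive
    roots coalesce and vanish.  Beyond m_c starvation is always fatal.
    """
    n_lo = 2.0 * p.m if n_lo is None else float(n_lo)
    n_hi = 3.0 * p.m if n_hi is None else float(n_hi)

    def has_positive(n: float) -> bool:
        return len(find_steady_states(p.with_n(n)).positive_roots) > 0

    if not has_positive(n_lo):
        raise ValueError(f"invalid bracket: no positive roots at n = {n_lo}")
    if has_positive(n_hi):
        raise ValueError(f"invalid bracket: positive roots persist at n = {n_hi}")
    while n_hi - n_lo > tol:
        mid = 0.5 * (n_lo + n_hi)
        if has_positive(mid):
            n_lo = mid
        else:
            n_hi = mid
    return 0.5 * (n_lo + n_hi)


def regime_map(p: NormalizedParameters, n_values, m_values):
    """Fate regime over a grid of (n, m), with the critical bias n - 2m.

    Returns a pandas DataFrame with columns ``n``, ``m``,
    ``critical_bias`` and ``regime``.  Sanity-checks the analytic
    guarantee that ``n <= 2m`` is always safe.
    """
    import pandas as pd
    import dataclasses as _dc

    rows = []
    for m in m_values:
        for n in n_values:
            q = _dc.replace(p, m=float(m), n=float(n))
            rep = find_steady_states(q)
            if n <= 2 * m and rep.regime != "safe":
                raise AssertionError(
                    f"n={n}, m={m}: n <= 2m must be safe, got {rep.regime}")
            rows.append({"n": float(n), "m": float(m),
                         "critical_bias": float(n - 2 * m), "regime": rep.regime})
    return pd.DataFrame(rows)
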