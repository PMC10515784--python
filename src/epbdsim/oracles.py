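"""Independent equilibrium references for tiny systems.

The Metropolis sampler targets the Boltzmann distribution restricted to the
hard displacement bounds.  For one or two base pairs that distribution can
be integrated numerically to machine-level accuracy, giving an oracle that
is completely independent of the sampling code: any expectation the sampler
estimates (mean opening, opening probability beyond a threshold, the
2-bp joint opening that seeds the bubble tensor) must agree with these
quadratures within Monte-Carlo error.

All quadratures integrate over exactly the sampler's bounded domain, so
the comparison involves no truncation mismatch.  They are also exposed to
users who want to validate a custom parameter file.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import integrate

from .model import KB_EV_PER_K, SiteParameters, morse_potential, stacking_potential


def _split_points(lo: float, hi: float, extra=()) -> list[float]:
    pts = [lo] + [p for p in extra if lo < p < hi] + [hi]
    return sorted(set(pts))


def _quad_piecewise(f: Callable[[float], float], lo: float, hi: float, extra=()) -> float:
    """Adaptive quadrature split at the well mouth and any thresholds."""
    pts = _split_points(lo, hi, extra)
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        val, _ = integrate.quad(f, a, b, limit=200, epsabs=1e-12, epsrel=1e-10)
        total += val
    return total


def boltzmann_average_custom(
    potential: Callable[[float], float],
    T: float,
    bounds: tuple[float, float],
    observable: Callable[[float], float],
    kB: float = KB_EV_PER_K,
) -> float:
    """<f(y)> under exp(-U(y)/kB T) for an arbitrary 1-D potential U."""
    lo, hi = bounds
    beta = 1.0 / (kB * T)

    def weight(y):
        return np.exp(-beta * potential(y))

    z = _quad_piecewise(weight, lo, hi, extra=(0.0,))
    num = _quad_piecewise(lambda y: observable(y) * weight(y), lo, hi, extra=(0.0,))
    return num / z


def boltzmann_average_1bp(
    D: float,
    a: float,
    T: float,
    bounds: tuple[float, float],
    observable: Callable[[np.ndarray], np.ndarray],
    kB: float = KB_EV_PER_K,
) -> float:
    """<f(y)> under exp(-V(y)/kB T) on the bounded domain, V the Morse well."""
    return boltzmann_average_custom(
        lambda y: morse_potential(y, D, a), T, bounds, observable, kB=kB
    )


def opening_probability_1bp(
    D: float,
    a: float,
    T: float,
    bounds: tuple[float, float],
    thr: float,
    kB: float = KB_EV_PER_K,
) -> float:
    """Pr[y > thr] for an isolated base pair, by exact-subdomain quadrature."""
    lo, hi = bounds
    beta = 1.0 / (kB * T)

    def weight(y):
        return np.exp(-beta * morse_potential(y, D, a))

    z = _quad_piecewise(weight, lo, hi, extra=(0.0,))
    if thr >= hi:
        return 0.0
    num = _quad_piecewise(weight, max(thr, lo), hi, extra=(0.0,))
    return num / z


def _gl_segment(lo: float, hi: float, res: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(res)
    half = 0.5 * (hi - lo)
    return lo + half * (x + 1.0), half * w


def _gl_grid(lo: float, hi: float, res: int) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise Gauss-Legendre nodes, dense across the Morse well.

    The Boltzmann weight varies on the ~0.1 Å scale near the well and is
    flat on the plateau, so half the nodes cover [lo, 1.5] and half the
    remainder.
    """
    split = 1.5
    if hi <= split or lo >= split:
        return _gl_segment(lo, hi, res)
    x1, w1 = _gl_segment(lo, split, res // 2)
    x2, w2 = _gl_segment(split, hi, res - res // 2)
    return np.concatenate([x1, x2]), np.concatenate([w1, w2])


def _boltzmann_weight_2bp(sp: SiteParameters, T: float, y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    beta = 1.0 / (sp.kB * T)
    e = (
        morse_potential(y1, sp.D[0], sp.a[0])
        + morse_potential(y2, sp.D[1], sp.a[1])
        + stacking_potential(y2, y1, sp.k[0], sp.rho, sp.b)
    )
    return np.exp(-beta * e)


def boltzmann_average_2bp(
    sp: SiteParameters,
    T: float,
    observable: Callable[[np.ndarray, np.ndarray], np.ndarray],
    res: int = 1200,
) -> float:
    """<f(y1, y2)> for a stacking-coupled base-pair dimer.

    Tensor-product Gauss-Legendre quadrature with ``res`` nodes per
    dimension (default 1200, well past self-convergence for smooth
    observables).  ``sp`` must describe exactly two base pairs.
    """
    if sp.n != 2:
        raise ValueError("boltzmann_average_2bp needs site parameters for N=2")
    x1, w1 = _gl_grid(sp.y_min, sp.y_max, res)
    x2, w2 = _gl_grid(sp.y_min, sp.y_max, res)
    Y1, Y2 = np.meshgrid(x1, x2, indexing="ij")
    W = np.outer(w1, w2)
    rho_w = _boltzmann_weight_2bp(sp, T, Y1, Y2) * W
    z = rho_w.sum()
    return float((observable(Y1, Y2) * rho_w).sum() / z)


def joint_opening_probability_2bp(
    sp: SiteParameters, T: float, thr: float, res: int = 1200
) -> float:
    """Pr[y1 > thr and y2 > thr] for the dimer.

    The indicator's discontinuity is handled exactly by integrating the
    numerator over the sub-square [thr, y_max]^2 with its own nodes.
    """
    if sp.n != 2:
        raise ValueError("joint_opening_probability_2bp needs site parameters for N=2")
    if thr >= sp.y_max:
        return 0.0
    lo = max(thr, sp.y_min)

    x1, w1 = _gl_grid(sp.y_min, sp.y_max, res)
    Y1, Y2 = np.meshgrid(x1, x1, indexing="ij")
    z = (_boltzmann_weight_2bp(sp, T, Y1, Y2) * np.outer(w1, w1)).sum()

    xs, ws = _gl_grid(lo, sp.y_max, res)
    Y1s, Y2s = np.meshgrid(xs, xs, indexing="ij")
    num = (_boltzmann_weight_2bp(sp, T, Y1s, Y2s) * np.outer(ws, ws)).sum()
    return float(num / z)


def marginal_mean_2bp(sp: SiteParameters, T: float, which: int, res: int = 1200) -> float:
    """<y_1> or <y_2> (``which`` in {0, 1}) for the dimer."""
    if which not in (0, 1):
        raise ValueError("which must be 0 or 1")
    return boltzmann_average_2bp(sp, T, lambda y1, y2: (y1, y2)[which], res=res)
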