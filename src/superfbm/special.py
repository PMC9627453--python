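"""Special functions: Krätzel Z, M-Wright/Mainardi M, and a Mellin-Barnes route.

The displacement density of the superstatistical fBm collapses, in the
dimensionless variable ``u = x^2 / (4 lambda0 t^(2H))``, onto

    P(u) = rho / Gamma(nu/rho) * (4 pi u)**(-1/2) * Z_rho^(nu - 1/2)(u)

where ``Z_rho^v(u) = int_0^inf s**(v-1) exp(-u/s - s**rho) ds`` is the Krätzel
function.  The same density admits a Mellin-Barnes contour representation with
kernel ``Gamma(s) * Gamma((s + v)/rho)`` (v = nu - 1/2), which this module
evaluates independently as a cross-checking oracle.  The M-Wright function
furnishes the fundamental solutions of the competing ggBm and CTRW models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath as mp
import numpy as np
from scipy import integrate, optimize
from scipy import special as sc

__all__ = [
    "KratzelQuery",
    "MWrightQuery",
    "kratzel_z",
    "mwright",
    "mellin_barnes_density",
]


@dataclass(frozen=True)
class KratzelQuery:
    """Argument triple of the Krätzel function Z_rho^nu_eff(u)."""

    nu_eff: float
    rho: float
    u: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rho) and self.rho > 0):
            raise ValueError("rho must be positive")
        if not (np.isfinite(self.u) and self.u >= 0):
            raise ValueError("u must be non-negative")
        if self.u == 0.0 and self.nu_eff <= 0.0:
            raise ValueError("Kratzel integral diverges at u=0 for nu_eff <= 0")


@dataclass(frozen=True)
class MWrightQuery:
    """Argument pair of the M-Wright function M_beta(z), 0 < beta < 1."""

    beta: float
    z: float

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < 1.0):
            raise ValueError("beta must lie in (0, 1)")
        if not (np.isfinite(self.z) and self.z >= 0.0):
            raise ValueError("z must be non-negative")


# ---------------------------------------------------------------------------
# Krätzel function
# ---------------------------------------------------------------------------

def _kratzel_mode(nu_eff: float, rho: float, u: float) -> float:
    """Stationary point of the log-integrand (nu-1)log s - u/s - s**rho.

    Solved on a log bracket; used only to split the quadrature domain, so a
    rough root suffices.
    """
    def dlog(ls: float) -> float:
        s = math.exp(ls)
        return (nu_eff - 1.0) + u / s - rho * s ** rho

    lo, hi = -40.0, 40.0 / max(rho, 1.0)
    if dlog(lo) <= 0.0:  # integrand decreasing from the origin
        return math.exp(lo)
    try:
        return math.exp(optimize.brentq(dlog, lo, hi, xtol=1e-10))
    except ValueError:
        return 1.0


def kratzel_z(q: KratzelQuery) -> float:
    """Krätzel function by adaptive quadrature split at the integrand's mode.

    Relative accuracy ~1e-8 over the argument range used by the densities.
    For extreme u the integrand is a narrow peak far from the origin; the
    split plus a log-scaled outer panel keeps quad from missing it.
    """
    v, rho, u = q.nu_eff, q.rho, q.u
    if u == 0.0:
        return float(sc.gamma(v / rho) / rho)

    mode = _kratzel_mode(v, rho, u)
    peak_log = (v - 1.0) * math.log(mode) - u / mode - mode ** rho

    def f(s: float) -> float:
        with np.errstate(over="ignore"):
            return math.exp((v - 1.0) * math.log(s) - u / s - s ** rho - peak_log)

    left, el = integrate.quad(f, 0.0, mode, epsabs=0.0, epsrel=1e-10, limit=200)
    right, er = integrate.quad(f, mode, np.inf, epsabs=0.0, epsrel=1e-10, limit=200)
    return math.exp(peak_log) * (left + right)


def kratzel(nu_eff: float, rho: float, u: float) -> float:
    """Convenience wrapper building the query inline."""
    return kratzel_z(KratzelQuery(nu_eff=nu_eff, rho=rho, u=u))


# ---------------------------------------------------------------------------
# M-Wright / Mainardi function
# ---------------------------------------------------------------------------

def _mwright_series_mp(beta: float, z: float) -> float:
    """Arbitrary-precision summation of M_beta(z) = sum (-z)^n / (n! Gamma(1-beta-n beta)).

    The series is entire but catastrophically cancelling for large z in double
    precision; working digits grow with z so that the returned double is
    correct to ~1e-12 relative.
    """
    # cancellation: the largest term exceeds the (stretched-exponentially
    # small) result by roughly exp(z + (1-beta) z**(1/(1-beta))) in magnitude
    extra = int(0.5 * z + 0.5 * (1.0 - beta) * z ** (1.0 / (1.0 - beta))) + 10
    if extra > 2000:  # pragma: no cover - guarded by the underflow gate
        raise RuntimeError("M-Wright series precision request out of range")
    with mp.workdps(30 + max(0, extra)):
        zb = mp.mpf(z)
        b = mp.mpf(beta)
        total = mp.mpf(0)
        term_scale = mp.mpf(1)
        n = 0
        small = 0
        while True:
            garg = -n * b + (1 - b)
            # reciprocal gamma handles the poles at non-positive integers
            term = (-zb) ** n / mp.factorial(n) * mp.rgamma(garg)
            total += term
            if abs(term) < mp.mpf(10) ** (-(mp.mp.dps - 5)) * max(1, abs(total)):
                small += 1
                if small >= 5:
                    break
            else:
                small = 0
            n += 1
            if n > 100000:  # pragma: no cover - safety valve
                raise RuntimeError("M-Wright series failed to converge")
        return float(total)


def mwright(q: MWrightQuery | None = None, *, beta: float | None = None,
            z: float | None = None) -> float:
    """M-Wright (Mainardi) function M_beta(z) for beta in (0,1), z >= 0.

    M_{1/2}(z) = exp(-z^2/4)/sqrt(pi) (the Gaussian case) is dispatched to the
    closed form; otherwise the alternating series is summed in adaptive
    arbitrary precision, which stays accurate on z in [0, 30] and beyond.
    """
    if q is None:
        q = MWrightQuery(beta=beta, z=z)
    if abs(q.beta - 0.5) < 1e-14:
        return math.exp(-q.z ** 2 / 4.0) / math.sqrt(math.pi)
    # leading decay exponent b z**(1/(1-beta)), b = (1-beta) beta**(beta/(1-beta));
    # once it underflows double precision, return 0 instead of summing an
    # astronomically cancelling series
    b = (1.0 - q.beta) * q.beta ** (q.beta / (1.0 - q.beta))
    if b * q.z ** (1.0 / (1.0 - q.beta)) > 700.0:
        return 0.0
    return _mwright_series_mp(q.beta, q.z)


# ---------------------------------------------------------------------------
# Mellin-Barnes contour integral for the rescaled density P(u)
# ---------------------------------------------------------------------------

def mellin_barnes_pu(u: float, nu: float, rho: float) -> float:
    """Rescaled displacement density P(u) via its Mellin-Barnes representation.

    P(u) = 1/Gamma(nu/rho) * (4 pi)**(-1/2) * (1/2 pi i)
           * int_L Gamma(s) Gamma((s + nu - 1/2)/rho) u**(-s) ds / u**(1/2)

    written here directly in terms of the Mellin pair of u**(-1/2) Z(u):
    the contour L is the vertical line Re(s) = c with c to the right of the
    poles of both Gamma factors (s = -n and s = 1/2 - nu - rho n), truncated
    at |Im s| = T with T grown until the tail is negligible.  Independent of
    the Krätzel quadrature route, hence usable as its oracle.
    """
    if not (u > 0.0):
        raise ValueError("u must be positive")
    v = nu - 0.5
    c = max(0.0, -v) + 0.5
    # pole check: c must avoid s = -n and (s+v)/rho = -n
    if min(abs(c + np.arange(0, 4)).min(), abs(c + v + rho * np.arange(0, 4)).min()) < 1e-9:
        raise ValueError("contour Re(s) placement hits a pole; adjust parameters")

    logu = math.log(u)

    def integrand(tau: float) -> float:
        s = complex(c, tau)
        val = sc.gamma(s) * sc.gamma((s + v) / rho) * np.exp(-s * logu)
        return val.real

    # |Gamma(c+i tau)| decays like exp(-pi |tau| / 2); the second factor adds
    # exp(-pi |tau| / (2 rho)).  Grow T until the endpoint integrand is tiny.
    T = 10.0
    while abs(integrand(T)) > 1e-12 and T < 2000.0:
        T *= 2.0
    total, _ = integrate.quad(integrand, 0.0, T, epsabs=1e-13, epsrel=1e-11, limit=400)
    contour = total / math.pi  # symmetry: integral over (-T, 0) mirrors (0, T)
    return contour / (sc.gamma(nu / rho) * math.sqrt(4.0 * math.pi * u))


def mellin_barnes_density(u: float, p) -> float:
    """Normalized density of u for a ModelParams via the Mellin-Barnes route.

    Twice the half-line contour value (both signs of x fold onto one u), so it
    integrates to 1 over (0, inf) and matches ``densities.pdf_u`` directly.
    """
    return 2.0 * mellin_barnes_pu(u, p.nu, p.rho)
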