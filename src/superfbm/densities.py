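"""Displacement densities of the competing anomalous-diffusion models.

Superstatistical fBm: the marginal displacement PDF is the Gaussian kernel of
the fBm, variance ``2 lam t^(2H)``, mixed over the generalized Gamma
population of scales,

    P(x; t) = int_0^inf G(x; t | lam) f(lam) dlam
            = rho / Gamma(nu/rho) * (4 pi lambda0 t^(2H))**(-1/2)
              * Z_rho^(nu-1/2)(x^2 / (4 lambda0 t^(2H))),

with the Krätzel function Z.  Its variance is ``2 <lam> t^(2H)``; in the
rescaled variable u the density P(u) behaves as u^d with
d = min(-1/2, nu - 1) near 0 and decays like a stretched exponential with
index rho/(rho+1) at infinity.  The comparison models, ggBm and CTRW, have
M-Wright fundamental solutions in the self-similar variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import special as sc

from .params import ModelParams, ScalePopulation, gengamma_mean, gengamma_pdf
from .special import KratzelQuery, MWrightQuery, kratzel_z, mellin_barnes_pu, mwright

__all__ = [
    "superstat_pdf",
    "gaussian_kernel",
    "pdf_u",
    "displacement_variance",
    "asymptotic_exponents",
    "ggbm_pdf",
    "ctrw_pdf",
    "ggbm_lambda_pdf",
]

ROUTES = ("mixture", "kratzel", "mellin-barnes")


def gaussian_kernel(x: float, t: float, lam: float, H: float) -> float:
    """Gaussian fBm kernel with variance 2 lam t^(2H) (the conditional law)."""
    if t <= 0:
        raise ValueError("t must be positive")
    var = 2.0 * lam * t ** (2.0 * H)
    return math.exp(-x * x / (2.0 * var)) / math.sqrt(2.0 * math.pi * var)


def _u_of(x: float, t: float, p: ModelParams) -> float:
    return x * x / (4.0 * p.lambda0 * t ** (2.0 * p.H))


def superstat_pdf(x: float, t: float, p: ModelParams, route: str = "kratzel") -> float:
    """Displacement density P(x; t) of the superstatistical fBm.

    Three numerically independent routes (cross-checking one another to
    ~1e-6 relative away from x = 0):

    - "mixture": adaptive quadrature of Gaussian kernel x genGamma population;
    - "kratzel": closed Krätzel form (default, fastest);
    - "mellin-barnes": vertical-contour Mellin-Barnes integral.

    At x = 0 the density is finite only for nu > 1/2; for nu <= 1/2 it has an
    integrable power singularity there and evaluation raises.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if route not in ROUTES:
        raise ValueError(f"route must be one of {ROUTES}")
    if x == 0.0 and p.nu <= 0.5:
        raise ValueError(
            "P(0; t) diverges (integrable singularity) for nu <= 1/2; "
            "evaluate at x != 0")
    scale = math.sqrt(4.0 * math.pi * p.lambda0 * t ** (2.0 * p.H))

    if route == "mixture":
        pop = ScalePopulation(p)
        def integrand(lam: float) -> float:
            return gaussian_kernel(x, t, lam, p.H) * gengamma_pdf(lam, pop)
        # split roughly at the population scale to help the adaptive rule
        a, _ = integrate.quad(integrand, 0.0, p.lambda0, epsabs=0.0,
                              epsrel=1e-10, limit=200)
        b, _ = integrate.quad(integrand, p.lambda0, np.inf, epsabs=0.0,
                              epsrel=1e-10, limit=200)
        return a + b

    u = _u_of(x, t, p)
    if route == "kratzel":
        z = kratzel_z(KratzelQuery(nu_eff=p.nu - 0.5, rho=p.rho, u=u))
        return p.rho / sc.gamma(p.nu / p.rho) * z / scale
    # mellin-barnes: contour evaluation of the u-profile, defined for x != 0;
    # the half-line contour value carries (4 pi u)^(-1/2), re-expressed in x
    if u == 0.0:
        raise ValueError("mellin-barnes route requires x != 0")
    return mellin_barnes_pu(u, p.nu, p.rho) * math.sqrt(4.0 * math.pi * u) / scale


def pdf_u(u: float, p: ModelParams) -> float:
    """Rescaled density of u = x^2/(4 lambda0 t^(2H)); free of H and lambda0.

    P(u) = rho/Gamma(nu/rho) * (pi u)^(-1/2) * Z_rho^(nu-1/2)(u),
    normalized to 1 on (0, inf).  This is twice the symmetric half-line
    collapse (4 pi u)^(-1/2) Z(u) form, which folds both signs of x into one
    value of u and hence carries only half the mass.
    """
    if u <= 0:
        raise ValueError("u must be positive")
    z = kratzel_z(KratzelQuery(nu_eff=p.nu - 0.5, rho=p.rho, u=u))
    return p.rho / sc.gamma(p.nu / p.rho) * z / math.sqrt(math.pi * u)


def displacement_variance(t: float, p: ModelParams) -> float:
    """<x^2>(t) = 2 <lam> t^(2H), the exact second moment of P(x; t)."""
    if t <= 0:
        raise ValueError("t must be positive")
    return 2.0 * gengamma_mean(ScalePopulation(p)) * t ** (2.0 * p.H)


@dataclass(frozen=True)
class AsymptoticExponents:
    """Leading exponents of P(u) at the origin and at infinity."""

    small_u: float          # d: P(u) = O(u^d), d = min(-1/2, nu - 1)
    stretch: float          # rho/(rho+1), the stretched-exponential index
    tail_power: float       # (nu - rho - 1)/(rho + 1), tail power prefactor
    degenerate: bool        # nu - 1 == -1/2: double-pole case, exponent only


def asymptotic_exponents(p: ModelParams, tol: float = 1e-12) -> AsymptoticExponents:
    """Exponents of the u->0 and u->inf expansions of the rescaled density."""
    d = min(-0.5, p.nu - 1.0)
    degenerate = abs((p.nu - 1.0) - (-0.5)) < tol
    return AsymptoticExponents(
        small_u=d,
        stretch=p.rho / (p.rho + 1.0),
        tail_power=(p.nu - p.rho - 1.0) / (p.rho + 1.0),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Comparison models: ggBm and CTRW
# ---------------------------------------------------------------------------

def ggbm_pdf(x: float, t: float, lambda0: float, rho: float, H: float) -> float:
    """Fundamental solution of the ggBm fractional diffusion equation.

    P_ggBm(x; t) = 1/2 * (lambda0 t^(2H))^(-1/2)
                   * M_{1/(2 rho)}(|x| / sqrt(lambda0 t^(2H))),
    valid for rho > 1 (so the M-Wright order 1/(2 rho) < 1/2 and the scale
    population order 1/rho lies in (0, 1)).
    """
    if rho <= 1.0:
        raise ValueError("ggbm_pdf requires rho > 1 (0 < 1/rho < 1)")
    if t <= 0:
        raise ValueError("t must be positive")
    s = math.sqrt(lambda0) * t ** H
    return 0.5 / s * mwright(MWrightQuery(beta=1.0 / (2.0 * rho), z=abs(x) / s))


def ctrw_pdf(x: float, t: float, lambda0: float, H: float) -> float:
    """Fundamental solution of the time-fractional (CTRW) diffusion equation.

    P_CTRW(x; t) = 1/2 * (lambda0 t^(2H))^(-1/2)
                   * M_H(|x| / sqrt(lambda0 t^(2H))).
    Coincides with ggbm_pdf at rho = 1/(2H).
    """
    if not (0.0 < H < 1.0):
        raise ValueError("H must lie in (0, 1)")
    if t <= 0:
        raise ValueError("t must be positive")
    s = math.sqrt(lambda0) * t ** H
    return 0.5 / s * mwright(MWrightQuery(beta=H, z=abs(x) / s))


def ggbm_lambda_pdf(lam: float, lambda0: float, rho: float) -> float:
    """M-Wright population of diffusion coefficients of the ggBm.

    f_ggBm(lam) = M_{1/rho}(lam/lambda0) / lambda0, rho > 1; the analogue of
    the generalized Gamma population in the superstatistical model.
    """
    if rho <= 1.0:
        raise ValueError("ggbm_lambda_pdf requires rho > 1")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    return mwright(MWrightQuery(beta=1.0 / rho, z=lam / lambda0)) / lambda0


# ---------------------------------------------------------------------------
# Analytic space/time derivatives of the superstatistical density
# (via d/du Z_rho^v(u) = -Z_rho^(v-1)(u)), used by the equation checks
# ---------------------------------------------------------------------------

def _z(v: float, rho: float, u: float) -> float:
    return kratzel_z(KratzelQuery(nu_eff=v, rho=rho, u=u))


def superstat_dx(x: float, t: float, p: ModelParams) -> float:
    """Exact first x-derivative of P(x; t) through the Krätzel recurrence."""
    if t <= 0:
        raise ValueError("t must be positive")
    v = p.nu - 0.5
    u = _u_of(x, t, p)
    pref = p.rho / (sc.gamma(p.nu / p.rho)
                    * math.sqrt(4.0 * math.pi * p.lambda0 * t ** (2.0 * p.H)))
    ux = x / (2.0 * p.lambda0 * t ** (2.0 * p.H))
    return -pref * _z(v - 1.0, p.rho, u) * ux


def superstat_dxx(x: float, t: float, p: ModelParams) -> float:
    """Exact second x-derivative of P(x; t) through the Krätzel recurrence."""
    if t <= 0:
        raise ValueError("t must be positive")
    v = p.nu - 0.5
    u = _u_of(x, t, p)
    pref = p.rho / (sc.gamma(p.nu / p.rho)
                    * math.sqrt(4.0 * math.pi * p.lambda0 * t ** (2.0 * p.H)))
    den = 2.0 * p.lambda0 * t ** (2.0 * p.H)
    ux = x / den            # du/dx
    uxx = 1.0 / den         # d2u/dx2
    z1 = _z(v - 1.0, p.rho, u)   # -dZ/du
    z2 = _z(v - 2.0, p.rho, u)   # +d2Z/du2
    return pref * (z2 * ux * ux - z1 * uxx)


def superstat_dt(x: float, t: float, p: ModelParams) -> float:
    """Exact time derivative of P(x; t) through the Krätzel recurrence."""
    if t <= 0:
        raise ValueError("t must be positive")
    v = p.nu - 0.5
    u = _u_of(x, t, p)
    pref = p.rho / (sc.gamma(p.nu / p.rho)
                    * math.sqrt(4.0 * math.pi * p.lambda0 * t ** (2.0 * p.H)))
    z0 = _z(v, p.rho, u)
    z1 = _z(v - 1.0, p.rho, u)
    # P = pref(t) Z(u(t)); dpref/dt = -H/t * pref; du/dt = -2H u / t
    return pref * (-p.H / t) * z0 + pref * (-z1) * (-2.0 * p.H * u / t)
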