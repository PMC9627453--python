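"""Model parameters and the diffusion-coefficient population.

The superstatistical fBm describes each tracer as ``X_t = sqrt(lam) * B_t^H``
with ``B^H`` a standard fractional Brownian motion and ``lam`` a random
diffusion scale drawn, particle by particle, from a generalized Gamma law

    f(lam) = rho / (lam0**nu * Gamma(nu/rho)) * lam**(nu-1) * exp(-(lam/lam0)**rho)

which contains the Weibull (nu == rho), Gamma (rho == 1) and exponential
(nu == rho == 1) families as special cases.  All closed-form results are
written in the scale variable ``lam``; the amplitude variable ``Y = sqrt(lam)``
only appears at the simulator/inference boundary, where single-particle
tracking work usually reports a Weibull law for Y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import special, stats

__all__ = [
    "ModelParams",
    "ScalePopulation",
    "PRESETS",
    "golding_cox_preset",
    "gengamma_pdf",
    "gengamma_mean",
    "gengamma_sample",
    "amplitude_law",
]

#: relative tolerance deciding whether nu == rho (the Weibull case changes
#: which fractional Fokker-Planck equation applies, so the flag is explicit)
WEIBULL_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Parameter quadruple (H, lambda0, nu, rho) of the superstatistical fBm.

    Parameters
    ----------
    H : float
        Hurst exponent of the underlying fBm, in (0, 1).  The ensemble MSD
        grows as ``t**(2H)``; subdiffusion corresponds to H < 1/2.
    lambda0 : float
        Scale of the diffusivity population, units length^2 / time^(2H).
    nu : float
        Shape exponent of the generalized Gamma population (power-law part).
    rho : float
        Stretching exponent of the generalized Gamma population.
    """

    H: float
    lambda0: float
    nu: float
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 < self.H < 1.0):
            raise ValueError(f"H must lie in (0, 1), got {self.H}")
        for name in ("lambda0", "nu", "rho"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0.0):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def is_weibull_case(self) -> bool:
        """True when nu == rho to relative tolerance 1e-12 (Weibull population)."""
        scale = max(abs(self.nu), abs(self.rho))
        return abs(self.nu - self.rho) <= WEIBULL_TOL * scale

    def with_nu(self, nu: float) -> "ModelParams":
        return replace(self, nu=nu)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {"H": self.H, "lambda0": self.lambda0, "nu": self.nu, "rho": self.rho}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(H=float(d["H"]), lambda0=float(d["lambda0"]),
                   nu=float(d["nu"]), rho=float(d["rho"]))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def golding_cox_preset() -> ModelParams:
    """Calibrated Weibull-case preset for mRNA tracers in live E. coli.

    2H = 0.70, sqrt(lambda0) = 0.06 and Weibull amplitude shape 2 rho = 1.84,
    i.e. H = 0.35, lambda0 = 0.0036, nu = rho = 0.92.
    """
    return ModelParams(H=0.35, lambda0=0.0036, nu=0.92, rho=0.92)


PRESETS = {"golding-cox": golding_cox_preset}


def resolve_preset(name: str) -> ModelParams:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class ScalePopulation:
    """The population law of the random diffusivity.

    ``representation`` is ``"scale"`` for the law of ``lam`` (the variance
    scale of the Gaussian kernel) or ``"amplitude"`` for the law of
    ``Y = sqrt(lam)``.  Only lambda0, nu, rho of ``params`` are used.
    """

    params: ModelParams
    representation: str = "scale"

    def __post_init__(self) -> None:
        if self.representation not in ("scale", "amplitude"):
            raise ValueError(f"unknown representation {self.representation!r}")

    @property
    def _frozen(self):
        """scipy gengamma frozen distribution: a = nu/rho, c = rho, scale = lambda0."""
        p = self.params
        return stats.gengamma(a=p.nu / p.rho, c=p.rho, scale=p.lambda0)

    def pdf(self, lam):
        return gengamma_pdf(lam, self)

    def mean(self) -> float:
        return gengamma_mean(self)

    def sample(self, n: int, seed) -> np.ndarray:
        return gengamma_sample(self, n, seed)


def gengamma_pdf(lam, pop: ScalePopulation):
    """Generalized Gamma density at ``lam`` (> 0).

    Reduces exactly to Weibull for nu == rho, Gamma for rho == 1 and the
    exponential for nu == rho == 1.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("gengamma_pdf requires lam > 0")
    out = pop._frozen.pdf(lam)
    return float(out) if out.ndim == 0 else out


def gengamma_mean(pop: ScalePopulation) -> float:
    """Population mean <lam> = lambda0 * Gamma((nu+1)/rho) / Gamma(nu/rho)."""
    p = pop.params
    return p.lambda0 * float(special.gamma((p.nu + 1.0) / p.rho)
                             / special.gamma(p.nu / p.rho))


def gengamma_sample(pop: ScalePopulation, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. scales via the exact transform lam = lambda0 * G**(1/rho).

    G is a standard Gamma(nu/rho) variate; the transform is exact (no
    rejection) and reproducible given the seed (an int or a Generator).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = pop.params
    g = rng.standard_gamma(p.nu / p.rho, size=int(n))
    return p.lambda0 * g ** (1.0 / p.rho)


def amplitude_law(pop: ScalePopulation) -> ScalePopulation:
    """Law of the amplitude Y = sqrt(lam) induced by a scale population.

    The change of variable doubles both shape exponents and square-roots the
    scale: generalized Gamma (lambda0, nu, rho) in lam becomes generalized
    Gamma (sqrt(lambda0), 2 nu, 2 rho) in Y.  In the Weibull case nu == rho
    this is the Weibull law with scale sqrt(lambda0) and shape 2 rho, the
    parameterization in which tracking studies report their diffusivity fits.
    """
    if pop.representation != "scale":
        raise ValueError("amplitude_law expects a population in scale representation")
    p = pop.params
    amp = replace(p, lambda0=float(np.sqrt(p.lambda0)), nu=2.0 * p.nu, rho=2.0 * p.rho)
    return ScalePopulation(params=amp, representation="amplitude")
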