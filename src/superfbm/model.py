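"""Model / results interface for fitting the superstatistical fBm to tracks.

``SuperstatFbm`` wraps a trajectory ensemble the way statsmodels wraps a
design matrix: construct from data, call ``fit()``, get a results object with
point estimates, bootstrap standard errors, diagnostics and a ``summary()``
table.  Simulation hangs off the fitted results for parametric-bootstrap or
posterior-predictive style checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import FitResult, fit_pipeline
from .params import ModelParams
from .simulate import TrajectoryEnsemble, simulate_ensemble

__all__ = ["SuperstatFbm", "SuperstatFbmResults"]


class SuperstatFbm:
    """Superstatistical fBm model for a single-particle-tracking ensemble.

    Parameters
    ----------
    ensemble : TrajectoryEnsemble
        Uniformly sampled 1-D trajectories.
    family : str
        Population family for the diffusivity amplitudes:
        "weibull" (default, the calibrated case), "gengamma", "gamma" or
        "exponential".
    lag_range : (int, int), optional
        TA-MSD fit range in step units; defaults to [2, n_steps // 10].
    """

    def __init__(self, ensemble: TrajectoryEnsemble, family: str = "weibull",
                 lag_range: tuple[int, int] | None = None):
        self.ensemble = ensemble
        self.family = family
        self.lag_range = lag_range

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SuperstatFbm":
        """Build the model from a wide-dialect trajectory CSV (+ sidecar)."""
        from .io import read_ensemble
        return cls(read_ensemble(path), **kwargs)

    @classmethod
    def simulate(cls, params: ModelParams, n_traj: int, n_steps: int,
                 dt: float, seed: int, **kwargs) -> "SuperstatFbm":
        """Build the model from a freshly simulated ensemble."""
        ens = simulate_ensemble(params, n_traj, n_steps, dt, seed)
        return cls(ens, **kwargs)

    def fit(self, n_boot: int = 200, seed: int = 0) -> "SuperstatFbmResults":
        res = fit_pipeline(self.ensemble, family=self.family,
                           lag_range=self.lag_range, n_boot=n_boot, seed=seed)
        return SuperstatFbmResults(model=self, _fit=res)


@dataclass(frozen=True)
class SuperstatFbmResults:
    """Fit results: estimates, uncertainties, diagnostics, summary table."""

    model: SuperstatFbm
    _fit: FitResult

    # -- point estimates ---------------------------------------------------
    @property
    def params(self) -> ModelParams:
        return self._fit.params

    @property
    def H(self) -> float:
        return self._fit.H_hat

    @property
    def lambda0(self) -> float:
        return self._fit.lambda0_hat

    @property
    def nu(self) -> float:
        return self._fit.nu_hat

    @property
    def rho(self) -> float:
        return self._fit.rho_hat

    @property
    def amplitude_shape(self) -> float:
        """Weibull shape of the amplitude law Y = sqrt(lam); estimates 2 rho."""
        return self._fit.shape_amplitude

    @property
    def amplitude_scale(self) -> float:
        """Weibull scale of the amplitude law; estimates sqrt(lambda0)."""
        return self._fit.scale_amplitude

    @property
    def bse(self) -> dict:
        return {"H": self._fit.H_se,
                "amplitude_shape": self._fit.shape_se,
                "amplitude_scale": self._fit.scale_se}

    @property
    def scales(self) -> np.ndarray:
        """Per-trajectory diffusion-scale estimates (NaN where excluded)."""
        return self._fit.scales

    @property
    def diagnostics(self) -> dict:
        return dict(self._fit.diagnostics,
                    n_excluded=self._fit.n_excluded,
                    lag_range=self._fit.lag_range,
                    family=self._fit.family)

    def simulate(self, n_traj: int | None = None, n_steps: int | None = None,
                 dt: float | None = None, seed: int = 0) -> TrajectoryEnsemble:
        """Simulate from the fitted parameters (defaults mirror the data)."""
        ens = self.model.ensemble
        return simulate_ensemble(self.params,
                                 n_traj or ens.n_traj,
                                 n_steps or ens.n_steps,
                                 dt or ens.dt, seed)

    def summary(self) -> str:
        f = self._fit
        lines = [
            "Superstatistical fBm fit",
            "=" * 58,
            f"trajectories: {self.model.ensemble.n_traj:>6d}    "
            f"steps: {self.model.ensemble.n_steps}    dt: {self.model.ensemble.dt:g}",
            f"population family: {f.family}    TA-MSD lags: {f.lag_range}",
            "-" * 58,
            f"{'parameter':<22}{'estimate':>12}{'std err':>12}",
            f"{'H (Hurst)':<22}{f.H_hat:>12.4f}{f.H_se:>12.4f}",
            f"{'2H (MSD exponent)':<22}{2 * f.H_hat:>12.4f}{2 * f.H_se:>12.4f}",
        ]
        se = lambda v: f"{v:>12.4f}" if v is not None else f"{'--':>12}"
        lines += [
            f"{'amplitude shape (2rho)':<22}{f.shape_amplitude:>12.4f}{se(f.shape_se)}",
            f"{'amplitude scale':<22}{f.scale_amplitude:>12.4f}{se(f.scale_se)}",
            f"{'lambda0':<22}{f.lambda0_hat:>12.6f}{'--':>12}",
            f"{'nu':<22}{f.nu_hat:>12.4f}{'--':>12}",
            f"{'rho':<22}{f.rho_hat:>12.4f}{'--':>12}",
            "-" * 58,
            f"excluded trajectories: {f.n_excluded}    "
            f"near-homogeneous: {f.diagnostics.get('near_homogeneous')}",
            f"population log-likelihood: {f.diagnostics.get('population_loglike'):.2f}"
            f"    AIC: {f.diagnostics.get('population_aic'):.2f}",
        ]
        return "\n".join(lines)
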