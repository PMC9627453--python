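"""Ensemble simulation of the superstatistical fBm and its TA-MSD diagnostics.

Each trajectory is ``X_t = sqrt(2 lam_i) * B_t^H`` with an independent standard
fBm ``B^H`` (Var B_t = t^(2H)) and an independent scale ``lam_i`` from the
generalized Gamma population, so that conditionally on its scale a trajectory
has exactly the Gaussian kernel variance ``2 lam_i t^(2H)``.  The heterogeneity
of the scales produces the two experimental signatures this module measures:
large trajectory-to-trajectory scatter of the time-averaged MSD (weak
ergodicity breaking) and its suppression when each trajectory is rescaled by
its own amplitude.

fBm paths use Davies-Harte circulant embedding (exact covariance, O(n log n))
with a Cholesky factorization fallback for the rare non-positive-definite
embeddings at H near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import ModelParams, ScalePopulation, gengamma_sample

__all__ = [
    "TrajectoryEnsemble",
    "TAMSDCurve",
    "simulate_fbm",
    "simulate_ensemble",
    "tamsd",
    "ensemble_tamsd",
    "tamsd_scatter",
    "rescale_ensemble",
]

_CHOLESKY_CAP = 1 << 13  # matrix-route fallback size cap


def _fbm_increment_covariance(n: int, H: float, dt: float) -> np.ndarray:
    k = np.arange(n, dtype=float)
    return 0.5 * dt ** (2.0 * H) * (np.abs(k + 1) ** (2 * H)
                                    - 2.0 * np.abs(k) ** (2 * H)
                                    + np.abs(k - 1) ** (2 * H))


def simulate_fbm(n_steps: int, dt: float, H: float, seed,
                 n_paths: int = 1) -> np.ndarray:
    """Standard fBm paths on a uniform grid, Var(B_t) = t^(2H).

    Returns an array of shape (n_paths, n_steps + 1) starting at 0, generated
    by Davies-Harte circulant embedding of the increment covariance; if the
    embedding spectrum is not non-negative (possible only for H close to 1),
    falls back to exact Cholesky factorization, capped at 2^13 steps.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if dt <= 0 or not (0.0 < H < 1.0):
        raise ValueError("need dt > 0 and H in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gamma = _fbm_increment_covariance(n_steps, H, dt)
    # circulant embedding of the Toeplitz increment covariance
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(circ).real
    m = circ.size
    if np.min(eig) >= -1e-12 * np.max(eig):
        eig = np.clip(eig, 0.0, None)
        nf = eig.size
        incs = np.empty((n_paths, n_steps))
        for i in range(n_paths):
            # complex spectral noise with Hermitian-symmetry endpoint handling
            re = rng.standard_normal(nf)
            im = rng.standard_normal(nf)
            w = re + 1j * im
            w[0] = re[0] * np.sqrt(2.0)
            if m % 2 == 0:
                w[-1] = im[-1] * np.sqrt(2.0)
            spec = np.sqrt(eig * m / 2.0) * w
            incs[i] = np.fft.irfft(spec, n=m)[:n_steps]
    else:  # pragma: no cover - only reachable for H near 1
        if n_steps > _CHOLESKY_CAP:
            raise RuntimeError(
                "circulant embedding failed and the Cholesky fallback is "
                f"capped at {_CHOLESKY_CAP} steps")
        idx = np.arange(n_steps)
        cov = _fbm_increment_covariance(np.abs(idx[:, None] - idx[None, :]).max() + 1,
                                        H, dt)[np.abs(idx[:, None] - idx[None, :])]
        L = np.linalg.cholesky(cov + 1e-14 * np.eye(n_steps))
        incs = rng.standard_normal((n_paths, n_steps)) @ L.T
    paths = np.concatenate([np.zeros((n_paths, 1)), np.cumsum(incs, axis=1)], axis=1)
    return paths


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Uniformly sampled trajectory ensemble with optional ground-truth scales."""

    times: np.ndarray                       # (n_steps + 1,)
    positions: np.ndarray                   # (n_traj, n_steps + 1)
    params: ModelParams | None = None
    scales: np.ndarray | None = None        # ground-truth lam_i when simulated
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        x = np.asarray(self.positions, float)
        if x.ndim != 2 or x.shape[1] != t.size:
            raise ValueError("positions must be (n_traj, len(times))")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.scales is not None and np.any(np.asarray(self.scales) <= 0):
            raise ValueError("ground-truth scales must be positive")

    @property
    def n_traj(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[1] - 1

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def simulate_ensemble(p: ModelParams, n_traj: int, n_steps: int, dt: float,
                      seed: int, fixed_lambda: float | None = None
                      ) -> TrajectoryEnsemble:
    """Simulate a superstatistical fBm ensemble X = sqrt(2 lam) * B^H.

    ``fixed_lambda`` replaces the random population by a point mass (the
    homogeneous control, whose marginal is exactly Gaussian).  All randomness
    derives from a single master seed through independent spawned substreams
    (one for the scales, one per trajectory), so enlarging the ensemble does
    not perturb earlier trajectories.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    master = np.random.SeedSequence(seed)
    scale_ss, path_ss = master.spawn(2)
    if fixed_lambda is None:
        lams = gengamma_sample(ScalePopulation(p), n_traj,
                               np.random.default_rng(scale_ss))
    else:
        if fixed_lambda <= 0:
            raise ValueError("fixed_lambda must be positive")
        lams = np.full(n_traj, float(fixed_lambda))
    positions = np.empty((n_traj, n_steps + 1))
    for i, child in enumerate(path_ss.spawn(n_traj)):
        b = simulate_fbm(n_steps, dt, p.H, np.random.default_rng(child))[0]
        positions[i] = np.sqrt(2.0 * lams[i]) * b
    times = np.arange(n_steps + 1, dtype=float) * dt
    return TrajectoryEnsemble(times=times, positions=positions, params=p,
                              scales=lams, seed=seed)


# ---------------------------------------------------------------------------
# TA-MSD diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TAMSDCurve:
    """Time-averaged MSD of one trajectory at a set of integer lags."""

    lags: np.ndarray      # lag times (units of t)
    values: np.ndarray    # TA-MSD per lag (length^2)
    trajectory: int = 0


def tamsd(x: np.ndarray, dt: float, lags_steps) -> TAMSDCurve:
    """Overlapping-window time-averaged MSD of a single trajectory.

    TA-MSD(k dt) = mean_i (x[i+k] - x[i])^2 over all admissible windows;
    overlapping windows use every sample, the common single-particle-tracking
    convention.
    """
    x = np.asarray(x, float)
    lags_steps = np.asarray(lags_steps, int)
    if lags_steps.size == 0:
        raise ValueError("need at least one lag")
    if np.any(lags_steps < 1) or np.any(lags_steps >= x.size):
        raise ValueError("lags must satisfy 1 <= k < n_points")
    vals = np.array([np.mean((x[k:] - x[:-k]) ** 2) for k in lags_steps])
    return TAMSDCurve(lags=lags_steps * dt, values=vals)


def ensemble_tamsd(ens: TrajectoryEnsemble, lags_steps) -> np.ndarray:
    """TA-MSD values for every trajectory, shape (n_traj, n_lags)."""
    return np.vstack([tamsd(ens.positions[i], ens.dt, lags_steps).values
                      for i in range(ens.n_traj)])


def tamsd_scatter(ens: TrajectoryEnsemble, lag_steps: int) -> float:
    """Coefficient of variation of TA-MSD(lag) across trajectories.

    The heterogeneous population keeps this bounded away from the homogeneous
    (fixed-scale) baseline, which shrinks with trajectory length: the weak
    ergodicity-breaking signature.
    """
    if ens.n_traj < 2:
        raise ValueError("scatter needs at least 2 trajectories")
    vals = ensemble_tamsd(ens, [lag_steps])[:, 0]
    return float(np.std(vals, ddof=1) / np.mean(vals))


def rescale_ensemble(ens: TrajectoryEnsemble, ref_lag_steps: int = 10
                     ) -> TrajectoryEnsemble:
    """Divide each trajectory by its estimated amplitude at a reference lag.

    The amplitude estimate is sqrt(TA-MSD(ref_lag)), normalized by the
    ensemble median so the homogeneous case is (approximately) the identity.
    Removing the per-trajectory amplitude suppresses the TA-MSD scatter and
    moves the single-time marginal back toward Gaussian.
    """
    if ens.n_steps < 2 ** 8:
        raise ValueError("rescaling needs >= 2^8 steps for stable amplitudes")
    amp2 = ensemble_tamsd(ens, [ref_lag_steps])[:, 0]
    if np.any(amp2 <= 0):
        raise ValueError("degenerate (all-zero) trajectory cannot be rescaled")
    amp = np.sqrt(amp2)
    amp = amp / np.median(amp)
    return replace(ens, positions=ens.positions / amp[:, None],
                   scales=None)
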