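"""Trajectory ensemble file formats and the seeded fixture generator.

Wide CSV dialect: header ``t, x_000001, x_000002, ...``, one row per time
point, numbers at 17 significant digits (lossless for float64).  A companion
JSON sidecar ``<stem>.json`` records the model parameters, the master seed and
the ground-truth per-trajectory scales; an ensemble loads without it, with
parameters marked unknown.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams, resolve_preset
from .simulate import TrajectoryEnsemble, simulate_ensemble

__all__ = ["write_ensemble", "read_ensemble", "generate_fixtures",
           "FIXTURE_SIZES"]

#: fixture sizes: "tiny" mirrors the 21-trajectory experimental dataset
FIXTURE_SIZES = {"tiny": (21, 2 ** 8), "standard": (500, 2 ** 10)}


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(".json")


def write_ensemble(ens: TrajectoryEnsemble, path) -> Path:
    """Write the wide CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    cols = {"t": ens.times}
    for i in range(ens.n_traj):
        cols[f"x_{i + 1:06d}"] = ens.positions[i]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.17g")
    side = {
        "params": ens.params.to_dict() if ens.params is not None else None,
        "seed": ens.seed,
        "scales": None if ens.scales is None else list(map(float, ens.scales)),
    }
    _sidecar_path(path).write_text(json.dumps(side, indent=2) + "\n")
    return path


def read_ensemble(path) -> TrajectoryEnsemble:
    """Load a wide-dialect CSV (+ sidecar if present) back into an ensemble.

    Raises distinct errors for a malformed header, ragged rows and a
    non-monotone time column.
    """
    path = Path(path)
    try:
        # round_trip parser: 17-significant-digit output must reload bit-exact
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged or malformed CSV row in {path.name}: {exc}") from exc
    if df.columns[0] != "t" or not all(c.startswith("x_") for c in df.columns[1:]):
        raise ValueError(
            f"malformed header in {path.name}: expected 't, x_000001, ...', "
            f"got {list(df.columns[:3])}...")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"ragged row (missing values) at data row {bad} of {path.name}")
    times = df["t"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"non-monotone time column in {path.name}")
    positions = df.iloc[:, 1:].to_numpy(float).T

    params = scales = seed = None
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        if meta.get("params"):
            params = ModelParams.from_dict(meta["params"])
        if meta.get("scales") is not None:
            scales = np.asarray(meta["scales"], float)
        seed = meta.get("seed")
    return TrajectoryEnsemble(times=times, positions=positions, params=params,
                              scales=scales, seed=seed)


def generate_fixtures(preset: str, size: str, seed: int, out_dir) -> Path:
    """Write a deterministic fixture bundle for a named parameter preset.

    "tiny" is 21 trajectories x 2^8 steps (the trajectory count of the
    benchmark experimental dataset); "standard" is 500 x 2^10.  Returns the
    CSV path; the sidecar carries seed, parameters and ground-truth scales.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    n_traj, n_steps = FIXTURE_SIZES[size]
    p = resolve_preset(preset)
    ens = simulate_ensemble(p, n_traj, n_steps, dt=1.0, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return write_ensemble(ens, out_dir / f"{preset}-{size}-seed{seed}.csv")
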