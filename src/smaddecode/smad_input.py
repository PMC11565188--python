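"""Nuclear SMAD2 input signals.

The pathway activity driving every gene-expression model in this package is
the background-subtracted nuclear-to-cytoplasmic SMAD2 ratio, sampled every
few minutes per TGF-beta dose. This module holds the trajectory container,
baseline subtraction, and the shape-preserving interpolant that the ODE
models evaluate at arbitrary solver times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "SmadTrajectory",
    "background_subtract",
    "read_smad_csv",
    "write_smad_csv",
]


@dataclass
class SmadTrajectory:
    """A single-dose nuclear SMAD2 signal.

    Parameters
    ----------
    dose_label : str
        Label of the TGF-beta dose (e.g. ``"2.5pM"``, ``"100pM"``).
    times : array-like
        Sampling times in minutes, strictly increasing, at least 2 samples.
    values : array-like
        Dimensionless background-subtracted nuc/cyt SMAD2 ratio; never
        negative once baseline-subtracted.
    """

    dose_label: str
    times: np.ndarray
    values: np.ndarray
    _interp: PchipInterpolator | None = field(
        default=None, repr=False, compare=False
    )
    _grid_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.values.shape != self.times.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("non-finite time or value in trajectory")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    # -- interpolation ----------------------------------------------------

    def _interpolator(self) -> PchipInterpolator:
        if self._interp is None:
            # PCHIP: monotone shape-preserving cubic; the interpolant never
            # leaves the [min, max] of the bracketing samples, so a
            # nonnegative input stays nonnegative (a natural cubic spline
            # would overshoot and inject spurious negative activity).
            self._interp = PchipInterpolator(self.times, self.values)
        return self._interp

    def interpolate(self, query_times) -> np.ndarray:
        """Evaluate the signal at arbitrary times (minutes).

        Within the sampled range a shape-preserving piecewise-cubic
        interpolant is used; outside it the nearest endpoint value is held
        constant (ODE solvers may step slightly past the last sample).
        """
        t = np.asarray(query_times, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite query time")
        tc = np.clip(t, self.times[0], self.times[-1])
        out = self._interpolator()(tc)
        return out if t.ndim else float(out)

    def __call__(self, t):
        return self.interpolate(t)

    def on_grid(self, step: float, t_end: float) -> tuple[np.ndarray, np.ndarray]:
        """Signal sampled on a uniform grid ``0..t_end`` (cached)."""
        key = (float(step), float(t_end))
        if key not in self._grid_cache:
            n = int(round(t_end / step))
            grid = np.linspace(0.0, t_end, n + 1)
            self._grid_cache[key] = (grid, self.interpolate(grid))
        return self._grid_cache[key]

    @property
    def max_value(self) -> float:
        return float(np.max(self.values))


def background_subtract(
    raw: SmadTrajectory, baseline_window: int | None = None
) -> SmadTrajectory:
    """Subtract the pre-stimulation baseline and clamp at zero.

    The mean of the first ``baseline_window`` samples is removed so the
    unstimulated signal is 0, matching the models' SMAD = 0 steady state;
    negative residuals are clamped to 0 because the Hill activation term is
    only meaningful for nonnegative activity.

    By default the window covers all samples at t <= 0 (and at least the
    first sample).
    """
    if baseline_window is None:
        baseline_window = max(1, int(np.sum(raw.times <= 0.0)))
    if not 1 <= baseline_window < raw.times.size:
        raise ValueError(
            f"baseline_window must be in [1, {raw.times.size - 1}], "
            f"got {baseline_window}"
        )
    baseline = float(np.mean(raw.values[:baseline_window]))
    values = np.maximum(raw.values - baseline, 0.0)
    return SmadTrajectory(raw.dose_label, raw.times.copy(), values)


def read_smad_csv(path) -> dict[str, SmadTrajectory]:
    """Read SMAD trajectories from a CSV with columns time_min, dose, value.

    One file may hold several doses; returns a mapping dose label ->
    trajectory, each sorted by time.
    """
    df = pd.read_csv(path)
    required = {"time_min", "dose", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SMAD CSV missing columns: {sorted(missing)}")
    out: dict[str, SmadTrajectory] = {}
    for dose, grp in df.groupby("dose", sort=False):
        grp = grp.sort_values("time_min")
        out[str(dose)] = SmadTrajectory(
            str(dose),
            grp["time_min"].to_numpy(float),
            grp["value"].to_numpy(float),
        )
    return out


def write_smad_csv(trajectories, path) -> None:
    """Write trajectories (mapping or iterable) to the standard CSV layout."""
    if isinstance(trajectories, dict):
        trajectories = trajectories.values()
    frames = [
        pd.DataFrame(
            {"time_min": tr.times, "dose": tr.dose_label, "value": tr.values}
        )
        for tr in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
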