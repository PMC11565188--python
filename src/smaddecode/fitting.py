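"""Multistart chi-square fitting of expression time courses.

Each gene's two-dose time course (canonically 6 time points x 2 doses,
N = 12 fold changes) is fitted by simulating the chosen ODE model with one
shared parameter vector for both doses and minimizing

    chi2 = sum_i [(y_data(t_i) - y_model(t_i)) / (Delta_r * y_data(t_i))]^2,

the residuals weighted by the relative measurement error Delta_r. The
optimizer is Latin-hypercube multistart (log-uniform over the parameter
bounds) followed by deterministic bounded least squares from every start.
Goodness of fit is a chi-square test at the 95% level; competing accepted
models are discriminated by AIC = chi2 + 2p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist
from scipy.stats import qmc

from .error_model import DEFAULT_REL_ERROR, ErrorModel
from .ode_models import (
    FFL_MODEL_IDS,
    ModelSpec,
    SimulationError,
    get_model,
)
from .smad_input import SmadTrajectory

__all__ = [
    "ExpressionTimeCourse",
    "FitResult",
    "chi2",
    "chi2_test",
    "fit_gene",
    "classify_simple",
    "fit_ffl_cascade",
]

log = logging.getLogger(__name__)

CANONICAL_TIMES = (45.0, 90.0, 180.0, 360.0, 720.0, 1440.0)


@dataclass
class ExpressionTimeCourse:
    """Per-gene fold-change observations over time and dose.

    Fold changes are linear-scale, relative to the unstimulated control
    (so 1 means no change); the t = 0 point is not part of the data.
    """

    gene_id: str
    dose_labels: np.ndarray
    times: np.ndarray
    fold_changes: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.dose_labels = np.asarray(self.dose_labels, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.fold_changes = np.asarray(self.fold_changes, dtype=float)
        n = self.times.size
        if not (self.dose_labels.size == n == self.fold_changes.size):
            raise ValueError("dose_labels, times, fold_changes must align")
        if n == 0:
            raise ValueError("empty time course")
        if np.any(self.fold_changes <= 0):
            raise ValueError(
                f"{self.gene_id}: fold changes must be positive (linear scale)"
            )
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.size != n:
                raise ValueError("sd must align with observations")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def doses(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for d in self.dose_labels:
            seen.setdefault(str(d))
        return tuple(seen)

    def dose_series(self, dose: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, fold changes) of one dose, in time order."""
        mask = self.dose_labels == dose
        if not mask.any():
            raise KeyError(f"{self.gene_id}: no observations for dose {dose!r}")
        order = np.argsort(self.times[mask], kind="stable")
        return self.times[mask][order], self.fold_changes[mask][order]

    @classmethod
    def from_records(cls, gene_id: str, observations, sd=None):
        """Build from a list of (dose_label, time_min, fold_change)."""
        obs = list(observations)
        return cls(
            gene_id,
            np.array([o[0] for o in obs], dtype=object),
            np.array([o[1] for o in obs], dtype=float),
            np.array([o[2] for o in obs], dtype=float),
            sd=None if sd is None else np.asarray(sd, float),
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one model to one gene."""

    gene_id: str
    model_id: str
    best_params: object
    theta: np.ndarray
    chi2: float
    n_points: int
    n_free: int
    dof: int
    critical_value: float
    accepted: bool
    aic: float = field(default=None)  # type: ignore[assignment]
    n_failed_starts: int = 0

    def __post_init__(self):
        if self.aic is None:
            object.__setattr__(self, "aic", self.chi2 + 2.0 * self.n_free)

    def to_row(self) -> dict:
        row = {
            "gene_id": self.gene_id,
            "model_id": self.model_id,
            "chi2": self.chi2,
            "n_points": self.n_points,
            "n_free": self.n_free,
            "dof": self.dof,
            "critical_value": self.critical_value,
            "accepted": self.accepted,
            "aic": self.aic,
        }
        for name, val in zip(_param_names(self), self.theta):
            row[f"param_{name}"] = float(val)
        return row


def _param_names(fr: FitResult) -> tuple[str, ...]:
    return get_model(fr.model_id).param_names


# ---------------------------------------------------------------------------
# chi-square machinery
# ---------------------------------------------------------------------------


def chi2(y_data, y_model, rel_error: float) -> float:
    """Weighted sum of squares with relative-error weights Delta_r * y_data."""
    y_data = np.asarray(y_data, dtype=float)
    y_model = np.asarray(y_model, dtype=float)
    if y_data.shape != y_model.shape:
        raise ValueError("y_data and y_model must have equal length")
    if rel_error <= 0:
        raise ValueError("rel_error must be positive")
    if np.any(y_data == 0):
        raise ValueError("zero data value: chi-square weight undefined")
    r = (y_data - y_model) / (rel_error * y_data)
    return float(np.dot(r, r))


def chi2_test(chi2_value: float, dof: int, alpha: float = 0.05
              ) -> tuple[float, bool]:
    """95%-level goodness-of-fit decision.

    Returns the (1 - alpha) quantile of the chi-square distribution with
    ``dof`` degrees of freedom and whether ``chi2_value`` falls below it
    (model accepted).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    critical = float(chi2_dist.ppf(1.0 - alpha, dof))
    return critical, bool(chi2_value < critical)


# ---------------------------------------------------------------------------
# multistart fitting
# ---------------------------------------------------------------------------


def _lhs_starts(
    lo: np.ndarray, hi: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Latin-hypercube start points, log-uniform within [lo, hi]."""
    sampler = qmc.LatinHypercube(d=lo.size, seed=rng)
    u = sampler.random(n)
    llo, lhi = np.log10(lo), np.log10(hi)
    return llo + u * (lhi - llo)  # log10-scale starts


#: fine-grid step (min) used inside fitting objectives; divides every
#: canonical observation time, so observations sit on exact grid nodes
FIT_SIM_STEP = 2.5


def _make_objective(
    spec: ModelSpec,
    tc: ExpressionTimeCourse,
    smad_by_dose: dict[str, SmadTrajectory],
    rel_error: float,
    sim_step: float = FIT_SIM_STEP,
):
    """Weighted-residual function over log10 parameters, both doses stacked."""
    series = []
    for dose in tc.doses:
        if dose not in smad_by_dose:
            raise KeyError(
                f"{tc.gene_id}: no SMAD trajectory for dose {dose!r}"
            )
        t, y = tc.dose_series(dose)
        series.append((smad_by_dose[dose], t, y, rel_error * y))

    def residuals(z: np.ndarray) -> np.ndarray:
        theta = 10.0 ** z
        out = []
        for smad, t, y, w in series:
            y_model = spec.simulate(theta, smad, t, step=sim_step)
            out.append((y_model - y) / w)
        return np.concatenate(out)

    return residuals


def _refine_starts(
    spec: ModelSpec,
    residuals,
    starts: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> tuple[np.ndarray | None, float, int]:
    """Bounded least squares from every start; returns (best z, chi2, failures).

    Ties (equal chi2) keep the earlier start, so the outcome is a
    deterministic function of the start sequence.
    """
    llo, lhi = np.log10(lo), np.log10(hi)
    best_z, best_chi2, failed = None, np.inf, 0
    for z0 in starts:
        try:
            sol = least_squares(
                residuals, z0, bounds=(llo, lhi), method="trf",
                xtol=1e-8, ftol=1e-8, gtol=1e-8, x_scale="jac",
                max_nfev=100,
            )
            c = 2.0 * sol.cost
        except (SimulationError, ValueError, FloatingPointError):
            failed += 1
            continue
        if not np.isfinite(c):
            failed += 1
            continue
        if c < best_chi2:
            best_z, best_chi2 = sol.x, c
    return best_z, best_chi2, failed


def fit_gene(
    tc: ExpressionTimeCourse,
    model_id: str,
    smad_by_dose: dict[str, SmadTrajectory],
    err: ErrorModel | float | None = None,
    n_starts: int = 500,
    seed=None,
    alpha: float = 0.05,
    dof: int | None = None,
    extra_starts: np.ndarray | None = None,
) -> FitResult:
    """Fit one model to one gene by Latin-hypercube multistart least squares.

    Both doses are fitted simultaneously with one shared parameter vector.
    ``dof`` defaults to N - p (simple models); the FFL cascade passes its
    calibrated effective value instead. ``extra_starts`` prepends warm
    starts (natural-scale parameter vectors) to the LHS draw, used by the
    degrees-of-freedom calibration refits.
    """
    spec = get_model(model_id)
    rel = _rel_error_of(err)
    smad_max = max(s.max_value for s in smad_by_dose.values())
    lo, hi = spec.bounds(smad_max)
    rng = np.random.default_rng(seed)
    starts = _lhs_starts(lo, hi, n_starts, rng) if n_starts > 0 else \
        np.empty((0, lo.size))
    if extra_starts is not None:
        warm = np.log10(np.clip(np.atleast_2d(extra_starts), lo, hi))
        starts = np.vstack([warm, starts])
    residuals = _make_objective(spec, tc, smad_by_dose, rel)
    best_z, best_chi2, failed = _refine_starts(spec, residuals, starts, lo, hi)
    if best_z is None:
        raise RuntimeError(
            f"{tc.gene_id}/{model_id}: all {len(starts)} starts failed "
            f"({failed} failures)"
        )
    n = tc.n_points
    dof_used = (n - spec.n_free) if dof is None else int(dof)
    critical, accepted = chi2_test(best_chi2, dof_used, alpha)
    theta = 10.0 ** best_z
    log.info("fit %s/%s: chi2=%.3g accepted=%s (%d/%d starts failed)",
             tc.gene_id, model_id, best_chi2, accepted, failed, len(starts))
    return FitResult(
        gene_id=tc.gene_id,
        model_id=model_id,
        best_params=spec.make_params(theta),
        theta=theta,
        chi2=best_chi2,
        n_points=n,
        n_free=spec.n_free,
        dof=dof_used,
        critical_value=critical,
        accepted=accepted,
        n_failed_starts=failed,
    )


def _rel_error_of(err) -> float:
    if err is None:
        return DEFAULT_REL_ERROR
    if isinstance(err, ErrorModel):
        return err.rel_error
    return float(err)


def classify_simple(fit_act: FitResult, fit_inh: FitResult) -> str:
    """Mechanism label from the two simple-model fits.

    Both accepted -> lower AIC wins (tie: fewer free parameters); one
    accepted -> that one; neither -> rejected.
    """
    if fit_act.gene_id != fit_inh.gene_id:
        raise ValueError(
            f"mismatched genes: {fit_act.gene_id!r} vs {fit_inh.gene_id!r}"
        )
    if fit_act.accepted and fit_inh.accepted:
        if fit_act.aic == fit_inh.aic:
            winner = fit_act if fit_act.n_free < fit_inh.n_free else fit_inh
        else:
            winner = fit_act if fit_act.aic < fit_inh.aic else fit_inh
        return f"explained_{winner.best_params.variant}"
    if fit_act.accepted:
        return "explained_activation"
    if fit_inh.accepted:
        return "explained_inhibition"
    return "rejected"


def fit_ffl_cascade(
    tc: ExpressionTimeCourse,
    smad_by_dose: dict[str, SmadTrajectory],
    err: ErrorModel | float | None = None,
    dof_effective: int = 6,
    n_starts: int = 500,
    seed=None,
    alpha: float = 0.05,
) -> tuple[FitResult, list[FitResult]]:
    """Fit all eight FFL variants and select the winner.

    Every variant is tested at the calibrated effective degrees of freedom
    (the raw N - p would be <= 3 for up to 12 parameters and 12 points);
    among accepted variants the lowest AIC wins (tie: fewer parameters).
    If no variant is accepted the lowest-AIC fit is returned with
    ``accepted=False``. Also returns the full per-variant table.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(FFL_MODEL_IDS))
    table = [
        fit_gene(tc, mid, smad_by_dose, err, n_starts=n_starts,
                 seed=s, alpha=alpha, dof=dof_effective)
        for mid, s in zip(FFL_MODEL_IDS, child_seeds)
    ]
    pool = [f for f in table if f.accepted] or table
    best = min(pool, key=lambda f: (f.aic, f.n_free))
    return best, table


def results_table(fits) -> pd.DataFrame:
    """Flatten FitResults into one row per gene x model."""
    return pd.DataFrame([f.to_row() for f in fits])
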