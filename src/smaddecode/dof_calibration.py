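"""Simulation-based effective degrees of freedom (simulate-refit method).

With up to 12 parameters and only 12 data points, the nominal N - p
degrees of freedom of the feedforward-loop models would be meaningless;
many parameter directions are not constrained by the data. The effective
dimension is estimated empirically: simulate the best-fit trajectory,
perturb it with multiplicative Gaussian noise many times, and compare the
mean chi-square of the noisy samples against the unperturbed trajectory
(chi2_before) with the mean chi-square after refitting the model to each
sample (chi2_after). The difference is the number of degrees of freedom
the model can absorb, and N minus that difference is used as the
chi-square test dof for the FFL stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .error_model import ErrorModel
from .fitting import ExpressionTimeCourse, FitResult, chi2, fit_gene
from .ode_models import get_model
from .smad_input import SmadTrajectory

__all__ = ["DofCalibration", "effective_dof"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DofCalibration:
    """Mean chi-square before/after refit and their difference."""

    model_id: str
    n_samples: int
    noise_sd: float
    chi2_before: float
    chi2_after: float

    @property
    def dof_raw(self) -> float:
        return self.chi2_before - self.chi2_after

    @property
    def dof(self) -> int:
        """Rounded effective degrees of freedom absorbed by the refit."""
        return int(round(self.dof_raw))


def effective_dof(
    model_id: str,
    reference_fit: FitResult,
    tc: ExpressionTimeCourse,
    smad_by_dose: dict[str, SmadTrajectory],
    err: ErrorModel | float,
    n_samples: int = 100,
    noise_sd: float = 0.11,
    seed=None,
    refit_n_starts: int = 8,
    max_failure_frac: float = 0.1,
) -> DofCalibration:
    """Estimate a model's effective degrees of freedom by simulate-refit.

    The reference trajectory is the ``reference_fit`` model evaluated at
    the data design of ``tc`` (same doses and time points). Each synthetic
    sample multiplies it by (1 + eps), eps ~ N(0, noise_sd), truncated to
    keep values positive. Refits are warm-started from the reference
    parameters plus a reduced Latin-hypercube draw.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    spec = get_model(model_id)
    rel = err.rel_error if isinstance(err, ErrorModel) else float(err)
    rng = np.random.default_rng(seed)

    # reference trajectory at the data time points, per dose
    ref_parts, design = [], []
    for dose in tc.doses:
        t, _ = tc.dose_series(dose)
        ref_parts.append(spec.simulate(reference_fit.theta, smad_by_dose[dose], t))
        design.extend((dose, ti) for ti in t)
    y_ref = np.concatenate(ref_parts)

    before, after = [], []
    failures = 0
    allowed_failures = int(max_failure_frac * n_samples)
    for i in range(n_samples):
        eps = rng.normal(0.0, noise_sd, size=y_ref.size) if noise_sd > 0 \
            else np.zeros(y_ref.size)
        y_noisy = y_ref * (1.0 + eps)
        bad = y_noisy <= 0
        while np.any(bad):  # truncate: redraw the rare non-positive values
            eps[bad] = rng.normal(0.0, noise_sd, size=int(bad.sum()))
            y_noisy = y_ref * (1.0 + eps)
            bad = y_noisy <= 0
        # chi2 before refit: noisy sample vs reference, reference-weighted
        before.append(chi2(y_ref, y_noisy, rel))
        if noise_sd == 0.0:
            after.append(0.0)
            continue
        sample_tc = ExpressionTimeCourse(
            tc.gene_id,
            np.array([d for d, _ in design], dtype=object),
            np.array([ti for _, ti in design]),
            y_noisy,
        )
        try:
            refit = fit_gene(
                sample_tc, model_id, smad_by_dose, rel,
                n_starts=refit_n_starts, seed=rng.integers(2**31),
                extra_starts=reference_fit.theta,
            )
            after.append(refit.chi2)
        except RuntimeError as exc:
            failures += 1
            log.warning("refit %d/%d failed: %s", i + 1, n_samples, exc)
            if failures > allowed_failures:
                raise RuntimeError(
                    f"{failures}/{i + 1} refits failed (limit "
                    f"{allowed_failures}); last error: {exc}"
                ) from exc
    return DofCalibration(
        model_id=model_id,
        n_samples=n_samples,
        noise_sd=noise_sd,
        chi2_before=float(np.mean(before)),
        chi2_after=float(np.mean(after)),
    )
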