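"""Ground-truth synthetic data for the whole pipeline.

Real inputs to this kind of analysis are nuclear SMAD2 imaging
trajectories and replicated RNA-seq fold-change time courses. This module
emulates both with known truth: SMAD input waveforms (a transient pulse
for the low dose, a sustained plateau for the high dose), gene panels
simulated from the package's own ODE models with archetype-specific
parameter draws, multiplicative Gaussian replicate noise with a relative
SD matching the error model, SD-proportional-to-mean replicate summary
tables, and knockdown scenarios with a prescribed global slope.

What it does not emulate: count-level (negative binomial) sequencing
noise, gene-gene correlation, or single-cell heterogeneity of the SMAD
signal — conclusions from synthetic tests carry over to real data only at
the level of the relative-error model used for fitting.

All generators are pure functions of their seed and arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fitting import CANONICAL_TIMES, ExpressionTimeCourse
from .ode_models import get_model
from .smad_input import SmadTrajectory

__all__ = [
    "SyntheticPanel",
    "example_delayed_ffl_gene",
    "make_smad_input",
    "default_smad_inputs",
    "simulate_gene_panel",
    "add_noise",
    "make_rpkm_replicates",
    "make_kd_scenario",
    "ARCHETYPES",
]

LOW_DOSE = "2.5pM"
HIGH_DOSE = "100pM"


def make_smad_input(
    shape: str,
    amplitude: float = 1.0,
    rise_tau: float | None = None,
    decay_tau: float | None = None,
    horizon: float = 1440.0,
    step: float = 5.0,
    dose_label: str | None = None,
) -> SmadTrajectory:
    """Synthetic nuclear-SMAD2 waveform sampled every ``step`` minutes.

    ``"transient"`` is a double-exponential pulse normalized to peak at
    ``amplitude`` (default taus 20/120 min: peak near 45 min, back below
    10% of peak by 720 min); ``"sustained"`` rises to a held plateau
    (default rise 60 min, >= 90% of plateau well before 1440 min). Both
    start at exactly 0.
    """
    if shape == "transient":
        rise = 20.0 if rise_tau is None else rise_tau
        decay = 120.0 if decay_tau is None else decay_tau
        if rise <= 0 or decay <= 0:
            raise ValueError("time constants must be positive")
        if rise >= decay:
            raise ValueError("transient pulse needs rise_tau < decay_tau")
        t = np.arange(0.0, horizon + step / 2, step)
        pulse = np.exp(-t / decay) - np.exp(-t / rise)
        t_peak = math.log(decay / rise) * rise * decay / (decay - rise)
        peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
        values = amplitude * pulse / peak
        label = dose_label or LOW_DOSE
    elif shape == "sustained":
        rise = 60.0 if rise_tau is None else rise_tau
        if rise <= 0:
            raise ValueError("time constants must be positive")
        t = np.arange(0.0, horizon + step / 2, step)
        values = amplitude * (1.0 - np.exp(-t / rise))
        label = dose_label or HIGH_DOSE
    else:
        raise ValueError(f"shape must be 'transient' or 'sustained', got {shape!r}")
    return SmadTrajectory(label, t, np.maximum(values, 0.0))


def default_smad_inputs() -> dict[str, SmadTrajectory]:
    """The default two-dose study design: low transient, high sustained.

    The low-dose pulse peaks at ~70% of the high-dose plateau, mirroring
    a signal that saturates between the two doses.
    """
    return {
        LOW_DOSE: make_smad_input("transient", amplitude=0.7),
        HIGH_DOSE: make_smad_input("sustained", amplitude=1.0),
    }


# ---------------------------------------------------------------------------
# gene panels
# ---------------------------------------------------------------------------

# archetype -> (model_id, log-uniform draw ranges for the free parameters
# that are drawn; derived parameters handled in _draw_params)
ARCHETYPES = (
    "activation_fast", "activation_slow", "inhibition",
    "ffl1", "ffl2", "ffl3", "ffl4", "ffl5", "ffl6", "ffl7", "ffl8",
)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))


def _draw_params(archetype: str, rng: np.random.Generator, smad_max: float
                 ) -> tuple[str, np.ndarray]:
    """Draw a plausible parameter vector for one archetype.

    Amplitudes are drawn as steady-state fold inductions (2-16x) and
    converted to rates, so every archetype responds visibly above the
    noise floor; degradation rates span mRNA half-lives from ~10 min
    (fast) to ~1 day (slow).
    """
    if archetype in ("activation_fast", "activation_slow"):
        beta0 = _loguniform(rng, 0.01, 0.1) if archetype == "activation_fast" \
            else _loguniform(rng, 5e-4, 5e-3)
        amp = _loguniform(rng, 2.0, 16.0)
        theta = {
            "beta0": beta0,
            "ksyn": beta0 * (amp - 1.0),
            "h": rng.uniform(1.0, 4.0),
            "k": _loguniform(rng, 0.2, 1.0) * smad_max,
        }
        model_id = "activation"
    elif archetype == "inhibition":
        theta = {
            "beta0": _loguniform(rng, 1e-3, 0.05),
            "h": rng.uniform(1.0, 4.0),
            "k": _loguniform(rng, 0.2, 1.0) * smad_max,
        }
        model_id = "inhibition"
    elif archetype.startswith("ffl"):
        tf_beta0 = _loguniform(rng, 0.005, 0.05)
        tf_amp = _loguniform(rng, 3.0, 20.0)
        b_tg = _loguniform(rng, 1e-3, 0.02)
        theta = {
            "tf_beta0": tf_beta0,
            "tf_r": tf_beta0 * (tf_amp - 1.0),
            "tf_h": rng.uniform(1.0, 4.0),
            "tf_k": _loguniform(rng, 0.2, 1.0) * smad_max,
            "syn_tg": _loguniform(rng, 0.1, 10.0),
            "rs": b_tg * _loguniform(rng, 2.0, 16.0),
            "rp": b_tg * _loguniform(rng, 2.0, 16.0),
            "hs1": rng.uniform(1.0, 4.0),
            "ks1": _loguniform(rng, 0.2, 1.0) * smad_max,
            "hp": rng.uniform(2.0, 6.0),
            "kp": _loguniform(rng, 1.5, 0.8 * tf_amp) if tf_amp > 2.0
            else 1.5,
            "b_tg": b_tg,
        }
        model_id = archetype
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    spec = get_model(model_id)
    return model_id, np.array([theta[n] for n in spec.param_names])


def example_delayed_ffl_gene():
    """A representative delayed-kinetics gene (fixed parameters).

    AND-gate FFL with SMAD and a slowly accumulating SMAD-induced TF both
    required at the target promoter (variant 1): the target barely moves
    for the first ~2 h, then rises steeply and keeps climbing at 24 h
    under sustained input, while the transient low-dose input leaves it
    almost silent — the hallmark of the delayed, dose-discriminating
    expression class. Used as the reference gene for effective-dof
    calibration examples.
    """
    from .ode_models import FflModelParams

    return FflModelParams(
        variant=1, tf_beta0=0.003, tf_r=0.021, tf_h=2.0, tf_k=0.5,
        rs=0.036, hs1=2.0, ks1=0.4, hp=4.0, kp=3.0, b_tg=0.003,
    )


@dataclass
class SyntheticPanel:
    """A simulated gene panel with its generating truth."""

    truth: dict[str, dict]
    clean: dict[str, ExpressionTimeCourse]
    seed: object
    noisy: dict[str, list[ExpressionTimeCourse]] = field(default_factory=dict)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.clean)


def simulate_gene_panel(
    n_genes: int,
    archetype_mix: dict[str, float],
    smad_by_dose: dict[str, SmadTrajectory] | None = None,
    seed=None,
    times=CANONICAL_TIMES,
    param_overrides=None,
) -> SyntheticPanel:
    """Simulate a panel of genes with known generating models.

    ``archetype_mix`` maps archetype names (see :data:`ARCHETYPES`) to
    proportions summing to 1; gene counts are the rounded proportions.
    ``param_overrides`` optionally maps archetype -> callable(rng,
    smad_max) -> (model_id, theta) replacing the default draw.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be nonnegative")
    if n_genes > 0 and not archetype_mix:
        raise ValueError("empty archetype mix")
    mix = dict(archetype_mix)
    if mix and not np.isclose(sum(mix.values()), 1.0):
        raise ValueError("archetype proportions must sum to 1")
    unknown = set(mix) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    smad_by_dose = smad_by_dose or default_smad_inputs()
    smad_max = max(s.max_value for s in smad_by_dose.values())
    rng = np.random.default_rng(seed)

    # integer counts per archetype, largest-remainder rounding
    names = list(mix)
    raw = np.array([mix[a] * n_genes for a in names])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_genes - counts.sum()]:
        counts[i] += 1

    truth: dict[str, dict] = {}
    clean: dict[str, ExpressionTimeCourse] = {}
    g = 0
    for arch, cnt in zip(names, counts):
        for _ in range(cnt):
            gene_id = f"g{g:04d}_{arch}"
            g += 1
            if param_overrides and arch in param_overrides:
                model_id, theta = param_overrides[arch](rng, smad_max)
            else:
                model_id, theta = _draw_params(arch, rng, smad_max)
            spec = get_model(model_id)
            doses, tt, fc = [], [], []
            for dose, smad in smad_by_dose.items():
                y = spec.simulate(theta, smad, np.asarray(times, float))
                doses.extend([dose] * len(times))
                tt.extend(times)
                fc.extend(y)
            truth[gene_id] = {
                "archetype": arch,
                "model_id": model_id,
                "theta": theta,
                "param_names": spec.param_names,
            }
            clean[gene_id] = ExpressionTimeCourse(
                gene_id, np.array(doses, dtype=object), np.array(tt),
                np.array(fc),
            )
    return SyntheticPanel(truth=truth, clean=clean, seed=seed)


def add_noise(
    clean: dict[str, ExpressionTimeCourse] | ExpressionTimeCourse,
    rel_sd: float = 0.11,
    n_replicates: int = 1,
    seed=None,
) -> dict[str, list[ExpressionTimeCourse]]:
    """Multiplicative Gaussian noise: obs = clean * (1 + eps), eps ~ N(0, rel_sd).

    Non-positive draws are redrawn (truncation), keeping fold changes
    valid; replicates are independent.
    """
    if rel_sd < 0:
        raise ValueError("rel_sd must be nonnegative")
    if isinstance(clean, ExpressionTimeCourse):
        clean = {clean.gene_id: clean}
    rng = np.random.default_rng(seed)
    out: dict[str, list[ExpressionTimeCourse]] = {}
    for gene_id, tc in clean.items():
        reps = []
        for _ in range(n_replicates):
            y = tc.fold_changes * (1.0 + rng.normal(0.0, rel_sd,
                                                    tc.fold_changes.size))
            bad = y <= 0
            while np.any(bad):
                y[bad] = tc.fold_changes[bad] * (
                    1.0 + rng.normal(0.0, rel_sd, int(bad.sum())))
                bad = y <= 0
            reps.append(ExpressionTimeCourse(
                gene_id, tc.dose_labels.copy(), tc.times.copy(), y))
        out[gene_id] = reps
    return out


def make_rpkm_replicates(
    n_genes: int,
    n_reps: int = 3,
    slope_m: float = 0.082,
    mean_range: tuple[float, float] = (1.0, 1000.0),
    seed=None,
) -> np.ndarray:
    """Replicate mean/SD table with SD proportional to the mean.

    Per-gene expression levels are drawn log-uniform over ``mean_range``;
    replicates get Normal(level, slope_m * level) noise. The reported SD
    is the bias-corrected sample SD (sample SD divided by c4(n)), so the
    through-origin SD-vs-mean slope of the table is ~slope_m rather than
    the c4-shrunken value small replicate numbers would otherwise give.
    """
    if slope_m < 0:
        raise ValueError("slope_m must be nonnegative")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    lo, hi = mean_range
    if not (0 < lo < hi):
        raise ValueError("mean_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    levels = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n_genes)
    reps = levels[:, None] * (
        1.0 + slope_m * rng.standard_normal((n_genes, n_reps)))
    c4 = math.sqrt(2.0 / (n_reps - 1)) * math.gamma(n_reps / 2) \
        / math.gamma((n_reps - 1) / 2)
    means = reps.mean(axis=1)
    sds = reps.std(axis=1, ddof=1) / c4
    return np.column_stack([means, sds])


def make_kd_scenario(
    control_log2fc: dict[str, float],
    global_slope: float,
    specific_gene_set=frozenset(),
    specific_slope: float | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed=None,
) -> dict:
    """Knockdown log2FC table with a prescribed global slope.

    Background genes respond with ``global_slope`` times the control
    log2FC, the ``specific_gene_set`` with ``specific_slope``; Gaussian
    noise of SD ``noise_sd`` is added per gene and replicate. Returns a
    dict with per-replicate tables and the recorded truth.
    """
    if global_slope <= 0 or (specific_slope is not None and specific_slope <= 0):
        raise ValueError("slopes must be positive")
    specific = set(specific_gene_set)
    unknown = specific - set(control_log2fc)
    if unknown:
        raise ValueError(f"specific genes not in control set: {sorted(unknown)}")
    if specific and specific_slope is None:
        raise ValueError("specific_gene_set given without specific_slope")
    rng = np.random.default_rng(seed)
    genes = list(control_log2fc)
    ctrl = np.array([control_log2fc[g] for g in genes])
    slopes = np.array([
        specific_slope if g in specific else global_slope for g in genes
    ])
    replicates = []
    for _ in range(n_replicates):
        kd = slopes * ctrl + rng.normal(0.0, noise_sd, size=len(genes))
        replicates.append({g: float(v) for g, v in zip(genes, kd)})
    return {
        "control": dict(control_log2fc),
        "replicates": replicates,
        "truth": {
            "global_slope": global_slope,
            "specific_slope": specific_slope,
            "specific_genes": sorted(specific),
            "noise_sd": noise_sd,
        },
    }
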