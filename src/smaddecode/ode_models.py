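"""ODE models of SMAD-driven target-gene expression.

Two simple single-gene models (SMAD as activator or repressor of
transcription via a Hill function) and eight feedforward-loop (FFL)
variants in which SMAD additionally induces an intermediate transcription
factor (TF) that co-regulates the target gene (TG) through AND- or OR-gate
promoter logic.

All models are expressed in fold change relative to the unstimulated
steady state, so every state variable equals 1 at t = 0 and stays at 1
for SMAD = 0. The simple activation model reads

    dy/dt = beta0 + ksyn * Hill(SMAD) - beta0 * y,

the inhibition model

    dy/dt = beta0 * (1 - Hill(SMAD)) - beta0 * y,

with Hill(s) = s^h / (s^h + k^h). The FFL variants share the TF equation

    dTF/dt = tf_beta0 + tf_r * Hill(SMAD) - tf_beta0 * TF

and differ in the TG synthesis term (activator/repressor roles of SMAD
and TF, AND or OR gate), normalized by the no-stimulus steady state.

Each state is a scalar linear ODE given its inputs, so the default solver
is the exact exponential cascade integrator in :mod:`smaddecode._integrate`;
``method="ivp"`` integrates the same right-hand sides with an adaptive
stiffness-switching solver as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._integrate import eval_off_grid, exp_integrate
from .smad_input import SmadTrajectory

__all__ = [
    "hill",
    "SimpleModelParams",
    "FflModelParams",
    "SimulationError",
    "simulate_simple",
    "simulate_ffl",
    "ffl_synthesis_raw",
    "ffl_steady_state",
    "simulate_ffl_raw",
    "ModelSpec",
    "get_model",
    "MODEL_IDS",
]

DEFAULT_STEP = 0.5  # minutes; fine-grid resolution of the exponential solver


class SimulationError(RuntimeError):
    """Raised when an integration produces a non-finite state."""


def hill(s, k: float, h: float):
    """Hill activation fraction s^h / (s^h + k^h), in [0, 1].

    Computed via (s/k)^h to avoid overflow for large h; s must be
    nonnegative, k > 0, h > 0.
    """
    if k <= 0 or h <= 0:
        raise ValueError("hill requires k > 0 and h > 0")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("hill input signal must be nonnegative")
    x = (s / k) ** h
    out = x / (x + 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimpleModelParams:
    """Parameters of the simple activation/inhibition model.

    beta0 is the shared basal synthesis and first-order degradation rate
    (min^-1) — it sets the response timescale; ksyn the maximal
    SMAD-induced synthesis rate (activation only); h and k the Hill
    coefficient and half-saturation point in SMAD-input units.
    """

    variant: str
    beta0: float
    h: float
    k: float
    ksyn: float | None = None

    def __post_init__(self):
        if self.variant not in ("activation", "inhibition"):
            raise ValueError(f"unknown simple-model variant {self.variant!r}")
        if self.beta0 <= 0 or self.k <= 0:
            raise ValueError("rates and half-saturations must be positive")
        if self.h < 1:
            raise ValueError("Hill coefficient must be >= 1")
        if self.variant == "activation":
            if self.ksyn is None or self.ksyn <= 0:
                raise ValueError("activation model requires ksyn > 0")
        elif self.ksyn is not None:
            raise ValueError("inhibition model has no ksyn")

    @property
    def n_free(self) -> int:
        return 4 if self.variant == "activation" else 3


# full FFL parameter order; per-variant activity masks below
FFL_PARAM_NAMES = (
    "tf_beta0",  # TF basal synthesis/degradation rate (min^-1)
    "tf_r",      # maximal SMAD-induced TF synthesis rate
    "tf_h",      # Hill coefficient, SMAD -> TF
    "tf_k",      # half-saturation, SMAD -> TF (SMAD units)
    "syn_tg",    # basal target synthesis rate (enters via steady-state ratio)
    "rs",        # maximal SMAD-induced target synthesis rate
    "rp",        # maximal TF-induced target synthesis rate
    "hs1",       # Hill coefficient, SMAD -> target
    "ks1",       # half-saturation, SMAD -> target (SMAD units)
    "hp",        # Hill coefficient, TF -> target
    "kp",        # half-saturation, TF -> target (TF fold-change units)
    "b_tg",      # target mRNA degradation rate (min^-1)
)

# variant -> (gate, smad_role, tf_role); smad/tf role: +1 activator, -1 repressor
FFL_VARIANTS = {
    1: ("AND", +1, +1),
    2: ("OR", +1, +1),
    3: ("AND", -1, +1),
    4: ("OR", -1, +1),
    5: ("AND", +1, -1),
    6: ("OR", +1, -1),
    7: ("AND", -1, -1),
    8: ("OR", -1, -1),
}

# parameters actually present in each variant's normalized target equation
# (syn_tg cancels exactly in variant 7; unused amplitudes are inactive)
_FFL_TG_ACTIVE = {
    1: ("rs", "hs1", "ks1", "hp", "kp", "b_tg"),
    2: ("syn_tg", "rs", "rp", "hs1", "ks1", "hp", "kp", "b_tg"),
    3: ("syn_tg", "rp", "hs1", "ks1", "hp", "kp", "b_tg"),
    4: ("rp", "hs1", "ks1", "hp", "kp", "b_tg"),
    5: ("rs", "hs1", "ks1", "hp", "kp", "b_tg"),
    6: ("syn_tg", "rs", "hs1", "ks1", "hp", "kp", "b_tg"),
    7: ("hs1", "ks1", "hp", "kp", "b_tg"),
    8: ("hs1", "ks1", "hp", "kp", "b_tg"),
}
_TF_PARAMS = ("tf_beta0", "tf_r", "tf_h", "tf_k")


@dataclass(frozen=True)
class FflModelParams:
    """Parameters of one feedforward-loop variant (1-8).

    Inactive parameters (not present in the variant's equations) may be
    left at their defaults; ``active_names`` lists the free ones.
    """

    variant: int
    tf_beta0: float = 0.01
    tf_r: float = 1.0
    tf_h: float = 2.0
    tf_k: float = 1.0
    syn_tg: float = 1.0
    rs: float = 1.0
    rp: float = 1.0
    hs1: float = 2.0
    ks1: float = 1.0
    hp: float = 2.0
    kp: float = 1.0
    b_tg: float = 0.01

    def __post_init__(self):
        if self.variant not in FFL_VARIANTS:
            raise ValueError(f"FFL variant must be 1-8, got {self.variant}")
        for name in ("tf_beta0", "tf_r", "syn_tg", "rs", "rp", "b_tg",
                     "tf_k", "ks1", "kp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("tf_h", "hs1", "hp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def active_names(self) -> tuple[str, ...]:
        return _TF_PARAMS + _FFL_TG_ACTIVE[self.variant]

    @property
    def n_free(self) -> int:
        return len(self.active_names)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def _simple_forcing(p: SimpleModelParams, s):
    hs = hill(s, p.k, p.h)
    if p.variant == "activation":
        return p.beta0 + p.ksyn * hs
    return p.beta0 * (1.0 - hs)


def ffl_synthesis_raw(variant: int, s, tf, p: FflModelParams):
    """Un-normalized TG synthesis rate of the chosen gate/role combination.

    fS/gS are the activating/repressing SMAD Hill fractions, fP/gP the TF
    ones; AND gates multiply the two regulator terms, OR gates combine
    them as f + g - f*g.
    """
    fS = hill(s, p.ks1, p.hs1)
    fP = hill(tf, p.kp, p.hp)
    gS = 1.0 - fS
    gP = 1.0 - fP
    if variant == 1:
        return p.syn_tg + p.rs * fS * fP
    if variant == 2:
        return p.syn_tg + p.rp * fP + p.rs * fS - p.rp * p.rs * fS * fP
    if variant == 3:
        return p.syn_tg + p.rp * gS * fP
    if variant == 4:
        return p.syn_tg * gS + p.rp * fP - p.rp * gS * fP
    if variant == 5:
        return p.syn_tg + p.rs * fS * gP
    if variant == 6:
        return p.syn_tg * gP + p.rs * fS - p.rs * fS * gP
    if variant == 7:
        return p.syn_tg * gP * gS
    if variant == 8:
        return p.syn_tg * (gS + gP - gS * gP)
    raise ValueError(f"FFL variant must be 1-8, got {variant}")


def ffl_steady_state(variant: int, p: FflModelParams) -> float:
    """TG steady state of the un-normalized equations at SMAD = 0, TF = 1."""
    fP1 = 1.0 / (p.kp ** p.hp + 1.0)
    gP1 = 1.0 - fP1
    if variant in (1, 4, 5, 8):
        return p.syn_tg / p.b_tg
    if variant in (2, 3):
        return (p.syn_tg + p.rp * fP1) / p.b_tg
    if variant in (6, 7):
        return p.syn_tg * gP1 / p.b_tg
    raise ValueError(f"FFL variant must be 1-8, got {variant}")


def _ffl_tg_forcing(p: FflModelParams, s, tf):
    """Normalized TG synthesis (fold-change equations, baseline rate b_tg).

    For variants whose normalized equation keeps syn_tg/rp/rs explicitly
    this is the raw synthesis divided by the steady state; for the others
    the amplitudes are already in normalized units and b_tg replaces the
    basal term.
    """
    v = p.variant
    fS = hill(s, p.ks1, p.hs1)
    fP = hill(tf, p.kp, p.hp)
    gS = 1.0 - fS
    gP = 1.0 - fP
    if v == 1:
        return p.b_tg + p.rs * fS * fP
    if v == 4:
        return p.b_tg * gS + p.rp * fP - p.rp * gS * fP
    if v == 5:
        return p.b_tg + p.rs * fS * gP
    if v == 8:
        return p.b_tg * (gS + gP - gS * gP)
    # denominator variants: raw synthesis over steady state
    return ffl_synthesis_raw(v, s, tf, p) / ffl_steady_state(v, p)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _check_t_grid(t_grid) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0 or not np.all(np.isfinite(t)):
        raise ValueError("t_grid must be a non-empty finite 1-D array")
    if np.any(t < 0):
        raise ValueError("t_grid times must be >= 0")
    return t


def _finite_or_raise(y: np.ndarray, params) -> None:
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state during simulation; params={params}")


def simulate_simple(
    params: SimpleModelParams,
    smad: SmadTrajectory,
    t_grid,
    method: str = "exp",
    step: float = DEFAULT_STEP,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Fold-change trajectory y(t) of the simple model, y(0) = 1.

    Activation output is >= 1 everywhere, inhibition output in (0, 1].
    """
    t = _check_t_grid(t_grid)
    if method == "exp":
        t_end = max(1440.0, float(t.max()))
        grid, s_grid = smad.on_grid(step, t_end)
        f = _simple_forcing(params, s_grid)
        y_grid = exp_integrate(f, params.beta0, step, 1.0)
        y = eval_off_grid(t, grid, y_grid, f, params.beta0)
    elif method == "ivp":
        def rhs(tt, yy):
            return _simple_forcing(params, max(smad.interpolate(tt), 0.0)) \
                - params.beta0 * yy[0]
        sol = solve_ivp(
            rhs, (0.0, float(t.max()) if t.max() > 0 else 1.0), [1.0],
            t_eval=t, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"solver failed: {sol.message}; params={params}")
        y = sol.y[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    _finite_or_raise(y, params)
    return y


def simulate_ffl(
    params: FflModelParams,
    smad: SmadTrajectory,
    t_grid,
    method: str = "exp",
    step: float = DEFAULT_STEP,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (TF(t), TG(t)) trajectories of an FFL variant, both 1 at t=0."""
    t = _check_t_grid(t_grid)
    if method == "exp":
        t_end = max(1440.0, float(t.max()))
        grid, s_grid = smad.on_grid(step, t_end)
        f_tf = params.tf_beta0 + params.tf_r * hill(s_grid, params.tf_k, params.tf_h)
        tf_grid = exp_integrate(f_tf, params.tf_beta0, step, 1.0)
        _finite_or_raise(tf_grid, params)
        f_tg = _ffl_tg_forcing(params, s_grid, np.maximum(tf_grid, 0.0))
        tg_grid = exp_integrate(f_tg, params.b_tg, step, 1.0)
        tf = eval_off_grid(t, grid, tf_grid, f_tf, params.tf_beta0)
        tg = eval_off_grid(t, grid, tg_grid, f_tg, params.b_tg)
    elif method == "ivp":
        def rhs(tt, state):
            tf_v, tg_v = state
            s = max(smad.interpolate(tt), 0.0)
            dtf = params.tf_beta0 + params.tf_r * hill(s, params.tf_k, params.tf_h) \
                - params.tf_beta0 * tf_v
            dtg = _ffl_tg_forcing(params, s, max(tf_v, 0.0)) - params.b_tg * tg_v
            return [dtf, dtg]
        sol = solve_ivp(
            rhs, (0.0, float(t.max()) if t.max() > 0 else 1.0), [1.0, 1.0],
            t_eval=t, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"solver failed: {sol.message}; params={params}")
        tf, tg = sol.y
    else:
        raise ValueError(f"unknown method {method!r}")
    _finite_or_raise(tf, params)
    _finite_or_raise(tg, params)
    return tf, tg


def simulate_ffl_raw(
    params: FflModelParams,
    smad: SmadTrajectory,
    t_grid,
    step: float = DEFAULT_STEP,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the un-normalized TG equation from its steady state.

    The TF input is the normalized TF trajectory (fold change, baseline 1),
    as in the normalized system. Returns (TG_raw(t), steady state x0);
    TG_raw/x0 must agree with the normalized route — a consistency check
    of the steady-state normalization, exercised in the test suite.
    """
    t = _check_t_grid(t_grid)
    t_end = max(1440.0, float(t.max()))
    grid, s_grid = smad.on_grid(step, t_end)
    f_tf = params.tf_beta0 + params.tf_r * hill(s_grid, params.tf_k, params.tf_h)
    tf_grid = exp_integrate(f_tf, params.tf_beta0, step, 1.0)
    x0 = ffl_steady_state(params.variant, params)
    f_raw = ffl_synthesis_raw(params.variant, s_grid, np.maximum(tf_grid, 0.0), params)
    tg_grid = exp_integrate(f_raw, params.b_tg, step, x0)
    tg = eval_off_grid(t, grid, tg_grid, f_raw, params.b_tg)
    _finite_or_raise(tg, params)
    return tg, x0


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Fitting-facing description of one model: free-parameter names,
    log-uniform bounds (a function of the maximal SMAD input), and a
    vector -> trajectory simulator."""

    model_id: str
    param_names: tuple[str, ...]

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def bounds(self, smad_max: float) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) bounds per free parameter, natural scale.

        Rates span half-lives from minutes to days; half-saturations span
        sub- to supra-saturating thresholds relative to the input range.
        """
        lo, hi = [], []
        for name in self.param_names:
            if name in ("beta0", "b_tg", "tf_beta0"):
                lo.append(1e-4), hi.append(1.0)
            elif name in ("ksyn", "rs", "rp", "tf_r", "syn_tg"):
                lo.append(1e-3), hi.append(1e3)
            elif name in ("h", "hs1", "hp", "tf_h"):
                lo.append(1.0), hi.append(8.0)
            elif name in ("k", "ks1", "tf_k"):
                lo.append(1e-3 * smad_max), hi.append(10.0 * smad_max)
            elif name == "kp":  # TF fold-change units, baseline 1
                lo.append(1e-2), hi.append(1e2)
            else:  # pragma: no cover
                raise KeyError(name)
        return np.asarray(lo), np.asarray(hi)

    def make_params(self, theta: np.ndarray):
        d = dict(zip(self.param_names, map(float, theta)))
        if self.model_id == "activation":
            return SimpleModelParams(variant="activation", **d)
        if self.model_id == "inhibition":
            return SimpleModelParams(variant="inhibition", **d)
        return FflModelParams(variant=int(self.model_id[3:]), **d)

    def simulate(self, theta: np.ndarray, smad: SmadTrajectory, t_grid,
                 **kw) -> np.ndarray:
        """Observable fold-change trajectory for a free-parameter vector."""
        p = self.make_params(theta)
        if isinstance(p, SimpleModelParams):
            return simulate_simple(p, smad, t_grid, **kw)
        return simulate_ffl(p, smad, t_grid, **kw)[1]


def _build_registry() -> dict[str, ModelSpec]:
    reg = {
        "activation": ModelSpec("activation", ("beta0", "ksyn", "h", "k")),
        "inhibition": ModelSpec("inhibition", ("beta0", "h", "k")),
    }
    for v in range(1, 9):
        reg[f"ffl{v}"] = ModelSpec(f"ffl{v}", _TF_PARAMS + _FFL_TG_ACTIVE[v])
    return reg


_REGISTRY = _build_registry()
MODEL_IDS = tuple(_REGISTRY)
FFL_MODEL_IDS = tuple(m for m in MODEL_IDS if m.startswith("ffl"))


def get_model(model_id: str) -> ModelSpec:
    """Look up a model by id: "activation", "inhibition", "ffl1".."ffl8"."""
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {', '.join(MODEL_IDS)}"
        ) from None
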