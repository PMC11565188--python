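"""Rule-based gene filters: differential expression, dose discrimination,
and temporal archetypes.

Three orthogonal labels are assigned per gene:

* a differential-expression flag (|FC| >= 1.5 and adjusted p < 0.01 in at
  least one dose/time condition, applied to precomputed statistics);
* a dose-discriminating-gene (DDG) flag — strong late response at the
  high dose (|FC| > 4) with essentially no late response at the low dose
  (|FC| < 2);
* for genes rejected by the mechanistic models, one of five dynamic
  groups (immediate early, biphasic, continuous, delayed, inconsistent)
  or ungrouped, decided by threshold rules on the high-dose log2
  fold-change time course in a fixed precedence order.

|FC| on the linear scale means max(FC, 1/FC), so a 4-fold repression
counts as strongly as a 4-fold induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import CANONICAL_TIMES, ExpressionTimeCourse

__all__ = [
    "GeneClass",
    "DynamicGroupThresholds",
    "de_filter",
    "call_ddg",
    "assign_dynamic_group",
    "abs_fold_change",
]

DYNAMIC_GROUPS = (
    "immediate_early", "biphasic", "continuous", "delayed", "inconsistent",
    "ungrouped",
)


def abs_fold_change(fc) -> np.ndarray:
    """Magnitude of regulation on the linear scale: max(FC, 1/FC)."""
    fc = np.asarray(fc, dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fold changes must be positive")
    out = np.maximum(fc, 1.0 / fc)
    return out if out.ndim else float(out)


@dataclass
class GeneClass:
    """Aggregated per-gene labels."""

    gene_id: str
    de_flag: bool = False
    mech_label: str = "rejected"
    dynamic_group: str = "not_applicable"
    is_ddg: bool = False

    def __post_init__(self):
        if self.dynamic_group != "not_applicable" and self.mech_label != "rejected":
            raise ValueError(
                "dynamic groups are defined on rejected genes only"
            )
        if self.is_ddg and not self.de_flag:
            raise ValueError("a DDG must be differentially expressed")


def de_filter(
    log2fc_by_condition: dict,
    adj_p_by_condition: dict,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
) -> bool:
    """Differential-expression flag from precomputed per-condition statistics.

    True iff |FC| >= fc_threshold and adjusted p < p_threshold in at least
    one condition (conditions keyed identically in both mappings).
    """
    missing = set(log2fc_by_condition) - set(adj_p_by_condition)
    if missing:
        raise ValueError(f"missing p-values for conditions: {sorted(missing)}")
    for cond, l2fc in log2fc_by_condition.items():
        p = adj_p_by_condition[cond]
        if p is None or (isinstance(p, float) and np.isnan(p)):
            raise ValueError(f"missing p-value for condition {cond!r}")
        if 2.0 ** abs(l2fc) >= fc_threshold and p < p_threshold:
            return True
    return False


def call_ddg(
    tc_low: ExpressionTimeCourse,
    tc_high: ExpressionTimeCourse,
    late_times=(720.0, 1440.0),
    high_fc: float = 4.0,
    low_fc: float = 2.0,
) -> bool:
    """Dose-discriminating gene call on late time points.

    True iff |FC| > high_fc at the high dose at some late time point AND
    |FC| < low_fc at the low dose at every late time point (both strict,
    so a gene sitting exactly on a threshold is not a DDG). Restricting
    ``late_times`` to (1440,) reproduces the stricter main-text variant.
    """
    def late_values(tc: ExpressionTimeCourse) -> np.ndarray:
        t = tc.times
        mask = np.isin(t, np.asarray(late_times, dtype=float))
        if {float(x) for x in late_times} - set(t[mask]):
            missing = sorted({float(x) for x in late_times} - set(t))
            raise ValueError(f"{tc.gene_id}: missing late time points {missing}")
        return abs_fold_change(tc.fold_changes[mask])

    high = late_values(tc_high)
    low = late_values(tc_low)
    return bool(np.any(high > high_fc) and np.all(low < low_fc))


@dataclass(frozen=True)
class DynamicGroupThresholds:
    """Tunable thresholds of the dynamic-group rules (log2 scale).

    ``responding`` is the minimal |log2FC| counted as a response
    (0.58 ~ 1.5-fold). The remaining fields parameterize the individual
    group rules; see :func:`assign_dynamic_group`.
    """

    responding: float = 0.58
    ie_late_frac: float = 0.5        # late |log2FC| < frac * early peak
    biphasic_dip_frac: float = 0.6   # dip at 360 below frac * early peak
    biphasic_rebound: float = 1.2    # late value above rebound * dip
    continuous_slack: float = 0.10   # tolerated decrease between steps
    delayed_late_min: float = 1.0    # |log2FC| >= 1 at 720 or 1440
    sign_neutral_band: float = 0.2   # |log2FC| below this carries no sign


def _signs_consistent(l2fc: np.ndarray, band: float) -> bool:
    signs = np.sign(l2fc[np.abs(l2fc) >= band])
    return signs.size == 0 or bool(np.all(signs == signs[0]))


def assign_dynamic_group(
    tc_high: ExpressionTimeCourse,
    thresholds: DynamicGroupThresholds | None = None,
) -> str:
    """Temporal archetype of a high-dose time course.

    Rules are evaluated in fixed precedence (immediate_early -> biphasic
    -> continuous -> delayed -> inconsistent -> ungrouped) on the
    canonical 45/90/180/360/720/1440-min design, so every trajectory gets
    exactly one label.
    """
    th = thresholds or DynamicGroupThresholds()
    times = np.asarray(CANONICAL_TIMES)
    t, fc = tc_high.dose_series(tc_high.doses[0]) if len(tc_high.doses) == 1 \
        else tc_high.dose_series(tc_high.doses[-1])
    if not np.all(np.isin(times, t)):
        missing = sorted(set(times) - set(t))
        raise ValueError(f"{tc_high.gene_id}: missing canonical times {missing}")
    idx = {float(ti): i for i, ti in enumerate(t)}
    l2 = np.array([np.log2(fc[idx[ti]]) for ti in times])
    a = np.abs(l2)
    resp = a >= th.responding
    i45, i90, i180, i360, i720, i1440 = range(6)

    early_peak = a[[i45, i90]].max()
    if resp[i45] or resp[i90]:
        if a[i1440] < th.ie_late_frac * early_peak:
            return "immediate_early"

    early3_peak = a[[i45, i90, i180]].max()
    if (resp[[i45, i90, i180]].any()
            and a[i360] < th.biphasic_dip_frac * early3_peak
            and a[[i720, i1440]].max() > th.biphasic_rebound * a[i360]
            and _signs_consistent(l2, th.sign_neutral_band)):
        return "biphasic"

    tail = a[[i90, i180, i360, i720, i1440]]
    if (np.all(resp[[i90, i180, i360, i720, i1440]])
            and _signs_consistent(l2[1:], th.sign_neutral_band)
            and np.all(np.diff(tail) >= -th.continuous_slack * tail[:-1])):
        return "continuous"

    if (not resp[i45] and not resp[i90]
            and a[[i720, i1440]].max() >= th.delayed_late_min):
        return "delayed"

    early_sign = l2[[i45, i90, i180]][np.argmax(a[[i45, i90, i180]])]
    late_sign = l2[[i720, i1440]][np.argmax(a[[i720, i1440]])]
    if (a[[i45, i90, i180]].max() >= th.responding
            and a[[i720, i1440]].max() >= th.responding
            and np.sign(early_sign) == -np.sign(late_sign)):
        return "inconsistent"

    return "ungrouped"
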