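"""Global knockdown-effect quantification.

Whether a co-factor acts as a transcriptional activator or repressor is
read off the scatter of knockdown-induced vs control-induced log2 fold
changes across all responding genes: a through-origin regression slope
below 1 means the response shrinks without the factor (activator), above
1 that it grows (repressor). Slopes are computed per biological replicate
and tested against 1 with a one-sample t-test. Group-level knockdown
effects over time are summarized by the paired log-ratio
log2[(KD_t/KD_0)/(control_t/control_0)] per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["KdSlopeResult", "kd_slope", "slope_test", "kd_group_effect"]


@dataclass(frozen=True)
class KdSlopeResult:
    """Replicate-level slope summary for one factor at one time point."""

    factor: str
    time_min: float
    slopes: tuple[float, ...]
    mean_slope: float
    pearson_r: float
    p_value: float
    role: str  # "activator", "repressor", or "ns"


def kd_slope(control_log2fc, kd_log2fc, intercept: bool = False
             ) -> tuple[float, float]:
    """Slope of KD vs control induced log2FC across genes, plus Pearson r.

    The default trend line goes through the origin (no induced response in
    control implies none in KD); ``intercept=True`` reports the ordinary
    least-squares slope instead.
    """
    x = np.asarray(control_log2fc, dtype=float)
    y = np.asarray(kd_log2fc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("control and KD vectors must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 genes")
    if np.all(x == 0):
        raise ValueError("all-zero control vector: slope undefined")
    if intercept:
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(x, y)[0, 1])
    return slope, r


def slope_test(replicate_slopes, alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided one-sample t-test of replicate slopes against 1.

    Degenerate replicates (zero variance) yield p = 0 if the common slope
    differs from 1 and p = 1 otherwise.
    """
    s = np.asarray(replicate_slopes, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 replicate slopes")
    if np.ptp(s) == 0.0:
        p = 0.0 if s[0] != 1.0 else 1.0
    else:
        p = float(stats.ttest_1samp(s, popmean=1.0).pvalue)
    return p, bool(p < alpha)


def classify_role(replicate_slopes, alpha: float = 0.05,
                  factor: str = "", time_min: float = np.nan,
                  pearson_r: float = np.nan) -> KdSlopeResult:
    """Bundle slopes, test, and the activator/repressor verdict."""
    s = tuple(float(v) for v in replicate_slopes)
    p, significant = slope_test(s, alpha)
    mean_slope = float(np.mean(s))
    if not significant:
        role = "ns"
    else:
        role = "activator" if mean_slope < 1.0 else "repressor"
    return KdSlopeResult(
        factor=factor, time_min=time_min, slopes=s, mean_slope=mean_slope,
        pearson_r=pearson_r, p_value=p, role=role,
    )


def kd_group_effect(kd_tc: dict, control_tc: dict, t: float
                    ) -> tuple[dict, int]:
    """Per-gene knockdown effect log2[(KD_t/KD_0)/(ctrl_t/ctrl_0)].

    ``kd_tc`` and ``control_tc`` map gene -> {time: expression}; both must
    contain t and 0 for a gene to be scored. Genes with a zero denominator
    are dropped; returns (per-gene log2 effects, number dropped).
    """
    out: dict = {}
    dropped = 0
    for gene, kd in kd_tc.items():
        if gene not in control_tc:
            continue
        ctrl = control_tc[gene]
        try:
            kd_t, kd_0 = kd[t], kd[0]
            c_t, c_0 = ctrl[t], ctrl[0]
        except KeyError as exc:
            raise ValueError(f"{gene}: missing time point {exc}") from None
        if kd_0 == 0 or c_0 == 0 or c_t == 0:
            dropped += 1
            continue
        out[gene] = float(np.log2((kd_t / kd_0) / (c_t / c_0)))
    return out, dropped


def group_effect_summary(effects: dict) -> dict:
    """Median and quartiles of a per-gene effect distribution."""
    v = np.fromiter(effects.values(), dtype=float)
    if v.size == 0:
        raise ValueError("empty gene group")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"n": int(v.size), "q1": float(q1), "median": float(med),
            "q3": float(q3)}
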