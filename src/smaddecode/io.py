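"""Tabular file formats and pipeline configuration.

Expression data travels as long/tidy TSV (gene_id, dose, time_min,
optional replicate, log2fc or fc), doses being labels rather than
numbers. Replicated observations are summarized to per-point means and
SDs before fitting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .fitting import ExpressionTimeCourse

__all__ = ["PipelineConfig", "read_expression_table", "write_expression_table"]


@dataclass
class PipelineConfig:
    """Validated knobs of the full pipeline run."""

    smad_csv: str | None = None
    expression_tsv: str | None = None
    rel_error: float = 0.11
    alpha: float = 0.05
    n_starts: int = 500
    ffl_dof: int = 6
    tau_minutes: float = 540.0
    ddg_high_fc: float = 4.0
    ddg_low_fc: float = 2.0
    ddg_late_times: tuple = (720.0, 1440.0)
    low_dose: str | None = None
    high_dose: str | None = None
    seed: int = 0
    threads: int = 1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.rel_error <= 0:
            raise ValueError("rel_error must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.ffl_dof < 1:
            raise ValueError("ffl_dof must be >= 1")
        if self.tau_minutes <= 0:
            raise ValueError("tau_minutes must be positive")
        if self.ddg_high_fc <= 1 or self.ddg_low_fc <= 1:
            raise ValueError("DDG thresholds are linear |FC| values > 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ddg_late_times" in d:
            d = {**d, "ddg_late_times": tuple(d["ddg_late_times"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ddg_late_times"] = list(self.ddg_late_times)
        return d

    def digest(self) -> str:
        """Short hash of the configuration, embedded in every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_expression_table(path) -> dict[str, ExpressionTimeCourse]:
    """Read a tidy expression TSV into per-gene time courses.

    Required columns: gene_id, dose, time_min, and either log2fc or fc
    (log2fc wins if both); optional replicate. Replicates are averaged on
    the linear fold-change scale and their SD recorded. Malformed numeric
    values are reported with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "dose", "time_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression TSV missing columns: {sorted(missing)}")
    if "log2fc" in df.columns:
        value_col, is_log = "log2fc", True
    elif "fc" in df.columns:
        value_col, is_log = "fc", False
    else:
        raise ValueError("expression TSV needs a log2fc or fc column")

    bad_lines = []
    for col in ("time_min", value_col):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        # +2: header line and 1-based numbering
        bad_lines.extend((int(i) + 2, col) for i in df.index[bad])
        df[col] = converted
    if bad_lines:
        where = ", ".join(f"line {ln} ({col})" for ln, col in bad_lines[:10])
        raise ValueError(f"non-numeric values in expression TSV: {where}")
    df = df.dropna(subset=["time_min", value_col])

    fc = 2.0 ** df[value_col].astype(float) if is_log \
        else df[value_col].astype(float)
    if np.any(fc <= 0):
        raise ValueError("fold changes must be positive")
    df = df.assign(_fc=fc)

    out: dict[str, ExpressionTimeCourse] = {}
    for gene, grp in df.groupby("gene_id", sort=False):
        agg = grp.groupby(["dose", "time_min"], sort=False)["_fc"] \
            .agg(["mean", "std", "count"]).reset_index()
        agg = agg.sort_values(["dose", "time_min"], kind="stable")
        sd = agg["std"].to_numpy(float)
        out[str(gene)] = ExpressionTimeCourse(
            str(gene),
            agg["dose"].to_numpy(object),
            agg["time_min"].to_numpy(float),
            agg["mean"].to_numpy(float),
            sd=None if np.all(np.isnan(sd)) else sd,
        )
    return out


def write_expression_table(time_courses, path, log_scale: bool = True) -> None:
    """Write time courses back to the tidy TSV layout (log2fc by default)."""
    if isinstance(time_courses, dict):
        time_courses = time_courses.values()
    rows = []
    for tc in time_courses:
        for dose, t, fc in zip(tc.dose_labels, tc.times, tc.fold_changes):
            rows.append({
                "gene_id": tc.gene_id, "dose": dose, "time_min": t,
                ("log2fc" if log_scale else "fc"):
                    np.log2(fc) if log_scale else fc,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
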