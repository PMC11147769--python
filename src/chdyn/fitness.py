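"""Clonal fitness under the sigmoid clone-growth model.

A heterozygous autosomal clone occupying the whole hematopoietic compartment
has VAF 1/2, so clone growth is modeled as a logistic curve with carrying
capacity 1/2:

    v(t) = (1/2) * 1 / (1 + A * exp(-s * t))

where ``v`` is the VAF at time ``t`` (years), ``A > 0`` anchors the curve so
that v(0) equals the first observed VAF, and ``s`` (per year) is the clonal
fitness.  With two timepoints the model is exactly identified and ``s`` has
the closed form

    s = (1/dt) * ln[ (1/(2 v0) - 1) / (1/(2 v1) - 1) ]

Clones are categorized increasing if s > 0.25/year, decreasing if
s < -0.25/year, and stable otherwise (boundaries are stable).  Endpoint VAFs
are clamped into [detection floor, just-below-1/2] before fitting; a clamped
endpoint marks the estimate as censored (the detection floor is the calling
limit, and VAFs at or above 1/2 — e.g. under loss of heterozygosity — sit
outside the model's domain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chdyn.config import DEFAULT_THRESHOLDS, Thresholds

__all__ = [
    "FitnessEstimate",
    "solve_A",
    "sigmoid_vaf",
    "fit_fitness",
    "categorize_fitness",
    "phase_fitness",
    "fit_fitness_table",
    "count_threshold_crossings",
    "gene_fitness_summary",
]


@dataclass(frozen=True)
class FitnessEstimate:
    """Fitness of one clone over one interval.

    Attributes
    ----------
    s : per-year clonal fitness.
    A : sigmoid anchoring constant, 1/(2 v0) - 1.
    category : 'increasing' | 'stable' | 'decreasing' (±0.25/year, strict).
    censored : True if either endpoint VAF was clamped before fitting.
    phase : interval label ('overall', 'carboplatin', 'maintenance', ...).
    v0, v1 : the (clamped) endpoint VAFs actually used.
    dt_years : interval length in years.
    """

    s: float
    A: float
    category: str
    censored: bool = False
    phase: str = "overall"
    v0: float = float("nan")
    v1: float = float("nan")
    dt_years: float = float("nan")


def solve_A(v0: float) -> float:
    """Anchoring constant A such that v(0) = v0: A = 1/(2 v0) - 1.

    Requires 0 < v0 < 0.5 (open interval; the sigmoid saturates at 1/2).
    """
    if not 0.0 < v0 < 0.5:
        raise ValueError(f"v0 must lie in (0, 0.5), got {v0}")
    return 1.0 / (2.0 * v0) - 1.0


def sigmoid_vaf(t, v0: float, s: float):
    """VAF at time t for a clone starting at v0 with fitness s (/year)."""
    A = solve_A(v0)
    t = np.asarray(t, dtype=float)
    out = 0.5 / (1.0 + A * np.exp(-s * t))
    return float(out) if out.ndim == 0 else out


def _clamp(v: float, lo: float, hi: float) -> tuple[float, bool]:
    if v < lo:
        return lo, True
    if v > hi:
        return hi, True
    return v, False


def fit_fitness(
    v0: float,
    v1: float,
    dt_years: float,
    *,
    phase: str = "overall",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> FitnessEstimate:
    """Closed-form fitness from a pair of VAFs dt_years apart.

    Endpoints are clamped into [detection_floor, vaf_clamp_high]; clamping
    flags the estimate censored but does not invalidate it.
    """
    if dt_years <= 0:
        raise ValueError(f"dt_years must be positive, got {dt_years}")
    lo, hi = thresholds.detection_floor, thresholds.vaf_clamp_high
    v0c, c0 = _clamp(float(v0), lo, hi)
    v1c, c1 = _clamp(float(v1), lo, hi)
    A0 = solve_A(v0c)
    A1 = solve_A(v1c)
    s = math.log(A0 / A1) / dt_years
    return FitnessEstimate(
        s=s,
        A=A0,
        category=categorize_fitness(s, thresholds=thresholds),
        censored=c0 or c1,
        phase=phase,
        v0=v0c,
        v1=v1c,
        dt_years=float(dt_years),
    )


def categorize_fitness(
    s: float, *, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """'increasing' if s > 0.25/yr, 'decreasing' if s < -0.25/yr, else 'stable'."""
    if not math.isfinite(s):
        raise ValueError(f"fitness must be finite, got {s}")
    cut = thresholds.fitness_category
    if s > cut:
        return "increasing"
    if s < -cut:
        return "decreasing"
    return "stable"


def phase_fitness(
    trajectory,
    *,
    phase_names: tuple[str, str] = ("carboplatin", "maintenance"),
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[FitnessEstimate, FitnessEstimate]:
    """Per-phase fitness from a 3-timepoint trajectory [(t0,v0),(t1,v1),(t2,v2)].

    Each phase is fit independently, re-anchoring A at its own starting VAF:
    phase 1 from (v0, v1), phase 2 from (v1, v2).
    """
    if len(trajectory) != 3:
        raise ValueError("phase_fitness requires exactly 3 (time, vaf) points")
    (t0, v0), (t1, v1), (t2, v2) = trajectory
    if not (t0 < t1 < t2):
        raise ValueError(f"timepoints must be strictly increasing: {t0}, {t1}, {t2}")
    first = fit_fitness(v0, v1, t1 - t0, phase=phase_names[0], thresholds=thresholds)
    second = fit_fitness(v1, v2, t2 - t1, phase=phase_names[1], thresholds=thresholds)
    return first, second


def fit_fitness_table(
    trajectories: pd.DataFrame,
    *,
    vaf_col: str = "vaf",
    time_col: str = "timepoint_years",
    key_cols: tuple[str, ...] = ("patient_id", "chrom", "pos", "ref", "alt", "gene"),
    per_phase: bool = False,
    phase_names: tuple[str, str] = ("carboplatin", "maintenance"),
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Fitness estimates for every variant in a long-format trajectory table.

    With ``per_phase=False`` the first and last timepoint of each variant give
    one 'overall' estimate; with ``per_phase=True`` variants with exactly 3
    timepoints give one estimate per treatment phase.  Variants with fewer
    than the required timepoints are skipped.
    """
    rows = []
    for key, grp in trajectories.groupby(list(key_cols), sort=False):
        grp = grp.sort_values(time_col)
        times = grp[time_col].to_numpy(dtype=float)
        vafs = grp[vaf_col].to_numpy(dtype=float)
        ests: list[FitnessEstimate] = []
        if per_phase:
            if len(grp) != 3:
                continue
            ests.extend(
                phase_fitness(
                    list(zip(times, vafs)),
                    phase_names=phase_names,
                    thresholds=thresholds,
                )
            )
        else:
            if len(grp) < 2:
                continue
            ests.append(
                fit_fitness(
                    vafs[0], vafs[-1], times[-1] - times[0], thresholds=thresholds
                )
            )
        for est in ests:
            rec = dict(zip(key_cols, key if isinstance(key, tuple) else (key,)))
            rec.update(
                phase=est.phase,
                s=est.s,
                A=est.A,
                category=est.category,
                censored=est.censored,
                v_start=est.v0,
                v_end=est.v1,
                dt_years=est.dt_years,
            )
            rows.append(rec)
    cols = list(key_cols) + [
        "phase", "s", "A", "category", "censored", "v_start", "v_end", "dt_years",
    ]
    return pd.DataFrame(rows, columns=cols)


def count_threshold_crossings(
    fitness_table: pd.DataFrame,
    *,
    gene_col: str = "gene",
    start_col: str = "v_start",
    end_col: str = "v_end",
    vaf_threshold: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-gene counts of clones crossing the clinically used 1% VAF line.

    emerging: start < threshold and end >= threshold;
    vanishing: start >= threshold and end < threshold.
    """
    cut = thresholds.ch_vaf if vaf_threshold is None else vaf_threshold
    df = fitness_table
    emerging = (df[start_col] < cut) & (df[end_col] >= cut)
    vanishing = (df[start_col] >= cut) & (df[end_col] < cut)
    out = (
        pd.DataFrame(
            {gene_col: df[gene_col], "emerging": emerging, "vanishing": vanishing}
        )
        .groupby(gene_col, sort=True)
        .sum()
        .astype(int)
        .reset_index()
    )
    return out


def gene_fitness_summary(
    fitness_table: pd.DataFrame, *, gene_col: str = "gene", s_col: str = "s"
) -> pd.DataFrame:
    """Median, IQR and clone count of fitness per gene (and phase if present)."""
    group_cols = [gene_col]
    if "phase" in fitness_table.columns:
        group_cols.append("phase")
    agg = (
        fitness_table.groupby(group_cols)[s_col]
        .agg(
            median="median",
            q1=lambda x: float(np.percentile(x, 25)),
            q3=lambda x: float(np.percentile(x, 75)),
            n="size",
        )
        .reset_index()
    )
    return agg
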