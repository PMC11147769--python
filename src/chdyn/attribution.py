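"""Paired whole-blood / cfDNA analysis: inclusion, origin, serial retention.

Plasma cfDNA is a mixture of hematopoietic and tumor-derived fragments.  A
variant seen in cfDNA is attributed to non-hematopoietic (tumor) origin when
its cfDNA VAF is at least 5-fold the whole-blood VAF; an undetected WB VAF is
replaced by the 0.1% detection floor before taking the ratio.  Serial
analysis keeps variants detected at two or more timepoints reaching 0.8% VAF
at least once, and rescues sub-threshold timepoints (any residual alt reads
in the pileup) to the 0.1% floor so fitness can be estimated; timepoints with
no evidence at all are floored too but flagged censored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chdyn.config import DEFAULT_THRESHOLDS, Thresholds

__all__ = [
    "include_paired",
    "classify_origin",
    "retain_serial",
    "rescue_below_threshold",
    "classify_tumor_dynamics",
    "merge_paired_tables",
    "build_trajectories",
]

VARIANT_KEY = ["patient_id", "chrom", "pos", "ref", "alt", "gene"]


def include_paired(
    wb_vaf: float, cf_vaf: float, *, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Paired-sample inclusion: either source at >= 0.8% VAF, or detected in
    both with VAF sum >= 0.8%.  Undetected is encoded as 0."""
    cut = thresholds.paired_inclusion_vaf
    if wb_vaf >= cut or cf_vaf >= cut:
        return True
    return wb_vaf > 0 and cf_vaf > 0 and (wb_vaf + cf_vaf) >= cut


def classify_origin(
    wb_vaf: float, cf_vaf: float, *, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """'non_hematopoietic' iff cfDNA VAF >= 5 x the WB VAF (inclusive).

    When WB is undetected (0), the 0.1% detection floor substitutes for the
    WB VAF — conservative toward the hematopoietic call and division-safe.
    """
    denom = max(wb_vaf, thresholds.detection_floor)
    if cf_vaf >= thresholds.cf_origin_fold * denom:
        return "non_hematopoietic"
    return "hematopoietic"


def retain_serial(
    vafs, *, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Serial retention: detected (VAF > 0 at the calling threshold) at >= 2
    timepoints and reaching >= 0.8% VAF at least once."""
    v = np.asarray(list(vafs), dtype=float)
    detected = (v > 0).sum()
    return bool(detected >= 2 and v.max() >= thresholds.paired_inclusion_vaf)


def rescue_below_threshold(
    vafs,
    pileup_alt_reads,
    *,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Floor undetected timepoints of a retained variant at 0.1% VAF.

    Timepoints with residual alt consensus reads in the raw pileup are genuine
    sub-threshold detections; timepoints with zero evidence keep the same
    floor as a censoring convention for the fitness math but are flagged.
    Returns (vafs, censored_flags).
    """
    v = np.asarray(list(vafs), dtype=float).copy()
    evidence = np.asarray(list(pileup_alt_reads), dtype=float)
    if v.shape != evidence.shape:
        raise ValueError("vafs and pileup evidence must align per timepoint")
    undetected = v <= 0
    censored = undetected & (evidence <= 0)
    v[undetected] = thresholds.detection_floor
    return v, censored


def classify_tumor_dynamics(
    v_start: float, v_end: float, *, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """VAF dynamics of a tumor variant: 10-fold rise = increasing, 10-fold
    fall = decreasing, all others stable (thresholds inclusive)."""
    fold = thresholds.tumor_dynamics_fold
    if v_end >= fold * v_start:
        return "increasing"
    if v_end <= v_start / fold:
        return "decreasing"
    return "stable"


def merge_paired_tables(
    wb: pd.DataFrame,
    cf: pd.DataFrame,
    *,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Outer-merge WB and cfDNA calls of one timepoint and attribute origin.

    Input tables need the VARIANT_KEY columns plus ``vaf``.  Undetected
    sources get VAF 0.  Output: one row per variant with wb_vaf, cf_vaf,
    included (inclusion rule) and origin (only for included variants).
    """
    wb_small = wb[VARIANT_KEY + ["vaf"]].rename(columns={"vaf": "wb_vaf"})
    cf_small = cf[VARIANT_KEY + ["vaf"]].rename(columns={"vaf": "cf_vaf"})
    merged = wb_small.merge(cf_small, on=VARIANT_KEY, how="outer")
    merged["wb_vaf"] = merged["wb_vaf"].fillna(0.0)
    merged["cf_vaf"] = merged["cf_vaf"].fillna(0.0)
    merged["included"] = [
        include_paired(w, c, thresholds=thresholds)
        for w, c in zip(merged["wb_vaf"], merged["cf_vaf"])
    ]
    merged["origin"] = [
        classify_origin(w, c, thresholds=thresholds) if inc else ""
        for w, c, inc in zip(merged["wb_vaf"], merged["cf_vaf"], merged["included"])
    ]
    return merged


def build_trajectories(
    calls: pd.DataFrame,
    *,
    timepoints: tuple[float, ...],
    source: str | None = None,
    pileup: pd.DataFrame | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Long-format serial trajectories with retention and rescue applied.

    ``calls`` is a long table (VARIANT_KEY + source + timepoint_years + vaf).
    Serial retention runs independently per DNA source and a variant is kept
    if it passes in either source (union).  For retained variants every
    configured timepoint appears; undetected ones are rescued via the
    ``pileup`` table (alt_reads at sub-threshold timepoints) or censored at
    the floor.  Output columns: VARIANT_KEY, source, timepoint_years, vaf,
    censored.
    """
    if source is not None:
        calls = calls[calls["source"] == source]
    pile = pileup if pileup is not None else calls

    keep_keys: set[tuple] = set()
    for key_all, grp in calls.groupby(VARIANT_KEY + ["source"]):
        by_tp = grp.set_index("timepoint_years")["vaf"]
        vafs = [float(by_tp.get(tp, 0.0)) for tp in timepoints]
        if retain_serial(vafs, thresholds=thresholds):
            keep_keys.add(tuple(key_all[:-1]))

    rows = []
    for key_all, grp in calls.groupby(VARIANT_KEY + ["source"]):
        key_t, src = tuple(key_all[:-1]), key_all[-1]
        if key_t not in keep_keys:
            continue
        by_tp = grp.set_index("timepoint_years")["vaf"]
        vafs = [float(by_tp.get(tp, 0.0)) for tp in timepoints]
        mask = pd.Series(True, index=pile.index)
        for col, val in zip(VARIANT_KEY, key_t):
            mask &= pile[col] == val
        psub = pile[mask & (pile["source"] == src)]
        p_by_tp = psub.set_index("timepoint_years")["alt_reads"]
        evidence = [float(p_by_tp.get(tp, 0.0)) for tp in timepoints]
        rescued, censored = rescue_below_threshold(
            vafs, evidence, thresholds=thresholds
        )
        for tp, v, cen in zip(timepoints, rescued, censored):
            rec = dict(zip(VARIANT_KEY, key_t))
            rec.update(source=src, timepoint_years=tp, vaf=v, censored=bool(cen))
            rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=VARIANT_KEY + ["source", "timepoint_years", "vaf", "censored"],
    )
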