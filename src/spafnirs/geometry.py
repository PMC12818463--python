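"""Optode/channel placement drift across sessions.

Works on fiducial-anchored MNI coordinates (mm) of digitized scans:
Euclidean shift of each optode between sessions, per-optode cross-subject
dispersion as the composite standard deviation
``SD = sqrt(sigma_x^2 + sigma_y^2 + sigma_z^2)`` (sample variances), and the
association between channel-midpoint shifts and across-session changes in
channel beta estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "euclidean_shift",
    "composite_sd",
    "channel_midpoint",
    "shift_summary",
    "ShiftSummary",
    "shift_beta_association",
]


def euclidean_shift(p1, p2) -> float:
    """D = sqrt((x2-x1)^2 + (y2-y1)^2 + (z2-z1)^2), in mm."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(b - a))


def composite_sd(points) -> float:
    """Composite positional SD: sqrt of the summed per-axis sample variances
    (n-1 denominator) of a cloud of xyz points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("need at least two xyz points")
    return float(np.sqrt(pts.var(axis=0, ddof=1).sum()))


def per_axis_sd(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    return pts.std(axis=0, ddof=1)


def channel_midpoint(source_xyz, detector_xyz) -> np.ndarray:
    """Componentwise mean of the source and detector coordinates."""
    a = np.asarray(source_xyz, dtype=float)
    b = np.asarray(detector_xyz, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return (a + b) / 2.0


@dataclass
class ShiftSummary:
    shifts: pd.DataFrame        # subject, optode, shift_mm
    per_optode: pd.DataFrame    # optode, mean_shift_mm, sd_shift_mm, n
    dispersion: pd.DataFrame    # optode, session, mean x/y/z, composite SD
    grand_mean_mm: float        # pooled over all subject x optode shifts
    grand_sd_mm: float
    grand_mean_of_optode_means_mm: float


def shift_summary(scans_session1, scans_session2) -> ShiftSummary:
    """Across-session placement drift over matched subjects.

    ``scans_session1``/``scans_session2`` are iterables of `DigitizedScan`;
    subjects present in only one session are dropped with a warning. Both
    a pooled grand mean (over all subject x optode shifts) and the mean of
    per-optode means are reported.
    """
    s1 = {sc.subject_id: sc for sc in scans_session1}
    s2 = {sc.subject_id: sc for sc in scans_session2}
    common = sorted(set(s1) & set(s2))
    dropped = sorted(set(s1) ^ set(s2))
    if dropped:
        import warnings

        warnings.warn(f"subjects missing one session dropped: {dropped}", RuntimeWarning)
    if not common:
        raise ValueError("no subjects with both sessions")

    rows = []
    for subj in common:
        a, b = s1[subj], s2[subj]
        for name in a.optode_coords:
            if name not in b.optode_coords:
                continue
            rows.append(dict(subject=subj, optode=name,
                             shift_mm=euclidean_shift(a.optode_coords[name],
                                                      b.optode_coords[name])))
    shifts = pd.DataFrame(rows)
    per_optode = (
        shifts.groupby("optode", as_index=False)["shift_mm"]
        .agg(mean_shift_mm="mean", sd_shift_mm=lambda v: v.std(ddof=1), n="count")
    )

    disp_rows = []
    for session, scans in ((1, s1), (2, s2)):
        optodes = set.intersection(*(set(scans[s].optode_coords) for s in common))
        for name in sorted(optodes):
            pts = np.array([scans[s].optode_coords[name] for s in common])
            mean = pts.mean(axis=0)
            disp_rows.append(dict(
                optode=name, session=session,
                mean_x_mm=mean[0], mean_y_mm=mean[1], mean_z_mm=mean[2],
                composite_sd_mm=composite_sd(pts) if len(pts) >= 2 else np.nan,
            ))
    dispersion = pd.DataFrame(disp_rows)

    return ShiftSummary(
        shifts=shifts,
        per_optode=per_optode,
        dispersion=dispersion,
        grand_mean_mm=float(shifts["shift_mm"].mean()),
        grand_sd_mm=float(shifts["shift_mm"].std(ddof=1)),
        grand_mean_of_optode_means_mm=float(per_optode["mean_shift_mm"].mean()),
    )


def shift_beta_association(
    channel_shifts_mm, abs_delta_beta, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between channel location shift and |change in beta|
    across sessions, pooled over channel x subject pairs.

    Returns ``(r, p)`` (two-sided). Pearson by default; ``method='spearman'``
    for the rank version.
    """
    x = np.asarray(channel_shifts_mm, dtype=float)
    y = np.asarray(abs_delta_beta, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in shifts or beta changes")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
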