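"""Test-retest reliability of beta estimates across sessions: ICC(3,1).

The intraclass correlation is computed from the two-way ANOVA without
interaction (two-way mixed-effects, consistency): targets (rows) are
subject x ROI beta estimates and raters (columns) are the two sessions.
Values are banded into the conventional categories: poor (< 0.40),
fair [0.40, 0.60), good [0.60, 0.75), excellent (>= 0.75).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["icc3", "icc_category", "reliability_report"]


def icc3(ratings: np.ndarray) -> float:
    """ICC(3,1) from an n_targets x k_raters matrix with no missing cells.

    ``ICC = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)`` where
    the mean squares come from the two-way ANOVA decomposition without
    interaction. Additive shifts between raters (sessions) do not lower
    this consistency-form ICC.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings contain missing cells; drop incomplete rows first")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - gm) ** 2)
    ss_cols = n * np.sum((col_means - gm) ** 2)
    ss_total = np.sum((x - gm) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise ValueError("degenerate ratings: no between-row or residual variance")
    return float((ms_rows - ms_err) / denom)


def icc_category(icc: float) -> str:
    """Reliability band: poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent.

    The printed band definitions leave the gaps (0.59, 0.60) and
    (0.74, 0.75) unassigned; half-open intervals are used, so e.g. 0.745
    bands to good.
    """
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def reliability_report(
    roi_betas: pd.DataFrame,
    chromophore: str = "HbO",
    condition: str = "speech",
) -> pd.DataFrame:
    """Per-model ICC(3,1) of ROI beta estimates across the two sessions.

    ``roi_betas`` must carry columns (model, subject, session, roi,
    chromophore, condition, beta) with sessions 1 and 2. The headline row
    per model pools subject x ROI targets; per-ROI ICCs are appended as a
    secondary breakdown (roi column set to the ROI name, "pooled"
    otherwise).
    """
    tab = roi_betas[
        (roi_betas["chromophore"] == chromophore) & (roi_betas["condition"] == condition)
    ]
    rows = []
    for model, grp in tab.groupby("model", sort=False):
        wide = grp.pivot_table(index=["subject", "roi"], columns="session", values="beta")
        if set(wide.columns) != {1, 2}:
            raise ValueError("both sessions must be present for every model")
        complete = wide.dropna()
        if len(complete) < len(wide):
            import warnings

            warnings.warn(
                f"{model}: dropped {len(wide) - len(complete)} subject x ROI rows "
                "with a missing session", RuntimeWarning)
        mat = complete.to_numpy()
        val = icc3(mat)
        rows.append(dict(model=model, chromophore=chromophore, roi="pooled",
                         icc=val, category=icc_category(val), n_rows=len(complete), k=2))
        for roi, sub in complete.groupby(level="roi"):
            if len(sub) >= 2:
                v = icc3(sub.to_numpy())
                rows.append(dict(model=model, chromophore=chromophore, roi=roi,
                                 icc=v, category=icc_category(v), n_rows=len(sub), k=2))
    return pd.DataFrame(rows)
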