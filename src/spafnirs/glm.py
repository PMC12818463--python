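"""Design matrices, per-channel GLM fits, ROI/group aggregation, block averages.

Task regressors are canonical double-gamma HRF responses to 6-s stimulus
boxcars; slow drifts are modelled with a discrete-cosine basis below
0.015 Hz; nuisance regressors (short-channel means, tCCA components) are
appended by the denoising stage. Betas are expressed in micromolar of the
peak canonical response to a single stimulus.

Group inference uses the balanced two-stage estimator: inverse-SE-weighted
ROI averages per subject/session, then a subject-level mean with a
one-sample t-test. For a balanced design this is the random-intercept
mixed-model estimate of the group response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "canonical_hrf",
    "task_regressors",
    "cosine_drift_basis",
    "DesignMatrix",
    "build_design_matrix",
    "fit_glm",
    "roi_weighted_beta",
    "group_summary",
    "block_average",
]

HRF_SUPPORT_S = 32.0
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_DISPERSION = 1.0
_UNDERSHOOT_RATIO = 6.0


def _hrf_unscaled(t: np.ndarray) -> np.ndarray:
    h = stats.gamma.pdf(t, _PEAK_DELAY / _DISPERSION, scale=_DISPERSION)
    h = h - stats.gamma.pdf(t, _UNDERSHOOT_DELAY / _DISPERSION, scale=_DISPERSION) / _UNDERSHOOT_RATIO
    h[(t < 0) | (t > HRF_SUPPORT_S)] = 0.0
    return h

# peak of the double-gamma on a dense grid, used for peak normalization
_HRF_PEAK = float(_hrf_unscaled(np.linspace(0, HRF_SUPPORT_S, 32001)).max())


def canonical_hrf(t_grid: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    Peak delay 6 s, undershoot delay 16 s, unit dispersions, 6:1
    peak-to-undershoot ratio, 32 s support.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    if np.any(t < 0):
        raise ValueError("t_grid must be nonnegative")
    return _hrf_unscaled(t) / _HRF_PEAK


def task_regressors(
    events,
    fs_hz: float,
    n_times: int,
    conditions: tuple[str, ...] = ("speech", "silence"),
    ref_duration_s: float = 6.0,
) -> pd.DataFrame:
    """HRF-convolved stimulus boxcars, one column per condition.

    Columns are scaled so that an isolated event of ``ref_duration_s``
    produces a response with peak 1; betas therefore read as micromolar of
    peak evoked response.
    """
    dt = 1.0 / fs_hz
    duration_total = n_times * dt
    kernel_t = np.arange(0.0, HRF_SUPPORT_S + dt / 2, dt)
    kernel = canonical_hrf(kernel_t)

    ref_box = np.zeros(int(round(ref_duration_s * fs_hz)) + len(kernel))
    ref_box[: int(round(ref_duration_s * fs_hz))] = 1.0
    ref_peak = float(np.convolve(ref_box, kernel)[: len(ref_box)].max() * dt)

    cols = {}
    for cond in conditions:
        box = np.zeros(n_times)
        for onset, dur, c in events:
            if c != cond:
                continue
            if onset >= duration_total:
                raise ValueError(f"event at {onset:.1f} s lies past the end of the recording")
            i0 = int(round(onset * fs_hz))
            i1 = min(int(round((onset + dur) * fs_hz)), n_times)
            box[i0:i1] = 1.0
        reg = np.convolve(box, kernel)[:n_times] * dt / ref_peak
        cols[cond] = reg
    return pd.DataFrame(cols)


def cosine_drift_basis(n_times: int, fs_hz: float, cutoff_hz: float = 0.015) -> pd.DataFrame:
    """Discrete-cosine drift columns with frequencies below ``cutoff_hz``.

    Order K = floor(2 * duration * cutoff); the constant term is housed
    separately in the design matrix. Columns are mutually orthogonal on the
    sample grid (DCT-II) and unit-normalized.
    """
    if n_times <= 0:
        raise ValueError("empty timebase")
    duration = n_times / fs_hz
    k_max = int(np.floor(2.0 * duration * cutoff_hz))
    i = np.arange(n_times)
    cols = {}
    for k in range(1, k_max + 1):
        c = np.cos(np.pi * k * (2 * i + 1) / (2 * n_times))
        cols[f"drift_{k}"] = c * np.sqrt(2.0 / n_times)
    return pd.DataFrame(cols, index=None) if cols else pd.DataFrame(index=range(n_times))


@dataclass
class DesignMatrix:
    frame: pd.DataFrame
    column_kind: dict[str, str]  # column -> task | drift | constant | nuisance

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def build_design_matrix(
    task: pd.DataFrame,
    drift: pd.DataFrame,
    nuisance: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Assemble columns in the order task | drift | constant | nuisance."""
    n = len(task)
    blocks = [("task", task), ("drift", drift)]
    const = pd.DataFrame({"constant": np.ones(n)})
    blocks.append(("constant", const))
    if nuisance is not None and nuisance.shape[1] > 0:
        blocks.append(("nuisance", nuisance))
    kinds: dict[str, str] = {}
    frames = []
    for kind, df in blocks:
        if len(df) != n:
            raise ValueError(f"{kind} block length {len(df)} != {n}")
        for col in df.columns:
            if col in kinds:
                raise ValueError(f"duplicate design column label: {col}")
            kinds[col] = kind
        frames.append(df.reset_index(drop=True))
    return DesignMatrix(pd.concat(frames, axis=1), kinds)


def fit_glm(y: np.ndarray, X) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Ordinary least squares of one or many series on a shared design.

    Parameters
    ----------
    y : (n,) or (n, m) array of responses.
    X : (n, p) array, DataFrame, or DesignMatrix.

    Returns ``(betas, ses, residual_df, sigma2)`` with betas/ses shaped
    (p,) or (p, m). Standard errors come from
    ``sigma2 * diag((X'X)^-1)``. Rank-deficient designs fall back to a
    small ridge with a warning.
    """
    if isinstance(X, DesignMatrix):
        X = X.values
    elif isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in GLM input")
    squeeze = y.ndim == 1
    Y = y[:, None] if squeeze else y
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than design columns")

    xtx = X.T @ X
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(diag.max(), 1e-300):
        import warnings

        warnings.warn("rank-deficient design; applying ridge regularization", RuntimeWarning)
        ridge = 1e-8 * np.trace(xtx) / p
        xtx_inv = np.linalg.inv(xtx + ridge * np.eye(p))
        betas = xtx_inv @ (X.T @ Y)
    else:
        # QR solve for numerical stability; (X'X)^-1 via R for the SEs
        betas = np.linalg.solve(R, Q.T @ Y)
        r_inv = np.linalg.inv(R)
        xtx_inv = r_inv @ r_inv.T
    resid = Y - X @ betas
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    ses = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    if squeeze:
        return betas[:, 0], ses[:, 0], df, sigma2[0]
    return betas, ses, df, sigma2


def roi_weighted_beta(channel_table: pd.DataFrame, roi_map: dict[str, str]) -> pd.DataFrame:
    """Inverse-standard-error weighted ROI averages of channel betas.

    ``beta_roi = sum(beta_c / se_c) / sum(1 / se_c)`` over retained channels
    in each ROI (weights are 1/se, following the study's convention, not the
    inverse-variance 1/se^2). ROIs with no surviving channels are absent
    from the output.
    """
    tab = channel_table.copy()
    tab["roi"] = tab["channel"].map(roi_map)
    tab = tab.dropna(subset=["roi"])
    tab["_w"] = 1.0 / np.clip(tab["se"].to_numpy(dtype=float), 1e-12, None)
    tab["_wb"] = tab["_w"] * tab["beta"]
    keys = [c for c in ("subject", "session", "model", "roi", "chromophore", "condition") if c in tab]
    g = tab.groupby(keys, as_index=False)[["_w", "_wb"]].sum()
    g["beta"] = g["_wb"] / g["_w"]
    return g.drop(columns=["_w", "_wb"])


def group_summary(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Group-level response estimate per (roi, condition, chromophore, session).

    Subject-level ROI betas are summarized by their mean, standard error,
    and a two-sided one-sample t-test against zero.
    """
    keys = [c for c in ("model", "roi", "condition", "chromophore", "session") if c in roi_table]
    rows = []
    for key, grp in roi_table.groupby(keys):
        b = grp["beta"].to_numpy(dtype=float)
        nsub = len(b)
        if nsub < 2:
            raise ValueError("group summary requires at least 2 subjects")
        est = b.mean()
        se = b.std(ddof=1) / np.sqrt(nsub)
        if se == 0:
            t, pval = (np.inf if est != 0 else 0.0), (0.0 if est != 0 else 1.0)
        else:
            t = est / se
            pval = 2 * stats.t.sf(abs(t), nsub - 1)
        rows.append(dict(zip(keys, key if isinstance(key, tuple) else (key,)))
                    | {"n": nsub, "estimate": est, "se": se, "t": t, "p": pval})
    return pd.DataFrame(rows)


def block_average(
    hb,
    events,
    window_s: tuple[float, float] = (-2.0, 15.0),
) -> dict[str, dict[str, np.ndarray]]:
    """Baseline-corrected per-condition epoch averages.

    For each condition, epochs of ``window_s`` around every onset are
    extracted from every channel, the pre-onset mean is subtracted, and the
    across-epoch mean and standard error are returned together with the
    epoch time axis.
    """
    fs = hb.fs_hz
    n = hb.hb.shape[-1]
    i_lo = int(np.floor(window_s[0] * fs))
    i_hi = int(np.ceil(window_s[1] * fs))
    rel = np.arange(i_lo, i_hi + 1)
    t_epoch = rel / fs
    out = {}
    conditions = sorted({c for _, _, c in events})
    for cond in conditions:
        epochs = []
        for onset, _dur, c in events:
            if c != cond:
                continue
            i0 = int(round(onset * fs))
            idx = i0 + rel
            if idx[0] < 0 or idx[-1] >= n:
                continue
            ep = hb.hb[:, :, idx]
            base = ep[:, :, rel < 0].mean(axis=-1, keepdims=True)
            epochs.append(ep - base)
        if not epochs:
            raise ValueError(f"no extractable epochs for condition {cond!r}")
        stack = np.stack(epochs)  # (n_ep, n_ch, 2, n_t)
        out[cond] = {
            "t": t_epoch,
            "mean": stack.mean(axis=0),
            "se": stack.std(axis=0, ddof=1) / np.sqrt(len(epochs)),
            "n_epochs": len(epochs),
        }
    return out
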