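"""Nuisance-regressor construction for the three denoising models.

Three configurations are supported: ``none`` (no nuisance regressors),
``ss`` (the mean of all retained short-separation channels, one column per
chromophore), and ``ss_tcca`` (the short-channel columns plus canonical
variates from a temporally embedded CCA between the lag-embedded,
conditioned physiology signals and the long-channel fNIRS block).

Physiology signals are admitted to the tCCA only if their maximum absolute
lagged correlation (lags 0..10 s) with the mean long-channel HbO series
reaches the inclusion criterion (default 0.3); canonical components are
retained by the same criterion applied to their canonical correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NuisanceSet",
    "TccaFit",
    "short_channel_nuisance",
    "embed_lags",
    "screen_physiology",
    "fit_tcca",
    "tcca_regressors",
]

MODELS = ("none", "ss", "ss_tcca")


@dataclass
class NuisanceSet:
    model: str  # none | ss | ss_tcca
    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown nuisance model {self.model!r}")
        if self.model == "none" and self.frame.shape[1] != 0:
            raise ValueError("the 'none' model carries no nuisance columns")
        if self.frame.size and not np.all(np.isfinite(self.frame.to_numpy())):
            raise ValueError("non-finite nuisance column")


def empty_nuisance(n_times: int) -> NuisanceSet:
    return NuisanceSet("none", pd.DataFrame(index=range(n_times)))


def short_channel_nuisance(hb, montage, retained: dict[str, bool] | None = None) -> NuisanceSet:
    """Mean of retained short-separation channels, per chromophore.

    Near-constant columns (degenerate montages) are flagged and dropped so
    they cannot render the design singular.
    """
    short = [c.name for c in montage.short_channels]
    if retained is not None:
        short = [name for name in short if retained.get(name, False)]
    if not short:
        raise ValueError(
            "no retained short channels: fall back to the 'none' denoising model"
        )
    idx = [hb.channel_names.index(name) for name in short]
    cols = {}
    prov = {}
    flagged = []
    for k, chrom in enumerate(hb.chromophores):
        series = hb.hb[idx, k, :].mean(axis=0)
        label = f"ss_mean_{chrom.lower()}"
        if series.std() < 1e-12 * max(1.0, np.abs(series).max()):
            flagged.append(label)
            continue
        cols[label] = series
        prov[label] = f"short_channel_mean_{chrom}"
    if flagged:
        warnings.warn(f"constant short-channel nuisance column(s) dropped: {flagged}",
                      RuntimeWarning)
    frame = pd.DataFrame(cols) if cols else pd.DataFrame(index=range(hb.hb.shape[-1]))
    return NuisanceSet("ss", frame, prov, flagged)


def embed_lags(
    x: np.ndarray, fs_hz: float, max_lag_s: float = 10.0, step_samples: int = 1
) -> np.ndarray:
    """Temporal embedding: columns are the signal delayed by 0, step,
    2*step, ... samples up to ``max_lag_s``, rows aligned to the undelayed
    timebase with leading gaps edge-padded."""
    x = np.asarray(x, dtype=float)
    max_lag = int(np.floor(max_lag_s * fs_hz))
    if max_lag >= len(x):
        raise ValueError("maximum lag exceeds the signal length")
    lags = range(0, max_lag + 1, step_samples)
    cols = []
    for k in lags:
        if k == 0:
            cols.append(x)
        else:
            cols.append(np.concatenate([np.full(k, x[0]), x[:-k]]))
    return np.column_stack(cols)


def _max_lagged_corr(sig: np.ndarray, ref: np.ndarray, fs_hz: float, max_lag_s: float):
    """Max |Pearson correlation| between `sig` and `ref` over relative
    delays of 0..max_lag_s applied to either series (physiology may lead or
    lag the hemodynamic signal)."""
    best, best_lag = 0.0, 0.0
    for a, b, sign in ((sig, ref, 1.0), (ref, sig, -1.0)):
        emb = embed_lags(a, fs_hz, max_lag_s)
        emb = emb - emb.mean(axis=0)
        r = b - b.mean()
        denom = np.sqrt((emb**2).sum(axis=0) * (r**2).sum())
        with np.errstate(invalid="ignore"):
            corr = np.nan_to_num(emb.T @ r / denom)
        k = int(np.argmax(np.abs(corr)))
        if abs(corr[k]) > best:
            best, best_lag = float(abs(corr[k])), sign * k / fs_hz
    return best, best_lag


def screen_physiology(
    conditioned_aux: dict[str, np.ndarray],
    fnirs_reference: np.ndarray,
    fs_hz: float,
    max_lag_s: float = 10.0,
    threshold: float = 0.3,
):
    """Inclusion screening of physiology signals against the fNIRS reference
    (mean retained long-channel HbO).

    Returns ``(included_names, correlations)`` where ``correlations`` maps
    every signal to its maximum absolute lagged Pearson correlation.
    """
    ref = np.asarray(fnirs_reference, dtype=float)
    if ref.size == 0 or ref.std() == 0:
        raise ValueError("empty or constant fNIRS reference series")
    corrs: dict[str, float] = {}
    for name, sig in conditioned_aux.items():
        c, _lag = _max_lagged_corr(np.asarray(sig, dtype=float), ref, fs_hz, max_lag_s)
        corrs[name] = c
    included = [n for n, c in corrs.items() if c >= threshold]
    return included, corrs


@dataclass
class TccaFit:
    included_signals: list[str]
    lags_s: pd.DataFrame                 # channels x signals, optimal lag (s)
    canonical_correlations: np.ndarray   # descending, in [0, 1]
    components: np.ndarray               # (n_times, n_components) aux-side variates
    aux_columns: list[str]               # labels of the embedded aux block


def fit_tcca(
    conditioned_aux: dict[str, np.ndarray],
    fnirs_block: np.ndarray,
    fs_hz: float,
    channel_names: list[str] | None = None,
    max_lag_s: float = 10.0,
    step_samples: int = 1,
    ridge: float | None = None,
) -> TccaFit:
    """Temporally embedded CCA between physiology and the fNIRS block.

    All included signals are lag-embedded (0..``max_lag_s``), concatenated
    into one aux block, and canonically decomposed against the multichannel
    fNIRS block. One global decomposition is fitted; per (channel, signal)
    optimal lags are recorded from the lagged cross-correlations.

    Rank-deficient blocks fall back to ridge-regularized whitening (ridge =
    1e-4 x mean block variance) with a warning.
    """
    if not conditioned_aux:
        raise ValueError("need at least one included physiology signal")
    names = list(conditioned_aux)
    Y = np.asarray(fnirs_block, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]

    blocks, labels = [], []
    max_lag = int(np.floor(max_lag_s * fs_hz))
    for name in names:
        emb = embed_lags(conditioned_aux[name], fs_hz, max_lag_s, step_samples)
        blocks.append(emb)
        labels.extend(f"{name}@{k}" for k in range(0, max_lag + 1, step_samples))
    A = np.column_stack(blocks)
    if n <= A.shape[1] + Y.shape[1]:
        raise ValueError("need more time samples than total embedded columns")

    A = A - A.mean(axis=0)
    B = Y - Y.mean(axis=0)

    def _whiten(M, lam):
        C = M.T @ M / n
        if lam:
            C = C + lam * np.eye(C.shape[0])
        return np.linalg.cholesky(C)

    lam_a = lam_b = 0.0 if ridge is None else ridge
    try:
        La, Lb = _whiten(A, lam_a), _whiten(B, lam_b)
        if (np.linalg.cond(La) > 1e8) or (np.linalg.cond(Lb) > 1e8):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient tCCA blocks; applying ridge regularization",
                      RuntimeWarning)
        lam_a = 1e-4 * float(np.mean(np.sum(A**2, axis=0) / n))
        lam_b = 1e-4 * float(np.mean(np.sum(B**2, axis=0) / n))
        La, Lb = _whiten(A, lam_a), _whiten(B, lam_b)

    Cab = A.T @ B / n
    M = np.linalg.solve(La, np.linalg.solve(Lb, Cab.T).T)
    U, s, _Vt = np.linalg.svd(M, full_matrices=False)
    corr = np.clip(s, 0.0, 1.0)
    wa = np.linalg.solve(La.T, U)  # aux-side canonical weights
    variates = A @ wa
    sd = variates.std(axis=0)
    sd[sd == 0] = 1.0
    variates = variates / sd

    # per (channel, signal) optimal lag via lagged cross-correlation
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(Y.shape[1])]
    lag_rows = {}
    for name in names:
        emb = blocks[names.index(name)]
        embc = emb - emb.mean(axis=0)
        norm_e = np.sqrt((embc**2).sum(axis=0))
        norm_b = np.sqrt((B**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = np.abs(embc.T @ B) / np.outer(norm_e, norm_b)
        cc = np.nan_to_num(cc)
        lag_rows[name] = np.argmax(cc, axis=0) * step_samples / fs_hz
    lags = pd.DataFrame(lag_rows, index=channel_names)

    return TccaFit(names, lags, corr, variates, labels)


def tcca_regressors(
    fit: TccaFit,
    ss: NuisanceSet,
    inclusion_threshold: float = 0.3,
) -> NuisanceSet:
    """SS + tCCA nuisance set: the short-channel columns plus canonical
    variates whose canonical correlation reaches the inclusion threshold.
    With zero retained components the set degenerates to the SS columns."""
    keep = np.where(fit.canonical_correlations >= inclusion_threshold)[0]
    frame = ss.frame.copy()
    prov = dict(ss.provenance)
    for rank, k in enumerate(keep, start=1):
        label = f"tcca_{rank}"
        frame[label] = fit.components[:, k]
        prov[label] = f"tcca_component_{rank}"
    return NuisanceSet("ss_tcca", frame, prov, list(ss.flagged))
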