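"""End-to-end study runs: simulate -> preprocess -> denoise -> GLM ->
reliability -> geometry, with deterministic seeding and audit logging.

`run_study` executes the full analysis for every requested denoising model
on both sessions of every subject and returns a results bundle of tidy
tables. All randomness flows from the single config seed through
per-subject/per-session substreams, so outputs are bit-reproducible for a
fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import denoise, geometry, glm, preprocess
from .reliability import reliability_report
from .synthetic import (
    EventConfig,
    GroundTruth,
    SessionRecording,
    StudyConfig,
    StudySimulation,
    simulate_study,
)

logger = logging.getLogger("spafnirs")

__all__ = ["RunConfig", "StudyResult", "run_study", "process_session", "load_recording"]

DEFAULT_MODELS = ("none", "ss", "ss_tcca")


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the study's settings."""

    seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    models: tuple[str, ...] = DEFAULT_MODELS
    sci_threshold: float | None = 0.7
    target_fs: float = 0.6
    dpf: float = 6.0
    drift_cutoff_hz: float = 0.015
    physio_lowpass_hz: float = 0.5
    tcca_max_lag_s: float = 10.0
    screening_threshold: float = 0.3
    tcca_inclusion_threshold: float = 0.3

    def hash(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, tuple):
                return list(o)
            return asdict(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SessionFeatures:
    """Per-session intermediates shared by all denoising models."""

    hb: preprocess.HemoglobinSeries      # working rate
    quality: preprocess.ChannelQuality
    cond_aux: dict[str, np.ndarray]      # conditioned physiology, working rate
    excluded_aux: list[str]
    design_blocks: tuple[pd.DataFrame, pd.DataFrame]  # task, drift
    recording: SessionRecording


def process_session(recording: SessionRecording, montage, cfg: RunConfig) -> SessionFeatures:
    """Preprocess one session: OD, SCI pruning, Beer-Lambert, resampling,
    physiology conditioning, and the model-independent design blocks."""
    od = preprocess.intensity_to_od(recording)
    if cfg.sci_threshold is not None:
        quality = preprocess.prune_channels(
            preprocess.scalp_coupling_index(od), cfg.sci_threshold
        )
        removed = [n for n, r in quality.retained.items() if not r]
        if removed:
            logger.info("%s ses-%d: pruned %d channels: %s",
                        recording.subject_id, recording.session_id, len(removed), removed)
    else:
        quality = preprocess.ChannelQuality(
            sci={n: float("nan") for n in recording.channel_names},
            retained={n: True for n in recording.channel_names},
        )
    hb_native = preprocess.beer_lambert(od, montage, cfg.dpf)
    hb_rs, fs_rs = preprocess.resample_series(hb_native.hb, recording.fs_hz, cfg.target_fs)
    hb = preprocess.HemoglobinSeries(hb_rs, fs_rs, hb_native.channel_names)

    # Task regressors are built on the acquisition grid and passed through
    # the same resampling operator as the data (design filtered like data).
    task_native = glm.task_regressors(recording.events, recording.fs_hz, recording.n_times)
    task_rs, _ = preprocess.resample_series(task_native.to_numpy().T, recording.fs_hz,
                                            cfg.target_fs)
    task = pd.DataFrame(task_rs.T, columns=task_native.columns)
    n_rs = hb.hb.shape[-1]
    task = task.iloc[:n_rs].reset_index(drop=True)
    drift = glm.cosine_drift_basis(n_rs, fs_rs, cfg.drift_cutoff_hz)

    cond_native, excluded = preprocess.condition_physiology(
        recording.aux, recording.fs_hz, recording.n_times, cfg.physio_lowpass_hz
    )
    cond_aux = {}
    for name, sig in cond_native.items():
        rs, _ = preprocess.resample_series(sig, recording.fs_hz, cfg.target_fs)
        cond_aux[name] = rs[:n_rs]
    if excluded:
        logger.info("%s ses-%d: constant aux signals excluded: %s",
                    recording.subject_id, recording.session_id, excluded)
    return SessionFeatures(hb, quality, cond_aux, excluded, (task, drift), recording)


def _nuisance_for(model: str, feats: SessionFeatures, montage, cfg: RunConfig):
    """Build the nuisance set and the screening/tCCA audit info for a model."""
    n_rs = feats.hb.hb.shape[-1]
    info: dict = {}
    if model == "none":
        return denoise.empty_nuisance(n_rs), info
    ss = denoise.short_channel_nuisance(feats.hb, montage, feats.quality.retained)
    if model == "ss":
        return ss, info
    # ss_tcca
    long_retained = [c.name for c in montage.long_channels
                     if feats.quality.retained.get(c.name, False)]
    idx = [feats.hb.channel_names.index(n) for n in long_retained]
    hbo_block = feats.hb.hb[idx, 0, :].T  # (n_times, n_channels)
    reference = hbo_block.mean(axis=1)
    if not feats.cond_aux:
        logger.info("no usable aux physiology; ss_tcca degenerates to ss")
        return denoise.NuisanceSet("ss_tcca", ss.frame, ss.provenance, ss.flagged), info
    included, corrs = denoise.screen_physiology(
        feats.cond_aux, reference, feats.hb.fs_hz,
        cfg.tcca_max_lag_s, cfg.screening_threshold,
    )
    info["screening"] = corrs
    info["included_signals"] = included
    if not included:
        logger.info("no physiology signal passed screening; ss_tcca degenerates to ss")
        return denoise.NuisanceSet("ss_tcca", ss.frame, ss.provenance, ss.flagged), info
    fit = denoise.fit_tcca(
        {k: feats.cond_aux[k] for k in included}, hbo_block, feats.hb.fs_hz,
        channel_names=long_retained, max_lag_s=cfg.tcca_max_lag_s,
    )
    info["canonical_correlations"] = fit.canonical_correlations
    nuis = denoise.tcca_regressors(fit, ss, cfg.tcca_inclusion_threshold)
    info["n_tcca_components"] = nuis.frame.shape[1] - ss.frame.shape[1]
    logger.info("tCCA retained %d components (cc1=%.3f)",
                info["n_tcca_components"],
                fit.canonical_correlations[0] if len(fit.canonical_correlations) else 0.0)
    return nuis, info


def _fit_session(feats: SessionFeatures, montage, cfg: RunConfig):
    """Fit every requested model on one session; returns channel beta rows."""
    task, drift = feats.design_blocks
    rows = []
    screen_rows = []
    rec = feats.recording
    Y = feats.hb.hb.reshape(len(feats.hb.channel_names) * 2, -1).T  # (n, ch*chrom)
    for model in cfg.models:
        nuis, info = _nuisance_for(model, feats, montage, cfg)
        X = glm.build_design_matrix(task, drift, nuis.frame)
        betas, ses, _df, _s2 = glm.fit_glm(Y, X)
        for cond in task.columns:
            irow = X.columns.index(cond)
            b = betas[irow].reshape(len(feats.hb.channel_names), 2)
            se = ses[irow].reshape(len(feats.hb.channel_names), 2)
            for i, ch in enumerate(feats.hb.channel_names):
                if not feats.quality.retained.get(ch, True):
                    continue
                for k, chrom in enumerate(feats.hb.chromophores):
                    rows.append(dict(
                        subject=rec.subject_id, session=rec.session_id, model=model,
                        channel=ch, chromophore=chrom, condition=cond,
                        beta=b[i, k], se=se[i, k],
                    ))
        if "screening" in info:
            for name, c in info["screening"].items():
                screen_rows.append(dict(
                    subject=rec.subject_id, session=rec.session_id, signal=name,
                    max_abs_corr=c, included=name in info["included_signals"],
                ))
    return pd.DataFrame(rows), pd.DataFrame(screen_rows)


@dataclass
class StudyResult:
    config: RunConfig
    config_hash: str
    simulation: StudySimulation
    channel_betas: pd.DataFrame
    roi_betas: pd.DataFrame
    group_summaries: pd.DataFrame
    reliability: pd.DataFrame
    screening: pd.DataFrame
    shift_summary: geometry.ShiftSummary | None
    association: tuple[float, float] | None

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": self.config_hash}
        for name, tab in [
            ("betas.tsv", self.channel_betas),
            ("roi_betas.tsv", self.roi_betas),
            ("group_summary.tsv", self.group_summaries),
            ("reliability.tsv", self.reliability),
            ("screening.tsv", self.screening),
        ]:
            t = tab.copy()
            t["config_hash"] = self.config_hash
            t.to_csv(out / name, sep="\t", index=False)
        if self.shift_summary is not None:
            self.shift_summary.shifts.assign(config_hash=self.config_hash).to_csv(
                out / "shifts.tsv", sep="\t", index=False)
            self.shift_summary.dispersion.assign(config_hash=self.config_hash).to_csv(
                out / "dispersion.tsv", sep="\t", index=False)
        if self.association is not None:
            meta["association_r"], meta["association_p"] = self.association

        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, tuple):
                return list(o)
            return asdict(o)

        meta["config"] = json.loads(json.dumps(asdict(self.config), default=default))
        (out / "run.json").write_text(json.dumps(meta, indent=2))


def run_study(config: RunConfig | None = None,
              simulation: StudySimulation | None = None) -> StudyResult:
    """Execute the full pipeline on a simulated (or supplied) study."""
    cfg = config or RunConfig()
    for m in cfg.models:
        if m not in DEFAULT_MODELS:
            raise ValueError(f"unknown denoising model {m!r}")
    sim = simulation if simulation is not None else simulate_study(cfg.study, cfg.seed)
    montage = sim.montage

    beta_tabs, screen_tabs = [], []
    for rec1, rec2 in sim.recordings:
        for rec in (rec1, rec2):
            try:
                feats = process_session(rec, montage, cfg)
                b, s = _fit_session(feats, montage, cfg)
            except Exception as exc:
                raise RuntimeError(
                    f"stage failure in subject {rec.subject_id} "
                    f"session {rec.session_id}: {exc}"
                ) from exc
            beta_tabs.append(b)
            if len(s):
                screen_tabs.append(s)
    channel_betas = pd.concat(beta_tabs, ignore_index=True)
    screening = (pd.concat(screen_tabs, ignore_index=True)
                 if screen_tabs else pd.DataFrame())

    roi_betas = glm.roi_weighted_beta(channel_betas, montage.roi_map)
    group = glm.group_summary(roi_betas)
    rel = reliability_report(roi_betas)

    shift = None
    assoc = None
    if sim.scans:
        shift = geometry.shift_summary([a for a, _ in sim.scans], [b for _, b in sim.scans])
        assoc = _shift_beta_assoc(sim, channel_betas, montage, cfg)

    return StudyResult(cfg, cfg.hash(), sim, channel_betas, roi_betas, group,
                       rel, screening, shift, assoc)


def _shift_beta_assoc(sim, channel_betas, montage, cfg):
    """Channel-midpoint shift vs |session change in speech HbO beta|.

    Uses the most corrected model available (ss_tcca, else ss, else none).
    """
    model = next((m for m in ("ss_tcca", "ss", "none") if m in cfg.models), None)
    if model is None:
        return None
    tab = channel_betas[
        (channel_betas["model"] == model)
        & (channel_betas["chromophore"] == "HbO")
        & (channel_betas["condition"] == "speech")
    ]
    wide = tab.pivot_table(index=["subject", "channel"], columns="session", values="beta")
    if set(wide.columns) != {1, 2}:
        return None
    pairs_x, pairs_y = [], []
    scans = {(s1.subject_id): (s1, s2) for s1, s2 in sim.scans}
    chan_by_name = {c.name: c for c in montage.long_channels}
    for (subj, ch), row in wide.dropna().iterrows():
        if subj not in scans or ch not in chan_by_name:
            continue
        s1, s2 = scans[subj]
        c = chan_by_name[ch]
        if c.source not in s1.optode_coords or c.detector not in s1.optode_coords:
            continue
        m1 = geometry.channel_midpoint(s1.optode_coords[c.source], s1.optode_coords[c.detector])
        m2 = geometry.channel_midpoint(s2.optode_coords[c.source], s2.optode_coords[c.detector])
        pairs_x.append(geometry.euclidean_shift(m1, m2))
        pairs_y.append(abs(row[2] - row[1]))
    if len(pairs_x) < 3:
        return None
    return geometry.shift_beta_association(pairs_x, pairs_y)


def load_recording(path, fmt: str = "tsv", **kwargs) -> SessionRecording:
    """Load a session from a TSV trio directory or a SNIRF file."""
    from . import io as _io

    if fmt == "tsv":
        return _io.read_session_tsv(path, **kwargs)
    if fmt == "snirf":
        return _io.read_snirf(path, **kwargs)
    raise ValueError(f"unrecognized format {fmt!r}")
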