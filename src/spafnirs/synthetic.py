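"""Synthetic two-session SPA-fNIRS studies with known ground truth.

The generator emulates the structure of a passive-listening test-retest
study: 15 subjects x 2 sessions, two-wavelength (760/850 nm) intensities at
5.1 Hz over 38 long (~30 mm) and 8 short (8 mm) channels, 40 speech + 10
silence trials of ~6 s with 15-30 s inter-stimulus intervals, six auxiliary
physiology sensors, and per-session digitized optode coordinates.

The forward model composes, in concentration space (micromolar):

* neural responses — canonical HRF x 6-s boxcar, long channels only, with
  ROI-specific amplitudes carrying subject- and session-level random
  effects;
* a scalp (extracerebral) component — a stimulus-locked vasoconstriction
  response with negative HbO sign plus a slow scalp oscillation, at full
  gain in short channels and partial gain in long channels;
* systemic physiology — latent respiration / cardiac / heart-rate / SpO2 /
  temperature / skin-conductance processes, each injected per channel at a
  lag of up to 10 s, with task-evoked components (arousal responses to the
  stimuli) whose session-varying amplitudes are what full-body denoising
  can remove and short-channel regression cannot;
* white optical-density measurement noise.

Intensities are ``exp(-OD)`` of the composed optical density, so the
preprocessing chain (log-ratio OD, Beer-Lambert) is its exact inverse. The
auxiliary sensors record the *same* latent processes (plus sensor noise),
which is what makes physiology-informed denoising identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .glm import task_regressors
from .montage import MontageSpec, make_montage
from .preprocess import extinction_matrix

__all__ = [
    "SIGNALS",
    "AuxSeries",
    "EventSchedule",
    "EventConfig",
    "GroundTruth",
    "SessionRecording",
    "DigitizedScan",
    "StudyConfig",
    "StudySimulation",
    "sample_events",
    "simulate_session",
    "simulate_study",
    "jitter_scan",
    "noise_free_truth",
]

SIGNALS = ("ppg", "heart_rate", "spo2", "temperature", "gsr", "respiration")

AUX_FS_HZ = {
    "ppg": 25.0,
    "heart_rate": 1.0,
    "spo2": 1.0,
    "temperature": 1.0,
    "gsr": 4.0,
    "respiration": 10.0,
}

# sensor-unit offset/scale applied on top of the unit-variance latents
AUX_UNITS = {
    "ppg": (0.0, 1.0),
    "heart_rate": (70.0, 6.0),   # bpm
    "spo2": (98.0, 0.4),         # percent
    "temperature": (33.5, 0.8),  # deg C, palm
    "gsr": (5.0, 1.5),           # microsiemens
    "respiration": (0.0, 1.0),   # a.u. (bioimpedance)
}


@dataclass
class AuxSeries:
    values: np.ndarray
    fs_hz: float


@dataclass
class EventSchedule:
    """Stimulus schedule: (onset_s, duration_s, condition) rows."""

    events: list[tuple[float, float, str]]

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e[0] for e in self.events])

    def span_s(self) -> float:
        if not self.events:
            return 0.0
        return self.events[-1][0] + self.events[-1][1]


@dataclass
class EventConfig:
    n_speech: int = 40
    n_silence: int = 10
    duration_s: float = 6.0
    isi_s: tuple[float, float] = (15.0, 30.0)
    pre_rest_s: float = 90.0
    post_rest_s: float = 90.0


@dataclass
class GroundTruth:
    """Generator parameters: the study conditions the simulator emulates.

    Amplitudes are micromolar; coupling gains are micromolar per unit
    (z-scored) latent physiology; lags are seconds in [0, 10].
    """

    # ROI-level neural response amplitudes, HbO, speech condition (uM).
    beta_speech_hbo: dict[str, float] = field(
        default_factory=lambda: {
            "IFG_L": 0.4, "IFG_R": 0.4,
            "A1_L": 1.2, "A1_R": 1.2,
            "A2_L": 0.7, "A2_R": 0.7,
        }
    )
    beta_silence_hbo: float = 0.0
    hbr_neural_ratio: float = -0.35

    # scalp (extracerebral) component
    scalp_amplitude: float = -1.5      # stimulus-locked HbO response, uM (negative)
    scalp_amplitude_sd: float = 0.5    # across subject-sessions
    scalp_osc_um: float = 0.8          # slow scalp oscillation amplitude, uM
    scalp_long_gain: float = 0.5       # long-channel fraction of the scalp signal
    scalp_hbr_ratio: float = -0.3

    # systemic physiology coupling (uM per z unit); 'ppg' is the cardiac
    # pulsation that also provides the scalp-coupling cardiac signal
    coupling_gain: dict[str, float] = field(
        default_factory=lambda: {
            "ppg": 1.5, "heart_rate": 0.35, "spo2": 0.12,
            "temperature": 0.6, "gsr": 0.4, "respiration": 0.7,
        }
    )
    # task-evoked physiological response amplitudes (z units)
    evoked_amp: dict[str, float] = field(
        default_factory=lambda: {
            "ppg": 0.0, "heart_rate": 0.2, "spo2": 0.03,
            "temperature": 0.08, "gsr": 0.25, "respiration": 0.25,
        }
    )
    evoked_session_sd: float = 0.5     # relative session-to-session variation
    lag_range_s: tuple[float, float] = (2.0, 8.0)
    lag_channel_jitter_s: float = 0.5
    gain_channel_sd: float = 0.3       # lognormal sd of per-channel gain modulation
    short_physio_factor: float = 0.05  # body-physiology leak into short channels
    short_cardiac_boost: float = 3.0   # scalp pulsatility in short channels
    physio_hbr_ratio: float = -0.3
    cardiac_hbr_ratio: float = 0.1

    noise_od: float = 1e-3             # white OD noise sd per sample
    aux_noise_sd: float = 0.05         # sensor noise (z units)
    between_subject_sd: float = 0.5    # uM, subject x ROI random effect
    between_session_sd: float = 0.1    # uM, session random effect
    decoupled_channels: tuple[str, ...] = ()  # channels with no optical coupling
    dpf: float = 6.0

    def __post_init__(self) -> None:
        if self.noise_od < 0 or self.between_subject_sd < 0 or self.between_session_sd < 0:
            raise ValueError("variance components must be nonnegative")
        lo, hi = self.lag_range_s
        if lo < 0 or hi > 10.0 or lo > hi:
            raise ValueError("physiology lags must lie within [0, 10] s")


def noise_free_truth() -> GroundTruth:
    """All noise, physiology, and scalp contributions switched off."""
    return GroundTruth(
        scalp_amplitude=0.0, scalp_amplitude_sd=0.0, scalp_osc_um=0.0,
        coupling_gain={s: 0.0 for s in SIGNALS},
        evoked_amp={s: 0.0 for s in SIGNALS},
        noise_od=0.0, aux_noise_sd=0.0,
        between_subject_sd=0.0, between_session_sd=0.0,
    )


@dataclass
class SessionRecording:
    intensities: np.ndarray  # (n_channels, 2, n_times), strictly positive
    channel_names: list[str]
    aux: dict[str, AuxSeries]
    events: EventSchedule
    subject_id: str
    session_id: int
    fs_hz: float = 5.1
    wavelengths: tuple[float, float] = (760.0, 850.0)

    @property
    def n_times(self) -> int:
        return self.intensities.shape[-1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs_hz


@dataclass
class DigitizedScan:
    fiducials: dict[str, np.ndarray]  # Iz, Cz, Nz, RPA, LPA -> MNI xyz (mm)
    optode_coords: dict[str, np.ndarray]
    subject_id: str
    session_id: int

    def __post_init__(self) -> None:
        for name in ("Iz", "Cz", "Nz", "RPA", "LPA"):
            if name not in self.fiducials:
                raise ValueError(f"missing fiducial {name}")
        for coords in list(self.fiducials.values()) + list(self.optode_coords.values()):
            if not np.all(np.isfinite(coords)):
                raise ValueError("non-finite coordinate")


def sample_events(config: EventConfig | None = None, seed: int = 0) -> EventSchedule:
    """Randomized block-design schedule with uniform inter-stimulus gaps."""
    cfg = config or EventConfig()
    if cfg.n_speech < 0 or cfg.n_silence < 0:
        raise ValueError("event counts must be nonnegative")
    lo, hi = cfg.isi_s
    if not 0 < lo <= hi:
        raise ValueError("ISI bounds must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    conditions = ["speech"] * cfg.n_speech + ["silence"] * cfg.n_silence
    rng.shuffle(conditions)
    events = []
    t = cfg.pre_rest_s
    for i, cond in enumerate(conditions):
        events.append((float(t), cfg.duration_s, cond))
        t += cfg.duration_s
        if i < len(conditions) - 1:
            t += float(rng.uniform(lo, hi))
    return EventSchedule(events)


def recording_duration_s(events: EventSchedule, config: EventConfig | None = None) -> float:
    cfg = config or EventConfig()
    return events.span_s() + cfg.post_rest_s


# ---------------------------------------------------------------------------
# latent physiology processes


def _smooth_noise(rng, n, fs, cutoff_hz, order=4):
    """Unit-variance low-frequency Gaussian process (filtered white noise)."""
    w = rng.standard_normal(n + 2 * n // 4)
    sos = sps.butter(order, min(cutoff_hz / (fs / 2.0), 0.99), btype="low", output="sos")
    x = sps.sosfilt(sos, w)[n // 4 : n // 4 + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _oscillator(rng, n, fs, f0, f_jitter_hz, harmonic=0.0):
    """Narrowband oscillator with slowly drifting instantaneous rate."""
    drift = _smooth_noise(rng, n, fs, 0.01)
    freq = f0 + f_jitter_hz * drift
    phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    x = np.sin(phase) + harmonic * np.sin(2 * phase)
    return x / x.std()


def _evoked_kernel(fs, delay_s=4.0, width_s=5.0):
    """Delayed gamma-shaped autonomic response kernel, peak 1."""
    t = np.arange(0.0, delay_s + 4 * width_s, 1.0 / fs)
    shape = max((delay_s / width_s) ** 2 * 4, 1.5)
    scale = delay_s / shape
    from scipy.stats import gamma

    k = gamma.pdf(t, shape, scale=scale)
    return k / k.max()


def _latent_processes(rng, n, fs, events, truth, evoked_amps):
    """Latent unit-variance physiology processes + task-evoked components."""
    hr_var = _smooth_noise(rng, n, fs, 0.05)
    latents = {
        "respiration": _oscillator(rng, n, fs, 0.25, 0.03, harmonic=0.2),
        "ppg": _oscillator(rng, n, fs, 1.1, 0.1, harmonic=0.3),
        "heart_rate": hr_var,
        "spo2": _smooth_noise(rng, n, fs, 0.01),
        "temperature": _smooth_noise(rng, n, fs, 0.03),
        "gsr": _smooth_noise(rng, n, fs, 0.08),
    }
    # stimulus-evoked autonomic responses (shared by channels and sensors)
    onset_train = np.zeros(n)
    for onset, _dur, _cond in events:
        i = int(round(onset * fs))
        if i < n:
            onset_train[i] = 1.0
    delays = {"respiration": 2.5, "heart_rate": 2.0, "gsr": 4.0,
              "temperature": 6.0, "spo2": 5.0, "ppg": 2.0}
    for name in SIGNALS:
        amp = evoked_amps.get(name, 0.0)
        if amp == 0.0:
            continue
        kern = _evoked_kernel(fs, delay_s=delays[name])
        ev = np.convolve(onset_train, kern)[:n]
        latents[name] = latents[name] + amp * ev
    return latents


@dataclass
class SessionEffects:
    """Realized per-session random effects (drawn by `simulate_study`)."""

    beta_hbo: dict[str, dict[str, float]]  # roi -> condition -> uM
    scalp_amplitude: float
    lag_s: np.ndarray        # (n_channels, n_signals)
    gain: np.ndarray         # (n_channels, n_signals), uM per z
    evoked_amps: dict[str, float]


def _default_effects(montage: MontageSpec, truth: GroundTruth, rng) -> SessionEffects:
    n_ch = len(montage.channels)
    n_sig = len(SIGNALS)
    lo, hi = truth.lag_range_s
    base_lag = rng.uniform(lo, hi, size=n_sig)
    lag = base_lag[None, :] + rng.uniform(
        -truth.lag_channel_jitter_s, truth.lag_channel_jitter_s, size=(n_ch, n_sig)
    )
    lag = np.clip(lag, 0.0, 10.0)
    gain = np.empty((n_ch, n_sig))
    is_short = np.array([c.kind == "short" for c in montage.channels])
    for j, name in enumerate(SIGNALS):
        g = truth.coupling_gain.get(name, 0.0)
        mod = np.exp(rng.normal(0.0, truth.gain_channel_sd, size=n_ch))
        gain[:, j] = g * mod
        if name == "ppg":
            gain[is_short, j] *= truth.short_cardiac_boost
        else:
            gain[is_short, j] *= truth.short_physio_factor
    beta = {
        roi: {"speech": truth.beta_speech_hbo[roi], "silence": truth.beta_silence_hbo}
        for roi in truth.beta_speech_hbo
    }
    scalp = truth.scalp_amplitude + truth.scalp_amplitude_sd * rng.standard_normal()
    evoked = {
        name: truth.evoked_amp.get(name, 0.0)
        * max(0.0, 1.0 + truth.evoked_session_sd * rng.standard_normal())
        for name in SIGNALS
    }
    return SessionEffects(beta, scalp, lag, gain, evoked)


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    """Delay a series by k samples, edge-padding the start."""
    if k <= 0:
        return x
    return np.concatenate([np.full(k, x[0]), x[:-k]])


def simulate_session(
    montage: MontageSpec,
    events: EventSchedule,
    truth: GroundTruth,
    seed,
    subject_id: str = "S01",
    session_id: int = 1,
    effects: SessionEffects | None = None,
    duration_s: float | None = None,
) -> SessionRecording:
    """Forward-model one subject-session into a raw `SessionRecording`."""
    rng = np.random.default_rng(seed)
    fs = 5.1
    dur = duration_s if duration_s is not None else events.span_s() + 90.0
    n = int(np.ceil(dur * fs))
    eff = effects if effects is not None else _default_effects(montage, truth, rng)
    if np.any(eff.lag_s < 0) or np.any(eff.lag_s > 10.0):
        raise ValueError("physiology lags must lie within [0, 10] s")

    chans = montage.channels
    n_ch = len(chans)
    hbo = np.zeros((n_ch, n))
    hbr = np.zeros((n_ch, n))

    # --- neural responses (long channels only)
    task = task_regressors(events, fs, n)
    for i, ch in enumerate(chans):
        if ch.kind != "long":
            continue
        roi = montage.roi_map[ch.name]
        for cond in task.columns:
            b = eff.beta_hbo.get(roi, {}).get(cond, 0.0)
            if b:
                hbo[i] += b * task[cond].to_numpy()
                hbr[i] += truth.hbr_neural_ratio * b * task[cond].to_numpy()

    # --- scalp component: stimulus-locked vasoconstriction + slow oscillation
    speech_resp = task["speech"].to_numpy() if "speech" in task else np.zeros(n)
    scalp = eff.scalp_amplitude * speech_resp
    if truth.scalp_osc_um > 0:
        band = sps.butter(3, [0.04 / (fs / 2), 0.12 / (fs / 2)], btype="band", output="sos")
        osc = sps.sosfilt(band, rng.standard_normal(n + n // 2))[n // 2 :]
        sd = osc.std()
        if sd > 0:
            scalp = scalp + truth.scalp_osc_um * osc / sd
    scalp_gain = np.array(
        [1.0 if c.kind == "short" else truth.scalp_long_gain for c in chans]
    )
    hbo += scalp_gain[:, None] * scalp[None, :]
    hbr += truth.scalp_hbr_ratio * scalp_gain[:, None] * scalp[None, :]

    # --- systemic physiology, injected at per-channel lags
    latents = _latent_processes(rng, n, fs, events, truth, eff.evoked_amps)
    for j, name in enumerate(SIGNALS):
        gains = eff.gain[:, j]
        if not np.any(gains):
            continue
        L = latents[name]
        hbr_ratio = truth.cardiac_hbr_ratio if name == "ppg" else truth.physio_hbr_ratio
        lag_samp = np.round(eff.lag_s[:, j] * fs).astype(int)
        for k in np.unique(lag_samp):
            sel = lag_samp == k
            shifted = _shift(L, int(k))
            hbo[sel] += gains[sel, None] * shifted[None, :]
            hbr[sel] += hbr_ratio * gains[sel, None] * shifted[None, :]

    # --- optical density and intensities
    E = extinction_matrix()
    d_cm = np.array([c.separation_mm for c in chans]) / 10.0
    conc_molar = np.stack([hbo, hbr], axis=1) * 1e-6  # (n_ch, 2, n)
    od = np.einsum("lk,ckt->clt", E, conc_molar) * (truth.dpf * d_cm)[:, None, None]
    for name in truth.decoupled_channels:
        i = montage.channel_names.index(name)
        od[i] = 0.0
    if truth.noise_od > 0:
        od = od + truth.noise_od * rng.standard_normal(od.shape)
    for name in truth.decoupled_channels:
        i = montage.channel_names.index(name)
        od[i] = max(truth.noise_od, 1e-3) * rng.standard_normal(od[i].shape)
    intensities = np.exp(-od)

    # --- auxiliary sensors record the same latent processes
    aux = {}
    t_fnirs = np.arange(n) / fs
    for name in SIGNALS:
        fs_aux = AUX_FS_HZ[name]
        t_aux = np.arange(int(np.ceil(dur * fs_aux)) + 1) / fs_aux
        v = np.interp(t_aux, t_fnirs, latents[name])
        if truth.aux_noise_sd > 0:
            v = v + truth.aux_noise_sd * rng.standard_normal(len(v))
        off, scale = AUX_UNITS[name]
        aux[name] = AuxSeries(off + scale * v, fs_aux)

    return SessionRecording(
        intensities=intensities,
        channel_names=list(montage.channel_names),
        aux=aux,
        events=events,
        subject_id=subject_id,
        session_id=session_id,
        fs_hz=fs,
    )


# ---------------------------------------------------------------------------
# digitization


def jitter_scan(
    base: DigitizedScan,
    sigma_mm: float,
    seed,
    translation_sigma_mm: float = 0.0,
) -> DigitizedScan:
    """Perturb optode coordinates by isotropic Gaussian noise (sd sigma_mm),
    optionally on top of a shared rigid cap translation. Fiducials are
    anatomical and remain fixed."""
    if sigma_mm < 0 or translation_sigma_mm < 0:
        raise ValueError("jitter sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    shift = translation_sigma_mm * rng.standard_normal(3)
    coords = {
        name: np.asarray(xyz, dtype=float) + shift + sigma_mm * rng.standard_normal(3)
        for name, xyz in base.optode_coords.items()
    }
    return DigitizedScan(
        fiducials={k: np.array(v, dtype=float) for k, v in base.fiducials.items()},
        optode_coords=coords,
        subject_id=base.subject_id,
        session_id=base.session_id,
    )


def _base_scan(montage: MontageSpec, subject_id: str, scale: float) -> DigitizedScan:
    optodes = {name: scale * montage.positions[name] for name in montage.optode_names()}
    fids = {
        name: scale * montage.positions[name] for name in ("Nz", "Iz", "Cz", "LPA", "RPA")
    }
    return DigitizedScan(fids, optodes, subject_id, 0)


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass
class StudyConfig:
    n_subjects: int = 15
    n_scanned: int = 11
    events: EventConfig = field(default_factory=EventConfig)
    truth: GroundTruth = field(default_factory=GroundTruth)
    optode_jitter_mm: float = 2.0
    cap_translation_mm: float = 3.2
    placement_scale_sd: float = 0.45   # lognormal subject-level digitization quality
    head_scale_sd: float = 0.03
    montage_config: dict | None = None


@dataclass
class StudySimulation:
    montage: MontageSpec
    recordings: list[tuple[SessionRecording, SessionRecording]]
    scans: list[tuple[DigitizedScan, DigitizedScan]]
    truth: GroundTruth
    true_betas: pd.DataFrame  # subject, session, roi, condition, chromophore, beta


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> StudySimulation:
    """Simulate a full two-session study.

    Per subject, the two sessions share subject-level effects (neural
    amplitudes per ROI, physiology lags) drawn with `between_subject_sd`,
    and differ by session-level effects (`between_session_sd` on the neural
    amplitude, fresh scalp amplitude, coupling-gain modulation and evoked
    physiology amplitudes) plus fresh noise. Digitized scans are produced
    for the first `n_scanned` subjects.
    """
    cfg = config or StudyConfig()
    if cfg.n_subjects < 1:
        raise ValueError("need at least one subject")
    truth = cfg.truth
    montage = make_montage(cfg.montage_config)
    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(cfg.n_subjects)

    recordings = []
    scans = []
    truth_rows = []
    rois = list(truth.beta_speech_hbo)
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1:02d}"
        s_events, s_effects, s_sess1, s_sess2, s_scan = subj_seeds[s].spawn(5)
        rng_sub = np.random.default_rng(s_effects)
        subj_beta = {
            roi: truth.beta_speech_hbo[roi]
            + truth.between_subject_sd * rng_sub.standard_normal()
            for roi in rois
        }
        lo, hi = truth.lag_range_s
        base_lag = rng_sub.uniform(lo, hi, size=len(SIGNALS))
        events = sample_events(cfg.events, s_events)
        dur = recording_duration_s(events, cfg.events)

        pair = []
        for sess, sess_seed in ((1, s_sess1), (2, s_sess2)):
            rng_sess = np.random.default_rng(sess_seed.spawn(1)[0])
            beta_sess = {
                roi: {
                    "speech": subj_beta[roi]
                    + truth.between_session_sd * rng_sess.standard_normal(),
                    "silence": truth.beta_silence_hbo,
                }
                for roi in rois
            }
            eff = _default_effects(montage, truth, rng_sess)
            n_ch = len(montage.channels)
            lag = base_lag[None, :] + rng_sess.uniform(
                -truth.lag_channel_jitter_s, truth.lag_channel_jitter_s,
                size=(n_ch, len(SIGNALS)),
            )
            eff = replace(eff, beta_hbo=beta_sess, lag_s=np.clip(lag, 0.0, 10.0))
            rec = simulate_session(
                montage, events, truth, sess_seed,
                subject_id=subject_id, session_id=sess, effects=eff, duration_s=dur,
            )
            pair.append(rec)
            for roi in rois:
                for cond in ("speech", "silence"):
                    b = beta_sess[roi][cond]
                    truth_rows.append(
                        dict(subject=subject_id, session=sess, roi=roi,
                             condition=cond, chromophore="HbO", beta=b)
                    )
                    truth_rows.append(
                        dict(subject=subject_id, session=sess, roi=roi,
                             condition=cond, chromophore="HbR",
                             beta=truth.hbr_neural_ratio * b)
                    )
        recordings.append(tuple(pair))

        if s < cfg.n_scanned:
            scan_rng = np.random.default_rng(s_scan)
            scale = 1.0 + cfg.head_scale_sd * scan_rng.standard_normal()
            base = _base_scan(montage, subject_id, scale)
            # subject-dependent digitization/placement quality (hair, cap fit)
            q = float(np.exp(cfg.placement_scale_sd * scan_rng.standard_normal()))
            sc1 = jitter_scan(base, q * cfg.optode_jitter_mm, scan_rng.integers(2**31),
                              q * cfg.cap_translation_mm)
            sc2 = jitter_scan(base, q * cfg.optode_jitter_mm, scan_rng.integers(2**31),
                              q * cfg.cap_translation_mm)
            sc1.session_id, sc2.session_id = 1, 2
            scans.append((sc1, sc2))

    return StudySimulation(
        montage=montage,
        recordings=recordings,
        scans=scans,
        truth=truth,
        true_betas=pd.DataFrame(truth_rows),
    )
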