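"""Simulate a two-session passive-listening study and inspect its structure.

Builds the default probe (38 long + 8 short channels over bilateral IFG and
auditory cortices), samples a randomized 40-speech/10-silence block design,
and forward-models raw two-wavelength intensities plus six auxiliary
physiology sensors for a handful of subjects.
"""

import numpy as np

import spafnirs as sp

cfg = sp.StudyConfig(n_subjects=3, n_scanned=2)
sim = sp.simulate_study(cfg, seed=42)

m = sim.montage
print(f"montage: {len(m.long_channels)} long + {len(m.short_channels)} short channels, "
      f"{len(set(m.roi_map.values()))} ROIs")

rec = sim.recordings[0][0]
print(f"subject {rec.subject_id} session {rec.session_id}: "
      f"{rec.n_times} samples at {rec.fs_hz} Hz "
      f"({rec.duration_s / 60:.1f} min), wavelengths {rec.wavelengths} nm")
ev = rec.events
conds = [c for _, _, c in ev]
print(f"events: {conds.count('speech')} speech + {conds.count('silence')} silence, "
      f"first onset {ev.onsets[0]:.0f} s")
for name, series in rec.aux.items():
    print(f"  aux {name:12s} {series.fs_hz:5.1f} Hz, "
          f"mean {np.mean(series.values):7.2f}")

tb = sim.true_betas
speech = tb[(tb.condition == 'speech') & (tb.chromophore == 'HbO')]
print("ground-truth speech HbO amplitudes (uM) by ROI, subject S01 session 1:")
print(speech[(speech.subject == 'S01') & (speech.session == 1)]
      [["roi", "beta"]].to_string(index=False))
print("These are the amplitudes the GLM stage should recover; every value "
      "downstream can be validated against them.")
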