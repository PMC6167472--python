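"""Generate a synthetic 240 Hz ECG/PPG pair and write it to disk.

The inter-beat process mixes respiratory and slow sinusoidal modulation
with white noise, rescaled to a target SDNN; the ECG renders one PQRST
complex per beat, the PPG one pulse with a dicrotic notch.
"""

import numpy as np

from tbivitals.io import write_waveform_csv, write_waveform_hdf5
from tbivitals.synthetic import MorphParams, RRGenParams, simulate_rr_series, synthesize_ecg, synthesize_ppg

params = RRGenParams(mean_rr=800.0, sdnn_target=50.0, rmssd_target=35.0, n_beats=200, seed=1)
beat_times, rr = simulate_rr_series(params)
print(f"{rr.size} intervals: mean {rr.mean():.1f} ms, "
      f"SDNN {rr.std(ddof=1):.1f} ms (target {params.sdnn_target}), "
      f"RMSSD {np.sqrt(np.mean(np.diff(rr) ** 2)):.1f} ms (target {params.rmssd_target})")

morph = MorphParams(notch_delay_frac=0.45, notch_depth_frac=0.15)
ecg = synthesize_ecg(beat_times + 0.5, morph, fs=240.0, noise_sd=0.01, seed=2)
ppg = synthesize_ppg(beat_times + 0.5, morph, fs=240.0, noise_sd=0.01, seed=3)
print(f"ECG: {len(ecg)} samples over {ecg.duration:.1f} s; PPG: {len(ppg)} samples")

write_waveform_csv(ecg, "ecg_demo.csv")
write_waveform_hdf5({"ecg": ecg, "ppg": ppg}, "waves_demo.h5")
print("wrote ecg_demo.csv and waves_demo.h5 "
      "(time in seconds from admission, amplitude in arbitrary units)")
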