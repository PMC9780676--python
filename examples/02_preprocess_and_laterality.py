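"""Denoise one recording and compute per-trial M1-LAT.

Runs the full chain (TDDR -> per-band delays -> modified Beer-Lambert ->
latent-common regression -> short-channel regression -> BOLD band-pass ->
CBSI -> onset baseline correction), then fits task-window slopes and
differences homotopic pairs (contralesional minus ipsilesional).
"""

import numpy as np

import fnirslat as fl

config = fl.SimConfig(n_participants=1, seed=7)
recordings, _, truth = fl.generate_cohort(config)
rec = recordings[0]

clean = fl.run_pipeline(rec)
print("stages applied:", " -> ".join(e["stage"] for e in clean.stage_log))

epochs = fl.epoch(clean)
slopes = fl.slope_matrix(epochs)
record = fl.m1_lat(slopes, clean.channel_ids, clean.montage,
                   clean.lesion_side, clean.participant_id)

est = np.nanmean(record.values, axis=0)
print(f"\n{rec.participant_id} (lesion {rec.lesion_side}), "
      f"{record.values.shape[0]} trials x 8 pairs")
print("pair  true M1-LAT   estimated (trial mean), µM/s")
for k in range(8):
    print(f"  {k + 1}     {truth.m1lat_mean[0, k]:+.4f}      {est[k]:+.4f}")
print()
print("Positive values mean the contralesional task-window slope exceeds")
print("the ipsilesional one; estimates track the injected truth up to the")
print("heavy-tailed trial noise averaged over 10 trials.")
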