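"""Spike detection, bout structure, terminal class and the severity score.

Severity is the 0.5-4 Hz band power of the last 10 minutes over the first
10 minutes: ~1 for a quiet recording, well above 1 once continuous
epileptiform activity develops.
"""

import csdscope as cs
from csdscope.filters import apply_filter
from csdscope.recording import EPI_FILTER

params = cs.group_preset("G301R", "female", seed=5)
rec, truth = cs.simulate_recording(params)

hp = apply_filter(rec.channel("M1_left"), rec.fs, EPI_FILTER)
ann = cs.annotate_channel(hp, rec.fs, channel="M1_left")

print(f"spikes detected: {ann.spike_times_s.size} "
      f"(ground truth {truth.spike_times['M1_left'].size})")
print(f"bouts: {len(ann.bouts)}; first bout "
      f"{ann.bouts[0][0]:.0f}-{ann.bouts[0][1]:.0f} s")
print(f"onset of epileptiform activity: {ann.onset_s:.0f} s "
      f"(simulated onset {params.epi_onset_s:.0f} s)")
print(f"terminal class: {ann.activity_class} "
      f"(simulated: {params.epi_escalation})")
print(f"severity (last/first 10-min 0.5-4 Hz power): {ann.severity:.1f}")

# generalization: spikes should be present on the contralateral channel too
anns = {"M1_left": ann}
hp_r = apply_filter(rec.channel("M1_right"), rec.fs, EPI_FILTER)
anns["M1_right"] = cs.annotate_channel(hp_r, rec.fs, channel="M1_right",
                                       compute_severity=False)
print(f"generalized across hemispheres: {cs.is_generalized(anns)}")
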