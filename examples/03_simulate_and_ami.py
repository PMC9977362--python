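"""Simulate one subject's EEG and recover the planted beta lateralization.

The generator plants ipsilateral enhancement / contralateral suppression of
beta power (14-24 Hz) relative to the attended ear. The attention
modulation index AMI = (attend left - attend right)/(attend left + attend
right) of beta power should therefore be positive over left-hemisphere
channels and negative over right-hemisphere ones.
"""

import numpy as np

from betalat import SimConfig, band_average, compute_ami, morlet_tfr, simulate_subject
from betalat.layout import balanced_subset_layout

layout = balanced_subset_layout(10, 2)
cfg = SimConfig(
    sampling_rate=200.0,
    channels=tuple(layout.names),
    lateralization_depth=0.3,
    snr=2.0,
    epochs_per_block=6,
)
subject = simulate_subject(cfg, seed=0)
print(f"{subject.epochs.n_epochs} epochs x {layout.n_channels} channels, "
      f"window {subject.epochs.times[0]:.1f}..{subject.epochs.times[-1]:.2f} s")

tfr = morlet_tfr(subject.epochs, freqs=np.arange(14.0, 25.0, 1.0))
power = band_average(tfr, "beta", (0.0, 2.2))
left_trials = np.asarray(subject.epochs.meta.attended_ear == "left")
ami = compute_ami(power[left_trials].mean(0), power[~left_trials].mean(0))

hemi = np.array(layout.hemisphere)
print(f"mean AMI over left-hemisphere channels : {ami[hemi == 'L'].mean():+.3f}")
print(f"mean AMI over right-hemisphere channels: {ami[hemi == 'R'].mean():+.3f}")
print(f"mean AMI over midline channels         : {ami[hemi == 'midline'].mean():+.3f}")
print("Positive left / negative right AMI reproduces the planted ipsilateral"
      " beta enhancement (depth 0.3, attenuated by background noise).")
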