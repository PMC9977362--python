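"""Build a counterbalanced dichotic-rhythm session and check its arithmetic.

Two tone streams, one per ear: slow (SOA 0.8 s, 1.25 Hz, 3 tones) and fast
(SOA 0.6 s, 5/3 Hz, 4 tones), forming repeating 2.4-s sequences. Irregular
sequences carry one tone shifted 90 ms earlier (the detection target).
"""

import numpy as np

from betalat import build_sequence, build_session
from betalat.schedule import deviant_sequence, regular_sequence

# one regular sequence: 7 tones, 6 distinct onsets
events = build_sequence(regular_sequence())
print("regular sequence tone onsets (s):")
for e in events:
    print(f"  {e.onset:5.2f}  {e.stream:4s} stream, ear={e.ear},"
          f" merged position {e.position_in_sequence}")

# a deviant at merged position 4 (= fast-stream tone 3): 1.2 s -> 1.11 s
dev = [e for e in build_sequence(deviant_sequence(4)) if e.is_deviant][0]
print(f"\ndeviant tone onset: {dev.onset:.2f} s (nominal 1.20 s, -90 ms)")

# a full 8-block session covers the 2 x 2 x 2 counterbalancing
session = build_session(np.random.default_rng(0))
print("\ncounterbalancing table:")
print(session.counterbalancing_table().to_string(index=False))
print(f"\nattended-ear deviants over the session: "
      f"{session.attended_deviant_total()} (design value: 70)")
for b in session.blocks[:2]:
    kept = len(b.retained_regular_indices())
    print(f"{b.predictability}-predictability block: {b.n_sequences} sequences,"
          f" {kept} regular sequences retained for EEG analysis")
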