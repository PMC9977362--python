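"""Simulate button presses and categorize them into hits / SE / RE.

A press within 2 s of an attended-ear deviant is a hit; within 2 s of an
unattended-ear deviant a spatial error (SE); anything else a random error
(RE). The target detection rate (TDR) is the fraction of attended deviants
that received a response, split by rhythm predictability.
"""

import numpy as np

from betalat import build_session, categorize_responses, simulate_behavior, summarize_behavior

rng = np.random.default_rng(1)
session = build_session(rng)

# an attentive observer: detects 80% of targets, rarely presses otherwise
responses = simulate_behavior(
    session, p_attended=0.8, p_unattended=0.15, false_alarm_rate=0.02, rng=rng
)
records = categorize_responses(responses, session)
s = summarize_behavior(records, session)

print(f"{s.n_responses} button presses")
print(f"hits {s.prop_hits:.1f}%   SE {s.prop_se:.1f}%   RE {s.prop_re:.1f}%"
      "   (percent of all presses)")
print(f"TDR high predictability: {s.tdr_high:.2f}   low: {s.tdr_low:.2f}")
print("A task-compliant observer shows hits >> SE, RE; TDR near the planted"
      " 0.8 attended sensitivity.")
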