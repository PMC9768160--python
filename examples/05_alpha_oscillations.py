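"""Alpha oscillations as rhythmic modulation of the inhibition constant.

Theta(t) = 0.13 + amplitude * sin(2*pi*f*t + phase) with f in 8-12 Hz.
Moderate amplitudes (0.05-0.06) raise the fraction of correct decisions
above the no-alpha baseline; large amplitudes (0.08-0.1) frequently lock
the network in the spontaneous state so that no decision forms within
2.5 s.  Desk scale: 120 trials per condition at contrast 8.21%.
"""

from satnet.validation import alpha_condition

for label, band, published in [
    ("no alpha      ", (0.0, 0.0), "86.2% correct"),
    ("amp 0.05-0.06 ", (0.05, 0.06), "94.4% correct"),
    ("amp 0.08-0.10 ", (0.08, 0.10), "39% no-decision"),
]:
    res = alpha_condition(band, n_trials=120, seed=4)
    print(f"{label}: {res['pct_correct_all_runs']:5.1f}% correct, "
          f"{res['pct_no_decision']:5.1f}% no decision   (published: {published})")
# Accuracy counts all runs (no-decisions in the denominator), so the drop at
# high amplitude reflects decision failure, not wrong choices.
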