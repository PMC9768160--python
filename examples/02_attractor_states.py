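"""Measure the network's three semi-stable attractor states.

Without input the network rests in a spontaneous state (published pool
rate 10.3 Hz).  Strong evidence drives it into a decision state where
the winning pool fires near 59.7 Hz and the losing pool is suppressed
to about 2 Hz; both persist after the stimulus is withdrawn.
"""

from satnet.validation import decision_state_rates, spontaneous_state_rate

sp = spontaneous_state_rate(n_runs=8, run_ms=5000, seed=1)
print(f"spontaneous state: {sp['mean_rate_hz']:.1f} Hz (published 10.3 Hz, band 4-20)")

dec = decision_state_rates(n_trials=10, seed=1)
print(f"decision state, winner: {dec['winner_rate_hz']:.1f} Hz (published 59.7, band 51-66)")
print(f"decision state, loser:  {dec['loser_rate_hz']:.1f} Hz (published 2.0, band 0-5)")
# Rates are population averages over 30-ms windows while the network
# occupies the corresponding attractor; small samples wobble by ~1 Hz.
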