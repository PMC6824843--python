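"""Population response onsets for contralateral versus ipsilateral loads.

The population trace averages each neuron's best-load response change
(cross-fitted so load selection never sees the averaged trials); the onset is
the first time the trace exceeds its baseline by three SDs for 20 consecutive
milliseconds.
"""

from bilat import SimConfig, population_onset, simulate_session, smooth_spike_trains

session, truth = simulate_session(SimConfig(n_neurons=100, seed=1))
rates = smooth_spike_trains(session)
neurons = list(range(len(session.neuron_ids)))

onsets = {}
for ctx in ("contra", "ipsi"):
    result, _trace = population_onset(rates, ctx, neurons)
    onsets[ctx] = result.onset_ms
    print(f"{ctx}: population onset {result.onset_ms:.0f} ms "
          f"(ground truth {truth.onset_ms[ctx]:.0f} ms)")
lag = onsets["ipsi"] - onsets["contra"]
print(f"recovered ipsilateral lag: {lag:.0f} ms (configured "
      f"{truth.onset_ms['ipsi'] - truth.onset_ms['contra']:.0f} ms)")
print("-> the detector adds a few ms of threshold-crossing delay per context,")
print("   but the contra/ipsi ordering and the lag magnitude are preserved;")
print("   averaging over sessions tightens the lag estimate (single sessions")
print("   carry a few ms of onset jitter from the 3-SD threshold rule)")
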