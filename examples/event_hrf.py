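"""Simulate the standard event stimulus and characterise its HRF.

A 2 s pulse of external drive at 4 Hz triggers a single astrocytic
calcium spike, functional hyperemia and a BOLD response.  The script
prints the hemodynamic response features and the double-gamma
canonical fit.
"""

from nvcsim.analysis import fit_canonical_hrf, hrf_features, spike_train_of
from nvcsim.params import SimulationConfig
from nvcsim.protocols import make_event, run

config = SimulationConfig()
onset = 5.0
result = run(config, make_event(4.0, 2.0, onset=onset, t_total=50.0))

spikes = spike_train_of(result)
print(f"calcium spikes: {spikes.n} "
      f"(amplitude {spikes.amplitudes[0]:.2f} uM, "
      f"{spikes.times[0] - onset:.2f} s after onset)")

feats = hrf_features(result.time, result.bold, onset)
print(f"BOLD onset latency t_ON  = {feats.t_ON:.2f} s")
print(f"BOLD peak latency t_peak = {feats.t_peak:.2f} s")
print(f"peak amplitude           = {feats.peak:.2f} %")
print(f"post-stimulus undershoot = {feats.undershoot:.2f} %")
print(f"total response duration  ~ {feats.duration:.0f} s")

mask = result.time >= onset
fit = fit_canonical_hrf(result.time[mask] - onset, result.bold[mask],
                        seed=0)
print(f"canonical double-gamma fit: d1={fit.d1:.1f} s, d2={fit.d2:.1f} s, "
      f"R^2={fit.r_squared:.3f}")
print("-> onset ~2 s, peak ~5 s and a 1-2% amplitude match the timing "
      "and size of event-related responses seen in fMRI.")
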