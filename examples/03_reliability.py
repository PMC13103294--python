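"""How much scan time does a stable FOCA matrix need?

Simulates one long (300-minute) low-SNR scan, censors high-motion frames at
the 0.5-mm FD threshold, and compares FOCA matrices from short sampled
segments against a held-out 70-minute reference.
"""

import foca
from foca.benchmarks import block_coupling
from foca.individualize import Parcellation
from foca.preprocess import scrub_frames
from foca.synthgen import SubjectMeta

geom = foca.make_geometry(20, 20)
model = foca.sample_latent_model(
    5, geom, block_coupling(5), foca.EffectSpec(noise_sd=20.0, global_weight=0.3),
    seed=0,
)
scan = foca.simulate_scan(model, SubjectMeta(subject_id="long"),
                          n_frames=9000, tr=2.0, seed=1)
scan = scrub_frames(scan, 0.5)
print(f"{scan.n_frames} frames survive motion censoring")

parc = Parcellation(labels=model.group_labels, n_networks=5, level="individual")
curve = foca.duration_reliability(scan, parc, [5, 10, 15, 30, 60],
                                  reference_min=70.0, n_reps=50, seed=2)
for d, m, s in zip(curve["durations_min"], curve["mean"], curve["sd"]):
    print(f"  {d:>4} min: similarity to reference r = {m:.3f} +/- {s:.3f}")
# similarity rises steeply then plateaus: a ~15-minute scan already captures
# most of the coupling pattern, and longer scans mostly shave residual noise.
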