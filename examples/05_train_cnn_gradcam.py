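"""Train the 1D-CNN and localize its decision evidence with Grad-CAM.

Simulates a cohort whose only class difference is one Raman band at
1342 cm^-1, trains the two-conv-layer network for 40 epochs, and checks that
the aggregated saliency map peaks at that band — the network's decision
evidence is where the biochemistry actually differs.
"""

import numpy as np

import ramanpipe as rp
from ramanpipe.classifiers import TrainRecipe, build_cnn1d, train_dl
from ramanpipe.interpret import aggregate_saliency, gradcam_maps

grid = rp.SpectralGrid(np.arange(700.0, 1800.0, 2.0))
band = 1342.0
peaks = [
    rp.PeakSpec(900.0, 15.0, 1.0, 1.0),              # shared band
    rp.PeakSpec(band, 15.0, 0.6, 1.6, group="protein"),  # the discriminative band
    rp.PeakSpec(1650.0, 15.0, 1.0, 1.0),             # shared band
]
cfg = rp.SimulatorConfig(
    n_patients=6, spectra_per_patient_per_class=8, extra_pairs_first_patient=0,
    peaks=peaks, baseline_amplitude=0.3, noise_sd=0.02, gain_sd=0.0,
    patient_effect_sd=0.05, spike_prob=0.0, seed=5)
cohort = rp.generate_cohort(cfg, grid=grid)

snip_only = rp.PipelineSpec(
    "snip_only", (rp.StageSpec("snip_baseline", {"iterations": 80}),), region="full")
proc, _ = rp.apply_pipeline(cohort, snip_only)
X, y = proc.matrix, cohort.labels

model = build_cnn1d(X.shape[1], seed=5)
trained = train_dl(model, X, y, recipe=TrainRecipe(epochs=40, seed=5))
acc = (trained.predict(X) == y).mean()
print(f"training accuracy after 40 epochs: {100 * acc:.1f}%")

maps = [m for m in gradcam_maps(model, X[y == 1], proc.grid) if not m.degenerate]
mean = np.mean([m.importance for m in maps], axis=0)
argmax = proc.grid.shifts[np.argmax(mean)]
print(f"saliency argmax: {argmax:.0f} cm^-1 (true band {band:.0f} cm^-1)")

bands = aggregate_saliency(maps, threshold=0.5)
for b in bands.bands:
    print(f"salient band {b.lo:.0f}-{b.hi:.0f} cm^-1, mean importance {b.mean_importance:.2f}")

# The saliency argmax within a few cm^-1 of the injected band means the model
# classifies for the right reason, not from a dataset artifact.
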