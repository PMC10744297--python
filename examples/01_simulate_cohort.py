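"""Simulate a patient-structured Raman cohort and write it to disk.

Builds the default 22-patient cohort (442 spectra, 221 healthy / 221
cancerous) on the reference 500-3200 cm^-1 axis, prints its shape, and
stores it as a CSV spectra matrix plus a JSON manifest.
"""

from pathlib import Path

import numpy as np

import ramanpipe as rp

cohort = rp.generate_cohort(rp.SimulatorConfig(seed=1))
counts = np.bincount(cohort.labels)

print(f"spectra:   {len(cohort)}")
print(f"patients:  {len(set(cohort.patient_ids))}")
print(f"healthy:   {counts[0]}  cancerous: {counts[1]}")
print(f"grid:      {len(cohort.grid)} points, "
      f"{cohort.grid.shifts[0]:.0f}-{cohort.grid.shifts[-1]:.1f} cm^-1")

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)
rp.write_cohort(cohort, out / "spectra.csv", out / "manifest.json")
print(f"wrote {out}/spectra.csv and {out}/manifest.json")

# The numbers above are the simulated study conditions: every patient
# contributes equally many healthy and cancerous spectra, so chance-level
# classification sits at 50%.
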