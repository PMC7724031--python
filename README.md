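# lvflow

Left-ventricular 4D-flow component analysis: Lagrangian pathline tracing
through time-resolved three-directional velocity fields, four-way
decomposition of the end-diastolic blood volume, per-component kinetic-energy
quantification, quality control, and paired rest-vs-stress statistics — with
a synthetic LV velocity phantom carrying exact ground truth.

## The problem

4D-flow cardiovascular MR measures blood velocity in every voxel of the
heart over the cardiac cycle.  Emitting a pathline from each voxel of the
end-diastolic LV volume (EDV) and tracing it forward to the following
end-systole and backward to the preceding end-systole splits the EDV into
four functional components by the blood's route:

* **Direct flow (DF)** — enters the LV in diastole and is ejected the next
  systole (the most efficient transit);
* **Retained inflow (RI)** — enters in diastole but is not ejected;
* **Delayed ejection flow (DEF)** — already in the LV, ejected that systole;
* **Residual volume (RV)** — resides in the LV for at least two cycles.

Each pathline carries one voxel volume V of blood with kinetic energy
KE(t) = ½ ρ V |v(t)|², ρ = 1060 kg/m³.  The DF share of the EDV and its
KE/mL at end-diastole are markers of efficient LV function; under
pharmacological stress (higher heart rate, inotropy, lusitropy) the DF share
rises and the RV share falls.  `lvflow` implements this analysis end to end
for researchers working with intracardiac flow, and validates every stage
against a phantom whose per-voxel component labels are exact by
construction (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from lvflow import (PhantomSpec, generate_lv_phantom, trace_all,
                    component_fractions, ke_per_ml_at_ed, label_agreement)

dataset = generate_lv_phantom(PhantomSpec())      # 64^3 grid, 20 frames, 66 bpm
paths   = trace_all(dataset.field, dataset.edv_mask)
frac    = component_fractions(paths, dataset.esv_mask_forward,
                              dataset.esv_mask_backward)
print("parcels:", len(paths))
print("DF/RI/DEF/RV (% of EDV):", np.round(frac.fractions_pct, 1))
print("truth agreement:", label_agreement(frac.labels, paths,
                                          dataset.truth_labels))
print("KE/mL at ED (uJ/mL):",
      {k: round(v, 2) for k, v in ke_per_ml_at_ed(paths, frac.labels).items()})
```

prints

```
parcels: 6600
DF/RI/DEF/RV (% of EDV): [36. 20. 17. 27.]
truth agreement: 1.0
KE/mL at ED (uJ/mL): {'DF': 0.23, 'RI': 0.23, 'DEF': 0.23, 'RV': 0.23}
```

6 600 pathlines — one per EDV voxel — are classified, the recovered
fractions match the phantom's prescribed rest-like decomposition exactly
(36/20/17/27 %), and every parcel label agrees with the generator truth.
The KE/mL values share one magnitude because the phantom's velocity field is
spatially uniform at any instant (a documented phantom idealization).

The same pipeline is scriptable from the shell:

```bash
lvflow simulate --out data/            # synthetic acquisition + truth
lvflow trace --data data/ --out pl.h5  # pathlines (HDF5)
lvflow classify --pathlines pl.h5 --data data/ --out fractions.csv \
       --vtp pathlines.vtp             # components + ParaView geometry
lvflow energetics --pathlines pl.h5 --data data/ --out ke.csv
lvflow run-study --subjects 12 --seed 1 --out study/   # full cohort + report
```

`run-study` generates a 12-subject rest-vs-dobutamine-like cohort, applies
the inflow-outflow QC rule (> 15 % discrepancy excludes a dataset), runs the
normality-gated paired tests, and writes the report tables and figures.

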