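# zfmri

Quantitative MRI relaxometry and morphometry for small-specimen imaging —
built for phenotyping zebrafish models of leukodystrophy (vanishing white
matter disease), where mutant animals show smaller brains, altered
white-matter signal and thinner myelin sheaths.

The package implements, as a tested and reusable library:

* **Voxelwise T1/T2 relaxometry** — fitting the monoexponential
  saturation-recovery and spin-echo decay models

  ```
  S(TR) = M0 · (1 − e^(−TR/T1))        S(TE) = M0 · e^(−TE/T2)
  ```

  to multi-TR / multi-TE magnitude series by plain gradient descent on the
  sum-of-squared-residuals loss (defaults: M0 init 8000, T1 init 150 ms /
  T2 init 75 ms, loop limit 75000, learning rate 10⁻⁶), with an independent
  nonlinear-least-squares oracle for verification.
* **Landmark-based rigid motion correction** — in-plane rotation +
  translation estimated by closed-form orthogonal Procrustes from named
  landmarks (the two eye-lens centers and the vagal-lobe tip) on one
  representative slice, applied to all slices, then repetition averaging.
* **Skull-normalized morphometry** — brain length, tectum width and brain
  height as landmark distances, each divided by the same specimen's skull
  width, compared across groups with a two-sample t-test (pooled Student by
  default, Welch by flag).
* **White-matter ROI intensity** — the mean of a 2×2-pixel periventricular
  grey zone ROI normalized to an equal optic-tectum ROI, on the slice at the
  caudal end of the rhombencephalic ventricle plus two more rostral slices.
* **Myelin G-ratio** — the ratio of axon-boundary perimeter to myelin
  outer-boundary perimeter per fiber (g = P_axon / P_myelin, 0 < g < 1),
  with perimeter-equivalent axon diameter and myelin thickness and group
  summaries.
* **A synthetic phantom generator** supplying ground-truth-known inputs for
  every stage: ellipsoidal skull/brain digital phantoms with piecewise
  constant (M0, T1, T2), imaged at the acquisition timing used in practice
  (TR = [50, 150, 275, 450, 600] ms ×4 repetitions; TE = [12.2, 36.6, 60.94]
  ms ×9 repetitions) with Rician magnitude noise and injected sub-pixel rigid
  motion; two-group cohorts; and fiber contour sets with exactly known
  G-ratios.

Everything is seeded and bit-reproducible; a thin `zfmri` CLI and an
orchestrated `run_pipeline` (simulate → register → fit → morpho → roi →
gratio → report) wrap the library with provenance capture.

## Worked example

```python
import numpy as np
from zfmri import PhantomSpec, make_phantom, simulate_series, fit_map

phantom = make_phantom(PhantomSpec(seed=0))
sim = simulate_series(phantom, "T2", noise_sigma=0.0, n_repetitions=1)
pmap = fit_map(sim.series, mask=phantom.masks["brain"])
rel = np.abs(pmap.t_value[pmap.mask] - phantom.t2.data[pmap.mask]) \
      / phantom.t2.data[pmap.mask]
print(f"fitted voxels:        {pmap.mask.sum()}")
print(f"median rel T2 error:  {np.median(rel):.2e}")
print(f"max rel T2 error:     {rel.max():.2e}")
```

prints

```
fitted voxels:        1872
median rel T2 error:  0.00e+00
max rel T2 error:     6.69e-05
```

i.e. on a clean multi-echo series the gradient-descent fit recovers every
brain voxel's T2 to well under 0.1% of the generating value. The scripts in
`examples/` walk through each capability the same way (motion correction,
morphometry with group statistics, ROI ratios against their closed-form
expectation, and G-ratio cohorts drawn at published group statistics of
0.593 ± 0.085 vs 0.690 ± 0.076, recovered to within 0.01 at n = 200/group).

The same stages are available from the shell:

```bash
zfmri simulate --seed 1 --out dataset/
zfmri fit --series dataset/t2_series --out t2_map/
zfmri run --out run1 --seed 17 && zfmri report run1
```

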