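# pbvckit

Longitudinal brain-atrophy measurement for multiple-sclerosis imaging
research: a lesion-aware tissue-segmentation and Jacobian-modulation
pipeline that turns a pair of T1/FLAIR scan sessions into a percentage
brain volume change (PBVC), an edge-displacement comparator in the SIENA
family, and a synthetic scan–rescan study that quantifies how reproducible
each method is within and across scanners.

Brain atrophy in MS progresses at roughly 0.5–1 %/year, so a clinically
useful longitudinal method needs a measurement error well below half a
percent — and it must hold up when the two scans come from different
scanners with different tissue contrast. `pbvckit` implements the
whole-brain approach: per session, an EM Gaussian-mixture segmentation with
anatomical priors classifies GM/WM/CSF on the T1 while FLAIR-hyperintense
white-matter lesions are detected, filled with normal-appearing WM
intensities and the filled image re-segmented to convergence; across
sessions, a symmetric-forces demons registration of the lesion-filled T1s
yields a deformation field whose Jacobian determinant, integrated against
the reference session's tissue probabilities,

&nbsp;&nbsp;&nbsp;&nbsp;ΔV = Σ<sub>x</sub> p(x)·(det(I + ∇u(x)) − 1)·v<sub>vox</sub>,&nbsp;&nbsp;PBVC = 100·ΔV/V₁,

is averaged over both directions, (forward − backward)/2, with negative =
atrophy. The comparator method instead tracks the perpendicular motion of
the parenchyma/CSF boundary by aligning derivative peaks of intensity
profiles — accurate within a scanner, but systematically biased when the
two sessions differ in contrast, which is exactly the behavior the
package's synthetic study demonstrates.

Because real scan–rescan MRI with known truth does not exist, all accuracy
claims run on nested-ellipsoid brain phantoms (T1 + FLAIR, two scanner
presets with different voxel grids and contrasts, bias fields, noise,
MS-like lesion loads) whose tissue volumes — and therefore the true PBVC
between any two phantoms — are closed-form exact.

## Worked example

Generate a phantom subject with a prescribed −1 % parenchymal change and
measure it:

```bash
pbvckit phantom generate --out demo/ --seed 4 --scale 2.0 --atrophy -1.0
pbvckit pbvc run --t1a demo/t1_a.nii.gz --flaira demo/flair_a.nii.gz \
                 --t1b demo/t1_b.nii.gz --flairb demo/flair_b.nii.gz \
                 --out demo/report.json
```

prints (about half a minute)

```json
{
  "pbvc_pv": -0.870433815201335,
  "pbvc_gm": -0.5860144723357443
}
```

The true change built into the phantom pair (recorded in
`demo/ground_truth.json`) is −1.0 % for both PV and GM: the pipeline
recovers the parenchymal change to 0.13 percentage points at this grid
resolution (2× the acquisition voxel), while the GM estimate is
attenuated — the cortical ribbon spans only a few voxels here, and GM
accuracy improves with finer grids. The full `demo/report.json`
additionally contains the forward/backward directional estimates, detected
lesion volumes, tissue volumes in ml, convergence flags and the resolved
configuration with its hash.

The same measurement through the library:

```python
from pbvckit import phantom as ph
from pbvckit.pipeline import measure_pair

spec_a = ph.preset_spec("T15", scale=3.0, rng_seed=4, noise_sigma=0.05)
spec_b = ph.apply_atrophy(spec_a, -1.0)
res = measure_pair(spec_a, spec_b)
print(res["jacobian"].pbvc_pv, "vs true", res["true_pbvc_pv"])
```

To run the scan–rescan reproducibility study (three conditions — two
same-day sessions on the 1.5T-like scanner, two on the 3T-like scanner,
and one session from each — for a synthetic cohort):

```bash
pbvckit study simulate --subjects 10 --seed 0 --out study/
```

`study/summary.json` holds the per-condition median/IQR error tables for
both methods and the paired Wilcoxon comparison; `study/records.csv` the
per-subject measurements.

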