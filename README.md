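# echolv

Semi-automatic segmentation of the left ventricle in dynamic
2D-echocardiography 4-chamber sequences over a complete cardiac cycle,
producing the **area variation curve** (AVC) — ventricular cavity area as a
function of time — and the **area variation fraction**

    AVF = 100 · (A − E) / A   [%]

where `A` and `E` are the end-diastolic and end-systolic cavity areas. The
AVF is a surrogate for global LV systolic function, analogous to the
shortening fraction.

The package is for researchers working on echocardiographic image analysis
who need a classical, fully deterministic baseline pipeline with an
end-to-end synthetic validation harness.

## Method

The only manual input is an atrioventricular **barrier** — a horizontal
pixel segment placed over the mitral valve in the first frame. The open
valve merges the atrial and ventricular blood pools during diastole; the
barrier acts as a watershed dam, and from the second frame on it is
re-placed automatically by tracking the basal border of the previous
frame's segmentation.

Per frame, the pipeline runs:

1. ECG-synchronized time averaging of four frames (frames *k*, *k*+1 of two
   consecutive R-wave-aligned cycles);
2. shift-invariant wavelet denoising (Daubechies-12, 4 levels, soft
   universal thresholding; optional for clean images);
3. self-reinforcing Laplacian-of-Gaussian edge enhancement,
   `clip(m − α·(LoG_σ ∗ m))`;
4. grayscale morphological smoothing, closing(1) → opening(1) → closing(3);
5. homotopy modification: regional minima at or below the median intensity
   are imposed as the image's only minima (markers);
6. marker-controlled watershed by immersion with explicit dam construction;
7. selection of the ventricular basin (largest central region / reference
   point);
8. contour correction: the basin boundary lies within the myocardium, so
   pixels brighter than 0.5 × the mean boundary intensity are removed and
   the cavity estimate is morphologically smoothed (disks r=3 and r=9).

Agreement with manual segmentations is quantified by four metrics: RMSd
(root mean squared distance between paired contour points), CCC (Pearson
correlation of the mean-removed binary masks), PE (percent area error),
and ES (error sum: false-positive plus false-negative pixels relative to
the manual area).

A synthetic beating-heart **phantom** with per-frame ground truth (cavity
masks, areas, valve state, true AVF ≈ 36%) drives the validation: speckled
two-cycle sequences with a diastolic mitral opening, plus an automated
analogue of an intra/inter-operator barrier-placement variability study.
See `docs/methods.md` for the full model description.

## Worked example

Simulate a phantom, segment it with the suggested barrier, and build the
AVC:

```
$ echolv simulate --out demo --seed 4
wrote 74 frames, true AVF 36.05%

$ python -c "import json; b=json.load(open('demo/truth.json'))['suggested_barrier']; print(','.join(map(str,b)))"
101,155,165

$ echolv segment --frames demo/frames --meta demo/meta.json --barrier 101,155,165 -o out
segmented 37 frames (0 failed) -> out

$ echolv avc --segdir out --meta demo/meta.json -o avc.csv --report avf.json
AVC with 37/37 areas -> avc.csv; AVF 34.90% (ED frame 1, ES frame 11)

$ echolv evaluate --auto out --manual demo/truth -o metrics.csv
37 pairs: RMSd 9.25±2.24 px, CCC 0.940±0.010, PE 8.84±4.07%, ES 10.62±2.12%
```

Reading the output: the measured AVF (34.9%) recovers the phantom's true
36.05% to about one percentage point — the systematic few-percent area
overshoot (the corrected boundary sits on the bright endocardial
interface) cancels between end-diastole and end-systole. `avc.csv` holds
one `frame,time_s,area_cm2` row per composite frame; `evaluate` compares
the automatic masks against the ground-truth cavity masks frame by frame
and appends the mean ± standard deviation summary row.

The same objects are available as a library:

```python
from echolv import (PhantomParams, generate_phantom, true_initial_barrier,
                    segment_sequence, build_avc, avf_from_curve)

seq, gt = generate_phantom(PhantomParams(seed=4))
results = segment_sequence(seq, true_initial_barrier(gt))
avf = avf_from_curve(build_avc(results, seq), r_wave_frame=0)
print(f"AVF {avf.avf:.1f}%  (truth {gt.true_avf:.1f}%)")
```

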