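# ctiq — Fourier-based CT image-quality metrology

`ctiq` measures how well a CT system renders a detection task, as a
function of spatial frequency, from phantom scans — and simulates those
scans with known ground truth so every measurement can be validated by
parameter recovery. It is written for medical physicists comparing
scanners or protocols (e.g. photon-counting vs dual-energy virtual
monoenergetic images at different dose levels), where a single CNR
number hides exactly the frequency-dependent trade-offs that matter.

The package implements the standard Fourier QA chain:

* **TTF** (task transfer function) by the circular-edge technique: an
  oversampled edge spread function from a contrast rod, differentiated
  and Fourier-transformed; reported with its 50% frequency f50.
* **NPS** (noise power spectrum) from ROI periodograms of a uniform
  water section, ensemble-averaged and radially rebinned (HU²·mm²).
* **SSP** (slice sensitivity profile) by the slant-edge method on a
  tilted rod; its FWHM is the effective slice thickness.
* **NPS slice-thickness correction**: NPS_c = NPS × (FWHM_other /
  FWHM_reference), since noise variance scales inversely with slice
  thickness.
* **Detectability index** of the ideal observer for a uniform disk of
  diameter d and contrast ΔHU,

      d′² = 2π ∫ f · TTF²(f)/NPS_c(f) · W²(f) df,
      W(f) = (π/2) |ΔHU| d² · J₁(πdf)/(πdf),

  and the task-independent **system performance function**
  SPF(f) = TTF²(f)/NPS_c(f) (with SPF²).
* A **synthetic phantom generator** (300-mm water bath, contrast rods,
  tilted rod) with parametric MTF, NPS and SSP truths and seeded,
  spectrally shaped noise.
* A **two-arm study pipeline** and CLI that runs the full design
  (2 scanners × 2 energy levels × 3 dose levels × 2 contrasts) and
  emits comparison tables.

## Worked example

Simulate a rod section with a known blur (f50 = 0.41 mm⁻¹) and noise,
average eight repeat scans as the measurement protocol prescribes, and
recover the blur from the rod edge:

```python
import numpy as np
from ctiq import (PhantomSpec, SyntheticTruth, GaussianMTF, FlatNPS,
                  TTFEstimator, NPSEstimator, TaskSpec,
                  generate_axial_stack, average_repeats,
                  detectability_index)

spec = PhantomSpec()                      # 30-mm rods at ±50 mm, 300-mm bath
truth = lambda s: SyntheticTruth(mtf_model=GaussianMTF(0.41),
                                 nps_model=FlatNPS(215.0), seed=s)
scans = [generate_axial_stack(spec, truth(k)) for k in range(8)]
avg = average_repeats(scans)

ttf = TTFEstimator(approx_center_mm=(200.0, 150.0)).fit(avg)
print(f"f50 = {ttf.f50_:.3f} mm^-1   edge CNR = {ttf.cnr_:.1f}")

water = generate_axial_stack(spec, truth(99), n_slices=50,
                             mode="water_section")
nps = NPSEstimator(detrend="mean").fit(water)
res = detectability_index(ttf.result_, nps.radial_,
                          TaskSpec(diameter_mm=5.0, delta_hu=600.0),
                          correction=1.13)
print(f"d' = {res.d_prime:.1f}  (NPS correction factor {res.correction_factor})")
```

Output:

```
f50 = 0.417 mm^-1   edge CNR = 33.8
d' = 154.2  (NPS correction factor 1.13)
```

The recovered f50 agrees with the configured truth (0.41 mm⁻¹) within
the estimator's documented tolerance; d′ is the ideal-observer SNR for
detecting a 5-mm, 600-HU disk against this blur and (slice-thickness
corrected) noise spectrum.

The same analyses run from the shell on DICOM series or raw stacks:

```bash
ctiq simulate --config sim.yaml --out scans/ --seed 1
ctiq ttf   --images scans/ --out ttf.csv
ctiq nps   --images water/ --out nps.csv
ctiq ssp   --images tilted/ --tilt 5 --out ssp.csv
ctiq dprime --ttf ttf.csv --nps nps.csv --fwhm-ref 1.26 --fwhm-this 1.43 \
            --task-d 5.0 --task-dhu 600 --out dprime.json
ctiq run   --config study.yaml --out results/   # full two-arm comparison
```

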