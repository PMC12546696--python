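# octacov

Volumetric coefficient-of-variation (CoV) analysis of retinal capillary
perfusion heterogeneity from serially acquired OCT angiography (OCTA)
volumes.

## The problem

Retinal blood flow fluctuates in space and time, and abnormal perfusion
heterogeneity is a candidate early biomarker for diseases such as
diabetic retinopathy, vein occlusion and glaucoma.  A practical way to
quantify it on a clinical OCTA system is to image the same 3 mm × 3 mm
fovea-centered field N times in a row (N = 10) and compute, per
location, the coefficient of variation of the angiographic signal
across the repeats.

The conventional recipes do this in 2D and are biased:

* **Protocol A** computes CoV on the device's contrast-refined en face
  images.  The proprietary rendering is a nonlinear remap of intensity,
  so the CoV of the rendered pixels misrepresents the temporal
  variability of the underlying signal.
* **Protocol B** computes CoV on maximum-intensity projections (MIP) of
  the raw volume.  The maximum is free to come from a *different depth*
  in every repeat; where two vessels share an A-scan, their signals mix
  and the projected CoV describes neither vessel.
* **Protocol C** (this package's core) computes CoV per *voxel* on the
  registered volumes:

      CoV(x,z;y) = σ(x,z;y) / Ī(x,z;y)

  with Ī the arithmetic mean and σ the sample (N−1) standard deviation
  of the N intensities at the voxel.  Each B-scan CoV is masked against
  a per-B-scan noise threshold T(y) = Ī_noise(y) + σ_noise(y) + δ
  estimated from the background band 10–30 px anterior to the ILM, and
  the masked volume V = CoV ⊙ M is median-projected through a retinal
  layer slab to give a depth-faithful en face heterogeneity map.

Supporting machinery covers the whole workflow: multi-volume 3D
registration (hybrid feature-based rigid, diffeomorphic-demons
non-rigid, per-A-scan axial matching, standardized 20-px cropping), a
two-component lognormal mixture fit of the CoV histogram whose
component intersection v* separates main arterioles/venules from
branching capillaries, and intersession repeatability summaries
(pairwise session variances in FAZ-centered rings z0/z1/z2 at 0.5 mm
and 1 mm).

Everything is testable without patient data through a synthetic phantom
(`octacov.phantom`) with known layer geometry, vessel classes with
prescribed temporal CoV, a controlled noise floor, and injectable
rigid / non-rigid / axial motion.

## Worked example

```python
import numpy as np
from octacov import phantom as ph, cov_engine as ce, mixture_analysis as mx

spec = ph.PhantomSpec(seed=0, n_repeats=10)
series, truth = ph.generate_phantom_series(spec)
result, enface = ce.protocol_c_enface(
    series, truth.layers, delta=5.0,
    vessel_probability=truth.vessel_probability,
)
for name, mask in truth.class_masks.items():
    med = np.median(result.filtered.data[mask])
    print(f"{name:16s} true CoV {truth.true_class_cov[name]:.3f}  "
          f"median measured {med:.3f}")

hist = mx.build_histogram(enface, n_bins=60)
fit = mx.fit_mixture(hist)
v_star = mx.component_intersection(fit)
print(f"v* = {v_star:.4f}")
```

prints

```
large_vessel     true CoV 0.100  median measured 0.097
shunt_near_faz   true CoV 0.458  median measured 0.437
capillary_svp    true CoV 0.299  median measured 0.288
capillary_dvp    true CoV 0.299  median measured 0.288
v* = 0.1615
```

The median Protocol C CoV recovers each vessel class's generative CoV
to within ~0.01–0.02 (the small shortfall is the finite-N bias of the
sample CoV), and the mixture intersection v\* = 0.16 lands between the
quiet large vessels (CoV ≈ 0.10) and the capillary/shunt population —
the threshold used to split the en face map into main vessels and
branches.  Note the shunt class truth of 0.458: its fluctuation is a
normal with σ = 0.5·mean truncated at zero, and 0.458 is the exact CoV
of that truncated law.

A command-line interface mirrors the pipeline stages:

```bash
octacov phantom --out-dir runs/phantom --seed 1
octacov register --manifest runs/phantom/manifest.yaml --out-dir runs/reg
octacov cov --manifest runs/phantom/manifest.yaml \
            --truth runs/phantom/truth.npz --out-dir runs/cov --protocol C
octacov mixture --cov-map runs/cov/cov_protocol_C.tiff --out-dir runs/mix
```

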