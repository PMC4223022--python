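# trifuse

Tri-modality (CT / MRI / PET) image fusion and GTV delineation-variation
analysis for radiotherapy planning.

Accurate gross tumor volume (GTV) delineation for brain tumors draws on
three complementary image sets — planning CT, contrast-enhanced T1 MRI, and
¹⁸F-FDG PET — but conventional treatment-planning software displays at most
two of them fused at a time.  `trifuse` provides:

- **Fusion.** A transparency-weighted composite of all three modalities in
  one image, with CT as the opaque background and PET/MR as semi-transparent
  layers:

      I_mix = t_P·I_PET + (1 − t_P)·[ t_M·I_MR + (1 − t_M)·I_CT ],
      t_P, t_M ∈ [0, 1]

  The weights are convex for every setting, so the fused image is bounded by
  its inputs; the corners (t_P, t_M) = (0,0), (0,1), (1,0) reproduce pure
  CT, MR and PET exactly.

- **Mask algebra.** The volume-combination steps of the tri-modality
  delineation protocol: GTV_common = GTV_MRI/CT ∩ GTV_PET, and the final GTV
  assembled from GTV_common plus the observer-kept parts of each
  single-scheme GTV.

- **Variation metrics.** Inter- and intra-observer delineation variability:
  the coefficient of variation of volumes (COV = sample SD / mean), the
  average distance between surface and centroid (ADSC) from marching-cubes
  meshes, the 50%-coverage *median surface*, the per-vertex local standard
  deviation SD_local of signed normal distances to each observer surface
  (with octant aggregation), and paired two-tailed t tests between
  delineation schemes.

- **Phantom.** A seeded synthetic generator producing co-registered CT-like,
  MR-like and PET-like head volumes with an ellipsoidal lesion, plus
  simulated observer masks obtained by smooth random radial perturbation of
  the ground truth — so every pipeline stage runs without clinical data.

Volumes are read and written as NIfTI-1/2 or NRRD, masks as uint8 NIfTI,
meshes as PLY/STL (the median surface carries `sd_local` per vertex for
color-wash rendering), reports as CSV.

## Worked example

```python
import numpy as np
from trifuse import *
from trifuse.volumes import GridSpec

# synthetic study: 64^3 grid at 2 mm, one lesion, three simulated observers
n, sp = 64, 2.0
origin = tuple(-(n - 1) * sp / 2 for _ in range(3))
spec = PhantomSpec(grid=GridSpec((n,)*3, (sp,)*3, origin),
                   lesion_center_mm=(10, 5, 8), lesion_radii_mm=(20, 17, 14),
                   head_radii_mm=(55, 58, 56), seed=1)
ct, mr, pet, truth = generate_phantom(spec)
obs = simulate_observers(truth, ObserverSpec(n_observers=3, radial_sd_mm=2.0, seed=1))

vols = [mask_volume_cm3(m) for m in obs]
print("observer volumes (cm^3):", [round(v, 2) for v in vols])
print(f"volume COV = {cov(vols).cov:.3f}")

meshes = [extract_surface(m) for m in obs]
print("ADSC (cm):", [round(adsc(me, mask_centroid(m)), 3)
                     for me, m in zip(meshes, obs)])

res = analyze_median_surface(obs)
print(f"mean SD_local = {res.overall_mean_cm:.3f} cm "
      f"over {len(res.sd_local_cm)} vertices")

ctn = window_normalize(ct, DEFAULT_WINDOWS["ct_bone"])
mrn = window_normalize(mr, percentile_window(mr))
petn = window_normalize(pet, percentile_window(pet))
fused = fuse(ctn, mrn, petn, TransparencyPair(t_p=0.3, t_m=0.3))
print(f"fused range: [{fused.data.min():.3f}, {fused.data.max():.3f}]")
```

Output:

```
observer volumes (cm^3): [20.5, 21.22, 21.15]
volume COV = 0.019
ADSC (cm): [1.729, 1.759, 1.742]
mean SD_local = 0.185 cm over 1484 vertices
fused range: [0.000, 0.693]
```

The three observers, perturbed with a 2 mm radial SD, disagree by about 2%
in volume; their ADSC values sit near 1.74 cm (the lesion's effective
radius); the mean SD_local of 0.185 cm ≈ 1.9 mm recovers the injected 2 mm
disagreement; and the fused image stays inside [0, 1] as the convex weights
guarantee.

The same chain is available from the shell:

```sh
trifuse phantom --out study/ --grid 64 --spacing 2 --seed 1
trifuse fuse --ct study/ct.nii --mr study/mr.nii --pet study/pet.nii \
             --tp 0.3 --tm 0.3 --out fused.nii
trifuse variation --masks study/obs1.nii --masks study/obs2.nii \
                  --masks study/obs3.nii --out report.csv \
                  --median-mesh median.ply
```

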