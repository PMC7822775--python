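# xrnav

Computational core of an X-ray fluoroscopy navigation system for
transcatheter interventions. During these procedures the interventionalist
works from live 2D fluoroscopy; overlaying a pre-interventional CT/MRI-derived
3D anatomic model onto the live images ("image fusion") restores the missing
third dimension. `xrnav` implements the geometry and image-analysis machinery
that makes such an overlay possible and testable without any hardware:

* **C-arm projection geometry** — a pinhole-camera model of the gantry. For
  image size $n_u \times n_v$, source–image distance $SID$, detector field
  diagonal $FD$, source-to-patient distance $SPD$, gantry rotation
  $R = R_{PA} R_{SA}$ (primary LAO$^+$/RAO$^-$ about the patient head–foot
  axis, secondary CRAN$^+$/CAUD$^-$ about the left–right axis) and world-frame
  table offset $t$, a world point $p$ (mm) maps to pixels through the
  $3\times4$ homogeneous matrix

  $$P = K\,[A \mid A(-t) + (0,0,SPD)^T],\qquad
    K = \begin{pmatrix} f & 0 & n_u/2\\ 0 & f & n_v/2\\ 0&0&1\end{pmatrix},
    \quad f = \frac{\sqrt{2}\, n_u\, SID}{FD}\ \text{px},$$

  with $A$ the world-to-camera rotation (which carries the v-axis flip: image
  rows grow caudally). The iso-center at zero table projects to the principal
  point for every angulation and the magnification there is $SID/SPD$.
* **Biplane 3D reconstruction** — a point marked in two views is
  back-projected to two rays whose least-squares intersection (midpoint of
  the common perpendicular) is the reconstructed working point; the ray gap
  is reported as an epipolar-consistency diagnostic.
* **Paired-point rigid registration** — the Kabsch/SVD solution of
  $\min_{R,t}\sum_i \lVert R\,p^{MRI}_i + t - p^{XR}_i\rVert^2$ (reflection-free),
  with quality reported as $\mathrm{RMSE}=\sqrt{\tfrac1n\sum_i\lVert T\,p^{MRI}_i - p^{XR}_i\rVert^2}$.
* **Template tracking & motion compensation** — zero-normalized
  cross-correlation matching in 2D, overlay shifting by the tracked motion
  vector, and biplane 3D catheter-tip tracking compensated by the
  triangulated 3D motion of a reference structure.
* **Live-panel character recognition** — the live video frame
  (1280×1024 px: a 1000×1000 image plus a configuration panel) displays the
  imaging geometry in whole centimeters/degrees; binarized template matching
  of the 13 analyzed character cells (minimum Frobenius norm of the
  difference to each glyph) recovers it independent of capture gain/offset.
* **Rounding-error bounds** — closed-form worst-case overlay displacement
  caused by the cm/degree display rounding:
  $\varepsilon_t = \frac{10\,\mathrm{mm}}{SPD}\,SID_{max}$ and
  $\varepsilon_a = \sqrt{b^2 + c^2 - 2bc\cos\theta}$ with $c = SID_{max}-SPD$,
  $b = c\,\sin 90°/\sin(90°-\theta)$.
* **Phantom simulator** — analytic forward projections of a glass-sphere
  phantom (6/10/20 mm spheres + tube), composed live-video frames with a
  rendered geometry panel, noisy marker sets and motion sequences — exact
  ground truth for every other module.
* **I/O** — X-ray DICOM runs (angiographic geometry tags via pydicom),
  legacy VTK POLYDATA meshes (ASCII and binary), CSV point lists, JSON
  transforms.

## Worked example

Emulate the biplane phantom registration experiment end to end — six marker
spheres observed at LAO 0°/LAO 90°, markers localized in tomographic space
with 0.5 mm RMS error, reconstructed from the two projections, then
registered:

```python
import numpy as np
from xrnav import *

scene = default_scene()
frontal = CArmGeometry(primary_angle=0, table=(-70, 60, -640),
                       sid=1200, fd=150, spd=810, label="frontal")
lateral = CArmGeometry(primary_angle=90, table=(-70, 60, -640),
                       sid=1300, fd=150, spd=765, label="lateral")
sample = sample_marker_sets(scene, sigma_mri_mm=0.5, sigma_px=0.0,
                            geom_a=frontal, geom_b=lateral, seed=1, n_markers=6)

pm_a, pm_b = build_projection(frontal), build_projection(lateral)
recon = np.array([triangulate(pm_a, qa, pm_b, qb).p
                  for qa, qb in zip(sample.points_a, sample.points_b)])
p_xr = PointSet3D(sample.truth.labels, recon, space="xr-world")
t = fit_rigid(sample.mri, p_xr)
print(f"registration RMSE: {rmse(t, sample.mri, p_xr):.3f} mm")
```

prints

```
registration RMSE: 0.253 mm
```

— a few-tenths-of-a-millimeter residual, the expected scale when the only
error source is the 0.5 mm tomographic marker localization (the median over
100 noise seeds is ≈0.39 mm). The display-rounding bounds are available from
the CLI:

```sh
$ xrnav error-bounds --spd 810 --sid-max 1200
{"eps_table_mm": 14.814814814814813, "eps_angulation_mm": 6.80747532200376}
```

i.e. two frontal acquisitions showing identical panel values can differ by up
to 14.8 mm of overlay displacement from table rounding and 6.8 mm from
angulation rounding at maximal magnification. Other subcommands: `simulate`,
`project`, `reconstruct`, `register`, `track`, `ocr`, `read-geometry`
(`xrnav --help`).

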