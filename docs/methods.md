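# Methods

## Coordinate systems and projection model

World coordinates (WCS) originate at the gantry iso-center: x = patient-left,
y = patient-anterior, z = cranial. At zero angulation the frontal source sits
at (0, −SPD, 0) and looks along +y; the image u axis follows the rotated +x,
the v axis the rotated −z (rows grow caudally, so the patient's head is up in
a frontal view). Primary angulation (LAO positive / RAO negative) is a
right-handed rotation about z, secondary (CRAN positive / CAUD negative)
about x, composed primary-then-secondary: R = R_PA·R_SA. Pixel centers sit
at integer coordinates with the origin at the upper-left corner; image
points outside the detector rectangle are representable (the virtual
detector plane is unbounded).

The projection is a pinhole camera: camera coordinates of a world point p
are A(p − t) + (0, 0, SPD), where A is the world-to-camera rotation
(including the fixed v-flip axis permutation) and t the table offset. The
intrinsic focal length is SID/pitch pixels, with pitch = FD/√(n_u²+n_v²)
mm/px computed from the detector diagonal and the image diagonal (the
familiar √2·n_u·SID/FD term for square images), or taken from a per-FD
calibration table when one is configured — displayed FD values are rounded
to whole centimeters, so calibrated pixel spacings from original DICOM
metadata remove that error source entirely.

**Table convention.** The displayed table position is treated as a
world-frame offset shared by both C-arms: the imaging system effectively
orbits the displaced iso-center, so the source sits at t + R·(0, −SPD, 0).
This is the only reading consistent with a biplane system imaging one
physical table, and it makes the in-plane component of a table shift
magnify by exactly SID/SPD while the along-axis component only changes
magnification — which is also what the closed-form table-rounding bound
assumes. At zero angulation it reproduces the conventional extrinsic
translation column (−t_x, −t_y, −SPD−t_z) up to the overall depth-sign
choice. Sign conventions are otherwise pinned by three testable properties:
the iso-center at zero table projects to (n_u/2, n_v/2) for every
angulation and SID, rows grow downward, and the iso-center magnification is
SID/SPD. The displayed long/lat/vert table coordinates map to world axes
via a configurable table (default long→z, lat→x, vert→y).

All distances are millimeters internally; angles are degrees at the API
boundary and radians inside. Vendor range guards (|primary| ≤ 185°,
|secondary| ≤ 90°) are configurable per geometry object.

## Biplane reconstruction

Two back-projected rays rarely intersect exactly; the reconstruction is the
midpoint of their common perpendicular, which for two lines is precisely the
least-squares point. The closest-approach distance (`gap_mm`) is returned as
a consistency diagnostic: a gap above 1 mm sets a warning flag (the pair is
probably not a true correspondence) without failing, while a view separation
below 15° raises a degenerate-geometry error — both thresholds are
parameters; the defaults are conditioning guards chosen at the scale of the
registration residuals, not physical constants. The epipolar-line helper
projects the viewing ray of one view into the other, restricted to the part
in front of both sources and clipped to the image rectangle.

## Rigid registration

The tomographic-to-XR transform is the closed-form Kabsch/SVD minimizer of
the paired-point squared error, with the determinant correction that
excludes reflections; Horn's quaternion method would give the identical
optimum. No scaling and no outlier rejection are applied — the registration
is deliberately rigid-only, and a deforming anatomy simply shows up as a
larger RMSE. Degenerate configurations (fewer than 3 pairs, collinear or
coincident markers) are rejected rather than silently fitted.

## Template tracking

Matching uses zero-normalized cross-correlation: template and candidate
region are both mean-subtracted, so scores are exactly invariant to positive
affine intensity changes of the frame. The argmax over all placements inside
the search window is taken with ties broken toward the smallest (v, u);
placements on constant image regions (NCC undefined) are excluded, and a
fully constant template or window yields an invalid match flag instead of an
arbitrary position. Optional parabolic sub-pixel refinement (off by default)
fits a 1D parabola through the score peak in u and v. The search window
defaults to 3× the template size re-centered on the last position; templates
are fixed at initialization — there is no drift-correcting template update,
re-initialization is a user action. For 3D tracking the tip is matched
independently in both views and triangulated; the 3D motion vector is the
displacement of one reference structure tracked the same way in both views
relative to its first-frame position, and the compensated tip is the raw tip
minus that vector. Biplane frames are paired by index; capture skew between
the two video chains is not modeled.

## Panel recognition

Each analyzed cell is binarized at the midpoint between its own minimum and
maximum intensity — exactly invariant to per-frame gain/offset — and
classified as the glyph (digits 0–9, '+', '−', blank) minimizing the
Frobenius norm of the element-wise difference matrix. A scalar "norm of the
cell" alone cannot separate glyphs with equal on-pixel counts; the
nearest-template reading is the one that identifies every character
uniquely. A constant cell binarizes to all-zeros and classifies as blank.
Any cell whose best distance exceeds the layout's mismatch tolerance
(default: exact match) marks its field invalid rather than guessing; an
inverted-polarity frame is therefore rejected field-by-field, not misread.

The shipped layout is synthetic: the vendor's panel pixel coordinates and
font are not redistributable, so layouts carry their own cell rectangles and
base64-encoded glyph bitmaps in JSON and real systems must be calibrated by
the user. Thirteen single-character cells are analyzed per frame. Seven
geometry fields at up to two digits each cannot fit into 13 single-glyph
cells simultaneously, which is why the panel time-multiplexes: nine cells in
three groups of three are shared between the table page (signed long/lat/
vert) and the angulation page (primary and secondary magnitudes), and four
distance cells are shared between SID and FD. The degree-sign mark — present
only when angles are displayed — discriminates the two pages; a full reading
merges one frame of each page, mirroring how a live system accumulates the
alternating display. Angulation signs come from the orientation words: the
first-letter cell separates LAO from RAO (their second letters coincide) and
the second-letter cell separates CRAN from CAUD. Converting a complete
reading to an imaging geometry multiplies centimeters by ten, passes degrees
through, and resolves FD through the configured pixel-spacing table (an FD
value absent from a configured table is an error).

## Rounding-error bounds

Displayed values are rounded to whole centimeters/degrees, so two
acquisitions with identical displayed values can differ by up to 10 mm in a
table coordinate and 1° in an angulation. Both bounds are evaluated at the
largest magnification (maximal SID). The table bound magnifies the 10 mm
span onto the detector: ε_t = 10 mm/SPD · SID_max (14.8 mm for SPD 810 mm /
SID_max 1200 mm; 16.99 mm for 765/1300). The angulation bound is the
law-of-cosines third side between the displaced and undisplaced positions
at distance c = SID_max − SPD from the iso-center, with
b = c·sin 90°/sin(90°−θ): 6.8 mm for the frontal geometry at θ = 1°. The
same formula gives 9.34 mm for the lateral geometry (765/1300); no single
SPD consistent with the lateral table bound yields a larger figure, so the
computed value is reported as-is. Simultaneous rounding of several
parameters can accumulate and is deliberately not modeled; SID rounding
itself only perturbs magnification, not alignment. SPD is not displayed
anywhere and must always be supplied explicitly; the shipped configuration
defaults (frontal 810 mm, lateral 765 mm) are per-C-arm vendor constants.

## Phantom simulator

The simulator emulates the accuracy-evaluation phantom: glass spheres of 6,
10 and 20 mm diameter plus a glass tube in a gel block. Projections are
analytic — per-pixel intensity background·exp(−Σ μᵢLᵢ) with Lᵢ the exact ray
chord length through each sphere/cylinder — rather than voxelized ray
casting, so the projected ground truth is exact and rendering is fast.
Default attenuation coefficients (0.05/mm spheres, 0.02/mm tube) are chosen
for clear contrast, not dosimetric realism. Live-video frames are 1280×1024
with the image in the fixed 1000×1000 region and the panel rendered at
display precision, rounding halves away from zero (the vendor's rounding
mode is unknown; the choice is centralized in one function).

Marker sampling emulates manual marker identification: tomographic-space
points are the sphere centers (optionally through the inverse of a known
rigid transform) plus isotropic Gaussian noise whose parameter σ is the RMS
**3D** displacement — per-axis standard deviation σ/√3. With σ = 0.5 mm,
the stated tomographic voxel size, the end-to-end biplane emulation (6
markers, LAO 0°/90°, exact 2D picks) yields a median registration RMSE of
≈0.39 mm over 100 seeds, consistent with per-set phantom results of
0.31–0.39 mm; a per-axis-σ reading would predict ≈0.69 mm, outside that
range. 2D picks get independent N(0, σ_px) noise per coordinate.

What the simulator does **not** model: X-ray spectra, scatter, detector blur
and glare, image-intensifier distortion (absent on flat panels anyway),
cardiac/respiratory deformation (all motion is rigid per structure), vendor
fonts and panel layouts, and capture-chain timing skew. Passing tests on
synthetic data therefore demonstrate the correctness of the geometry and
algorithms, not robustness to clinical image quality.

## Numerical choices and problem sizes

Triangulation and registration are closed-form (no iteration, no
initialization). NCC is computed with exact sliding-window sums; score ties
and sub-pixel refinement behave as described above. Projection/oracle
agreement is verified to 1e-9 px over 1000 random geometry/point pairs;
projective round-trips to 1e-6 mm. Tracking tests run on 220×220 px views
(50-frame sequences), panel-recognition checks on 500 randomized frames, and
the registration emulation on 100 noise seeds — sizes at which the full
suite completes in well under a minute while estimates (medians, rates) are
stable. The motion-compensation closure criterion is 1.5× the half-pixel
triangulation noise, i.e. the 3D error induced by 0.5 px offsets in both
views of the tracked structure.

## Known limitations

Rigid-only registration; single fixed template per structure (no drift
handling, no multi-template or articulated models); exact-match glyph
tolerance assumes a clean digital capture chain (a lossy/noisy chain needs a
nonzero mismatch tolerance and a calibrated layout); DICOM support covers
the angiographic geometry tags and uncompressed secondary-capture writing,
not full conformance; legacy VTK POLYDATA only (no XML VTK, no strips).
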