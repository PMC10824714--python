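# Methods

## Optical model

The simulator implements a single-beam (Gabor) in-line geometry: there is
no separate reference arm; the undiffracted illumination itself is the
reference wave, and the twin image that this geometry produces is
accepted, not removed. Illumination is a unit-intensity circularly
polarized plane wave with Jones vector `(1, i)/√2` (Stokes
`(1, 0, 0, −1)` under the Mueller convention used by the test oracles;
the handedness is a fixed convention, recorded with every other sign
choice in `holopol/constants.py`).

Each particle is a uniform linear retarder with scalar amplitude
transmittance *t*: its Jones matrix is
`R(θ)·diag(e^{−iδ/2}, e^{+iδ/2})·R(−θ)` with fast axis θ and retardance
δ. δ is drawn **once per particle** from `Normal(δ̄, sd)` clipped to
`[0, π]` — birefringence is treated as a material property, uniform
within a particle. Water and the channel glass are treated as isotropic,
so the two Cartesian field components propagate independently to the
sensor through the scalar angular-spectrum operator, and the analyzer
projection `I_α = |cos α·E_x + sin α·E_y|²` happens at the detector
plane, where the wire-grid mosaic physically sits.

Under these conventions a retarder-filled frame at z = 0 satisfies the
closed forms the whole polarimetric chain is tested against:

    I_α   = ½ (1 − sin δ · sin(2α − 2θ)) · t²
    DoLP  = |sin δ|                (independent of θ)
    SSD   = |sin δ| · I_total / (2√2)

The per-channel population standard deviation divisor is N = 4; with a
fixed channel count the sample/population choice only rescales the
feature, and the population form makes the closed form exact. AoP uses
the single-argument arctangent, giving the `[−π/4, +π/4]` range; the
two-argument form would double it.

### Propagation and its sampling limit

Forward propagation multiplies the spectrum by
`exp(−i·2πz/λ·√(1−λ²f²))`; evanescent components (negative root
argument) are hard-zeroed rather than decayed, which avoids overflow at
large z and makes the operator exactly unitary on band-limited fields
(round-trip and energy checks hold to 1e−8). The kernel is adequately
sampled only up to `|z| ≤ N·p²/λ` (N = smaller grid dimension, p = pixel
pitch); renders beyond that raise a sampling error instead of silently
aliasing.

When rendering, the uniform background is propagated analytically (a
global phase `e^{−i2πz/λ}`) and only the compactly supported scattered
component goes through the FFT, on a 2× zero-padded grid. Without this
split, fringes wrap around the periodic FFT domain and create ghost
particles at the opposite image edge — visible as spurious tracks in
video.

### Autofocus

The focus metric is the mean squared gradient of the reconstructed
amplitude (Tenengrad), evaluated on the back-propagation of the **raw**
hologram, DC term retained. This matters: after mean subtraction the
back-propagated object wave is rotated against the reference by the
phase `2πz/λ`, so amplitude contrast no longer sharpens at focus and
variance-style metrics become monotone in z. Keeping the DC in the
propagated field keeps reference and real image phase-aligned, and the
gradient metric then peaks at the recording depth (verified by simulator
round trips at z₀ ∈ {3, 5, 7} mm for 20–30 µm beads). Ties in the depth
scan — including the completely flat metric of an empty hologram —
resolve to the smallest z.

Depth discrimination is only physically meaningful when the scan range
is comparable to the defocus distance d²/λ of the particle (d =
diameter); for millimetre-scale particles that is metres, so autofocus
tests use 20–55 µm particles.

## Synthetic data: what it emulates, what it does not

The generator reproduces the acquisition geometry of the target
instrument: 632.8 nm illumination, 3.45 µm mosaic pixels in 2×2 analyzer
groups (0/45/90/135°), 2464×2056 mosaic (1232×1028 per channel, 6.9 µm
channel pitch), magnification 1 (lensless assumption; the object-plane
pixel equals the channel pitch), and a 5×10 mm flow channel driven at
8 ml/min (pump range 2–15 ml/min), giving a mean flow speed of
2.667 mm/s. Six plastic materials plus glass, lens paper and algae
controls are provided.

**The material retardances are synthetic placeholders.** Real
birefringence magnitudes for the six polymers are not tabulated in the
package's sources; the defaults (glass 0, PMMA 0.15, PS 0.35, PVC 0.45,
PC 0.60, PP 0.90, PET 1.30 rad; sd 0.05) exist only to create distinct,
orderable birefringence classes with glass as the zero-retardance
control. Consequently, passing classification tests show that *if*
materials differ in retardance by the configured amounts, the SSD/DoLP
feature chain separates them — they say nothing about the actual
separability of real polymers.

Noise is modelled as (i) additive Gaussian intensity noise on the
channel stack (suspended-matter scattering, relative to the mean
illumination level), (ii) Poisson shot noise on the mosaic with a
configurable photon scale, (iii) Gaussian read noise on the mosaic. Not
modelled: multiple scattering and turbidity, absorption spectra,
polarization aberrations of the optics, radiometric camera calibration,
motion blur within an exposure.

Rasterized shapes (disk beads, ellipse pellets, thin rotated-rectangle
fibers, irregular radial-polygon fragments, lobed low-solidity foam,
large irregular films) are deterministic given the particle seed, so a
moving particle keeps its outline between frames.

## Morphometry conventions

All caliper measures use the pixel-corner (outer boundary) convention:
the convex hull is built from the corner points of the mask's boundary
pixels. A single pixel therefore has max Feret √2 and min Feret 1, and a
30×40 px rectangle has max Feret 50. The rotating-calipers implementation
is tested for exact equality against a brute-force hull-vertex pairwise
scan (1000 random masks) — the brute-force oracle, not a formula, defines
truth. Sub-pixel conventions are otherwise arbitrary, and this one is
stated rather than implied.

The perimeter is the length of the marching-squares half-level boundary
polygon after **one** circular vertex-averaging pass. The raw
marching-squares polygon overestimates smooth perimeters by ≈ 5%
(staircase bias); one averaging pass brings a rasterized disk to within
≈ 1% of 2πr while leaving corners sharp enough that a square still
measures within ±0.03 of its continuous value √π/2. Circularity uses the
perimeter-equivalence form `2√(πA)/P` (the convention of
Morphologi-style particle analyzers); the squared ISO form `4πA/P²` is
exposed as an option. Area is pixel count × (object-plane pixel size)²,
and the sphere-equivalent volume is `(π/6)·CED³` with `CED = 2√(A/π)`.

Shape classes are a fixed-order rule cascade (fiber by aspect ≥ 5; bead
by circularity ≥ 0.92 and aspect ≤ 1.2; pellet by circularity ≥ 0.85 and
aspect ≤ 1.5; foam by solidity < 0.85; film by mean transmittance ≥ 0.9
and area above a configurable threshold; else fragment). A mask-only
classifier cannot detect films, hence the transmittance feature; all
thresholds are configuration.

## Tracking and counting

Detection runs on the raw-hologram SSD map: birefringent particles stand
out against an SSD background of exactly zero (ideal optics), and the
map needs no reconstruction. The linker is a constant-velocity greedy
nearest-neighbour with gating: per frame, each live track predicts its
position by extrapolating the last matched position with its velocity
estimate; candidate (track, detection) pairs inside the gate are taken
in order of increasing distance with ties to the lower track id;
unmatched detections spawn tentative tracks. Tracks confirm after 3
consecutive hits (transient noise blobs never confirm) and terminate
after 5 consecutive misses; a terminated track that was confirmed still
counts once. There is no appearance model or re-identification — at flow
cell number densities, position gating is sufficient and keeps the stage
fully deterministic. The default gate is 2× the expected per-frame flow
displacement + 10 px.

Against ground truth, a track is matched to the particle whose
trajectory it overlaps most (centroids within 12 px on ≥ 50% of the
track's frames), counting accuracy is `1 − |count − true|/true`, and the
per-particle correct rate is the fraction of true particles matched by
at least one confirmed track.

## Classification

The discriminative signal for material identity is birefringence, which
the feature maps expose directly (DoLP and SSD ∝ |sin δ|), so the
classifier is a nearest-centroid model on four features per particle
(mean SSD, 90th-percentile SSD, mean DoLP, mean amplitude
transmittance), standardized by training statistics, zero-variance
features dropped, ties to the first class in sorted order. A closed-form
model keeps every test deterministic and keeps the feature claim
falsifiable; the model serializes to JSON.

Feature statistics are taken over the eroded mask interior (4 px by
default in the video pipeline): at the detector plane, edge diffraction
mixes particle and background light, and edge pixels dilute the interior
plateau. An optional refocus path back-propagates each analyzer channel
to the particle plane before extracting features; it restores the
plateau for large recording distances but carries a twin-image bias that
depends on the particle's fast-axis angle (the reconstructed DoLP can
read anywhere between ≈ 0.6× and 1.3× of |sin δ| depending on θ), so the
default pipeline samples raw-map interiors at a short recording distance
instead.

Splitting is stratified by class and seeded, with largest-remainder
allocation per class plus a global rebalancing pass, so both the global
8:1:1 sizes and the per-class proportions are exact to within one
record. The validation slice is reserved for tuning segmentation
thresholds; the centroid model itself has no hyperparameters to tune on
it.

## The flowing-video battery

The end-to-end self-check (`holopol.benchmark.run_flow_battery`, also
what `scripts/acceptance.py` runs) renders 20 videos of 60 frames at
256×256 channel resolution — a deliberately reduced problem size that
keeps the whole battery at a few minutes on one CPU. Conditions, fixed
as part of the battery's definition of "easy": recording distance
0.5 mm; 4–5 particles per video, radii 6–11 px (≈ 80–150 µm), each in
its own flow lane (48 px spacing, i.e. ≥ 2× the largest diameter, so
"well-separated" holds against edge diffraction too); 8 ml/min flow at
60 fps (6.44 px/frame drift, particles enter and exit the field); six
plastics with retardance sd 0.02 rad so adjacent class means are ≥ 4
pooled standard deviations apart, and per-material transmittances
0.81–0.96; videos 10–19 add mild scatter/shot/read noise. The recording
distance is short because the interior retarder plateau of an 80–150 µm
particle survives 0.5 mm of propagation (Fresnel zone √(λz) ≈ 18 µm)
but not several millimetres — at 2 mm, diffraction erases the class
separation no matter the classifier.

The battery reports the pooled fraction of ground-truth particles that
are both correctly counted (matched by a confirmed track) and correctly
material-classified by a centroid model trained on the 8:1:1 split of
the extracted track features.

## Numerical choices and degenerate inputs

- DoLP is clipped at 1 (for ideal stacks `√(Q²+U²) ≤ I` holds exactly;
  clipping only absorbs noise excursions) and pixels below an intensity
  floor (default 1e−3 of the frame maximum) are flagged invalid rather
  than NaN. `AoP(Q=0, U≠0) = sign(U)·π/4`; `AoP(0, 0) = 0`, flagged
  invalid.
- Noiseless channel intensities can locally exceed the illumination
  level: Fresnel edge ripples of an absorbing object overshoot, so
  energy-sanity checks bound the overshoot rather than demand ≤ 1.
- Blank (constant) images segment to an empty list, not an error; empty
  masks raise.
- Seeds: a scene seed fully determines the render (per-particle seeds
  and per-frame noise seeds are spawned from it via `SeedSequence`);
  identical inputs reproduce bit-identical outputs, including mosaics
  and JSON summaries.
- All internal units are SI; tables report µm/mm.

## Known limitations

- The simulator's retardance values are placeholders (above); absolute
  classification accuracies transfer to real instruments only insofar as
  real materials separate comparably.
- The refocused-feature path's θ-dependent twin bias (above) is
  documented but not corrected; twin-image suppression is out of scope.
- The tracker has no occlusion reasoning beyond coasting through
  missed frames, and no identity features; crossing trajectories within
  one gate radius can swap identities.
- Segmentation is global-threshold based; heavily textured or
  low-contrast backgrounds would need the thresholds retuned via the
  validation split.
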