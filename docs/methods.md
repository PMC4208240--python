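# Methods

`ringoxsim` is a Monte Carlo design study for ring-type (finger-base) pulse
oximeters.  It answers a probe-design question: where around the finger base
should the light source and the photodetector(s) sit so that the
photoplethysmographic (PPG) signal is strong and the oximetry calibration
quantity is stable against anatomical variation?  Everything is simulated;
there is no external data.

## The finger-base model (synthetic geometry)

The finger base is represented as nested prisms along the finger axis
(40 mm long), with the cross-section in the (y, z) plane:

* an elliptical outer surface — two presets with bounding boxes
  40 × 18.4 × 22.4 mm (model 1) and 40 × 22.3 × 25.8 mm (model 2);
* a 0.2 mm epidermis shell (an inner ellipse with semi-axes reduced by the
  shell thickness; the thickness is exact on the axes and within a few
  percent elsewhere for these aspect ratios);
* one circular bone cylinder, the proximal phalanx, offset dorsally;
* two digital arteries (circular cylinders) on the palmar side beneath the
  bone — diameter 1.2 mm in diastole and 1.416 mm in systole, the only
  difference between the two cardiac phases of a model;
* four veins (diameters 0.4–0.7 mm) around the bone;
* everything else inside is a single dermis/soft-pulp compartment.

Angle convention: 0° is the dorsal top, angles increase toward +y, 180° is
the palmar bottom.  Units are mm and mm⁻¹.

Only the bounding sizes, epidermis thickness and vessel diameters are
fixed reference inputs; the internal placement is this package's design,
chosen to reproduce the qualitative anatomy the design question relies on:

* the proximal phalanx is large (radius 6 mm / 7 mm in models 1 / 2) and
  sits close beneath the dorsal skin (≈2 mm of soft tissue cover), so it
  shadows trans-illumination from dorsal sources;
* the arteries sit at the palmar-lateral corners, ±40° from the palmar
  midline in model 1 (140°/220°) and ±35° in model 2 (145°/215°), a few mm
  deep.  This is the standard course of the proper palmar digital arteries
  and it places them adjacent to the favourable source positions
  (135°–165°), with the 75°–105° detector arc on the same side — sources
  there illuminate the arteries directly and the pulsatile signal reaches
  those detectors.  (Placing the arteries within ±20° of the palmar midline
  was tried first and puts them behind the 135°–165° sources; the pulsatile
  signal then never reaches the 75°–105° window.)
* model 2 differs from model 1 by the larger outer section, a
  proportionally scaled bone and slightly rotated arteries — a structural
  perturbation, not a claim about any particular finger.

All positions are overridable per geometry (`build_finger_model(...,
overrides=...)`, or a YAML config via `geometry_from_config`), so none of
these choices is load-bearing for users with better anatomical data.

## Tissue optics

Per tissue and wavelength (656 and 943 nm) the model carries the absorption
coefficient μa, scattering coefficient μs, refractive index n and
Henyey–Greenstein anisotropy g of the five compartments (dermis/pulp,
epidermis, bone, arterial blood at 97 % SaO₂, venous blood at 60 % SvO₂).
The mean free path is derived, MFP = 1/(μa + μs).  Interfaces between
tissue regions are described by Lambertian reflect/transmit probabilities
per region (epidermis 32/68 %, dermis 26/74 %, veins 34/66 %, phalanx
47/53 %, proximal phalanx 26/74 %, digital arteries 53/47 %).

Two modelling decisions deserve emphasis:

* **Lambertian-only interfaces.**  The refractive indices are carried as
  metadata but Fresnel refraction is not applied; an interface event
  reflects with the entered region's tabulated probability (cosine-weighted
  about the normal, on the incoming side) or transmits (cosine-weighted on
  the far side).  Combining Fresnel and Lambertian probabilities would
  double-count the interface physics.  The outer epidermis–air surface
  transmits totally: a photon reaching it exits and is tallied.
* **Entered-region ownership.**  The probabilities of the region being
  *entered* govern each event (entering an artery uses 53/47; leaving any
  solid into dermis uses 26/74).  The single bone solid carries the
  proximal-phalanx parameters by default; the 47/53 "phalanx" surface is
  available per geometry.

## Transport

Analog (photon-termination) Monte Carlo: free-flight lengths are
exponential with mean 1/(μa+μs); at each collision the photon survives as a
scatter with probability μs/(μa+μs) — deflected by the Henyey–Greenstein
inverse CDF — or terminates absorbed.  Analog transport makes every tally an
integer and conservation exact:

    detected + missed + absorbed + end_cap + capped = launched

for every run (`missed` only arises when a detector axial window narrower
than the finger is configured; end caps are the x = 0/40 mm faces; `capped`
photons hit the 10⁴-event safety cap, in practice ≪ 0.1 %).

The source is a point emitter on the outer surface at a chosen angle,
axially centred, radiating into the tissue in a cosine-weighted cone of
half-angle 60° (LED-like; configurable down to a pencil beam).  Detectors
are 48 equiangular 7.5° bins over the full lateral surface.

Randomness: each photon owns a PCG32 stream derived (via splitmix64) from
the run seed and the photon index, so runs are bitwise reproducible and two
runs with the same seed launch identical photons.  Phase pairs
(diastole/systole) run with the same seed by default — common random
numbers (CRN): since the geometries differ only inside the artery
cylinders, paired walks are identical until a photon meets the systolic
artery shell, and the diastole-minus-systole difference has dramatically
lower variance than independent seeding.  The kernel is a numba-compiled
scalar loop (~15 M events/s on one desktop core; a 10⁶-photon configuration
runs in a few seconds).

Numerical details: boundary distances come from ray/conic quadratics with a
10⁻⁹ mm minimum-step guard; after each interface event the photon is nudged
10⁻⁷ mm along its new direction; survival and deflection share one uniform
variate (conditional on survival, u/albedo is again uniform); azimuths are
drawn trig-free by rejection on the unit disk.

## PPG metrics

From a CRN phase pair, per detector selection and wavelength:

* AC = I_dia − I_sys (pulsatile component), DC = (I_dia + I_sys)/2
  (baseline; DC = I_dia is available as a config alternative — the mean is
  symmetric and budget-invariant);
* P-I ratio = (I_dia − I_sys)/I_incident × 100 %, with incident intensity
  equal to the launched photon count (unit weight per photon);
* ratio of ratios R = (AC_red/DC_red)/(AC_ir/DC_ir), the quantity pulse
  oximeters calibrate against SpO₂;
* screening: R undefined (zero infrared AC or empty bins), negative, or
  above 2.5 is recorded as 0.  The threshold itself is kept (the screen
  drops strictly unreasonable values only).

The three-element multi-detector sums raw intensities over three adjacent
bins *before* AC/DC computation (physically a larger collection area;
averaging would leave R unchanged but would scale P-I).

## The design study

The sweep runs sources 0°–180° in 15° steps (the geometry's left–right
symmetry makes 180°–360° redundant up to mirror), 48 detectors, both
wavelengths, both phases, both models, single and multi3 modes: 2 496
metric rows, each reproducible from (config, master seed); a manifest
records every run seed and conservation tally.  The ranking score
formalises "strong and stable": worst-case infrared P-I over models,
penalised by the relative cross-model spread, restricted to placements with
a positive screened R in every model.  The verbal design conclusion this
mirrors — sources at 135°–165° with detectors at 75°–90°/90°–105° — emerges
in the heat maps and rankings.

## Problem sizes

The reference budget for a full-scale study of this kind is 10⁷ photons
per configuration.  Desk-scale defaults here are 10⁶ per configuration for
the sweep, and the test suite
uses 1.5–2 × 10⁵ for directional checks (bone shadowing, source-angle
dependence of the windowed P-I ratio) and 6 × 10⁵ per configuration for the
multi-detector stability comparison, which needs resolvable red-band AC
counts per bin.  At 2 × 10⁵ photons the windowed P-I contrasts reported by
the tests are many counting σ wide; per-bin R values at red wavelengths
remain noisy below several 10⁵ photons, which is exactly why the screening
of unreasonable R values exists.

## What the synthetic model does and does not show

The generator emulates the *structure* of the design problem: a strongly
scattering, weakly absorbing bulk; an optically dominant bone; small
pulsatile absorbers near the palmar surface; diffuse interfaces.  Passing
tests therefore support the placement conclusions as properties of this
class of geometry, not of any individual finger: real fingers add
irregular bone sections, perfusion gradients, skin pigmentation,
ring-pressure deformation and motion, none of which are modelled.  SpO₂
itself is out of scope — converting R to saturation needs an empirical
calibration curve that simulation alone cannot supply.

One deliberate asymmetry against intuition is documented in the tests: with
Lambertian interfaces and analog transport, *total* escaped weight is
slightly higher for dorsal sources (the bone is a weak absorber and a
strong diffuser, while palmar blood absorbs strongly), even though the
*useful* light reaching the artery-side detector window is an order of
magnitude lower.  Bone "shadowing" is a statement about where light can
still go, not about how much of it survives in total.
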