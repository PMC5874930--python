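# Methods

This note documents the models behind `arcqa`: what each stage assumes,
which parameters matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Geometry and conventions

Coordinates are right-handed with the isocenter at the origin and `z`
along the cylinder axis; lengths in cm, dose in cGy, angles in degrees.
Gantry angle 0 means the beam enters from the top, increasing clockwise
viewed from the couch foot; diode azimuths use the same frame, normalized
to the half-open interval [0, 360). All angle arithmetic is modulo 360.

The default array build places 1386 diodes on a left-handed helix: diode
*i* sits at `z = −L/2 + i·L/(N−1)` and azimuth `(i·360·T/N) mod 360` with
`T = 21` turns over the `L = 21` cm length, i.e. 66 diodes per turn at
360/66 ≈ 5.45° spacing, one turn per cm of axial travel. The handedness
and ordering are a fixed, documented convention; only the diode count and
the detector depth (3.3 g cm⁻² water-equivalent, 2.9 cm physical) are
device-quoted. The remaining dimensions — detector radius 10.4 cm,
phantom outer radius 13.3 cm, length 21 cm — are manufacturer-typical
defaults, configurable through `ArrayConfig`.

The beam-relative incidence angle of a diode reduces, in this shared
angular frame, to `(gantry − azimuth) mod 360`: 0 when the beam enters
directly over the diode, 180 when the diode is on the exit side.

## Synthetic beam and response model

The dose model is an analytic broad-beam Co-60 approximation, not a
transport calculation:

    dose = output_rate · t/60 · (SAD/d)² · exp(−μ_w ρ · depth) · T(u, v)

with `d` the distance from the source, `depth` the geometric path from
the beam's entry into the finite PMMA cylinder to the point, and `T` the
aperture transmission built from error functions at the projected
rectangular field edges (penumbra σ = 3 mm at the isocenter plane, field
half-widths diverging with distance from the source). Defaults: SAD
105 cm, μ_eff = 0.0657 cm⁻¹ in water scaled by relative density, PMMA
density 1.19, output 550 cGy/min per head. These are plausible Co-60
values chosen once; none is device-measured. A `tps_density` override
(e.g. the commissioning-tuned 1.125 g cm⁻³) can generate reference grids
in a deliberately mistuned medium; by default it is off so reference and
truth coincide and correction-recovery experiments are exact.

The diode response multiplies the planned per-frame dose share by

    (1 + δ) · a(φ) · s_i · f(A) · (1 + ε),   ε ~ N(0, noise_sd)

* `a(φ) = 1 + 0.02 cos φ + 0.01 cos 2φ + 0.005 sin φ` — a smooth periodic
  angular response with ±3% range and mild entry/exit asymmetry;
* `s_i` — per-diode sensitivities, lognormal with σ = 0.5%;
* `f(A) = 1 + 0.001(A − 10)` — a weak equivalent-square field-size
  dependence;
* `δ` — a global multiplicative over-response emulating the
  magnetic-field effect; the default **+5%** reproduces the observed
  median discrepancy this pipeline was built to analyze;
* `noise_sd` — relative frame noise, default 1%.

Each beam's dose is spread evenly over its own beam-on frames (50 ms
each); `simultaneous=True` runs all heads at once, `False` delivers
sequential single-beam segments (the temporal interleaving of a real
three-head delivery at frame resolution is unpublished, so both modes
exist). Totals equal frame sums exactly, and all randomness flows through
one seeded generator.

**What the generator does not emulate:** magnetic-field electron-return
physics, MLC leaf sequencing and intensity modulation within a beam,
dose-rate or repetition-rate response, leakage between heads, scatter
beyond the penumbra model, and detector electronics. Passing tests
therefore demonstrate the *analysis machinery* — angle recovery, factor
application, gamma, statistics — under controlled conditions, not the
physics fidelity of any real device.

## Virtual inclinometer

For a single-beam frame the entry region receives the highest dose, so
the increment-weighted circular mean of diode azimuths points at the
gantry angle. The weights are soft-tapered, `max(inc − 0.3·max_inc, 0)`:
a hard membership threshold makes the cluster composition jump as the
beam sweeps past the 5.45°-spaced azimuth lattice and can push the
estimate past 1° of error, while the taper keeps it smooth (measured
maximum error 0.6° over all integer angles with 1% frame noise; the
0.3 taper level was selected on noiseless sweeps for exactly this
smoothness). Two guards classify frames instead of guessing:

* **empty** — frame total below 10⁻⁴ cGy;
* **ambiguous** — circular resultant length of the tapered weights below
  0.5 (balanced multi-beam frames produce two or three entry clusters and
  an incoherent distribution), or the exit-side cluster, searched within
  ±45° of entry + 180°, deviating by more than 20°.

All thresholds are keyword-configurable. The estimate is invariant to
overall signal scaling and equivariant under azimuthal rotation of the
signal pattern. A strongly unbalanced two-beam frame may still be
reported `ok` with the dominant beam's angle; the guards are tuned for
the balanced simultaneous deliveries the three-head system produces.

## Correction factors and their application

`make_correction_tables` builds reciprocal tables from a response model:
C_AD(φ) = 1/a(φ) on a 1° grid, C_ID,i = 1/s_i, C_FS(A) = 1/f(A) on a
1–40 cm equivalent-square grid, C_HF from a configurable heterogeneity
curve (unity by default). The systematic term δ is deliberately *not*
inverted — real factor tables are indexed by angle, diode and field size
only, which is precisely why a global offset survives correction.
Interpolation rules are fixed and serialized with the tables: linear with
360° wraparound in angle, linear without extrapolation in field size,
exact per-diode lookup.

Two application paths:

* **Framewise** — each frame's increments are multiplied by the selected
  factor product at that frame's estimated angle and summed. Frames with
  `empty`/`ambiguous` status are accumulated uncorrected and counted;
  refusing to guess an angle is the conservative choice.
* **Dose-fraction weighted** — the accumulated total is multiplied by
  Σ_k F_ik · Π(factors at beam k's static incidence angle). F_ik comes
  from trilinear interpolation of the per-beam planned grids at the diode
  positions; rows whose planned total falls below ε = 10⁻³ cGy are
  flagged and left uncorrected (a fraction of nearly nothing is noise).
  Unflagged rows sum to 1 within 10⁻⁹.

The default factor selection is {AD, ID, HF}. The field-size factor needs
a separate field-size-detection step and depends on the number of active
heads, so it is selectable (`FS`, with the equivalent square 2WL/(W+L))
but off by default. For a noiseless static-gantry single-beam delivery
the two paths coincide exactly on unflagged diodes (the K = 1 collapse of
the weighted formula); flagged diodes differ by construction, since only
the weighted path exempts them.

`max_correction_reduction` reports the largest over-response the tables
can fully cancel, `1/min(combined product) − 1`, in percent.

## Ion-chamber dose-to-water

The simplified conversion applies exactly
`M_raw · P_elec · P_TP · N_D,w · 0.986 · 0.973`, with
`P_TP = (273.2 + T)/295.2 · 101.33/P`. The full form additionally
multiplies P_pol, P_ion, P_MF, k_Q and the wall-factor ratio, every one
of which defaults to exactly 1 and is never applied silently: for a Co-60
measurement k_Q = 1.000 by definition, the wall ratio is 1.000 for this
chamber family, and the unapplied influence factors are carried in the
uncertainty budget instead. The stopping-power ratio is treated as
depth-independent (valid at or beyond d_max for Co-60); measurement
locations carry both the physical PMMA depth and the water-equivalent
depth.

Budget components are stated at k = 1 and combined in quadrature;
rectangular distributions of half-width M contribute M/√3. The built-in
13-component chamber budget totals 3.0%. Its volume-averaging row is
carried at its printed 0.8% even though the quoted rectangular M = 2%
would imply 1.15% — printed component values are combined as printed, and
the rectangular helper exists for constructing new budgets, not for
re-deriving old rows. Budgets nest: a total can become a component of a
comparison-level budget.

## Gamma analysis

Gamma is computed on the unwrapped cylinder surface: distances are
(arc length at the detector radius, Δz) with azimuthal wraparound, in mm.
For each evaluated diode the engine scans reference samples within a
search radius of 3 × DTA on a 0.1 mm lattice anchored at the diode,
interpolated trilinearly from the plan grid, and takes

    γ_i = min √( (m_i − ref(p))² / ΔD² + d(p)² / DTA² ),  capped at 10.

ΔD is the dose criterion times the maximum reference dose at the diode
positions (global, the default) or times the local reference dose. The
inclusion threshold applies to the reference dose at the diode; diodes
below the threshold percentage of the global maximum carry no γ. Only the
reference is searched — measured diode values are points, not a surface.
A reference can also be given per-diode, in which case the search runs
over the diode lattice itself. `gamma_brute_force` is an independently
written exhaustive scan for small instances used to validate the engine
to 10⁻⁶; it refuses more than 200 evaluated diodes by design. The
vendor-style "apply measurement uncertainty" softening is not
implemented; all results correspond to that option off.

## Statistics

Differences are signed (measured − reference); percent differences are
local (relative to the reference at that diode) and undefined where the
reference is 0. Histograms use 1 cGy / 1% bins by default. The p50 is the
empirical-CDF crossing — the smallest absolute difference at which the
cumulative frequency reaches 50% — because that is well-defined on
discrete data. The two-sample test is Welch's (unequal variance), the
dependent-sample test is the paired t; zero-variance inputs return a
degenerate flag rather than a p-value. Which readings form a "sample" in
a chamber-vs-array comparison is a study-design choice, so the tests take
plain arrays and leave the pairing to the caller.

## Problem sizes used in tests and the acceptance script

Dose grids default to 7 mm voxels over the phantom plus margin (the
analytic beam model is smooth, and the same grids feed both the reference
and the simulated measurement, so grid resolution cancels out of
difference statistics); gamma validation toys use a 100-diode cylinder;
campaign-level checks use 3 to 19 three-beam plans with beam-on times of
a few seconds. These sizes were chosen so the full suite documents the
behavior at interactive speed; every size is a parameter, and nothing in
the algorithms depends on them.

## Known limitations

* The beam model is analytic; penumbra, scatter and depth dose are
  qualitative. Absolute doses are plausible, not commissioned.
* The inclinometer guards are tuned for balanced simultaneous beams;
  pathological unbalanced multi-beam frames can evade the ambiguity flag.
* Framewise field-size correction assumes one delivery-wide equivalent
  square.
* The gamma engine evaluates measured points against a reference surface
  only; volumetric (3D) gamma and measured-distribution interpolation are
  out of scope.
* DICOM support is limited to axis-aligned RT Dose grids with uniform
  frame offsets; RT Plan / RT Struct objects are not parsed.
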