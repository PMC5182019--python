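# Methods

`ssrox` implements the single-frame processing and merging strategy used
in serial synchrotron rotation crystallography (SS-ROX): many randomly
oriented microcrystals each contribute one snapshot taken while the
goniometer rotates through a small wedge, and a complete dataset is
assembled by Monte-Carlo merging of these snapshots.  Because no real
beamline data ship with the package, a synthetic experiment generator
produces integrated observations with known ground truth, so every
stage — corrections, scaling, merging, statistics, anomalous signal —
can be validated end to end.

## The intensity model

An observation of reflection *h* on frame *i* is modelled as

    I_obs = s_i · p · L · I_true(h; D) + ε,

where

* `s_i` is the per-crystal linear scale (crystal volume, illuminated
  fraction), drawn log-normal with σ = 0.3 by default — the
  experimental per-crystal variation is not tabulated anywhere, and 0.3
  gives the order-of-magnitude spread in frame intensity that serial
  snapshot data typically show;
* `p` is the partiality: the fraction of the reflection's rocking curve
  swept by the wedge.  The rocking curve is Gaussian with standard
  deviation equal to the mosaic spread (0.03° by default, the measured
  mosaicity of the study crystals), truncated at ±3σ so that a fully
  swept reflection has partiality exactly 1.  For stills (wedge width
  0°) the partiality is the Gaussian profile ordinate at the static
  offset, so an exactly-centred still reflection gets 1;
* `L = 1/|ẑ·(ŝ₁×ŝ₀)|` is the rotation-method Lorentz factor (ẑ spindle
  axis, ŝ₀/ŝ₁ unit incident/diffracted beam directions): nodes crossing
  the Ewald sphere slowly accumulate proportionally more intensity;
* `I_true(h; D)` is the dose-dependent true Bijvoet intensity (below);
* `ε` is Gaussian noise with σ² = g·max(I,0) + b₀² (Poisson-like gain
  `g` = 1 plus a constant background term).  The default background
  σ b₀ = 2000 is ≈ 5 % of the mean reflection intensity on the
  generator's arbitrary scale, chosen so that weak crystals sink toward
  the ⟨I/σ⟩ ≈ 1 regime where frame rejection starts to matter.  With
  noise disabled the recorded sigmas are set to 1 so that downstream
  divisions stay defined.

The diffraction condition is solved exactly: for each candidate
reflection the crystal orientation and reciprocal metric give the
rotation angle(s) at which the node crosses the sphere, and only
crossings whose rocking interval overlaps the wedge are emitted.
Observations whose inverse Lorentz factor is below 10⁻³ (node nearly
parallel to the spindle) are dropped by the generator and counted on the
frame record; the correction step independently applies a floor of 0.01,
because the correction variance is unbounded near the spindle and the
choice of floor is otherwise free.

## Ground truth

Protein structure factors come from direct summation over 300 randomly
placed dummy atoms (f = 6 e, B = 20 Å²) expanded over the point-group
rotations, treated as a symmorphic group with the origin on the
rotation axes.  This guarantees — rather than imposes — Friedel
conjugacy, centric phase restrictions and point-group symmetry of the
intensities.  Heavy-atom sites (defaults approximate Hg at λ ≈ 0.98 Å:
f₀ = 80, f′ = −5, f″ = 7.7 e) enter through per-site geometric factors
so that occupancies can be re-weighted at any dose without re-summing.
Because 300 dummy atoms stand in for a few thousand protein atoms, the
Bijvoet ratio is a few times larger than for a real Hg derivative; the
anomalous-signal tests probe trends and geometry, not absolute peak
heights.

Two built-in point groups ship: "1" and "222" (the study crystal is
primitive orthorhombic).  The ASU representative of an orbit is the
lexicographically greatest triple in the combined orbit of ±h; the
Friedel sign records which half-orbit the observation came from.  A
consequence worth noting: both mates of a centric reflection map to the
same (friedel = +) entry, so a spurious "centric anomalous difference"
cannot be formed anywhere downstream.

## Radiation damage

Two mechanisms, both driven by the accumulated dose D in MGy:

* global decay `exp(−B₁·D·s²/2)` with s = 1/d and B₁ the B-inflation
  rate (Å²/MGy).  The default of 0.5 Å²/MGy reproduces the commonly
  reported behaviour of cryo-cooled protein crystals whose diffraction
  power falls to ~70 % after ≈ 10 MGy at the resolutions used here;
* site-specific damage: heavy-atom occupancy decays as
  `exp(−D/D_half)` with D_half the dose at which occupancy reaches 1/e.
  Repeated scans of the same sample are modelled by raising the base
  dose scan by scan.

Dose per frame is a configuration input; dose simulation proper
(beam-profile integration) is out of scope.

## Corrections and merging

* Inverse-Lorentz correction multiplies intensity and sigma by
  |ẑ·(ŝ₁×ŝ₀)|; stills are left untouched.
* Full-intensity estimation divides a partial observation and its error
  by the recorded PEAK fraction; the default pipeline merges these
  full estimates after discarding low-PEAK observations.  The default
  cutoff table is 30 % at 0.1°, 50 % at 0.25°, 70 % at 0.5° and 80 % at
  ≥ 1.0° rotation per frame.
* The two-parameter error model σ′² = a(σ² + b·I²) with defaults a = 4,
  b = 10⁻⁴ is available for sigma inflation of counting-statistics
  errors.
* The per-frame scale minimises Σ(I_obs − s·I_ref)² against the current
  merged reference, closed form s = ΣI_obs·I_ref / ΣI_ref².  Scaling
  and merging alternate (default 5 rounds, relative tolerance 10⁻⁴ —
  one round reproduces a single-pass scheme); afterwards scales are
  normalised to geometric mean 1, since the global scale is a gauge
  freedom.  Frames with no usable overlap or a non-positive solution
  are excluded and logged; whole frames, never single observations, are
  rejected.
* Merged sigma is the standard error of the mean of the scaled
  observations (multiplicity ≥ 2) or the propagated single-observation
  sigma (multiplicity 1).  Negative merged intensities are retained;
  Monte-Carlo averaging is unbiased and the half-set statistics expect
  them.

## Quality statistics

Frames are split uniformly at random into two halves (frames, not
observations, are the independent unit), each half merged
independently.  CC1/2 correlates Friedel-averaged merged intensities;
CCano correlates the half-set anomalous differences ΔI = I(+) − I(−)
over acentric reflections with both mates in both halves; Rsplit is
(1/√2)Σ|I_A−I_B| / (Σ(I_A+I_B)/2).  Shells are equal reciprocal volume
(uniform in 1/d³); a shell with fewer than 3 common reflections reports
a missing value rather than 0.  The resolution cutoff walks shells from
low to high resolution and returns the d of the last shell passing the
chosen threshold (no interpolation), CC1/2 ≥ 0.5 by default.

Per-frame triage: the hit rule (≥ 3 spots at resolution lower than
5 Å), ⟨I/σ⟩ = mean(I/σ) over a frame's corrected observations,
descending-⟨I/σ⟩ sorting with frame-id tie-break, rejection-threshold
scans and cumulative-image curves over any metric callable.

## Anomalous difference synthesis

Bijvoet differences are converted to amplitude estimates through the
first-order relation ΔF = ΔI / (2√max(I̅, ε)) with a scale-free floor
ε = 10⁻⁶·max(I̅); coefficients ΔF·exp(i(φ−π/2)) with model phases φ are
summed over the symmetry-expanded acentric set with Hermitian symmetry
enforced, so the map is real by construction.  No figure-of-merit
weighting is applied (an optional column is the natural extension).
The grid spacing is ≤ d_min/3.  The synthesis is evaluated by FFT by
default; a plain direct-summation path produces the identical map (the
tests assert agreement to 10⁻¹⁰ of the rms) and serves as the
unambiguous reference.  Peak heights are reported in map-rms units at
the fixed input site — the convention used when quoting "peak height at
the heavy-atom position" — with the offset to the nearest local
maximum within 2 Å as a diagnostic.  In synthetic runs the phases come
from the generator's protein-only structure factors, standing in for
refined-model phases; rms-unit heights are comparable only within this
package.

## Problem sizes and what the tests show

The behavioural test suite and the acceptance script run the pipeline
at desk scale: ground truth to 3.5 Å in the 47.3 × 76.7 × 84.0 Å cell
(~4 200 unique reflections), 400–2 000 frames per run, 0.5° wedges,
40 % hit rate, and a 10-step dose series at 1 200 frames per step.
These sizes give stable Monte-Carlo statistics for the properties
tested (scale recovery r > 0.99, anomalous-peak localisation to one
grid step, monotone dose and multiplicity trends) while each check
stays in the seconds-to-a-minute range.

The generator emulates integrated observations, not detector images:
there is no pixel-level peak finding, no indexing ambiguity, no
detector gaps, and partialities are known exactly rather than
estimated by profile fitting.  Passing tests therefore demonstrate the
correctness and the qualitative behaviour of the processing chain —
not that any particular real dataset would reach the same numbers.
Hit/indexing-rate tables from real loops, absolute peak heights, and
minimum image counts for phasing real data are outside what the
synthetic study can certify.

## Known limitations

* Only symmorphic rotation point groups are handled; screw axes and
  centred lattices would need phase-shift bookkeeping in the symmetry
  expansion.
* Partialities are closed-form Gaussian fractions; no post-refinement
  of partialities is attempted.
* The "incomplete rotation" effect (crystal entering/leaving the beam
  mid-frame) has no established quantitative model; the generator
  offers only a uniform per-frame attenuation applied to a configurable
  fraction of frames (`weak_frame_fraction` / `weak_frame_factor`, off
  by default), which also serves to emulate poorly diffracting
  crystals.
* The XDS_ASCII reader handles the column-declaration dialect needed
  for interchange, not every historical variant of the format.
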