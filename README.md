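# ssrox

Serial synchrotron rotation crystallography (SS-ROX) processing at desk
scale: single-frame corrections, Monte-Carlo merging with per-frame
scaling, half-dataset quality statistics, anomalous difference Fourier
peak scoring — plus a synthetic experiment generator with radiation
damage, so the entire method can be exercised and validated without
beamline data.

## The problem

In SS-ROX, a loop carrying many protein microcrystals is raster-scanned
through a microbeam while the goniometer rotates, so each snapshot is a
small rotation wedge (0–2°) from a randomly oriented crystal.  No
crystal contributes more than one frame, so conventional rotation-series
integration does not apply; instead each frame is integrated on its own
and thousands of frames are averaged ("Monte-Carlo merging").  Getting
an accurate merged dataset — accurate enough for single-wavelength
anomalous diffraction (SAD) phasing from Bijvoet differences of a few
percent — requires per-observation and per-frame care:

* **Lorentz correction.**  A rotational snapshot over-records
  reflections near the spindle axis by the Lorentz factor
  L = 1/|ẑ·(ŝ₁×ŝ₀)|; intensities and sigmas are multiplied by the
  inverse factor (stills are exempt).
* **Partiality handling.**  A wedge sweeps only a fraction (PEAK) of
  each reflection's rocking curve.  Full intensities estimated from
  single-frame profiles work well *if* low-partiality observations are
  discarded; the default cutoffs are 30/50/70/80 % for rotation steps
  of 0.1/0.25/0.5/≥1.0°.
* **Per-frame scaling.**  Each frame receives the least-squares scale
  s_i = ΣI_obs·I_ref / ΣI_ref² against the merged reference, iterated to
  convergence, before the final merge I_merged = (1/N)Σ I_j/s_j.
* **Frame triage.**  Frames are ranked by ⟨I/σ⟩; merging the best
  frames, or rejecting frames below a threshold, measurably raises the
  anomalous signal.
* **Validation metrics.**  Random half-datasets give CC1/2, CCano and
  Rsplit per resolution shell; the anomalous difference Fourier map
  with coefficients |ΔF|·exp(i(φ−90°)) is scored by its height, in
  map-rms units, at the heavy-atom sites.

The synthetic generator emulates the study system: an orthorhombic
protein crystal (a = 47.3, b = 76.7, c = 84.0 Å, point group 222) with
one major and one minor mercury-like site, 0.03° mosaic rocking width,
log-normal per-crystal scales, a configurable hit rate, and
dose-dependent damage (global Wilson-B decay plus exponential
heavy-atom occupancy loss with a characteristic half dose).

## Worked example

```sh
cat > sim.yaml <<'YAML'
cell: [47.3, 76.7, 84.0, 90.0, 90.0, 90.0]
point_group: "222"
d_min: 3.5
sites:
  - frac_xyz: [0.1, 0.2, 0.3]
    occupancy: 1.0
  - frac_xyz: [0.4, 0.15, 0.62]
    occupancy: 0.3
simulation:
  n_frames: 600
  hit_fraction: 0.4
  seed: 1
YAML

ssrox simulate --config sim.yaml -o run/
ssrox correct run/observations.tsv --min-peak AUTO -o corrected.tsv
ssrox merge corrected.tsv -o merged.tsv
ssrox stats corrected.tsv -o quality
ssrox anomalous merged.tsv --phases phases.tsv --sites sites.txt \
      --dmin 3.5 -o anom.json
```

(`phases.tsv` is an `h k l phase(deg)` table — for synthetic runs export
it from `run/truth.json`; `sites.txt` lists fractional coordinates plus
a label per site.)

`quality_summary.json` from this run:

```json
{
  "cc_half_overall": 0.9059017831498918,
  "cc_ano_overall": -0.07668611921385818,
  "r_split_overall": 0.21155045376017192,
  "n_unique": 6786,
  "multiplicity_mean": 2.6027114647804304,
  "resolution_cc_half_0.5": 3.500007173683611
}
```

240 hit frames already merge to CC1/2 ≈ 0.91 with the CC1/2 = 0.5
resolution cutoff at the simulation limit; CCano between 120-frame
halves is still in the noise, which is exactly why the anomalous map —
which pools all acentric differences coherently — is the better
low-multiplicity signal detector.  `anom.json`:

```json
{
  "sites": {
    "Hg1": {"height_rms": 37.26, "nearest_max_offset_A": 0.52},
    "Hg2": {"height_rms": 8.97,  "nearest_max_offset_A": 0.73}
  }
}
```

The major site stands at 37 rms (minor at 9 rms, matching its 0.3
occupancy), each within one grid step of the planted position.

The same pipeline is available as library calls
(`ssrox.simulate`, `ssrox.corrections`, `ssrox.merging`, `ssrox.stats`,
`ssrox.anomalous`, `ssrox.pipeline`); the CLI and the library produce
byte-identical outputs for the same seed.

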