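# Methods

## The generative model

Each simulated well contains `n_cells_per_well` biosensor-expressing
neurons imaged in two channels on a fixed grid: one frame every
`frame_interval_h` (default 2 h) for `frames` frames (default 84, i.e.
7 d), with the first frame `t0_offset_h` (default 2 h, at most one
interval) after seed addition. All per-cell event histories are driven by
independent piecewise-constant exponential clocks, chosen so that every
downstream estimator can be validated against closed forms:

- **Aggregation onset** — hazard
  `onset_base_hazard_per_h x line_multiplier x (dose/10 µg)^dose_exponent`.
  The base hazard applies to the control line at the 10 µg reference
  dose; the mutant line multiplies it by `onset_hazard_line_multiplier`.
  Control lysate and the no-lysate condition have onset hazard 0: the
  biosensor never aggregates without seed-competent tau.
- **Death** — base hazard `death_base_hazard_per_h` before onset,
  multiplied by `death_post_onset_multiplier` afterwards (aggregate
  toxicity), and additionally by `ordered_death_multiplier` for cells
  whose strain is Ordered (strain-dependent toxicity; default 1 = off).
  Aggregate-free deaths therefore occur, and death may precede onset.
- **Field-of-view exit** — an independent exponential
  (`exit_hazard_per_h`); exit censors everything after it.
- **Transient aggregation** — with probability `transient_prob` an onset
  dissolves after an exponential dwell (`transient_dwell_mean_h`),
  producing the "Trans" phenotype.

Events are continuous in time; anything observable is discretised to the
frame grid (an event is seen at the first frame at or after it occurs),
so recorded times are multiples of the frame interval and ties are
ubiquitous — which is why the Cox fits use the Efron approximation.

### Default rates

The defaults are calibrated to the published single-cell fractions of the
assay the package models: control-line onset hazard 0.004/h at 10 µg
gives P(onset <= 48 h) = 0.17 and P(onset <= 7 d) = 0.49 (printed values
17.4% and 49.7%); the line multiplier 2.0 sits between the 48-h ratio
(~2.0) and 7-d ratio (~1.3) implied by the mutant fractions; the base
death hazard 0.0015/h yields ~22% aggregate-free death over 7 d, matching
the aggregate-free survival level; the post-onset multiplier 4 reproduces
the strong early-aggregator/others survival separation; exit hazard
0.0005/h censors ~7% of cells by drift. A single exponential cannot match
both the 48-h and 7-d onset fractions simultaneously (real onset shows a
~15 h delay); the defaults favour the 48-h behaviour, which drives the
early-aggregator analyses.

### Rendering

Cells are additive Gaussian primitives plus Gaussian read noise (sigma
`noise_sigma_gray`, default 500) on a flat background (default 1000):
a soma (sigma 4 px) with 2–4 neurite segments, a dim nucleus in the
far-red channel (amplitude 3000, sigma 2.5 px); after onset, a soma
aggregate rendered per strain archetype and neurite seed puncta accruing
as a Poisson process along the neurites (amplitude
`punctum_amplitude_gray`, default 15,000 — by construction at least the
detection contrast above local background). At death the nucleus is
replaced by three bright fragments (brightness scaled by
`death_flash_fold`, with a x2 factor compensating the disc-mean dilution
of point-like fragments so the measured nucleus-region mean jumps by
roughly the configured fold) which persist and decay — dead-cell
background nuclei. The reporter fades over two frames after lysis.
Archetypes:

- **Ordered** — one cytoplasmic condensation 4 px off-centre that grows
  for ~6 frames and then compacts (area −2%/frame) while brightening.
- **Disordered** — six puncta on a jittered two-radius ring (3.6/6.2 px)
  spaced >= ~5.4 px so their above-threshold footprints stay distinct
  components even on top of the diffuse soma pedestal.
- **Speckles** — four puncta within 2 px of the nuclear centre, which
  merge into a nuclear blob (nuclear-overlap fraction >~0.8).
- **Other** — two lenticular (anisotropic) blobs at ±4.5 px with major
  axes perpendicular to their separation.

Geometry is deliberately disambiguating: cells are placed with >= 24 px
separation and drift slowly (0.02–0.08 px/frame, straight lines); soma
archetypes stay within ~6 px of the centre; neurite seeds sit >= 12 px
from their own soma and are placed >= 14 px from every other cell's
initial position. A human scorer separates somatic aggregates from
neuritic puncta using context the automated rules lack; the generator
encodes that separation geometrically instead. Determinism: one master
seed spawns independent per-well streams, so identical config + seed is
bit-identical and wells can be regenerated individually.

### What the simulator does not emulate

No photobleaching, focus drift, stage jitter, optics-faithful PSFs, shot
noise (read noise only), uneven illumination, cell division, overlapping
or touching cells at seeding time, tiled multi-field wells, or plate
effects. Passing tests therefore demonstrate that the analysis rules are
implemented correctly and are well-calibrated under the stated model —
not that the detector or tracker would meet the same accuracy on real
microscopy, where segmentation is far harder.

## Detection rules

- **Local background** — windowed median of radius 15 px. The median is
  evaluated exactly on a coarse grid (stride `radius // 3`) and
  bilinearly interpolated for frames larger than 96 px (dense filtering
  at every pixel costs ~0.9 s per 256² frame and adds nothing for
  smoothly varying backgrounds; the approximation error is far below the
  noise floor). `stride=1` gives the exact dense filter.
- **Neurite seeds** — 8-connected components above background + 10,000
  gray levels, equivalent diameter (2·sqrt(area/pi)·pixel size) within
  0.1–4 µm. The 0.1 µm lower bound is sub-pixel at the default
  0.65 µm/px (a typical 10x objective), so the effective floor is one
  pixel. Components above the band maximum are rejected and, dilated by
  2 px, veto any detection they touch — the large-bright-area exclusion
  that prevents overcounting within cell bodies and clusters.
- **Baseline subtraction** — the grand mean of the no-lysate raw counts
  (quantification noise) is subtracted from every time point; negative
  corrected counts are retained so AUC statistics stay unbiased.
- **Soma aggregates** — components above the same contrast threshold
  inside a 7.5 px soma mask of the tracked 70x70 px patch, minimum area
  4 px (suppresses single-pixel noise). Per-frame descriptors (component
  count, largest-component area fraction, nuclear-overlap fraction) feed
  the morphology classifier.
- **Neurite area surrogate** — somata are bright above-background
  regions (threshold 3000, dilated 2 px); neurites the remaining pixels
  above 600; areas reported in µm². This replaces trainable segmentation
  with a transparent two-threshold rule.

## Tracking and event calling

Somata are detected per frame (components >= 15 px above a scalar frame
median + 2500, after an opening with a 1-px disk that severs noise
bridges to nearby bright clusters) and gated on nuclear-channel signal:
a neuron is a reporter-positive object with a dye-labelled nucleus (live
or lysed), which excludes cell-free debris such as neurite-aggregate
clusters. Linking is frame-to-frame minimal-total-displacement
assignment (Hungarian; ties broken toward lower incumbent ids) with gate
6 px/frame and gaps up to 4 frames bridged. A track left unmatched may
share a detection >= 1.45x the median first-frame component area within
1.8x the gate: two touching somata merge into one oversized component and
both identities ride through the merge. Tracks beginning after frame 0
(cells entering the field) are excluded, mirroring selection of cells
present at t0.

These linking defaults were set by measuring truth recovery on the
simulator at default signal-to-noise: wider gates let a dead cell's track
adopt a neighbour's detection, and 2-frame gap bridging breaks tracks
during transient merges. With the defaults, >= 95% of onset and death
calls land within one frame of ground truth and censored-vs-dead status
agrees with truth for >= 98% of tracks.

- **Death** — first frame where the nuclear intensity reaches
  `flash_fold` (3) times the rolling median of the preceding 5 observed
  frames. The intensity is measured in a 3-px disc anchored at the local
  nuclear-channel maximum within 9 px of the track position, because the
  reporter centroid shifts when bright aggregates form while the nucleus
  stays put. Nuclear fragmentation is corroborative in the rendering but
  not required by the rule. A grace of 2 frames past the last link
  catches the flash of a cell whose soma has already faded.
- **Onset** — first frame opening a run of >= 2 aggregate-positive
  frames; a later negative run of >= 2 frames before track end marks the
  aggregate transient.
- **Censoring** — death takes precedence; otherwise a track ending early
  (border exit or gap timeout) is censored at its last observed frame,
  and survivors are censored at the horizon. Exactly one of death/censor
  is set, and no observations are kept past it.
- **Classes** — Initial_State+End_State+Survival_Status with A/O for
  aggregate/none and A/D for alive/dead, e.g. `O+A+D`; a transient flag
  may accompany any label.

## Survival statistics

Kaplan–Meier estimation and Cox proportional-hazards fits are delegated
to `lifelines` (product-limit with Greenwood-based 95% bands; Efron tie
handling — the 2-h grid ties many event times; Breslow fitting is not
provided because the backend implements Efron only). The two-group
log-rank statistic is computed in-package in vectorised form so that
permutation p-values (10,000 label shuffles) and replicate sweeps are
cheap; it is cross-checked against `lifelines` exactly in the tests. The
Cox score test at beta=0 for a single binary covariate is implemented
with the Breslow likelihood, whose score statistic coincides with the
log-rank chi-square (exactly so for untied times).

Design choices, each fixed once:

- The "early aggregator" group forms a soma aggregate within 48 h of
  seed addition; the comparison group is every other neuron still under
  observation at 48 h. Configurable.
- The post-onset clock restarts each aggregate-forming cell's time at
  its onset and ignores left truncation — a deliberate simplification
  matching the design it models; zero-length intervals are nudged by
  half a frame.
- Cumulative onset is 1 − KM treating onset as the event and
  death/censoring before onset as censoring.
- Aggregate fractions at 48 h / 7 d use as denominator the neurons still
  under observation at the time point; dead or censored cells drop out.
- AUC is the trapezoid rule on baseline-corrected counts vs hours;
  the line x dose ANOVA uses Type II sums of squares (Type I/II/III
  coincide on the balanced simulated designs); the early-seeding slope is
  the least-squares slope within 24–48 h per replicate, compared between
  lines by Welch's t.
- Expression correlations report Pearson r, r² and adjusted R² side by
  side — near zero these are easily conflated (an adjusted R² can be
  negative), so all three are given.
- No multiple-testing correction is applied by default, matching
  per-comparison reporting; `statsmodels` is available for Holm
  adjustment where users want it.

## Morphology classification

Features are medians over the aggregate-positive frames between onset and
death/track end (fewer than 3 such frames → Unclassifiable, excluded
from statistics): punctum-count median, largest-component area fraction,
nuclear-overlap fraction, and the compaction slope (least-squares slope
of log largest-component area vs hours; negative = compaction). Rules,
in order: nuclear overlap > 0.5 → Speckles; largest fraction > 0.6 →
Ordered; count >= 5 → Disordered; else Other. The thresholds were tuned
once against the simulator archetypes and then frozen. "Toxic" is
accepted as an input label for interoperability but never emitted (no
archetype exists for it). Residual confusion is concentrated in
Disordered cells whose puncta merge on bright somata and read out as
Ordered — by construction the hardest boundary. Classification is
deterministic, and invariant to uniform intensity rescaling when the
detection threshold is scaled with the image.

## Problem sizes

The test and acceptance runs use one 256² imaging field per well (tiling
adds nothing to the analysis contract), 84 frames, 35–50 cells per well;
event-calling fidelity is scored on ~300 tracked neurons, the
early-aggregator comparison on ~500, the dissociation rates on 40
event-level replicates of ~300 cells per line (image rendering is
bypassed where only event statistics are exercised — the clocks are
identical), morphology recovery on ~150 rendered archetype cells, and
the seeding ANOVA on the full 2 lines x 3 doses x 4 wells design plus
no-lysate baselines. These sizes put binomial/statistical noise well
inside the margins being asserted while keeping a full run in the
minutes range.

## Known limitations

- Exponential clocks have no onset delay; real seeding shows a ~15 h lag.
- The detector/tracker accuracy claims are conditional on the simulator's
  geometry (separated cells, slow drift, flat background).
- The morphology classifier is a fixed-threshold surrogate for blinded
  human scoring; agreement with human raters on real imagery is untested
  and untestable here.
- The post-onset survival comparison ignores left truncation; with
  late-entry designs this would bias it.
- Technical-replicate summation and labelled-lysate uptake comparisons
  operate on user-provided tables; the pipeline does not simulate the
  uptake-labelling experiment itself.
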