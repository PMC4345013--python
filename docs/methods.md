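# Methods

## The measurement model

A crawling larva is represented per frame by 13 ordered midline points in
plate-frame millimetres (head, …, centre = point 7, …, tail).  All
locomotion parameters derive from this series:

* **Shape** — body length (chordal midline length), head/body angles and
  the three >45° bending-time fractions.
* **Peristalsis** — centre-point speed, time striding, striding-only speed,
  and per-stride duration, distance, extension and contraction rates.
* **Stamina** — per-run distance, duration and stride count, plus stride
  and run counts per minute.
* **Track** — total path distance (mm/min), direction-change fraction, and
  the time fraction spent away from the ring ("inside").

Time fractions are reported in [0, 1].  Striding-only parameters are
missing (NaN, never 0) in a video with no strides.  Per-frame parameters
average over valid frames; a video with more than 20% invalid frames is
flagged.

## Recognition

Frames are thresholded per frame with Otsu's method (a fixed override is
available); the foreground is the dark side, inclusive of the threshold so
pure black-on-white imagery binarizes correctly.  Only the largest
connected component is kept (specks vanish), holes are filled, and the
component must have a plausible area (default 0.8–10 mm²).

The mask's topological skeleton is pruned by repeatedly deleting the
shortest endpoint branch until exactly two endpoints remain; branches
longer than 15% of the skeleton abort the frame as a topology failure
(loops, self-touching postures).  The ordered path is smoothed with a
short moving average because raw 8-connected paths overestimate arc length
anisotropically (axis steps count 1, diagonals √2), which would make
equal-arc resampling locally uneven.  Each end is then extended along its
tangent: discrete skeletons stop roughly one half-width short of a rounded
tip, so the extension runs to the mask boundary minus the local medial
radius (from the Euclidean distance transform).  A lateral-width probe
distinguishes rounded tips from square-cut ends (a rectangle keeps its full
width to the wall and is extended all the way).  The path is resampled at
arc-length fractions k/12, k = 0…12.

Head/tail disambiguation happens at the series level: per frame the point
order closer to the previous valid pose is kept; globally the end with the
larger mean instantaneous speed becomes the head (peristalsis moves head
and tail symmetrically, but pause-time head sweeps make the head end
strictly faster on average).  `orientation_confidence` is the relative
speed margin; a single frame gets confidence 0.

Stage mapping: plate position = stage position + scaled offset of the pixel
point from the image centre, with image y down mapped to plate y up (three
other axis-aligned orientations are selectable).  Missing stage entries are
interpolated across gaps of at most 2 frames; longer gaps invalidate the
frame.

## Stride detection

The length signal is smoothed with a 0.4 s moving average and scanned for
extrema with topographic prominence ≥ 3% of the mean body length (both
defaults configurable).  Candidate strides are min→min intervals containing
a maximum, with duration within [0.4, 5] s, length excursion above the
prominence floor, and centre displacement ≥ 0.1 mm.  Rates are read off the
raw signal at the located extremum frames, so piecewise-linear signals give
exact rates.

Two refinements proved necessary beyond the plain extremum scan:

* **Pause excision.**  Quiescent time — where the smoothed centre's
  displacement over a 0.5 s window corresponds to less than 0.15 mm/s —
  is masked out before extrema detection, and each active block contributes
  boundary minima at its edges (the near edge of the deepest valley beside
  the flanking maximum).  Without this, a pause flanked by strides reads as
  one wide valley whose single minimum sits mid-pause, and the
  duration/excursion/displacement tests happily accept pause-spanning
  pseudo-strides (stride duration biased upward ~10%, runs merged).  The
  motion criterion is the behavioural definition of striding — the animal
  travels — so pausing time can never be inside a stride.
* **Plateau edges.**  A near-flat valley (within a quarter of the
  prominence) wider than a few frames emits both its edges as minima rather
  than one collapsed midpoint, so noiseless pauses behave like noisy ones.

Strides separated by at most `max_gap` = 0.5 s merge into runs.  A stride
straddling an invalid-frame gap is dropped, never interpolated.

## The synthetic crawler

The simulator emulates the assay: a 10 cm plate with a 1.5 cm ring, 7.5
frames/s, 4-minute sessions.  Defaults are anchored to wild-type
third-instar values — body length 4.34 mm, stride period 1.61 s, stride
distance 0.89 mm, time striding 0.76 — with a half peak-to-peak length
oscillation of 0.255 mm (matching contracted/extended lengths of ~4.12 and
~4.63 mm) and 9 runs per 4 minutes (≈2.25 runs/min).

Striding: within a run the length follows a piecewise-cosine cycle with a
configurable extension-phase fraction (default 0.5); the tail is planted
during extension and advances `stride_distance` during contraction, so
head, centre and tail each gain one stride distance per cycle.  The body
lies along the head's path, which wanders with Ornstein–Uhlenbeck
curvature, steers smoothly away from the ring, and wall-slides (bounded
heading rotation toward the tangent) instead of reflecting — an
instantaneous reflection would fold the body into hairpins no recognizer
(and no larva) produces.

Pauses: run and pause times are scheduled to hit the target striding
fraction and run count, pause lengths drawn from a floored exponential (the
minimal memoryless choice; the floor keeps pauses longer than `max_gap` so
runs remain separable).  During a pause the body holds its contracted
length and sweeps its head: two equal kinks at points 2 and 3 whose sum is
chosen so the measured head angle equals the commanded sweep angle exactly
on a straight body, with a sinusoidal profile (4 s period, default 60°
amplitude) under a short on/off envelope.  With these defaults the
bending-time fraction lands near observed wild-type values.

Rendering stamps disks of one body-width (default 0.7 mm) along the
midline onto a white canvas; the emulated stage jumps to re-centre the
animal whenever its centroid leaves the central third of the frame, and the
per-frame stage position is logged — exactly the mapping the recognizer
inverts.

What the simulator does **not** emulate: segmental anatomy and denticle
bands, backward crawling, rolling/curling (self-occlusion), photometric
noise, illumination gradients, or multi-animal scenes.  Passing recovery
tests therefore demonstrates the correctness of the geometry and the event
logic, not robustness to imaging pathologies of real video.

## Numerical choices

* Calibration default 0.045 mm/px on 240×240 frames; the worm must be >2 px
  wide to render or recognize.
* Speed window 0.5 s centred (≈4 frames at 7.5 frames/s): sub-stride, so
  the head/tail speed alternation survives while pixel jitter is damped.
* Track distance uses a 0.5 s moving average on the centre path (unsmoothed
  sums overestimate under jitter); direction changes subsample at 1 s with
  a 60° turn threshold; "inside" means more than `inner radius − margin`
  from the ring, margin defaulting to half a body length.
* Overall "Speed" averages per-frame speeds; dividing total displacement by
  total time is available as `speed_mode = "total_displacement"`.
* CV and normalized-SD profiles use the sample (n−1) SD.
* Day matching for control normalization uses an explicit metadata column,
  never filename parsing.  The control row of a mean profile is exactly 1;
  a profile's self-correlation is defined as 1 (the control row is constant,
  where Pearson is degenerate).
* Determinism: a config's integer seed fixes the schedule, path, noise and
  rendering bit-for-bit.

## Problem sizes

Recovery tests run 40–240 s sessions at 7.5 frames/s (300–1800 frames); the
stochastic recovery check draws 20 random configurations at 240 s and
analyzes the pose series directly, with the full render→recognize round
trip exercised on the wild-type-anchored configuration.  These sizes were
chosen to cover several runs and >100 strides per session, the scale at
which per-video means stabilize.

## Known limitations

* Head/tail orientation relies on pause-time head sweeps; a video that is
  100% striding gives a near-zero orientation confidence (peristaltic head
  and tail speeds are symmetric).
* The stall-speed default (0.15 mm/s) assumes striding advances the centre
  at ≳0.2 mm/s sustained; extremely slow crawlers need the threshold (or
  `stall_speed_mm_s = None`) adjusted.
* Self-touching postures are dropped as invalid rather than resolved.
* Backward peristalsis is not modelled or detected.
* Statistical testing of group differences is out of scope; the summary
  tables are designed for direct import into standard statistics tools.
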