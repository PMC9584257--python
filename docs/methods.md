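# Methods

## Marker model

A marker is a 4×4 grid of binary cells (a 16-bit code word, 1 = white),
wrapped in one ring of black border cells and one ring of white quiet-zone
cells. The black border gives the detector a high-contrast convex
quadrilateral to find; the white quiet zone is what isolates that
quadrilateral from the background — a marker lying flush against a dark
surface produces no closed border contour and is deliberately not detected.
This mirrors the physical deployment rule that the white edge of the collar
sticker must be visible.

Dictionaries are built by seeded rejection sampling: candidate 16-bit words
are drawn uniformly and accepted when (a) all four 90° rotations of the
candidate are mutually distinct — otherwise orientation would be ambiguous —
and (b) the rotation-invariant Hamming distance
`min_r Hamming(a, rot^r(b))` to every accepted code is at least
`min_distance`. For the deployed configuration (16 markers, 16-bit codes)
the floor is 1, i.e. rotation-distinctness itself; higher floors buy
error-correction capacity at the cost of dictionary capacity, and the
generator fails with a clear message when the constraint set is infeasible
within its draw budget. Generation is deterministic per seed. The exact 16
code words used in the original deployment are not recoverable and do not
matter: every guarantee is a property of the constraint set, not of
specific words.

Collar strips tile one id repeatedly (default 250 mm × 25 mm at the chosen
DPI, marker side = strip height) so that some repeat faces the camera
regardless of how the collar is rotated on the neck.

## Detection pipeline

1. **Grayscale + adaptive threshold.** Colour frames are reduced by BT.601
   luma weights. A pixel is dark when it falls below its 15 px-window local
   mean minus an offset of 5 % of the frame's global intensity range;
   tying the offset to the intensity range keeps the binarization invariant
   under affine illumination changes with positive gain. Windows larger
   than the frame fall back to a global threshold with a logged warning.
2. **Quad extraction.** Closed contours of dark regions (sub-pixel
   level-set contours at 0.5) are simplified by Douglas–Peucker at 3 % of
   perimeter; because the contour's arbitrary start point is always kept as
   a vertex, near-collinear vertices are pruned afterwards. Corners are
   then refined by fitting total-least-squares lines to the contour points
   of each edge (central 70 %, excluding corner neighbourhoods) and
   intersecting adjacent lines; this reaches well under 1 px of corner
   error on clean renders. Candidates must be convex, within area fractions
   [1e-4, 0.4] of the frame, have side ratio ≤ 2.5 and interior angles
   ≥ 35°, and their contour must stay within 1.5 px of the fitted quad
   (marker borders are straight; noise blobs are jagged — this is the
   filter that rejects salt-and-pepper structure).
3. **Decode.** The quad is perspective-unwarped to a canonical square with
   12 px cells, each cell sampled by the mean of its central 50 % against
   the patch's mid-range threshold. The ring outside the border must be
   ≥ 75 % white (quiet-zone check), the border ring fully black, and the
   inner 16 bits are matched against all codes × 4 rotations. The unique
   best match within the correction budget `floor((min_distance−1)/2)` is
   accepted; ties are rejected. Orientation re-orders the reported corners
   so the first is the decoded top-left.
4. **Deduplication and ordering.** Overlapping quads for one physical
   marker (e.g. outer and inner border contours) keep the lowest-Hamming,
   then largest-area detection. Output is sorted by (id, center y, center
   x) so runs are deterministic.

The detection coordinate convention is pixels, origin top-left, x
rightward, y downward, sub-pixel floats; the logged (x, y) is the mean of
the four corners. Whether the original field system logged the center or a
corner is unknown; the center was chosen and is stated here for
comparability.

## ROIs and event logging

ROIs are static, axis-aligned rectangles; containment of the detection
center uses half-open right/bottom edges so adjacent rectangles partition
the plane. A detection may fall in several ROIs (overlapping or too-close
layouts); all indices are logged, which is exactly how the
resources-too-close failure mode manifests in the data. `validate_layout`
warns about overlapping or near rectangles before a session starts.

Two session modes share one log schema
(`frame,timestamp,id,x,y,rois`, rois semicolon-joined):

* **post-event** analyzes every frame in order; the log is a pure function
  of the clip and config (byte-identical across runs), timestamps are media
  time (frame / fps, fixed 3-decimal format).
* **real-time** prioritises temporal currency: the processor always takes
  the newest available frame and frames that arrived while it was busy are
  dropped and counted, so `frames_analyzed + frames_dropped =
  frames_total` holds exactly. The scheduler is driven by arrival times and
  a per-frame processing-cost model, which makes the drop behaviour
  testable as a discrete-event simulation (cost = 2× inter-arrival ⇒ every
  other frame dropped); rows are flushed as produced so an interrupted
  session (the field failure mode is power loss) leaves a valid partial
  log.

MP4 I/O requires an ffmpeg-backed imageio plugin; the package's own
formats are PNG frame directories, in-memory frame sequences, CSV logs and
JSON session reports, which are sufficient for fully reproducible runs.

## Bouts and summaries

Presence series are binary per frame (1 iff the subject was detected in the
ROI in that frame) or per second (1 iff any frame of that second was).
Bout segmentation applies the ethogram's disengagement rule: a gap of at
least 60 s — 1800 frames at the sustained 30 fps — starts a new event;
shorter gaps are bridged. The strict convention is "new bout iff gap ≥
threshold", with gaps measured from presence-end to next presence-start;
bout ends are actual presence units, so segmentation conserves total
presence and is monotone in the threshold. Summaries bin bouts by hour or
day; a bout straddling a boundary is split with duration conserved and
counted once, in its starting bin.

## Agreement statistics

Tracker-vs-coder comparisons are computed on aligned binary unit series.
Cohen's kappa comes from the 2×2 table with the Fleiss null-hypothesis
standard error for the z test and the large-sample delta-method interval.
ICC is computed from two-way ANOVA mean squares; all six Shrout–Fleiss
forms are available and cross-checked, with ICC(2,1) (two-way random
effects, absolute agreement, single measurement) as the default — the
appropriate model when a method is compared against a human rater regarded
as sampled from a population of raters. Because the original analysis did
not state its ICC form, the study-table reproduction path sweeps all forms
and reports each. Degenerate inputs (both series constant; expected
agreement 1) return reports flagged undefined instead of numbers.

The study-style table (`table1_analysis`) reproduces the three validation
arms: post-event (frame resolution; behaviour-vs-detection and
ROI-presence-vs-detection), post-event with corrected resource placement
(the drinking/water comparisons restricted to the interval with proper
placement), and real-time (second resolution, behaviour only). Sniffing is
excluded from agreement analysis owing to its rarity and brevity. The coder
CSV reader is schema-tolerant (lower-cased headers, synonym mapping,
explicit overrides) since external coding files vary in layout.

## Synthetic scenes and the simulated coder

The generator emulates the deployment geometry, not photometric realism: a
smooth textured gray background, markers warped by per-frame homographies
(center, scale, in-plane rotation, and out-of-plane tilt projected with a
pinhole at focal length 2× marker side), then occlusion ellipses ("fur"
covering a stated fraction of the code, soft-edged, dark), Gaussian blur,
affine illumination, and additive Gaussian noise — in that order. Ground
truth records per-frame marker geometry, ROI membership, and a latent
behaviour state distinguishing *using* a resource from merely being present
in its ROI; the latter reproduces the known presence-without-use error
source, which depresses agreement below 1 by construction.

The simulated coder corrupts the latent truth with independent per-unit
misses and false alarms plus uniform bout-boundary jitter. Its expected
kappa against the truth has a closed form from the expected 2×2 table
(prevalence π, miss m, false-alarm f):
`p_o = π(1−m) + (1−π)(1−f)`, coder marginal `q = π(1−m) + (1−π)f`,
`p_e = πq + (1−π)(1−q)`, `κ = (p_o − p_e)/(1 − p_e)` — used as the
parameter-recovery oracle.

What passing synthetic tests does **not** show: robustness to real fur
texture, specular bowls, rolling-shutter artefacts, compression noise, or
real coder behaviour (human errors are correlated in time, not
independent). The synthetic results bound the geometry/decoding logic, not
field performance.

## Problem sizes and defaults

Defaults throughout are the study conditions: 16-marker 4×4 dictionary,
30 fps, 1800-frame/60 s bout gap, ROI rectangles in pixels. Test scenes use
frames of 120×160 to 240×320 px with marker border sides of 40–50 px
(matching the ≥ 40 px regime where round-trip recovery is exact), clips of
100–3,000 frames, and Monte-Carlo sizes of 10⁴ units for the statistical
checks — sizes chosen so every documented property is exercised at full
strength while the whole suite runs in a few minutes on one CPU.

## Known limitations

* The detector assumes near-planar markers and moderate tilt (validated to
  30°); no lens-distortion model, no 3D pose estimation.
* Bout attribution is per (subject, ROI); competing interpretations of
  simultaneous multi-ROI membership are logged, not resolved.
* Real-time wall-clock capture shares the scheduler code path but is not
  exercised by the offline test suite (the cost model stands in for
  measured processing time).
* Agreement analysis treats units as exchangeable; serial correlation in
  behaviour inflates nominal test precision, as it does in the original
  frame-by-frame design.
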