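# Methods

This note documents the models, defaults and design choices behind
`boutondyn`: what the synthetic scenes emulate, how boutons are sized,
tracked and counted, and what the tests do and do not establish about
real data.

## Synthetic scenes

A scene is one imaging field followed over a session schedule (default
days 0, 2, 4, 7): an axon centerline, a bouton population with
per-session true weights, and a rendered 3D stack per session.

**Axon geometry.** Traced axons are planar polylines at a fixed imaging
depth. In an unconfined space the generator uses a persistent random
walk (per-step heading turn ~ N(0, tortuosity·√step)). Inside an imaging
field it lays a randomly oriented serpentine course — straight passes
joined by half-circle turns, with smooth random lateral wiggle scaled by
the tortuosity — because a self-avoiding random walk repeatedly traps
itself in pockets of its own trail when ~200 um of cable must fold into
a 40 um field; the serpentine guarantees ≥ 2 um self-clearance, so
distinct stretches of axon never blur together in the rendered stack.
Real axons wander in depth and curvature more freely; the geometry here
is deliberately regular so that detection failures cannot be blamed on
trace topology.

**Bouton population.** Bouton positions follow a homogeneous Poisson
process along arc length (count ~ Poisson(ρ·L), default density
ρ = 0.12 um⁻¹, the layer-1 thalamocortical value), realized by
sequential rejection so a minimum spacing of 2 um holds while the
expected count stays ρ·L (Matérn-style thinning would bias the density
~20% low at these parameters). The spacing is a deliberate
detection-friendly simplification: with a 0.7 um identity tolerance,
2 um keeps every bouton unambiguous, so rate-recovery tests measure the
statistics, not peak separation. Day-0 weights are lognormal
(log-mean ln 4, log-sd 0.35 → median 4 for thalamic-like axons; use
log-mean ln 3 for smaller corticocortical-like boutons), truncated below
at 2 because a "bouton" is by definition a swelling of weight > 2 and
reported densities count exactly those structures.

**Longitudinal evolution.** Per interval, each present bouton is
eliminated with probability *e* (default solves (1−e)³ = 0.85, the
observed magnitude of 7-day survival of pre-existing boutons); survivors
drift multiplicatively by exp(N(0, 0.05)) — the drift magnitude is a
free parameter, as session-to-session size fluctuation of persistent
boutons is not well constrained; new boutons appear as
Binomial(n_prev, f) (default f = 0.08) at spacing-respecting positions;
eliminated boutons optionally reappear at their old position with
probability `reappear_prob` (default 0). Fates
(persistent/eliminated/formed/transient/reappearing) are labelled from
the realized weight sequences.

**Forward imaging model.** The shaft is a Gaussian tube (intrinsic
radius sigma 0.25 um convolved with a two-photon-scale PSF of 0.4 um
lateral / 1.0 um axial sigma) of peak amplitude `shaft_amplitude`
(100 counts). A bouton of weight *w* adds a Gaussian blob whose peak
raises the centerline intensity to `w · shaft_amplitude`, which is the
calibration contract: noise-free rendering followed by the package's own
weight computation must return *w* (verified to ≤ 10%, typically ≤ 5%).
The tube is computed from the exact distance to the centerline (2D
distance field × axial Gaussian for planar paths; scaled 3D
nearest-neighbour query otherwise). Noise is Poisson (default),
Gaussian, or absent. Not simulated: vasculature and background
structures, bleaching, motion artifacts, or nonrigid session-to-session
deformation — a configurable rigid per-session arc-length offset stands
in for registration error. Passing tests therefore show the analysis is
correct *given* a faithful trace and rigid-ish alignment, not that it is
robust to every in-vivo artifact.

**Study-condition defaults.** Field length 200 um (realistic traced
lengths per field are ~200–240 um), acquisition geometry 0.11 um/pixel
and 0.7 um z-step. `ImagingParams()` matches the full acquisition
(1024×1024×30 planes); `ImagingParams.desk()` (360×360×10, noise off) is
the field used throughout the simulation studies — it holds a folded
200 um axon while keeping a full 30-field recovery run under half a
minute. All simulation sizes in the tests (30 fields per condition,
≥ 500 pre-existing boutons for survival) were chosen as the package's
own desk-scale study sizes.

## Profile extraction

Traces are resampled at 0.1 um (below the 0.11 um pixel size, so the
0.7 um identity tolerance spans 7 samples); the realized step is
adjusted to divide the total length so both endpoints are samples. The
intensity at each arc position is the maximum trilinearly interpolated
value over a disc of radius 0.33 um (3 lateral pixels) normal to the
local tangent: the max is robust to sub-voxel tracing error, whereas a
mean dilutes bouton peaks. Interpolation happens in anisotropic world
coordinates (voxel centres at (i+0.5)·voxel size); out-of-stack samples
are masked and carried as NaN. Background subtraction is off by default
(configurable upstream of the profile if needed).

## Bouton weight and detection

The shaft baseline is an iterative robust Gaussian smooth (sigma 5 um
arc length): smooth, clip samples exceeding `clip_factor ×` baseline
down to the baseline, re-smooth. Defaults are clip 1.05 with 8
iterations: at realistic bouton density the flanks of bouton peaks
otherwise leak into the baseline and depress every measured weight — a
loose clip of 1.5 with 3 iterations leaves a −17% systematic size error,
violating the calibration contract, while 1.05/8 leaves −3% (noise-free)
and −4% (Poisson); the max-over-disc extraction statistic offsets the
residual downward clip bias under noise. Edges are handled by
reflection; masked samples are linearly interpolated before smoothing.

Peaks of the weight profile require prominence ≥ 0.3 and pairwise
separation ≥ 1.4 um (twice the identity tolerance, so one physical
swelling is never split); position and height are refined by parabolic
interpolation. All threshold comparisons are strict, exactly as the
definitions state: putative means `w > 2`, analysis inclusion means
`w > 3` in ≥ 1 session, elimination means `w < 1.3`. Sub-threshold peaks
(1.3–2) are recorded — they sustain an existing track (hysteresis: a
bouton may shrink into that band and remain itself) but can never open a
new identity.

## Tracking

The manual step of visually choosing a landmark bouton is automated:
landmarks are large (weight ≥ 3) boutons mutually nearest between two
sessions within 2 um, accepted greedily by descending size; their
position differences give a piecewise-linear arc-length offset between
the sessions. If coverage is poorer than about one landmark per 50 um
the offset falls back to 0 and the landmark set is flagged. Matching is
greedy one-to-one by ascending landmark-relative discrepancy with the
strict 0.7 um cut, ties broken by position — on realistically spaced
boutons this equals the brute-force optimal assignment (tested against
`linear_sum_assignment` on 200 random instances).

Tracks chain pairwise matches through the ordered sessions. The expected
position of a temporarily absent bouton is its landmark-corrected last
known position, carried through the chain of consecutive offsets, so a
reappearing detection within 0.7 um re-joins its old identity. Newly
formed boutons are unmatched detections with weight > 2 appearing after
day 0; formation is judged against the immediately preceding session
only (absence in *all* earlier sessions is not required). Whether a
newborn must exceed 2 or 3 at first appearance is genuinely open; the
birth threshold is 2 by default and configurable (`birth_min`), while
analysis inclusion (> 3 somewhere) gates every reported statistic
either way.

## Statistics

Event counts per interval are restricted to analysis-included tracks.
The bookkeeping identity n(later) = n(prev) + formed − eliminated holds
exactly when no reappearances occur; with reappearances the identity
gains a `+ reappeared` term, and the event table carries that column
separately (reappearances are not formations — the bouton is the same
synapse). Survival counts a reappeared-by-that-day bouton as surviving
(identical-bouton rule; `count_reappeared=False` gives the stricter
variant). Period-averaged rates are unweighted over the three intervals
even though days 4–7 spans three days — intervals are treated as units.
Tercile survival ranks pre-existing boutons by day-0 weight (ties broken
by axon position), takes floor(n/3) per tail, and requires ≥ 3 boutons.
Per-field summaries are the diagnostic unit here; for group comparisons
the proper unit is the animal (rates averaged over an animal's fields),
which matches the degrees of freedom of the pooled t-test reported by
`t_unpaired` (df = n1 + n2 − 2, e.g. 14 for two groups of 8). The
Kolmogorov–Smirnov p-value is the asymptotic two-sided form (calibrated
at the sample sizes where it is used; the exact-p variant is a scipy
switch away). All group summaries are mean ± SEM.

## Numerical and degenerate-input conventions

Zero-baseline samples are masked rather than divided; all-zero profiles
raise. A resampling step longer than the trace degenerates to the two
endpoints and is flagged. Units with n_prev = 0, an empty initial
survival set, a zero day-0 count, or fewer than 3 pre-existing boutons
are excluded with a dedicated error type rather than silently reported
as 0. Greedy matching and tercile ranking break ties deterministically;
a single master seed drives scene generation through spawned child
sequences, so identical seeds give bit-identical scenes.

## Known limitations

Rendered axons are planar and self-avoiding by construction; crossing
axons from other cells, varying imaging depth and tracing errors are not
modelled. The landmark surrogate assumes at least a few large stable
boutons per 50 um; sparse axons fall back to uncorrected positions. In a
toy field containing a single displaced bouton the surrogate will adopt
that bouton as its own landmark and absorb the displacement — alignment
should be given explicitly (`landmark_sets`) in such degenerate cases.
Analysis inclusion (> 3) slightly filters newly formed boutons relative
to pre-existing ones (fewer sessions in which to exceed 3), a small
conservative bias on formation rates inherent to the definitions.
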