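# Methods

## Display model

Space is measured in degrees of visual angle, time in milliseconds,
speed in deg/s; x increases rightward, y upward, with the origin at the
first dot.  Monitor geometry (pixels, gamma, viewing distance) is not
modelled; rasterization to a frame/pixel grid exists only as an input
stage for the motion-energy filters.

**Sawtooth arrays.**  Dot centres sit at `x_i = i·h` with y-offsets
following the triangle cycle `[0, s, 2s, s]` (period four columns,
"five dots per cycle" counting the closing dot of one rise–fall
excursion).  Only the peak-to-trough extent `2s` is load-bearing; with
the vertical step equal to the spacing it reaches 4° at the widest
tested spacing (2.0°).  The reference display uses 0.4° spacing with 33
dots; the dot count is a pinned constant, not derived from the screen
width, because the quoted field width does not force it exactly.

**Timing algebra.**  For a vertical bar, `SOA = h/v`, `EOD = w/v`,
`ISI = SOA − EOD`.  The identity `SOA = ISI + EOD` is enforced in
canonical form `ISI := SOA − EOD` (bit-exact in that direction; floating
point cannot guarantee both directions simultaneously).  Tilted bars
have no single timing triple — their per-element intervals vary across
the fold — so `timing_from_bar` rejects them and the event scheduler
computes each element's crossing times directly.

**Event schedules.**  An element transforms when the relevant edge line
crosses its *centre* (not its rim).  Event times are kept continuous and
exact; quantisation happens only at rasterization, using a floor rule
(an event takes effect at the first frame whose start time is at or
after the event time).  A 1 µs guard protects frame-boundary comparisons
when event times are exactly commensurate with the frame raster (the
zero-ISI displays).  Simultaneous events are ordered by element id.
Polygon (shape) schedules compute entry/exit times of each element's
polygon-relative path by exact segment–polygon intersection (shapely).

## Edge recovery

The crossing model `n(θ)·p_i = s·t_i + c` is solved in closed form for
three events (a 2×2 linear solve on position/time differences) and by
least squares for more, regressing time on position:
`t = αx + βy + γ`, with `(α, β) = n/s`, so `s = 1/‖(α, β)‖` and
residuals are in milliseconds.  The two routes agree exactly for three
non-collinear events.  The `(θ+180°, −s)` ambiguity is removed by
reporting orientation mod 180°, speed ≥ 0, and an explicit normal
direction.

Degenerate inputs: collinearity is declared when the normalised triangle
area (triple solver) or the singular-value ratio of the centred
positions (least squares) falls below `1e-9`; such inputs always return
`ambiguous_collinear`, never a numeric orientation.  Simultaneous
non-collinear events would require an infinite-speed edge and return
`inconsistent`.  A fit whose RMS residual exceeds `residual_tol_ms`
(default 5 ms, chosen to pass millisecond-scale sensory noise while
rejecting structurally wrong groupings) is also flagged inconsistent.

**Temporal gating.**  Defaults: `soa_gate_ms = 80` (ratings decline
steeply past ~76 ms and vanish near 100 ms, so the gate sits between
those anchors), `window_ms = 165`.  Same-kind events chain while
successive gaps stay within the gate; a chain is integrable when at
least three consecutive events span no more than the window.  A literal
"total group span ≤ window" rule would contradict the intended behaviour
that an arbitrarily long constant-SOA sweep integrates as one group, so
the window is applied to event triplets, which reduces to the stated
160 ms three-event bound at an 80 ms SOA.  No spatial gate is
implemented: whether wide spacings fail through a genuinely spatial
limit or only through the SOA limit is left open, and SOA-only gating is
the default model.

**Bar estimation.**  Leading edge from gated disappearances, trailing
edge from reappearances (kept separate by kind; no mixing rule is
assumed).  Width uses `w = s · mean(EOD)` over elements present in both
groups, cross-checked against the perpendicular separation of the two
recovered edge lines; disagreement beyond 0.1% flags the schedule as
inconsistent.  For tilted bars the recovered speed is the edge-normal
speed and the recovered width is perpendicular width — the quantities
the crossing data actually constrain.

## Motion-energy account

Filters are classic quadrature energy units: an oriented Gabor spatial
profile (envelope σ = `spatial_scale_deg`, default carrier frequency
`0.5/σ` cycles/deg for broad tuning) drifting along its normal at a
preferred speed, windowed by a symmetric temporal Gaussian (default
σ = 40 ms).  Kernels are zero-meaned so a blank display yields zero
energy; the even/odd pair separates into spatial cos/sin maps times
temporal carriers, making the space-time correlation cheap.  Energy is
the total squared quadrature response over all temporal lags, which
makes opposite-direction filters exact time-mirrors (time-reversing a
movie swaps their energies).  Exact kernel shapes are configuration, not
claims: the framework, not its parameters, is the point.  Filter banks
always include at least one unit whose envelope spans the sawtooth's
vertical extent, since those are the units that can integrate events
across the fold.

Because a single filter responds above half its maximum to both a
vertical and an oblique virtual bar (and vice versa), filter energy
alone cannot name the edge.  The testable readout is therefore a
constant-velocity constraint applied to the event space-time points: for
each candidate orientation, event times are regressed on the coordinate
projected onto the candidate normal; the linearity score is the R² of
that regression, the winner is the argmax, and its inverse slope is the
normal speed.  On noiseless schedules the winner coincides with the edge
solver.  An energy-map variant of the readout is deliberately not relied
on for any quantitative claim; no model is offered for how local
element-motion signals and large-edge signals are adjudicated — both
channel outputs are simply reported.

## Simulated experiments

Design 1: 4 widths (0.13–0.53°) × 2 speeds (2.6, 13.2 deg/s) × 15
repetitions at 0.4° spacing = 120 trials.  Design 2: 4 widths × 5 speeds
(2.6–13.2) × 10 spacings (0.2–2.0°) × 10 repetitions = 2000 trials in 50
velocity × spacing cells.  Orders are seeded permutations; the condition
multiset is seed-invariant.

**Observer.**  No observer model exists in the source experiments; the
one here is the minimal mechanistic chain consistent with the reported
behaviours.  Per trial: (1) the display's SOA passes a logistic gate,
`p = σ((τ − SOA)/softness)` with τ = 76 ms (the empirical knee) and
softness 8 ms by default (a hard step when 0); (2) if the gate admits
the display, the trial's event schedule (9 dots — two sawtooth cycles,
enough for both edges while keeping 2000-trial runs fast) is perturbed
by Gaussian time noise (default sd 2 ms) and position noise (default sd
0.01°), and the bar is recovered with a per-trial permissive recovery
window so that the probabilistic gate is the *only* temporal filter;
(3) the chosen width is the candidate nearest the estimate (ties to the
narrower), the rating is `1 + round(6p)`; (4) otherwise the observer
defaults to the narrowest width and a rating of 1.  A lapse (default
2%) replaces the choice with a uniform draw.  The rating map is a
placeholder: it is monotone non-increasing in SOA and collapses to 7/1
under a hard gate, but no EOD modulation of ratings is modelled.

**Analysis.**  Per-cell slope of judged width (the degree value of the
chosen alternative) regressed on true width, computed by the covariance
formula with an exact-zero guard for constant responses (so ideal
observers produce exact 0/1 slopes rather than 1e-16 jitter); per-cell
mean rating; Spearman rank correlation between the 50 slopes and 50 mean
ratings; replot tables keyed by (SOA, EOD), where EOD > SOA rows are
exactly the conditions with bar width exceeding the spacing.  The
temporal threshold is re-estimated from the slope-vs-SOA profile by an
exhaustive change-point fit (best step boundary between consecutive
distinct SOAs, squared-error scored).

## What the synthetic data does and does not show

The generator reproduces the *structure* of the reference displays
(geometry, timing, event discreteness) and the observer reproduces
qualitative behavioural regularities (default-to-narrowest, SOA-limited
performance, slope/rating concordance).  It does not emulate human
sensory encoding, eye movements or pursuit (which the phenomenon depends
on for sparse displays), criterion variation in ratings, or graded
EOD effects at intermediate SOAs.  Passing tests therefore validate the
algebra, the solvers and the pipeline — not the claim that any human
implements this chain; headline human values (slopes 0.702/0.083,
ρ = 0.893) are qualitative anchors only and are never asserted by tests.

## Numerical choices

Degrees/milliseconds throughout; conversions centralised in one
constant.  Collinearity tolerance 1e-9 (relative); round-trip identities
hold to ≤1e-12 relative; seeds are explicit everywhere
(`numpy.random.default_rng`), and CLI outputs are byte-identical for
identical (config, seed).  Event CSVs are written with 17 significant
digits and parsed with round-trip float precision so write→read is
lossless.

## Known limitations

* No contour interpolation/relatability: recovered fragments are not
  linked into closed global shapes, and the single recovered bar's
  global motion retains the classical aperture ambiguity.
* First-order (luminance) transformations only; equiluminant or
  second-order element changes are reduced to a generic property-flip
  event kind.
* The motion-energy front end is exploratory; quantitative claims rest
  on the event-based readout.
* Rasterization renders discrete occlusions only — no gradual covering,
  no anti-aliased dot edges.
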