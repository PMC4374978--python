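# Methods

## Trajectories and kinematics

Input is a pair of 2-D positions on a uniform 20 ms grid (`dt` is
configurable; all delays and times live on integer sample indices
internally so the (t, τ) lattice never drifts).  Positions are smoothed
with an unweighted moving average over `2w + 1 = 5` samples per
coordinate, which suppresses pixelation-scale measurement noise;
velocities are central differences of the smoothed track,
`v[k] = (p[k+1] − p[k−1]) / (2 dt)`.  Central differences were chosen for
symmetry with the smoothing window.  The `w + 1` samples at each end carry
no kinematics and are excluded from every downstream quantity.  Headings
are stored wrapped to (−π, π] and all angular arithmetic uses shortest-arc
differences.

## Delay maps

The delayed directional correlation of the pair (i, j) is the windowed
mean over `2w + 1` samples of `cos(φ_i(t) − φ_j(t + τ))`, and the delayed
separation is the windowed mean of `|p_i(t) − p_j(t + τ)|`, both computed
from the smoothed coordinates.  A lattice cell is defined only when every
sample of both windows carries defined kinematics; undefined cells are
carried as NaN — never zero — so path extraction cannot score them.  The
separation map is masked to the identical domain as the correlation map so
the two maps always share one lattice.  The τ lattice step equals `dt` and
the τ range is maximal for a nonempty domain, which produces the
characteristic slope −1 domain boundaries `t + τ = const` at the two ends
of the recording.

Sign convention: high correlation at τ > 0 means bat j reproduces bat i's
past headings, so i is the actor.  With this convention a follower that
trails the leader's positions by a lag L yields zero delayed separation at
τ = +L, consistently with the correlation map.  Both maps satisfy the swap
identity `C_ij(t, τ) = C_ji(t + τ, −τ)` exactly, which the tests verify by
brute force.

## Time-ordered delay extraction

A path assigns one delay per time step over the whole recording.
Admissible paths satisfy Δτ/Δt ≥ −1: the delay may grow by any lattice
amount but shrink by at most one step per step, so the reactor revisits
the actor's actions in order.  The score of a path is the sum over
super-threshold cells (`C ≥ v_c`) of the correlation, minus a fixed
penalty `q` whenever the delay changed at a scored cell; sub-threshold and
undefined cells are traversed at zero contribution, which is what makes
the extracted black segments disjoint on real maps.  The optimum is found
by dynamic programming in O(T·J) per map using an incremental
best/second-best prefix scan (numba-compiled).  Ties are broken
lexicographically: highest score, then fewest delay changes, then smallest
cumulative |τ| — interactions are presumed persistent and minimal-delay.
On fully aligned (parallel straight) pairs this returns the constant τ = 0
path while the uncertainty interval widens to the whole super-threshold
extent, making the unidentifiability explicit.

The tests compare the kernel against an independently written O(T·J²)
Bellman recursion on random 30×30 lattices and against exhaustive
enumeration (including the tie-break order) on lattices small enough to
enumerate.

Chase paths are extracted first, over cells that simultaneously satisfy
`C ≥ v_c` and `R ≤ d_c`: the same DP maximises the number of qualifying
cells visited (a large constant bonus per qualifying cell) and, among
those, minimises the cumulative delayed separation with the same change
penalty.  The coordinated path is then constrained to coincide with the
chase path wherever the latter is defined ("connects to" is read as exact
coincidence).  If no cell qualifies, the chase path is empty.

Delay uncertainty: for each classified sample the raw bound is the
contiguous super-threshold τ interval containing the path (for chase
samples, the usually much narrower qualifying window).  Bounds are then
tightened by requiring that the bounds themselves obey time ordering —
lower bounds may fall by at most one step per step going forward, upper
bounds by at most one step per step going backward — i.e. slope −1 lines
propagated from per-time minima and maxima.  Straight flight therefore
inherits the tighter delay knowledge of neighbouring curved flight.

## Classification and roles

Each map time sample gets a label: chase where the chase path is defined
(chase takes precedence; every chase sample also meets the coordinated
criterion), coordinated where the merged path sits in a super-threshold
cell, unclassified otherwise.  Roles follow the delay sign; τ = 0 samples
keep their label but report unresolved roles rather than being dropped.
Pairs whose members never come within the 0 dB echo range of the default
sound field are flagged as out-of-range outliers (and can be discarded via
a CLI flag); discarding is not automatic.

Defaults: `v_c = 0.95` (relative headings within ≈ 18.2°), `d_c = 0.15 m`
(below a bat's wingspan), `q = 0.02`, `w = 2`.

## Biosonar field

`α(ρ, ζ) = SL + TS + (A + h)[cos ζ − 1] + 2[20 log10(ref/ρ) + ρ c]` with
defaults SL = 110 dB, TS = −10 dB, A = 16, h = 2 dB, ref = 0.1 m,
c = −1.28 dB/m.  The bracket grouping is the unique reading in which the
spreading term is referenced to 0.1 m and the combined front-to-rear
directionality difference equals 2(A + h) = 36 dB; the emission-only
fitted cosine (A = 7.3) gives 14.6 dB.  The absorption coefficient is
stored negative and added as written, so amplitude decreases with range
through both terms.  Detection is `α ≥ B`: although one printed form of
the detection rule reads as "interact when α ≤ B", the surrounding results
(reactions occur when the echo is *above* the 0–10 dB hearing threshold)
fix the orientation adopted here; the quantity is an amplitude, not an
attenuation.  Isocontours are solved per angle by bracketed root-finding
(`brentq`); the amplitude is strictly decreasing in ρ and diverges as
ρ → 0, so every finite level has a unique range at every angle.

## The movement-interaction simulator

Each bat, per 20 ms step: draw speed from the Rician 𝓡(4.81, 2.18) m/s
(constructively, as the norm of a bivariate normal offset by (μ, 0); the
closed-form moments from `scipy.stats.rice` serve as the test oracle);
draw a desired heading from a von Mises — centred on its previous heading
with κ = 557 when independent, or on the circular midpoint of its previous
heading and the partner heading one reaction delay τ in the past with
κ = 2473 when interacting; then turn towards it at most `(a_c / v) dt`
with `a_c = 4 g` (lateral-acceleration limit), and advance `v dt` along
the new heading.

Both bats call every 5 steps (100 ms) along their headings.  The outcome
of the call at step c — detected or not, plus the partner heading at that
call — takes effect at step c + τ/dt (at the earliest one step after
emission, so an "instantaneous" τ = 0 response still acts on the next
motion update); between effective calls the last outcome persists, and the
stored partner heading is refreshed at each subsequent effective call, so
the interaction information ages by at most the call interval.  During the
first τ seconds no call has taken effect and bats behave independently.
An interacting bat escapes to independence with probability 0.05 per step
(dwell ≈ geometric with mean 0.4 s under forced detection) until the next
positive call takes effect.  Both bats may be interacting simultaneously;
the rule is applied per bat.

Pairs are initialised uniformly in a 30 × 30 m square with uniform
headings and run for 10 s; the arena constrains only the initial
placement — motion is unbounded, and pairs that separate beyond detection
simply stay independent.  Ensembles use one seed sequence with per-pair
substreams, so enlarging an ensemble never perturbs earlier pairs.

## Relative geometry and calibration

Relative samples use same-time positions: the actor's position is rotated
into the reactor's frame (reactor at the origin, heading along +y); the
extracted delay enters only through role assignment.  The exposure angle
is the signed angle of the actor from the reactor's heading; the relative
heading is the shortest-arc difference of the two headings.  For
unclassified (or role-unresolved) samples the centred individual is picked
at random once per pair, seed-controlled.

Calibration bins coordinated-flight relative positions into 1.5 m cells
over ±9 m about the reactor (cells beyond the extent go to an overflow
bucket excluded from the normalisation and the RMS mean), normalises to
probability mass, and minimises the root mean square cell difference over
a grid of (A, B, τ).  Every grid point simulates its own ensemble from a
substream indexed by grid position, so the surface is invariant to
evaluation order and grid extension.  Grid points whose ensemble yields no
in-extent coordinated sample are recorded as missing and flagged.

## Synthetic ground truth

Leaders are correlated random walks: von Mises step noise (κ = 557, the
concentration fitted to independent flight) plus a smoothly varying
turn-rate bias modelled as an Ornstein–Uhlenbeck process (stationary sd
1.0 rad/s, correlation time 0.7 s) that emulates sustained foraging turns.
The turns matter: reaction delays are identifiable only where trajectories
curve, so the interacting scenarios default to the biased walker, while
the independent scenario defaults to the pure von Mises walk that the
independent behavioural state of the simulator also uses.  Followers copy
the leader's headings at the specified lag with κ = 2473 noise and their
own speed draws (coordinated; only headings are coupled, as in the
simulator), or occupy the leader's past positions exactly (chase).
Role-swap and piecewise-lag scenarios switch leadership or lag at the
midpoint; parallel-straight and curved-then-parallel are deterministic
fixtures for the uncertainty procedure.  Positional jitter (default sd
0.01 m) mimics pixelation noise.  The generator does not emulate camera
geometry, occlusion or frame drops.

What passing tests show — and do not show: recovery of lags, false-positive
control and the fit self-consistency are demonstrated on these synthetic
study conditions (10 s recordings, the parameter defaults above).  Real
recordings are shorter, have gaps and occlusions, and their independent
flights need not follow a von Mises walk, so the measured error rates do
not transfer to field data as-is.

## Problem sizes and numerical choices

The test suite runs 50 coordinated pairs (lags 0.1–0.5 s) for delay
recovery, 20 independent pairs for false-positive control, 200 mixed-delay
and 80 zero-delay model pairs for the delayed-response contrast, and
3 replicates of a 4 × 4 (A, B) grid with 150 pairs per grid point and 150
observed pairs for the self-consistency fit — sizes chosen to put each
statistic's sampling noise well inside its asserted margin while keeping
the suite fast.  Map values are clipped to [−1, 1] after windowing;
threshold comparisons treat NaN as "not super-threshold"; the chase DP's
coverage bonus (10⁶) exceeds any attainable separation sum by orders of
magnitude while leaving double precision far beyond the separation
resolution.  Degenerate inputs (stationary bats, empty super-threshold
regions, all-overflow densities) yield all-unclassified results, empty
paths or flagged missing evaluations rather than exceptions.

## Known limitations

* On long recordings the unbounded delay search lets two near-straight
  independent trajectories satisfy the correlation criterion over
  monotone-matchable stretches, so classifier precision degrades with
  recording length; short field-style recordings bound |τ| implicitly.
  Consequently, on 10 s simulator output a substantial share of
  coordinated labels falls outside the reactor's hearing range, and the
  delayed-response contrast is sharper in chase occurrence than in the
  position-in-sound-field statistic.
* The classifier handles exactly two individuals; multi-animal
  generalisation (multiple simultaneous interaction paths) is out of
  scope, as are 3-D flight, frequency-dependent absorption and call-timing
  jitter.
* The RMS calibration surface is shallow along an (A, B) trade-off ridge
  (a narrower beam with a lower threshold yields a similar detection
  footprint); argmin estimates jitter by one grid step between replicates,
  which is why the self-consistency check asserts the median of three.
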