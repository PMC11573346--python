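# Methods

## Probed-connection combinatorics

All counts are in *directed* connections: a paired recording of cells (i, j)
probes i→j and j→i, so directed probes are twice the pair count. For `n`
cells and `p` pipettes:

- **Traditional**, `(n/p)(p² − p)`, assumes `n/p` fully inter-probed groups.
  Two functions expose two readings of that formula. `traditional_possible`
  is the *realizable* integer count: `⌊n/p⌋` whole groups plus a final group
  of `r = n mod p` cells contributing `r² − r` (zero when a single cell is
  left over — 71 cells on 2 pipettes give 35 pairs, one cell unpaired).
  `traditional_possible_ideal` evaluates the formula as an exact rational,
  `n(p − 1)`, without rounding to whole groups.
- **Patch-walking**, `(p² − p) + 2(p − 1)(n − p)` for `n ≥ p`: the first `p`
  cells are fully inter-probed, then each new cell is probed against the
  `p − 1` still held. For `n < p` the physical upper bound `n² − n` is
  returned (the formula is undefined there).
- `improvement_percent` compares patch-walking against the **ideal** baseline
  in exact rational arithmetic. This is a deliberate choice: the 80–92%
  improvement range for 10–100 cells and 2–8 pipettes only reproduces against
  `n(p − 1)` (the grouped integer baseline is smaller when `p ∤ n`, which
  would inflate the percentage — 96.5% instead of 92% at n=100, p=8).

Probe matrices make the same counts constructively: block-diagonal for the
traditional strategy, a (p−1)-banded pattern for walking. Matrix counts equal
the closed forms over the whole tested grid (p ≤ 8, n ≤ 200); this
matrix-vs-formula equivalence is the main oracle for the module.

## Synthetic slices and the distance model

`generate_slice` emulates cell selection in an acute slice: positions i.i.d.
uniform over a 200 µm × 200 µm field at 20–100 µm depth, 8–10 cells by
default (the count itself drawn when unspecified). An optional
`min_separation_um` (off by default) rejection-samples a minimum intersomatic
spacing. Distances are 3-D Euclidean — the choice of 3-D over 2-D is a design
decision; somata depths differ, so pipette-relevant distance is spatial.

Ground-truth connectivity is drawn independently per *directed* ordered pair
with probability `p(d) = min(a·e^(−d/λ), 1)`. The exponential form is the
simplest monotone two-parameter family through the two literature operating
points used for calibration, p(91.6 µm) = 0.169 and p(200 µm) = 0.10, solved
in closed form (`λ = (200 − 91.6)/ln(0.169/0.10) ≈ 206.6 µm`,
`a = 0.169·e^(91.6/λ) ≈ 0.263`). Parameters are explicit model fields, not
hidden constants. Whether the literature's 16.9% is per pair or per directed
connection is ambiguous (at-least-one-in-three-pairs is 42.6% per-pair but
67.1% per-direction); this package treats it **per directed pair** in
sampling, and `prob_at_least_k` lets users compute either reading.

What the generator does *not* model: cortical layer structure, cell-type
specific connectivity, reciprocity correlations (directions are independent
here; real reciprocal pairs are over-represented), cell-health decline over a
session, and tissue deformation. Passing tests therefore validate the
*coordination logic and statistics*, not biological realism of any particular
circuit.

## Virtual rig criteria

Decision rules use the printed thresholds exactly, with boundary semantics
chosen to match their wording: gigaseal at R ≥ 1000 MΩ ("reaches"); break-in
success requires R strictly under 800 MΩ **and** |I_hold| < 200 pA at −70 mV
— the holding-current criterion is read as a magnitude bound, since a large
negative holding current indicates a leaky seal and cannot be "low"; QC
includes a recording only when initial access resistance is strictly below
40 MΩ and aborts at the first sample strictly above 50 MΩ.

Neuron-hunt detection is a sliding-window cumulative rise: earliest step `k`
with `R[k] − R[k−5] ≥ 0.2 MΩ` across 0.1 µm descending steps — not five
consecutive monotone increments, which is a stricter reading than the rule
states. The synthetic hunt-trace generator ramps resistance at 1.2× the
detection slope to a plateau 2× the delta above baseline, so noiseless
detection lands exactly at `neuron_at_step + window − 1` while small
measurement noise (≈0.01 MΩ) moves detection by at most a step or two.

Stimulus builders are pure data constructors: the 16-sweep firing-pattern
family (−20 to +280 pA in 20 pA steps, 3 s pulses, each preceded 500 ms
earlier by a 2 s −20 pA step), the whole-cell current-clamp check (0 / ±300 /
0 pA at 1 s), and the connectivity test (5 presynaptic pulses at 20 Hz,
postsynaptic side clamped at −70 mV, 3 sweeps, both directions). Both
current-step families are provided as separate builders since they serve
different stages. Postsynaptic waveforms are not synthesized; a probed
direction reports a Boolean, true iff the latent ground truth holds and a
Bernoulli(detect_prob) draw succeeds (default 1).

## Scheduler

A minimal discrete-event kernel (time-ordered callback heap) drives two
pipette state machines sharing a cell queue and a microscope token:

- **Assignment**: the queue cell nearest the pipette's home position, ties to
  the lower cell id; a cell leaves the queue exactly once. In constrained
  mode candidates are first filtered to within `[d_min, d_max]` of the
  partner's held cell (a 200 µm cap keeps pairs above ~10% connection
  probability), falling back to unconstrained nearest if none qualify.
- **Microscope**: exclusive FIFO token held from pipette-finding through the
  end of neuron hunting, released on success or failure; hunting intervals of
  the two pipettes can never overlap.
- **Stages**: finding → hunting → gigasealing (plus the 5 s post-seal wait) →
  break-in, each with a Bernoulli outcome and a truncated-normal duration.
  Failures always route through cleaning before reassignment.
- **Pairing**: when both pipettes hold, a bidirectional connectivity test
  runs; afterwards patch-walking releases the pipette with the *earliest*
  whole-cell timestamp (ties to pipette "a") while the traditional baseline
  releases both. The traditional baseline retries failed cells with the
  next-nearest from the queue rather than abandoning a group — the strategy
  is defined by its retract-all rule, not by a fixed grouping.
- **Termination**: queue exhausted (a still-held recording is reported
  unpaired — the session simply ends) or `max_duration_s` (default 4 h)
  reached.

Only `p = 2` is supported: with more pipettes, collision-safe cell-pipette
assignment becomes a route-planning problem outside this engine's scope, and
the engine refuses rather than pretend. Successful recordings are labelled
"n.p" (recording number + pipette letter, e.g. "3.a") in the connectivity
matrix; the event log is append-only JSON-lines `{t, pipette, event, cell,
detail}` with simulated seconds from session start, and identical seed +
config replays to an identical log.

### Defaults

Per-stage success defaults are hunt 0.9, seal 0.725, break-in 0.8 — their
product is exactly 0.522, a realistic end-to-end whole-cell rate for an
automated two-pipette rig (reported robot rates span ~30–80%);
`whole_cell_success` is a single-probability shortcut that overrides the
decomposition (applied at break-in). Default stage-duration means (finding
40 s, hunting 90 s, gigaseal 100 s, break-in 30 s, connectivity test 120 s,
cleaning 60 s, each with moderate SD, truncated at zero) were chosen once so
that simulated mean time-to-pair lands near the ~12.6 min scale of real
walking sessions (simulated: ≈13 min). Durations are configuration, used only
as sanity anchors — no test asserts them.

## Statistics

`summarize` reduces a session to attempts, successes, success rate (one
decimal, null when no attempts), pairs, directed probes (= 2 × pairs),
connections found, mean pair-to-pair interval (first pair timed from session
start), and mean intersomatic distance. `prob_at_least_k` uses the binomial
survival function; it is cross-checked against brute-force enumeration of all
outcome vectors for m ≤ 12. `expected_connections` sums `p(d)` over probed
directed pairs (a Poisson-binomial mean); simulations agree with it within
3σ. `compare_strategies` runs paired replicates with common random numbers —
both strategies see the same slice, ground truth, and engine seed — removing
between-slice variance from the yield comparison (toggleable). Confidence
intervals are normal-approximation by default, Clopper–Pearson on request.

## Problem sizes and numerical choices

The shipped test-and-acceptance runs use: the full (p ≤ 8, n ≤ 200) matrix
grid; deterministic engine checks for n ≤ 50; ~2000 simulated attempts for
rate recovery (99% binomial interval); 300–500 replicates for yield and
expectation checks (3σ); 10⁴ random traces for the hunt-detection oracle.
Closed-form percentages use exact rational arithmetic; simulation seeds
derive from a single `SeedSequence`, and every stochastic quantity is
reproducible from the seed.

## Known limitations

No pipette-shaft collision geometry, no manipulator kinematics, no pressure
or amplifier physics, no synthesized electrophysiology waveforms, no >2
pipette routing, no user-in-the-loop mode. The yield statistics inherit the
independence assumptions of the distance model; real connectivity is
clustered and reciprocal, so simulated connection counts should be read as a
calibrated baseline, not a circuit prediction.
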