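# Methods

This note documents the models and numerical choices behind movesyll: what
each stage computes, which parameters matter, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Signal conditioning

Raw device recordings (any rate above the analysis band; 128 Hz and 250 Hz
are typical wrist devices) are reduced to a common 25 Hz working rate by
polyphase rational resampling (`scipy.signal.resample_poly`), which applies
its own anti-alias low-pass. Non-integer ratios such as 128→25 use a
rational approximation of the rate ratio. Upsampling is refused — the
pipeline only ever reduces rates.

Band-pass filtering keeps 0.2–3 Hz with an order-3 Butterworth filter
applied **forward–backward** (`sosfiltfilt`). Zero-phase filtering preserves
the timing and shape of movement motifs, at the price of squaring the
magnitude response: the single-pass design gain exceeds 0.9 at 1 Hz and is
below 0.2 at 6 Hz, so the applied amplitude gains are those values squared.
The band excludes both the gravity/DC component and the 4–6 Hz parkinsonian
tremor band: the representation is built from voluntary movement, not
tremor oscillation.

Axis harmonization negates the right wrist's y-axis so both wrists share a
body-relative frame; the transform is an involution and the identity for
left-wrist recordings.

Windowing cuts the 25 Hz signal into 1 s windows (25 samples/axis) stepped
by 0.24 s (exactly 6 samples at 25 Hz, so no rounding policy is exercised at
the defaults; for other configurations window and step lengths round to the
nearest sample). Windows flatten axis-block-wise — all x, then all y, then
all z — giving 75-vectors. This order is fixed by configuration and must be
identical between vocabulary fitting and assignment. With L = 25 and S = 6,
each interior sample is covered by at least 4 windows (a minority land in 5;
we treat 4 as the minimum/modal coverage). Window count follows
floor((N − L)/S) + 1.

Units: window vectors are unit-sensitive (clustering uses raw Euclidean
distance), so recordings carry a unit tag and cohorts with mixed units are
refused.

## Tokenization

The vocabulary is learned by k-means (k-means++ init, 10 restarts, fixed
seed) over pooled window vectors, with K = 24 by default; the elbow-method
helper reports the inertia curve and the point of maximum perpendicular
distance to the endpoint chord. No per-window normalization is applied:
amplitude is clinically informative (bradykinesia shrinks it), so windows
cluster on their raw band-limited values. Assignment is nearest-centroid in
Euclidean distance with ties broken toward the lowest index. Two training
sources are supported: the pooled healthy participants (in-clinic mode) or a
single least-affected reference participant (at-home mode).

## Movement grammar and the SMR

Adjacent symbols within one sequence contribute transition counts; pairs
never span sequence (activity or session) boundaries, so concatenation order
cannot create spurious transitions. Maximum-likelihood rates
P(a,b) = N(a,b)/N_a are smoothed by adding ε = 1e-10 to zero entries and
renormalizing rows; a syllable never observed as a source receives a uniform
row. All entries strictly positive makes the chain irreducible, so the
stationary distribution exists and is unique.

The stationary solve uses the linear system (I − Pᵀ)π = 0 with one equation
replaced by Σπ = 1, via LU factorization plus one step of iterative
refinement (near-absorbing chains make the system ill-conditioned; the
refinement step recovers ~machine-precision solutions), with a stacked
least-squares fallback if the factorization fails. Power iteration exists in
the code base solely as an independent test oracle and is never on the
production path. Every emitted SMR satisfies ‖π − πP‖₁ < 1e-10.

Sessions are compared by the unhalved L1 norm ‖p − q‖₁ ∈ [0, 2] (the
total-variation distance equals half of this; the unhalved form is the
package's dissimilarity throughout). The dissimilarity matrix optionally
orders sessions by distance from the mean SMR of a reference group, which
makes severity gradients visible by eye.

SMR stability is quantified by the shuffled-concatenation curve: for each
m, the order of a session's activities is shuffled (50 times by default),
the SMR of the first m activities is built, and the variance of the leading
principal component across shuffles is reported. Because counting never
crosses boundaries, the SMR of a set of activities is order-invariant, so at
m = all activities the variance is exactly zero; the informative content is
how quickly the curve decays.

## Embedding and severity regression

Classical (Torgerson) MDS is the default: double-center −D²/2, take the top
three eigenvectors scaled by root eigenvalues. It is deterministic and
reproduces exactly-Euclidean dissimilarities to numerical precision. L1
dissimilarities are not guaranteed Euclidean; negative eigenvalues are
clamped to zero and the clamped mass is recorded on the embedding. SMACOF
(via scikit-learn) is available behind a flag for stress-majorization
embeddings; it is seeded and its stress is reported.

Severity models are ordinary least squares of a score (UPDRS-III total or a
subscore; healthy participants enter with score 0) on the three embedding
coordinates plus intercept. The in-sample r² is always co-reported with a
leave-one-out (PRESS) r² to expose optimism — with 40 sessions and 3
predictors the two are close; with 10 participants and 6 predictors (the
combined at-home model) the in-sample number is near-saturated and the
PRESS value is the honest one. Cook's distance per observation supports the
participant QC rule (flag above 0.16). Rank-deficient designs (e.g.
identical day and night coordinates in combined mode) fall back to the
minimum-norm pseudoinverse solution.

UPDRS-III subscores are sums over fixed item lists (15 bradykinesia/rigidity
items, 10 tremor items, 5 postural-instability/gait items, facial
expression, speech); the total is their sum. Item labels are validated —
unknown or missing items are errors, never silently zero.

## At-home analysis

Streams carry naive local-clock timestamps (no timezone arithmetic).
Each stream is cut into clock-aligned 30-minute segments; a segment's SMR is
estimated from its own transitions with the usual smoothing. Segments
starting in [00:00, 06:00) are nocturnal, [08:00, 20:00) diurnal, anything
else excluded; segments with fewer than 100 transitions are excluded too,
since an idle half-hour yields a near-uniform, uninformative SMR. All
segments of all participants are embedded jointly (one MDS), participant
coordinates are averaged per phase, and night (3 predictors), day (3), and
combined (6) models are fitted.

## The synthetic-data generator

The generator emulates syllable-structured wrist movement so every stage of
the pipeline runs — and every end-to-end claim is measured — without
clinical data.

* **Templates.** K = 24 one-second, three-axis waveforms synthesized from
  random Fourier coefficients confined to 0.2–3 Hz of a one-window DFT
  (out-of-band energy is zero by construction, so templates survive the
  band-pass), scaled to 0.5 g RMS, with a redraw loop enforcing pairwise
  separation.
* **Grammar.** The healthy base grammar draws each row from a Dirichlet with
  concentration 0.02 — nearly deterministic preferred successors, reflecting
  how stereotyped scripted activities are. Each participant's grammar mixes
  5 % of a personal Dirichlet draw into the base (inter-individual
  variability), then severity s ∈ [0, 1] interpolates toward the uniform
  matrix: P_s = (1 − s)P + sU. This is the simplest one-parameter family in
  which transitions grow disorganized while the chain stays irreducible; row
  entropies are nondecreasing in s.
* **Rendering.** A syllable path sampled from the chain is rendered at 25 Hz
  by concatenating templates at 1 s hops with a 0.2 s linear crossfade,
  adding i.i.d. Gaussian sensor noise (0.05 g), band-limited upsampling to
  the device rate (250 Hz default), and — for right-wrist participants —
  mirroring the y-axis, since a right-worn device records the mirrored body
  frame (the pipeline's harmonization undoes it). Severity also scales
  amplitude by (1 − 0.3 s) to mimic bradykinesia (configurable off to
  isolate grammar effects).
* **Cohort.** Default in-clinic conditions: 40 participants — 8 healthy at
  severity 0 and 32 affected spanning (0, 0.8] — each contributing 12
  activities of 30 s. Scores follow total = 50·severity + N(0, 2²) clamped
  at zero (healthy participants are assigned 0), yielding the 0–45 range of
  a moderate-severity cohort, and are split into integer subscores in fixed
  proportions. The at-home mode renders 2 days of clock-aligned half-hour
  blocks per participant (4 night blocks, 6 day blocks per day, 10
  participants, 25 Hz device rate — sizes chosen to keep the demonstration
  cohort small while leaving the phase models well-posed); template 0 is
  shrunk to a low-amplitude rest syllable that dominates night grammar with
  weight 0.85 − 0.3·s, so disturbed sleep movement grows with severity.
* **Seeding.** All randomness flows from one master seed through
  per-participant spawned seeds, so extending a cohort does not reshuffle
  existing participants and identical configs reproduce byte-identical
  outputs.

What the generator does **not** emulate: biomechanically realistic limb
dynamics, tremor oscillation (the analysis band excludes it by design),
medication ON/OFF fluctuation, autocorrelated real-world noise, or the
continuous (non-templated) nature of real movement. Consequently, passing
end-to-end tests demonstrates that the pipeline recovers a severity signal
expressed through transition disorder and amplitude decline in
syllable-structured data — not that it would achieve the same accuracy on
clinical recordings.

## Numerical and design notes

* Stationary solve: LU + one refinement step; residual tolerance 1e-10;
  probability clipping at 0 then renormalization guards sub-epsilon
  negatives.
* Overlapping windows mean most windows straddle two generated syllables;
  tokenization-fidelity checks therefore sample paths from the uniform
  grammar (balanced template usage) and compare one recovered symbol per
  generated syllable at 1 s-aligned windows, with Hungarian matching between
  centroids and templates.
* The elbow suggestion normalizes both axes to [0, 1] before measuring
  chord distance, making k and inertia commensurate.
* k-means empty clusters are handled by scikit-learn's relocation rule.
* Degenerate inputs: empty recordings, upsampling requests, mixed units,
  symbols outside the vocabulary, asymmetric dissimilarities, constant
  embeddings and scoreless regressions all raise typed validation errors;
  a constant score vector yields r² = 0 rather than an error in the phase
  models.
* Problem sizes in the test-suite and acceptance script (cohort of 40 × 12
  activities × 30 s; at-home 10 × 2 days; 100 oracle matrices; 1000 metric
  triples) were chosen so the full suite completes in about a minute while
  keeping every statistical margin wide.

## Known limitations

* In-sample r² with few observations and many predictors (the combined
  at-home model) is optimistic; rely on the co-reported PRESS r².
* The L1→MDS step discards the part of the dissimilarity structure carried
  by negative eigenvalues (reported as `clamped_eigenmass`).
* Transition smoothing at ε = 1e-10 makes stationary distributions of
  near-absorbing chains ill-conditioned; the solver's refinement step covers
  this, but such chains indicate too little data per segment in practice
  (hence the 100-transition minimum for at-home segments).
* Sequence files store symbols per (session, activity); two activities with
  the same label within one session would be merged on reading.
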