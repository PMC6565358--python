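# Methods

`seqerp` models a serial pattern detection experiment — coloured digits
presented at 2 Hz, with colour-cued ascending sequences embedded in a random
stream — and re-implements its complete analysis chain on synthetic
participants. This note documents the models, the choices behind their
parameters, and what the synthetic data can and cannot show.

## Task model

A session is a sequence of blocks. Each block holds a fixed number of cued
sequences separated by random trials. A sequence starts with a cue-coloured
digit: one colour announces a regular length of 5 digits (short), another a
length of 7 (long). Expectation compliance is manipulated per sequence:
*terminated* sequences are 2 items shorter than cued, *extended* sequences 2
items longer. Block-level *irreducible uncertainty* is realised through the
composition of compliances: low-uncertainty blocks use proportions
(.05, .90, .05) for (terminated, regular, extended), high-uncertainty blocks
(.15, .70, .15). With 4 blocks of each level and 20 sequences per block the
marginal cue validity — the probability that a cue is followed by a sequence
of the cued length — is exactly .80. Composition is realised by exact counts
shuffled within block rather than i.i.d. sampling, so these proportions are
deterministic. The alternative reading of "validity .80" (probability that a
cue colour starts any sequence at all) is not modelled; cues always start
sequences here.

Digits ascend by one modulo 10. Random trials draw digits that never
continue the predecessor by +1, so the sequence rule holds exactly on
sequences and nowhere else, and draw colours from reshuffled round-robin
filler pools, which keeps presentation frequencies balanced within a block
up to rounding without a constraint solver. Inter-sequence gaps are uniform
on 4–9 trials (gap lengths are a design choice; they only need to be long
enough to separate attribution windows). Trial duration defaults to 500 ms.

Event labels, with positions counted 1-based from the cue: for cued regular
length L and delta = 2, position L − 1 carries the termination check
(`PE_termination` when the sequence was terminated — the first random digit
appearing early — otherwise `CP_term_check`); position L + 1 carries the
extension check (`PE_extension` when extended — a sequential digit past the
regular end — `CP_ext_check` when the sequence ended regularly). Position 4
of every long extended sequence is a deterministic standard (`STD`). Note
that a termination checkpoint sits on a rule-continuing digit while an
extension checkpoint sits on the first non-continuing digit; both are the
*expected* outcome at their position, which is what "model-compliant"
means here.

In post-measurement sessions half of the sequences (configurable) are cued
by two fixed colours that served as ordinary fillers before, so they carry
no learned length information.

## Ideal-observer surprise

Each sequence outcome j ∈ {terminated, regular, extended} is scored with
I(x) = −ln p(x), p(x) = (n_j + 1) / (Σ_k n_k + 1), where counts accumulate
over past outcomes only. The weight is deliberately not a normalised
distribution (an empty history gives p = 1 for every outcome); it is kept
exactly in this add-one form, with a properly normalised
(Σ n_k + K)-denominator variant available for sensitivity analyses only.
Counts reset per block by default, because uncertainty is manipulated
blockwise and the within-block fluctuation of surprise is what the subgroup
analyses use; whole-session and block-by-cue scopes are selectable.

## Behavioural scoring

A press is attributed to a sequence when it falls between the cue onset and
2000 ms after the sequence's end reference; a sequence with at least one
attributed press is a hit, presses attributable to no sequence are false
alarms. PR = hit rate − false-alarm rate (two-high-threshold); the
false-alarm denominator is the number of inter-sequence gaps, the natural
count of opportunities, since no denominator is implied by the design
itself. Onset latency is press time minus the onset of the sequence's
second trial (the earliest pattern-detectable point); offset latency is
release time minus the onset of the first random trial after the sequence.
Offset latencies below −500 ms or above 2000 ms are flagged excluded from
latency means; they still count in the windowed release analyses, which
deliberately look at the [−1000, 500) ms band around sequence ends.

The 2 (uncertainty) × 3 (compliance) within-subject ANOVA is the classical
sums-of-squares decomposition with each effect tested against its own
participant-by-effect interaction; with 30 complete participants the
compliance effect has df (2, 58). The implementation is cross-checked in
the test suite against pingouin's independent rm-ANOVA. FDR correction is
Benjamini–Hochberg via statsmodels. (The BH adjustment is *not* idempotent
— reapplying it to adjusted values can only increase them — so the property
tests assert monotonicity and boundedness instead.)

The cue-learning median split computes each participant's gain score (mean
onset latency to new minus learned cues in the post session) and assigns
scores strictly above the median to the *gain* group; exact ties go to
no-gain first and are promoted in participant-id order only to keep group
sizes within one — a deterministic, seed-free rule. Surprise–latency
correlations pool (I, offset latency) pairs of extended sequences across
participants within a group (pooled trials, not participant means; with two
groups of 15 and default composition this yields on the order of 70+ pairs
per group), and groups are compared with the Fisher-z statistic, one-tailed.

## Synthetic cohorts

The response generator is calibrated so the analyses recover the group
statistics the pipeline is designed around: offset latency means/SDs of
619.48/96.55 ms (terminated), 532.81/99.74 ms (regular), 346.68/219.35 ms
(extended); onset latency 788.02 ms to learned cues; and a two-population
gain score of 178.54 ± 106.62 ms (gain) versus −45.40 ± 82.24 ms (no gain).
The printed SDs are treated as between-participant SDs of condition means;
trial-to-trial noise adds a within-participant SD of 150 ms (a conventional
RT-noise magnitude; the recovered between-participant SD is then slightly
above the configured value, which the 2-SEM recovery checks absorb).
Latencies are Gaussian, truncated only by the press-before-release
constraint. The surprise slope (−80 ms/nat, extensions only) is applied to
surprise *centred within compliance class*, so it induces the negative
surprise–latency correlation without moving condition means. Premature
releases place a configurable fraction of extended-sequence releases
1–2 trials before the actual end (offset latency −1000…−500 ms), more often
in the gain group. Misses (4%) and false alarms (3% per gap) produce PR
scores near .9. All of these values live in `generator_defaults.yaml`
(version 1) and are the single source of the model's defaults.

EEG epochs are a linear forward model on a synthetic 62-channel 10-10
layout (procedurally generated schematic positions — adequate for
adjacency, ROIs, and distance-based smoothing, but not a digitised cap).
Components are unit-norm Gaussian topographies times Gaussian temporal
kernels: P3b (Pz, 5 µV, peak 388 ms for PE / 420 ms for CP, absent for
STD), N400 (CPz, −2.5 µV, 418 ms, PE only), P600 (P6, 2 µV, 500/554 ms,
with a small negative STD weight), and an early frontal map (Fz, 2.5 µV,
300 ms, strongest for STD). Relative amplitudes are unconstrained by the
modelled design and were chosen once so the qualitative contrast pattern
(P3b-dominated PE−STD, N400-dominated PE−CP) emerges; they are a
calibration, not an inference. Because components superpose, the noiseless
PE−STD difference peaks slightly earlier than the configured P3b latency —
the forward model's placement is therefore tested with a single-component
model. Sensor noise is Gaussian with a spatial Gaussian covariance
(scale 0.35 layout units, SD 3 µV); there is no 1/f structure, no temporal
autocorrelation, and no ocular artifacts — the ICA step real pipelines need
is out of scope here precisely because the generator never produces what it
would remove. Passing tests therefore show the *statistics* behave
correctly under their assumptions, not that the pipeline is robust to real
EEG noise.

Microstate-style group ERPs are piecewise sequences from a pool of
orthonormal, average-referenced topographies shared across conditions
(condition c starts its 6-segment rotation at map 3c, so conditions share
and omit maps), scaled so the noise-free GFP follows a smooth positive
profile (mean ≈ 3 µV).

## ERP preprocessing

Band-pass 0.1–30 Hz is a zero-phase Butterworth cascade; high-pass and
low-pass are designed separately because a single band-pass design with
cut-offs three decades apart is numerically ill-conditioned, and filtfilt
padding is extended to several high-pass time constants to keep edge
transients out. Epochs are [−100, 600) ms (350 samples at the default
500 Hz — a 2 ms grid, which is also the grid on which the whole-brain and
ROI comparison counts of 18600 and 1350 come out exactly); baseline
[−100, 0) ms is subtracted (an assumption — configurable, including off).
Rejection drops epochs exceeding ±200 µV or 50 µV per sampling step, fully
automatically (the "semiautomatic" inspection of a human pipeline reduces
to its automatic rule here). Channels whose excess kurtosis across all
samples z-scores above 6 (population SD across channels) are replaced by
the unweighted mean of their Delaunay neighbours; spline interpolation is a
noted alternative, not the default. Common average reference subtracts the
per-sample channel mean. Averages are arithmetic means per condition;
grand averages are unweighted across participants.

## Cluster-mass permutation tests

Paired t-maps over the selected channel × time grid are thresholded at
uncorrected p = .05 (two-sided |t|, one-sided signed); supra-threshold
points of equal sign join clusters when temporally adjacent on a channel or
simultaneous on adjacent channels. Channel adjacency is a Delaunay
triangulation pruned at 1.5× the median edge length, overridable by a JSON
neighbour list. Cluster mass is the summed t. The null exchanges condition
labels within participants (sign flips of difference maps); each
permutation contributes its most extreme mass, the observed assignment
counts as one member of the null set, and p is the observed mass's rank —
so p ≥ 1/(n_permutations + 1), never 0. When the requested permutation
count reaches 2^n the test enumerates all sign assignments exactly (at the
conventional 5000 permutations this makes every n ≤ 12 analysis exact);
otherwise it samples. Zero-variance points produce ±∞ t-scores, which are
capped at the largest finite |t| of their map so masses stay finite.
Windows are half-open [lo, hi) on the sampling grid; an inclusive-endpoint
option exists because the 300–500 ms count of 6262 comparisons is only
consistent with a closed window (62 × 101 samples) — both conventions are
selectable, and neither is asserted as canonical.

## Microstate segmentation

GFP is the spatial population SD of an average-referenced map. AAHC starts
from singleton clusters and repeatedly atomizes the cluster contributing
least globally explained variance, reassigning freed samples to the
centroid with the highest squared spatial correlation; centroids are
normalised means of members, sign-aligned to the first member. One descent
snapshots every K in the requested range, so explained variance is
non-decreasing in K by construction. The default segmentation mode
concatenates all conditions into one descent (shared template pool); this
matches how the pool is identified in the recovery analyses, and a
per-condition mode is provided for the alternative workflow of clustering
each condition and merging pools afterwards. Map count selection minimises
CV(K) = σ²_K ((C − 1)/(C − 1 − K))² with C channels; a Krzanowski–Lai
curvature index and a median "meta" vote over both criteria approximate
richer toolbox meta-criteria. The CV criterion over-selects when the
remaining residual is noise-dominated and samples are few (each extra
cluster can absorb a whole sample direction); with the ~1400-sample group
descents used here it is well behaved. Back-fitting labels each sample with
its best-correlated template — signed correlation by default (ERP
convention; samples with no positively correlated template stay
unassigned), squared correlation optionally (labels then invariant to
polarity flips). No temporal smoothing or minimum-duration constraint is
applied by default; a minimum-duration merge is available. Segment
statistics report every visit of a template (split onsets preserved, in
order) and compare conditions with Welch t-tests (Satterthwaite df),
one-sided where directional hypotheses exist.

## Problem sizes and determinism

All randomness flows from `numpy.random.SeedSequence` spawns of a single
seed; cohorts, epochs, and permutation tests are bit-reproducible. The
calibration and recovery analyses are run at the sizes the package's own
acceptance script uses: 1000 null datasets of 12 participants × 8 channels
× 100 samples with 500 permutations for the familywise-error check; 100
replicates of 62-channel, 4-condition group ERPs (350 samples each) for
map-count recovery; and 30-participant cohorts with 4 + 4 blocks of 20
sequences for behavioural recovery. The demo pipeline configuration scales
these down further (8 participants, 2 + 2 blocks, 200 permutations) so a
full end-to-end run finishes in seconds.

## Known limitations

- The synthetic ERP noise model (spatially smoothed white noise) makes
  cluster tests better behaved than on real EEG; calibration results bound
  the method's type-I error under exchangeability, not under physiological
  artifacts.
- The behavioural generator draws per-condition participant effects
  independently, so cross-condition correlations of individual means are
  not modelled.
- The 2-D electrode layout is schematic; analyses that depend on true
  geodesic distances (e.g. source-space arguments) are out of scope.
- PR's false-alarm denominator and the pooled-trials correlation design are
  documented conventions, not uniquely determined by the task design.
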