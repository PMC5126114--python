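# Methods

`vocalnet` analyzes group vocal interactions of small birds (the design
case is four zebra finches) recorded in individual cages at the corners of
a square, with one microphone suspended above each cage. Because every
microphone hears every bird, the central problem is to turn four
synchronized audio channels into a single attributed event stream — who
vocalized, when — and then to summarize the group's dynamics as burst
statistics and two dyadic networks.

## Detection

Each channel is reduced to a short-time spectral energy envelope: Hann
windows of `fft_size` samples (default 1024) hopped so the envelope is
sampled at `envelope_rate_hz` (default 441 Hz; a 100-sample hop at
44.1 kHz), summing FFT power strictly above the 500 Hz high-pass cutoff.
The cutoff discards low-frequency room rumble; zebra finch calls carry
their energy well above it. The signal is zero-padded by half a window on
each side so frame *n* is centered on sample `n·hop` and the envelope
covers the entire recording.

Detection proceeds in three stages: (1) frames exceeding a threshold that
are local maxima over a ±3-frame neighborhood (plateau ties broken toward
the earlier frame) become peaks; (2) each peak's extent grows outward
frame-by-frame while the envelope stays at or above 10% of the peak
energy, stopping at the first frame strictly below (half-open extent), so
every event spans the same relative amplitude range regardless of its
absolute level; (3) overlapping extents are merged, the merged event
keeping the larger peak.

**Threshold.** The threshold is data-driven:
`max(median + k·MAD, 0.05·max(envelope))` with `k = 8` (raw MAD, no
normal-consistency scaling). In sparse-event recordings the envelope is
dominated by background frames, so the robust term tracks the noise
floor. The 5%-of-maximum floor is essential, not cosmetic: a summed-power
envelope over any broadband background has a *nonzero floor median*, and
a peak sitting just above `median + k·MAD` would have its 10%-of-peak
stopping level *below* that floor — its extent would grow across the
entire recording and stage 3 would merge every event into one. With the
floor, the weakest detectable peak is 5% of the session maximum and its
stopping level (0.5% of max) clears typical background fluctuation by a
comfortable margin. Both terms scale with the envelope, so detection is
equivariant under amplitude scaling (scaling audio by `c` and any
absolute threshold by `c²` leaves event times unchanged). An all-equal
envelope degenerates to `value × 1.01` with a warning; an all-zero
envelope is an error.

The temporal resolution of this stage is set by the analysis window
(1024 samples ≈ 23 ms): two sounds whose onsets fall within one window
blur into a single event on every channel, and no parameter choice can
separate them.

## Attribution

A call by one bird appears on all four channels, attenuated and delayed.
With cages 1 m apart and the microphone ~0.25 m above the singing bird,
the emitter's own microphone receives roughly 17× (adjacent) to 33×
(diagonal) more energy than the others and is the earliest arrival by
2–4 ms. Attribution clusters per-channel detections greedily in
decreasing peak-energy order: the loudest unassigned event anchors a
cluster, then on every other channel the unassigned event that (a)
overlaps the anchor in time, (b) has onset within
`max inter-mic delay + onset_tolerance_s` of the anchor's onset, and (c)
has peak energy not above the anchor's is absorbed (closest onset wins if
several qualify). Each cluster becomes one vocalization owned by the
anchor channel's bird, with the anchor's times.

The onset tolerance defaults to 15 ms — far above the maximum geometric
delay for this room (≈ 4.1 ms mic-to-mic) plus envelope-frame
quantization (≈ 2.3 ms) — so the gate only rejects onsets that are
physically impossible for copies of one sound. Overlapping calls by two
birds survive as two clusters exactly when their onsets differ by more
than the gate *and* the per-channel detector kept them apart, i.e. onset
separation beyond roughly one analysis window. Energy ties below 1e−9
relative are broken by earlier onset, then bird id.

`delay_consistency_score` is a diagnostic: the fraction of a cluster's
members whose onset lag from the anchor matches the geometric prediction
`(d_member − d_anchor)/c` within the tolerance, under the
anchor-as-emitter hypothesis. It is not used by the algorithm itself; it
surfaces clusters whose geometry contradicts their energy ordering.

No general sound-source localization is attempted: the hypothesis space
is the discrete set of caged birds, which is what makes the greedy rule
sufficient.

## Noise filtering

Cage knocks and wing flutter pass detection but are not vocalizations. A
random forest separates the two classes from a fixed-size spectrogram
feature: log(1+magnitude) STFT (256-sample FFT, 128-sample hop at
44.1 kHz) restricted to 500–6000 Hz (32 bins) over a 50 ms span
(17 frames; 544 values). Clips longer than 50 ms contribute their central
50 ms, cropped in the waveform domain so the feature depends only on that
central content; shorter clips are centered among exactly-zero columns.
The fixed dimensionality means a 30 ms tet and a 300 ms distance call
yield commensurable vectors. `log1p` rather than `log` keeps padded
regions exactly zero.

The forest uses 100 trees, unlimited depth, a mandatory seed (training
and prediction are deterministic given it), and the corpus as given — no
class reweighting. Models persist as a joblib payload plus a JSON sidecar
carrying the feature geometry; a model refuses to predict on features of
a different geometry.

## Activity and bursts

The group rate series uses 60 s windows advancing by 30 s; an event
belongs to a window iff its *onset* falls inside (half-open intervals
everywhere; whether the original analyses used onset or any-overlap
membership is not determinable, so the choice is config-exposed). Bursts
are unions of windows whose rate strictly exceeds `burst_factor` (default
1.10) times a reference rate — by default the session's overall mean rate
— with overlapping or touching flagged windows merged. Six metrics
summarize them: burst count, mean of per-burst mean rates, mean and total
burst duration, mean inter-burst interval (gap between consecutive
bursts), and latency from session start to the first burst. Undefined
metrics (no bursts; a single burst's inter-burst interval) are NaN and
flagged, never silently zero.

## Networks

**Cross-correlation (synchrony).** Time is split into 0.5 s bins; each
bird's binary signal is 1 in a bin iff one of its vocalizations overlaps
it (onset-only semantics available). The dyad weight is the zero-lag
Pearson correlation of the two signals with population (divide-by-*n*)
standard deviations — centering and scaling makes the weight independent
of the total number of vocalizations (duplicating a session leaves it
unchanged). All-silent or all-active signals have zero variance; their
edges are undefined (NaN), not zero. Only the zero-lag value is computed
by default; a lag parameter exists but defaults to 0.

**Turn-taking (Markov).** The attributed table is reduced to the caller
sequence in onset order (simultaneous onsets ordered by end time then
bird id, deterministically, and logged). Pair counting over consecutive
callers gives a 4×4 count matrix; rows are normalized to transition
probabilities, rows with no outgoing transition are undefined-flagged.
Self-transitions are retained in the matrix — birds do call twice in a
row — but dyad edges use off-diagonal entries only: the undirected edge
weight for {i, j} is `max(p(i→j), p(j→i))`, with an undefined direction
treated as absent and the dyad undefined only when both are.

## The synthetic-data generator

The generator is first-class, tested code: it defines the study
conditions under which every pipeline guarantee is checked.

Geometry: unit cage square, microphone 0.25 m above each bird's perch
position (source at z = 0, mic at z = 0.25 m), speed of sound 343 m/s.
Calls are parametric caricatures of the two pooled call types: "tet"
calls are 50–150 ms harmonic stacks with flat F0 drawn from 500–700 Hz,
and "distance" calls are 100–300 ms harmonic series with sinusoidal FM
(5–15% depth, 25–60 Hz) and AM, F0 550–750 Hz; both with harmonics to
6 kHz at 1/h amplitudes and 2 ms raised-cosine attack/decay ramps. The
sharp attack matters: the detector's onset is by construction the
31.6%-amplitude point of the attack, so a call whose rise time exceeds an
envelope frame (2.3 ms) would make sub-frame onset recovery impossible
for *any* detector; real zebra finch calls have comparably abrupt
onsets. Propagation is free-field: amplitude × 1/d, delay d/c, no
reverberation (the attribution contract depends only on energy/delay
ordering; a reverberant room would perturb but not invert it).

Caller identities follow a configurable first-order Markov chain over a
group-level homogeneous Poisson onset process (default 0.1 calls/s per
bird). Background noise is Gaussian (σ = 0.003 against own-channel call
peak amplitudes around 0.11–0.21, ≈ 30 dB); impulsive noise is a Poisson
stream (0.05/s) of cage clicks (4–15 ms exponentially decaying bandpassed
noise bursts with random resonance) and wing-flutter pulse trains,
propagated from a random cage like any other source. The classifier
corpus draws calls and amplitude-matched noises from the same
distributions. All randomness descends from one seed via
`SeedSequence.spawn` into three named streams (stream, render, corpus),
so each stage is independently reproducible.

`simulate_spaced_stream` builds structured scenarios for controlled
experiments: calls in round-robin slots with guaranteed gaps, optionally
with a fraction of slots holding overlapping diagonal-bird pairs. Pair
onset offsets are floored at 40 ms, above the detector's one-window
resolution (~23 ms) and the attribution gate (~19 ms): tighter overlaps
are unresolvable in principle by an envelope-based method, so including
them would measure the scenario, not the implementation.

**What the generator does not emulate.** Real call spectra and song
syntax; reverberation and moving birds; overlapping choruses of more than
two birds; nonstationary noise (heating, doors); recorder clock drift.
Passing the recovery suites therefore demonstrates the pipeline's logic
under the stated geometry and SNR, not field performance on arbitrary
recordings.

## Problem sizes and numerical choices

Test and benchmark workloads are sized for a laptop-class single core:
recovery suites use 200-call rendered sessions (~4 minutes of 4-channel
44.1 kHz audio), the classifier benchmark uses a 4500-clip corpus
(train on one third, evaluate on two thirds; the in-suite variant is a
1500-clip scaled analogue), and chain-recovery uses 100 000 events.
Envelope computation processes frames in chunks of 8192 to bound memory.

Times are seconds from session start; all intervals are half-open
`[start, end)`. Event tables serialize times at microsecond precision and
energies at six significant digits; network weights at 12 significant
digits; pipeline CSVs are written at fixed precision so identical
configs yield byte-identical outputs. Undefined quantities are NaN plus
an explicit flag, never sentinel zeros.

## Known limitations

- Calls overlapping within one analysis window (~23 ms) merge on every
  channel and cannot be attributed separately; same-bird back-to-back
  calls closer than the window merge likewise.
- Attribution assumes the emitter's channel is loudest; a bird calling
  while facing away from its microphone, or strong reverberation, could
  violate the energy ordering.
- The noise classifier is only as good as its corpus; the shipped
  generator produces cleanly separable classes, so its ≤10% error bound
  is a necessary sanity check, not evidence about field recordings.
- The burst reference rate is the whole-session mean; recordings with
  strong slow trends may flag long stretches rather than discrete bursts.
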