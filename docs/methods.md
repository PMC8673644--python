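# Methods

This note documents the models, algorithms and parameter choices behind
`clickchain`, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Signal model and units

All processing operates on calibrated pressure in µPa. WAV files carry
raw integer counts; a flat sensitivity (counts/µPa) in a JSON sidecar
makes calibration invertible. Real hydrophone transfer functions are
frequency dependent; a flat response is sufficient for synthetic-data
validation and keeps every level exactly recoverable. Event levels are
peak-to-peak: RL_pp = 20·log₁₀(max − min) dB re 1 µPa. Noise is specified
as a spectral density (dB re 1 µPa²/Hz); white Gaussian noise with
variance 10^(NF/10)·fs/2 realizes a floor NF.

## Detector

The detection chain band-passes each chunk with a five-pole Butterworth
filter (defaults 5–100 kHz; an edge exactly at Nyquist is nudged just
below for the design), computes the Hilbert envelope, and marks candidate
events where the envelope exceeds half the linear pp-threshold amplitude
— the peak-equivalent of the pp criterion. Envelope-crossing extent
defines event duration (kept in [30, 1200] µs after merging events closer
than 100 µs); the pp criterion itself is then verified on the extracted
snippet, so no reported detection can fall below threshold. The snippet
is a fixed 1 ms centred on the envelope peak (long events are truncated;
the classifier consumes fixed-length inputs). Spectra are Hann-windowed
periodograms of the snippet, zero-padded to fs/500 points so the native
grid is exactly 500 Hz — no interpolation — converted to dB re 1 µPa²/Hz
and sliced to the detection band.

Filtering is causal by default, as a monitoring detector runs. The
zero-phase option (`zero_phase=True`, used by the synthetic pipeline)
exists because causal phase dispersion distorts the pp level of
100–300-µs pulses by 1–2 dB; when measured levels are compared against
ground truth, zero-phase filtering keeps the mean absolute RL error
around 0.2 dB. Note that no per-event error bound is possible at finite
signal-to-noise ratio: noise at the event peak shifts individual pp
measurements, and about 1% of near-threshold (121 dB over a 50-dB floor)
events exceed 1 dB of error. Accuracy statements therefore use the mean
absolute error.

Streaming: chunk *k* owns the half-open window [kC, (k+1)C) and is padded
with context on both sides (at least snippet + max event duration), so
every event is processed by exactly one chunk with its full snippet in
view, and detector output is invariant to the chunk size.

The received-level distribution diagnostic histograms RL_pp in 1-dB bins
above the threshold and requires the lowest five bins to be nonincreasing
with increasing RL. Under the uniform-area model (sources uniform over
area, spherical spreading), N(≥ RL) ∝ 10^((SL−RL)/10), so counts must
keep rising toward the threshold; a roll-off means near-threshold events
are being missed. Fewer than 100 detections returns "insufficient data".

## Clustering

Similarity is Pearson correlation clipped to [0, 1]: anticorrelated
shapes carry no attraction, matching a 0–1 similarity scale, and
correlation is insensitive to amplitude offsets (transmission loss).
Zero-variance feature rows get zero similarity everywhere, with a
warning. Phase 1 compares detections on spectra alone (envelope optional
via `use_envelope`); phase 2 compares bin summaries on the unweighted
mean of spectrum and envelope correlations. IDI histograms are carried
through to classifier inputs but excluded from phase-2 similarity —
IDI-based similarity tends to produce duplicate classes.

Edge pruning keeps the globally strongest fraction of all pairwise
scores (default 10%, i.e. a 90% pruning threshold; ties at the cutoff are
all kept, zero-weight edges never). Isolated nodes stay singletons and
are eventually dropped — highly dissimilar events may end up in no class.

Chinese Whispers starts from singleton labels and, in a fresh seeded
random node order per iteration, assigns each node the label with the
largest summed edge weight among its neighbours (ties seeded-random),
stopping at convergence or 25 iterations. It needs no preset cluster
count; on disconnected clique graphs it recovers components exactly.

Phase 2 runs Chinese Whispers five times and keeps the consensus-most
partition — the one minimizing the mean of (1 − NMI) against the other
repeats, where NMI = 2·I(p;q)/(H(p)+H(q)). Selecting by *minimum* raw NMI
would pick the outlier run; a `minimize_consensus` switch exposes that
literal alternative. NMI conventions: two degenerate (single-cluster)
partitions score 1.0; degenerate against non-degenerate scores 0.0.
Afterwards the most weakly connected 10% of each cluster's members
(summed within-cluster edge weight, ceil rounding, never below one
survivor) are marked unclustered, and clusters below the minimum size are
dropped.

Near-duplicate merging (transitive closure over pairs with similarity
≥ 0.98) exists as a graph-size reduction; the synthetic pipeline disables
it because under a 2000-node subsample cap it is unnecessary, and
transitive chaining can fuse two overlapping classes through a single
borderline pair.

## Training sets and classifier

Encounters — per-class bouts separated by ≥ 900 s without that class —
are the unit of the 60/10/30 train/validation/test split (largest-
remainder rounding per class; every split gets at least one encounter
when a class has three). Balanced sets draw exactly n per class, with
replacement when a class is short (flagged). An assertion verifies that
no encounter feeds more than one split.

Detection inputs concatenate the spectrum standardized as
(S − 70)/130 — the literal low/high-typical-value rule; dividing by the
60-dB range instead is available via `range_normalize` — with the snippet
scaled by a typical maximum pressure (10^(132/20) µPa). Bin inputs
concatenate the min-max-normalized mean spectrum, the IDI histogram
rescaled to peak 1, and the normalized mean envelope.

The network is fixed: four fully connected hidden layers of 512 units,
leaky ReLU (slope 0.01), dropout 0.5 after each hidden activation,
softmax output; cross-entropy loss, RMSprop (decay 0.9) at a constant
3·10⁻⁴; batches of 2000 detections or 100 bins; validation evaluated per
epoch; stop after 3 epochs without improvement of validation loss
(accuracy optional via `monitor`) or at 15 epochs, restoring the
best-validation-epoch weights. The implementation is plain numpy
(explicit forward/backward, He initialization), which keeps training
bit-reproducible under a fixed seed on CPU.

## Evaluation

Confusion matrices index (predicted, true); precision is row-wise,
recall column-wise — some published tables label the per-true-class
column "precision" where the computed quantity is recall, so the module
names both explicitly. Threshold sweeps retain predictions with
confidence (max probability) ≥ τ: discarded items count against recall
but not precision, and precision over zero retained items is reported as
undefined (NaN), not 0 or 1. Bin-level accounting pairs each (bin, true
class) with a same-class prediction, else an unmatched prediction, else
the "none" row (no cluster formed or no label emitted); accuracy is
reported both including and excluding "none". A class counts as truly
present in a bin when at least `min_bin_count` of its events fall there,
mirroring the clustering minimum so "none" is well defined.

## Synthetic scenes: what they emulate, and what not

`simulate` renders Gaussian background noise plus scheduled events into
16-bit PCM WAV, block-streamed (30-s blocks) so hours of audio need
block-sized memory; a fixed seed gives byte-identical output. Clicks are
Gabor pulses (Gaussian-windowed cosine) — the spectral peak sits at the
class center frequency and the −3 dB width approximates the class
bandwidth; ship-like events are deterministic low-frequency-weighted
broadband bursts, sonar-like events Tukey-windowed narrowband pings.
Event times follow modal IDI plus Gaussian jitter within encounters;
received levels follow the uniform-area model truncated at `min_rl`.
Variability enters at three scales, as in real data: per event (3%
frequency, 10% duration jitter), per encounter (1–2% frequency offset —
different animal groups), and additive noise. Full scale sits
`headroom_db` above the loudest source level; a scene that would clip
raises an error instead of distorting.

Not emulated: propagation beyond spherical spreading, beam-pattern and
off-axis spectral distortion, multipath, frequency-dependent absorption,
duty-cycled recording, and clicks overlapping within one snippet.
Passing tests therefore demonstrate the pipeline's correctness on data
satisfying its own assumptions — class separability in spectral shape,
uniform-area level statistics, encounter structure — not its performance
on any particular ocean recording.

## Problem sizes and demo-scene parameterization

The bundled validation scenes are sized for a desktop run: 48 kHz
sampling with the detection band at 5–22 kHz (the band scales with
Nyquist; defaults remain 200 kHz / 5–100 kHz), a 10-minute single-class
scene for detector recovery, and a 2-hour five-class scene for the full
pipeline. Against the defaults tuned for months-long deployments, four
parameters are rescaled to the 2-hour scene and ~24 five-minute bins it
contains, all documented at their call sites: the phase-1 subsample cap
is 2000 nodes per bin; near-duplicate merging is disabled (see above);
the phase-2 minimum cluster size is 5 summaries — the default of 50
cannot be reached when a class contributes at most ~12 bin summaries;
and phase-2 edge retention is 20% rather than 10%. The retention change
is forced by arithmetic, not preference: with ~65 summaries in 5
balanced classes, within-class pairs make up ~25% of all pairs, so a
10% global retention cannot keep every class connected no matter how
separable the classes are. At 20%, measured on the scene, every
within-class pair survives while all between-class pairs fall below the
cutoff. At deployment scale, where any one class contributes a small
share of a large summary pool, the 2–10% default regains its meaning.
The class-discovery quality criteria themselves (coverage of all planted
classes, ≥ 0.9 template purity) are independent of this rescaling.

Bin summaries become unstable when computed from few events: the mean
spectrum of ~100 events is visibly noisier than one of ~1000, its
similarities to same-class summaries rank lower, and global edge pruning
then starves the class. The demo scene therefore keeps every class's
per-bin event count above ~200. This mirrors a real operating constraint
of the method — classes that appear only in sparsely occupied bins are
the first to be lost by phase-2 pruning.

## Known limitations

- Chinese Whispers is stochastic; a class at the edge of the similarity
  ranking can fragment under an unlucky seed. The five-repeat consensus
  reduces but does not eliminate this.
- Correlation similarity on dB spectra is sensitive to the shared noise
  baseline; two classes in the same band with overlapping tails can
  exceed the pruning cutoff and merge at phase 1.
- The detector measures duration as envelope-crossing extent, which
  shrinks toward zero for events barely above threshold; durations of
  near-threshold events are systematically short.
- The numpy network trains at desk scale (10⁴–10⁵ rows); it is not a
  GPU-class implementation.
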