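# Methods

This note documents the models and procedures implemented in motifscope,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic test surface does and does not show
about real recordings.

## Sound segmentation

Segmentation assumes song syllables are separated by silence and operates
purely on amplitude. Two thresholds on two different metrics discriminate
sound from silence: the on-threshold `t_on` (default 0.5) applies to the
absolute sample value of the normalized signal, and the off-threshold
`t_off` (default 0.5) applies to the peak-to-peak amplitude over a window
of `w` samples (default 325, ≈ 6.8 ms at 48 kHz). From each trigger the
onset is found by searching backwards for the last index whose trailing
window is quiet, and the offset forwards for the first index whose leading
window is quiet. The defaults equal each other numerically but remain
independent parameters, since they act on different metrics.

Conventions the implementation fixes where the scheme leaves room:

- Indices are 0-based; segments are half-open `[onset, offset)`.
- After a segment (kept or duration-filtered), scanning resumes at
  `offset + 1`, so one syllable can never emit two overlapping segments.
- Backward (onset) windows are clipped at the buffer start — a recording
  begins in silence and earlier stream history is unavailable. Forward
  (offset) windows must be complete: at the end of the data the future is
  unknown, so the candidate is closed at the boundary and flagged
  `truncated` instead. This choice also makes the online variant exact:
  a streamed candidate is released only once its complete leading quiet
  window has been received, which guarantees bit-identical output to the
  offline scan for any chunking (a tested invariant).
- Duration filtering keeps segments with `min_dur ≤ d ≤ max_dur`
  (defaults 30–300 ms, the expected zebra finch syllable range).
- Normalization is per-file peak normalization to [−1, 1] (a config
  choice; `normalize=False` on `read_wav` disables it).

The optimized implementation (rank filters + prefix scans) is tested for
exact equality against a literal per-index evaluation of the definitions.

## Compressed-spectrogram features

The fixed feature geometry is derived from the syllable duration band and
the sample rate. The FFT window is the largest fitting the shortest
admissible syllable, `⌊min_dur · fs⌋` (1440 samples at the defaults); the
stride spreads the longest syllable over the desired number of time bins,
`round((max_dur · fs − fft) / bins)` (25 at the defaults). The magnitude
STFT (rectangular window by default — the bare transform; Hann available
by config) is cropped to the zebra finch audible band and to the first 512
time columns, zero-padding shorter segments.

Frequency-bin inclusion uses the half-open rule `f_low ≤ f < f_high`. At
48 kHz / FFT 1440 the bin centres 200.0 Hz and 8000.0 Hz both fall exactly
on bins (k = 6 and k = 240), so a closed interval would keep 235 bins; the
half-open rule keeps the 234 that fix the overall feature dimensionality
at 234 + 512 = 746.

Naming hazard: `F_t` is the sum **over** time — a frequency profile of
length 234 — and `F_f` the sum over frequency — a time profile of length
512. The subscript names the summation axis. Each profile is normalized to
unit sum before concatenation, which makes the features invariant to
recording gain (a tested invariant).

## Behaviour map

Training embeds the N × 746 feature matrix into 2D with t-SNE
(scikit-learn Barnes–Hut, PCA initialization, seed-controlled;
perplexity default 30 — an effective nearest-neighbour count). The
production-scale training set is nominally 60 000 syllables per bird;
tests and examples run at a few hundred to a few thousand.

The density surface places a Gaussian kernel on every embedded point
(histogram + Gaussian blur on a 1000 × 1000 grid over the bounding box
padded by twice the bandwidth). Peaks separated by at least
`min_peak_distance` seed a watershed of the inverted density; every grid
cell belongs to a region, lettered by decreasing peak density. The numeric
defaults (bandwidth 15, peak distance 15, in embedding units) correspond
to production scale. Because t-SNE layouts grow with the number of
embedded points, both parameters also accept `"auto"`: bandwidth = 4% of
the embedding bounding-box diagonal and peak distance twice that, which
reproduces ≈ 15 at production scale and scales consistently down to the
desk-scale maps used in the tests.

### Post-embedding

A new syllable `z` is placed into the trained embedding without re-running
t-SNE. Its conditional neighbour distribution is

    p(x_j | z) ∝ exp(−D(z‖x_j)² / 2σ_z²)

over the nearest training points, where D is the KL divergence between the
unit-sum feature vectors (0·log 0 := 0; zero neighbour bins floored) and
σ_z is found by binary search (on β = 1/2σ², in units of the largest D²)
so that 2^H(p) equals the perplexity within 1%. When all distances tie the
entropy has a floor above the target and no calibration exists; the search
is capped and the near-uniform p used as-is. The low-dimensional
conditional is the Student-t kernel

    q(x′_j | z′) ∝ (1 + ‖z′ − x′_j‖²)⁻¹

and z′ minimizes KL(p‖q) by Nelder–Mead.

Design choices in this module:

- **Neighbour count.** The neighbour set defaults to 3× the perplexity
  (the conventional t-SNE transform ratio). With exactly `perplexity`
  neighbours the calibration is degenerate: the maximum entropy of k
  outcomes is log₂ k, so matching perplexity k forces p uniform, and
  KL(uniform‖q) is globally minimized by sending z′ to infinity, where q
  is exactly uniform — every query would diverge. `neighbor_multiple=1`
  restores the literal variant.
- **Starts.** The optimizer runs from three informed starts — the plain
  centroid of the neighbours' embeddings, the p-weighted centroid, and
  the heaviest neighbour — each polished by a fresh-simplex restart, and
  keeps the best. The objective is multimodal when p spans distinct 2D
  basins, and the single centroid start demonstrably lands in the wrong
  basin on such queries (a dense grid-search oracle checks the optimizer
  in the tests).
- **Divergence detection.** A query unlike any training sound has no
  finite optimum and its solution "shoots towards infinity". Two
  complementary checks implement this: a solution further than 5× the
  embedding's bounding-box diagonal from the centroid is diverged; and a
  solution whose objective does not beat the closed-form value at
  infinity, log k − H(p), is diverged **unless** it sits within 20 median
  nearest-neighbour spacings of the neighbour set (queries inside one
  tight clump tie with infinity while being perfectly classifiable — the
  two regimes are separated by orders of magnitude in measured distance).
- **Affinity form.** The Gaussian affinity above is standard; a literal
  unnormalized quadratic variant (`p ∝ D²`, under which σ cancels and no
  perplexity calibration exists) is available behind
  `literal_affinity=True` for auditability.

Classification assigns the watershed region containing z′ (UNCLASSIFIED if
diverged or off-grid) and reports the Euclidean distance to the region's
density peak as a certainty score — the further from the peak, the more
likely the classification is wrong. Batch classification is
order-independent under any worker count (tested).

## Motif discovery

First-order transition counts are accumulated over adjacent label pairs
within each sequence (never across sequences; UNCLASSIFIED tokens are
dropped). Because the motif is repeated several times per bout, its
transitions dominate the matrix and form a cycle: starting from the
globally most frequent arc and greedily following each label's most
frequent continuation (ties broken lexicographically, for
reproducibility), the first revisited label closes the cycle. Dead ends —
labels with no outgoing counts, possible with repeated syllables or many
introductory notes — are escaped by depth-first backtracking over each
predecessor's next-best arcs, including the start label's remaining arcs.
The cycle is canonicalized to its lexicographically smallest rotation. An
independent oracle (exhaustive simple-cycle enumeration, maximizing the
minimum arc count) confirms the greedy result on all tested inputs.

Since birds sing variations of the full motif, detection screens sequences
for the motif's substrings: all contiguous runs of the cyclically extended
cycle with length from 2 (a single letter is not evidence of a motif;
configurable) up to the cycle length, ranked by non-overlapping
leftmost-greedy occurrence count in the training sequences, top ten
retained. A sequence containing any retained substring emits one motif
event carrying the most frequent substring in that sequence and its count.

## Event processing

Behaviour is represented as half-open timestamped intervals. Audio metrics
are computed per frame (1024 samples, hop 512 — ≈ 21 ms at 48 kHz, suited
to call/syllable timescales; the frame size is a config choice, the
original system does not state one): power is the mean squared sample, and
entropy is the spectral flatness (Wiener entropy) of the frame's magnitude
spectrum — the geometric over arithmetic mean, ≈ 0 for tones and ≈ 1 for
white noise. Flatness is computed on the spectrum rather than on signed
time samples, for which a geometric mean is ill-defined.

Hysteresis thresholding (ON above `on_threshold`, OFF below
`off_threshold`) suppresses switch bouncing near the noise level; no
faithful default thresholds exist for real recordings, so the CLI requires
them explicitly. Complex events are interval intersections:
bout = power ∧ entropy, contact = front-perch(bird 1) ∧ front-perch(bird 2),
directed song = bout ∧ contact. Syllable events chain into sequences while
the inter-syllable gap is under 0.5 s, emitted within 3 s of sequence end.
The stimulus controller resets a 3-minute timer on every motif event and
advances a cyclic video playlist whenever the timer expires. Perch
occupancy sums event durations per state over a horizon; uncovered time is
attributed to "other" so proportions always sum to 1, and overlapping
perch states are an error.

## Acoustic statistics

**YIN.** The fundamental frequency of harmonic-stack syllables is
estimated on 2048-sample windows (≈ 42 ms at 48 kHz): squared difference
function over half the window, cumulative mean normalized difference,
absolute threshold 0.1, descent to the local minimum, parabolic
interpolation of the selected lag. The search band defaults to
300–1500 Hz, bracketing zebra finch stack fundamentals (400–1000 Hz);
windows with no lag under the threshold are unvoiced. Threshold and band
are config, as the exact parameterization is not canonical.

**CV of FF.** Sample standard deviation over mean of the voiced estimates;
lower CV across renditions indicates female-directed song. The measurement
window is taken at caller-provided timestamps — selecting the flat part of
the stack is an annotation decision, not guessed by the package.

**Call timing.** For each playback of the mate's call, the delay to the
bird's strictly-next own call is kept if ≤ 2 s; delays are histogrammed in
200 bins over [0, 2] s and summarized by the argmax of a Gaussian KDE. The
KDE bandwidth default is 0.1 s — 100 units on the millisecond axis the
histogram is conventionally plotted on; the unit is ambiguous in the
source description, so it is configurable. A `--delay` CLI offset lets the
caller correct playback onsets for a known system delay.

## Synthetic data

Real recordings are not redistributable, so the `synthetic` module renders
zebra-finch-like song with known ground truth: harmonic stacks (k·ff
partials at 1/k amplitude), linear frequency sweeps, and band-limited
noise bursts, each 30–300 ms with 5 ms cosine ramps; bouts of introductory
notes plus repeated 4-syllable motifs, within-bout gaps of 80 ms,
between-bout silences over 0.5 s, an additive Gaussian noise floor, and
optional label noise (random syllable substitution). All generators are
deterministic given their seed.

Per-rendition variability matters more than acoustic realism for the
behaviour map. Renditions jitter the pitch (log-normal, sd 1% — whole
trajectory shifts together), the duration (sd 2%, clipped to the 30–300 ms
band), and the *timbre*: per-harmonic amplitudes, sweep curvature and
envelope tilt, and noise-band edges (log-normal, sd 0.3). The jitters are
of the order of the rendition-to-rendition variability of stereotyped
zebra finch song. The timbre jitter is essential: with only one or two
jittered parameters each type forms a thin filament (or, with none, a set
of exchangeable near-duplicates) in feature space, and t-SNE renders
filaments as coils and duplicate sets as fragmented archipelagos on which
watershed segmentation is meaningless. Many-dimensional smooth
variability — which real vocalizations have — produces the compact fuzzy
blobs the density-based map is designed for.

What passing tests show, and do not show: recovery of planted types at
desk scale (5 types × 1000 renditions) demonstrates the pipeline's
internal consistency, not its performance on real song, whose within-type
variability, amplitude dynamics, reverberation and overlapping cage noise
are absent here; region counts on real data also reflect map
hyperparameters (the source system observed merged and split syllables).

## Problem sizes and numerical choices

Tests and examples run the map at 500–5000 training syllables with
`"auto"` smoothing, chosen so the full suite completes in minutes; the
production configuration (60 000 syllables, bandwidth 15) is the
documented default of `build_behaviour_map`. The KDE grid is 1000 × 1000;
σ calibration tolerance is 10⁻⁶ in log₂ perplexity; Nelder–Mead uses
xatol 10⁻⁴/10⁻⁶ and fatol 10⁻⁸/10⁻¹⁰ across the two passes. Zero
spectrograms, empty segments, empty transition matrices, overlapping perch
states and NaN features raise errors rather than propagating silently.

## Known limitations

- The two-threshold segmentation has no adaptive noise floor; loud cage
  noise within the duration band becomes a (usually unclassifiable)
  segment.
- Watershed regions can merge acoustically close syllable types or split
  one type across two density modes; no hierarchical region merging is
  attempted.
- The greedy cycle extraction returns a single motif; repertoires with
  several motifs, or motif variants differing by more than substring
  deletion, are out of scope.
- Post-embedding cost is one kNN query plus a handful of 2D simplex
  optimizations per syllable (~10 ms at desk scale) — real-time at song
  rates, but the package does not manage worker pools across machines.
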