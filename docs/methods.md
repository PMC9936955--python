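# Methods

`sigmer` detects target sequences directly in raw nanopore current traces
("squiggles") with an array of small, independently trained per-k-mer
convolutional classifiers.  This note records the models, the synthetic
data the package is validated on, the numerical choices, and the design
decisions taken where the design was genuinely open.

## Signal model and simulator

A nanopore read is modelled as a sequence of current levels, one per
`model_k`-base context (default `model_k = 6`).  The synthetic pore model
draws each context's mean level i.i.d. uniform on 60–120 pA from a
counter-based (Philox) generator keyed by the seed, approximating the
dynamic range of an R9.4-class pore without reproducing any vendor table;
the per-context level spread is fixed at 1.5 pA.  During simulation each
context emits a geometric run of samples (mean dwell 10 samples,
minimum 1 — roughly 450 b/s at a 4 kHz sampling rate) at its level plus
i.i.d. Gaussian noise (default sd 2 pA).  Ground truth (source sequence,
per-context segment boundaries, source coordinates and strand) is carried
on every simulated read, which replaces the signal-to-reference alignment
("resquiggling") step needed with real data.

Deliberately not modelled: signal drift, stalls, skips, adapter/barcode
signal, per-read gain variation, and basecalling of any kind.  Two
consequences matter for interpreting results.  First, because levels are
drawn uniformly, distinct contexts frequently have nearly identical
levels, which makes short-dwell occurrences genuinely ambiguous — an
idealized matched filter fares no better than the trained networks here
(we verified this with a dynamic-programming template matcher).  Second,
passing tests show the machinery works under this noise model; they do
not certify accuracy on real flowcell data.

## False-positive model and the choice of k

Assuming all canonical k-mers equally likely, a k-mer's expected number of
occurrences in a random read of length `L` is `L·2·4^-k`, and the
probability of at least one occurrence follows a Poisson approximation,
`P(X≥1) = 1 − exp(−L·2·4^-k)`.  With a library `A` of per-k-mer detectors,
the expected number found in a target of length `L_target` is
`E = P(X_target≥1)·|A|`, and the false-positive rate — a random read
containing all selected k-mers by chance — is `FPR = P(X_read≥1)^E`,
treating per-k-mer occurrences as independent.  `choose_k` evaluates this
on a grid of representative lengths (reads 30/50 kb; targets 0.6/1.5/30 kb,
i.e. barcode-, 16S- and small-viral-genome-sized) and picks the k with the
smallest worst-case FPR; k = 8 and k = 9 are both near-optimal on this
grid and both are supported downstream.

The Monte-Carlo validation fixes the number of selected k-mers at the
model's own expectation, `round(E)` for a 16S-length (1.5 kb) target: a
naive simulation that redraws the selected set per target mixes over the
binomial distribution of the number selected and sits systematically
above the closed form by Jensen's inequality — that discrepancy is a
property of the formula's use of the *expected* exponent, not an
implementation error.  The selected k-mers are redrawn for every read so
the estimate averages over k-mer identity, matching the model's
all-k-mers-equal premise (individual words deviate through their
self-overlap structure: occurrences of periodic words clump, lowering
their containment probability — a bias that compounds with the exponent
and is visible when many k-mers must co-occur).  Under this design the
empirical all-k-mers-present fraction over 10 000 random reads agrees
with the closed form to within three binomial standard errors for
k ∈ {5,6}, read lengths 2/5 kb and library sizes 5/20, quantifying the
Poisson and independence approximations together.

## Detectors

Each detector is a 1D conv net: three valid-convolution blocks
(kernel 9, ReLU, max-pool 2; 8/16/16 channels), global max pooling over
time, and a single sigmoid unit — about 3.6 k parameters against a
library-wide cap of 50 000 (`p_max`).  Global max pooling makes the
posterior position-invariant within the 200-sample input window, and lets
a whole read be scanned by running the convolution stack once and
max-pooling a sliding window-sized span of the feature map (feature
stride 8 samples); this windowed-feature scan is exactly equivalent to
dense window scanning at aligned offsets.  Reads are median/MAD-normalized
before windows are cut, identically at training and scan time.

Training: Adam on binary cross-entropy, minibatch 32, learning rate
3·10⁻³, up to 150 epochs with early stop, Gaussian noise augmentation
(sd 0.08 in normalized units) on every minibatch, and restoration of the
best-validation-loss weights.  Positive windows are jittered around each
ground-truth occurrence span (3 placements); negatives are windows at
least one window-length from any occurrence, subsampled to twice the
positive count.  The whole procedure, including the train/validation
split, is a pure function of the seed.  The size-penalized selection
objective `L = (1−F1) + λ·p_c/p_max` with λ = 0.01 is implemented and
logged per detector; the fixed architecture above plays the role of the
search's winner, and an optional random-search hook can minimize `L` over
architecture variants.

Posterior thresholds are grid-calibrated on validation data over
0.750–0.999 in steps of 0.001 (250 points), maximizing F1 with ties
broken toward the lowest threshold.  For detectors destined for scanning,
the calibration negatives are cut at scanning density from k-mer-free
background reads, so the operating point reflects the extreme class
imbalance a scanning detector actually faces.  Each trained detector also
records a response calibration measured on held-out simulated reads: its
per-occurrence sensitivity and its background occurrence rate per read
(with the read length it was measured at).

## Abundance mode (MSRD)

Detector occurrence counts are summed over all reads; the k-mer set is
ranked by summed abundance (fractional ranks on ties, rank 1 most
abundant) and compared to each candidate genome's reference ranking by
the mean-squared rank difference, `MSRD = (1/N)·Σ(m_obs,n − m_ref,n)²`.
MSRD is 0 iff the rankings coincide and at most `(N²−1)/3` for untied
rankings (at reversal).  The genome with the smallest final MSRD is
called; exact ties are reported as ambiguous, never broken arbitrarily,
and MSRD values are only comparable within one library run.  Observed
counts are not read-length normalized — ranking absorbs overall scale.

Two reference-ranking sources are supported.  The plain source ranks the
genome's k-mer counts (canonical counting), which is appropriate when
detectors approach exactness — the oracle-detector tests use it.  The
robust source, used by the end-to-end study, ranks the *detector array's
own response* to simulated reads of each candidate genome, after
subtracting each detector's calibrated background baseline (scaled to the
amount of signal scanned) and dividing by its sensitivity; the observed
stream is corrected identically.  This choice is forced by measurement at
this noise level: each detector fires spuriously at genome-specific
confusable loci at rates that dwarf low-abundance marker signals, and a
random-read background estimate leaves a genome-dependent residual.
Putting reference and sample in the same corrected response space cancels
detector idiosyncrasies exactly for the true source genome while
preserving between-genome contrast.  The cost is compression of MSRD
contrasts relative to their count-space values; the classification margin
(lowest vs second-lowest MSRD) remains a factor of several in the studies
below.

An optional stability diagnostic reports the read count after which the
MSRD argmin stayed constant for a configurable number of update windows;
no early stopping is performed by default.

## Read-detection mode

Each read is flagged when at least a fraction `f` of the library's k-mers
has at least one detected occurrence in it; comparisons at thresholds are
inclusive (3 of 4 detectors passes f = 0.75 exactly).  The posterior
thresholds and `f` are calibrated jointly on labeled reads by maximizing
read-level F1.  Because independently trained detectors settle on quite
different posterior scales, the posterior dimension of the joint search
is a shared logit offset applied to each detector's own calibrated
threshold (shifted values snapped back to the 0.75–0.999 grid), crossed
with a fraction grid (0.05–1.00, step 0.05); ties break toward the
smaller offset, then the lower fraction, and the winning per-detector
thresholds are written back.  A sample is called positive when the
flagged-read fraction reaches the sample threshold, and flagged reads'
raw squiggles are archived to the signal container for later analysis.

Which k-mers make workable single-read detectors is governed by signal
physics.  A template level in the middle of the current range is swept by
the smoothed signal at almost every segment transition (a transition
between levels a and b passes through everything in between), so
mid-range templates fire on background signal constantly; a level at
table quantile q is crossed by a random transition with probability
2q(1−q).  The `signal_distinctiveness` score sums −log(2q(1−q)+0.05)
over a k-mer's contexts, ranking k-mers whose levels hug the edges of
the current range first.  Even so, realized per-k-mer separability
varies widely, so detection-mode library building trains a surplus of
candidate detectors, measures each one's read-level
sensitivity-minus-background gap on held-out simulated reads (placing
each detector's threshold at its own best gap point on the grid), and
keeps the best.  This selection uses only training-side data.

## K-mer selection

*Discriminative abundance* (abundance mode): profiles are converted to
frequencies with a pseudo-frequency of `1/(total + 4^k)`; each k-mer gets
the signed score `(f_target − mean(f_backgrounds)) / sqrt(pooled mean
frequency)` — a Poisson-stabilized standardized difference.  With only
two or three genomes an empirical across-genome spread is too noisy to
standardize by and lets single-copy background fluctuations outrank
hundred-fold abundance differences; the sampling-noise scale is the
defensible denominator.  The top n is split between over- and
under-represented tails in proportion to their sizes and topped up from
the overall order; ties break lexicographically.

*Evolutionary library design* (detection mode): starting from random
k-mers that pass all hard constraints, 10 rounds propose point mutations
per member on the schedule 5,5,4,4,3,3,2,2,1,1 (dropping by one every two
rounds).  A proposal replaces its member only if (a) its maximum
Smith-Waterman score against the rest stays ≤ 6 under scores
match 1 / mismatch −1 / gap −4, (b) it has no single-base run of ≥ 4 G/C
or ≥ 5 A/T (homopolymer stretch lengths are poorly resolved in signal; a
switch treats {G,C}/{A,T} as combined run groups instead, since the rule
is ambiguous as stated), (c) its abundance over the reference set stays
inside the 10th–90th percentile band of the candidate-pool count
distribution, anchored once at initialization so the filter means the
same thing in every round (both tails removed by default — rare and
ubiquitous k-mers are equally uninformative — with an upper-side-only
switch), and (d) both the minimum
and the mean DTW distance between its simulated squiggle and the other
members' squiggles strictly increase.  DTW uses squared-difference local
cost, full window and symmetric steps on z-normalized noise-free level
sequences.  Rejected proposals are discarded without repair; iteration is
by member index, so the run is a pure function of the seed.  Because only
rows that raise both their minimum and mean are accepted, the logged mean
pairwise DTW of the library is non-decreasing over rounds by
construction, and the output is re-validated by an independent constraint
checker.

## End-to-end synthetic studies

*Abundance (three-genome recovery).*  Three 100 kb genomes carry 12
marker 9-mers (k = 9 chosen because the FPR grid favours k of 8–9 and a
9-mer spans one more pore context) implanted at geometric copy numbers
(base 25, ratio 1.3) into non-overlapping 50-base slots.  Genomes A and B
are sisters — B's backbone is A's with 2% point mutations and its copy
vector has two disjoint distance-4 rank swaps — while outgroup C has an
independent backbone and the copy vector reversed.  Markers are
homopolymer-clean, mutually dissimilar (pairwise SW ≤ 6) and canonically
distinct; selection runs on the genome profiles and the selected set is
greedily filtered for mutual dissimilarity, because implanted repeats
make their shift-by-one neighbours discriminative too and near-duplicate
detectors add no information.  Detectors are trained per selected k-mer
on simulated squiggles; each of three 500-read streams (read length
1200 ± 300 bases) is classified against all three corrected-response
reference rankings.  Expected outcome, asserted by the tests: every
stream's source genome attains the strictly minimal MSRD, and on the two
sister streams the non-source sister scores below the outgroup.

*Read detection (amplicon vs background).*  A synthetic 1.5 kb amplicon
supplies 24 candidate 9-mers (signal-distinctiveness-ranked, mutually
dissimilar); each candidate detector is trained on occurrences embedded
in their native amplicon context, given a read-level threshold on
held-out reads, and the 16 with the best read-level gaps form the
library.  Amplicon reads are simulated in a fixed orientation with small
random end truncations, as in a directional amplicon/cDNA protocol —
detectors are strand-specific, and a mixed-orientation protocol would
simply pair each k-mer detector with its reverse-complement twin.  After
joint calibration on a labeled 60-read mixture, performance is measured
on a fresh 50/50 mixture of 60 reads; the tests require read-level
F1 ≥ 0.9 and verify that flagged squiggles round-trip through the signal
container.

Problem sizes (100 kb genomes, 500-read streams, 12 + 8 detectors,
10 000-read Monte-Carlo batches) were chosen so the statistics above are
comfortably resolvable on a single CPU core; the acceptance script runs
the identical studies from scratch at the same sizes.

## Numerical choices and degenerate inputs

Ranks use scipy's fractional (average) ties so rank sums are fixed at
N(N+1)/2, bounding MSRD.  Degenerate calibration posteriors (all equal)
return the grid minimum with a warning; single-class validation sets are
errors.  Reads shorter than a detector's window scan as zero occurrences
with a short-read flag; a read shorter than every window is flagged
negative.  Percentile filtering on an all-equal count distribution
retains everything.  DTW on constant sequences z-normalizes to zeros
(distance 0 to any other constant sequence).  The signal containers
(HDF5 or NPZ) store float32 samples, so round trips are bit-exact.
All randomness flows from explicit integer seeds through
`numpy.random.Generator`; no global state is used.

## Known limitations

The simulator's uniform level table overstates level collisions relative
to a real pore (real 6-mer tables are structured), so per-window detector
F1 here (0.55–0.75) is pessimistic in one respect while the absence of
drift and stalls is optimistic in another.  The abundance mode's
corrected-response referencing requires candidate genomes at
configuration time (as does k-mer selection itself).  Detectors are
strand-specific.  The FPR model treats k-mer occurrences as independent;
the Monte-Carlo section above measures the size of that approximation
rather than correcting it.
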