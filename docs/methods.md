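# Methods

`motifbench` re-implements a cross-platform benchmarking stack for
transcription-factor (TF) sequence motifs: given position matrices from any
discovery tool and experimental data from five assay families — ChIP-Seq
(CHS), genomic HT-SELEX (GHTS), HT-SELEX (HTS), SMiLE-Seq (SMS) and
protein-binding microarrays (PBM) — it measures how well each motif
separates bound from unbound sequences, aggregates the measurements into a
single ranking, filters recurrent artifact motifs, and combines several
PWMs into a random-forest site predictor (Archipelago).  Every consumer of
real data has a seeded synthetic twin, so the full stack runs end to end at
desk scale.

## Motif models and the log-odds transform

Motifs are positional matrices over A,C,G,T: counts (PCM), frequencies
(PFM) or additive log-odds weights (PWM).  Frequencies multiply across
positions (occupancy semantics); weights add (hit-scoring semantics).
PFMs are converted to PWMs by

    count_ij   = count * freq_ij
    pseudocount = log(max(2, count))
    pwm_ij     = log((count_ij + 0.25 * pseudocount)
                     / (0.25 * (count + pseudocount)))

with `count = 100` for tools emitting normalized PFMs and the true aligned
word count for tools emitting counts.  **Logs are natural.**  The base is
not fixed by the transform's definition; every downstream use is rank- or
threshold-based, so the choice rescales all scores by one global constant
and affects nothing that is reported.  The uniform column maps exactly to
zero weights for any `count`, and the transform is strictly increasing in
`freq_ij`.

Motif feature summaries follow the usual definitions: per-position
information content `2 + sum_b f_b log2 f_b` in bits (with `0 log 0 = 0`)
and GC fraction as the positional mean of `f_C + f_G`.

## Sequence scoring

Two scanners, both double-stranded, both skipping windows that overlap
non-ACGT characters:

* **sum-occupancy** — the sum over all valid windows on both strands of the
  product of window frequencies, a soft multi-hit affinity proxy used by
  the classification benchmarks.  Zero frequencies would annihilate
  products, so frequencies are regularized as `(f + eps) / (1 + 4 eps)`
  with `eps = 1e-4`; the uniform column is a fixed point of this map, so a
  flat motif scores identically for any epsilon and rankings are stable in
  the regularizer.
* **best hit** — the maximal additive log-odds window score, with ties
  broken by the smaller position and then the forward strand.  Sequences
  with no valid window return an explicit sentinel.

Synthetic-ligand platforms expose constant sequence next to the variable
region (HT-SELEX/SMiLE-Seq primers and barcodes, the PBM linker), and
binding sites may straddle the boundary; `scan_with_flanks` scores the
concatenation.  The PBM benchmark prepends exactly the first 6 bases of the
static linker.

## Score distributions, P-values and pseudo-auROC

The exact PMF of the one-window PWM score under a mono- or dinucleotide
background is computed by dynamic programming on a discretized grid: every
matrix cell is multiplied by the discretization `d` and floored to an
integer bin, and the DP convolves per-position bins (for order-1
backgrounds the DP state carries the previous base; the chain starts from
the stationary mononucleotide vector).  The grid **defines** the score
scale: wherever an observed scanning score is converted to a P-value, the
scan uses the grid-quantized weights so that lookups are self-consistent
(floor-of-sum and sum-of-floors differ otherwise).  `d = 10` follows the
artifact-filter convention; sequence-level machinery uses `d = 100` so the
small tail probabilities entering 300-bp best-hit P-values are resolved.

The sequence-level best-hit P-value uses the independence approximation
over the `2(L - w + 1)` window/strand combinations,
`1 - (1 - p_win)^(2(L-w+1))`.  Overlapping windows are positively
dependent, so the approximation overestimates in the dense regime
(`p_win` around 1e-2 and above); Monte-Carlo tests validate it in the
regime it is actually used (windows at or below ~1e-3).

The **pseudo-auROC** of a motif on a positive set is `1 - mean(u_i)`, where
`u_i` is the best-hit P-value of positive `i` at its own length under an
order-1 background fitted from the positive set itself.  When the false
positive rate at P-value threshold `alpha` is `alpha` (null uniformity),
this equals the area under the ROC curve; a threshold-sweep integration is
asserted against the closed form in the tests.  Positives are the first up
to 1000 test peaks in chromosome/coordinate order, standardized to summit
±150 bp.

## Benchmark protocols

Train/test separation is a complete chromosome holdout for genomic data
(odd-numbered autosomes train, even test; at least 50 test peaks for
benchmarking, 50 training peaks for discovery) and a seeded 2:1 read split
per SELEX cycle, pooled afterwards.

* **PBM**: positives are probes above mean + 4 sd of normalized intensity
  (SD track) or Z > 4 (QNZS track), falling back to the top 50 probes when
  fewer pass; scores are sum-occupancy with the 6-bp linker prefix.
* **Peaks**: up to the top 1000 test peaks by signal give 250-bp positives
  `[summit-124, summit+126)`; each positive contributes two negatives — the
  same window shifted ±300 bp ("shades") — leaving a 50-bp gap so the sets
  never overlap.  Windows running off a contig are dropped.
* **Reads**: cycles pooled, reads deduplicated, at most 500,000 sampled;
  the top 10%, 25% or 50% by the tested motif's own flanked sum-occupancy
  score become positives.  The protocol family leaves the negative set
  unprinted; this implementation uses seeded dinucleotide-shuffled copies
  of every sampled read (Altschul–Erickson Eulerian-path shuffle, exact
  dinucleotide counts preserved).  Because positives are defined by the
  tested motif itself, absolute auROC is inflated uniformly across motifs;
  the quantity is meaningful for ranking, which is how it is consumed.

auROC is computed in the Mann–Whitney form (ties at half weight), auPRC as
the step-interpolated precision sum over distinct thresholds; both are
checked against brute-force oracles to 1e-12.

## Rank aggregation and harmonization

Within each TF, motifs are ranked (fractional ranks, rank 1 best) per
metric inside every (dataset, benchmark, variant) leaf, then combined by
geometric mean of ranks followed by re-ranking, climbing metric → variant →
benchmark → dataset/replicate → experiment type → global.  Remaining ties
break lexicographically by motif id so orderings are reproducible.  A motif
missing any leaf within a TF's table is excluded from that TF's aggregation
with a logged reason rather than imputed.

Harmonization rescales raw metric values to [0, 1] by min–max within each
(TF, dataset, benchmark, metric) scope; degenerate scopes (all values
equal) map to 0.5.  Overall platform performance is the mean harmonized
value across the platform's metrics and datasets.

## Artifact filtering

Recurrent platform artifacts are removed in two ways.  The **catalog
filter** compares each motif to artifact matrices by the Jaccard index of
high-scoring word sets: each matrix admits words above its own P = 5e-4
threshold (uniform background, `d = 10`); at every relative shift and both
orientations, the matrices are extended to the common span with free
columns that accept any base, and |A∩B| is counted exactly by a joint-score
DP that prunes partial states which can no longer cross (or can no longer
miss) either threshold — counts stay exact integers.  The maximal Jaccard
over alignments at or above 0.15 removes the motif.  The similarity is
symmetric and invariant to reverse-complementing either argument.  For
matrices too short for any threshold to reach P = 5e-4 (a 5-mer's consensus
already has P ~ 1e-3), the word set falls back to the top score bin so it
is never empty and self-similarity stays 1 for all lengths.
Family-specific exemptions (positive-control TFs) are an explicit
allow-list, not hardcoded biology.

The **flank filter** removes motifs whose best hit inside the constant
primer/barcode flanks reaches a window P-value below 1e-4 — i.e. the motif
matches the ligand scaffold.  Flanks are joined with runs of N so no
window straddles two flanks.  Datasets of the GFP-tagged IVT design are
exempt.  The printed phrase "scoring below P-value 1e-4" is read as
*stronger than* P = 1e-4 (small P-value = strong match).

## PBM normalization

* **QNZS**: log2 intensities are quantile-normalized across replicate
  arrays (tied values receive the mean of their tied quantile values), then
  each probe is Z-scored with its own mean/sd across arrays.  Probes with
  zero cross-array variance get NaN and a flag rather than a silent 0.
* **SD**: spatial detrending divides each probe by the ratio of its 11×11
  neighborhood median (unflagged probes only, windows truncated at edges)
  to the global median — a multiplicative model, following the DREAM5-era
  practice the procedure cites.  Whether the original variant divides or
  subtracts is not printed; multiplicative is the committed choice.
* **SDQN**: detrending followed by quantile normalization.

Note one subtlety the tests document: detrending creates exact ties (a
probe equal to its own window median lands exactly on the global median),
so after tie-averaged quantile normalization the shared sorted vector is
identical only up to those ties.

## Archipelago

For a TF with peaks from two genomic platforms, peak sets are merged
(overlapping intervals unioned, summits averaged with floor rounding) and
301-bp positives are cut at the merged summits.  Three negative sets:
GC-matched random genomic regions (1:100 per positive), GC-matched "alien"
peaks of other TFs (1:100, all taken unmatched when unachievable) and
"shades" with summits uniform in ±[450, 750] bp of the true summit (up to
1:2, fewer when exclusions bite).  GC matching draws negatives from the
positives' GC histogram in 2% bins (bin width unstated upstream; 2% is this
package's choice).  All negatives avoid the positives' whole peaks, any
provided blacklist, and N-containing windows.

Features are per-sequence best-hit log-odds scores of a PWM panel that
excludes motifs discovered from the test platform (a hard error otherwise).
Sequences without a valid window take the panel matrix's minimum possible
score minus 1, preserving order without missing values.  Features are
standardized with statistics fit on training data only (train-only is the
leakage-safe reading of an unprinted detail), and a random forest with the
fixed hyperparameters `max_depth=6, max_samples=0.8, n_estimators=100` is
trained on the random-negative set, then evaluated with auROC/auPRC against
all three negative sets plus their mean.  Gains are reported against the
auROC-best and auPRC-best single PWMs separately (possibly different
motifs), with `average_gain` their mean; motifs are ranked by impurity
feature importance.  A logistic-regression comparator sits behind the same
interface.

## Synthetic data

The generators produce every input the stack consumes, bit-reproducibly
from (config, seed):

* **genome** — iid bases at a target GC, or an order-1 chain (previous base
  repeated with probability 0.3) so dinucleotide backgrounds are
  non-trivially exercised; chromosomes named chr1..chrN so parity splits
  apply.
* **peaks** — one site per peak sampled from the motif (a mixture over
  modes for multi-mode TFs), written at the summit plus an optional
  Normal jitter; the narrowPeak signal is the site's log-odds score plus
  noise.  Candidate events are oversampled 1.5x and only the top-signal
  events become peaks, emulating the detection bias of peak calling (weak
  binding events exist in the genome but are not called).  Planted summits
  keep at least 1 kb spacing so one peak's shade windows never cover
  another peak's site.
* **SELEX** — cycle 0 is a random 40-mer pool; each cycle resamples the
  previous pool with probability proportional to flanked sum-occupancy
  raised to the selection strength.  This is a minimal enrichment model (a
  stand-in, not a biophysical claim); strength 0 reduces to uniform
  resampling.  The default flank/barcode constants follow the published
  HT-SELEX ligand design.
* **PBM** — a 50×50 grid (2,500 probes) of 36-mers, a configurable fraction
  carrying a sampled site; intensity = baseline × smooth diagonal trend ×
  (1 + gain × occupancy) × lognormal noise.  Besides the signal replicates,
  30 background arrays share the design but carry no signal for the motif:
  they stand in for the other experiments on the same array design that
  per-probe Z-scoring normalizes against.  The count matters — the Z-score
  of one probe across n arrays is bounded by (n−1)/√n, so with only a
  handful of arrays a genuinely bound probe cannot stand out.
* **decoys** — column-shuffled (exact column multiset, same length and IC),
  dinucleotide-shuffled-consensus near-one-hot, or fresh Dirichlet motifs.

The reference planted motif is a 10-mer at 90% consensus (~12.7 bits), the
information content of a typical specific TF; the two-mode TF adds a
dissimilar GC-rich 10-mer.  What the generators do **not** emulate:
chromatin context, repeats and copy-number structure, sequencing error,
PCR amplification bias, probe secondary structure.  Passing tests therefore
demonstrate the correctness and discriminative behavior of the protocols on
data with planted ground truth, not performance levels on real corpora.

## Problem sizes and numerical choices

Experiments run at desk scale, chosen so the full suite completes on one
CPU: 4 chromosomes of 120–300 kb, 200–500 peaks, 1,000 reads per SELEX
cycle over 3 cycles, 50×50 PBM grids, and a 1:25 negative ratio for the
Archipelago experiments (the 1:100 protocol ratio is kept as the library
default; the reduced ratio changes class balance, not the protocol).  The
ranking-recovery experiment uses 20 seeds; the Archipelago gain is a sign
test across 20 seeds (two binding modes) and a 5-seed mean (single mode).

Degenerate inputs are handled explicitly: sequences shorter than the motif
score 0 (occupancy) or the no-hit sentinel (best hit); empty score classes
raise naming the class; all-equal harmonization scopes map to 0.5;
zero-variance QNZS probes are flagged; fully flagged detrending windows
flag the probe.  All randomness flows through `numpy.random.default_rng`
seeds; re-running any generator or experiment with the same seed reproduces
its output bit for bit.

## Known limitations

* The sequence-level P-value ignores overlap dependence between windows;
  calibration degrades for very permissive thresholds (documented and
  bounded by Monte-Carlo tests).
* The reads benchmark's PWM-dependent positive definition inflates absolute
  auROC; only relative comparisons between motifs are meaningful.
* The occupancy scorer weighs flank-overlapping windows like any other
  window; the upstream protocol's exact flank weighting is unprinted.
* Artifact-filter overhang columns accept any base on both matrices; this
  free-column convention is validated against the internal enumeration
  oracle only.
* Dataset-counting conventions for sequencing replicates are left to the
  caller: the benchmark table schema supports treating technical replicates
  as separate datasets or merging them.
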