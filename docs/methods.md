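# Methods

## The screening problem

A transposon mutagenesis screen mobilises a DNA transposon (here modelled
on piggyBac) in a sensitised tissue; each resulting lesion carries a
private set of genomic insertions, recovered by splinkerette PCR from
transposon–genome junctions. Loci hit in more lesions than chance allows —
Common Insertion Sites — nominate driver genes. The statistical task is to
distinguish genuine recurrence from the artefacts the protocol creates:
PCR duplicates at jittered coordinates, reads internal to the transposon,
low-complexity read support, and the strong excess of insertions near the
donor concatemer ("local hopping").

## Read processing

Reads are `barcode + transposon tag + genomic fragment [+ adaptor]`.
Barcode and tag matching is prefix-anchored Hamming distance with a
configurable mismatch budget (default 1); indels are not modelled because
the primers fix these elements at constant offsets. A read matching zero
or ≥ 2 barcodes is unassigned — conservative, preventing cross-sample
bleed-through. After tag removal, an exact adaptor hit truncates the read;
fragments that remain (near-)exact substrings of the transposon sequence
are discarded as internal amplification products. No quality trimming is
performed; qualities are carried through untouched. The restriction site
(default GATC, Sau3AI) is recorded as metadata only: sequencing frequently
ends before the adaptor, so fragments are not required to terminate in it.

## Sites

The integration coordinate is the junction-proximal alignment end:
leftmost aligned base for `+` alignments, rightmost for `-`. Calls are
collapsed per (lesion, chromosome, position, orientation); read counts are
group sizes. Merging then chains sites of one lesion/chromosome whose
consecutive gaps are ≤ 5 bp (inclusive, transitive single linkage): PCR
duplicates of one integration reappear within a few base pairs, and
single-linkage is the closure of "within 5 bp of each other". The merged
representative is the member with the highest read count (leftmost on
ties) — deterministic and favouring the best-supported coordinate — with
counts summed. Opposite orientations do merge (a duplicate can be
recovered from either primer); each such event is logged. Merging is
idempotent, order-invariant, and read-count-conserving; these are tested
against an exhaustive union-find oracle.

Two filters follow, in order: donor-chromosome exclusion (always advisable
for CIS statistics) and an optional strictly-greater read-depth rule
(keep read_count > 10). The read filter defaults OFF for CIS calling and
is intended ON for candidate gene lists — screens typically call CISs on
all merged sites but report per-gene candidates only at > 10 reads.

## Gaussian kernel convolution

Density per chromosome and kernel width h:
`f_h(x) = Σ_i exp(−(x − x_i)²/(2h²))`, unit weight per merged site.
The kernel is deliberately unnormalized so heights are effective site
counts; any normalisation would cancel in the permutation test anyway.
Per-site weight is 1 regardless of read count: lesion support is reported
(`n_lesions`) for triage rather than used to down-weight.

Evaluation is on a regular grid from `min(x)−4h` to `max(x)+4h` with step
h/10 by default, truncating each kernel at ±8h where its contribution is
below 1.4e-14 — numerically indistinguishable from full summation (tested
to 1e-9 against a brute-force oracle). The grid underestimates a continuous
peak by at most a factor `exp(−step²/(8h²))` for a single site (the true
maximum lies within step/2 of a grid point); at the default step this is
below 0.04 %.

Null model: positions are re-drawn uniformly on [1, chromosome length],
conditioned on the observed per-chromosome site count; each permutation
records the chromosome-wide maximum of f_h. The threshold at level α is
the ⌈(n_perm+1)(1−α)⌉-th order statistic of the maxima, and an observed
local maximum's p-value is `(1 + #{null maxima ≥ height})/(n_perm + 1)` —
the add-one estimator, never exactly zero. Because every local maximum is
compared against the distribution of the chromosome-wide maximum, the test
controls the family-wise error within a chromosome; with 199 permutations
at α = 0.05 the realised per-chromosome false-positive rate is 9/200 =
0.045 (verified by a 200-screen null simulation in the test suite).

The CIS window is the maximal contiguous grid run around the peak with
density at or above the α-threshold height; supporting sites and distinct
lesions are counted inside it. Scanning runs at h ∈ {10, 30, 100} kb by
default — spanning the window magnitudes at which screen clusters are
accepted (tens of kb) or doubted (hundreds of kb) — and overlapping
windows across scales merge, represented by the smallest-p (then
smallest-h) member with full provenance kept. A uniform null is an
approximation: real insertion density varies with chromatin and TTAA
availability, so empirical calibration on real data may be anti-
conservative in open chromatin. TTAA-site snapping is not modelled;
positions are free integers.

## Annotation and triage

"In a gene" means within the full transcriptional span (introns included),
`start ≤ pos ≤ end`, assigned to *all* overlapping genes; relative
orientation is transposon strand vs gene strand. CIS windows list
overlapping gene bodies; a window in a gene desert reports the single
nearest gene with its distance from the CIS peak (peak rather than window
edge — a decision left open by convention, configurable in principle).

Triage flags: `low_read_depth` iff **no** supporting site exceeds 10 reads
(one strong site clears the flag); `large_span` for windows above 100 kb —
an explicit package default sitting between the spans screens accept
(~20 kb) and reject (115–340 kb), reported alongside raw spans so users
can re-cut; `multi_gene`; `blacklisted` (default blacklist {Nav2}, a
recurrent transposon-screen false positive, user-extensible);
`single_lesion` when enabled. A call is strong iff flag-free (multi_gene
alone may be tolerated via `lenient_multi_gene`).

## Signature scores

Score_j = Σ_g z_gj over signature genes, z computed across **all** samples
of the provided matrix with population SD (divisor n; the score is
descriptive scaling, and the divisor choice is documented because neither
convention is universal). Genes missing or constant are dropped and
reported. Scores therefore sum to zero over the cohort — an invariant the
tests assert to 1e-9. Stratified analyses re-use these full-matrix
z-scores; to re-standardise within a stratum, pass the subset matrix.

Median split: strictly above the median is "high", at or below is "low" —
a deterministic tie rule chosen because "higher/lower than median" leaves
ties unspecified. Spearman correlation uses mid-ranks; p-values by exact
enumeration of all pairings for n ≤ 10 and the t-approximation
`t = ρ√((n−2)/(1−ρ²))` otherwise. Group comparison is Welch's unequal-
variance t-test (safer than pooled when an "unpaired t-test" is wanted),
with explicit handling of zero-variance degeneracies.

## Synthetic data

`sim_screen` states one generative world per stage:

* **Insertions** — per lesion and chromosome, background counts are
  Poisson(rate × length/1 Mb) with uniform positions (default 0.05/Mb per
  lesion, giving a median of a few well-supported sites per lesion at
  mouse-genome scale, matching the sparse screens this pipeline targets);
  planted clusters place a stated number of insertions uniformly in a
  stated window across a random subset of lesions (each carrier gets ≥ 1);
  local hopping adds Poisson(2)/lesion insertions in a ±2 Mb hotspot
  centred at the donor-chromosome midpoint (centre configurable; the
  hotspot's true position in a real screen is the concatemer locus);
  duplicates spawn with probability 0.1 at a uniform ±1..5 bp offset,
  never 0, so merging is always exercised. Read counts are negative
  binomial (mean 50, size 2) with a 0.2-probability low-depth contaminant
  drawn uniformly from 1..9, so the > 10-read rules have something to
  remove. Lesions are generated independently — real screens couple
  lesions within one animal, which is not modelled.
* **Reads** — barcode + tag + fragment (+ adaptor) over an i.i.d. random
  genome materialised only here; fragment lengths are truncated normal
  (default 80 ± 15, min 25), substitution errors optional. Truth records
  each fragment's exact interval. No indels, no Ion-Torrent-specific error
  structure, no insertion-sequence bias.
* **Expression** — the target gene and m signature genes load a shared
  latent N(0,1) factor with common loading a plus N(0, σ²) noise; other
  genes are pure noise. The implied population Pearson correlation between
  target and score is `m a² / √((a²+σ²)(m²a²+mσ²))`, converted to Spearman
  via the bivariate-normal identity ρ_S = (6/π)·asin(ρ_P/2);
  `loading_for_spearman` inverts this numerically, which is how worlds
  with a stated population ρ_S (e.g. 0.6) are constructed. Real cohorts
  have correlated "background" genes, batch structure and non-Gaussian
  tails; a green recovery test establishes estimator correctness under the
  stated model, not robustness to those.

All generators are deterministic in (seed, config).

## Numerical and degenerate-input choices

* Permutation count must be ≥ 19 so α = 0.05 is attainable; 999 default,
  199 in the heavier simulation tests (budget, not calibration).
* Empty site lists yield empty tracks/calls, never errors; malformed
  alignment or annotation lines are logged and skipped, but a gene file
  yielding zero genes is an error.
* Spearman on a constant vector, signature scoring with one sample or no
  present genes, and group tests with < 2 samples per group raise
  `ValueError`; zero-variance t-tests return the documented limits
  (t = 0, p = 1 for identical constants; p → 0 flagged degenerate
  otherwise).
* Coordinates are 1-based inclusive in memory and in TSV output; BED I/O
  converts to 0-based half-open.

## Known limitations

The uniform permutation null ignores sequence-driven insertion bias; the
analytic GKC significance of the original kernel-convolution literature is
not implemented (permutation only); paired-end data, multi-mapping rescue
and junction indel refinement are out of scope; and the triage span/read
thresholds are screen conventions, not fitted quantities — they are
exposed as configuration for exactly that reason.
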