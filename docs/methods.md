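# Methods

This note documents the models, conventions, and parameter choices behind
`pirnasig`, and what the synthetic-data tests do and do not demonstrate
about real libraries.

## Read preparation and alignment

Small-RNA reads are 3′-trimmed and collapsed to *species* — unique
post-trim sequences with occurrence counts. Two trim modes exist because
library protocols differ: `fixed3p` (default) removes a fixed 30-nt suffix,
appropriate when the sequencing length leaves the adapter as a
constant-length tail; `adapter` removes everything from the first match of
the adapter's leading 8 nt, appropriate for variable-length inserts.
Post-trim sequences shorter than 15 nt are dropped.

Alignment is exact full-length matching of each species (and its reverse
complement, recorded as strand −) against every panel sequence, via a
15-mer seed index with base-for-base verification; 15 nt is also the
minimum accepted species length. Exact matching is sufficient because the
quantification model excludes non-perfect mappings anyway; a
`max_mismatches > 0` brute-force path and a SAM/BAM import (primary +
secondary records as locations) exist for users who want an external
aligner. "Locations" for multimapper apportioning are all perfect-match
locations across the supplied panel — no separate genome is consulted. A
species with count c and n locations contributes weight c/n at each, so
summed weight equals aligned read count exactly; weights are doubles and
conservation is asserted at 1e-9 relative tolerance.

Coordinates are 0-based half-open throughout (SAM import converts; BED is
native). End profiles store summed weights of 5′ and 3′ ends per
(reference, strand) in *transcript orientation*: on the − strand position p
maps to L−1−p, so within-strand distances read left-to-right along the
piRNA regardless of strand.

## Signature statistics

All distance histograms are weighted pair counts: a pair of end positions
(a, b) adds weight(a)·weight(b) to its integer distance bin; pairs never
cross references, and per-reference histograms are summed before scoring
(a library-level score; per-reference scoring uses the same primitives).
Product weighting follows from enumerating all location pairs of
apportioned alignments.

Distance conventions are chosen so canonical events score the textbook
values exactly:

- ping-pong 5′–5′: d = antisense5′ − sense5′ + 1 in reference coordinates;
  a 10-nt 5′ overlap gives d = 10;
- phasing 3′→5′: d = 5′(downstream) − 3′(upstream) − 1 in transcript
  orientation; a head-to-tail junction gives d = 0;
- phasing 5′–5′: d = 5′(down) − 5′(up); consecutive ~27-nt phased reads
  give peaks near 27, 54, 81.

Z scores treat empty bins as zeros and use the sample (n−1) standard
deviation — the denominator convention is not fixed by the literature, so
it is stated here and kept consistent. Z₁₀ scores bin 10 against
backgrounds {1–9, 11–20}; Z₀ scores bin 0 against {−10…−1} ∪ {1…50}. A
zero-variance background leaves the score flagged undefined rather than
infinite. Both scores are invariant under uniform scaling of counts and
under translating all alignments, which the tests assert.

Peak metrics for the 5′–5′ histogram: peak k is the argmax within
k·period ± tolerance (default 27 ± 2); the baseline is the mean over
distances strictly between peaks 1 and 2 excluding ± tolerance around
each ("the valley"); peak height is peak 1 minus baseline. The valley
definition is an implementation choice — the quantity is only used
comparatively.

Nucleotide biases use the binary species selector: a species is eligible
if its count within the scope is ≥ 5 (default), and scores 1 if it carries
the queried base at the queried 1-based position (U ≡ T), else 0 — species
shorter than the position are eligible non-hits. Percent = 100·hits/
eligible. Scopes are sense (≥1 + alignment), antisense, and both; the
IP-restricted variant intersects the sample with one IP-assigned group
first. Statistical comparison of bias percentages between genotypes is
done by a two-proportion test on the selector counts rather than a
count-model GLM; the selector itself is unchanged.

## Quantification and differential expression

pkb = weight·1000/length; rpkm = weight/(length_kb · mapped-millions).
piRNA-level analyses apply the ≥ 5-count species filter before summing;
RNA-level tables do not.

Normalization is median-of-ratios (per-feature geometric mean over
samples, using features with no zeros; size factor = per-sample median of
count/geomean), falling back to total-count scaling with a warning when no
feature is zero-free. The DE engine tests log2(normalized + 0.5) with a
two-sided Welch t (or a label-permutation null of the same statistic,
exact over all label splits when few), adjusts with Benjamini–Hochberg,
and calls up/down at p-adj ≤ 0.05 and |log2FC| ≥ 0.58 by default;
log2FC = log2((meanB+0.5)/(meanA+0.5)). The 0.5 pseudocount is a
conventional choice for count data. Features with all-zero counts are
dropped before testing. A pure fold-change mode (2-fold cutoff, no test)
serves strand-level piRNA comparisons, where per-strand tables must *not*
be renormalized: a uniform strand suppression would be absorbed by
within-table size factors, so depth-matched libraries are compared on raw
apportioned counts.

## Interaction analytics

GI score = FC_double / (FC_single1 + FC_single2) on linear fold changes
against the shared control, read literally as a ratio (an alternative
excess-over-baseline reading, FC−1 in the denominator, is *not* the
default). GI > 1 marks super-additive de-silencing; GI > 2 is the strong
flag. Quadrants: long iff log10(length) ≥ 3.7 (~5 kb), high iff
log10(rpkm) ≥ 1.0 (10 rpkm), boundaries assigned upward (tie handling is
unstated in the conventions this follows; upward is the documented choice
here); control-genotype rpkm defines expression. Distribution percent is a
quadrant's share of all de-silenced TEs; density percent is de-silenced /
total within the quadrant. Concomitant groups over TEs whose both-strand
piRNAs fell ≥ 2-fold: group 1 if sense fell ≥ 2-fold more than antisense,
group 3 for the mirror case, group 2 otherwise. IP assignment normalizes
the three IP libraries to counts-per-million (depths differ and no
normalization is prescribed; CPM is the minimal choice), adds a 0.5
pseudocount, and assigns a species to a protein iff its CPM is ≥ 3-fold
both others — groups are disjoint by construction and shrink monotonically
in the fold threshold.

## The synthetic generator

The generator emulates a *Drosophila* ovary small-RNA library at the level
the statistics consume; it is the test substrate, not a biological model.

- **Panel**: iid uniform ACGT sequences, lengths log-uniform in [500,
  5000] nt by default; a configurable fraction of TE pairs share one
  copied 60-nt segment as multi-mapping bait.
- **Ping-pong pairs**: sense 5′ at s, antisense 5′ at s+9 (reference
  coordinates) — a 10-nt overlap by construction. The sense-read placement
  realizes the 10A bias: a coin with probability `a10_prob` (default 0.65,
  the Ago3-bound level) decides whether position s+9 must be an A, and the
  position is sampled from the matching base class. Because the antisense
  partner's first base is the complement of that A, the 10A bias induces
  the antisense 1U automatically, as in the real cycle.
- **Phased trails**: geometric trail lengths (mean 6 reads), head-to-tail
  (next 5′ = previous 3′ + 1). Trail starts realize the 1U bias (default
  `u1_prob` 0.78, the TE-mapped level) by conditional position sampling.
  At junctions the 5′ position is fixed by the upstream read's length, so
  the bias is imposed through length choice among 23–28 nt; the junction
  coin probability is solved in closed form from the uniform background
  base frequency (`_junction_coin_prob`) so the realized marginal equals
  the target even though ~(3/4)^6 of junctions admit no U start. Biases
  are therefore imposed purely by placement — reads stay perfect matches.
- **Lengths**: planted reads round a normal(26.5, 1.5) clipped to [23,
  28]; noise reads use sd 3.0 clipped to [19, 35], populating the tails
  of the 19–35 reporting histogram.
- **Depth**: `n_reads` counts reads including duplicates; each planted
  read receives 1 + Poisson(`copies_mean` − 1) copies (default mean 8),
  giving a count spectrum that straddles the ≥ 5-count eligibility rule.
  Genotype effects scale pathway fractions (slack renormalizes into
  noise) and thin reads per strand.
- **Count tables**: per-TE expression is log-normal in rpkm (median 10,
  log-sd 1.5), independent of length; mean counts = rpkm × length_kb ×
  mapped-millions with a 2×10⁷ non-TE background read pool, so `.rpkm()`
  recovers the planted levels on a realistic scale. Replicates are
  gamma-Poisson with variance μ + αμ² (default α 0.05–0.1; α = 0 is
  Poisson).
- **IP libraries**: ping-pong sense species are "Ago3-bound", ping-pong
  antisense "Aub-bound", phased "Piwi-bound"; the bound protein's library
  sees 10× the base abundance, Poisson-sampled.

What passing tests show — and do not. The generator plants each signature
in its pure geometric form: real libraries have sequencing errors, partial
3′ trimming, genomic piRNA clusters with nested repeats, mismatched and
clipped alignments, and biological correlations between pathways that the
generator omits (no UMI handling, no error model, no realistic repeat
structure). Recovery tests therefore validate the *statistics and their
conventions* — that the scores measure what they claim, conserve weight,
and respond monotonically to planted signal — not pipeline robustness to
real-data artifacts.

## Numerical and design choices

- Histogram computation is an offset sum over position dictionaries,
  verified bin-for-bin against O(n²) pair enumeration at 1e-9 relative
  tolerance.
- Self-pairing of a location with itself is excluded when both ends of a
  pair come from the same profile and end; with the shipped windows this
  term never lands in-window, but the guard keeps the definition correct
  for custom windows containing the zero-offset bin.
- Determinism: every stochastic component takes a seed; derived seeds stay
  below 2³¹; identical configs reproduce byte-identical outputs (asserted
  on file digests in the pipeline tests).
- Problem sizes in tests and the acceptance script (20–200 TEs, 20k–100k
  reads, 3 replicates) were chosen as the smallest sizes at which the
  binomial/Z-score error bands in the checks are comfortably resolved.
- The pipeline's default four-genotype study (control; a strong ping-pong
  knockdown; a milder mutant that also thins sense reads; their double
  mutant) encodes a qualitative WT → single → double signature collapse;
  the suppression factors are illustrative conditions, not fitted values.

## Known limitations

- Exact matching only (by design); highly diverged TE copies would be
  missed where a mismatch-tolerant aligner would place them.
- Apportioning is panel-relative: reads that would multimap to the genome
  outside the panel are treated as unique to their panel locations.
- Z₀ saturates: it detects the presence of head-to-tail geometry, not the
  abundance of phased reads, so moderate suppression of the phased
  fraction leaves Z₀ high while pkb levels drop (visible in the default
  cohort report).
- The Welch-on-log2 DE engine is conservative at n = 3 replicates compared
  with shrinkage-based count models; its null calibration (FPR ≤ 0.05) is
  asserted, its power at small n is not claimed.
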