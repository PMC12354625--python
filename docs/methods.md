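# Methods

This note documents the models, parameters and numerical choices behind
`scatdiet`, and what the synthetic validation does and does not demonstrate
about real data.

## The analysis model

A scat sample is a mixture of amplicons: host template, prey templates,
human contamination and positive-control spikes, observed through
sequencing noise (substitutions) and PCR artifacts (bimeras). The pipeline
recovers the mixture composition in two phases — sequence cleaning, which
estimates the set of true templates and their read counts, and taxonomic
inference, which maps templates to taxa and taxa to diet summaries.

### Sequence cleaning

*Dereplication* is exact: two reads belong to one cluster iff they are the
same string (length is therefore part of identity). Clustering pools reads
across samples while keeping per-sample membership counts; pooling matches
the single shared reference-database comparison that follows and gives rare
taxa the best chance of clearing the minimum cluster size of 3 reads.

*Denoising* follows the published UNOISE abundance-skew rule. With
α > 0 (default 2) the threshold β(d) = 1 / 2^(αd + 1) is strictly
decreasing in the edit distance d; a candidate cluster of size s merges
into the first accepted centroid of size S (processing in decreasing-size
order, ties broken lexicographically by sequence) whenever s/S ≤ β(d).
Distances are Levenshtein rather than Hamming so that rare indel slippage
does not block a merge; the distance cap implied by the skew rule
(d ≤ (log2(S/s) − 1)/α) is passed to the aligner, which keeps the pass fast
even with thousands of clusters. The skew test uses the centroid's
accumulated size, which only ever loosens a merge already sanctioned by a
larger centroid. No minimum size is applied inside this step — all cluster
sizes are retained — and total read count is conserved exactly.

*Chimera screening* uses an exact two-parent bimera model: a cluster Q is
removed iff distinct clusters P1 ≠ P2, each at least 16 times more abundant
than Q, reconstruct Q as P1[1..k] + P2[k+1..] for some crossover
1 ≤ k < |Q|. This is deliberately stricter than heuristic partial-match
scoring: it cannot flag a genuine biological sequence (which is never an
exact crossover of two others), at the cost of missing chimeras whose
copies carry additional errors — those fall below the minimum cluster size
or fail the downstream identity filter instead. Both the denoising rule and
the chimera model are self-contained re-implementations of the cited
tools' documented stage semantics, so external binaries are not required;
the functions are pluggable if a user prefers to substitute them.

### Taxonomic inference

Hits are read from the standard 12-column BLAST tabular layout plus an
appended percent-query-coverage column (documented in
`scatdiet.synthetic.HIT_COLUMNS`). Per query, hits are retained when the
bit-score is ≥ 98% of the query's best bit-score ("top 2%" read as an
inclusive window on the per-query maximum, the only reading that works for
small hit sets), query coverage ≥ 90% and identity ≥ 98%, all inclusive.

The MLCA consensus votes over *unique* lineages (duplicate reference
entries do not over-weight a taxon). Walking domain → species, the modal
taxon among lineages consistent with the accepted prefix is adopted when
its count is ≥ 80% **of all unique lineages** for the query; the
denominator is the full unique set, not the consistent subset, so deeper
ranks can only lose support. A tie for the modal taxon stops the walk, as
does a failed vote; the assignment is the deepest accepted prefix, a single
unique lineage is assigned in full, and anything resolving above order is
unassigned. A consequence worth noting: with two or more unique lineages a
species-level assignment is impossible (two distinct 7-rank lineages cannot
share their species under one genus), so species assignments arise exactly
from single unique lineages — which is why the single-hit rule exists.

A minimal built-in pairwise scorer (`align_clusters`) supports end-to-end
runs without an external aligner: global Levenshtein alignment against
every reference, identity = matches / alignment span, full-query coverage,
and a surrogate bit-score of 2 × matches (monotone in alignment quality;
the bit-score window is invariant to its scale). Real BLAST tabular output
is the primary input path for field data.

### Diet filters and summaries

The canonical order is: remove controls/unassigned → per-sample noise
threshold (0.1% of the sample's reads at that stage; at-threshold retained)
→ ambiguous-species roll-up → host identification → host + contaminant
subtraction → per-taxon 100-read minimum (at-threshold retained) →
summaries. The source analysis pins only fragments of this order; the rest
is a documented choice, configurable, and preserves the reported behaviour
that a 92-read detection is removed by the 100-read rule. The noise
threshold denominator is taken before host/human subtraction.

Host identification takes the candidate predator with the most reads,
subject to a floor of 10 reads (configurable). The host is *not* required
to out-read every prey taxon — hosts dominate only "generally" — and
samples with no qualifying candidate are dropped as indeterminate. The
other candidate predator's reads are never subtracted: predator-predator
DNA is a reported diet/contact item. The minimum read threshold is
per-taxon-per-sample, the only reading consistent with a single sample's
below-threshold detection being discarded.

%FOO is 100 × occupancy within a predator group; group aggregates (small
mammals = Rodentia + Soricidae, birds = Aves, passerines = Passeriformes,
all configurable as (rank, name) predicates) count a sample once if any
member occurs. RRA defaults to pooled reads per group (columns sum to 1);
a per-sample-mean variant is available behind a flag. Habitat ratios are
computed over distinct prey species classified woodland vs open; aquatic
and unclassified species are excluded from the ratio.

## The synthetic generator

The generator emulates the structure the analysis assumes: two candidate
hosts at a 50:50 mix; a field label flipped to the other host with
probability `misid_rate` (default 14/48 ≈ 0.292, the realized rate in the
study system); per-host prey profiles as (inclusion probability, read
weight) pairs, with defaults shaped like the reported fox / pine marten
diets; host read fraction drawn uniformly on (0.55, 0.85) so the host
dominates any single prey in expectation; included-prey shares drawn from a
Dirichlet with concentration 50 × weight; sequencing depth log-normal with
median 20,000 reads and σ = 0.5 (the source study does not state depth;
this is typical Illumina metabarcoding output and is fully configurable);
human contamination at 1% and control spikes at 0.5% of reads binomially;
substitution errors i.i.d. per base at 0.002; and bimeras at 0.005 per
read, formed as single crossovers of two templates present in the sample at
a uniform breakpoint. Reference amplicons are 97 nt, random, with pairwise
identity forced below 96% (the 98% species threshold minus a 2% margin).
Per-sample substreams derive deterministically from one master seed, so
identical configurations are byte-identical and single samples can be
regenerated.

What the generator does **not** model: quality scores and position-
dependent error profiles, PCR duplicates and amplification bias, index
hopping, real cross-species sequence similarity gradients (reference
sequences are random, so interspecies distances are large and uniform),
and environmental DNA transport. Passing the synthetic validation
therefore demonstrates the correctness of the pipeline's logic and its
statistical calibration under the stated noise model — not marker-specific
resolution or primer-bias behaviour on real communities.

## Validation design

- The MLCA walk is checked against a brute-force oracle that enumerates
  every rank prefix and independently verifies the vote chain, on fuzzed
  pools of up to 8 lineages with both nested and colliding rank names.
- Statistical recovery uses 200 simulated scats with noise on; recovered
  misidentification, per-predator %FOO and pooled RRA are required to fall
  inside exact-binomial / Monte-Carlo 95% bounds of the configured values.
  Families of simultaneous checks use Bonferroni-adjusted per-quantity
  levels so the family-wise level stays at 95%. The Monte-Carlo band for
  RRA re-draws the configured count distribution (the generator's own
  count model) with the host/contaminant subtraction and 100-read threshold
  applied, at 1,500 replicates.
- The noise-free limit (substitution, chimera and contamination rates 0)
  must reproduce the ground-truth composition exactly: the per-sample prey
  tables, %FOO and RRA computed by the pipeline equal the same arithmetic
  applied directly to the truth table, to machine precision.
- Conservation invariants (read counts through dereplication, denoising and
  count propagation; RRA normalization; confusion-matrix marginals) are
  asserted on every fixture.

Problem sizes (50-scat study-scale runs, a 200-scat recovery experiment at
median depth 20,000, 1,000 fuzz cases) were chosen as the smallest designs
that exercise every code path while keeping binomial intervals informative;
the full suite runs in well under a minute of compute per experiment.

## Known limitations

- The chimera screen requires exact parent reconstruction; heavily eroded
  chimeras are caught indirectly (minimum cluster size, identity filter)
  rather than flagged.
- With random reference sequences the denoiser's wrong-merge risk is
  negligible; on real databases with congeners a few substitutions apart,
  the α and `max_distance` parameters deserve study-specific review.
- Host identification among more than two candidate predators is supported
  by the API but the generator models exactly two.
- The per-sample-mean RRA variant is provided but untuned; the pooled
  definition is the tested default.
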