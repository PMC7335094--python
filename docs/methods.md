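# Methods

## Data model

The pipeline operates on per-region gapped multiple alignments (FASTA, gap
character `-`), with all coordinates 1-based and inclusive within each
region's own alignment; concatenated coordinates are never exposed.  The
six default study regions have aligned lengths 906, 804, 813, 632, 397 and
1,047 bp (4,599 bp total).  IUPAC ambiguity codes and `N` are folded into a
single missing token (`?`) everywhere: they never found new states, never
count toward a site's variability, and are excluded from distances.  This
is the conservative convention for Sanger-era data, where ambiguities are
read artefacts rather than polymorphisms.

Variant events carry one state token per sample: a base for substitutions,
the present (inserted/retained) string versus `-` for indel events, and the
forward versus reverse-complement span string for inversions.

## Variant scanning

**Substitutions.**  A column is a substitution event when it shows two or
more distinct bases.  Columns whose only variation involves gaps belong to
indel events.  Gapped or ambiguous samples get the missing token at a
substitution event.

**Indel events (simple indel coding).**  Insertions and deletions are
scored as single mutational steps regardless of length.  A maximal gap run
becomes one multi-column event only when every sequence gapped anywhere in
its span shares exactly the same run extent (same start and same end) —
that run is then one historical event, e.g. the two 5-bp insertions in the
study data.  Overlapping runs with different extents are decomposed into
per-column presence/absence events.  The alternative — any-overlap
clustering — would fuse independent events that merely abut, and a
multi-column event spanning conflicting run extents has no well-defined
two-state coding.  Leading and trailing gap runs are treated as missing
data, not mutations, since they usually reflect incomplete reads; pass
`keep_terminal_gaps=True` to score them.

**Inversions.**  Short spans replaced by their exact reverse complement are
biologically one mutation (hairpin-mediated flips in the chloroplast
genome), so they are recoded as single two-state events.  The detector
scans spans of 3–10 columns containing at least two substitution columns
and no gaps; a span qualifies when its sequences fall into exactly two
span-strings, one the reverse complement of the other.  Candidate spans
are trimmed to their variable columns (invariant flanking bases that
happen to be mutually complementary must not widen the span), nested
candidates resolve to the largest, and partially overlapping candidates
raise an error that defers to manual curation — an automatic rule cannot
arbitrate them, and the study data never needed it.  Requiring ≥ 2
substitution columns prevents every lone transversion from being read as a
1-bp "inversion".  Detection is **off by default**, because published
polymorphic-site tables (and this package's packaged matrix) list inversion
columns among the substitutions; it is switched on when building
single-event distances for networks.

## Haplotype collapsing and lettering

Samples with identical state vectors (exact match, gap state included)
share a haplotype.  A vector containing the missing token matches nothing:
the sample becomes its own provisional haplotype and is flagged in the log,
because any merge rule for partial data would be an invented method.
Letters are assigned A, B, C, … by first appearance in the input sample
order — deterministic, but arbitrary — and an explicit relabelling map
(`data/relabel_published.tsv` for the packaged study data) recovers a
published lettering.  All summaries are invariant under relabelling and
under input-order permutations; the package does not attempt to infer what,
if anything, a published letter order encodes.

When a population lists fewer haplotype labels than samples (site tables
list each label once), the labels are dealt to samples in order and the
last label fills the remainder; this reproduces the published per-population
contents exactly for the packaged table, where only fixed populations have
more samples than labels.

## Distances and the parsimony network

Three indel treatments are supported for pairwise distances:

* `missing` — events where either haplotype carries the absent or missing
  state are excluded; mismatches among the rest are counted;
* `fifth_state` — the gap state is an ordinary fifth character state;
* `single_event` — identical to `fifth_state` once indel runs are merged
  (one unit per indel event); kept as a distinct name because the three
  treatments are standard analysis variants.

Inversion events contribute at most one step in every mode, by
construction of the event coding.  Note that `missing`-mode distances are
not a metric (two haplotypes at distance zero can differ in their distances
to a third); distance-zero groups are merged before network building, and
distances between merged nodes are defined as the minimum over member
pairs, which is deterministic and errs toward connecting.

**Connection limit.**  Links are drawn only up to the largest step count
whose parsimonious (homoplasy-free) interpretation exceeds a confidence
threshold (default 0.95), after Templeton, Crandall & Sing (1992).  The
original recursion is not reprinted here; instead the probability is
computed from an explicit generative model with the same rationale:

* the total number of mutations separating a pair of sequences of length
  *L* is Poisson, with mean fitted to the observed number of differing
  sites *j* by the Jukes–Cantor multiple-hit correction;
* mutations strike sites independently and uniformly; a site hit *k* times
  under the symmetric four-state chain still shows a difference with
  probability (3/4)(1 − (−1/3)^k);
* the pair is parsimonious exactly when the mutation count equals *j* with
  all hits on distinct sites; the reported value is the posterior
  probability of that outcome given *j* visible differences, evaluated by
  exact enumeration over hit-count partitions (truncated where terms fall
  below 10⁻¹² of the running sum).

At 0.95 confidence this yields limits of 3 steps at 100 bp, 14 at
2,000 bp and 21 at 4,599 bp, in the empirical range TCS reports for
comparable lengths.  The implementation is
cross-checked in the test suite against an independent Monte-Carlo
simulation of the same model.  `fixed_limit` (CLI `--fixed-limit`)
bypasses the computation when a curated limit is preferred; no claim is
made of bit-level fidelity to TCS v1.21 internals.

**Linking rule.**  Pairs are processed in order of increasing distance
(lexicographic label tie-break, so output is platform-independent).  A link
of length *d* inserts *d* − 1 inferred intermediate nodes, one mutation per
edge.  Between already-connected nodes a link is added only when the
existing network path is *longer* than the pair's mutational distance: the
direct link is then needed to honour the distance, and cycles (reticulation)
arise exactly where the data demand them.  Equal-length existing paths
already account for the distance, and links longer than any existing path
are never added.  Pairs beyond the connection limit stay in separate
components, which are reported rather than force-joined.

## Synthetic data

`synthesize_alignments` writes haplotype states into event spans on top of
per-region invariant backgrounds drawn uniformly from A/C/G/T with a seed
stream independent of event placement, so backgrounds can never create
accidental variable sites and scanning the output reproduces the input
matrix exactly (a property the test suite asserts for the packaged matrix
and for simulated data).  Insertions are realised in alignment space
(present in carriers, gapped in the rest); no realignment is simulated.

`simulate_genealogy` grows a genealogy from an ancestral haplotype, one new
mutation per new haplotype at a previously unused locus (homoplasy-free by
default; an optional homoplasy rate lets substitutions strike used columns
to stress-test reticulation handling).  Event spans keep one background
column of separation from each other and from region ends so independent
events cannot fuse into a single gap run or substitution cluster, and
simulated inversion strings differ from their reverse complement at every
position so the full span is recoverable.  Defaults (six regions at the
study lengths, 1–5 bp indels, 3–6 bp inversions) bracket the event sizes
observed in the study data.

What the simulator deliberately does **not** model: coalescent history,
mutation-rate heterogeneity, alignment error, recombination, or realistic
base composition.  Passing tests therefore certify the pipeline's
book-keeping (event extraction, coding, collapsing, network topology) on
clean data, not robustness to alignment artefacts in real surveys.

## Packaged fixtures

`data/study_haplotypes.tsv` holds the study's 23 haplotype × 42 event
variant-state matrix (30 substitutions, 12 indels, with the two inversions
printed at substitution-column granularity and the two 5-bp insertions,
ACTAT and AGTAA, as single events); `data/study_populations.csv` the 52
populations with range class, coordinates (missing for two populations of
unknown location), sample counts and haplotype contents.  Altitude ranges
are stored as their lower bound; altitude feeds no computation.  Both files
were transcribed once by hand and are locked by the test suite against the
study's internal cross-checks (per-region event counts, haplotype identity
sets, range/fixation/prevalence counts).

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own scale — 86 samples,
52 populations, 4,599 aligned bp — plus simulated genealogies of 5–8
haplotypes over 20 seeds and small-case network oracles of ≤ 6 haplotypes;
everything completes in seconds.  All randomness flows through explicit
seeds (`numpy.random.default_rng`); identical seeds give byte-identical
FASTA output.  Parsimony probabilities use log-space accumulation and a
relative truncation of 10⁻¹²; connection-limit search stops at the first
step count whose probability drops to or below the confidence.

## Known limitations

* The automatic inversion detector is a reconstruction: published studies
  typically spot inversions by eye.  Its thresholds (3–10 bp span, ≥ 2
  substitution columns, exact reverse-complement equality) cover both
  events in the study data but are not tuned beyond it.
* The connection limit follows the statistical-parsimony rationale, not the
  TCS binary; on the study data the network is reported at merge-set and
  unit-step granularity rather than as a claim of figure-exact topology.
* `missing`-mode distance-zero merging depends on the min-over-members
  convention for merged-node distances (documented above); other choices
  could alter long links in degenerate cases.
* Group/subgroup labels in the site table are pass-through metadata from
  tree analyses outside this package's scope; nothing is inferred from
  them.
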