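# cpnet — chloroplast-DNA haplotype analysis

`cpnet` is a tested, reusable implementation of a chloroplast-DNA
phylogeography workflow for tracing the introduction sources of an invasive
plant.  It was built around the Himalayan balsam (*Impatiens glandulifera*)
study system — six non-coding cpDNA regions (*trnL-trnF*, *atpB-rbcL*,
*rps16* intron, *trnG* intron, *psbA-trnH*, *rpl32-trnL*) sequenced for 86
plants from 52 populations across the introduced range (British Isles) and
the native Himalayan range (India, Pakistan) — but every stage works on any
set of pre-aligned, non-recombining loci.

Because cpDNA is maternally inherited and effectively non-recombining, each
plant carries one haplotype: a unique combination of states across all
scored variable sites.  Matching introduced-range haplotypes to native-range
populations tells a biological-control programme where to search for
co-evolved natural enemies.

## Pipeline stages

1. **Variant scan** (`cpnet.variant_scan`) — per-region gapped FASTA
   alignments are reduced to an ordered catalogue of variant events:
   substitution columns; indel events under *simple indel coding* (one
   shared gap run = one mutation, whatever its length, so a 5-bp insertion
   counts one step); and, optionally, *inversions* — short spans where one
   group of sequences reads the exact reverse complement of the rest —
   recoded as single two-state events.
2. **Haplotype collapsing** (`cpnet.haplotyping`) — per-sample state
   vectors are collapsed by exact match into haplotypes lettered A, B, C, …
   in order of first appearance (with an optional relabelling map to a
   published lettering), then summarised per population and range class:
   haplotypes unique to / shared between ranges, within-population
   fixation, per-haplotype prevalence, GeoJSON/CSV export for mapping.
3. **Statistical-parsimony network** (`cpnet.network`) — pairwise
   mutational distances under three indel treatments (missing / fifth
   state / single event), distance-zero merging, and a unit-step haplotype
   network with inferred intermediates, joined up to the 95% parsimony
   connection limit in the spirit of Templeton, Crandall & Sing (1992) —
   the approach behind the TCS program.
4. **Synthetic data** (`cpnet.synthetic`) — embeds any variant-state matrix
   into invariant random backgrounds (an exact inverse of scanning), and
   simulates haplotype genealogies with known mutation events for
   property-based testing.

The package ships two plain-text fixtures transcribed from the study:
the 23-haplotype × 42-event variant-state matrix
(`cpnet.load_haplotype_matrix()`) and the 52-population site table
(`cpnet.load_populations()`).

## Worked example

```python
import cpnet as cp

haplotype_table = cp.load_haplotype_matrix()     # 23 haplotypes x 42 events
pops = cp.load_populations()            # 52 populations, 86 samples

# round-trip the matrix through a full-length synthetic alignment
alignments = cp.synthesize_alignments(haplotype_table, seed=11)
events = cp.scan_all(alignments)
print(len(events))                      # 42

# collapse the 86 per-sample vectors into haplotypes
sample_ev, samples, spmap = cp.sample_events(haplotype_table, pops)
matrix = cp.collapse_haplotypes(sample_ev, samples)
matrix = cp.relabel(matrix, cp.match_labels_to_reference(matrix, haplotype_table))
print(len(matrix.haplotypes))           # 23

rs = cp.range_summary(matrix, pops, spmap)
print(len(rs.introduced), len(rs.native), rs.shared)
#  10 15 ['A', 'E']

fx = cp.fixation_summary(matrix, pops, spmap)
print(fx.eligible, fx.fixed, fx.polymorphic)
#  24 22 [('IR03', ('E', 'H')), ('UK30', ('E', 'J'))]

net = cp.build_network(matrix, cp.IndelMode.missing)
print(sorted(g for n in net.sampled_nodes
             if len(g := net.merged_labels(n)) > 1))
#  [('A', 'B', 'C'), ('E', 'F', 'M', 'N', 'V'), ('L', 'P', 'U'), ('S', 'T')]
```

Reading the output: 42 variable sites (30 substitutions + 12 indels) over
the 4,599 aligned bp; 23 haplotypes among 86 plants, of which 10 occur in
the introduced and 15 in the native range with two (A, E) shared — the
shared haplotypes are the strongest lead for source populations.  Of the 24
populations with ≥ 2 samples, 22 are fixed for a single haplotype.  Under
indels-as-missing distances, four published identity sets merge into single
network nodes.

The same flow is available from a shell:

```sh
cpnet simulate --out sim --n-haplotypes 6 --n-substitutions 3 \
      --n-indels 1 --n-inversions 1
cpnet scan --regions sim --out events.tsv --detect-inversions
cpnet haplotypes --events events.tsv --pops sim/populations.csv \
      --out matrix.tsv --summary summary.json
cpnet network --matrix matrix.tsv --mode missing --out net.graphml
cpnet geo --events events.tsv --pops sim/populations.csv --out sites.geojson
```

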