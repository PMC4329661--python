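# Methods

This note documents the models, conventions and numerical choices behind
metacompare, and what the synthetic experiments do and do not demonstrate.

## Synthetic communities and the read model

A community is a set of reference genomes with an abundance vector
(summing to 1), a per-genome divergence, and global read-set parameters.
Reads are simulated as:

1. **Source draw.** Each non-duplicate read's genome is a categorical draw
   from the abundance vector; its start is uniform over placements that
   keep the read fully on the genome; its length is drawn from a normal
   distribution truncated to [50 bp, 2 × mean] (defaults mean 387 bp,
   SD 50 — the read-length regime of 454 Titanium shotgun data). Only the
   means of real 454 length distributions are well established; the
   truncated normal is the simplest shape honoring them and is a stand-in,
   not a calibrated model.
2. **Substitution errors.** Each base is replaced by one of the other
   three bases independently with probability equal to the genome's
   divergence. Divergence must stay below 0.45, the rate at which expected
   full-read identity would fall to the 55 % recruitment floor and the
   simulation would become unresolvable by construction. The error model
   is substitution-only by default; 454-style homopolymer indels can be
   enabled (`indel_rate`) but are off because every downstream statistic
   here depends on identical-base fractions, not on indels. With indels
   enabled, identity is still identical bases over read length.
3. **emPCR duplicates.** A fraction `duplicate_rate` of reads are
   duplicates: each copies the genome, start and length of a parent read
   chosen with weight `exp(gc_dup_coupling × parent GC)`, receives an
   independent error draw by default (`duplicate_fresh_errors=False`
   yields byte-identical copies, appropriate when emulating re-reads of
   one template molecule), and records `is_duplicate_of`. Parents precede
   duplicates in the output, so provenance-based evaluation of duplicate
   removal is unambiguous.

All draws flow from the single integer seed of the spec; identical specs
give byte-identical FASTA output. Generated genomes are i.i.d. base draws
with P(G or C) = `gc_target`, so realized GC concentrates within ~0.02 of
the target for ≥ 10 kb.

What the simulator does *not* emulate: flowgram/quality-coupled errors,
chimeras, repeat structure, conserved genes shared between genomes, or
compositional biases of real genomes. Tests passing on these communities
therefore demonstrate the correctness of the pipeline's accounting and its
statistical calibration under the stated model — not classifier accuracy
or recruitment behavior on real, repeat-rich genomes.

## Read QC

**Duplicate removal** clusters reads sharing an identical (case-insensitive)
first-50-bp prefix whose lengths agree within 2 % (single-linkage on sorted
lengths); the longest member of each cluster survives, ties broken toward
the earliest read, and output order preserves input order. Reads with an N
in the prefix never cluster — conservative toward retention. Keeping one
representative (rather than discarding whole clusters) is the default
behavior; both thresholds are parameters. On synthetic sets with
10 % duplicates this achieves sensitivity ≥ 0.95 at FPR ≤ 0.01 against
ground-truth labels; note that on small genomes unrelated reads can share
a start coordinate by chance and form genuine byte-duplicate clusters that
count against provenance labels, which is a property of the instance, not
the filter.

**GC filtering** removes reads whose GC fraction deviates from the sample
mean by more than `z_cutoff` (default 3) sample SDs, iterating to a fixed
point (sigma clipping). Iteration makes the filter idempotent — a second
application never removes anything — at the cost of occasionally trimming
a few near-threshold reads beyond the single-pass result. Fewer than two
reads, or zero GC variance, is a no-op. The canonical composition order is
duplicates first, then GC, and is recorded in the QC report.

## Profiles and comparisons

Per-read classifier output is consumed as tables; records with E-value
above 10⁻⁵ (inclusive threshold) are dropped. A profile maps taxa to counts
at one rank with `total_reads` — the full sample size, assigned or not —
as the relative-abundance denominator; a read may carry at most one
assignment per rank, and conflicting duplicates are a hard error rather
than silently resolved, which keeps profiles a partition. Profile exports
report relative abundances against both denominators (all reads and
assigned reads), since published community percentages do not always state
which was used.

**Normalization** scales counts by `N_min / N_sample`; the smallest profile
is a fixed point and within-sample ratios are preserved exactly.
**Scatter data** retain taxa whose two relative abundances sum to ≥ 0.01 %
(interpreted as the sum over the two samples of each sample's own relative
abundance) and use `log10(count + 1)`. **Unique EGTs** require a raw zero
in one sample (zero scales to zero, so the test is on the raw count) and
normalized abundance ≥ 5 (inclusive) in the other. **Recruitment
percentages** are rounded half-up to 2 decimals; normalized counts are
kept at full precision internally.

**Rarefaction** subsamples assigned reads without replacement. Each
replicate permutes the reads once and reads richness off prefixes, which
is distributionally identical to independent nested draws and makes every
replicate's curve non-decreasing by construction. Defaults: 10 replicates,
10 evenly spaced depths, seeded. The Monte-Carlo mean is validated against
the exact hypergeometric expectation (and its exact variance, from pairwise
absence probabilities) in the tests; the same closed form is what vegan's
`rarefy` computes.

**Methanogenesis comparison** restricts functional records to superkingdom
*Archaea* and to Pfam families in a pathway map (acetyl-CoA pathway,
methanogenesis, Wood-Ljungdahl pathway), then normalizes per-family counts
to the smallest dataset. The shipped map is a small curated starting set of
methyl-CoM reductase subunits, acetate-activation enzymes and
Wood-Ljungdahl branch enzymes; supply a project-specific map for serious
use.

## Fragment recruitment

Identity is `identical_bases / read_length` — deliberately not the
aligned-span identity; a partial local alignment of a long read scores low
by construction. Hits below 55 % identity are discarded; both the 55 %
floor and the 90 % high-identity threshold are inclusive (a floor stated
as "below 55 % discarded" implies 55 % retained; both are config-flippable
to exclusive). Flooring commutes with best-by-identity hit selection, which
a property test asserts. Rankings count reads per genome at ≥ 90 % after
best-hit-per-(read, genome) reduction; percentages always divide by the
minimum of the supplied dataset totals — the only convention that
reproduces published recruitment tables' percentages from their printed
counts. Histograms use 1 % bins over [55, 100], the last bin closed so
perfect hits are counted, scaled by `N_min / N_sample` so the smallest
sample's histogram equals its raw histogram. Recruitment-plot abscissa is
the alignment midpoint by default (start/end are config-visible options).

Coordinates are 0-based half-open internally and 1-based inclusive in all
exports (BLAST tabular convention); minus-strand hits are normalized to
`subject_start ≤ subject_end`.

**Built-in aligner.** Exact k-mer seeding (k = 15, sampling every ⌈k/2⌉
positions plus the final one) on both strands, followed by ungapped
evaluation of every distinct seeded offset over the full read span;
placements running off a genome end count the overhang as mismatches. A
read occurring verbatim in a genome is guaranteed a hit with identity 1.0
at the true coordinates. At 5 % divergence and 400 bp the probability that
no sampled 15-mer is error-free is < 10⁻¹⁴, and tests verify ≥ 99 % of
reads hit with identities equal to brute-force mismatch counts; an
all-offsets brute-force aligner serves as the equivalence oracle on small
instances. The aligner performs no gapped extension and computes no
E-values; it exists to make the pipeline self-contained at desk scale, not
to replace a database search tool. External BLAST outfmt-6 hits are the
intended production input: `identical_bases` is reconstructed as
`round(pident × length / 100)` and the identity denominator is taken from
the read file, as the identity definition requires.

## Pipeline runs

`run_pipeline` executes simulate → QC → profiles → recruitment from one
YAML config whose defaults are the published conventions (E ≤ 10⁻⁵,
floor 0.55, high 0.90, pseudocount 1, 0.01 % scatter filter, unique
minimum 5). When reads are simulated, assignment tables are derived from
ground truth (each read inherits its source genome's lineage), i.e. the
demonstration runs a perfect classifier; this exercises every statistic
downstream of classification while classifiers themselves stay out of
scope. Every output is listed with a SHA-256 checksum in `manifest.json`;
identical configs produce identical checksums, and partial outputs are
removed on failure.

## Problem sizes

The shipped experiments use 10,000 reads × 100 kb genomes for recruitment
recovery, 5,000 reads × 500 kb for QC recovery, 200 replicates on a
100-read 5-taxon profile for rarefaction calibration, and a two-sample
demo of 4,000 + 3,000 reads × five 40 kb genomes — sizes chosen so the
full suite and the acceptance script each complete in seconds while
keeping every statistical check well-powered.

## Known limitations

* The duplicate filter's prefix heuristic cannot detect duplicates whose
  independent error draws differ within the prefix; at high divergence
  with fresh errors, sensitivity drops by design.
* Iterated GC clipping can trim slightly more than a single-pass z-score
  rule; the trade-off buys idempotence.
* The built-in aligner is ungapped; indel-containing reads score lower
  than a gapped aligner would report, consistently with the identity
  definition but not with BLAST's `pident`.
* Synthetic genomes are repeat-free i.i.d. sequences; recruitment
  specificity results do not transfer to paralog-rich or horizontally
  transferred regions of real genomes.
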