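# Methods

This note documents the models and procedures behind `shotgunbarcode`, the
parameters that matter, what the synthetic data does and does not emulate,
and the design choices made where the method left room.

## Problem setting

A multi-ingredient herbal product contains genomic DNA from every ingredient:
eight plants, one fungus, one animal in the formula this package models, plus
environmental fungi and processing contaminants. PCR-free shotgun sequencing
of total DNA samples all of it in proportion to mass x genomic copy number.
The pipeline's task is to pull the five standard barcode regions (ITS2,
psbA-trnH, matK, rbcL, COI) out of that read soup, reconstruct them exactly,
and assign each to a species — falling back to whole-organelle read
recruitment for ingredients whose barcodes cannot be assembled.

## Synthetic data model

`simulate.generate_reference_fixtures` builds a 17-taxon reference database
deterministic in its seed: 10 labeled ingredients (the fungus has only ITS2
and a toy mitochondrion whose genes include COX1; the animal only COI; one
plant also carries a toy chloroplast with psbA, ndhK, ndhB, ycf2 and rpl2), a
plant positive control, three unlabeled plants (two of them congeners of
database species, diverged at ~3% of barcode sites), and three contaminant
fungal genera. Barcode contexts embed the inter-primer region between exact
primer sites with 250 nt of random genomic flank, so enrichment, assembly and
extraction all see realistic sequence structure.

`simulate_sample` draws a multinomial over (taxon, source) with expected
share proportional to mass_proportion x copy_weight inside the budget left
after the contaminant fraction (default 0.02) and the random-decoy background
fraction (default 0.10). Fragments get Gaussian insert sizes (350 +/- 35 nt,
truncated at the read length), a uniformly random strand, Phred+33 qualities
in the Q35-Q40 band, and substitution errors whose per-position probability
ramps linearly to double from 5' to 3' while preserving the configured mean
(default 2e-3). Every pair is recorded in a truth table (origin taxon, source,
coordinates, strand).

Default copy weights — ITS2 100, plastid loci 20, COI 20, organelle genomes
20 — make the simulated per-locus read counts qualitatively reproduce the
heavy ribosomal/organellar skew seen in real shotgun libraries of plant
material; they are configurable per reference.

What the generator does **not** emulate: indels and optical duplicates
(negligible for current short-read chemistry at this scale), quality-score
structure correlated with errors (qualities are decorative; trimming is
exercised by dedicated tests), PCR bias (the method is PCR-free by design),
intragenomic ITS2 paralog variation, and degraded/processed DNA. Passing
tests therefore demonstrate the pipeline's logic and its behaviour under
sampling noise and substitution error, not robustness to those further
real-data effects.

## Stage contracts and numerical choices

**Trimming.** LEADING/TRAILING 3, SLIDINGWINDOW 4:15, MINLEN 50, applied to
both mates, with the pair dropped when either mate fails; the window cut
re-triggers end trimming until a fixed point, which makes trimming
idempotent. These are deliberately gentle, conventional defaults; the
upstream tool parameterization this emulates is not standardized.

**Enrichment.** Canonical 31-mers (odd k, packed 2-bit into int64; k <= 31)
of every reference context, both strands collapsed by canonicalization. A
pair joins the locus with the most matching k-mers across both mates if that
count >= 3; ties go to no assignment so the bins stay disjoint. k = 31 with
min_hits = 3 tolerates 1-2 substitutions per read while a random 150 nt pair
essentially never reaches 3 matches (measured < 1% decoy recruitment,
typically 0).

**Assembly.** One de Bruijn assembler run at k = 21 and k = 31, unioned —
two k values stand in for running two independent assemblers, preserving the
observable contract (union, then uniqueness). k-mers with count < 2 are
dropped; unitigs are maximal non-branching paths over oriented nodes iterated
in packed-integer (lexicographic) order, so construction is deterministic and
input-order free. Cleaning is iterative (<= 8 rounds): dangling tips shorter
than 2k whose coverage is below 10% of their anchor branch node, and bubble
arms attached at both ends carrying < 10% of the coverage flowing through
their flanking branch nodes. Judging arms against branch-node counts rather
than against a matched sibling arm keeps the rule effective when recurrent
sequencing errors fragment the main path. Equal-coverage alleles (true SNP
bubbles) are far above the 10% line and survive as parallel contigs.
Very deep bins are evenly subsampled to 30,000 mates before assembly; at the
default scale that caps ITS2-bin depth near 400x, where the error-bubble
density stays low, without touching minority members (a 2% contaminant still
assembles at ~45x). Merging keeps the longest representative of every
exact/reverse-complement/containment duplicate class, ties broken
lexicographically; the operation is idempotent and commutative.

**Extraction.** Primer matching is IUPAC-aware, ungapped, <= 3 mismatches
(assembled contigs carry almost no indels). The barcode is the region
strictly between a forward site and a downstream reverse-complemented
reverse site; among multiple pairings the longest region wins, ties leftmost;
both contig orientations are searched and the result is canonicalized to the
F->R strand. ITS2 is instead located between two 20-column position-weight
profiles (match probability 0.91 per column) modelling the conserved 5.8S
tail and 28S head, scored as log-odds against a uniform background with
threshold 12 — permissive to ~4 mismatches per flank yet with a false-hit
probability per random window around 1e-8. A contig that ends inside one
flank yields a candidate flagged partial. Candidates shorter than 60 nt are
discarded as uninformative scraps. The chimera screen aligns each candidate's
two halves against the same-locus references and discards candidates whose
halves best-hit different genera; partial candidates are exempt.

**OTU clustering and validation.** 100% identity: only identical sequences
or exact substrings co-cluster (a truncated barcode joins the full-length
cluster of the same ingredient instead of founding a spurious OTU; an OTU is
marked partial only when every member is partial). Reads are mapped back
ungapped (15-mer seed, identity >= 0.95 over the overlap, each read to its
single best OTU: identity, then overlap length, then lexicographic id).
Reliability thresholds — coverage >= 0.8 and mean depth >= 5x, inclusive —
are the single most consequential tunables and are surfaced in the
configuration, the provenance record, and the OTU table; failing OTUs are
retained flagged invalid, never silently deleted.

**Taxonomy.** End-gap-free global alignment (match +1, mismatch −1, gap open
−2, extend −1) against every same-locus reference; base differences =
mismatches + internal gap columns over the overlap. Because an overlap
alignment of unrelated sequences degenerates to a short perfect overhang, an
alignment counts as a hit only when its span covers >= 60% of the shorter
sequence. Hits within 1 percentage point of the best identity (and above a
0.90 floor) vote by seven-rank LCA; a species-rank result with best identity
< 0.99 is demoted to genus, which prevents overcalling between congeners a
few sites apart. Detection in the matrix requires a validated, full-length
OTU assigned at species rank (or genus rank when the database holds a single
congener of that genus).

**Organelle fallback.** The same mapping contract applied to whole organelle
genomes; per annotated region the pipeline reports reads overlapping it,
fraction of positions covered, and mean depth. The detection rule — at least
2 regions at >= 50% coverage — is this package's own decision rule, chosen so
that a genuinely present organelle (dozens of x deep here) is called while a
handful of cross-mapping reads in one region is not; both thresholds are
configuration-visible and the rule is labelled as such in reports.

**Determinism.** All randomness flows from explicit seeds (per-sample
generators derived from seed + a CRC of the sample id, kept below 2^31); all
iteration orders are sorted; reruns of the same configuration produce
byte-identical TSV outputs. Results are independent of thread count because
everything runs single-threaded.

## Problem sizes

The default study conditions used by the test suite and the acceptance
script: two mock samples (one with the positive control spiked at the
proportion of the fungal ingredient) at 100,000 read pairs each, a
pharmaceutical-style sample (trace unlabeled plants at 0.4% mass each) at the
same depth, and a 10,000-pair error-free sample for recall/specificity
measurements. At this scale every present (taxon, locus) pair is recovered
as exactly one validated OTU identical to its reference barcode, and the full
suite runs in minutes on one CPU.

## Known limitations

- A trace congener sharing long k-mer stretches with an abundant sibling
  (e.g., an adulterant a few percent diverged at ~4% of the sibling's
  abundance) can be pruned as a bubble arm at assembly; its reads then map to
  the sibling's OTU. Divergent unlabeled taxa are unaffected.
- Ungapped read mapping understates depth/coverage for references with
  indel variation relative to the reads; representatives originate from the
  same read pool, so this is negligible here but matters for mapping reads
  from one accession onto another's organelle genome.
- The ITS2 locator is a two-profile approximation of a full profile HMM: it
  has no indel states, so flanks with insertions relative to the consensus
  would score poorly.
- The reconciliation of conflicting assignments across multiple public
  databases is out of scope; the package queries a single merged local
  reference collection.
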