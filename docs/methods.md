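# Methods

## The model

A genome is treated as an ordered sequence of protein domains.  Domains are
detected directly from nucleotide sequence by translating all six reading
frames and scanning them with profile HMMs, so detection does not depend on
gene annotation: domains in unannotated ORFs, pseudogenes and
double-coding regions are all visible.  Stop codons are kept as a sentinel
residue rather than splitting frames into ORFs — profile alignments simply
do not extend across them — and codons containing ambiguous bases translate
to `X`, which profile scoring treats neutrally.

Genomic coordinates are 1-based inclusive; frame-internal amino-acid
coordinates are 0-based half-open internally and 1-based inclusive in every
emitted table.  Reverse-frame hits are reported on the forward axis with
strand `-`, which gives all six frames one shared coordinate system for
ordering.  The mapping is exact and invertible: re-extracting a hit's
genomic span and re-translating it in its frame reproduces the reported
amino acids, which the test suite checks for every curated hit.

Splicing and ribosomal slippage are not modelled; a domain split across
frames will be missed or reported with a weaker E-value.

## Windowed search

`hmmsearch` sensitivity depends on target length, so frames are cut into
200-aa windows offset by 13 aa.  Windows introduce no new sequence; the
tail window is emitted even when shorter than 200 aa so that coverage of
the frame is complete (tail handling was an open choice; full coverage is
the conservative one).  Search uses a per-domain bit-score reporting floor
of -5 rather than an E-value threshold, deferring all significance
decisions to curation.  Profiles are partitioned into order-preserving,
near-even bundles (40 by default) and each (frame, bundle) pair is an
independent job; outputs are moved into the results directory only when
complete, so interrupted runs resume by re-running missing jobs.  FAA
headers encode `accession|frame|window|offset` (and, for gene-mode targets,
the gene span, strand and genome length); this naming contract is what lets
the domtblout parser place every hit in frame coordinates without side
lookups.

## E-value adjustment

The engine's independent E-value scales with the number of target
sequences searched.  Adjusted E-values are

    E_adj = iE / n_targets * (L_frame / L_window)

The first factor normalizes to a single-sequence search space; the second
linearly undoes the sensitivity gain of searching a short window instead
of the whole frame, and is 1 for whole-frame and gene-mode searches (gene
searches are not windowed).  Hits with E_adj > 1 are excluded, and hits
identical in (profile, frame, alignment span) — the same domain recovered
from several overlapping windows — collapse to the copy with the best
E-value.

## De-overlap rules

Overlap resolution runs per (genome, frame); opposite strands never
compete, preserving double coding.  Each hit's effective start is the
"calculated start" `max(ali_start - min(hmm_from - 1, 20), 1)`: where the
profile would normally begin, extended at most 20 residues.  Overlap is the
intersection of `[calc_start, ali_end]` intervals divided by the shorter
domain's length — the shorter-domain denominator makes a small domain
nested inside a large one register as fully overlapping, which is one of
the two overlap pathologies the rules target.  Alignment (not envelope)
coordinates are used; envelopes are retained in the tables.

For every adjacent and skip-1 pair in calc_start order (A-B, B-C and A-C),
in order:

1. *Same clan* (both carry the same non-null clan) and overlap ≥ 33%:
   remove the worse E-value.  Same-clan co-detection over one region is
   expected redundancy; only the best representative is kept.
2. *Different clans*: if both hits have E_adj ≤ 1e-7 both are kept
   regardless of overlap; otherwise removal requires overlap ≥ 45% *and* a
   10,000-fold E-value gap.  When the overlap threshold is crossed but the
   gap is not met, both hits are kept: the engine never deletes without
   both printed justifications.
3. *Database precedence*: a vFAM/pVOG hit overlapping (any fraction) a
   PFAM hit survives only if `log10(E_v) <= 5 * log10(E_PFAM)`, with both
   E-values clamped just below 1 so the logarithms are negative; the PFAM
   hit is always retained by this rule.  This applies even when both hits
   are individually significant — the viral collections overlap PFAM in
   content, so a vFAM/pVOG call over a PFAM region must be much stronger to
   stand.

Removed hits leave the comparison pool immediately and the pass repeats to
a fixed point, which makes the kept-set invariant under input permutation.
E-value ties break by higher bit score, then earlier calculated start, then
profile name, so output is fully deterministic.  The significance threshold
of 1e-7 is configurable: it approximates a 0.01 per-genome threshold
divided by a corpus of order 10^4 genomes (the exact quotient would be
~1.1e-6).

The adjacent/skip-1 scan equals an all-pairs brute-force resolver whenever
every overlapping pair sits within two positions in sort order — always
true for ≤ 3 hits per frame, and checked exhaustively there.  With ≥ 4 hits
per frame, pile-ups where a pair overlaps at sorted distance > 2 can
diverge from the all-pairs answer; the tests verify that divergences occur
only in such instances and remain rare under random architectures.
Removals never cross frames and never touch non-overlapping hits.
Curation only selects among engine-reported domains; it never re-scores or
realigns.

## Neighborhoods and features

Kept domains are ranked by genomic start (ties: end, then profile name),
strands interleaved.  A neighborhood is every domain within a rank radius
(default 10) of a domain-of-interest occurrence, with signed
ordered-domain distance: rank offset, negative upstream.  Rank distance,
not nucleotide distance, is used throughout — between Dom1 and Dom3 in
Dom1-Dom2-Dom3 the distance is 2.

Feature rows key members by clan (profiles without a clan key by name) and
weigh them w(d) = 1/d²; the center contributes 1 (d = 0 maps to weight 1,
avoiding division by zero and anchoring all DOI rows in the DOI column);
absent clans are 0, equivalent to infinite distance.  For clustering the
per-clan reduction is `max` (the nearest occurrence dominates); mosaic
summaries use `sum` over all occurrences and all neighborhoods, excluding
the center itself, so they rank the DOI's conserved partners.  Per-genome
rows use the best-scoring DOI occurrence (one-row-per-occurrence is
available).

"Fuzzy" clustering is realized as ordinary agglomerative hierarchical
clustering (SciPy; average linkage, Euclidean metric by default) on these
soft features — the fuzziness lives in the inverse-square weights, not the
algorithm.  An integer cut requests that many flat clusters; a float cuts
at a dendrogram height; the default cut for taxonomy comparison is k = the
number of observed families.  Cluster-vs-family agreement is measured with
the Hubert–Arabie adjusted Rand index (scikit-learn's implementation,
cross-validated in the tests against exhaustive pair counting) and a
contingency matrix scaled per cluster row to its maximum.

## Synthetic corpora

The generator emulates exactly what the pipeline consumes: families defined
by an ordered architecture of profiles, each profile owning a fixed
50-residue motif derived deterministically from its name; genomes carry the
motifs in-frame (optionally alternating strands) separated by uniform
random gaps (100-400 nt by default) of random background, padded to ≥ 2 kb.
Matching domtblout tables emit one row per window fully containing a motif
(log-uniform i-E-values in 1e-30..1e-12, as for a single-target search),
reproducing the duplicate structure of real windowed output, plus optional
per-genome decoy rows with i-E-values in 0.6-0.95 that the frame/window
rescaling pushes above the exclusion threshold.  All randomness derives
from the spec seed; the same seed reproduces the same corpus byte for byte.

The generator does not model realistic base composition, codon usage,
profile-score noise, partial-motif hits or homology between families, so
passing tests demonstrate correctness of the bookkeeping, rules and
recovery logic — not detection power on real viral sequence.  Real-engine
behaviour is exercised separately by building actual profile HMMs from the
motifs and searching planted windows with pyhmmer.

Default study sizes — 2 families x 10 genomes, 5 domains per architecture,
dropout and decoys off for recovery checks — are desk-scale choices that
keep the full suite in seconds while exercising every stage; the
acceptance script regenerates them from its seed at each run.

## Known limitations

* One linear order per genome: segmented genomes (multiple contigs) are
  treated as separate records, so neighborhoods never span contigs.
* The de-overlap adjacent/skip-1 scan is a deliberate faithful restriction;
  see above for where it can differ from all-pairs resolution.
* Gene-mode searches default to frame 1 of the annotated span; a
  `codon_start` qualifier other than 1 is not applied.
* No interactive visualization; outputs are machine-readable TSV/JSON plus
  Newick dendrograms.
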