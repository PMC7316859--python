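# domainhood

Domain-centric annotation of (viral) genomes, without relying on gene
annotations.  `domainhood` decomposes a nucleotide sequence into an ordered
string of protein domains — the reusable functional building blocks
detectable by profile Hidden Markov Models — and turns the local context of
any domain into a quantitative "domain neighborhood" that can be clustered
and compared across genomes.  The intended users are virologists and
comparative genomicists who want to characterize poorly annotated genomes,
find domains outside annotated ORFs, or classify sequences by shared domain
architecture rather than by primary-sequence similarity.

## What it does

1. **Six-frame translation and windowing.**  Each genome is translated in
   all six frames (stops retained as `*`) and every frame is partitioned
   into overlapping 200-aa windows offset by 13 aa.  Searching small
   windows makes `hmmsearch` markedly more sensitive than searching a whole
   translated contig; no sequence content is added or lost.
2. **Profile-HMM search.**  Profiles (PFAM plus viral-specific vFAM/pVOG
   collections, with clan and source metadata in a sidecar TSV) are split
   into bundles; one job = (frame FAA x bundle), so 6 frames x 40 bundles =
   240 independent, resumable jobs.  The engine is pyhmmer's in-process
   hmmsearch with a per-domain bit-score floor (`domT -5`); precomputed
   `--domtblout` tables can be ingested instead.
3. **E-value curation.**  Per-domain independent E-values are adjusted
   twice — normalized to a single-sequence search space, then rescaled by
   the frame/window length ratio L_frame/L_window — so a window hit's
   E-value means "expected chance hits in this genome".  Hits with adjusted
   E > 1 are excluded and 100%-overlapping window duplicates collapse to
   the best copy.
4. **Clan-aware de-overlap.**  Within each frame, sorted hits are compared
   pairwise (adjacent and skip-1 neighbors, iterated to a fixed point):
   same-clan pairs tolerate < 33% overlap; different-clan pairs < 45%
   overlap unless both have E ≤ 1e-7 (keep both) — removal additionally
   requires a 10^4-fold E-value gap; and a vFAM/pVOG hit overlapping a PFAM
   hit survives only if log10(E_v) ≤ 5·log10(E_PFAM).  Opposite-strand
   frames never compete, preserving viral double coding.
5. **Neighborhoods and clustering.**  Kept domains are ordered along the
   genome; a neighborhood is the set of domains within a rank radius of a
   *domain of interest*, with signed ordered-domain distances (upstream
   negative).  Feature matrices key members by clan and weigh them by the
   inverse square of the ordered distance, w(d) = 1/d² (nearest neighbor
   1, four ranks away 0.0625, absent clan 0).  Rows are clustered
   hierarchically, summarized in mosaic tables (summed 1/d² per partner
   domain), and compared against taxonomy with the adjusted Rand index and
   a per-cluster-scaled contingency matrix.

A synthetic-data module generates desk-scale corpora — genomes with
planted, ordered 50-aa motif architectures per family, matching domtblout
tables with window duplicates and decoy rows, and family labels — so every
stage is testable end to end without downloads or a cluster.

## Worked example

```sh
domainhood synth --families 2 --genomes 4 --seed 7 -o fixtures/
# 8 genomes, 40 planted domains -> fixtures/

mkdir -p results && cp fixtures/synthetic.domtblout results/
domainhood curate --results-dir results --genomes fixtures/genomes.fna \
    --profile-meta fixtures/profiles.tsv -o curated.tsv
# 427 raw hits -> 40 kept of 40 unique

domainhood cluster curated.tsv --doi FAM0_DOM2 --k 2 \
    --labels fixtures/labels.tsv -o clusters/
# {"rows": 4, "clusters": 1, "ari_vs_taxonomy": 1.0}
```

The `curate` line reports that the 427 raw rows (each planted domain is
re-found in ~10 overlapping windows) collapse to 40 unique domains, all
kept — the planted architectures survive curation exactly.  The `cluster`
line clusters only family-0 genomes (the chosen domain of interest,
`FAM0_DOM2`, occurs only there); their noise-free neighborhoods are
identical, so even a 2-cluster cut cannot split them (`clusters: 1`) and
the partition matches the (single-family) taxonomy perfectly.  The
acceptance script runs the cross-family version of this comparison, where
a DOI set spanning both families gives ARI 1.0 against the planted labels.

Library use mirrors the CLI: `parse_genomes` / `six_frame_translate` /
`make_windows`, `run_search` / `parse_domtblout`, `pipeline.curate`,
`pipeline.neighborhoods_by_genome`, `build_feature_matrix`, `cluster_rows`,
`adjusted_rand`.

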