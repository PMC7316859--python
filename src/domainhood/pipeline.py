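"""End-to-end orchestration: from genomes and hit tables to neighborhoods.

Thin glue over the stage modules; every step here is also reachable on its
own.  The pipeline is engine-agnostic past the hit table: hits can come
from an in-process hmmsearch run or from ingested ``--domtblout`` files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from domainhood.curation import (
    CurationParams,
    CuratedDomain,
    adjust_hits,
    deoverlap,
    filter_hits,
    kept_only,
    prune_exact_duplicates,
)
from domainhood.genome_io import (
    GenomeRecord,
    make_windows,
    map_to_genomic,
    six_frame_translate,
    write_window_faa,
)
from domainhood.neighborhood import (
    Neighborhood,
    build_neighborhoods,
    order_domains,
)
from domainhood.search import DomainHit, annotate_hits


def frame_lengths(genomes: Sequence[GenomeRecord]) -> dict[tuple[str, int], int]:
    """Amino-acid length of every frame of every genome."""
    out = {}
    for g in genomes:
        L = len(g.sequence)
        for k in range(1, 7):
            offset = (k - 1) if k <= 3 else (k - 4)
            out[(g.accession, k)] = (L - offset) // 3
    return out


def write_all_window_faas(
    genomes: Sequence[GenomeRecord],
    out_dir: str | Path,
    window_width: int = 200,
    step: int = 13,
) -> list[Path]:
    """Translate all genomes and write one windowed FAA per frame."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for g in genomes:
        for frame in six_frame_translate(g):
            windows = make_windows(frame, window_width, step)
            if windows:
                p = out_dir / f"{g.accession}.frame{frame.frame}.windows.faa"
                write_window_faa(windows, p)
                paths.append(p)
    return paths


def assign_genomic_coordinates(
    hits: Sequence[CuratedDomain], genomes: Sequence[GenomeRecord]
) -> None:
    """Fill nt_start/nt_end/strand on hits from their frame coordinates."""
    lengths = {g.accession: len(g.sequence) for g in genomes}
    for h in hits:
        nt_start, nt_end, strand = map_to_genomic(
            h.frame, h.ali_start - 1, h.ali_end, lengths[h.accession]
        )
        h.nt_start, h.nt_end, h.strand = nt_start, nt_end, strand


def curate(
    hits: Sequence[DomainHit],
    genomes: Sequence[GenomeRecord],
    params: CurationParams = CurationParams(),
    n_targets_in_search: int = 1,
    profile_meta: Mapping | None = None,
) -> list[CuratedDomain]:
    """Full curation: adjust, exclude, dedup, de-overlap, map to genome.

    Returns the audited list (removed hits marked with their reason);
    genomic coordinates are assigned to every surviving stage-4 hit.
    """
    if profile_meta:
        annotate_hits(hits, dict(profile_meta))
    adjusted = adjust_hits(hits, frame_lengths(genomes), n_targets_in_search, params)
    survivors = filter_hits(adjusted, params.max_adj_evalue)
    unique = prune_exact_duplicates(survivors)
    resolved = deoverlap(unique, params)
    assign_genomic_coordinates(resolved, genomes)
    return resolved


def neighborhoods_by_genome(
    curated: Sequence[CuratedDomain], doi, radius: int = 10
) -> list[Neighborhood]:
    """Order each genome's kept domains and build DOI neighborhoods."""
    by_acc: dict[str, list[CuratedDomain]] = {}
    for h in kept_only(curated):
        by_acc.setdefault(h.accession, []).append(h)
    out: list[Neighborhood] = []
    for acc in sorted(by_acc):
        ordered = order_domains(by_acc[acc])
        out.extend(build_neighborhoods(ordered, doi, radius))
    return out


def domain_strings(curated: Sequence[CuratedDomain]) -> dict[str, list[str]]:
    """Each genome's curated, ordered domain string (profile names by rank)."""
    by_acc: dict[str, list[CuratedDomain]] = {}
    for h in kept_only(curated):
        by_acc.setdefault(h.accession, []).append(h)
    return {
        acc: [od.curated.profile for od in order_domains(group)]
        for acc, group in sorted(by_acc.items())
    }
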