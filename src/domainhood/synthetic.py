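"""Desk-scale synthetic fixtures: genomes with planted domain architectures.

Each synthetic "profile" owns a fixed, high-information 50-residue motif
derived deterministically from its name.  A family's architecture is an
ordered list of profiles; genomes of the family carry the motifs in-frame
at sampled positions (optionally alternating strands), separated by random
background sequence.  The generator returns ground-truth placements so
recovery can be checked end to end, and can emit a matching synthetic
HMMER3 ``--domtblout`` table — including the duplicate rows that
overlapping windows produce and near-E=1 decoy rows — so every pipeline
stage downstream of the search engine is exercisable without one.

Profiles can also be materialized as real profile HMMs (built from copies
of the motif), so plant-and-recover works with actual hmmsearch runs too.

All randomness flows from the spec's seed; there is no global random state.
Base composition, codon usage and mutation processes are deliberately not
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from domainhood.genome_io import (
    GenomeRecord,
    reverse_complement,
    translate_nt,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# one deterministic codon per residue (first codon of the standard table,
# alphabetically) so motif -> nucleotide encoding is reproducible
_CODON_FOR: dict[str, str] = {}


def _build_codon_map() -> dict[str, str]:
    if not _CODON_FOR:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1].forward_table
        for codon in sorted(table):
            aa = table[codon]
            _CODON_FOR.setdefault(aa, codon)
    return _CODON_FOR


def motif_for(profile_name: str, length: int = 50) -> str:
    """The fixed amino-acid motif owned by a synthetic profile.

    Deterministic in the profile name alone, so the same profile always
    plants the same motif regardless of run seed.
    """
    import zlib

    rng = np.random.default_rng(zlib.crc32(profile_name.encode()) % (2**31))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def encode_motif(motif: str) -> str:
    """Reverse-translate a motif with the fixed codon map."""
    codons = _build_codon_map()
    return "".join(codons[aa] for aa in motif)


@dataclass(frozen=True)
class ArchitectureSpec:
    """One synthetic family: an ordered domain architecture plus noise knobs.

    ``ordered_profiles`` is a list of (profile name, clan, source_db).
    ``spacing`` bounds the uniform nucleotide gap between consecutive
    motifs; ``dropout_prob`` independently omits each planted domain;
    ``decoy_rate`` is the per-genome probability of one spurious near-E=1
    hit in the synthetic hit table.  Genomes are padded with background to
    ``min_length`` so window-mode E-value rescaling is well exercised.
    """

    family: str
    ordered_profiles: tuple[tuple[str, str | None, str], ...]
    spacing: tuple[int, int] = (100, 400)
    dropout_prob: float = 0.0
    decoy_rate: float = 0.0
    alternate_strands: bool = False
    motif_length: int = 50
    min_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_prob < 1 and 0 <= self.decoy_rate < 1):
            raise ValueError("dropout_prob and decoy_rate must lie in [0, 1)")
        if self.spacing[0] < 0 or self.spacing[1] < self.spacing[0]:
            raise ValueError("spacing bounds must satisfy 0 <= lo <= hi")
        if self.spacing[1] < 1:
            raise ValueError("spacing too tight: need room between motifs")


@dataclass
class Placement:
    """Ground truth for one planted domain occurrence."""

    profile: str
    clan: str | None
    source_db: str
    strand: str
    nt_start: int  # 1-based inclusive
    nt_end: int
    frame: int
    aa_start: int  # 0-based position within the frame
    aa_sequence: str


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


def generate_genome(
    spec: ArchitectureSpec, genome_index: int = 0
) -> tuple[GenomeRecord, list[Placement]]:
    """One synthetic genome of a family, with its true domain placements.

    Deterministic in (spec.seed, genome_index).  Each surviving profile's
    motif is encoded in-frame at a sampled position; placements record the
    frame and frame-relative amino-acid start for recovery tests.
    """
    rng = np.random.default_rng((spec.seed, genome_index))
    lo, hi = spec.spacing
    segments: list[str] = []
    pending: list[tuple[str, str | None, str, str, int, str]] = []
    cursor = 0

    for name, clan, source in spec.ordered_profiles:
        if rng.random() < spec.dropout_prob:
            continue
        gap = int(rng.integers(lo, hi + 1))
        segments.append(_random_nt(rng, gap))
        cursor += gap
        motif = motif_for(name, spec.motif_length)
        nt = encode_motif(motif)
        if spec.alternate_strands and len(pending) % 2 == 1:
            strand = "-"
            segments.append(reverse_complement(nt))
        else:
            strand = "+"
            segments.append(nt)
        pending.append((name, clan, source, strand, cursor + 1, motif))
        cursor += len(nt)

    tail = int(rng.integers(lo, hi + 1))
    segments.append(_random_nt(rng, tail))
    cursor += tail
    if cursor < spec.min_length:
        segments.append(_random_nt(rng, spec.min_length - cursor))
        cursor = spec.min_length

    sequence = "".join(segments)
    L = len(sequence)
    placements = []
    for name, clan, source, strand, nt_start, motif in pending:
        nt_end = nt_start + 3 * len(motif) - 1
        if strand == "+":
            offset = (nt_start - 1) % 3
            frame = 1 + offset
            aa_start = (nt_start - 1 - offset) // 3
        else:
            prc = L - nt_end  # 0-based start on the reverse complement
            offset = prc % 3
            frame = 4 + offset
            aa_start = (prc - offset) // 3
        placements.append(
            Placement(
                profile=name,
                clan=clan,
                source_db=source,
                strand=strand,
                nt_start=nt_start,
                nt_end=nt_end,
                frame=frame,
                aa_start=aa_start,
                aa_sequence=motif,
            )
        )

    acc = f"{spec.family}_{genome_index:03d}"
    record = GenomeRecord(
        accession=acc,
        description=f"synthetic {spec.family} genome {genome_index}",
        sequence=sequence,
        family=spec.family,
    )
    return record, placements


@dataclass
class SyntheticDataset:
    """A generated corpus: genomes, truth, labels and a synthetic hit table."""

    genomes: list[GenomeRecord]
    placements: dict[str, list[Placement]]
    labels: dict[str, str]
    domtblout: Path | None = None
    profile_meta: dict[str, tuple[str | None, str]] = field(default_factory=dict)


DECOY_PROFILES = tuple(f"DECOY_{i}" for i in range(1, 6))


def _domtbl_row(
    target: str,
    tlen: int,
    query: str,
    qlen: int,
    i_evalue: float,
    score: float,
    hmm_from: int,
    hmm_to: int,
    ali_from: int,
    ali_to: int,
) -> str:
    return (
        f"{target} - {tlen} {query} - {qlen} {i_evalue:.2g} {score:.1f} 0.0 1 1 "
        f"{i_evalue:.2g} {i_evalue:.2g} {score:.1f} 0.0 {hmm_from} {hmm_to} "
        f"{ali_from} {ali_to} {ali_from} {ali_to} 0.98 -\n"
    )


def generate_hit_table(
    specs: Sequence[ArchitectureSpec],
    n_genomes: int,
    out_dir: str | Path,
    window_width: int = 200,
    step: int = 13,
    evalue_range: tuple[float, float] = (1e-30, 1e-12),
    decoy_evalue_range: tuple[float, float] = (0.6, 0.95),
) -> SyntheticDataset:
    """Genomes plus a matching synthetic ``--domtblout`` table.

    Planted hits are emitted once per search window that fully contains the
    motif — deliberately duplicating each domain across overlapping windows,
    exactly as a real windowed search would, so duplicate pruning is
    exercised.  Planted i-E-values are log-uniform in ``evalue_range`` (as
    if the search space were a single sequence); decoys sit just below 1 so
    the window-to-frame rescaling pushes them over the exclusion threshold.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genomes: list[GenomeRecord] = []
    placements: dict[str, list[Placement]] = {}
    labels: dict[str, str] = {}
    meta: dict[str, tuple[str | None, str]] = {}
    rows: list[tuple[str, str, int, str]] = []

    for spec in specs:
        for name, clan, source in spec.ordered_profiles:
            meta[name] = (clan, source)
        rng = np.random.default_rng((spec.seed, 10_007))
        for gi in range(n_genomes):
            rec, pls = generate_genome(spec, gi)
            genomes.append(rec)
            placements[rec.accession] = pls
            labels[rec.accession] = spec.family
            L = len(rec.sequence)
            for pl in pls:
                offset = (pl.frame - 1) if pl.frame <= 3 else (pl.frame - 4)
                frame_len = (L - offset) // 3
                aa_end = pl.aa_start + len(pl.aa_sequence)
                log_lo, log_hi = math.log10(evalue_range[0]), math.log10(evalue_range[1])
                i_ev = 10 ** rng.uniform(log_lo, log_hi)
                score = float(rng.uniform(60, 150))
                for wi, w in enumerate(range(0, frame_len, step)):
                    if w <= pl.aa_start and aa_end <= min(w + window_width, frame_len):
                        target = f"{rec.accession}|frame{pl.frame}|win{wi}|start{w}"
                        tlen = min(window_width, frame_len - w)
                        rows.append(
                            (
                                pl.profile,
                                target,
                                w,
                                _domtbl_row(
                                    target,
                                    tlen,
                                    pl.profile,
                                    len(pl.aa_sequence),
                                    i_ev,
                                    score,
                                    1,
                                    len(pl.aa_sequence),
                                    pl.aa_start - w + 1,
                                    aa_end - w,
                                ),
                            )
                        )
            if rng.random() < spec.decoy_rate:
                decoy = str(rng.choice(DECOY_PROFILES))
                meta.setdefault(decoy, (None, "PFAM"))
                frame = int(rng.integers(1, 7))
                offset = (frame - 1) if frame <= 3 else (frame - 4)
                frame_len = (L - offset) // 3
                w = int(rng.integers(0, max(frame_len - window_width, 1) // step + 1)) * step
                tlen = min(window_width, frame_len - w)
                a = int(rng.integers(1, max(tlen - 40, 2)))
                i_ev = float(rng.uniform(*decoy_evalue_range))
                target = f"{rec.accession}|frame{frame}|win{w // step}|start{w}"
                rows.append(
                    (
                        decoy,
                        target,
                        w,
                        _domtbl_row(
                            target, tlen, decoy, 40, i_ev,
                            float(rng.uniform(-2, 8)), 1, 40, a, min(a + 39, tlen),
                        ),
                    )
                )

    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    domtbl = out_dir / "synthetic.domtblout"
    with open(domtbl, "w") as fh:
        fh.write("# synthetic per-domain hits table (domtblout layout)\n")
        for _, _, _, line in rows:
            fh.write(line)

    labels_path = out_dir / "labels.tsv"
    with open(labels_path, "w") as fh:
        for acc, fam in labels.items():
            fh.write(f"{acc}\t{fam}\n")
    meta_path = out_dir / "profiles.tsv"
    with open(meta_path, "w") as fh:
        for name, (clan, source) in sorted(meta.items()):
            fh.write(f"{name}\t{clan or ''}\t{source}\n")
    from domainhood.genome_io import write_fna

    write_fna(genomes, out_dir / "genomes.fna")

    return SyntheticDataset(
        genomes=genomes,
        placements=placements,
        labels=labels,
        domtblout=domtbl,
        profile_meta=meta,
    )


def default_family_specs(
    n_families: int = 2, n_domains: int = 5, seed: int = 0
) -> list[ArchitectureSpec]:
    """Architecturally distinct families with disjoint profile/clan sets."""
    specs = []
    for f in range(n_families):
        profiles = tuple(
            (f"FAM{f}_DOM{d}", f"CL{f}{d // 2}", "PFAM") for d in range(n_domains)
        )
        specs.append(
            ArchitectureSpec(
                family=f"famF{f}",
                ordered_profiles=profiles,
                seed=seed * 1000 + f,
            )
        )
    return specs


def build_profile_hmm(profile_name: str, motif_length: int = 50, n_copies: int = 20):
    """A real profile HMM built from copies of the profile's motif.

    Lets plant-and-recover tests run the actual search engine against
    synthetic genomes.
    """
    import pyhmmer

    abc = pyhmmer.easel.Alphabet.amino()
    motif = motif_for(profile_name, motif_length)
    seqs = [
        pyhmmer.easel.TextSequence(name=f"{profile_name}_{i}".encode(), sequence=motif)
        for i in range(n_copies)
    ]
    msa = pyhmmer.easel.TextMSA(name=profile_name.encode(), sequences=seqs).digitize(abc)
    builder = pyhmmer.plan7.Builder(abc)
    hmm, _, _ = builder.build_msa(msa, pyhmmer.plan7.Background(abc))
    return hmm
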