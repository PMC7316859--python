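"""Genome ingestion, six-frame translation, windowing and coordinate mapping.

Coordinate conventions
----------------------
Genomic nucleotide positions are 1-based inclusive (GenBank convention).
Amino-acid positions inside a translated frame are 0-based half-open
internally; anything written to tables is converted to 1-based inclusive.

Frames are numbered 1-6: frames 1-3 read the forward strand at codon
offsets 0-2, frames 4-6 read the reverse complement at offsets 0-2.
Stop codons are retained as the sentinel residue ``*`` (frames are searched
whole, not split into ORFs), and any codon containing a non-ACGT symbol
translates to ``X``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STOP_SENTINEL = "*"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
_CODON_TO_AA.update({codon: STOP_SENTINEL for codon in _TABLE.stop_codons})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class GeneAnnotation:
    """A gene/CDS interval on a genome, 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -, got {self.strand!r}")


@dataclass
class GenomeRecord:
    """One genome (or contig): sequence, gene annotations and family label."""

    accession: str
    description: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: empty sequence")
        for g in self.genes:
            if g.start < 1 or g.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: gene {g.name} interval [{g.start}, {g.end}] "
                    f"outside [1, {len(self.sequence)}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranslatedFrame:
    """One of the six translation frames of a genome."""

    accession: str
    frame: int
    aa_sequence: str

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)

    @property
    def offset(self) -> int:
        """Codon offset (0-2) of this frame on its strand."""
        return (self.frame - 1) if self.frame <= 3 else (self.frame - 4)

    @property
    def strand(self) -> str:
        return "+" if self.frame <= 3 else "-"


@dataclass
class Window:
    """A slice of a translated frame fed to the search engine."""

    accession: str
    frame: int
    index: int
    aa_start: int
    aa_sequence: str

    @property
    def target_id(self) -> str:
        """FAA header used for search targets; decoded by the domtblout parser."""
        return f"{self.accession}|frame{self.frame}|win{self.index}|start{self.aa_start}"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_nt(seq: str) -> str:
    """Translate a nucleotide string in frame 0 with the standard code.

    Trailing 1-2 nt that do not fill a codon are ignored.  Codons with any
    character outside ACGT become ``X``; stops become the sentinel.
    """
    seq = seq.upper()
    n = len(seq) // 3
    return "".join(_CODON_TO_AA.get(seq[3 * i : 3 * i + 3], "X") for i in range(n))


def parse_genomes(path: str | Path, format: str = "fasta") -> list[GenomeRecord]:
    """Read genomes from a GenBank flat file or nucleotide FASTA.

    GenBank CDS features become :class:`GeneAnnotation` entries; the family
    is taken from the taxonomy lines when one ends in ``viridae``.  FASTA
    input yields records with empty gene lists.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"format must be 'fasta' or 'genbank', got {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), format):
        try:
            genes: list[GeneAnnotation] = []
            family: str | None = None
            if format == "genbank":
                for feat in rec.features:
                    if feat.type != "CDS":
                        continue
                    quals = feat.qualifiers
                    name = (
                        quals.get("gene", quals.get("locus_tag", quals.get("product", ["?"])))
                    )[0]
                    genes.append(
                        GeneAnnotation(
                            name=name,
                            start=int(feat.location.start) + 1,
                            end=int(feat.location.end),
                            strand="-" if feat.location.strand == -1 else "+",
                        )
                    )
                for taxon in rec.annotations.get("taxonomy", []):
                    if taxon.lower().endswith(("viridae", "virinae")):
                        family = taxon
                        break
            if rec.id in seen:
                raise ValueError(f"duplicate accession {rec.id}")
            seen.add(rec.id)
            records.append(
                GenomeRecord(
                    accession=rec.id,
                    description=rec.description,
                    sequence=str(rec.seq).upper(),
                    genes=genes,
                    family=family,
                )
            )
        except ValueError as exc:
            raise ValueError(f"malformed record {rec.id!r} in {path}: {exc}") from exc
    return records


def six_frame_translate(g: GenomeRecord) -> list[TranslatedFrame]:
    """Translate a genome in all six frames.

    Frames 1-3 read the forward strand at offsets 0-2; frames 4-6 read the
    reverse complement at offsets 0-2.  Each frame has
    ``floor((L - offset) / 3)`` residues, so the six frames jointly cover
    every codon start on both strands exactly once.
    """
    fwd = g.sequence.upper()
    rev = reverse_complement(fwd)
    frames = []
    for k in range(1, 7):
        strand_seq = fwd if k <= 3 else rev
        offset = (k - 1) if k <= 3 else (k - 4)
        frames.append(
            TranslatedFrame(
                accession=g.accession, frame=k, aa_sequence=translate_nt(strand_seq[offset:])
            )
        )
    return frames


def make_windows(f: TranslatedFrame, window_width: int = 200, step: int = 13) -> list[Window]:
    """Partition a frame into overlapping windows of ``window_width`` residues.

    Window starts are 0, step, 2*step, ... up to the last start strictly below
    the frame length; the tail window may be shorter than ``window_width``.
    Consecutive full windows overlap by ``window_width - step`` residues and
    every residue of the frame lies in at least one window.
    """
    if not (window_width >= step >= 1):
        raise ValueError(f"need window_width >= step >= 1, got {window_width}, {step}")
    return [
        Window(
            accession=f.accession,
            frame=f.frame,
            index=i,
            aa_start=start,
            aa_sequence=f.aa_sequence[start : start + window_width],
        )
        for i, start in enumerate(range(0, f.aa_length, step))
    ]


def extract_gene_sequences(g: GenomeRecord) -> list[tuple[GeneAnnotation, str]]:
    """Translate each annotated gene span in frame 1 of the span.

    Minus-strand genes are reverse-complemented first.  Spans that are not a
    codon multiple are truncated by the trailing 1-2 nt with a warning
    (splicing and slippage are not modelled).
    """
    out = []
    for gene in g.genes:
        span = g.sequence[gene.start - 1 : gene.end]
        if gene.strand == "-":
            span = reverse_complement(span)
        if len(span) % 3:
            logger.warning(
                "%s gene %s: span length %d not a codon multiple; truncating %d nt",
                g.accession,
                gene.name,
                len(span),
                len(span) % 3,
            )
        out.append((gene, translate_nt(span)))
    return out


def map_to_genomic(
    frame: int, aa_start: int, aa_end_exclusive: int, nt_length: int
) -> tuple[int, int, str]:
    """Map a half-open amino-acid interval in a frame to genomic coordinates.

    Returns ``(nt_start, nt_end, strand)`` with 1-based inclusive positions on
    the forward strand; reverse-frame intervals are reflected so that
    ``nt_start <= nt_end`` and strand is ``-``.  The span length is always
    ``3 * (aa_end_exclusive - aa_start)``.
    """
    if not 1 <= frame <= 6:
        raise ValueError(f"frame must be 1-6, got {frame}")
    offset = (frame - 1) if frame <= 3 else (frame - 4)
    frame_len = (nt_length - offset) // 3
    if not (0 <= aa_start < aa_end_exclusive <= frame_len):
        raise ValueError(
            f"aa interval [{aa_start}, {aa_end_exclusive}) out of bounds for "
            f"frame {frame} of a {nt_length} nt genome (frame length {frame_len})"
        )
    if frame <= 3:
        nt_start = offset + 3 * aa_start + 1
        nt_end = offset + 3 * aa_end_exclusive
        return nt_start, nt_end, "+"
    # reverse frames: aa positions index the reverse complement; reflect back
    nt_end = nt_length - offset - 3 * aa_start
    nt_start = nt_length - offset - 3 * aa_end_exclusive + 1
    return nt_start, nt_end, "-"


def extract_frame_subsequence(
    g: GenomeRecord, frame: int, nt_start: int, nt_end: int, strand: str
) -> str:
    """Re-translate a mapped genomic span in its original frame.

    Used by the round-trip validation: extracting the genomic span of a
    domain hit and translating it must reproduce the hit's amino acids.
    """
    span = g.sequence[nt_start - 1 : nt_end]
    if strand == "-":
        span = reverse_complement(span)
    return translate_nt(span)


# ---------------------------------------------------------------------------
# writers

def write_fna(records: Iterable[GenomeRecord], path: str | Path) -> Path:
    """Write genomes as a standardized nucleotide FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.description}\n{rec.sequence}\n")
    return path


def write_frame_faas(
    frames: Sequence[TranslatedFrame], out_dir: str | Path
) -> list[Path]:
    """Write one FAA per frame, named ``<accession>.frame<k>.faa``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        p = out_dir / f"{f.accession}.frame{f.frame}.faa"
        with open(p, "w") as fh:
            fh.write(f">{f.accession}|frame{f.frame}\n{f.aa_sequence}\n")
        paths.append(p)
    return paths


def write_window_faa(windows: Sequence[Window], path: str | Path) -> Path:
    """Write search windows as a FAA with self-describing headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for w in windows:
            if w.aa_sequence:
                fh.write(f">{w.target_id}\n{w.aa_sequence}\n")
    return path
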