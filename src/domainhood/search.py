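"""Profile-HMM search: bundling, job planning, hmmsearch execution, parsing.

The search engine is pyhmmer's reimplementation of HMMER3's hmmsearch,
run in-process with a per-domain bit-score reporting floor (``domT``) rather
than an E-value threshold.  Profiles are partitioned into bundles so that
one job = (one frame FAA, one bundle); jobs are independent and resumable
through a line-oriented tracking log.

When no profile database is available the downstream stages run in "ingest
mode" on externally produced ``--domtblout`` tables; everything after
:func:`parse_domtblout` is engine-agnostic.

Search targets are named so the parser can recover their provenance:

* whole frame:  ``<accession>|frame<k>``
* window:       ``<accession>|frame<k>|win<index>|start<aa_start>``
* gene:         ``<accession>|gene|<name>|<start>-<end><strand>|L<genome_len>``

Window- and gene-relative alignment coordinates are shifted into frame
coordinates at parse time, so every DomainHit lives on a translated frame.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, TypeVar

from Bio import SearchIO

T = TypeVar("T")

SOURCE_DBS = ("PFAM", "VFAM", "PVOG")


@dataclass(frozen=True)
class ProfileMeta:
    """Clan and source-database metadata for one profile HMM.

    Clan membership is not carried uniformly inside .hmm files, so it comes
    from a sidecar TSV (``name<TAB>clan<TAB>source_db``); vFAM/pVOG profiles
    have no clan unless one is provided.
    """

    name: str
    clan: str | None = None
    source_db: str = "PFAM"
    length: int | None = None

    def __post_init__(self) -> None:
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"source_db must be one of {SOURCE_DBS}, got {self.source_db!r}")


@dataclass
class DomainHit:
    """One profile-HMM domain match, in translated-frame coordinates.

    ``ali_start``/``ali_end`` (and the envelope) are 1-based inclusive
    amino-acid positions on the *frame* (window/gene offsets already
    applied).  ``adj_evalue`` and genomic coordinates are filled later by
    the curation stage.
    """

    profile: str
    accession: str
    frame: int
    search_mode: Literal["genome", "window", "gene"]
    target_id: str
    ali_start: int
    ali_end: int
    env_start: int
    env_end: int
    hmm_from: int
    hmm_to: int
    bit_score: float
    i_evalue: float
    target_len: int
    clan: str | None = None
    source_db: str = "PFAM"
    adj_evalue: float | None = None
    nt_start: int | None = None
    nt_end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (self.env_start <= self.ali_start <= self.ali_end <= self.env_end):
            raise ValueError(
                f"{self.profile}@{self.target_id}: envelope must contain alignment "
                f"({self.env_start},{self.ali_start},{self.ali_end},{self.env_end})"
            )
        if self.i_evalue <= 0:
            raise ValueError(f"{self.profile}@{self.target_id}: i_evalue must be > 0")


def load_profile_metadata(path: str | Path) -> dict[str, ProfileMeta]:
    """Read the sidecar profile metadata TSV (name, clan, source_db)."""
    metas: dict[str, ProfileMeta] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            name, clan, source = parts[:3]
            if name in metas:
                raise ValueError(f"{path}:{ln}: duplicate profile name {name!r}")
            metas[name] = ProfileMeta(
                name=name, clan=clan or None, source_db=source.upper()
            )
    return metas


def annotate_hits(hits: Iterable[DomainHit], metas: dict) -> None:
    """Fill clan/source_db on hits from the profile metadata, in place.

    ``metas`` maps profile name to a :class:`ProfileMeta` or a
    ``(clan, source_db)`` pair.
    """
    for h in hits:
        meta = metas.get(h.profile)
        if meta is None:
            continue
        if isinstance(meta, tuple):
            h.clan, h.source_db = meta
        else:
            h.clan = meta.clan
            h.source_db = meta.source_db


def bundle_profiles(profiles: Sequence[T], n_bundles: int = 40) -> list[list[T]]:
    """Partition profiles into ``n_bundles`` near-even bundles.

    Input order is preserved and bundle sizes differ by at most one, so the
    concatenation of all bundles reproduces the database.
    """
    if n_bundles < 1:
        raise ValueError("n_bundles must be >= 1")
    if not profiles:
        raise ValueError("cannot bundle an empty profile database")
    n = len(profiles)
    base, extra = divmod(n, n_bundles)
    bundles, pos = [], 0
    for i in range(n_bundles):
        size = base + (1 if i < extra else 0)
        bundles.append(list(profiles[pos : pos + size]))
        pos += size
    return bundles


def write_hmm_bundles(
    hmm_path: str | Path, out_dir: str | Path, n_bundles: int = 40
) -> list[Path]:
    """Split an HMMER3 ASCII profile database into bundle files."""
    import pyhmmer

    with pyhmmer.plan7.HMMFile(str(hmm_path)) as hf:
        hmms = list(hf)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, bundle in enumerate(bundle_profiles(hmms, n_bundles)):
        p = out_dir / f"bundle{i:03d}.hmm"
        with open(p, "wb") as fh:
            for hmm in bundle:
                hmm.write(fh)
        paths.append(p)
    return paths


def plan_jobs(frames: Sequence[T], bundles: Sequence[T]) -> list[tuple[T, T]]:
    """Cross every frame FAA with every profile bundle: frames x bundles jobs."""
    if not frames or not bundles:
        raise ValueError("need at least one frame and one bundle")
    return [(f, b) for f in frames for b in bundles]


def run_search(
    faa: str | Path,
    bundle: str | Path | Sequence,
    out: str | Path,
    domT: float = -5.0,
    cpus: int = 1,
) -> Path:
    """Run hmmsearch (pyhmmer) of a profile bundle against an FAA file.

    Reporting is thresholded on the per-domain bit score (``domT``), not an
    E-value, and a standard HMMER3 ``--domtblout`` per-domain table is
    written.  E-values are computed against the actual number of target
    sequences in the FAA; the curation stage renormalizes this.
    """
    try:
        import pyhmmer
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "no profile-search engine available; supply precomputed "
            "--domtblout tables and use ingest mode"
        ) from exc

    out = Path(out)
    alphabet = pyhmmer.easel.Alphabet.amino()
    if isinstance(bundle, (str, Path)):
        with pyhmmer.plan7.HMMFile(str(bundle)) as hf:
            hmms = list(hf)
    else:
        hmms = list(bundle)

    sequences = []
    faa = Path(faa)
    if faa.stat().st_size > 0:
        with pyhmmer.easel.SequenceFile(str(faa), digital=True, alphabet=alphabet) as sf:
            sequences = list(sf)

    with open(out, "wb") as fh:
        if not sequences or not hmms:
            fh.write(b"# no targets searched\n")
            return out
        first = True
        for tophits in pyhmmer.hmmsearch(hmms, sequences, cpus=cpus, domT=domT):
            tophits.write(fh, format="domains", header=first)
            first = False
    return out


def count_faa_sequences(faa: str | Path) -> int:
    """Number of target sequences in an FAA (the engine's search-space size)."""
    with open(faa) as fh:
        return sum(1 for line in fh if line.startswith(">"))


_WINDOW_RE = re.compile(r"^(?P<acc>.+)\|frame(?P<frame>[1-6])\|win(?P<win>\d+)\|start(?P<start>\d+)$")
_FRAME_RE = re.compile(r"^(?P<acc>.+)\|frame(?P<frame>[1-6])$")
_GENE_RE = re.compile(
    r"^(?P<acc>.+)\|gene\|(?P<name>[^|]*)\|(?P<start>\d+)-(?P<end>\d+)(?P<strand>[+-])\|L(?P<L>\d+)$"
)


def gene_target_id(accession: str, gene, genome_length: int) -> str:
    """Self-describing FAA header for a gene-mode search target."""
    return (
        f"{accession}|gene|{gene.name}|{gene.start}-{gene.end}{gene.strand}"
        f"|L{genome_length}"
    )


def _decode_target(target_id: str) -> tuple[str, int, str, int]:
    """Return (accession, frame, search_mode, aa_shift) for a target name.

    ``aa_shift`` is the 0-based offset of the searched sequence within its
    frame, so target-relative alignment coordinates + shift are frame
    coordinates.
    """
    m = _WINDOW_RE.match(target_id)
    if m:
        return m["acc"], int(m["frame"]), "window", int(m["start"])
    m = _FRAME_RE.match(target_id)
    if m:
        return m["acc"], int(m["frame"]), "genome", 0
    m = _GENE_RE.match(target_id)
    if m:
        start, end, L = int(m["start"]), int(m["end"]), int(m["L"])
        if m["strand"] == "+":
            offset = (start - 1) % 3
            frame = 1 + offset
            shift = (start - 1 - offset) // 3
        else:
            prc = L - end  # 0-based position on the reverse complement
            offset = prc % 3
            frame = 4 + offset
            shift = (prc - offset) // 3
        return m["acc"], frame, "gene", shift
    raise ValueError(f"unrecognized target naming scheme: {target_id!r}")


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` table into frame-coordinate DomainHits.

    Target names must follow the package naming scheme (see module docs);
    window/gene-relative coordinates are shifted to frame coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.split()) < 23:
                raise ValueError(f"{path}:{ln}: malformed domtblout row (need >= 23 columns)")
    hits: list[DomainHit] = []
    for qres in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        for hit in qres:
            acc, frame, mode, shift = _decode_target(hit.id)
            for hsp in hit:
                hits.append(
                    DomainHit(
                        profile=qres.id,
                        accession=acc,
                        frame=frame,
                        search_mode=mode,
                        target_id=hit.id,
                        ali_start=hsp.hit_start + 1 + shift,
                        ali_end=hsp.hit_end + shift,
                        env_start=hsp.env_start + 1 + shift,
                        env_end=hsp.env_end + shift,
                        hmm_from=hsp.query_start + 1,
                        hmm_to=hsp.query_end,
                        bit_score=float(hsp.bitscore),
                        i_evalue=float(hsp.evalue),
                        target_len=int(hit.seq_len),
                    )
                )
    return hits


def compile_hits(paths: Iterable[str | Path]) -> list[DomainHit]:
    """Concatenate per-job domtblout tables into one hit list (idempotent)."""
    hits: list[DomainHit] = []
    for p in sorted(Path(p) for p in paths):
        hits.extend(parse_domtblout(p))
    return hits


STAGES = ("compiled", "translated", "searched", "curated", "neighborhoods")
STATUSES = ("pending", "done", "failed")


@dataclass
class TrackingLog:
    """Append-only progress log: one ``accession\\tstage\\tstatus\\ttime`` line.

    The latest line for an (accession, stage) pair wins, so re-running a
    pipeline appends corrections rather than rewriting history.  A stage is
    marked done only after its outputs exist on disk.
    """

    path: Path
    _state: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "TrackingLog":
        log = cls(path=Path(path))
        if log.path.exists():
            with open(log.path) as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) >= 3:
                        log._state[(parts[0], parts[1])] = parts[2]
        return log

    def mark(self, accession: str, stage: str, status: str) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if status not in STATUSES:
            raise ValueError(f"unknown status {status!r}")
        self._state[(accession, stage)] = status
        with open(self.path, "a") as fh:
            fh.write(f"{accession}\t{stage}\t{status}\t{time.strftime('%Y-%m-%dT%H:%M:%S')}\n")

    def status(self, accession: str, stage: str) -> str:
        return self._state.get((accession, stage), "pending")


def run_jobs(
    jobs: Sequence[tuple[Path, Path]],
    out_dir: str | Path,
    domT: float = -5.0,
    engine=run_search,
    force: bool = False,
) -> list[Path]:
    """Execute (frame FAA, bundle) jobs, skipping those whose output exists.

    Jobs are independent and may run in any order; an output file is written
    only on success, so a failed or deleted job is simply re-run on the next
    pass.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for faa, bundle in jobs:
        out = out_dir / f"{Path(faa).stem}__{Path(bundle).stem}.domtblout"
        if force or not out.exists():
            tmp = out.with_suffix(".part")
            engine(faa, bundle, tmp, domT=domT)
            tmp.rename(out)  # move into place only when complete
        outputs.append(out)
    return outputs
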