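"""Hit curation: E-value rescaling, filtering, dedup, clan-aware de-overlap.

Windowed searching deliberately over-identifies domains: the same region is
searched in many overlapping windows and by many related profiles.  This
module turns the raw hit table into a non-redundant set:

1.  Independent E-values are adjusted twice — normalized to a
    single-sequence search space (divide by the number of targets the
    engine searched) and rescaled linearly by the frame-to-window length
    ratio, so a hit's E-value means "expected chance hits in one genome".
2.  Hits with adjusted E-value > 1 are excluded.
3.  Hits that are 100% identical (same profile, frame and alignment span,
    found in several overlapping windows) collapse to one copy.
4.  Remaining overlaps are resolved per frame with clan-aware rules:
    same-clan hits tolerate < 33% overlap, different-clan hits < 45% (and
    removal additionally requires a 10,000-fold E-value ratio unless both
    are below the significance threshold, in which case both stay), and a
    vFAM/pVOG hit overlapping a PFAM hit survives only if its log10
    E-value is at least five times the PFAM hit's.  Adjacent and skip-1
    neighbors along the sorted frame are compared, repeating to a fixed
    point so the result is order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from domainhood.search import DomainHit

RemovalReason = Literal[
    "none", "duplicate", "same_clan_overlap", "diff_clan_overlap", "db_precedence"
]


@dataclass(frozen=True)
class CurationParams:
    """Thresholds governing filtering and de-overlap.

    same_clan_max_overlap / diff_clan_max_overlap
        Maximum tolerated overlap fraction (of the shorter domain) for
        same-clan and different-clan pairs.
    fold_ratio
        E-value ratio the better hit must exceed before a different-clan
        overlap removes the worse hit.
    significance_threshold
        Adjusted E-value below which a hit counts as high quality; two
        significant different-clan hits may overlap freely.
    calc_start_slack
        How far (residues) a domain's effective start may be extended
        toward where the profile would normally begin.
    db_log_factor
        A vFAM/pVOG hit overlapping a PFAM hit survives only if
        ``log10(E_v) <= db_log_factor * log10(E_pfam)``.
    max_adj_evalue
        Hits with adjusted E-value above this are excluded outright.
    """

    same_clan_max_overlap: float = 0.33
    diff_clan_max_overlap: float = 0.45
    fold_ratio: float = 1e4
    significance_threshold: float = 1e-7
    calc_start_slack: int = 20
    db_log_factor: float = 5.0
    max_adj_evalue: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.same_clan_max_overlap < 1 and 0 < self.diff_clan_max_overlap < 1):
            raise ValueError("overlap thresholds must be in (0, 1)")
        if self.fold_ratio <= 1:
            raise ValueError("fold_ratio must be > 1")


@dataclass
class CuratedDomain(DomainHit):
    """A DomainHit annotated with its curation outcome.

    ``calc_start`` extends the alignment start toward where the profile
    would normally begin (bounded by the slack); it is the effective start
    used for overlap computation.  ``kept`` is true iff ``removal_reason``
    is ``"none"``.
    """

    calc_start: int = 0
    kept: bool = True
    removal_reason: RemovalReason = "none"

    @classmethod
    def from_hit(cls, hit: DomainHit, params: CurationParams = CurationParams()) -> "CuratedDomain":
        d = dict(hit.__dict__)
        d["calc_start"] = calc_start(hit.ali_start, hit.hmm_from, params.calc_start_slack)
        return cls(**d)


def calc_start(ali_start: int, hmm_from: int, slack: int = 20) -> int:
    """Effective domain start: alignment start pulled back toward the
    profile's first match state, by at most ``slack`` residues, floored at 1."""
    return max(ali_start - min(hmm_from - 1, slack), 1)


def adjust_evalue(
    hit: DomainHit,
    searched_length: int,
    frame_aa_length: int,
    n_targets_in_search: int = 1,
) -> float:
    """Two-step E-value adjustment for windowed searching.

    First the engine's per-database scaling is normalized to a
    single-sequence search space (divide by the number of targets); then,
    for window-mode hits, the E-value is rescaled linearly by the ratio of
    the frame length to the searched window length.  Whole-frame (and
    gene-mode) searches get no second factor.
    """
    if searched_length < 1 or frame_aa_length < 1 or n_targets_in_search < 1:
        raise ValueError("lengths and target counts must be >= 1")
    adj = hit.i_evalue / n_targets_in_search
    if hit.search_mode == "window":
        adj *= frame_aa_length / searched_length
    return adj


def adjust_hits(
    hits: Iterable[DomainHit],
    frame_lengths: Mapping[tuple[str, int], int],
    n_targets_in_search: int = 1,
    params: CurationParams = CurationParams(),
) -> list[CuratedDomain]:
    """Adjust every hit's E-value and wrap it as a CuratedDomain."""
    out = []
    for h in hits:
        cur = CuratedDomain.from_hit(h, params)
        cur.adj_evalue = adjust_evalue(
            h,
            searched_length=h.target_len,
            frame_aa_length=frame_lengths[(h.accession, h.frame)],
            n_targets_in_search=n_targets_in_search,
        )
        out.append(cur)
    return out


def filter_hits(hits: Sequence[CuratedDomain], max_adj: float = 1.0) -> list[CuratedDomain]:
    """Exclude hits with adjusted E-value above ``max_adj``; survivors unchanged."""
    for h in hits:
        if h.adj_evalue is None:
            raise ValueError(f"{h.profile}@{h.target_id}: adj_evalue not populated")
    return [h for h in hits if h.adj_evalue <= max_adj]


def _quality_key(h: CuratedDomain) -> tuple:
    """Sort key: smaller = better.  Adjusted E-value, then bit score (higher
    wins), then earlier calculated start, then profile name."""
    return (h.adj_evalue, -h.bit_score, h.calc_start, h.profile, h.target_id)


def prune_exact_duplicates(hits: Sequence[CuratedDomain]) -> list[CuratedDomain]:
    """Collapse 100%-overlapping copies of a hit to the best single copy.

    Hits identical in (profile, accession, frame, ali_start, ali_end) — the
    same domain re-found in several overlapping windows — keep only the
    smallest adjusted E-value.
    """
    best: dict[tuple, CuratedDomain] = {}
    for h in hits:
        key = (h.profile, h.accession, h.frame, h.ali_start, h.ali_end)
        if key not in best or _quality_key(h) < _quality_key(best[key]):
            best[key] = h
    # preserve input order of the survivors
    kept = set(id(h) for h in best.values())
    return [h for h in hits if id(h) in kept]


def overlap_fraction(a: CuratedDomain, b: CuratedDomain) -> float:
    """Overlap of the [calc_start, ali_end] intervals, as a fraction of the
    shorter domain.

    The shorter-domain denominator makes a small domain nested inside a
    large one register as fully overlapping.  Overlap is only defined
    within one frame of one genome.
    """
    if a.accession != b.accession or a.frame != b.frame:
        raise ValueError("overlap is defined per accession and frame")
    inter = min(a.ali_end, b.ali_end) - max(a.calc_start, b.calc_start) + 1
    if inter <= 0:
        return 0.0
    shorter = min(a.ali_end - a.calc_start, b.ali_end - b.calc_start) + 1
    return inter / shorter


def _resolve_pair(
    a: CuratedDomain, b: CuratedDomain, params: CurationParams
) -> tuple[CuratedDomain, RemovalReason] | None:
    """Apply the de-overlap rules to one overlapping pair.

    Returns (loser, reason) or None if both hits survive this comparison.
    Rules are applied in order: same-clan overlap, different-clan overlap,
    then vFAM/pVOG-vs-PFAM precedence.
    """
    frac = overlap_fraction(a, b)
    if frac <= 0.0:
        return None
    worse = max(a, b, key=_quality_key)
    better = a if worse is b else b

    same_clan = a.clan is not None and a.clan == b.clan
    if same_clan:
        if frac >= params.same_clan_max_overlap:
            return worse, "same_clan_overlap"
    else:
        both_significant = (
            a.adj_evalue <= params.significance_threshold
            and b.adj_evalue <= params.significance_threshold
        )
        if not both_significant and frac >= params.diff_clan_max_overlap:
            if better.adj_evalue <= worse.adj_evalue / params.fold_ratio:
                return worse, "diff_clan_overlap"

    # database precedence: vFAM/pVOG over PFAM needs a much stronger E-value
    srcs = {a.source_db, b.source_db}
    if "PFAM" in srcs and srcs & {"VFAM", "PVOG"}:
        v = a if a.source_db in ("VFAM", "PVOG") else b
        p = b if v is a else a
        # clamp below 1 so both logs are negative
        log_v = math.log10(min(v.adj_evalue, 1.0 - 1e-12))
        log_p = math.log10(min(p.adj_evalue, 1.0 - 1e-12))
        if not (log_v <= params.db_log_factor * log_p):
            return v, "db_precedence"
    return None


def _sort_key(h: CuratedDomain) -> tuple:
    return (h.calc_start, h.ali_start, h.ali_end, h.profile, h.target_id)


def deoverlap(
    hits: Sequence[CuratedDomain], params: CurationParams = CurationParams()
) -> list[CuratedDomain]:
    """Resolve overlapping hits within each (accession, frame).

    Hits are sorted by calculated start; every adjacent and skip-1 pair
    (A-B, B-C and A-C) is compared with :func:`_resolve_pair`.  Removed
    hits drop out of later comparisons and the pass repeats until no
    removal occurs, so the kept-set is independent of input order.  Hits on
    different frames never compete (double coding on opposite strands is
    preserved).

    Returns the full list with ``kept``/``removal_reason`` marked; input
    order is preserved.
    """
    by_frame: dict[tuple[str, int], list[CuratedDomain]] = {}
    for h in hits:
        h.kept, h.removal_reason = True, "none"
        by_frame.setdefault((h.accession, h.frame), []).append(h)

    for group in by_frame.values():
        changed = True
        while changed:
            changed = False
            alive = sorted((h for h in group if h.kept), key=_sort_key)
            for i in range(len(alive)):
                if not alive[i].kept:
                    continue
                for j in (i + 1, i + 2):
                    if j >= len(alive) or not alive[i].kept or not alive[j].kept:
                        continue
                    verdict = _resolve_pair(alive[i], alive[j], params)
                    if verdict is not None:
                        loser, reason = verdict
                        loser.kept = False
                        loser.removal_reason = reason
                        changed = True
    return list(hits)


def kept_only(hits: Iterable[CuratedDomain]) -> list[CuratedDomain]:
    return [h for h in hits if h.kept]


# ---------------------------------------------------------------------------
# tabular I/O — the curated-hit table ("trimmed domain compile" analogue)

_COLUMNS = [
    "profile", "clan", "source_db", "accession", "frame", "search_mode",
    "target_id", "ali_start", "ali_end", "env_start", "env_end",
    "hmm_from", "hmm_to", "bit_score", "i_evalue", "adj_evalue",
    "target_len", "calc_start", "nt_start", "nt_end", "strand",
    "kept", "removal_reason",
]


def write_curated_table(hits: Sequence[CuratedDomain], path) -> None:
    """Write curated hits as a TSV, one row per hit, removal reasons retained."""
    import pandas as pd

    rows = [{c: getattr(h, c) for c in _COLUMNS} for h in hits]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_curated_table(path) -> list[CuratedDomain]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict("records"):
        for key in ("clan", "strand"):
            if isinstance(row.get(key), float) and math.isnan(row[key]):
                row[key] = None
        for key in ("nt_start", "nt_end"):
            row[key] = None if row[key] is None or (
                isinstance(row[key], float) and math.isnan(row[key])
            ) else int(row[key])
        out.append(CuratedDomain(**row))
    return out
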