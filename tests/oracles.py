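"""Independent reference implementations used only to check the package.

These re-derive expected results from first principles (brute force,
pair counting) and never call the code paths they validate.
"""

from __future__ import annotations

import math
from itertools import combinations


def ari_pair_counting(labels_a, labels_b) -> float:
    """Adjusted Rand index from exhaustive pair counting.

    Classify every unordered item pair by whether the two items share a
    cluster in each labeling, then chance-correct the Rand agreement.
    """
    n11 = n10 = n01 = n00 = 0
    for i, j in combinations(range(len(labels_a)), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


def oracle_deoverlap(hits, params):
    """Brute-force de-overlap: apply the rules to ALL pairs to a fixed point.

    Pairs are scanned in the calc_start sort order; a removed hit drops out
    immediately.  Rules, per overlapping pair (fraction of the shorter
    domain's [calc_start, ali_end] span):

    * same non-null clan and overlap >= 33%: drop the worse E-value;
    * different clans, not both significant, overlap >= 45% and a
      10,000-fold E-value gap: drop the worse;
    * a vFAM/pVOG hit over a PFAM hit survives only if
      log10(E_v) <= 5 * log10(E_pfam) (clamped below 1).

    Returns the set of kept hits' identity keys.
    """

    def badness(h):
        return (h.adj_evalue, -h.bit_score, h.calc_start, h.profile, h.target_id)

    def pair_loser(a, b):
        inter = min(a.ali_end, b.ali_end) - max(a.calc_start, b.calc_start) + 1
        if inter <= 0:
            return None
        shorter = min(a.ali_end - a.calc_start, b.ali_end - b.calc_start) + 1
        frac = inter / shorter
        worse = max(a, b, key=badness)
        better = a if worse is b else b
        if a.clan is not None and a.clan == b.clan:
            if frac >= params.same_clan_max_overlap:
                return worse
        else:
            both_sig = (
                a.adj_evalue <= params.significance_threshold
                and b.adj_evalue <= params.significance_threshold
            )
            if (
                not both_sig
                and frac >= params.diff_clan_max_overlap
                and better.adj_evalue <= worse.adj_evalue / params.fold_ratio
            ):
                return worse
        if {a.source_db, b.source_db} >= {"PFAM"} and {a.source_db, b.source_db} & {
            "VFAM",
            "PVOG",
        }:
            v = a if a.source_db in ("VFAM", "PVOG") else b
            p = b if v is a else a
            lv = math.log10(min(v.adj_evalue, 1 - 1e-12))
            lp = math.log10(min(p.adj_evalue, 1 - 1e-12))
            if not (lv <= params.db_log_factor * lp):
                return v
        return None

    alive = sorted(
        hits, key=lambda h: (h.calc_start, h.ali_start, h.ali_end, h.profile, h.target_id)
    )
    removed = set()
    changed = True
    while changed:
        changed = False
        order = [h for h in alive if id(h) not in removed]
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                a, b = order[i], order[j]
                if id(a) in removed or id(b) in removed:
                    continue
                if a.accession != b.accession or a.frame != b.frame:
                    continue
                loser = pair_loser(a, b)
                if loser is not None:
                    removed.add(id(loser))
                    changed = True
    return {
        (h.profile, h.target_id, h.ali_start, h.ali_end)
        for h in hits
        if id(h) not in removed
    }
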