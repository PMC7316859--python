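import copy
import itertools

import numpy as np
import pytest

from domainhood.curation import (
    CurationParams,
    CuratedDomain,
    adjust_evalue,
    calc_start,
    deoverlap,
    filter_hits,
    kept_only,
    overlap_fraction,
    prune_exact_duplicates,
)
from domainhood.search import DomainHit
from oracles import oracle_deoverlap

PARAMS = CurationParams()


def mk(
    start,
    end,
    *,
    clan=None,
    source="PFAM",
    adj=1e-10,
    bit=50.0,
    profile="P",
    hmm_from=1,
    acc="g",
    frame=1,
    tid=None,
    mode="genome",
):
    """A curated hit with explicit interval, clan, source and adjusted E-value."""
    h = CuratedDomain(
        profile=profile,
        accession=acc,
        frame=frame,
        search_mode=mode,
        target_id=tid or f"{acc}|frame{frame}",
        ali_start=start,
        ali_end=end,
        env_start=start,
        env_end=end,
        hmm_from=hmm_from,
        hmm_to=hmm_from + (end - start),
        bit_score=bit,
        i_evalue=max(adj, 1e-300),
        target_len=10_000,
        clan=clan,
        source_db=source,
        adj_evalue=adj,
    )
    h.calc_start = calc_start(start, hmm_from, PARAMS.calc_start_slack)
    return h


def kept_keys(hits):
    return {(h.profile, h.target_id, h.ali_start, h.ali_end) for h in kept_only(hits)}


class TestAdjustEvalue:
    def test_window_rescaling(self):
        h = mk(1, 50, mode="window")
        h.i_evalue = 1e-10
        assert adjust_evalue(h, 200, 10_000, 1) == pytest.approx(5e-9)

    def test_genome_mode_only_normalizes_targets(self):
        h = mk(1, 50, mode="genome")
        h.i_evalue = 4e-8
        assert adjust_evalue(h, 3333, 3333, 4) == pytest.approx(1e-8)

    def test_identity_when_window_equals_frame(self):
        h = mk(1, 50, mode="window")
        h.i_evalue = 0.5
        assert adjust_evalue(h, 200, 200, 1) == pytest.approx(0.5)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            adjust_evalue(mk(1, 50), 0, 100, 1)


class TestFilterHits:
    def test_threshold_straddle(self):
        keep, drop = mk(1, 50, adj=0.99), mk(60, 110, adj=1.01)
        assert filter_hits([keep, drop]) == [keep]

    def test_empty(self):
        assert filter_hits([]) == []

    def test_counts(self):
        hits = [mk(i * 10, i * 10 + 40, adj=(2.0 if i < 4 else 1e-8), tid=f"t{i}") for i in range(10)]
        assert len(filter_hits(hits)) == 6


class TestPruneExactDuplicates:
    def test_window_copies_collapse(self):
        copies = [
            mk(100, 149, adj=a, tid=f"g|frame1|win{w}|start{w*13}", mode="window")
            for w, a in [(0, 1e-9), (1, 1e-12), (2, 1e-10)]
        ]
        out = prune_exact_duplicates(copies)
        assert len(out) == 1 and out[0].adj_evalue == 1e-12

    def test_near_duplicates_both_kept(self):
        a, b = mk(100, 149), mk(100, 150)
        assert prune_exact_duplicates([a, b]) == [a, b]

    def test_single_unchanged(self):
        h = mk(1, 50)
        assert prune_exact_duplicates([h]) == [h]


class TestOverlapFraction:
    def test_identical(self):
        assert overlap_fraction(mk(1, 100), mk(1, 100)) == 1.0

    def test_disjoint(self):
        assert overlap_fraction(mk(1, 100), mk(200, 300)) == 0.0

    def test_partial(self):
        assert overlap_fraction(mk(1, 100), mk(61, 160)) == pytest.approx(0.40)

    def test_uses_calculated_start(self):
        # hmm_from=11 pulls the effective start back 10 residues
        a = mk(1, 100)
        b = mk(111, 210, hmm_from=11)
        assert b.calc_start == 101
        assert overlap_fraction(a, b) == 0.0
        b2 = mk(91, 190, hmm_from=11)
        assert b2.calc_start == 81
        assert overlap_fraction(a, b2) == pytest.approx(20 / 100)

    def test_cross_frame_is_error(self):
        with pytest.raises(ValueError):
            overlap_fraction(mk(1, 100, frame=1), mk(1, 100, frame=4))


class TestDeoverlapRules:
    def test_same_clan_overlap_removes_worse(self):
        good = mk(1, 100, clan="CL1", adj=1e-20, profile="A", tid="a")
        bad = mk(51, 150, clan="CL1", adj=1e-5, profile="B", tid="b")
        out = deoverlap([good, bad], PARAMS)
        assert good.kept and not bad.kept
        assert bad.removal_reason == "same_clan_overlap"
        assert out == [good, bad]

    def test_same_clan_below_threshold_keeps_both(self):
        a = mk(1, 100, clan="CL1", adj=1e-20, profile="A", tid="a")
        b = mk(69, 168, clan="CL1", adj=1e-5, profile="B", tid="b")  # 32% of 100
        deoverlap([a, b], PARAMS)
        assert a.kept and b.kept

    def test_different_clans_both_significant_coexist(self):
        a = mk(1, 100, clan="CL1", adj=1e-12, profile="A", tid="a")
        b = mk(21, 120, clan="CL2", adj=1e-12, profile="B", tid="b")  # 80% overlap
        deoverlap([a, b], PARAMS)
        assert a.kept and b.kept

    def test_different_clans_insignificant_needs_fold_ratio(self):
        a = mk(1, 100, clan="CL1", adj=1e-12, profile="A", tid="a")
        b = mk(21, 120, clan="CL2", adj=1e-5, profile="B", tid="b")
        deoverlap([a, b], PARAMS)
        assert a.kept and not b.kept
        assert b.removal_reason == "diff_clan_overlap"

    def test_different_clans_ratio_not_met_keeps_both(self):
        a = mk(1, 100, clan="CL1", adj=1e-6, profile="A", tid="a")
        b = mk(21, 120, clan="CL2", adj=1e-5, profile="B", tid="b")
        deoverlap([a, b], PARAMS)
        assert a.kept and b.kept

    def test_db_precedence_vfam_removed(self):
        p = mk(1, 100, adj=1e-10, profile="PF", tid="p", source="PFAM")
        v = mk(41, 140, adj=1e-20, profile="VF", tid="v", source="VFAM")
        deoverlap([p, v], PARAMS)
        assert p.kept and not v.kept
        assert v.removal_reason == "db_precedence"

    def test_db_precedence_strong_vfam_kept(self):
        p = mk(1, 100, adj=1e-10, profile="PF", tid="p", source="PFAM")
        v = mk(41, 140, adj=1e-60, profile="VF", tid="v", source="PVOG")
        deoverlap([p, v], PARAMS)
        assert p.kept and v.kept

    def test_opposite_strand_frames_never_compete(self):
        # double coding: same genomic region, frames 1 and 4
        a = mk(1, 100, clan="CL1", adj=1e-20, frame=1, profile="A", tid="a")
        b = mk(1, 100, clan="CL1", adj=1e-3, frame=4, profile="B", tid="b")
        deoverlap([a, b], PARAMS)
        assert a.kept and b.kept

    def test_skip_one_neighbor_pass(self):
        # A and C overlap; B sits between them without forcing adjacency
        a = mk(1, 100, clan="CL1", adj=1e-20, profile="A", tid="a")
        b = mk(30, 59, clan="CL2", adj=1e-30, profile="B", tid="b")
        c = mk(41, 140, clan="CL1", adj=1e-4, profile="C", tid="c")
        deoverlap([a, b, c], PARAMS)
        assert a.kept and b.kept and not c.kept


def random_instance(rng, max_hits=6, acc="g", frame=1):
    n = int(rng.integers(2, max_hits + 1))
    hits = []
    for i in range(n):
        start = int(rng.integers(1, 150))
        length = int(rng.integers(30, 101))
        clan = str(rng.choice(["CA", "CB", "NONE"]))
        source = str(rng.choice(["PFAM", "VFAM", "PVOG"]))
        hits.append(
            mk(
                start,
                start + length - 1,
                clan=None if clan == "NONE" else clan,
                source=source,
                adj=float(10.0 ** rng.uniform(-30, 0)),
                bit=float(rng.uniform(5, 100)),
                profile=f"P{i}",
                tid=f"t{i}",
                acc=acc,
                frame=frame,
            )
        )
    return hits


class TestDeoverlapProperties:
    def test_exhaustive_pairs_match_oracle(self):
        """Sweep overlap, clan, E-value-ratio and precedence boundaries."""
        fracs = [0.32, 0.33, 0.34, 0.44, 0.45, 0.46]
        clans = [("C1", "C1"), ("C1", "C2"), (None, "C2"), (None, None)]
        evals = [
            (1e-12, 1e-12), (1e-12, 1e-7), (1e-20, 1e-5), (1e-6, 1e-5),
            (1e-9, 1e-5), (1e-50, 1e-10), (1e-49, 1e-10), (1e-51, 1e-10),
        ]
        sources = [("PFAM", "PFAM"), ("PFAM", "VFAM"), ("VFAM", "PVOG")]
        count = 0
        for f, (c1, c2), (e1, e2), (s1, s2) in itertools.product(
            fracs, clans, evals, sources
        ):
            b0 = round(101 - 100 * f)
            hits = [
                mk(1, 100, clan=c1, source=s1, adj=e1, profile="A", tid="a"),
                mk(b0, b0 + 99, clan=c2, source=s2, adj=e2, profile="B", tid="b"),
            ]
            expect = oracle_deoverlap(copy.deepcopy(hits), PARAMS)
            deoverlap(hits, PARAMS)
            assert kept_keys(hits) == expect, (f, c1, c2, e1, e2, s1, s2)
            count += 1
        assert count == len(fracs) * len(clans) * len(evals) * len(sources)

    def test_three_hit_chains_match_oracle(self):
        """All pairs of a 3-hit frame are adjacent or skip-1, so the windowed
        scan must agree with the all-pairs oracle exactly."""
        rng = np.random.default_rng(401)
        for _ in range(300):
            hits = random_instance(rng, max_hits=3)
            expect = oracle_deoverlap(copy.deepcopy(hits), PARAMS)
            deoverlap(hits, PARAMS)
            assert kept_keys(hits) == expect

    def test_divergence_from_oracle_only_beyond_skip1(self):
        """On up to 6 hits the windowed scan may miss overlapping pairs more
        than two apart in sorted order; any disagreement must come from such
        an instance."""
        rng = np.random.default_rng(402)
        diverged = 0
        for _ in range(300):
            hits = random_instance(rng, max_hits=6)
            expect = oracle_deoverlap(copy.deepcopy(hits), PARAMS)
            deoverlap(hits, PARAMS)
            if kept_keys(hits) != expect:
                diverged += 1
                order = sorted(hits, key=lambda h: (h.calc_start, h.ali_start))
                far_overlaps = [
                    (i, j)
                    for i in range(len(order))
                    for j in range(i + 3, len(order))
                    if overlap_fraction(order[i], order[j]) > 0
                ]
                assert far_overlaps, "divergence without a beyond-skip-1 overlap"
        assert diverged <= 60  # bounded: distant-overlap pile-ups are rare

    def test_idempotent(self):
        rng = np.random.default_rng(403)
        for _ in range(100):
            hits = random_instance(rng)
            deoverlap(hits, PARAMS)
            first = kept_keys(hits)
            deoverlap(kept_only(hits), PARAMS)
            assert kept_keys(hits) == first

    def test_permutation_invariant(self):
        rng = np.random.default_rng(404)
        for _ in range(100):
            hits = random_instance(rng)
            shuffled = copy.deepcopy(hits)
            rng.shuffle(shuffled)
            deoverlap(hits, PARAMS)
            deoverlap(shuffled, PARAMS)
            assert kept_keys(hits) == kept_keys(shuffled)

    def test_never_removes_nonoverlapping(self):
        rng = np.random.default_rng(405)
        for _ in range(50):
            hits = random_instance(rng)
            before = {id(h) for h in hits}
            deoverlap(hits, PARAMS)
            for h in hits:
                if not h.kept:
                    assert any(
                        other is not h and overlap_fraction(h, other) > 0
                        for other in hits
                    )
            assert {id(h) for h in hits} == before
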