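"""Domain ordering, neighborhoods, inverse-square features, clustering.

Curated domains are ordered along the genome (all six frames merged into
one linear order by genomic start).  A "domain neighborhood" is the set of
domains within a rank radius of an occurrence of a domain of interest
(DOI); member positions are *ordered-domain* distances — the rank offset,
negative upstream, positive downstream — not nucleotide distances.

For clustering, each neighborhood (or genome) becomes a row of a feature
matrix keyed by clan: a clan observed at ordered distance d contributes
1/d^2 (so the nearest neighbor scores 1, a domain four ranks away scores
0.0625), and a clan absent from the row scores 0.  The soft weights make
hierarchical clustering tolerant to small rearrangements — the fuzziness
lives in the features, not the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import adjusted_rand_score

from domainhood.curation import CuratedDomain


@dataclass
class OrderedDomain:
    """A curated domain with its rank along the genome."""

    curated: CuratedDomain
    order_index: int

    @property
    def key_clan(self) -> str:
        """Feature key: the clan, falling back to the profile name."""
        return self.curated.clan if self.curated.clan else self.curated.profile


@dataclass
class Neighborhood:
    """A DOI occurrence plus its flanking domains with signed rank distances."""

    center: OrderedDomain
    members: list[tuple[OrderedDomain, int]]
    radius: int

    @property
    def id(self) -> str:
        c = self.center.curated
        return f"{c.accession}|{c.profile}|{self.center.order_index}"

    @property
    def accession(self) -> str:
        return self.center.curated.accession


def order_domains(curated: Sequence[CuratedDomain]) -> list[OrderedDomain]:
    """Rank one genome's kept domains by genomic start position.

    Both strands interleave in a single linear order; ties break by end
    position, then profile name, so the ordering is deterministic.
    """
    for h in curated:
        if not h.kept:
            raise ValueError("order_domains expects only kept hits")
        if h.nt_start is None:
            raise ValueError(f"{h.profile}@{h.target_id}: genomic coordinates not assigned")
    ranked = sorted(curated, key=lambda h: (h.nt_start, h.nt_end, h.profile, h.target_id))
    return [OrderedDomain(curated=h, order_index=i) for i, h in enumerate(ranked)]


def _matches_doi(od: OrderedDomain, doi) -> bool:
    names = {doi} if isinstance(doi, str) else set(doi)
    return od.curated.profile in names or (od.curated.clan in names)


def build_neighborhoods(
    ordered: Sequence[OrderedDomain], doi, radius: int = 10
) -> list[Neighborhood]:
    """One neighborhood per DOI occurrence within one genome's ordering.

    ``doi`` selects centers by profile name, clan, or a set of names.
    Members are the domains within ``radius`` ranks of the center, with
    signed distance = member rank − center rank (upstream negative).  A
    genome without the DOI yields no neighborhoods; edges truncate, there
    is no wraparound.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    by_index = sorted(ordered, key=lambda od: od.order_index)
    out = []
    for center in by_index:
        if not _matches_doi(center, doi):
            continue
        members = [
            (od, od.order_index - center.order_index)
            for od in by_index
            if abs(od.order_index - center.order_index) <= radius
        ]
        out.append(Neighborhood(center=center, members=members, radius=radius))
    return out


def weight(distance: int) -> float:
    """Inverse-square weight of an ordered-domain distance.

    1/d^2 for |d| >= 1; the center itself (d = 0) contributes 1 by
    convention.  Distance 1 gives 1.0, distance 4 gives 0.0625.
    """
    d = abs(distance)
    return 1.0 if d == 0 else 1.0 / (d * d)


def build_feature_matrix(
    neighborhoods: Sequence[Neighborhood],
    key: Literal["clan", "profile"] = "clan",
    reduce: Literal["max", "sum"] = "max",
    rows: Literal["neighborhood", "genome"] = "neighborhood",
) -> pd.DataFrame:
    """Clan-keyed inverse-square feature matrix for clustering.

    One row per neighborhood (or per genome, using the best-scoring DOI
    occurrence).  A cell holds the reduce (max by default: the nearest
    occurrence dominates) of 1/d^2 over all member occurrences of that
    key; keys never observed in a row are 0.
    """
    if not neighborhoods:
        raise ValueError("no neighborhoods supplied")
    if rows == "genome":
        best: dict[str, Neighborhood] = {}
        for nb in neighborhoods:
            acc = nb.accession
            if acc not in best or (
                nb.center.curated.adj_evalue < best[acc].center.curated.adj_evalue
            ):
                best[acc] = nb
        items = [(acc, nb) for acc, nb in best.items()]
    else:
        items = [(nb.id, nb) for nb in neighborhoods]

    cells: list[dict[str, float]] = []
    for _, nb in items:
        row: dict[str, float] = {}
        for od, dist in nb.members:
            k = od.key_clan if key == "clan" else od.curated.profile
            w = weight(dist)
            if reduce == "max":
                row[k] = max(row.get(k, 0.0), w)
            else:
                row[k] = row.get(k, 0.0) + w
        cells.append(row)
    m = pd.DataFrame(cells, index=[rid for rid, _ in items]).fillna(0.0)
    return m.reindex(sorted(m.columns), axis=1)


def mosaic_weights(
    neighborhoods: Iterable[Neighborhood], key: Literal["profile", "clan"] = "profile"
) -> pd.Series:
    """Summed inverse-square weight of each flanking key across neighborhoods.

    Aggregates every DOI occurrence together, so the keys that most often
    sit close to the domain of interest get the largest totals (the mosaic
    plot's block sizes).  The center domain itself (d = 0) is excluded:
    the tally describes the DOI's partners, not the DOI.
    """
    totals: dict[str, float] = {}
    for nb in neighborhoods:
        for od, dist in nb.members:
            if dist == 0:
                continue
            k = od.curated.profile if key == "profile" else od.key_clan
            totals[k] = totals.get(k, 0.0) + weight(dist)
    s = pd.Series(totals, dtype=float)
    return s.sort_values(ascending=False)


@dataclass
class ClusterResult:
    """Hierarchical clustering of feature-matrix rows."""

    linkage: np.ndarray
    labels: np.ndarray
    row_ids: list[str]
    leaf_order: list[int]
    linkage_method: str
    metric: str

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = sch.to_tree(self.linkage)

        def esc(name: str) -> str:
            return name.replace(" ", "_").replace(":", "_").replace(",", "_")

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{esc(self.row_ids[node.id])}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def cluster_rows(
    m: pd.DataFrame,
    linkage: str = "average",
    metric: str = "euclidean",
    k_or_height: int | float = 2,
) -> ClusterResult:
    """Agglomerative clustering of feature-matrix rows.

    ``k_or_height``: an int requests a flat cut into that many clusters,
    a float cuts the dendrogram at that height.  Deterministic given the
    matrix.
    """
    if m.shape[0] < 2:
        raise ValueError("clustering requires at least 2 rows")
    Z = sch.linkage(m.values, method=linkage, metric=metric)
    if isinstance(k_or_height, int) and not isinstance(k_or_height, bool):
        labels = sch.fcluster(Z, t=k_or_height, criterion="maxclust")
    else:
        labels = sch.fcluster(Z, t=float(k_or_height), criterion="distance")
    leaf_order = sch.leaves_list(Z).tolist()
    return ClusterResult(
        linkage=Z,
        labels=labels,
        row_ids=list(m.index),
        leaf_order=leaf_order,
        linkage_method=linkage,
        metric=metric,
    )


def adjusted_rand(labels_a: Sequence, labels_b: Sequence) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings.

    1 for identical partitions, about 0 for independent ones; can be
    negative for worse-than-chance agreement.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    return float(adjusted_rand_score(labels_a, labels_b))


def contingency_scaled(labels: Sequence, families: Sequence) -> pd.DataFrame:
    """Cluster-vs-family contingency matrix scaled per cluster.

    Counts of (cluster, family) co-occurrence, each cluster's row divided
    by that row's maximum, so every row's dominant family scores exactly 1.
    """
    if len(labels) != len(families):
        raise ValueError("labels and families differ in length")
    if len(labels) == 0:
        raise ValueError("empty input")
    counts = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(families, name="family"))
    return counts.div(counts.max(axis=1), axis=0)


def write_spacing_table(neighborhoods: Sequence[Neighborhood], path) -> None:
    """Long-format neighborhood table: row id, key, signed distance, weight."""
    rows = []
    for nb in neighborhoods:
        for od, dist in nb.members:
            rows.append(
                {
                    "neighborhood": nb.id,
                    "accession": nb.accession,
                    "profile": od.curated.profile,
                    "clan": od.key_clan,
                    "signed_distance": dist,
                    "weight": weight(dist),
                    "nt_start": od.curated.nt_start,
                    "nt_end": od.curated.nt_end,
                    "strand": od.curated.strand,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
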