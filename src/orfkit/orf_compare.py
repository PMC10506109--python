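"""Similarity relation and unique-ORF clustering across replicates/callers.

Two ORFs are similar when one's exonic base set is fully contained in the
other's, both share chromosome, strand, and stop-codon position, and the
contained ORF covers at least ``min_frac`` of the container's length
(nucleotides excluding stop codons). Similarity edges are closed
transitively: the unique-ORF clusters are the connected components of the
undirected similarity graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .orf_model import ORFRecord, orf_nt_length

__all__ = [
    "SimilarityEdge",
    "UniqueORFCluster",
    "is_similar",
    "similarity_edges",
    "build_unique_clusters",
    "replicate_sharing_curve",
    "category_composition",
    "length_distribution",
]


@dataclass(frozen=True)
class SimilarityEdge:
    child_id: str
    parent_id: str
    overlap_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.overlap_fraction <= 1:
            raise ValidationError(f"overlap fraction {self.overlap_fraction} outside (0,1]")


@dataclass(frozen=True)
class UniqueORFCluster:
    cluster_id: str
    member_ids: tuple[str, ...]
    representative: ORFRecord
    replicate_support: int
    category: Optional[str]

    def __post_init__(self) -> None:
        if self.replicate_support < 1:
            raise ValidationError("replicate_support must be >= 1")


def _blocks_contained(child: ORFRecord, parent: ORFRecord) -> bool:
    """True iff every exonic base of child lies in parent's exonic base set.

    Both block chains are sorted and non-overlapping, so a linear sweep
    suffices: each child block must fit inside a single parent block.
    """
    pi = 0
    parents = parent.blocks
    for cb in child.blocks:
        while pi < len(parents) and parents[pi].end < cb.end:
            pi += 1
        if pi == len(parents) or not (parents[pi].start <= cb.start and cb.end <= parents[pi].end):
            return False
    return True


def is_similar(child: ORFRecord, parent: ORFRecord, min_frac: float) -> bool:
    """The containment-based similarity relation (directional: child in parent)."""
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac {min_frac} outside (0,1]")
    if (child.chrom, child.strand, child.stop_codon_pos) != (
        parent.chrom,
        parent.strand,
        parent.stop_codon_pos,
    ):
        return False
    if not _blocks_contained(child, parent):
        return False
    return orf_nt_length(child) / orf_nt_length(parent) >= min_frac


def similarity_edges(orfs: Sequence[ORFRecord], min_frac: float) -> list[SimilarityEdge]:
    """All is_similar pairs. Candidates are grouped by shared stop codon first."""
    groups: dict[tuple[str, str, int], list[ORFRecord]] = {}
    for orf in orfs:
        groups.setdefault((orf.chrom, orf.strand, orf.stop_codon_pos), []).append(orf)
    edges: list[SimilarityEdge] = []
    for members in groups.values():
        for a, b in combinations(members, 2):
            child, parent = (a, b) if orf_nt_length(a) <= orf_nt_length(b) else (b, a)
            if is_similar(child, parent, min_frac):
                edges.append(
                    SimilarityEdge(
                        child.orf_id,
                        parent.orf_id,
                        orf_nt_length(child) / orf_nt_length(parent),
                    )
                )
    return edges


def _default_support_key(orf: ORFRecord) -> str:
    return str(orf.source.replicate)


def build_unique_clusters(
    orfs: Sequence[ORFRecord],
    min_frac: float,
    support_key: Callable[[ORFRecord], str] = _default_support_key,
) -> list[UniqueORFCluster]:
    """Connected components of the similarity graph, one cluster per unique ORF.

    The representative is the longest member (ties broken by smallest
    orf_id); replicate_support counts distinct ``support_key`` values among
    members. Raises on duplicate orf_ids.
    """
    by_id: dict[str, ORFRecord] = {}
    for orf in orfs:
        if orf.orf_id in by_id:
            raise ValidationError(f"duplicate orf_id {orf.orf_id}")
        by_id[orf.orf_id] = orf

    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for edge in similarity_edges(orfs, min_frac):
        graph.add_edge(edge.child_id, edge.parent_id)

    clusters: list[UniqueORFCluster] = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        # representative = longest member; ties broken by smallest orf_id
        longest = max(orf_nt_length(by_id[m]) for m in members)
        rep = by_id[min(m for m in members if orf_nt_length(by_id[m]) == longest)]
        support = len({support_key(by_id[m]) for m in members})
        clusters.append(
            UniqueORFCluster(
                cluster_id=rep.orf_id,
                member_ids=tuple(members),
                representative=rep,
                replicate_support=support,
                category=rep.category.value if rep.category else None,
            )
        )
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def replicate_sharing_curve(
    callsets: Mapping[str, Sequence[ORFRecord]],
    min_frac_grid: Sequence[float],
    k_values: Sequence[int],
) -> pd.DataFrame:
    """Unique-ORF counts shared by at least k replicates, per overlap threshold.

    ``callsets`` maps replicate (or caller) identifier to its ORF calls; the
    mapping key defines the sharing dimension. Returns a tidy table with
    columns (min_frac, k, n_unique_shared).
    """
    if not callsets:
        raise ValueError("at least one replicate call set required")
    for frac in min_frac_grid:
        if not 0 < frac <= 1:
            raise ValueError(f"min_frac grid value {frac} outside (0,1]")
    pooled: list[ORFRecord] = []
    owner: dict[str, str] = {}
    for rep_id in sorted(callsets):
        for orf in callsets[rep_id]:
            owner[orf.orf_id] = str(rep_id)
            pooled.append(orf)
    rows = []
    for frac in min_frac_grid:
        clusters = build_unique_clusters(pooled, frac, support_key=lambda o: owner[o.orf_id])
        for k in k_values:
            n = sum(1 for c in clusters if c.replicate_support >= k)
            rows.append({"min_frac": frac, "k": k, "n_unique_shared": n})
    return pd.DataFrame(rows, columns=["min_frac", "k", "n_unique_shared"])


def category_composition(clusters: Iterable[UniqueORFCluster], k: int = 1) -> pd.DataFrame:
    """Per-category percentages among clusters with replicate_support >= k."""
    kept = [c for c in clusters if c.replicate_support >= k]
    if not kept:
        return pd.DataFrame(columns=["category", "n", "percent"])
    counts = (
        pd.Series([c.category or "unclassified" for c in kept])
        .value_counts()
        .rename_axis("category")
        .reset_index(name="n")
    )
    counts["percent"] = 100.0 * counts["n"] / counts["n"].sum()
    return counts


def length_distribution(clusters: Iterable[UniqueORFCluster], k: int = 1) -> list[int]:
    """Representative nt lengths (excluding stop) for clusters with support >= k."""
    return [
        orf_nt_length(c.representative)
        for c in clusters
        if c.replicate_support >= k
    ]
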