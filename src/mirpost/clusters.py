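"""miRNA gene-cluster detection.

Two miRNA genes belong to the same cluster when they lie on the same contig,
are transcribed in the same direction and are less than a threshold distance
apart (10 kb by default, the miRBase convention).  Clustering is transitive,
so a cluster is a maximal chain of genes in which every gene is within the
threshold of the previous span.  Singletons are not clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

DEFAULT_MAX_GAP = 10_000

GapMode = Literal["edge", "start"]


@dataclass(frozen=True)
class GeneLocus:
    """Genomic location of one miRNA gene (1-based inclusive coordinates)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: coordinates are 1-based")


@dataclass(frozen=True)
class Cluster:
    """A maximal chain of ≥2 co-oriented, closely spaced miRNA genes."""

    cluster_id: str
    member_ids: tuple[str, ...]
    contig: str
    strand: str
    span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.member_ids)


def gap_between(prev_end: int, next_start: int) -> int:
    """Nucleotides separating two intervals; 0 when they touch or overlap."""
    return max(0, next_start - prev_end - 1)


def detect_clusters(
    loci: Sequence[GeneLocus],
    max_gap: int = DEFAULT_MAX_GAP,
    gap_mode: GapMode = "edge",
) -> list[Cluster]:
    """Detect miRNA gene clusters.

    Within each (contig, strand), genes are sorted by start coordinate and
    chained while the gap to the running span is strictly less than
    ``max_gap`` nucleotides.  With ``gap_mode="edge"`` (default) the gap is
    measured between the end of the previous gene span and the start of the
    next; ``gap_mode="start"`` measures start-to-start distance instead.
    Chains with at least two members are emitted as clusters, ordered by
    (contig, strand, start); cluster ids are ``contig:strand:start`` of the
    first member, so output is deterministic.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    seen: set[str] = set()
    for locus in loci:
        if locus.gene_id in seen:
            raise ValueError(f"duplicate gene_id {locus.gene_id!r}")
        seen.add(locus.gene_id)

    by_region: dict[tuple[str, str], list[GeneLocus]] = {}
    for locus in loci:
        by_region.setdefault((locus.contig, locus.strand), []).append(locus)

    clusters: list[Cluster] = []
    for (contig, strand) in sorted(by_region):
        members = sorted(by_region[(contig, strand)], key=lambda g: (g.start, g.end))
        chain: list[GeneLocus] = []
        max_end = None
        last_start = None
        for locus in members:
            if chain:
                if gap_mode == "edge":
                    gap = gap_between(max_end, locus.start)
                else:
                    gap = locus.start - last_start
                if gap < max_gap:
                    chain.append(locus)
                    max_end = max(max_end, locus.end)
                    last_start = locus.start
                    continue
                _emit(chain, clusters)
            chain = [locus]
            max_end = locus.end
            last_start = locus.start
        _emit(chain, clusters)
    return clusters


def _emit(chain: list[GeneLocus], clusters: list[Cluster]) -> None:
    if len(chain) < 2:
        return
    first = chain[0]
    clusters.append(
        Cluster(
            cluster_id=f"{first.contig}:{first.strand}:{first.start}",
            member_ids=tuple(g.gene_id for g in chain),
            contig=first.contig,
            strand=first.strand,
            span=(min(g.start for g in chain), max(g.end for g in chain)),
        )
    )


def cluster_membership(clusters: Sequence[Cluster]) -> dict[str, str]:
    """Map gene_id → cluster_id for all clustered genes."""
    membership: dict[str, str] = {}
    for cluster in clusters:
        for gene_id in cluster.member_ids:
            membership[gene_id] = cluster.cluster_id
    return membership
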