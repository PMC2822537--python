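"""Detection of sense-antisense gene pairs and complex architectures.

A sense-antisense gene pair (SAGP) is two genes on opposite strands of the
same locus whose genomic intervals overlap, so their transcripts are
partially complementary.  Pairs are classified by orientation:

* ``convergent`` — tail-to-tail: the overlap covers the 3' ends of both
  genes (plus-strand gene upstream of the minus-strand gene);
* ``divergent`` — head-to-head: the overlap covers both 5' ends;
* ``embedded`` — one gene's interval contains the other's.

Chaining SAGPs that share genes yields complex sense-antisense gene
architectures (CSAGAs): connected components of the pair graph in which at
least one gene has an antisense partner.  An optional rule additionally
links opposite-strand, non-overlapping genes whose 5' starts face each
other across a short gap (a shared bidirectional promoter), which is how
tightly packed loci recruit a fifth member that overlaps nobody directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .datamodel import GeneAnnotationSet, GeneRecord

__all__ = [
    "SagPair",
    "Csaga",
    "NeighbourWindow",
    "detect_sagps",
    "promoter_edges",
    "chain_csagas",
    "neighbour_window",
]

CONVERGENT = "convergent"
DIVERGENT = "divergent"
EMBEDDED = "embedded"
PROMOTER = "divergent_promoter"


@dataclass(frozen=True)
class SagPair:
    """A sense-antisense gene pair with its overlap geometry."""

    gene_a: str
    gene_b: str
    orientation: str
    overlap_len: int
    overlap_start: int
    overlap_end: int
    chrom: str

    @property
    def genes(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class Csaga:
    """A complex sense-antisense gene architecture (connected pair chain)."""

    component_id: int
    member_genes: list  # ordered by genomic start
    sag_pairs: list

    def __len__(self) -> int:
        return len(self.member_genes)


@dataclass
class NeighbourWindow:
    """Non-member genes flanking a CSAGA within a distance bound."""

    focal: Csaga
    upstream_genes: list
    downstream_genes: list
    max_dist: int

    @property
    def all_genes(self) -> list:
        return self.upstream_genes + self.downstream_genes


def _classify(a: GeneRecord, b: GeneRecord) -> str:
    """Orientation of an overlapping opposite-strand pair."""
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    if (plus.start <= minus.start and plus.end >= minus.end) or (
        minus.start <= plus.start and minus.end >= plus.end
    ):
        return EMBEDDED
    # plus 3' end = plus.end; minus 3' end = minus.start
    if plus.start < minus.start:
        # plus gene lies 5' (left); overlap covers plus.end and minus.start
        return CONVERGENT
    # minus gene lies left; overlap covers plus.start (5') and minus.end (5')
    return DIVERGENT


def detect_sagps(
    genes: GeneAnnotationSet, min_overlap: int = 1
) -> list[SagPair]:
    """Find all opposite-strand gene pairs with interval overlap.

    Uses a sweep over genes sorted by start within each chromosome;
    equivalent to the all-vs-all intersection test but near-linear on
    sparse loci.  ``min_overlap`` (bp) is the smallest intersection length
    that still counts as a pair.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    pairs: list[SagPair] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in genes:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: (r.start, r.end))
        active: list[GeneRecord] = []
        for rec in recs:
            active = [g for g in active if g.end > rec.start]
            for other in active:
                if other.strand == rec.strand:
                    continue
                lo = max(rec.start, other.start)
                hi = min(rec.end, other.end)
                if hi - lo >= min_overlap:
                    first, second = sorted(
                        (other, rec), key=lambda r: (r.start, r.end)
                    )
                    pairs.append(
                        SagPair(
                            gene_a=first.gene_id,
                            gene_b=second.gene_id,
                            orientation=_classify(first, second),
                            overlap_len=hi - lo,
                            overlap_start=lo,
                            overlap_end=hi,
                            chrom=chrom,
                        )
                    )
            active.append(rec)
    pairs.sort(key=lambda p: (p.chrom, p.overlap_start, p.gene_a, p.gene_b))
    return pairs


def promoter_edges(
    genes: GeneAnnotationSet, max_gap: int = 1000
) -> list[SagPair]:
    """Divergent-promoter links between non-overlapping opposite-strand genes.

    A minus-strand gene whose 5' end (its right coordinate) faces the 5'
    start of a downstream plus-strand gene across a gap of at most
    ``max_gap`` bp is taken to share a bidirectional promoter with it.
    The returned records reuse :class:`SagPair` with zero overlap and
    orientation ``"divergent_promoter"``.
    """
    edges: list[SagPair] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in genes:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: (r.start, r.end))
        for i, left in enumerate(recs):
            if left.strand != "-":
                continue
            for right in recs[i + 1:]:
                if right.start - left.end > max_gap:
                    break
                if right.strand != "+" or right.start < left.end:
                    continue
                edges.append(
                    SagPair(
                        gene_a=left.gene_id,
                        gene_b=right.gene_id,
                        orientation=PROMOTER,
                        overlap_len=0,
                        overlap_start=left.end,
                        overlap_end=right.start,
                        chrom=chrom,
                    )
                )
    return edges


def chain_csagas(
    pairs: list[SagPair],
    genes: GeneAnnotationSet | None = None,
    extra_edges: list[SagPair] | None = None,
) -> list[Csaga]:
    """Chain sense-antisense pairs into connected architectures.

    Each connected component of the gene-pair graph with at least two
    genes becomes one :class:`Csaga`.  ``extra_edges`` (e.g. from
    :func:`promoter_edges`) join the graph but are kept in ``sag_pairs``
    alongside the overlap pairs so provenance stays visible.  Components
    are ordered, and members within a component are ordered, by leftmost
    genomic start when annotation is supplied (insertion order otherwise).
    """
    all_edges = list(pairs) + list(extra_edges or [])
    graph = nx.Graph()
    for p in all_edges:
        graph.add_edge(p.gene_a, p.gene_b)

    def start_of(g: str) -> tuple:
        if genes is not None and g in genes:
            rec = genes[g]
            return (rec.chrom, rec.start)
        return ("", 0)

    components = []
    for comp in nx.connected_components(graph):
        members = sorted(comp, key=lambda g: (start_of(g), g))
        comp_pairs = [p for p in all_edges if p.gene_a in comp and p.gene_b in comp]
        components.append((members, comp_pairs))
    components.sort(key=lambda mc: (start_of(mc[0][0]), mc[0][0]))
    return [
        Csaga(component_id=i, member_genes=members, sag_pairs=comp_pairs)
        for i, (members, comp_pairs) in enumerate(components)
    ]


def neighbour_window(
    csaga: Csaga, genes: GeneAnnotationSet, max_dist: int = 200_000
) -> NeighbourWindow:
    """Genes flanking a CSAGA within ``max_dist`` bp of its genomic span.

    Members of the CSAGA are never neighbours.  A non-member gene is
    included when its interval lies within ``max_dist`` of the span
    ``[min(start), max(end))`` of the member genes; it is upstream if its
    interval ends at or before the span start, downstream otherwise.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    members = set(csaga.member_genes)
    recs = [genes[g] for g in csaga.member_genes if g in genes]
    if not recs:
        raise ValueError("no member gene of the CSAGA is present in the annotation")
    chrom = recs[0].chrom
    span_start = min(r.start for r in recs)
    span_end = max(r.end for r in recs)
    upstream, downstream = [], []
    for rec in genes.sorted_by_position():
        if rec.gene_id in members or rec.chrom != chrom:
            continue
        if rec.end <= span_start:
            gap = span_start - rec.end
            if gap <= max_dist:
                upstream.append(rec.gene_id)
        elif rec.start >= span_end:
            gap = rec.start - span_end
            if gap <= max_dist:
                downstream.append(rec.gene_id)
        else:
            # interval intersects the span without being a member
            (upstream if (rec.start + rec.end) / 2 < (span_start + span_end) / 2
             else downstream).append(rec.gene_id)
    return NeighbourWindow(
        focal=csaga,
        upstream_genes=upstream,
        downstream_genes=downstream,
        max_dist=max_dist,
    )
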