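"""Seven-mode alternative-splicing event enumeration from transcript models.

Events are local: each is defined by comparing one pair of transcripts of
the same gene, then deduplicated across all pairs by a coordinate
signature.  The seven modes are exon skipping (ES), mutually exclusive
exons (MX), alternative 5'/3' splice site (A5/A3), intron retention (IR),
and alternative first/last exon (AF/AL).  Naming is strand-aware: the
donor (5') side of a junction is its left edge on the + strand and its
right edge on the - strand, so the same genomic configuration is called A5
on one strand and A3 on the other, and likewise AF/AL.

Disjointness of the seven classes follows splice-site-centric practice:
alternative splice sites (A5/A3) require the two alternative flanking
exons to overlap; non-overlapping alternative *terminal* exons are AF/AL.
Without the overlap requirement every ES and MX pair would additionally
register spurious A5/A3 events at its flanking junctions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

from .models import GeneModel, TranscriptModel

__all__ = [
    "AS_TYPES",
    "ASEvent",
    "enumerate_events",
    "summarize_events",
    "overlap_gene_sets",
    "per_chromosome_counts",
]

AS_TYPES = ("ES", "MX", "A5", "A3", "IR", "AF", "AL")


@dataclass(frozen=True)
class ASEvent:
    """A typed, deduplicated local splicing event.

    ``signature`` is the ordered tuple of genomic coordinates defining the
    event (type-specific arity); (gene_id, event_type, signature) is unique
    within any event set.
    """

    event_type: str
    gene_id: str
    chrom: str
    strand: str
    signature: tuple[int, ...]
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]


def _pair_events(
    a: TranscriptModel, b: TranscriptModel, strand: str
) -> list[tuple[str, tuple[int, ...], str, str]]:
    """Events between one transcript pair.

    Returns (type, signature, inclusion_tid, exclusion_tid) tuples; the
    "inclusion" form is the one carrying more sequence (the exon for ES,
    the retained intron for IR) or, for the symmetric modes, the
    genomically left alternative.
    """
    out: list[tuple[str, tuple[int, ...], str, str]] = []
    ja, jb = set(a.junctions()), set(b.junctions())
    ea, eb = set(a.exons), set(b.exons)

    # --- ES: skipped internal exon ------------------------------------
    for inc, exc, jexc in ((a, b, jb), (b, a, ja)):
        exons = inc.exons
        for i in range(1, len(exons) - 1):
            e1 = exons[i - 1][1]
            s2, e2 = exons[i]
            s3 = exons[i + 1][0]
            if (e1, s3) in jexc:
                out.append(("ES", (e1, s2, e2, s3), inc.transcript_id,
                            exc.transcript_id))

    # --- IR: retained intron ------------------------------------------
    for spliced, retained, eret in ((a, b, eb), (b, a, ea)):
        exons = spliced.exons
        for i in range(len(exons) - 1):
            s1, e1 = exons[i]
            s2, e2 = exons[i + 1]
            if (s1, e2) in eret:
                out.append(("IR", (s1, e1, s2, e2), retained.transcript_id,
                            spliced.transcript_id))

    # --- MX: mutually exclusive internal exons ------------------------
    for i in range(1, len(a.exons) - 1):
        s2, e2 = a.exons[i]
        a_left, a_right = a.exons[i - 1][1], a.exons[i + 1][0]
        for j in range(1, len(b.exons) - 1):
            s3, e3 = b.exons[j]
            b_left, b_right = b.exons[j - 1][1], b.exons[j + 1][0]
            if a_left != b_left or a_right != b_right:
                continue
            if (s2, e2) == (s3, e3):
                continue
            # middle exons must not overlap
            if e2 <= s3:
                sig = (a_left, s2, e2, s3, e3, a_right)
                out.append(("MX", sig, a.transcript_id, b.transcript_id))
            elif e3 <= s2:
                sig = (a_left, s3, e3, s2, e2, a_right)
                out.append(("MX", sig, b.transcript_id, a.transcript_id))

    # --- shared-edge junction pairs: A5/A3 or AF/AL -------------------
    def exon_ending_at(t: TranscriptModel, end: int) -> tuple[int, int]:
        return next(e for e in t.exons if e[1] == end)

    def exon_starting_at(t: TranscriptModel, start: int) -> tuple[int, int]:
        return next(e for e in t.exons if e[0] == start)

    for j1 in sorted(ja):
        for j2 in sorted(jb):
            if j1 == j2:
                continue
            if j1[1] == j2[1] and j1[0] != j2[0]:
                # shared right edge; alternative left edges
                x1 = exon_ending_at(a, j1[0])
                x2 = exon_ending_at(b, j2[0])
                left, right = sorted((x1, x2))
                if max(x1[0], x2[0]) < min(x1[1], x2[1]):
                    # overlapping flanking exons -> alternative splice site
                    etype = "A5" if strand == "+" else "A3"
                    sig = (min(j1[0], j2[0]), max(j1[0], j2[0]), j1[1])
                    inc, exc = (
                        (a, b) if x1[1] > x2[1] else (b, a)
                    )  # longer exon = inclusion
                    out.append((etype, sig, inc.transcript_id, exc.transcript_id))
                elif x1 == a.exons[0] and x2 == b.exons[0]:
                    # disjoint alternative leftmost exons -> AF (+) / AL (-)
                    etype = "AF" if strand == "+" else "AL"
                    sig = left + right + (j1[1],)
                    inc, exc = (a, b) if x1 <= x2 else (b, a)
                    out.append((etype, sig, inc.transcript_id, exc.transcript_id))
            elif j1[0] == j2[0] and j1[1] != j2[1]:
                # shared left edge; alternative right edges
                x1 = exon_starting_at(a, j1[1])
                x2 = exon_starting_at(b, j2[1])
                left, right = sorted((x1, x2))
                if max(x1[0], x2[0]) < min(x1[1], x2[1]):
                    etype = "A3" if strand == "+" else "A5"
                    sig = (j1[0], min(j1[1], j2[1]), max(j1[1], j2[1]))
                    inc, exc = (a, b) if x1[0] < x2[0] else (b, a)
                    out.append((etype, sig, inc.transcript_id, exc.transcript_id))
                elif x1 == a.exons[-1] and x2 == b.exons[-1]:
                    etype = "AL" if strand == "+" else "AF"
                    sig = (j1[0],) + left + right
                    inc, exc = (a, b) if x1 <= x2 else (b, a)
                    out.append((etype, sig, inc.transcript_id, exc.transcript_id))

    return out


def enumerate_events(gene: GeneModel) -> set[ASEvent]:
    """Enumerate the gene's AS events over all transcript pairs.

    Events found in several pairs are merged: their signature identifies
    them and the inclusion/exclusion transcript sets accumulate.  A gene
    with a single (or duplicated) transcript yields the empty set.
    """
    # drop duplicate exon chains so re-enumeration after duplicating a
    # transcript is a no-op
    seen: dict[tuple, TranscriptModel] = {}
    for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
        seen.setdefault(t.exons, t)
    transcripts = list(seen.values())

    acc: dict[tuple[str, tuple[int, ...]], tuple[set[str], set[str]]] = {}
    for a, b in combinations(transcripts, 2):
        for etype, sig, inc, exc in _pair_events(a, b, gene.strand):
            incs, excs = acc.setdefault((etype, sig), (set(), set()))
            incs.add(inc)
            excs.add(exc)
    return {
        ASEvent(
            event_type=etype,
            gene_id=gene.gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            signature=sig,
            inclusion_transcripts=frozenset(incs),
            exclusion_transcripts=frozenset(excs),
        )
        for (etype, sig), (incs, excs) in acc.items()
    }


def summarize_events(genes: list[GeneModel]) -> dict:
    """Per-type event counts, total, genes with >= 1 event, and the
    events-per-gene distribution over a gene set."""
    per_type = Counter({t: 0 for t in AS_TYPES})
    per_gene: Counter[str] = Counter()
    events: list[ASEvent] = []
    for gene in genes:
        evs = enumerate_events(gene)
        events.extend(sorted(evs, key=lambda e: (e.event_type, e.signature)))
        for ev in evs:
            per_type[ev.event_type] += 1
            per_gene[gene.gene_id] += 1
    total = sum(per_type.values())
    n_events_dist = Counter(per_gene.values())
    return {
        "per_type": dict(per_type),
        "total_events": total,
        "genes_with_as": set(per_gene),
        "events_per_gene": dict(per_gene),
        "events_per_gene_distribution": dict(n_events_dist),
        "events": events,
    }


def overlap_gene_sets(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Cardinality of every Venn region over named gene-id sets.

    Keys are the sorted tuple of group names whose exclusive intersection
    the region is; values sum to the size of the union.
    """
    if not sets:
        raise ValueError("overlap_gene_sets requires at least one set")
    names = sorted(sets)
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for elem in universe:
        member = tuple(n for n in names if elem in sets[n])
        regions[member] = regions.get(member, 0) + 1
    # report empty regions explicitly for every non-empty subset
    from itertools import combinations as _comb

    for r in range(1, len(names) + 1):
        for combo in _comb(names, r):
            regions.setdefault(tuple(combo), 0)
    return regions


def per_chromosome_counts(
    gene_ids: set[str], genes: list[GeneModel]
) -> dict[str, int]:
    """Count genes per chromosome among ``gene_ids``; unknown ids warned
    and excluded."""
    import warnings

    chrom_of = {g.gene_id: g.chrom for g in genes}
    counts: Counter[str] = Counter()
    unknown = []
    for gid in gene_ids:
        chrom = chrom_of.get(gid)
        if chrom is None:
            unknown.append(gid)
        else:
            counts[chrom] += 1
    if unknown:
        warnings.warn(
            f"{len(unknown)} gene id(s) not in annotation, excluded "
            f"(e.g. {sorted(unknown)[:3]})",
            stacklevel=2,
        )
    return dict(counts)
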