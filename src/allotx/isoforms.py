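"""Classify observed transcripts against a reference annotation.

Three classes, as in long-read transcriptome cataloging:

* ``KNOWN_ISOFORM`` — the observed intron chain exactly equals that of a
  same-strand reference transcript (terminal-end variation does not
  demote a transcript); mono-exon transcripts are known when they have
  reciprocal overlap >= 0.8 with a same-strand reference mono-exon
  transcript.
* ``NOVEL_ISOFORM_KNOWN_GENE`` — shares >= 1 splice junction or >= 1 bp of
  same-strand exonic overlap with a reference gene.
* ``NOVEL_GENE_ISOFORM`` — neither; novel transcripts are clustered into
  novel genes by same-strand single-linkage exonic overlap.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from intervaltree import IntervalTree

from .models import GeneModel, TranscriptModel

__all__ = [
    "KNOWN_ISOFORM",
    "NOVEL_ISOFORM_KNOWN_GENE",
    "NOVEL_GENE_ISOFORM",
    "IsoformClass",
    "intron_chain",
    "classify_transcripts",
    "isoforms_per_gene",
    "class_counts",
]

KNOWN_ISOFORM = "KNOWN_ISOFORM"
NOVEL_ISOFORM_KNOWN_GENE = "NOVEL_ISOFORM_KNOWN_GENE"
NOVEL_GENE_ISOFORM = "NOVEL_GENE_ISOFORM"

MONO_EXON_RECIPROCAL_OVERLAP = 0.8


@dataclass(frozen=True)
class IsoformClass:
    isoform_class: str
    assigned_gene_id: str


def intron_chain(t: TranscriptModel) -> list[tuple[int, int]]:
    """Ordered intron intervals (0-based half-open); [] for mono-exon."""
    return list(t.intron_chain())


def _exonic_overlap(t: TranscriptModel, exons: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in t.exons:
        for s2, e2 in exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def classify_transcripts(
    observed: list[GeneModel], reference: list[GeneModel]
) -> dict[str, IsoformClass]:
    """Assign each observed transcript exactly one isoform class.

    Gene assignment for novel isoforms of known genes is by most shared
    junctions, ties broken by largest exonic overlap, then lexicographic
    gene_id.  Novel genes are labelled NOVELG%06d in (chrom, start) order.
    """
    # reference lookup structures
    chain_to_gene: dict[tuple, str] = {}
    junction_to_genes: dict[tuple, set[str]] = {}
    ref_exons: dict[str, list[tuple[int, int]]] = {}
    ref_mono: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    trees: dict[tuple[str, str], IntervalTree] = {}
    ref_chroms: set[str] = set()
    for gene in reference:
        ref_chroms.add(gene.chrom)
        key = (gene.chrom, gene.strand)
        tree = trees.setdefault(key, IntervalTree())
        for t in gene.transcripts:
            if t.is_mono_exon:
                ref_mono.setdefault(key, []).append(
                    (t.start, t.end, gene.gene_id)
                )
            else:
                chain_to_gene.setdefault(
                    (key, t.intron_chain()), gene.gene_id
                )
                for j in t.junctions():
                    junction_to_genes.setdefault((key, j), set()).add(
                        gene.gene_id
                    )
            ref_exons.setdefault(gene.gene_id, [])
            for s, e in t.exons:
                ref_exons[gene.gene_id].append((s, e))
                tree.addi(s, e, gene.gene_id)

    result: dict[str, IsoformClass] = {}
    novel: list[TranscriptModel] = []

    all_obs = sorted(
        (t for g in observed for t in g.transcripts),
        key=lambda t: (t.chrom, t.start, t.transcript_id),
    )
    for t in all_obs:
        key = (t.chrom, t.strand)
        if t.chrom not in ref_chroms:
            warnings.warn(
                f"transcript {t.transcript_id} on chromosome {t.chrom} absent "
                "from reference; classified as novel-gene isoform",
                stacklevel=2,
            )
            novel.append(t)
            continue
        if t.is_mono_exon:
            s, e = t.exons[0]
            best = None
            for rs, re_, gid in ref_mono.get(key, []):
                ov = max(0, min(e, re_) - max(s, rs))
                if ov / (e - s) >= MONO_EXON_RECIPROCAL_OVERLAP and ov / (
                    re_ - rs
                ) >= MONO_EXON_RECIPROCAL_OVERLAP:
                    cand = (ov, gid)
                    if best is None or cand[0] > best[0] or (
                        cand[0] == best[0] and gid < best[1]
                    ):
                        best = cand
            if best is not None:
                result[t.transcript_id] = IsoformClass(KNOWN_ISOFORM, best[1])
                continue
        else:
            gid = chain_to_gene.get((key, t.intron_chain()))
            if gid is not None:
                result[t.transcript_id] = IsoformClass(KNOWN_ISOFORM, gid)
                continue
        # novel isoform of a known gene?
        shared: Counter[str] = Counter()
        for j in t.junctions():
            for gid in junction_to_genes.get((key, j), ()):
                shared[gid] += 1
        overlap_genes: set[str] = set(shared)
        tree = trees.get(key)
        if tree is not None:
            for s, e in t.exons:
                for iv in tree.overlap(s, e):
                    overlap_genes.add(iv.data)
        if overlap_genes:
            best_gid = min(
                overlap_genes,
                key=lambda g: (
                    -shared.get(g, 0),
                    -_exonic_overlap(t, ref_exons[g]),
                    g,
                ),
            )
            result[t.transcript_id] = IsoformClass(
                NOVEL_ISOFORM_KNOWN_GENE, best_gid
            )
        else:
            novel.append(t)

    # cluster novel transcripts into novel genes by same-strand
    # single-linkage exonic overlap; ids assigned in (chrom, start) order
    novel.sort(key=lambda t: (t.chrom, t.start, t.end, t.transcript_id))
    clusters: list[dict] = []  # {chrom, strand, start, exons, members}
    for t in novel:
        hits = [
            ci
            for ci, cl in enumerate(clusters)
            if cl["chrom"] == t.chrom
            and cl["strand"] == t.strand
            and any(
                min(e1, e2) > max(s1, s2)
                for s1, e1 in t.exons
                for s2, e2 in cl["exons"]
            )
        ]
        if not hits:
            clusters.append(
                {
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "start": t.start,
                    "exons": list(t.exons),
                    "members": [t.transcript_id],
                }
            )
        else:
            # single linkage: a transcript overlapping several clusters
            # merges them all
            keep = clusters[hits[0]]
            for ci in reversed(hits[1:]):
                other = clusters.pop(ci)
                keep["exons"].extend(other["exons"])
                keep["start"] = min(keep["start"], other["start"])
                keep["members"].extend(other["members"])
            keep["exons"].extend(t.exons)
            keep["start"] = min(keep["start"], t.start)
            keep["members"].append(t.transcript_id)
    clusters.sort(key=lambda c: (c["chrom"], c["start"]))
    for i, cl in enumerate(clusters, start=1):
        gid = f"NOVELG{i:06d}"
        for tid in cl["members"]:
            result[tid] = IsoformClass(NOVEL_GENE_ISOFORM, gid)
    return result


def isoforms_per_gene(catalog: dict[str, IsoformClass]) -> dict[int, float]:
    """Proportion of genes (known + novel) with k observed isoforms."""
    if not catalog:
        raise ValueError("empty isoform catalog")
    per_gene = Counter(c.assigned_gene_id for c in catalog.values())
    n_genes = len(per_gene)
    dist = Counter(per_gene.values())
    return {k: v / n_genes for k, v in sorted(dist.items())}


def class_counts(catalog: dict[str, IsoformClass]) -> dict[str, int]:
    """Number of observed transcripts per isoform class."""
    counts = Counter(c.isoform_class for c in catalog.values())
    return {
        k: counts.get(k, 0)
        for k in (KNOWN_ISOFORM, NOVEL_ISOFORM_KNOWN_GENE, NOVEL_GENE_ISOFORM)
    }
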