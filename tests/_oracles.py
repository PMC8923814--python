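"""Independent brute-force oracles used to cross-check the package.

Everything here is written as a literal transcription of the event /
statistic definitions, with naive nested loops and no shared code with
the package implementation.
"""

from __future__ import annotations

import numpy as np


def _junctions(exons):
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def pair_events_bruteforce(exons1, exons2, strand):
    """All AS events between one transcript pair as (type, signature)."""
    found = set()
    j1, j2 = _junctions(exons1), _junctions(exons2)

    # exon skipping: an internal exon of one form, spliced over by the other
    for inc, other_j in ((exons1, j2), (exons2, j1)):
        for i in range(1, len(inc) - 1):
            e1 = inc[i - 1][1]
            s2, e2 = inc[i]
            s3 = inc[i + 1][0]
            for (a, b) in other_j:
                if a == e1 and b == s3:
                    found.add(("ES", (e1, s2, e2, s3)))

    # intron retention: consecutive exons of one form exactly spanned by
    # a single exon of the other
    for spliced, other_e in ((exons1, exons2), (exons2, exons1)):
        for i in range(len(spliced) - 1):
            s1, e1 = spliced[i]
            s2, e2 = spliced[i + 1]
            for (xs, xe) in other_e:
                if xs == s1 and xe == e2:
                    found.add(("IR", (s1, e1, s2, e2)))

    # mutually exclusive exons: shared outer junction coordinates, middle
    # exons non-overlapping
    for i in range(1, len(exons1) - 1):
        for k in range(1, len(exons2) - 1):
            left1, right1 = exons1[i - 1][1], exons1[i + 1][0]
            left2, right2 = exons2[k - 1][1], exons2[k + 1][0]
            if left1 != left2 or right1 != right2:
                continue
            s2, e2 = exons1[i]
            s3, e3 = exons2[k]
            if (s2, e2) == (s3, e3):
                continue
            if e2 <= s3:
                found.add(("MX", (left1, s2, e2, s3, e3, right1)))
            elif e3 <= s2:
                found.add(("MX", (left1, s3, e3, s2, e2, right1)))

    # alternative splice sites and alternative terminal exons
    for (a1, b1) in j1:
        for (a2, b2) in j2:
            if (a1, b1) == (a2, b2):
                continue
            if b1 == b2 and a1 != a2:
                # junctions share their genomic right edge
                x1 = [e for e in exons1 if e[1] == a1][0]
                x2 = [e for e in exons2 if e[1] == a2][0]
                overlap = min(x1[1], x2[1]) - max(x1[0], x2[0])
                if overlap > 0:
                    sig = (min(a1, a2), max(a1, a2), b1)
                    if strand == "+":
                        found.add(("A5", sig))
                    else:
                        found.add(("A3", sig))
                elif x1 == exons1[0] and x2 == exons2[0]:
                    lo, hi = sorted((x1, x2))
                    sig = (lo[0], lo[1], hi[0], hi[1], b1)
                    if strand == "+":
                        found.add(("AF", sig))
                    else:
                        found.add(("AL", sig))
            if a1 == a2 and b1 != b2:
                # junctions share their genomic left edge
                x1 = [e for e in exons1 if e[0] == b1][0]
                x2 = [e for e in exons2 if e[0] == b2][0]
                overlap = min(x1[1], x2[1]) - max(x1[0], x2[0])
                if overlap > 0:
                    sig = (a1, min(b1, b2), max(b1, b2))
                    if strand == "+":
                        found.add(("A3", sig))
                    else:
                        found.add(("A5", sig))
                elif x1 == exons1[-1] and x2 == exons2[-1]:
                    lo, hi = sorted((x1, x2))
                    sig = (a1, lo[0], lo[1], hi[0], hi[1])
                    if strand == "+":
                        found.add(("AL", sig))
                    else:
                        found.add(("AF", sig))
    return found


def gene_events_bruteforce(gene):
    """Deduplicated (type, signature) set over all transcript pairs."""
    chains = []
    for t in gene.transcripts:
        if t.exons not in chains:
            chains.append(t.exons)
    found = set()
    for i in range(len(chains)):
        for k in range(i + 1, len(chains)):
            found |= pair_events_bruteforce(chains[i], chains[k], gene.strand)
    return found


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(p[i] * m / rank, prev)
        adj[i] = val
        prev = val
    return adj


def single_linkage_1d(positions, window):
    """Clusters of 1-D points by union-find with linkage <= window."""
    pts = list(positions)
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for k in range(i + 1, n):
            if abs(pts[i] - pts[k]) <= window:
                parent[find(i)] = find(k)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(pts[i])
    return sorted(sorted(g) for g in groups.values())


def venn_regions_bruteforce(sets):
    """Exclusive-region counts by per-element membership tests."""
    names = sorted(sets)
    regions = {}
    universe = set()
    for s in sets.values():
        universe |= s
    for elem in universe:
        key = tuple(n for n in names if elem in sets[n])
        regions[key] = regions.get(key, 0) + 1
    return regions


def median_of_ratios_bruteforce(counts):
    """Direct transcription of the median-of-ratios size-factor formula."""
    counts = np.asarray(counts, dtype=float)
    keep = np.all(counts > 0, axis=1)
    ref = np.exp(np.mean(np.log(counts[keep]), axis=1))
    factors = np.array(
        [np.median(counts[keep, j] / ref) for j in range(counts.shape[1])]
    )
    return factors / np.exp(np.mean(np.log(factors)))
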