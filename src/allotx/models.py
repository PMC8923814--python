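"""Core data model: transcript/gene structures, sample sheets, count matrices.

All genomic intervals are 0-based half-open ``[start, end)``.  GTF I/O
(:mod:`allotx.annotation_io`) converts to and from the 1-based inclusive
convention at the file boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "TranscriptModel",
    "GeneModel",
    "SampleSheet",
    "CountMatrix",
    "union_exon_length",
]


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as a strand-aware chain of exon intervals.

    Exons are 0-based half-open, sorted by start, pairwise disjoint with a
    gap of at least 1 nt between consecutive exons (an intron of length
    >= 1).  The exon chain is the substrate of isoform classification and
    alternative-splicing event enumeration.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if start < 0 or end <= start:
                raise ValidationError(
                    f"transcript {self.transcript_id}: bad exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end + 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or abut "
                    f"at {prev_end}/{start}"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Splice junctions as (donor-side end, acceptor-side start) pairs
        in genomic order, i.e. the intron intervals."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Alias for :meth:`junctions`; empty for mono-exon transcripts."""
        return self.junctions()

    @property
    def is_mono_exon(self) -> bool:
        return len(self.exons) == 1


@dataclass
class GeneModel:
    """A gene locus: one or more transcripts sharing chrom and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id}: no transcripts")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValidationError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} on "
                    f"{t.chrom}{t.strand}, gene on {self.chrom}{self.strand}"
                )

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def union_exon_length(gene: GeneModel) -> int:
    """Length of the union of all exon intervals of a gene (nt).

    Used as the gene length for TPM normalisation of gene-level counts.
    """
    ivs = sorted(iv for t in gene.transcripts for iv in t.exons)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


@dataclass
class SampleSheet:
    """Sample metadata: sample_id -> (group, replicate).

    Groups follow the study design: two diploid parents (A, C), the in
    silico hybrid (A_C), and the resynthesized / natural allopolyploids
    (RAC, NAC); arbitrary additional group labels are allowed.
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "group", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = self.df.loc[:, list(self.REQUIRED)].copy()
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        if df.duplicated(subset=["group", "replicate"]).any():
            raise ValidationError("duplicate (group, replicate) in sample sheet")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.df["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> list[str]:
        sub = self.df[self.df["group"] == group]
        if sub.empty:
            raise ValidationError(f"unknown group {group!r}")
        return list(sub.sort_values("replicate")["sample_id"])


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with metadata.

    ``counts`` is indexed by gene_id with one column per sample in sample
    sheet order.  ``lengths`` (nt, union-exon) is optional and only needed
    for TPM normalisation.
    """

    counts: pd.DataFrame
    sheet: SampleSheet
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.sheet.sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"count matrix missing samples: {missing}")
        extra = [c for c in self.counts.columns if c not in self.sheet.sample_ids]
        if extra:
            raise ValidationError(f"count matrix samples absent from sheet: {extra}")
        counts = self.counts.loc[:, self.sheet.sample_ids]
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if counts.index.duplicated().any():
            raise ValidationError("duplicate gene_id in count matrix")
        self.counts = counts
        if self.lengths is not None:
            lengths = self.lengths.reindex(counts.index)
            if lengths.isna().any():
                raise ValidationError("gene lengths missing for some genes")
            if (lengths <= 0).any():
                raise ValidationError("gene lengths must be > 0")
            self.lengths = lengths.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def group_counts(self, group: str) -> pd.DataFrame:
        return self.counts.loc[:, self.sheet.samples_of(group)]
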