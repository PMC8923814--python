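"""Readers/writers for the formats the pipeline touches.

GTF parsing uses gffutils' attribute parser line-by-line so malformed lines
can be reported with their line number; written GTF is Ensembl-dialect
(gene_id/transcript_id attributes), 1-based inclusive, exons sorted, so
``read_gtf(write_gtf(genes))`` is the identity on the data model.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml
from gffutils.feature import feature_from_line

from .models import (
    CountMatrix,
    GeneModel,
    SampleSheet,
    TranscriptModel,
    ValidationError,
)

__all__ = [
    "read_gtf",
    "write_gtf",
    "read_counts",
    "read_read_ends",
    "read_run_stats",
    "read_sample_sheet",
    "write_sample_sheet",
    "RUN_STATS_COLUMNS",
]


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF into validated :class:`GeneModel` objects.

    Only ``exon`` features are used; coordinates are converted from the
    file's 1-based inclusive convention to internal 0-based half-open.
    Genes are returned sorted by (chrom, start, gene_id) and transcripts
    within a gene by (start, transcript_id), so two reads of the same file
    give identical structures.
    """
    path = Path(path)
    # transcript_id -> (gene_id, chrom, strand, [exons])
    tx: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValidationError(
                    f"{path.name}:{lineno}: malformed GTF line "
                    f"(expected 9 tab-separated fields)"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise ValidationError(
                    f"{path.name}:{lineno}: malformed GTF line ({exc})"
                ) from exc
            if feat.featuretype != "exon":
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ValidationError(
                    f"{path.name}:{lineno}: exon missing {exc} attribute"
                ) from exc
            exon = (feat.start - 1, feat.end)  # 1-based incl -> 0-based half-open
            rec = tx.get(transcript_id)
            if rec is None:
                tx[transcript_id] = (gene_id, feat.seqid, feat.strand, [exon])
            else:
                g, c, s, exons = rec
                if g != gene_id or c != feat.seqid or s != feat.strand:
                    raise ValidationError(
                        f"{path.name}:{lineno}: transcript {transcript_id} spans "
                        "multiple genes/chromosomes/strands"
                    )
                exons.append(exon)

    genes: dict[str, list[TranscriptModel]] = {}
    for transcript_id, (gene_id, chrom, strand, exons) in tx.items():
        exons.sort()
        t = TranscriptModel(transcript_id, gene_id, chrom, strand, tuple(exons))
        genes.setdefault(gene_id, []).append(t)

    out = []
    for gene_id, ts in genes.items():
        ts.sort(key=lambda t: (t.start, t.transcript_id))
        out.append(GeneModel(gene_id, ts[0].chrom, ts[0].strand, ts))
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Write GeneModels as 1-based inclusive Ensembl-dialect GTF.

    Output ordering is deterministic: genes by (chrom, start, gene_id),
    transcripts by (start, transcript_id), exons by start.
    """
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            for t in sorted(gene.transcripts, key=lambda t: (t.start, t.transcript_id)):
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                )
                for start, end in t.exons:
                    fh.write(
                        f"{gene.chrom}\tallotx\texon\t{start + 1}\t{end}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


def read_counts(path: str | Path, sheet: SampleSheet) -> CountMatrix:
    """Read a genes x samples TSV (first column gene_id) into a CountMatrix.

    Columns are normalised to sample-sheet order, so column order in the
    file is irrelevant.  Missing values and non-integer entries are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in count matrix")
    return CountMatrix(counts=df, sheet=sheet)


READ_END_COLUMNS = ["chrom", "position", "strand", "read_id", "gene_id"]


def read_read_ends(
    path: str | Path, known_gene_ids: set[str] | None = None
) -> pd.DataFrame:
    """Read a BED-like TSV of read 3'-end positions with gene assignment.

    Columns: chrom, 0-based position of the read's 3' terminus, strand,
    read_id, gene_id.  When ``known_gene_ids`` is given, records whose
    gene_id is absent are kept but warned about.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=READ_END_COLUMNS,
                     dtype={"chrom": str, "read_id": str, "gene_id": str})
    if df.empty:
        return df
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValidationError(
            f"{path}: invalid strand value(s) {sorted(df.loc[bad_strand, 'strand'].unique())}"
        )
    df["position"] = df["position"].astype(int)
    if (df["position"] < 0).any():
        raise ValidationError(f"{path}: negative read-end position")
    if known_gene_ids is not None:
        unknown = sorted(set(df["gene_id"]) - known_gene_ids)
        if unknown:
            warnings.warn(
                f"{len(unknown)} gene_id(s) in read-end file absent from "
                f"annotation (e.g. {unknown[:3]}); records kept",
                stacklevel=2,
            )
    return df


RUN_STATS_COLUMNS = [
    "sample_id",
    "clean_reads",
    "full_length_reads",
    "consensus_reads",
    "mean_quality",
    "fl_over_clean_pct",
    "mapping_pct",
    "gc_pct",
]


def read_run_stats(path: str | Path) -> pd.DataFrame:
    """Read a per-sample sequencing run-statistics CSV.

    Expected columns: sample_id, clean_reads, full_length_reads,
    consensus_reads, mean_quality, fl_over_clean_pct, mapping_pct, gc_pct.
    """
    df = pd.read_csv(path)
    missing = [c for c in RUN_STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: run-stats table missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: empty run-stats table")
    for col in ("clean_reads", "full_length_reads", "consensus_reads"):
        df[col] = df[col].astype(int)
        if (df[col] < 0).any():
            raise ValidationError(f"{path}: negative value in {col}")
    for col in ("fl_over_clean_pct", "mapping_pct", "gc_pct"):
        if ((df[col] < 0) | (df[col] > 100)).any():
            raise ValidationError(f"{path}: {col} outside [0, 100]")
    return df.set_index("sample_id", drop=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a YAML sample sheet: a list of {sample_id, group, replicate}."""
    with open(path) as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise ValidationError(f"{path}: sample sheet must be a YAML list")
    return SampleSheet(pd.DataFrame.from_records(records))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    records = sheet.df.to_dict(orient="records")
    with open(path, "w") as fh:
        yaml.safe_dump(records, fh, sort_keys=False)
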