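from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from allotx.annotation_io import (
    read_counts,
    read_gtf,
    read_read_ends,
    read_run_stats,
    write_gtf,
)
from allotx.models import GeneModel, SampleSheet, TranscriptModel, ValidationError
from allotx.report import packaged_run_stats
from allotx.simulate import SimConfig, generate_annotation


def _write(path, text):
    path.write_text(text)
    return path


class TestReadGtf:
    def test_one_based_inclusive_to_half_open(self, tmp_path):
        """1-based inclusive exons [101-200, 301-400, 501-600] become
        [100,200), [300,400), [500,600)."""
        gtf = _write(
            tmp_path / "a.gtf",
            "".join(
                f'chr1\tx\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
                for s, e in [(101, 200), (301, 400), (501, 600)]
            ),
        )
        genes = read_gtf(gtf)
        assert len(genes) == 1
        assert genes[0].transcripts[0].exons == ((100, 200), (300, 400), (500, 600))

    def test_round_trip_identity(self, tmp_path):
        genes, _ = generate_annotation(SimConfig(seed=7, n_genes=30))
        write_gtf(genes, tmp_path / "a.gtf")
        back = read_gtf(tmp_path / "a.gtf")
        assert [(g.gene_id, [t.exons for t in g.transcripts]) for g in back] == [
            (g.gene_id, [t.exons for t in g.transcripts]) for g in genes
        ]

    def test_round_trip_byte_stable(self, tmp_path):
        genes, _ = generate_annotation(SimConfig(seed=7, n_genes=30))
        write_gtf(genes, tmp_path / "a.gtf")
        write_gtf(read_gtf(tmp_path / "a.gtf"), tmp_path / "b.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_counts_match_generator_truth(self, tmp_path):
        cfg = SimConfig(seed=9, n_genes=40)
        genes, truth = generate_annotation(cfg)
        write_gtf(genes, tmp_path / "a.gtf")
        back = read_gtf(tmp_path / "a.gtf")
        assert len(back) == 40
        assert {g.gene_id: len(g.transcripts) for g in back} == truth.n_transcripts

    def test_parse_deterministic(self, tmp_path):
        genes, _ = generate_annotation(SimConfig(seed=3, n_genes=25))
        write_gtf(genes, tmp_path / "a.gtf")
        assert read_gtf(tmp_path / "a.gtf") == read_gtf(tmp_path / "a.gtf")

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = _write(tmp_path / "bad.gtf", "chr1\tonly-two-fields\n")
        with pytest.raises(ValidationError, match="bad.gtf:1"):
            read_gtf(gtf)

    def test_exon_missing_transcript_id(self, tmp_path):
        gtf = _write(
            tmp_path / "bad.gtf", 'chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "g";\n'
        )
        with pytest.raises(ValidationError, match="transcript_id"):
            read_gtf(gtf)

    def test_overlapping_exons_rejected(self, tmp_path):
        gtf = _write(
            tmp_path / "bad.gtf",
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t50\t150\t.\t+\t.\tgene_id "g"; transcript_id "t";\n',
        )
        with pytest.raises(ValidationError, match="overlap"):
            read_gtf(gtf)

    def test_transcript_spanning_two_chroms_rejected(self, tmp_path):
        gtf = _write(
            tmp_path / "bad.gtf",
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr2\tx\texon\t200\t300\t.\t+\t.\tgene_id "g"; transcript_id "t";\n',
        )
        with pytest.raises(ValidationError, match="multiple"):
            read_gtf(gtf)


class TestWriteGtf:
    def test_empty_gene_list(self, tmp_path):
        write_gtf([], tmp_path / "e.gtf")
        lines = (tmp_path / "e.gtf").read_text().splitlines()
        assert all(l.startswith("#") for l in lines)

    def test_mono_exon_convention(self, tmp_path):
        t = TranscriptModel("t1", "g1", "chr1", "+", ((100, 200),))
        write_gtf([GeneModel("g1", "chr1", "+", [t])], tmp_path / "m.gtf")
        line = [
            l for l in (tmp_path / "m.gtf").read_text().splitlines()
            if not l.startswith("#")
        ][0]
        fields = line.split("\t")
        assert (fields[3], fields[4]) == ("101", "200")


class TestReadCounts:
    @pytest.fixture
    def sheet(self):
        return SampleSheet(
            pd.DataFrame(
                {"sample_id": ["s1", "s2", "s3"], "group": ["A", "A", "C"],
                 "replicate": [1, 2, 1]}
            )
        )

    def test_basic_shape(self, tmp_path, sheet):
        f = _write(tmp_path / "c.tsv", "gene_id\ts1\ts2\ts3\ng1\t0\t1\t2\ng2\t3\t4\t5\n")
        m = read_counts(f, sheet)
        assert m.counts.shape == (2, 3)
        assert list(m.counts.loc["g2"]) == [3, 4, 5]

    def test_column_order_normalised(self, tmp_path, sheet):
        f1 = _write(tmp_path / "c1.tsv", "gene_id\ts1\ts2\ts3\ng1\t1\t2\t3\n")
        f2 = _write(tmp_path / "c2.tsv", "gene_id\ts3\ts1\ts2\ng1\t3\t1\t2\n")
        assert read_counts(f1, sheet).counts.equals(read_counts(f2, sheet).counts)

    def test_negative_rejected(self, tmp_path, sheet):
        f = _write(tmp_path / "c.tsv", "gene_id\ts1\ts2\ts3\ng1\t-1\t2\t3\n")
        with pytest.raises(ValidationError, match="non-negative"):
            read_counts(f, sheet)

    def test_unknown_sample_rejected(self, tmp_path, sheet):
        f = _write(tmp_path / "c.tsv", "gene_id\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\n")
        with pytest.raises(ValidationError, match="s4"):
            read_counts(f, sheet)

    def test_generator_counts_round_trip(self, tmp_path):
        from allotx.simulate import generate_counts

        cfg = SimConfig(seed=4, n_genes=25)
        genes, _ = generate_annotation(cfg)
        m, _ = generate_counts(genes, cfg)
        m.counts.to_csv(tmp_path / "c.tsv", sep="\t", index_label="gene_id")
        back = read_counts(tmp_path / "c.tsv", m.sheet)
        assert back.counts.equals(m.counts)


class TestReadReadEnds:
    def test_records_preserved(self, tmp_path):
        f = _write(
            tmp_path / "e.tsv",
            "A01\t100\t+\tr1\tg1\nA01\t105\t+\tr2\tg1\nA01\t400\t+\tr3\tg1\n",
        )
        df = read_read_ends(f)
        assert list(df["position"]) == [100, 105, 400]

    def test_empty_file(self, tmp_path):
        df = read_read_ends(_write(tmp_path / "e.tsv", ""))
        assert df.empty

    def test_bad_strand_rejected(self, tmp_path):
        f = _write(tmp_path / "e.tsv", "A01\t100\t*\tr1\tg1\n")
        with pytest.raises(ValidationError, match="strand"):
            read_read_ends(f)

    def test_unknown_gene_warned_but_kept(self, tmp_path):
        f = _write(tmp_path / "e.tsv", "A01\t100\t+\tr1\tgX\n")
        with pytest.warns(UserWarning, match="absent"):
            df = read_read_ends(f, known_gene_ids={"g1"})
        assert len(df) == 1

    def test_record_count_matches_generator(self, tmp_path):
        from allotx.simulate import generate_read_ends

        cfg = SimConfig(seed=4, n_genes=25)
        genes, _ = generate_annotation(cfg)
        ends, _ = generate_read_ends(genes, cfg)
        ends.to_csv(tmp_path / "e.tsv", sep="\t", index=False, header=False)
        assert len(read_read_ends(tmp_path / "e.tsv")) == len(ends)


class TestRunStats:
    def test_packaged_fixture_values(self):
        table = packaged_run_stats()
        assert len(table) == 12
        assert table.loc["A1", "clean_reads"] == 8_053_769
        assert table.loc["A1", "fl_over_clean_pct"] == 79.5
        assert table.loc["C2", "mean_quality"] == 9.2

    def test_missing_column_rejected(self, tmp_path):
        f = _write(tmp_path / "r.csv", "sample_id,clean_reads\nA1,10\n")
        with pytest.raises(ValidationError, match="missing columns"):
            read_run_stats(f)

    def test_empty_table_rejected(self, tmp_path):
        cols = ",".join(
            ["sample_id", "clean_reads", "full_length_reads", "consensus_reads",
             "mean_quality", "fl_over_clean_pct", "mapping_pct", "gc_pct"]
        )
        with pytest.raises(ValidationError, match="empty"):
            read_run_stats(_write(tmp_path / "r.csv", cols + "\n"))
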