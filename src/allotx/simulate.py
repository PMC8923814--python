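"""Synthetic annotations, counts, and read 3' ends with planted truth.

The generator emulates the study design this pipeline targets: two
diploid parents (groups A and C), an in silico hybrid derivable from
them, and two allopolyploids (RAC, NAC), three replicates each, on
chromosomes A01-A10 and C01-C09.  It plants, in a machine-readable truth
table, (a) one local alternative-splicing event of a chosen mode per AS
gene, (b) an expression class per gene (additive, dominance toward either
parent, transgressive up/down, silenced or activated in the progeny, or
null), realised as negative-binomial counts, and (c) poly(A) sites whose
read 3' ends scatter normally around them.  At zero dispersion and zero
scatter every downstream stage recovers the planted truth exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    CountMatrix,
    GeneModel,
    SampleSheet,
    TranscriptModel,
    ValidationError,
    union_exon_length,
)
from .events import AS_TYPES, enumerate_events

__all__ = ["SimConfig", "TruthTable", "generate_annotation", "generate_counts",
           "generate_read_ends", "generate_dataset"]

DEFAULT_CHROMS = tuple(f"A{i:02d}" for i in range(1, 11)) + tuple(
    f"C{i:02d}" for i in range(1, 10)
)

# expression classes
CLASSES = (
    "additive",
    "eld_a",
    "eld_c",
    "transgressive_up",
    "transgressive_down",
    "silenced",
    "activated",
    "null",
)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic data generator.

    Defaults mirror the targeted design: 3 replicates per group, 4-fold
    planted effects, NB dispersion 0.1, and a poly(A)-site-count
    distribution under which three quarters of multi-site genes carry two
    sites.
    """

    n_genes: int = 200
    chrom_names: tuple[str, ...] = DEFAULT_CHROMS
    planted_event_counts: dict[str, int] = field(
        default_factory=lambda: {t: 3 for t in AS_TYPES}
    )
    expression_class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "additive": 0.15,
            "eld_a": 0.15,
            "eld_c": 0.20,
            "transgressive_up": 0.12,
            "transgressive_down": 0.08,
            "silenced": 0.05,
            "activated": 0.05,
            "null": 0.20,
        }
    )
    effect_size_log2: float = 2.0
    nb_dispersion: float = 0.1
    mean_expression_log10_range: tuple[float, float] = (1.0, 3.0)
    replicates_per_group: int = 3
    polya_site_probs: tuple[float, ...] = (0.30, 0.525, 0.175)  # 1..3 sites
    polya_site_separation: int = 100
    polya_end_sd: float = 5.0
    reads_per_site: tuple[int, int] = (10, 30)  # uniform inclusive range
    polya_cluster_window: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.expression_class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"expression class proportions sum to {total}, expected 1"
            )
        unknown = set(self.expression_class_proportions) - set(CLASSES)
        if unknown:
            raise ValidationError(f"unknown expression classes: {sorted(unknown)}")
        if self.nb_dispersion < 0:
            raise ValidationError("NB dispersion must be >= 0")
        bad = {t: c for t, c in self.planted_event_counts.items() if c < 0}
        if bad or set(self.planted_event_counts) - set(AS_TYPES):
            raise ValidationError(
                f"invalid planted event counts: {self.planted_event_counts}"
            )
        if sum(self.planted_event_counts.values()) > self.n_genes:
            raise ValidationError("planted AS events exceed the gene budget")
        if self.polya_end_sd > 0 and self.polya_site_separation <= max(
            3 * self.polya_end_sd, self.polya_cluster_window
        ):
            raise ValidationError(
                "poly(A) site separation must exceed both 3*sd and the "
                "clustering window"
            )


@dataclass
class TruthTable:
    """Machine-readable record of everything the generator planted."""

    expression_class: dict[str, str] = field(default_factory=dict)
    parental_means: dict[str, tuple[float, float]] = field(default_factory=dict)
    progeny_means: dict[str, float] = field(default_factory=dict)
    as_events: list[dict] = field(default_factory=list)  # gene_id, type, signature
    polya_sites: dict[str, list[int]] = field(default_factory=dict)
    n_transcripts: dict[str, int] = field(default_factory=dict)
    gene_chrom: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# -- planted AS gene templates ---------------------------------------------
# exon chains (offsets within the gene) realising exactly one local event.
# Keys are the genomic configuration; the event type each realises depends
# on strand for the splice-site and terminal-exon modes.
_TEMPLATES: dict[str, tuple[list[tuple[int, int]], list[tuple[int, int]]]] = {
    "ES": ([(0, 100), (200, 300), (400, 1100)], [(0, 100), (400, 1100)]),
    "MX": (
        [(0, 100), (200, 300), (500, 1200)],
        [(0, 100), (350, 450), (500, 1200)],
    ),
    "IR": ([(0, 100), (200, 900)], [(0, 900)]),
    # shared-right-edge junction, overlapping flanking exons: A5 on +, A3 on -
    "ALT_RIGHT_SHARED": ([(0, 100), (200, 900)], [(0, 150), (200, 900)]),
    # shared-left-edge junction, overlapping acceptor exons: A3 on +, A5 on -
    "ALT_LEFT_SHARED": ([(0, 100), (200, 900)], [(0, 100), (250, 900)]),
    # disjoint alternative leftmost exons: AF on +, AL on -
    "ALT_FIRST": ([(0, 100), (400, 1100)], [(200, 300), (400, 1100)]),
    # disjoint alternative rightmost exons: AL on +, AF on -
    "ALT_LAST": ([(0, 100), (200, 800)], [(0, 100), (900, 1500)]),
}


def _template_for(event_type: str, strand: str) -> tuple[list, list]:
    if event_type in ("ES", "MX", "IR"):
        return _TEMPLATES[event_type]
    if event_type == "A5":
        return _TEMPLATES["ALT_RIGHT_SHARED" if strand == "+" else "ALT_LEFT_SHARED"]
    if event_type == "A3":
        return _TEMPLATES["ALT_LEFT_SHARED" if strand == "+" else "ALT_RIGHT_SHARED"]
    if event_type == "AF":
        return _TEMPLATES["ALT_FIRST" if strand == "+" else "ALT_LAST"]
    if event_type == "AL":
        return _TEMPLATES["ALT_LAST" if strand == "+" else "ALT_FIRST"]
    raise ValidationError(f"unknown AS type {event_type}")


def generate_annotation(config: SimConfig) -> tuple[list[GeneModel], TruthTable]:
    """Generate gene models with planted AS events.

    For each AS mode t, exactly ``planted_event_counts[t]`` genes carry a
    transcript pair realising t and no other local event; the remaining
    genes are single-transcript with 1-3 exons.  Deterministic under the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    genes: list[GeneModel] = []

    plan: list[str | None] = []
    for t in AS_TYPES:
        plan.extend([t] * config.planted_event_counts.get(t, 0))
    plan.extend([None] * (config.n_genes - len(plan)))

    # lay genes down chromosome by chromosome with 10 kb spacing
    n_chrom = len(config.chrom_names)
    for i, event_type in enumerate(plan):
        chrom = config.chrom_names[i % n_chrom]
        offset = 1000 + (i // n_chrom) * 10_000
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"SYNG{i + 1:05d}"
        if event_type is None:
            # single-transcript gene, 1-3 exons, long terminal exon so
            # poly(A) sites fit inside the span
            n_ex = int(rng.integers(1, 4))
            exons = [(j * 200, j * 200 + 100) for j in range(n_ex - 1)] + [
                ((n_ex - 1) * 200, (n_ex - 1) * 200 + 600)
            ]
            chains = [exons]
        else:
            ex1, ex2 = _template_for(event_type, strand)
            chains = [list(ex1), list(ex2)]
        transcripts = []
        for k, chain in enumerate(chains):
            shifted = tuple((s + offset, e + offset) for s, e in chain)
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.t{k + 1}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=shifted,
                )
            )
        gene = GeneModel(gene_id, chrom, strand, transcripts)
        genes.append(gene)
        truth.gene_chrom[gene_id] = chrom
        truth.n_transcripts[gene_id] = len(transcripts)
        if event_type is not None:
            evs = enumerate_events(gene)
            assert len(evs) == 1 and next(iter(evs)).event_type == event_type, (
                f"template for {event_type} ({strand}) produced {evs}"
            )
            ev = next(iter(evs))
            truth.as_events.append(
                {
                    "gene_id": gene_id,
                    "event_type": event_type,
                    "signature": list(ev.signature),
                }
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion phi) with var = mu + phi mu^2; phi=0 degenerates
    to deterministic rounding of the mean (zero-noise mode)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return np.round(mean).astype(np.int64)
    r = 1.0 / phi
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def generate_counts(
    genes: list[GeneModel],
    config: SimConfig,
    truth: TruthTable | None = None,
) -> tuple[CountMatrix, TruthTable]:
    """NB counts for groups A, C, RAC, NAC with planted expression classes.

    Progeny means derive from the planted class: additive (muA+muC)/2,
    dominance toward A or C (muA or muC), transgressive up/down
    (max * 2^effect, min * 2^-effect), silenced (0 in progeny), activated
    (0 in both parents).  The same class applies to both allopolyploids.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = truth if truth is not None else TruthTable()
    classes = list(config.expression_class_proportions)
    probs = np.array([config.expression_class_proportions[c] for c in classes])
    lo, hi = config.mean_expression_log10_range
    eff = 2.0**config.effect_size_log2

    gene_ids = [g.gene_id for g in genes]
    assignment = rng.choice(len(classes), size=len(gene_ids), p=probs)
    mu_a = 10 ** rng.uniform(lo, hi, len(gene_ids))
    direction = rng.random(len(gene_ids)) < 0.5

    rows = {"A": [], "C": [], "RAC": [], "NAC": []}
    for i, gid in enumerate(gene_ids):
        cls = classes[assignment[i]]
        ma = mu_a[i]
        if cls in ("additive", "eld_a", "eld_c", "transgressive_up",
                   "transgressive_down", "silenced"):
            mc = ma * eff if direction[i] else ma / eff
        elif cls == "activated":
            ma = mc = 0.0
        else:  # null
            mc = ma
        if cls == "additive":
            mp = (ma + mc) / 2.0
        elif cls == "eld_a":
            mp = ma
        elif cls == "eld_c":
            mp = mc
        elif cls == "transgressive_up":
            mp = max(ma, mc) * eff
        elif cls == "transgressive_down":
            mp = min(ma, mc) / eff
        elif cls == "silenced":
            mp = 0.0
        elif cls == "activated":
            mp = 10 ** rng.uniform(lo, hi)
        else:
            mp = (ma + mc) / 2.0  # null genes sit at the common parental mean
        truth.expression_class[gid] = cls
        truth.parental_means[gid] = (float(ma), float(mc))
        truth.progeny_means[gid] = float(mp)
        n = config.replicates_per_group
        rows["A"].append(_nb_draw(rng, np.full(n, ma), config.nb_dispersion))
        rows["C"].append(_nb_draw(rng, np.full(n, mc), config.nb_dispersion))
        rows["RAC"].append(_nb_draw(rng, np.full(n, mp), config.nb_dispersion))
        rows["NAC"].append(_nb_draw(rng, np.full(n, mp), config.nb_dispersion))

    n = config.replicates_per_group
    sheet_rows = []
    data = {}
    for group in ("A", "C", "RAC", "NAC"):
        block = np.vstack(rows[group])
        for j in range(n):
            sid = f"{group}{j + 1}"
            sheet_rows.append({"sample_id": sid, "group": group, "replicate": j + 1})
            data[sid] = block[:, j]
    sheet = SampleSheet(pd.DataFrame.from_records(sheet_rows))
    lengths = pd.Series({g.gene_id: float(union_exon_length(g)) for g in genes})
    counts = pd.DataFrame(data, index=gene_ids)
    return CountMatrix(counts=counts, sheet=sheet, lengths=lengths), truth


def generate_read_ends(
    genes: list[GeneModel],
    config: SimConfig,
    truth: TruthTable | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Read 3'-end records scattered around planted poly(A) sites.

    Each gene receives 1-3 sites (per the configured distribution) near
    its 3' end, separated by ``polya_site_separation`` nt; each site emits
    a uniform number of reads whose end positions are Normal(site, sd)
    rounded to integers (exact at sd = 0).
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = truth if truth is not None else TruthTable()
    records = []
    n_sites_choices = np.arange(1, len(config.polya_site_probs) + 1)
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        n_sites = int(rng.choice(n_sites_choices, p=config.polya_site_probs))
        sep = config.polya_site_separation
        if gene.strand == "+":
            anchor = gene.end
            sites = [anchor - i * sep for i in range(n_sites)]
        else:
            anchor = gene.start
            sites = [anchor + i * sep for i in range(n_sites)]
        truth.polya_sites[gene.gene_id] = sorted(sites)
        lo, hi = config.reads_per_site
        for s_i, site in enumerate(sites):
            n_reads = int(rng.integers(lo, hi + 1))
            if n_reads == 0:
                continue
            ends = np.round(
                rng.normal(site, config.polya_end_sd, n_reads)
            ).astype(int) if config.polya_end_sd > 0 else np.full(n_reads, site)
            for r_i, pos in enumerate(ends):
                records.append(
                    (
                        gene.chrom,
                        int(max(pos, 0)),
                        gene.strand,
                        f"{gene.gene_id}.s{s_i}.r{r_i}",
                        gene.gene_id,
                    )
                )
    df = pd.DataFrame(
        records, columns=["chrom", "position", "strand", "read_id", "gene_id"]
    )
    return df, truth


def generate_dataset(config: SimConfig, outdir: str | Path) -> TruthTable:
    """Write a complete synthetic dataset (GTF, counts TSV, read-end TSV,
    sample-sheet YAML, truth-table JSON) to a directory."""
    from .annotation_io import write_gtf, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, truth = generate_annotation(config)
    matrix, truth = generate_counts(genes, config, truth)
    ends, truth = generate_read_ends(genes, config, truth)

    write_gtf(genes, outdir / "annotation.gtf")
    matrix.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    matrix.lengths.rename("length").to_csv(
        outdir / "gene_lengths.tsv", sep="\t", index_label="gene_id", header=True
    )
    ends.to_csv(outdir / "read_ends.tsv", sep="\t", index=False, header=False)
    write_sample_sheet(matrix.sheet, outdir / "samples.yaml")
    truth.to_json(outdir / "truth.json")
    return truth
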