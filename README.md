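# allotx

Comparative full-length-transcriptome analysis for allopolyploids and
their diploid parents: isoform cataloging against a reference annotation,
seven-mode alternative-splicing (AS) event enumeration, alternative
polyadenylation (APA) gene calling, expression activation/silencing and
differential expression, in silico hybrid construction, and the
twelve-pattern additive / expression-level-dominance / transgressive
classification of progeny gene expression.

The package targets the study design of allopolyploid *Brassica napus*:
two diploid parents (the A-genome parent *B. rapa* and the C-genome
parent *B. oleracea*), an in silico "hybrid" built by mixing the parental
read sets 1:1, a resynthesized allopolyploid (RAC), and the natural
allopolyploid (NAC), three biological replicates each, on chromosomes
A01–A10 / C01–C09. It is written for transcriptome researchers who have
gene-level long-read data (transcript models as GTF, gene counts, read
3′-end positions) and want the downstream comparative analyses as a
tested, reproducible pipeline. A synthetic-data generator plants
machine-readable truth for every stage, so the entire pipeline is
testable without any sequencing data.

## Core methods

* **Isoform catalog** — an observed multi-exon transcript is a *known
  isoform* when its intron chain exactly equals a same-strand reference
  transcript's chain (terminal-end variation does not demote it); a
  *novel isoform of a known gene* when it shares ≥ 1 splice junction or
  ≥ 1 bp same-strand exonic overlap with a reference gene; otherwise a
  *novel-gene isoform*, clustered into novel genes by single-linkage
  exonic overlap.
* **AS events** — local events from all transcript pairs of a gene,
  deduplicated by coordinate signature, in the seven standard modes:
  exon skipping (ES), mutually exclusive exons (MX), alternative 5′/3′
  splice site (A5/A3), intron retention (IR), alternative first/last
  exon (AF/AL), with strand-aware donor/acceptor naming.
* **APA** — read 3′ ends are clustered per gene by single linkage
  (window 24 nt, min support 2); genes retaining ≥ 2 poly(A) sites are
  APA genes.
* **Expression** — TPM normalisation (gene length = union-exon length);
  a gene is expressed in a group when TPM > 0 in at least one replicate;
  activation/silencing are set differences of expressed-gene sets.
* **Differential expression** — a self-contained negative-binomial Wald
  test: median-of-ratios size factors, method-of-moments dispersion
  shrunk toward a log-linear mean–dispersion trend, delta-method SE on
  log2FC, BH adjustment; DEGs at |log2FC| ≥ 1 and padj ≤ 0.001.
* **Expression patterns** — per progeny gene, four contrasts (vs each
  parent, parent vs parent, vs the mid-parent value MPV = (A+C)/2) feed
  a decision table that assigns one of 12 fine patterns grouped into
  additive, ELD-A, ELD-C, transgressive up, transgressive down — or
  no-change/ambiguous when the contrasts cannot distinguish.

## Worked example

Generate a 60-gene synthetic dataset with three planted AS events of
each mode, enumerate the events, test parent-vs-parent differential
expression, and classify the resynthesized allopolyploid's expression
patterns:

```
$ allotx simulate --out demo --seed 1 --n-genes 60
synthetic dataset written to demo

$ allotx events --gtf demo/annotation.gtf --out demo/events.tsv
{"per_type": {"ES": 3, "MX": 3, "A5": 3, "A3": 3, "IR": 3, "AF": 3, "AL": 3},
 "total": 21, "genes_with_as": 21}

$ allotx de --counts demo/counts.tsv --sheet demo/samples.yaml \
    --group1 A --group2 C --out demo/de.tsv
{"tested": 58, "degs": 37}

$ allotx eld --counts demo/counts.tsv --sheet demo/samples.yaml --out demo/eld.tsv
{"counts": {"ADDITIVE": 2, "ELD_A": 3, "ELD_C": 8, "TRANSGRESSIVE_UP": 10,
 "TRANSGRESSIVE_DOWN": 9, "NO_CHANGE": 12, "AMBIGUOUS": 16},
 "proportions": {"additive": 0.0625, "eld": 0.34375, "transgressive": 0.59375}}
```

All 21 planted events are recovered with their exact signatures
(`demo/truth.json` holds the planted truth). The 37 DEGs are the planted
parental 4-fold differences that clear the |log2FC| ≥ 1, padj ≤ 0.001
thresholds at three replicates; of the 60 genes, 32 receive a confident
expression pattern while genes whose contrasts cannot separate, e.g.,
additivity from dominance toward the higher parent are reported as
ambiguous rather than forced into a pattern.

`allotx summary` aggregates the packaged per-sample sequencing table of
the targeted twelve-library design:

```
$ allotx summary
{"group_mean_mapping_pct": {"A": 71.013..., "C": 61.8, "NAC": 78.5, "RAC": 70.336...},
 "mean_fl_over_clean_pct": 77.675, "mean_gc_pct": 43.323..., "min_mean_quality": 9.2,
 "n_samples": 12, "total_clean_reads_millions": 113.54}
```

`allotx run --config pipeline.yaml` executes every stage from one YAML
config and writes diff-able TSV tables plus a JSON manifest; re-running
the same config reproduces byte-identical outputs.

## Documentation

`docs/methods.md` describes the models, parameter choices, decision
table, what the synthetic generator does and does not emulate, and known
limitations.
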