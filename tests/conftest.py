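from __future__ import annotations

import numpy as np
import pytest

from allotx.models import GeneModel, TranscriptModel


def random_gene(rng: np.random.Generator, gene_id: str = "G1") -> GeneModel:
    """A random multi-transcript gene built from a shared exon-slot
    skeleton with slot dropping (exon skipping), adjacent-slot merging
    (intron retention), and boundary jitter (alternative splice sites /
    terminal exons)."""
    n_slots = int(rng.integers(3, 7))
    slots = [(200 * i + 100, 200 * i + 200) for i in range(n_slots)]
    strand = "+" if rng.random() < 0.5 else "-"
    n_tx = int(rng.integers(2, 6))
    transcripts = []
    for t in range(n_tx):
        keep = [i for i in range(n_slots) if rng.random() < 0.75]
        if not keep:
            keep = [int(rng.integers(0, n_slots))]
        exons: list[list[int]] = []
        for i in keep:
            s, e = slots[i]
            if exons and exons[-1][1] == slots[i - 1][1] and rng.random() < 0.3:
                exons[-1][1] = e  # merge with previous slot: retained intron
            else:
                exons.append([s, e])
        # jitter is often zero so junctions frequently coincide across
        # transcripts, which is what makes events fire
        shifts = (0, 0, 0, -30, 30)
        jittered = []
        for s, e in exons:
            s2 = s + int(rng.choice(shifts))
            e2 = e + int(rng.choice(shifts))
            jittered.append((s2, e2))
        transcripts.append(
            TranscriptModel(f"{gene_id}.t{t + 1}", gene_id, "A01", strand,
                            tuple(jittered))
        )
    return GeneModel(gene_id, "A01", strand, transcripts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
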