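"""In silico hybrid construction, mid-parent values, and the 12-pattern
additive/dominance/transgressive classification.

The in silico hybrid mixes the two parents' reads 1:1 per replicate pair,
downsampling the larger library to the smaller, and serves as the null
expectation for the mere union of the parental transcriptomes.  Expressed
genes in an allopolyploid are then classified, from four pairwise
differential tests (progeny vs each parent, parent vs parent, progeny vs
mid-parent value), into additive expression, expression-level dominance
toward either parent (ELD-A / ELD-C), or transgressive up/down
expression — twelve fine patterns in the standard 2+2+2+3+3 layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ValidationError

__all__ = [
    "GROUPS",
    "ELDPattern",
    "build_hybrid",
    "build_hybrid_reads",
    "mpv_samples",
    "classify_patterns",
    "pattern_summary",
    "FINE_PATTERN_GROUP",
]

ADDITIVE = "ADDITIVE"
ELD_A = "ELD_A"
ELD_C = "ELD_C"
TRANSGRESSIVE_UP = "TRANSGRESSIVE_UP"
TRANSGRESSIVE_DOWN = "TRANSGRESSIVE_DOWN"
NO_CHANGE = "NO_CHANGE"
AMBIGUOUS = "AMBIGUOUS"

GROUPS = (ADDITIVE, ELD_A, ELD_C, TRANSGRESSIVE_UP, TRANSGRESSIVE_DOWN)

# fine patterns 1-12 in the 2+2+2+3+3 layout; the second element records
# the parental relation that distinguishes patterns within a group
FINE_PATTERN_GROUP = {
    1: (ADDITIVE, "A>C"),
    2: (ADDITIVE, "A<C"),
    3: (ELD_A, "A>C"),
    4: (ELD_A, "A<C"),
    5: (ELD_C, "A>C"),
    6: (ELD_C, "A<C"),
    7: (TRANSGRESSIVE_UP, "A>C"),
    8: (TRANSGRESSIVE_UP, "A<C"),
    9: (TRANSGRESSIVE_UP, "A=C"),
    10: (TRANSGRESSIVE_DOWN, "A>C"),
    11: (TRANSGRESSIVE_DOWN, "A<C"),
    12: (TRANSGRESSIVE_DOWN, "A=C"),
}
_PATTERN_OF = {v: k for k, v in FINE_PATTERN_GROUP.items()}


@dataclass(frozen=True)
class ELDPattern:
    gene_id: str
    fine_pattern: int | None  # 1-12, or None for NO_CHANGE / AMBIGUOUS
    group: str


def build_hybrid(
    parent_a: pd.Series | np.ndarray,
    parent_c: pd.Series | np.ndarray,
    seed: int,
) -> pd.Series | np.ndarray:
    """Mix one replicate pair of parental count vectors 1:1.

    Let n be the smaller library total; the larger parent is downsampled
    to n reads by a multivariate-hypergeometric draw (sampling reads
    without replacement at the count level), then the two vectors are
    summed, so the hybrid library totals 2n.  Deterministic under seed.
    """
    a = np.asarray(parent_a, dtype=np.int64)
    c = np.asarray(parent_c, dtype=np.int64)
    if a.shape != c.shape:
        raise ValidationError("parental count vectors differ in length")
    ta, tc = int(a.sum()), int(c.sum())
    if ta == 0 or tc == 0:
        raise ValidationError("a parent has zero reads; cannot build hybrid")
    n = min(ta, tc)
    rng = np.random.default_rng(seed)
    if ta > n:
        a = rng.multivariate_hypergeometric(a, n)
    elif tc > n:
        c = rng.multivariate_hypergeometric(c, n)
    out = a + c
    if isinstance(parent_a, pd.Series):
        return pd.Series(out, index=parent_a.index)
    return out


def build_hybrid_reads(
    reads_a: list[str], reads_c: list[str], seed: int
) -> list[str]:
    """Read-level 1:1 mixing: sample min(len) reads without replacement
    from each parent and pool them (order-invariant: inputs are sorted
    before sampling)."""
    if not reads_a or not reads_c:
        raise ValidationError("a parent has zero reads; cannot build hybrid")
    rng = np.random.default_rng(seed)
    n = min(len(reads_a), len(reads_c))
    picked = []
    for reads in (sorted(reads_a), sorted(reads_c)):
        idx = rng.choice(len(reads), size=n, replace=False)
        picked.extend(reads[i] for i in sorted(idx))
    return picked


def mpv_samples(parent_a: pd.DataFrame, parent_c: pd.DataFrame) -> pd.DataFrame:
    """Mid-parent-value pseudo-replicates: MPV_i = (A_i + C_i) / 2.

    Inputs are normalised expression matrices (genes x replicates) with
    equal replicate counts; replicate i of A is paired with replicate i of
    C by column position.  No silent recycling on unequal counts.
    """
    if parent_a.shape[1] != parent_c.shape[1]:
        raise ValidationError(
            "mid-parent values need equal replicate counts "
            f"({parent_a.shape[1]} vs {parent_c.shape[1]})"
        )
    if not parent_a.index.equals(parent_c.index):
        raise ValidationError("parental matrices have different gene universes")
    vals = (parent_a.to_numpy(dtype=float) + parent_c.to_numpy(dtype=float)) / 2.0
    cols = [f"MPV_{i + 1}" for i in range(parent_a.shape[1])]
    return pd.DataFrame(vals, index=parent_a.index, columns=cols)


def classify_patterns(
    test_pa: pd.DataFrame,
    test_pc: pd.DataFrame,
    test_ac: pd.DataFrame,
    test_pmpv: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each gene into one of the twelve expression patterns.

    The four inputs are differential-test results (from
    :func:`allotx.expression.nb_wald_from_matrix`) for progeny vs parent
    A, progeny vs parent C, parent A vs parent C, and progeny vs
    mid-parent value, all over the same gene universe; log2FC is second
    group over first, so e.g. test_pa has log2FC of progeny over A.
    Significance is padj <= alpha on each contrast.

    Priority order (strongest evidence first):

    1. transgressive up: progeny significantly above both parents
       (3 fine patterns by the parental relation A>C / A<C / A~C);
    2. transgressive down: mirror;
    3. ELD-A: progeny non-additive (significant vs MPV), ~ A,
       significantly different from C, and A != C (2 patterns);
    4. ELD-C: mirror;
    5. additive: progeny ~ MPV, significantly different from both
       parents (hence intermediate), and A != C (2 patterns);
    6. no change: no contrast significant;
    7. ambiguous otherwise.

    Each pattern demands its complete evidence signature; a gene whose
    contrasts cannot distinguish, say, additivity from dominance toward
    the higher parent (a 1.6-fold difference at the default effect size)
    is AMBIGUOUS rather than forced into a pattern.  Pattern proportions
    are reported over confidently classified genes only.

    Returns a DataFrame indexed by gene with fine_pattern (1-12 or <NA>)
    and group.
    """
    idx = test_pa.index
    for other in (test_pc, test_ac, test_pmpv):
        if not idx.equals(other.index):
            raise ValidationError("contrast results have different gene universes")

    sig_pa = (test_pa["padj"] <= alpha).fillna(False).to_numpy()
    sig_pc = (test_pc["padj"] <= alpha).fillna(False).to_numpy()
    sig_ac = (test_ac["padj"] <= alpha).fillna(False).to_numpy()
    sig_pm = (test_pmpv["padj"] <= alpha).fillna(False).to_numpy()
    # log2FC sign conventions: test_pa/pc/pmpv are progeny over the
    # reference; test_ac is C over A
    p_above_a = (test_pa["log2FC"] > 0).fillna(False).to_numpy()
    p_above_c = (test_pc["log2FC"] > 0).fillna(False).to_numpy()
    c_above_a = (test_ac["log2FC"] > 0).fillna(False).to_numpy()

    groups = np.full(len(idx), AMBIGUOUS, dtype=object)
    fine = np.full(len(idx), -1, dtype=object)

    def relation(i: int) -> str:
        if not sig_ac[i]:
            return "A=C"
        return "A<C" if c_above_a[i] else "A>C"

    for i in range(len(idx)):
        if sig_pa[i] and sig_pc[i] and p_above_a[i] and p_above_c[i]:
            groups[i] = TRANSGRESSIVE_UP
            fine[i] = _PATTERN_OF[(TRANSGRESSIVE_UP, relation(i))]
        elif sig_pa[i] and sig_pc[i] and not p_above_a[i] and not p_above_c[i]:
            groups[i] = TRANSGRESSIVE_DOWN
            fine[i] = _PATTERN_OF[(TRANSGRESSIVE_DOWN, relation(i))]
        elif sig_pm[i] and not sig_pa[i] and sig_pc[i] and sig_ac[i]:
            groups[i] = ELD_A
            fine[i] = _PATTERN_OF[(ELD_A, relation(i))]
        elif sig_pm[i] and not sig_pc[i] and sig_pa[i] and sig_ac[i]:
            groups[i] = ELD_C
            fine[i] = _PATTERN_OF[(ELD_C, relation(i))]
        elif not sig_pm[i] and sig_pa[i] and sig_pc[i] and sig_ac[i]:
            groups[i] = ADDITIVE
            fine[i] = _PATTERN_OF[(ADDITIVE, relation(i))]
        elif not (sig_pa[i] or sig_pc[i] or sig_ac[i] or sig_pm[i]):
            groups[i] = NO_CHANGE
            fine[i] = -1
        else:
            groups[i] = AMBIGUOUS
            fine[i] = -1

    out = pd.DataFrame(
        {"fine_pattern": pd.array([f if f > 0 else pd.NA for f in fine],
                                  dtype="Int64"),
         "group": groups},
        index=idx,
    )
    return out


def pattern_summary(patterns: pd.DataFrame) -> dict:
    """Grouped proportions over the classified denominator (the twelve
    patterns; NO_CHANGE/AMBIGUOUS counted but excluded from proportions)."""
    if patterns.empty:
        raise ValidationError("no genes to summarise")
    counts = patterns["group"].value_counts().to_dict()
    classified = int(sum(counts.get(g, 0) for g in GROUPS))
    props = {}
    if classified:
        props = {
            "additive": counts.get(ADDITIVE, 0) / classified,
            "eld": (counts.get(ELD_A, 0) + counts.get(ELD_C, 0)) / classified,
            "transgressive": (
                counts.get(TRANSGRESSIVE_UP, 0) + counts.get(TRANSGRESSIVE_DOWN, 0)
            )
            / classified,
        }
    return {
        "counts": {g: counts.get(g, 0) for g in GROUPS + (NO_CHANGE, AMBIGUOUS)},
        "classified": classified,
        "proportions": props,
        "transgressive_up": counts.get(TRANSGRESSIVE_UP, 0),
        "transgressive_down": counts.get(TRANSGRESSIVE_DOWN, 0),
    }
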