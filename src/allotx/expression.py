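"""Normalisation, expressed/activated/silenced calls, and NB differential
expression.

The differential test is a self-contained negative-binomial Wald test:
median-of-ratios size factors, per-gene method-of-moments dispersion
pooled within the two groups and shrunk toward a log-linear
mean-dispersion trend (default weight 0.1 on the per-gene estimate: at
two or three replicates per group the moment estimate carries only a few
degrees of freedom, and a trend-dominated combination is what keeps the
test's type-I error at its nominal level), delta-method standard error of
the log2 fold change, normal reference distribution, Benjamini-Hochberg
adjustment.  Genes are called differentially expressed at |log2FC| >= 1
and padj <= 0.001 by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import CountMatrix, ValidationError

__all__ = [
    "size_factors",
    "tpm",
    "expressed_genes",
    "activation_silencing",
    "nb_wald_test",
    "nb_wald_from_matrix",
    "bh_adjust",
    "DEFAULT_LFC_THRESHOLD",
    "DEFAULT_PADJ_THRESHOLD",
]

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_PADJ_THRESHOLD = 0.001

_LN2 = np.log(2.0)
_DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene with nonzero counts in all samples, the ratio of its
    count to its geometric mean across samples is formed; a sample's
    factor is the median ratio.  Factors are rescaled to geometric mean 1.
    If no gene is nonzero in every sample, an add-one pseudo-reference is
    used (with a warning).
    """
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        warnings.warn(
            "no gene with nonzero counts in every sample; falling back to "
            "add-one pseudo-reference for size factors",
            stacklevel=2,
        )
        arr = arr + 1.0
        all_pos = np.ones(arr.shape[0], dtype=bool)
    sub = arr[all_pos]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def tpm(m: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million normalisation.

    Counts are divided by gene length in kb, then each column is scaled to
    sum to 1e6.  Requires union-exon gene lengths on the matrix.
    """
    if m.lengths is None:
        raise ValidationError("TPM requires gene lengths on the count matrix")
    rate = m.counts.to_numpy(dtype=float) / (
        m.lengths.to_numpy(dtype=float)[:, None] / 1e3
    )
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(
            f"sample(s) with zero total counts: "
            f"{list(m.counts.columns[zero_cols])}; TPM column left at zero",
            stacklevel=2,
        )
        colsum[zero_cols] = 1.0
    out = rate / colsum * 1e6
    return pd.DataFrame(out, index=m.counts.index, columns=m.counts.columns)


def expressed_genes(
    tpm_df: pd.DataFrame, sheet, group: str, min_replicates: int = 1
) -> set[str]:
    """Genes with TPM > 0 in at least ``min_replicates`` replicates of a
    group (the literal TPM > 0 rule by default)."""
    cols = sheet.samples_of(group)
    positive = (tpm_df.loc[:, cols] > 0).sum(axis=1)
    return set(tpm_df.index[positive >= min_replicates])


def activation_silencing(
    expr_x: set[str],
    expr_y: set[str],
    partition_by: set[str] | None = None,
) -> dict:
    """Activated (in X but not Y) and silenced (in Y but not X) gene sets.

    With ``partition_by`` Z, each set is split into the part inside and
    outside Z; the two parts sum to the total — the arithmetic used when a
    silenced/activated count is reported as the sum of two Venn regions.
    """
    activated = expr_x - expr_y
    silenced = expr_y - expr_x
    out = {"activated": activated, "silenced": silenced}
    if partition_by is not None:
        out["activated_split"] = (activated & partition_by, activated - partition_by)
        out["silenced_split"] = (silenced & partition_by, silenced - partition_by)
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    monotone, padj >= p)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


DEFAULT_DISPERSION_SHRINK_WEIGHT = 0.1


def _pooled_dispersion(
    x1: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments NB dispersion pooled within the two groups.

    Returns (grand mean, raw dispersion estimate), using the NB variance
    parameterisation var = mu + phi * mu^2.  The raw estimate is left
    unfloored (it can be negative when the pooled sample variance falls
    below the mean): flooring before the trend fit would bias the trend
    downward and make the Wald test anticonservative.
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / max(n1 + n2 - 2, 1)
    grand_mean = (x1.sum(axis=1) + x2.sum(axis=1)) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (pooled_var - grand_mean) / np.square(grand_mean)
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return grand_mean, phi


def _dispersion_trend(mean: np.ndarray, phi_raw: np.ndarray) -> np.ndarray | None:
    """Log-linear mean-dispersion trend fitted to binned means of the raw
    (unfloored) moment estimates.

    Binned averaging keeps the fit unbiased: per-gene moment estimates at
    a handful of degrees of freedom are individually far too noisy (and
    often negative) to regress in log space.  Returns None when the fit is
    degenerate.
    """
    ok = mean > 0
    if ok.sum() < 30:
        return None
    lx = np.log(mean[ok])
    y = phi_raw[ok]
    nbins = min(20, max(3, ok.sum() // 50))
    qs = np.quantile(lx, np.linspace(0, 1, nbins + 1))
    idx = np.clip(np.searchsorted(qs, lx, side="right") - 1, 0, nbins - 1)
    bx, by = [], []
    for b in range(nbins):
        sel = idx == b
        if sel.sum() >= 10 and y[sel].mean() > 0:
            bx.append(lx[sel].mean())
            by.append(np.log(y[sel].mean()))
    if len(bx) < 3 or np.ptp(bx) == 0:
        return None
    slope, intercept = np.polyfit(bx, by, 1)
    with np.errstate(over="ignore"):
        trend = np.exp(intercept + slope * np.log(np.maximum(mean, 1e-8)))
    return np.clip(trend, _DISPERSION_FLOOR, 1e4)


def _shrink_dispersion(
    mean: np.ndarray,
    phi_raw: np.ndarray,
    weight: float = DEFAULT_DISPERSION_SHRINK_WEIGHT,
) -> np.ndarray:
    """Combine the per-gene raw dispersion (floored at 1e-8) with the
    fitted trend: weight * raw + (1 - weight) * trend.

    Falls back to the floored raw estimates (with a warning) when the
    trend fit is degenerate.
    """
    floored = np.maximum(phi_raw, _DISPERSION_FLOOR)
    trend = _dispersion_trend(mean, phi_raw)
    if trend is None:
        warnings.warn(
            "degenerate mean-dispersion trend fit; using unshrunk dispersions",
            stacklevel=2,
        )
        return floored
    return weight * floored + (1.0 - weight) * trend


def nb_wald_from_matrix(
    data: pd.DataFrame,
    cols1: list[str],
    cols2: list[str],
    factors: pd.Series | None = None,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    padj_threshold: float = DEFAULT_PADJ_THRESHOLD,
    dispersion_shrink_weight: float = DEFAULT_DISPERSION_SHRINK_WEIGHT,
) -> pd.DataFrame:
    """NB Wald test of group2 over group1 on a (possibly pre-normalised)
    expression matrix.

    ``factors`` are per-sample size factors to divide by (already-
    normalised data passes None).  Genes with all-zero counts in both
    groups are excluded from testing.  Returns a DataFrame indexed by gene
    with baseMean, log2FC, SE, p, padj, is_DEG.
    """
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValidationError("each group needs >= 2 replicates")
    norm = data.loc[:, cols1 + cols2].to_numpy(dtype=float)
    if factors is not None:
        norm = norm / factors.loc[cols1 + cols2].to_numpy(dtype=float)[None, :]
    x1 = norm[:, : len(cols1)]
    x2 = norm[:, len(cols1):]
    tested = (x1.sum(axis=1) + x2.sum(axis=1)) > 0

    grand_mean, phi_raw = _pooled_dispersion(x1, x2)
    phi = _shrink_dispersion(
        np.where(tested, grand_mean, 0.0),
        np.where(tested, phi_raw, 0.0),
        weight=dispersion_shrink_weight,
    )

    m1 = x1.mean(axis=1) + 0.5  # pseudocount bounds the fold change
    m2 = x2.mean(axis=1) + 0.5
    lfc = np.log2(m2 / m1)
    # delta method on log2 of an NB mean: var(log2 m) = (1/m + phi) / (n ln2^2)
    v1 = (1.0 / m1 + phi) / (len(cols1) * _LN2**2)
    v2 = (1.0 / m2 + phi) / (len(cols2) * _LN2**2)
    se = np.sqrt(v1 + v2)
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    res = pd.DataFrame(
        {
            "baseMean": grand_mean,
            "log2FC": lfc,
            "SE": se,
            "p": p,
            "padj": np.nan,
            "is_DEG": False,
        },
        index=data.index,
    )
    res.loc[~tested, ["log2FC", "SE", "p"]] = np.nan
    mask = tested
    if mask.any():
        res.loc[mask, "padj"] = bh_adjust(res.loc[mask, "p"].to_numpy())
        res.loc[mask, "is_DEG"] = (
            res.loc[mask, "log2FC"].abs() >= lfc_threshold
        ) & (res.loc[mask, "padj"] <= padj_threshold)
    return res


def nb_wald_test(
    m: CountMatrix,
    group1: str,
    group2: str,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    padj_threshold: float = DEFAULT_PADJ_THRESHOLD,
    dispersion_shrink_weight: float = DEFAULT_DISPERSION_SHRINK_WEIGHT,
) -> pd.DataFrame:
    """Differential expression of ``group2`` over ``group1`` on raw counts.

    Counts are scaled by median-of-ratios size factors computed over the
    two groups' samples, then tested as in :func:`nb_wald_from_matrix`.
    """
    cols1 = m.sheet.samples_of(group1)
    cols2 = m.sheet.samples_of(group2)
    factors = size_factors(m.counts.loc[:, cols1 + cols2])
    return nb_wald_from_matrix(
        m.counts,
        cols1,
        cols2,
        factors=factors,
        lfc_threshold=lfc_threshold,
        padj_threshold=padj_threshold,
        dispersion_shrink_weight=dispersion_shrink_weight,
    )
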