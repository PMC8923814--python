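"""Run-level summary statistics and packaged reference tables.

``summarize_run_stats`` recomputes the aggregate sequencing statistics a
study reports alongside its per-sample table: total clean reads (in
millions), the mean full-length/clean ratio, mean GC content, per-group
mean mapping rates, and the minimum per-sample mean read quality.  The
package ships the per-sample statistics of the twelve libraries of the
targeted study design (three replicates each of the two diploid parents
and the resynthesized and natural allopolyploids) as a CSV fixture, and
the region cardinalities of the three-way expressed-gene Venn (hybrid /
resynthesized / natural) as a JSON fixture from which synthetic gene-id
sets with exactly those overlaps can be rebuilt.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .annotation_io import read_run_stats
from .models import ValidationError

__all__ = [
    "packaged_run_stats",
    "summarize_run_stats",
    "packaged_expressed_venn_regions",
    "expressed_sets_from_regions",
    "group_of_sample",
]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("allotx").joinpath("data", name)))


def packaged_run_stats() -> pd.DataFrame:
    """The shipped per-sample sequencing statistics table."""
    return read_run_stats(_data_path("run_stats.csv"))


def group_of_sample(sample_id: str) -> str:
    """Group label from a sample id of the form <GROUP><replicate>."""
    return sample_id.rstrip("0123456789")


def summarize_run_stats(
    table: pd.DataFrame, groups: dict[str, str] | None = None
) -> dict:
    """Aggregate a run-statistics table.

    Returns total clean reads in millions (2 dp), the mean of the
    full-length/clean percentages, mean GC percentage, per-group mean
    mapping percentage, and the minimum mean quality — each computed from
    the table's columns as printed.
    """
    if table.empty:
        raise ValidationError("empty run-stats table")
    if groups is None:
        groups = {s: group_of_sample(s) for s in table["sample_id"]}
    per_group = (
        table.assign(group=table["sample_id"].map(groups))
        .groupby("group")["mapping_pct"]
        .mean()
        .to_dict()
    )
    return {
        "total_clean_reads_millions": round(table["clean_reads"].sum() / 1e6, 2),
        "mean_fl_over_clean_pct": float(table["fl_over_clean_pct"].mean()),
        "mean_gc_pct": float(table["gc_pct"].mean()),
        "group_mean_mapping_pct": per_group,
        "min_mean_quality": float(table["mean_quality"].min()),
        "n_samples": int(len(table)),
    }


def packaged_expressed_venn_regions() -> dict[frozenset[str], int]:
    """Region cardinalities of the shipped three-way expressed-gene Venn,
    keyed by the frozenset of group names sharing the region."""
    with open(_data_path("expressed_venn_regions.json")) as fh:
        raw = json.load(fh)["regions"]
    return {frozenset(k.split("&")): int(v) for k, v in raw.items()}


def expressed_sets_from_regions(
    regions: dict[frozenset[str], int]
) -> dict[str, set[str]]:
    """Build synthetic gene-id sets realising exactly the given Venn
    region cardinalities.

    Ids are deterministic ("R<region>_<i>"), so set arithmetic on the
    result reproduces the region counts exactly.
    """
    names = sorted({n for key in regions for n in key})
    sets: dict[str, set[str]] = {n: set() for n in names}
    for key, count in sorted(regions.items(), key=lambda kv: sorted(kv[0])):
        tag = "&".join(sorted(key))
        ids = {f"R{tag}_{i}" for i in range(count)}
        for name in key:
            sets[name] |= ids
    return sets
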