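"""Gene-region CpG methylation statistics from per-cytosine coverage.

Workflow mirrors a standard whole-genome bisulfite analysis downstream of
the aligner: per-cytosine read counts are filtered to a 10-50x coverage
window, a site is called methylated when at least half of its reads are
methylated, and per-gene summaries report the proportion of covered sites
called methylated within four regions: the gene body, the exons, and 1 kb
up- and down-stream (strand-aware).  Group contrasts (laterally acquired vs
vertically inherited; degenerating vs putatively stable) are linear mixed
models on the region proportions with random intercepts for gene family and
accession within family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog_io import RegionSet, ValidationError
from .lmm import ModelReport, fit_gaussian_lmm

__all__ = [
    "REGIONS",
    "filter_cytosines",
    "call_site_methylation",
    "summarize_region_methylation",
    "compare_methylation",
]

REGIONS = ("gene_body", "exons", "upstream_1kb", "downstream_1kb")


def filter_cytosines(
    records: pd.DataFrame, min_coverage: int = 10, max_coverage: int = 50
) -> pd.DataFrame:
    """Keep cytosines with min_coverage <= reads <= max_coverage (inclusive)."""
    cov = records["count_methylated"] + records["count_unmethylated"]
    return records[(cov >= min_coverage) & (cov <= max_coverage)].reset_index(drop=True)


def call_site_methylation(count_methylated, count_unmethylated):
    """A site is methylated iff at least 50% of its reads are methylated.

    Accepts scalars or aligned arrays; zero-coverage sites are an error
    (they must be removed by the coverage filter first)."""
    m = np.asarray(count_methylated, dtype=float)
    u = np.asarray(count_unmethylated, dtype=float)
    cov = m + u
    if np.any(cov <= 0):
        raise ValidationError("zero-coverage site: filter records before calling")
    out = m / cov >= 0.5
    return bool(out) if np.isscalar(count_methylated) else out


def summarize_region_methylation(
    records: pd.DataFrame, regions: RegionSet
) -> pd.DataFrame:
    """Per gene x region counts of covered and methylated cytosine sites.

    ``records`` must already be coverage-filtered.  A cytosine overlapping
    two exon intervals is counted once; regions with no covered sites get a
    NaN proportion (excluded from downstream models).
    """
    records = records.reset_index(drop=True)
    rows = []
    methylated = call_site_methylation(
        records["count_methylated"], records["count_unmethylated"]
    ) if len(records) else np.zeros(0, dtype=bool)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in records.groupby("chrom"):
        pos0 = sub["pos"].to_numpy() - 1  # to 0-based
        order = np.argsort(pos0, kind="mergesort")
        by_chrom[str(chrom)] = (pos0[order], np.asarray(methylated)[sub.index[order]])
    for gid in sorted(regions):
        reg = regions[gid]
        chrom_data = by_chrom.get(reg.chrom)
        for region in REGIONS:
            if chrom_data is None:
                n_cov = n_meth = 0
            else:
                pos, meth = chrom_data
                hit = np.zeros(pos.size, dtype=bool)
                for s, e in reg.region_intervals(region):
                    lo, hi = np.searchsorted(pos, [s, e])
                    hit[lo:hi] = True  # union: overlapping intervals count once
                n_cov = int(hit.sum())
                n_meth = int(meth[hit].sum())
            rows.append(
                {
                    "gene_id": gid,
                    "region": region,
                    "n_covered_sites": n_cov,
                    "n_methylated_sites": n_meth,
                    "proportion": n_meth / n_cov if n_cov else np.nan,
                }
            )
    return pd.DataFrame(rows)


def compare_methylation(
    summaries: pd.DataFrame,
    meta: pd.DataFrame,
    region: str = "gene_body",
    group_col: str = "group",
    reference: str | None = None,
) -> ModelReport:
    """LMM contrast of region methylation proportions between two groups.

    ``summaries`` as returned by :func:`summarize_region_methylation`;
    ``meta`` supplies per-gene labels (gene_id, group, family, accession).
    The group coefficient is the difference in proportion of methylated
    sites; undefined proportions are dropped with a flag.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    data = summaries[summaries["region"] == region].merge(meta, on="gene_id", how="inner")
    flags = []
    n_undefined = int(data["proportion"].isna().sum())
    if n_undefined:
        flags.append(f"undefined_proportion_dropped:{n_undefined}")
        data = data.dropna(subset=["proportion"])
    levels = sorted(data[group_col].unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups for region {region}, got {levels}")
    if reference is None:
        reference = levels[0]
    data = data.rename(columns={group_col: "grp"})
    report = fit_gaussian_lmm(
        data,
        formula=f"proportion ~ C(grp, Treatment(reference='{reference}'))",
        term="C(grp",
        model_name=f"methylation_lmm_{region}",
    )
    report.flags.extend(flags)
    means = data.groupby("grp")["proportion"].mean()
    report.extras["group_means"] = dict(means)
    report.extras["reference"] = reference
    report.extras["region"] = region
    return report
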