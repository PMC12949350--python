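"""Expression-based fate classification of laterally acquired genes.

For each transferred gene the pipeline assembles a *triplet*: its own
expression across the recipient accession's RNA-seq samples, the vertically
inherited homolog's expression across the same samples (paired), and the
donor ortholog's expression across the donor species' samples (unpaired).
Expression is log2(TPM + 1).

Fate call: a gene is *degenerating* when it is expressed significantly below
both comparators — paired Wilcoxon signed-rank vs the vertical homolog and
Wilcoxon rank-sum vs the donor ortholog, both BH-adjusted across all genes in
the run, both adjusted p < alpha, and the gene's median log-expression below
each comparator's.  Everything else is *putatively stable* (truncation-based
reclassification happens downstream).

Putatively stable genes are then placed in one of five expression categories
(no_difference / higher / intermediate / recipient_like / donor_like) by a
BH-adjusted Kruskal-Wallis test followed by Dunn's post hoc pairwise tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog_io import ValidationError
from .lmm import (  # noqa: F401  (model contracts re-exported from this module)
    ModelReport,
    fit_difference_lmm,
    fit_interaction_lmm,
    fit_type_lmm,
)
from .stats import bh_adjust, dunn_test, exact_binomial_test, kruskal_wallis
from .stats import rank_sum_test, signed_rank_test

__all__ = [
    "DEFAULT_TPM_THRESHOLD",
    "TripletExpression",
    "log_transform",
    "detect_expression",
    "paired_log_difference",
    "build_triplets",
    "classify_fate",
    "classify_expression_categories",
    "categorize_triplet",
    "test_category_enrichment",
    "expression_divergence",
    "fit_difference_lmm",
    "fit_type_lmm",
    "fit_interaction_lmm",
]

DEFAULT_TPM_THRESHOLD = 0.5
CATEGORIES = ("no_difference", "higher", "intermediate", "recipient_like", "donor_like")


def log_transform(tpm, base: float = 2.0, offset: float = 1.0):
    """log(tpm + offset) in the given base; with the defaults, TPM 0 maps to
    0 and the transform is monotone on [0, inf)."""
    arr = np.asarray(tpm, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("TPM values must be >= 0")
    out = np.log(arr + offset) / math.log(base)
    return float(out) if np.isscalar(tpm) else out


def detect_expression(tpm_vector, threshold: float = DEFAULT_TPM_THRESHOLD) -> bool:
    """True iff the gene reaches the detection threshold (TPM >= 0.5 by
    default) in at least one sample."""
    arr = np.asarray(tpm_vector, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty TPM vector")
    return bool(np.any(arr >= threshold))


@dataclass
class TripletExpression:
    """Per-sample expression of one LGT gene and its two comparators.

    ``lgt`` and ``vertical`` are index-aligned to ``sample_ids`` (the
    recipient accession's samples); ``donor`` covers the donor species'
    samples and may have a different length.  TPM and log vectors are kept
    side by side: detection uses TPM, the tests use log values.
    """

    lgt_id: str
    accession: str
    family_id: str
    sample_ids: list[str]
    tissues: list[str]
    lgt_tpm: np.ndarray
    lgt_log: np.ndarray
    vertical_tpm: np.ndarray | None = None
    vertical_log: np.ndarray | None = None
    donor_tpm: np.ndarray | None = None
    donor_log: np.ndarray | None = None
    donor_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vertical_log is not None and len(self.vertical_log) != len(self.lgt_log):
            raise ValidationError(
                f"{self.lgt_id}: vertical vector not aligned to LGT samples"
            )


def paired_log_difference(triplet: TripletExpression) -> np.ndarray:
    """Per-sample log-expression difference, LGT minus vertical homolog."""
    if triplet.vertical_log is None:
        raise ValidationError(f"{triplet.lgt_id}: no vertical homolog vector")
    return np.asarray(triplet.lgt_log) - np.asarray(triplet.vertical_log)


def _gene_vector(pivot: pd.DataFrame, gene_ids: list[str]) -> np.ndarray | None:
    for gid in gene_ids:
        if gid in pivot.index:
            return pivot.loc[gid].to_numpy()
    return None


def build_triplets(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    catalog: pd.DataFrame,
    log_base: float = 2.0,
    exclude_tissues: tuple[str, ...] = (),
) -> list[TripletExpression]:
    """Assemble aligned triplet vectors from the (paralog-aggregated)
    expression table.

    Comparator ids listed in the catalog are resolved against the table; the
    first id found is used (after paralog aggregation a group is carried by
    its representative id).  Missing comparators yield None vectors — the
    gene is kept and flagged unclassifiable downstream.
    """
    keep = samples[~samples["tissue"].isin(exclude_tissues)]
    donor_sheet = keep[keep["species_role"] == "donor"].sort_values("sample_id")
    pivot = expression.pivot(index="gene_id", columns="sample_id", values="tpm")

    triplets = []
    for row in catalog.itertuples(index=False):
        acc_sheet = keep[
            (keep["accession"] == row.accession)
            & (keep["species_role"] == "recipient")
        ].sort_values("sample_id")
        if acc_sheet.empty:
            raise ValidationError(f"no recipient samples for accession {row.accession}")
        sample_ids = list(acc_sheet["sample_id"])
        sub = pivot[sample_ids]
        if row.lgt_id not in sub.index:
            raise ValidationError(f"catalog gene missing from table: {row.lgt_id}")
        lgt_tpm = sub.loc[row.lgt_id].to_numpy()
        vert_tpm = _gene_vector(sub, list(row.vertical_ids))
        donor_ids = list(row.donor_ids)
        donor_cols = list(donor_sheet["sample_id"])
        donor_tpm = (
            _gene_vector(pivot[donor_cols], donor_ids) if donor_ids and donor_cols else None
        )
        triplets.append(
            TripletExpression(
                lgt_id=row.lgt_id,
                accession=row.accession,
                family_id=row.family_id,
                sample_ids=sample_ids,
                tissues=list(acc_sheet["tissue"]),
                lgt_tpm=lgt_tpm,
                lgt_log=log_transform(lgt_tpm, base=log_base),
                vertical_tpm=vert_tpm,
                vertical_log=None if vert_tpm is None else log_transform(vert_tpm, base=log_base),
                donor_tpm=donor_tpm,
                donor_log=None if donor_tpm is None else log_transform(donor_tpm, base=log_base),
                donor_sample_ids=donor_cols,
            )
        )
    return triplets


def classify_fate(
    triplets: list[TripletExpression],
    alpha: float = 0.05,
    detection_threshold: float = DEFAULT_TPM_THRESHOLD,
) -> pd.DataFrame:
    """Degenerating vs putatively stable fate calls.

    Genes without an expressed vertical homolog or donor ortholog are flagged
    unclassifiable and excluded from the BH families.  Returns one row per
    input triplet, input order preserved.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    rows = []
    for t in triplets:
        rec: dict = {
            "lgt_id": t.lgt_id,
            "accession": t.accession,
            "family_id": t.family_id,
            "classifiable": True,
            "unclassifiable_reason": "",
            "p_vertical": np.nan,
            "p_donor": np.nan,
            "lower_than_vertical": False,
            "lower_than_donor": False,
        }
        if t.vertical_tpm is None or not detect_expression(t.vertical_tpm, detection_threshold):
            rec["classifiable"] = False
            rec["unclassifiable_reason"] = "no_expressed_vertical_homolog"
        elif t.donor_tpm is None or not detect_expression(t.donor_tpm, detection_threshold):
            rec["classifiable"] = False
            rec["unclassifiable_reason"] = "no_expressed_donor_ortholog"
        elif len(t.lgt_log) < 2 or len(t.donor_log) < 2:
            rec["classifiable"] = False
            rec["unclassifiable_reason"] = "too_few_samples"
        else:
            diffs = paired_log_difference(t)
            _, rec["p_vertical"] = signed_rank_test(diffs)
            _, rec["p_donor"] = rank_sum_test(t.lgt_log, t.donor_log)
            rec["lower_than_vertical"] = float(np.median(t.lgt_log)) < float(
                np.median(t.vertical_log)
            )
            rec["lower_than_donor"] = float(np.median(t.lgt_log)) < float(
                np.median(t.donor_log)
            )
        rows.append(rec)
    calls = pd.DataFrame(rows)
    mask = calls["classifiable"].to_numpy()
    calls["p_vertical_adj"] = np.nan
    calls["p_donor_adj"] = np.nan
    if mask.any():
        calls.loc[mask, "p_vertical_adj"] = bh_adjust(calls.loc[mask, "p_vertical"])
        calls.loc[mask, "p_donor_adj"] = bh_adjust(calls.loc[mask, "p_donor"])
    degenerating = (
        mask
        & (calls["p_vertical_adj"] < alpha)
        & (calls["p_donor_adj"] < alpha)
        & calls["lower_than_vertical"]
        & calls["lower_than_donor"]
    )
    calls["fate"] = np.where(
        ~mask, "", np.where(degenerating, "degenerating", "putatively_stable")
    )
    calls["truncation_override"] = False
    return calls


def categorize_triplet(
    triplet: TripletExpression, kw_p_adj: float, alpha: float = 0.05
) -> dict:
    """Apply the five-way decision table given the gene's BH-adjusted
    Kruskal-Wallis p-value.

    Dunn's pairwise tests (LGT vs vertical, LGT vs donor) are only consulted
    when the adjusted omnibus test is significant.  A gene significantly
    *below* both comparators belongs to the degenerating fate by definition;
    if it surfaces here it is recorded as intermediate with a flag.
    """
    rec = {
        "lgt_id": triplet.lgt_id,
        "accession": triplet.accession,
        "family_id": triplet.family_id,
        "kw_p_adj": kw_p_adj,
        "dunn_p_vs_vertical": np.nan,
        "dunn_p_vs_donor": np.nan,
        "category": "",
        "flags": "",
    }
    if (
        triplet.vertical_log is None
        or triplet.donor_log is None
        or min(len(triplet.lgt_log), len(triplet.vertical_log), len(triplet.donor_log)) < 2
    ):
        rec["flags"] = "unclassifiable_group_too_small"
        return rec
    if not np.isfinite(kw_p_adj) or kw_p_adj >= alpha:
        rec["category"] = "no_difference"
        return rec
    groups = [triplet.lgt_log, triplet.vertical_log, triplet.donor_log]
    _, p_v = dunn_test(groups, (0, 1))
    _, p_d = dunn_test(groups, (0, 2))
    rec["dunn_p_vs_vertical"] = p_v
    rec["dunn_p_vs_donor"] = p_d
    sig_v, sig_d = p_v < alpha, p_d < alpha
    med_l = float(np.median(triplet.lgt_log))
    med_v = float(np.median(triplet.vertical_log))
    med_d = float(np.median(triplet.donor_log))
    if sig_v and sig_d:
        if med_l > med_v and med_l > med_d:
            rec["category"] = "higher"
        elif med_l < med_v and med_l < med_d:
            rec["category"] = "intermediate"
            rec["flags"] = "lower_than_both"
        else:
            rec["category"] = "intermediate"
    elif sig_v:
        rec["category"] = "donor_like"
    elif sig_d:
        rec["category"] = "recipient_like"
    else:
        rec["category"] = "no_difference"
    return rec


def classify_expression_categories(
    triplets: list[TripletExpression], alpha: float = 0.05
) -> pd.DataFrame:
    """Five-way expression categorisation across a set of genes.

    Kruskal-Wallis p-values are BH-adjusted across all genes with complete
    triplets, then each gene runs through the Dunn decision table."""
    kw_ps, usable = [], []
    for t in triplets:
        ok = (
            t.vertical_log is not None
            and t.donor_log is not None
            and min(len(t.lgt_log), len(t.vertical_log), len(t.donor_log)) >= 2
        )
        usable.append(ok)
        if ok:
            _, p = kruskal_wallis([t.lgt_log, t.vertical_log, t.donor_log])
            kw_ps.append(p)
    adj_iter = iter(bh_adjust(kw_ps) if kw_ps else [])
    rows = []
    for t, ok in zip(triplets, usable):
        kw_adj = float(next(adj_iter)) if ok else np.nan
        rows.append(categorize_triplet(t, kw_adj, alpha=alpha))
    return pd.DataFrame(rows)


def test_category_enrichment(categories: pd.DataFrame) -> dict:
    """Binomial enrichment tests on the category counts.

    Test 1: are no_difference genes a majority (null p0 = 0.5)?  Test 2:
    among the remaining genes, are donor_like genes over-represented relative
    to a uniform null over the 4 informative categories (p0 = 0.25)?"""
    assigned = categories[categories["category"] != ""]
    if assigned.empty:
        raise ValidationError("no categorised genes")
    counts = {c: int((assigned["category"] == c).sum()) for c in CATEGORIES}
    n_total = int(len(assigned))
    n_nd = counts["no_difference"]
    report = {
        "counts": counts,
        "n_total": n_total,
        "p_no_difference_majority": exact_binomial_test(n_nd, n_total, 0.5),
        "flags": [],
    }
    n_rest = n_total - n_nd
    if n_rest == 0:
        report["p_donor_like_enrichment"] = np.nan
        report["flags"].append("no_genes_outside_no_difference")
    else:
        report["p_donor_like_enrichment"] = exact_binomial_test(
            counts["donor_like"], n_rest, 0.25
        )
    return report


test_category_enrichment.__test__ = False  # name is domain API, not a pytest test


def expression_divergence(
    triplets: list[TripletExpression], fates: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Absolute vertical-donor mean log-expression divergence per gene, and
    its rank-sum contrast between fate classes.

    A larger divergence for putatively stable transfers indicates that
    retained genes tend to come with expression states distinct from the
    recipient's own copy."""
    fate_map = dict(zip(fates["lgt_id"] + "@" + fates["accession"], fates["fate"]))
    rows = []
    for t in triplets:
        if t.vertical_log is None or t.donor_log is None:
            continue
        rows.append(
            {
                "lgt_id": t.lgt_id,
                "accession": t.accession,
                "family_id": t.family_id,
                "abs_divergence": abs(
                    float(np.mean(t.vertical_log)) - float(np.mean(t.donor_log))
                ),
                "fate": fate_map.get(t.lgt_id + "@" + t.accession, ""),
            }
        )
    records = pd.DataFrame(rows)
    contrast: dict = {"flags": []}
    stable = records.loc[records["fate"] == "putatively_stable", "abs_divergence"]
    degen = records.loc[records["fate"] == "degenerating", "abs_divergence"]
    for name, grp in (("putatively_stable", stable), ("degenerating", degen)):
        contrast[f"mean_{name}"] = float(grp.mean()) if len(grp) else np.nan
        contrast[f"sd_{name}"] = float(grp.std(ddof=1)) if len(grp) > 1 else np.nan
        contrast[f"n_{name}"] = int(len(grp))
    if len(stable) == 0 or len(degen) == 0:
        contrast["pvalue"] = np.nan
        contrast["flags"].append("fate_class_empty_contrast_omitted")
    else:
        _, contrast["pvalue"] = rank_sum_test(stable.to_numpy(), degen.to_numpy())
    return records, contrast
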