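"""End-to-end orchestration: from a fixture bundle (or equivalently shaped
real inputs) to the consolidated fate report.

Stage order follows the analysis logic: paralog grouping and TPM
aggregation, expression detection, fate calls, truncation calls and
reclassification, expression categories and enrichment, expression
divergence and mixed-model contrasts, methylation summaries and contrasts,
pairwise dN/dS, and transfer-age tests.  All outputs are plain TSV/JSON with
deterministic ordering, so identical seed/config runs produce byte-identical
report bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import age as age_mod
from . import methylation as meth_mod
from .catalog_io import ValidationError, identify_recent_paralogs
from .catalog_io import aggregate_paralog_tpm
from .divergence import compare_rates_by_fate, compute_pairwise_rates, pick_representative
from .expression import (
    build_triplets,
    classify_expression_categories,
    classify_fate,
    detect_expression,
    expression_divergence,
    fit_difference_lmm,
    fit_interaction_lmm,
    fit_type_lmm,
    paired_log_difference,
)
from .synth import read_fixture_bundle
from .truncation import (
    OrthologAlignment,
    classify_truncation,
    compare_truncation_rates,
    reclassify_by_truncation,
    test_truncation_vs_category,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and analysis knobs for one pipeline run."""

    input_dir: str | Path
    output_dir: str | Path
    alpha: float = 0.05
    log_base: float = 2.0
    exclude_tissues: tuple[str, ...] = ()
    paralog_mode: str = "sum"  # or "max": most highly expressed paralog only
    detection_threshold: float = 0.5
    reference_gate: str = "all"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.paralog_mode not in {"sum", "max"}:
            raise ValidationError(f"paralog_mode must be sum or max, got {self.paralog_mode}")
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory not found: {self.input_dir}")


def _refine_groups_by_taxon(
    groups: list[frozenset[str]], taxon_map: dict[str, str]
) -> list[frozenset[str]]:
    """Split tree-derived paralog groups by taxon: expression can only be
    aggregated among copies residing in the same accession's genome."""
    refined = []
    for group in groups:
        by_taxon: dict[str, set[str]] = {}
        for gid in group:
            by_taxon.setdefault(taxon_map[gid], set()).add(gid)
        refined.extend(frozenset(v) for _, v in sorted(by_taxon.items()))
    return refined


def _family_members(gene_trees: dict[str, str]) -> dict[str, str]:
    """leaf id -> family id, read off the gene trees."""
    import dendropy

    members: dict[str, str] = {}
    for fam in sorted(gene_trees):
        tree = dendropy.Tree.get(
            data=gene_trees[fam], schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        for leaf in tree.leaf_node_iter():
            members[leaf.taxon.label] = fam
    return members


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage; returns the result objects and writes the
    report bundle under ``config.output_dir``."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logged_cfg = {
        k: v for k, v in asdict(config).items() if k not in {"input_dir", "output_dir"}
    }
    log_lines: list[str] = [
        f"run config: {json.dumps(logged_cfg, default=str, sort_keys=True)}"
    ]

    bundle = read_fixture_bundle(config.input_dir)
    expression = bundle["expression"]
    samples = bundle["samples"]
    catalog = bundle["catalog"]
    taxon_map = bundle["taxon_map"]
    taxon_roles = bundle["taxon_roles"]
    recipient_taxa = bundle["recipient_taxa"]

    # --- paralog grouping and aggregation ---------------------------------
    raw_groups: list[frozenset[str]] = []
    for fam in sorted(bundle["gene_trees"]):
        raw_groups.extend(
            identify_recent_paralogs(bundle["gene_trees"][fam], recipient_taxa, taxon_map)
        )
    groups = _refine_groups_by_taxon(raw_groups, taxon_map)
    expressed_genes = set(expression["gene_id"])
    groups = [g for g in groups if g <= expressed_genes]  # trees may hold CDS-only leaves
    aggregated = aggregate_paralog_tpm(expression, groups, mode=config.paralog_mode)
    log_lines.append(
        f"paralog groups: {len(groups)} ({sum(1 for g in groups if len(g) > 1)} multi-copy), "
        f"mode={config.paralog_mode}"
    )

    # --- detection --------------------------------------------------------
    pivot = aggregated.pivot(index="gene_id", columns="sample_id", values="tpm")
    detection_rows = []
    for row in catalog.itertuples(index=False):
        acc_samples = samples.loc[
            (samples["accession"] == row.accession)
            & (~samples["tissue"].isin(config.exclude_tissues)),
            "sample_id",
        ]
        vec = pivot.loc[row.lgt_id, acc_samples].to_numpy()
        detection_rows.append(
            {
                "lgt_id": row.lgt_id,
                "accession": row.accession,
                "expressed": detect_expression(vec, config.detection_threshold),
            }
        )
    detection = pd.DataFrame(detection_rows)

    # --- fate calls -------------------------------------------------------
    triplets = build_triplets(
        aggregated,
        samples,
        catalog,
        log_base=config.log_base,
        exclude_tissues=config.exclude_tissues,
    )
    fates = classify_fate(triplets, alpha=config.alpha, detection_threshold=config.detection_threshold)

    # --- truncation -------------------------------------------------------
    family_of = _family_members(bundle["gene_trees"])
    cds = bundle["cds"]
    refs_by_family: dict[str, list[tuple[str, str]]] = {}
    for gid, seq in cds.items():
        if taxon_roles.get(taxon_map.get(gid, ""), "") == "reference":
            refs_by_family.setdefault(family_of.get(gid, ""), []).append((gid, seq))
    for fam in refs_by_family:
        refs_by_family[fam].sort()

    lgt_ids = set(catalog["lgt_id"])
    vertical_ids = {v for vs in catalog["vertical_ids"] for v in vs}
    group_of: dict[str, frozenset[str]] = {}
    for g in groups:
        for gid in g:
            group_of[gid] = g
    lgt_copy_ids = set().union(*(group_of.get(g, frozenset({g})) for g in lgt_ids))
    vertical_copy_ids = set().union(
        *(group_of.get(g, frozenset({g})) for g in vertical_ids)
    )

    trunc_rows = []
    call_map = {}
    for gid in sorted(lgt_copy_ids | vertical_copy_ids):
        if gid not in cds:
            continue
        fam = family_of.get(gid, "")
        refs = refs_by_family.get(fam, [])
        if not refs:
            log_lines.append(f"truncation skipped (no references): {gid}")
            continue
        call = classify_truncation(
            OrthologAlignment(gid, cds[gid], refs), reference_gate=config.reference_gate
        )
        call_map[gid] = call
        trunc_rows.append(
            {
                "gene_id": gid,
                "gene_type": "lgt" if gid in lgt_copy_ids else "vertical",
                "accession": taxon_map.get(gid, ""),
                "family": fam,
                "truncated": call.truncated,
                "reasons": ";".join(sorted(call.reasons)),
                "length_ratio_min": call.length_ratio_min,
            }
        )
    trunc_calls = pd.DataFrame(trunc_rows)

    fates = reclassify_by_truncation(fates, call_map, groups)
    fate_map = dict(zip(fates["lgt_id"], fates["fate"]))

    # --- categories and enrichment (putatively stable genes only) ---------
    stable_ids = set(fates.loc[fates["fate"] == "putatively_stable", "lgt_id"])
    stable_triplets = [t for t in triplets if t.lgt_id in stable_ids]
    categories = (
        classify_expression_categories(stable_triplets, alpha=config.alpha)
        if stable_triplets
        else pd.DataFrame()
    )
    enrichment = (
        _enrichment_or_flag(categories) if len(categories) else {"flags": ["no_stable_genes"]}
    )

    # --- expression divergence and mixed-model contrasts ------------------
    divergence_records, divergence_contrast = expression_divergence(triplets, fates)

    diff_rows, type_rows, inter_rows = [], [], []
    for t in triplets:
        if t.vertical_log is None:
            continue
        for d in paired_log_difference(t):
            diff_rows.append(
                {"family": t.family_id, "accession": t.accession, "log_difference": float(d)}
            )
        if t.donor_log is not None:
            for v in t.lgt_log:
                type_rows.append(
                    {"family": t.family_id, "accession": t.accession,
                     "gene_type": "lgt", "log_expression": float(v)}
                )
            for v in t.donor_log:
                type_rows.append(
                    {"family": t.family_id, "accession": t.accession,
                     "gene_type": "donor", "log_expression": float(v)}
                )
            status = fate_map.get(t.lgt_id, "")
            if status in {"degenerating", "putatively_stable"}:
                for gene_type, vec in (("vertical", t.vertical_log), ("donor", t.donor_log)):
                    for v in vec:
                        inter_rows.append(
                            {"family": t.family_id, "accession": t.accession,
                             "status": status, "gene_type": gene_type,
                             "log_expression": float(v)}
                        )

    models = {}
    if diff_rows:
        models["difference_lmm"] = fit_difference_lmm(pd.DataFrame(diff_rows))
    if type_rows:
        models["type_lmm"] = fit_type_lmm(pd.DataFrame(type_rows))
    inter_df = pd.DataFrame(inter_rows)
    if len(inter_rows) and inter_df["status"].nunique() == 2:
        models["interaction_lmm"] = fit_interaction_lmm(inter_df)
    else:
        log_lines.append("interaction LMM skipped: need both fate classes")

    if len(trunc_calls):
        models["truncation_rate_glmm"] = compare_truncation_rates(
            trunc_calls[["family", "gene_type", "truncated"]]
        )
        fate_trunc = fates.loc[fates["classifiable"], ["lgt_id", "family_id", "fate"]].copy()
        fate_trunc["truncated"] = fate_trunc["lgt_id"].map(
            lambda g: call_map[g].truncated if g in call_map else np.nan
        )
        fate_trunc = fate_trunc.dropna(subset=["truncated"]).rename(
            columns={"family_id": "family"}
        )
        if len(fate_trunc):
            models["fate_vs_truncation_glmm"] = test_truncation_vs_category(fate_trunc)

    # --- methylation ------------------------------------------------------
    filtered = meth_mod.filter_cytosines(bundle["cytosines"])
    meth_summaries = meth_mod.summarize_region_methylation(filtered, bundle["regions"])
    meta_rows = []
    for gid in sorted(bundle["regions"]):
        gene_type = (
            "lgt" if gid in lgt_copy_ids else "vertical" if gid in vertical_copy_ids else ""
        )
        if not gene_type:
            continue
        meta_rows.append(
            {
                "gene_id": gid,
                "group": gene_type,
                "family": family_of.get(gid, ""),
                "accession": taxon_map.get(gid, ""),
                "fate": fate_map.get(gid, ""),
            }
        )
    meth_meta = pd.DataFrame(meta_rows)
    meth_models = {}
    for region in meth_mod.REGIONS:
        try:
            meth_models[f"lgt_vs_vertical_{region}"] = meth_mod.compare_methylation(
                meth_summaries, meth_meta, region=region, reference="vertical"
            )
        except (ValidationError, ValueError) as exc:
            log_lines.append(f"methylation contrast skipped ({region}): {exc}")
    lgt_meta = meth_meta[meth_meta["group"] == "lgt"].copy()
    lgt_meta["group"] = lgt_meta["fate"]
    lgt_meta = lgt_meta[lgt_meta["group"].isin(["degenerating", "putatively_stable"])]
    if lgt_meta["group"].nunique() == 2:
        for region in ("gene_body", "exons"):
            meth_models[f"fate_{region}"] = meth_mod.compare_methylation(
                meth_summaries, lgt_meta, region=region, reference="putatively_stable"
            )

    # --- pairwise dN/dS ---------------------------------------------------
    dnds_rows = []
    for fam, fam_cat in catalog.groupby("family_id"):
        vert_seqs = {
            v: cds[v]
            for vs in fam_cat["vertical_ids"]
            for v in vs
            if v in cds
        }
        donor_seqs = {
            d: cds[d] for ds in fam_cat["donor_ids"] for d in ds if d in cds
        }
        if not vert_seqs or not donor_seqs:
            continue
        vid = pick_representative(vert_seqs)
        did = pick_representative(donor_seqs)
        va, do = vert_seqs[vid], donor_seqs[did]
        n = min(len(va) // 3, len(do) // 3) * 3
        try:
            rates = compute_pairwise_rates(va[:n], do[:n], id_a=vid, id_b=did)
        except ValidationError as exc:
            log_lines.append(f"dN/dS skipped ({fam}): {exc}")
            continue
        rep_acc = taxon_map.get(vid, "")
        rep_fate = ""
        for row in fam_cat.itertuples(index=False):
            if row.accession == rep_acc:
                rep_fate = fate_map.get(row.lgt_id, "")
                break
        dnds_rows.append(
            {
                "family": fam,
                "vertical_id": vid,
                "donor_id": did,
                "n_codons": rates.n_codons,
                "S": rates.S,
                "N": rates.N,
                "Sd": rates.Sd,
                "Nd": rates.Nd,
                "dS": rates.dS,
                "dN": rates.dN,
                "omega": rates.omega,
                "fate": rep_fate,
                "flags": ";".join(rates.flags),
            }
        )
    dnds = pd.DataFrame(dnds_rows)
    dnds_contrast = (
        compare_rates_by_fate(dnds[dnds["fate"] != ""]) if len(dnds) else {"flags": ["no_pairs"]}
    )

    # --- transfer age -----------------------------------------------------
    ages = bundle["ages"]
    age_records = []
    for row in catalog.itertuples(index=False):
        acc_samples = samples.loc[
            (samples["accession"] == row.accession)
            & (~samples["tissue"].isin(config.exclude_tissues)),
            "sample_id",
        ]
        vec = pivot.loc[row.lgt_id, acc_samples].to_numpy()
        age_records.append(
            {
                "lgt_id": row.lgt_id,
                "accession": row.accession,
                "family_id": row.family_id,
                "mean_log_expression": float(
                    np.mean(np.log2(np.asarray(vec, dtype=float) + 1.0))
                ),
                "fate": fate_map.get(row.lgt_id, ""),
            }
        )
    age_df = pd.DataFrame(age_records).merge(
        ages[["lgt_id", "age_ma"]], on="lgt_id", how="inner"
    )
    age_report = {
        "regression": age_mod.test_age_expression(age_df),
        "fate_contrast": age_mod.compare_age_by_fate(age_df),
    }
    age_bins = age_mod.bin_ages(age_df.drop_duplicates("family_id")["age_ma"])

    # --- per-accession summary --------------------------------------------
    summary_rows = []
    pre_reclass = fates.copy()
    pre_reclass.loc[pre_reclass["truncation_override"], "fate"] = "putatively_stable"
    for acc in sorted(catalog["accession"].unique()):
        sub_det = detection[detection["accession"] == acc]
        sub_fate = fates[(fates["accession"] == acc) & fates["classifiable"]]
        sub_pre = pre_reclass[(pre_reclass["accession"] == acc) & pre_reclass["classifiable"]]
        row = {
            "accession": acc,
            "n_lgt_genes": int((catalog["accession"] == acc).sum()),
            "pct_expressed": 100.0 * sub_det["expressed"].mean() if len(sub_det) else np.nan,
            "n_classifiable": int(len(sub_fate)),
            "pct_degenerating_pre_reclass": (
                100.0 * (sub_pre["fate"] == "degenerating").mean() if len(sub_pre) else np.nan
            ),
            "pct_degenerating": (
                100.0 * (sub_fate["fate"] == "degenerating").mean() if len(sub_fate) else np.nan
            ),
        }
        if len(categories):
            sub_cat = categories[categories["accession"] == acc]
            for cat in ("no_difference", "higher", "intermediate", "recipient_like", "donor_like"):
                row[f"n_{cat}"] = int((sub_cat["category"] == cat).sum())
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    # --- write the report bundle ------------------------------------------
    results = {
        "detection": detection,
        "fates": fates,
        "categories": categories,
        "enrichment": enrichment,
        "divergence_records": divergence_records,
        "divergence_contrast": divergence_contrast,
        "truncation_calls": trunc_calls,
        "models": models,
        "methylation_summaries": meth_summaries,
        "methylation_models": meth_models,
        "dnds": dnds,
        "dnds_contrast": dnds_contrast,
        "age_report": age_report,
        "age_bins": age_bins,
        "summary": summary,
        "log": log_lines,
    }
    _write_outputs(results, out_dir)
    return results


def _enrichment_or_flag(categories: pd.DataFrame) -> dict:
    from .expression import test_category_enrichment

    try:
        return test_category_enrichment(categories)
    except ValidationError as exc:
        return {"flags": [str(exc)]}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_row"):
        return _jsonable(obj.to_row())
    return obj


def _write_outputs(results: dict, out_dir: Path) -> None:
    def _tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out_dir / name, sep="\t", index=False)

    _tsv(results["detection"], "detection.tsv")
    _tsv(results["fates"], "fates.tsv")
    if len(results["categories"]):
        _tsv(results["categories"], "categories.tsv")
    _tsv(results["divergence_records"], "divergence.tsv")
    _tsv(results["truncation_calls"], "truncation_calls.tsv")
    _tsv(results["methylation_summaries"], "methylation_summaries.tsv")
    if len(results["dnds"]):
        _tsv(results["dnds"], "dnds.tsv")
    _tsv(results["age_bins"], "age_bins.tsv")
    _tsv(results["summary"], "summary.tsv")

    model_rows = [m.to_row() for m in results["models"].values()]
    model_rows += [m.to_row() for m in results["methylation_models"].values()]
    if model_rows:
        _tsv(pd.DataFrame(model_rows), "models.tsv")

    stats_json = {
        "enrichment": results["enrichment"],
        "divergence_contrast": results["divergence_contrast"],
        "dnds_contrast": results["dnds_contrast"],
        "age_report": results["age_report"],
    }
    (out_dir / "statistics.json").write_text(
        json.dumps(_jsonable(stats_json), indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
    (out_dir / "run_log.txt").write_text("\n".join(results["log"]) + "\n")
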