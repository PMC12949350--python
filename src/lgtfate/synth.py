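"""Seeded generator of a synthetic LGT pangenome cohort with planted truth.

The generator emulates the statistical structure of a pangenome expression /
methylation study of laterally acquired genes: a handful of recipient
accessions, each carrying LGT genes alongside their vertically inherited
homologs, a donor species providing the donor-ortholog expression reference,
gene trees in which recent paralogs form recipient-only clades, coding
sequences with planted truncations, per-cytosine bisulfite coverage with an
elevated gene-body methylation probability on transferred genes, and transfer
ages.  Every planted effect is recorded in ground-truth tables so downstream
decision procedures can be validated end to end.

Expression model: per-family baseline log2 mean ~ Normal(mu, sigma), shared
tissue offsets, additive replicate noise on the log2 scale, TPM = 2^x - 1
truncated at zero.  Degenerating LGT genes sit ``degeneration_log2fc`` log2
units below the nearer of their two comparators (hence below both); stable
genes follow one of five planted expression modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog_io import (
    GeneRegions,
    RegionSet,
    ValidationError,
    write_catalog,
    write_cytosine_report,
    write_fasta,
    write_regions_gff3,
)

__all__ = [
    "STABLE_MODES",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "write_fixture_bundle",
    "read_fixture_bundle",
    "simulate_difference_table",
    "simulate_type_table",
    "simulate_interaction_table",
    "simulate_truncation_table",
    "simulate_methylation_table",
    "simulate_age_records",
]

STABLE_MODES = ("donor_like", "recipient_like", "higher", "intermediate", "no_difference")
STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"


def _default_mode_probs() -> dict[str, float]:
    return {
        "donor_like": 0.35,
        "recipient_like": 0.10,
        "higher": 0.05,
        "intermediate": 0.05,
        "no_difference": 0.45,
    }


@dataclass
class SimulationConfig:
    """Cohort structure and planted effect sizes.

    Defaults mirror the study conditions the generator emulates: five
    accessions with up to three replicates from four tissues, roughly
    two-thirds of transfers degenerating, truncation probabilities of 0.33
    (LGT) vs 0.16 (vertical), a +0.027 gene-body methylated-site delta on
    transferred genes, and transfer ages spread over 0-8 Ma.
    """

    seed: int = 0
    n_accessions: int = 5
    n_lgt_genes_per_accession: int = 40
    tissues: tuple[str, ...] = ("leaf_base", "leaf_tip", "sheath", "root")
    n_replicates: int = 3
    frac_degenerating: float = 0.65
    degeneration_log2fc: float = 2.0
    stable_mode_probs: dict[str, float] = field(default_factory=_default_mode_probs)
    # SD of the planted donor-vertical mean log2-expression difference
    divergence_sd_stable: float = 2.0
    divergence_sd_degenerating: float = 1.0
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    accession_sd: float = 0.3
    tissue_sd: float = 1.0
    replicate_noise_sd: float = 0.5
    paralog_prob: float = 0.25
    p_trunc_lgt: float = 0.33
    p_trunc_vertical: float = 0.16
    meth_baseline: float = 0.10
    meth_lgt_delta: float = 0.027
    meth_degenerating_delta: float = 0.03
    meth_sites_per_region: int = 40
    coverage_range: tuple[int, int] = (5, 60)
    n_codons: int = 200
    subst_rate: float = 0.05
    age_range_ma: tuple[float, float] = (0.0, 8.0)
    age_expression_slope: float = 0.0

    def validate(self) -> None:
        for name in (
            "frac_degenerating",
            "paralog_prob",
            "p_trunc_lgt",
            "p_trunc_vertical",
            "meth_baseline",
            "meth_lgt_delta",
            "meth_degenerating_delta",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if set(self.stable_mode_probs) != set(STABLE_MODES):
            raise ValidationError(
                f"stable_mode_probs must have keys {STABLE_MODES}"
            )
        total = sum(self.stable_mode_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"stable_mode_probs must sum to 1, got {total}")
        if any(v < 0 for v in self.stable_mode_probs.values()):
            raise ValidationError("stable_mode_probs must be non-negative")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2 (paired tests need pairs)")
        if self.n_accessions < 1:
            raise ValidationError("n_accessions must be >= 1")
        if self.n_lgt_genes_per_accession < 1:
            raise ValidationError("n_lgt_genes_per_accession must be >= 1")
        lo, hi = self.coverage_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"coverage_range invalid: {self.coverage_range}")
        if lo > 50 or hi < 10:
            raise ValidationError(
                "coverage_range must overlap the 10-50 read-depth filter window"
            )
        if self.n_codons < 10:
            raise ValidationError("n_codons must be >= 10")
        if not 0 <= self.age_range_ma[0] < self.age_range_ma[1]:
            raise ValidationError(f"age_range_ma invalid: {self.age_range_ma}")
        for name in (
            "degeneration_log2fc",
            "divergence_sd_stable",
            "divergence_sd_degenerating",
            "baseline_log2_sd",
            "accession_sd",
            "tissue_sd",
            "replicate_noise_sd",
            "subst_rate",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class SyntheticCohort:
    """In-memory bundle of all generated artifacts plus ground truth."""

    config: SimulationConfig
    expression: pd.DataFrame  # gene_id, sample_id, tpm
    samples: pd.DataFrame  # sample_id, species_role, accession, tissue, replicate
    catalog: pd.DataFrame  # lgt_id, accession, vertical_ids, donor_ids, family_id
    gene_trees: dict[str, str]  # family_id -> newick
    cds: dict[str, str]  # gene_id -> sequence
    regions: RegionSet
    cytosines: pd.DataFrame  # chrom, pos, count_methylated, count_unmethylated
    ages: pd.DataFrame  # lgt_id, accession, family_id, age_ma
    truth: pd.DataFrame  # per LGT gene planted labels
    truncation_truth: pd.DataFrame  # per recipient CDS copy
    taxon_map: dict[str, str]  # gene_id/leaf -> taxon
    taxon_roles: dict[str, str]  # taxon -> recipient|donor|reference|outgroup
    recipient_taxa: set[str]


# ---------------------------------------------------------------------------
# coding sequences
# ---------------------------------------------------------------------------

def _random_sense_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            return codon


def _make_ancestor(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(_random_sense_codon(rng) for _ in range(n_codons - 2))
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + body + stop


def _mutate(seq: str, rng: np.random.Generator, expected_subs: float) -> str:
    """Poisson number of interior point substitutions avoiding in-frame stops
    (start and terminal stop codons are left intact)."""
    n_codons = len(seq) // 3
    n_sub = int(rng.poisson(expected_subs))
    chars = list(seq)
    for _ in range(n_sub):
        for _attempt in range(100):
            codon_idx = int(rng.integers(1, n_codons - 1))
            pos = int(rng.integers(3))
            i = codon_idx * 3 + pos
            old = chars[i]
            new = BASES[int(rng.integers(4))]
            if new == old:
                continue
            candidate = chars[codon_idx * 3 : codon_idx * 3 + 3]
            candidate[pos] = new
            if "".join(candidate) in STOP_CODONS:
                continue
            chars[i] = new
            break
    return "".join(chars)


def _apply_truncation(seq: str, rng: np.random.Generator) -> tuple[str, str]:
    """Plant one truncation mechanism, chosen uniformly."""
    mechanism = ("short_length", "no_start", "no_stop")[int(rng.integers(3))]
    if mechanism == "short_length":
        keep = int(len(seq) // 3 * 0.6) * 3  # 60% of codons, < the 70% rule
        return seq[:keep], mechanism
    if mechanism == "no_start":
        return "CTG" + seq[3:], mechanism
    return seq[:-3] + "TGG", mechanism


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    accessions = [f"ACC{i + 1}" for i in range(cfg.n_accessions)]
    families = [f"fam{i:03d}" for i in range(cfg.n_lgt_genes_per_accession)]
    tissues = list(cfg.tissues)

    # --- sample sheet -----------------------------------------------------
    sample_rows = []
    for acc in accessions:
        for tissue in tissues:
            for rep in range(1, cfg.n_replicates + 1):
                sample_rows.append((f"{acc}_{tissue}_r{rep}", "recipient", acc, tissue, rep))
    for tissue in tissues:
        for rep in range(1, cfg.n_replicates + 1):
            sample_rows.append((f"DONOR_{tissue}_r{rep}", "donor", "DONOR", tissue, rep))
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "species_role", "accession", "tissue", "replicate"],
    )

    # --- family-level planted parameters ----------------------------------
    mode_names = list(STABLE_MODES)
    mode_probs = np.array([cfg.stable_mode_probs[m] for m in mode_names])
    family_params: dict[str, dict] = {}
    for fam in families:
        mu_v = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd)
        degenerating = rng.random() < cfg.frac_degenerating
        if degenerating:
            mode = "degenerating"
            sd = cfg.divergence_sd_degenerating
        else:
            mode = mode_names[int(rng.choice(len(mode_names), p=mode_probs))]
            sd = cfg.divergence_sd_stable
        delta = 0.0 if mode == "no_difference" else float(rng.normal(0.0, sd))
        mu_d = mu_v + delta
        tissue_offsets = {t: float(rng.normal(0.0, cfg.tissue_sd)) for t in tissues}
        age = float(rng.uniform(*cfg.age_range_ma))
        family_params[fam] = {
            "mu_v": mu_v,
            "mu_d": mu_d,
            "mode": mode,
            "degenerating": degenerating,
            "tissue_offsets": tissue_offsets,
            "age": age,
        }

    # --- expression -------------------------------------------------------
    recipient_samples = {
        acc: samples[samples["accession"] == acc] for acc in accessions
    }
    donor_samples = samples[samples["species_role"] == "donor"]

    expr_rows: list[tuple[str, str, float]] = []

    def _emit(gene_ids_weights, mean, sample_frame, offsets):
        """Simulate the paralog-group total and split it across copies."""
        tvec = np.array([offsets[t] for t in sample_frame["tissue"]])
        x = mean + tvec + rng.normal(0.0, cfg.replicate_noise_sd, size=len(sample_frame))
        total = np.maximum(np.exp2(x) - 1.0, 0.0)
        for gid, w in gene_ids_weights:
            for sid, tpm in zip(sample_frame["sample_id"], total * w):
                expr_rows.append((gid, sid, float(tpm)))

    def _copies(base_id: str) -> list[tuple[str, float]]:
        if rng.random() < cfg.paralog_prob:
            w1 = float(rng.uniform(0.6, 0.9))
            return [(base_id, w1), (f"{base_id}_p2", 1.0 - w1)]
        return [(base_id, 1.0)]

    gene_meta: dict[str, dict] = {}  # per recipient family x accession
    for fam in families:
        fp = family_params[fam]
        _emit([(f"DON_{fam}", 1.0)], fp["mu_d"], donor_samples, fp["tissue_offsets"])
        for acc in accessions:
            mu_va = fp["mu_v"] + rng.normal(0.0, cfg.accession_sd)
            mode = fp["mode"]
            if mode == "degenerating":
                mu_l = min(mu_va, fp["mu_d"]) - cfg.degeneration_log2fc
            elif mode == "donor_like":
                mu_l = fp["mu_d"]
            elif mode == "recipient_like":
                mu_l = mu_va
            elif mode == "higher":
                mu_l = max(mu_va, fp["mu_d"]) + 2.0
            elif mode == "intermediate":
                mu_l = 0.5 * (mu_va + fp["mu_d"])
            else:  # no_difference
                mu_l = mu_va
            mu_l += cfg.age_expression_slope * fp["age"]
            lgt_copies = _copies(f"{acc}_L_{fam}")
            vert_copies = _copies(f"{acc}_V_{fam}")
            frame = recipient_samples[acc]
            _emit(lgt_copies, mu_l, frame, fp["tissue_offsets"])
            _emit(vert_copies, mu_va, frame, fp["tissue_offsets"])
            gene_meta[f"{acc}:{fam}"] = {
                "mu_va": mu_va,
                "mu_l": mu_l,
                "lgt_copies": [g for g, _ in lgt_copies],
                "vert_copies": [g for g, _ in vert_copies],
            }

    expression = pd.DataFrame(expr_rows, columns=["gene_id", "sample_id", "tpm"])

    # --- catalog, trees, taxon map ----------------------------------------
    catalog_rows = []
    gene_trees: dict[str, str] = {}
    taxon_map: dict[str, str] = {}
    for fam in families:
        lgt_subs, vert_subs = [], []
        for acc in accessions:
            meta = gene_meta[f"{acc}:{fam}"]
            for gid in meta["lgt_copies"] + meta["vert_copies"]:
                taxon_map[gid] = acc
            lgt_subs.append(
                "(" + ",".join(meta["lgt_copies"]) + ")"
                if len(meta["lgt_copies"]) > 1
                else meta["lgt_copies"][0]
            )
            vert_subs.append(
                "(" + ",".join(meta["vert_copies"]) + ")"
                if len(meta["vert_copies"]) > 1
                else meta["vert_copies"][0]
            )
            catalog_rows.append(
                (f"{acc}_L_{fam}", acc, [f"{acc}_V_{fam}"], [f"DON_{fam}"], fam)
            )
        taxon_map[f"DON_{fam}"] = "DONOR"
        taxon_map[f"OUT_{fam}"] = "OUTGROUP"
        refs = [f"REF{k}_{fam}" for k in range(1, 6)]
        for k, ref in enumerate(refs, 1):
            taxon_map[ref] = f"REFSP{k}"
        lgt_clade = "(" + ",".join(lgt_subs) + ")" if len(lgt_subs) > 1 else lgt_subs[0]
        vert_clade = "(" + ",".join(vert_subs) + ")" if len(vert_subs) > 1 else vert_subs[0]
        ref_clade = f"({refs[0]},({refs[1]},({refs[2]},({refs[3]},{refs[4]}))))"
        gene_trees[fam] = (
            f"(({lgt_clade},DON_{fam}),({vert_clade},OUT_{fam}),{ref_clade});"
        )
    catalog = pd.DataFrame(
        catalog_rows,
        columns=["lgt_id", "accession", "vertical_ids", "donor_ids", "family_id"],
    )

    # --- coding sequences with planted truncations -------------------------
    cds: dict[str, str] = {}
    trunc_rows = []
    for fam in families:
        anc = _make_ancestor(rng, cfg.n_codons)
        exp_subs = cfg.subst_rate * cfg.n_codons
        for k in range(1, 6):
            cds[f"REF{k}_{fam}"] = _mutate(anc, rng, 2.0 * exp_subs)
        donor_seq = _mutate(anc, rng, exp_subs)
        cds[f"DON_{fam}"] = donor_seq
        vert_base = _mutate(anc, rng, exp_subs)
        for acc in accessions:
            meta = gene_meta[f"{acc}:{fam}"]
            for gid in meta["vert_copies"]:
                seq = _mutate(vert_base, rng, 0.5 * exp_subs)
                truncated = rng.random() < cfg.p_trunc_vertical
                reason = ""
                if truncated:
                    seq, reason = _apply_truncation(seq, rng)
                cds[gid] = seq
                trunc_rows.append((gid, "vertical", acc, fam, truncated, reason))
            for gid in meta["lgt_copies"]:
                seq = _mutate(donor_seq, rng, 0.5 * exp_subs)
                truncated = rng.random() < cfg.p_trunc_lgt
                reason = ""
                if truncated:
                    seq, reason = _apply_truncation(seq, rng)
                cds[gid] = seq
                trunc_rows.append((gid, "lgt", acc, fam, truncated, reason))
    truncation_truth = pd.DataFrame(
        trunc_rows,
        columns=["gene_id", "gene_type", "accession", "family_id", "truncated", "reason"],
    )

    # --- gene models and per-cytosine methylation --------------------------
    regions = RegionSet()
    cyt_rows: list[tuple[str, int, int, int]] = []
    cov_lo, cov_hi = cfg.coverage_range
    gene_len = cfg.n_codons * 3 * 2  # CDS split over two exons plus intron
    spacing = gene_len + 3000
    meth_truth: dict[str, float] = {}
    for acc in accessions:
        chrom = f"{acc}_c1"
        cursor = 2000
        for fam in families:
            fp = family_params[fam]
            for gene_type in ("lgt", "vertical"):
                gid = f"{acc}_L_{fam}" if gene_type == "lgt" else f"{acc}_V_{fam}"
                strand = "+" if (len(regions) % 2 == 0) else "-"
                start, end = cursor, cursor + gene_len
                half = cfg.n_codons * 3 // 2
                exons = [(start, start + half), (end - half, end)]
                regions.add(
                    GeneRegions(
                        gene_id=gid, chrom=chrom, strand=strand,
                        start=start, end=end, exons=exons,
                    )
                )
                delta = 0.0
                if gene_type == "lgt":
                    delta = cfg.meth_lgt_delta
                    if fp["mode"] == "degenerating":
                        delta += cfg.meth_degenerating_delta
                meth_truth[gid] = delta
                body_p = cfg.meth_baseline + delta
                for (lo, hi), p_site in (
                    ((start, end), body_p),
                    ((max(0, start - 1000), start), cfg.meth_baseline),
                    ((end, end + 1000), cfg.meth_baseline),
                ):
                    span = hi - lo
                    n_sites = min(cfg.meth_sites_per_region, span)
                    positions = np.sort(
                        rng.choice(span, size=n_sites, replace=False)
                    ) + lo
                    status = rng.random(n_sites) < p_site
                    cov = rng.integers(cov_lo, cov_hi + 1, size=n_sites)
                    p_read = np.where(status, 0.9, 0.05)
                    m = rng.binomial(cov, p_read)
                    for pos, c, mm in zip(positions, cov, m):
                        cyt_rows.append((chrom, int(pos) + 1, int(mm), int(c - mm)))
                cursor += spacing
    cytosines = pd.DataFrame(
        cyt_rows, columns=["chrom", "pos", "count_methylated", "count_unmethylated"]
    )

    # --- ages and truth ----------------------------------------------------
    age_rows, truth_rows = [], []
    for fam in families:
        fp = family_params[fam]
        for acc in accessions:
            meta = gene_meta[f"{acc}:{fam}"]
            lgt_id = f"{acc}_L_{fam}"
            age_rows.append((lgt_id, acc, fam, fp["age"]))
            copies = meta["lgt_copies"]
            copy_status = truncation_truth.set_index("gene_id").loc[copies, "truncated"]
            truth_rows.append(
                (
                    lgt_id,
                    acc,
                    fam,
                    "degenerating" if fp["degenerating"] else "putatively_stable",
                    fp["mode"],
                    fp["age"],
                    bool(np.all(copy_status)),
                    len(copies),
                    meth_truth[lgt_id],
                )
            )
    ages = pd.DataFrame(age_rows, columns=["lgt_id", "accession", "family_id", "age_ma"])
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "lgt_id", "accession", "family_id", "fate", "mode", "age_ma",
            "all_copies_truncated", "n_paralogs", "meth_body_delta",
        ],
    )

    taxon_roles = {acc: "recipient" for acc in accessions}
    taxon_roles["DONOR"] = "donor"
    taxon_roles["OUTGROUP"] = "outgroup"
    for k in range(1, 6):
        taxon_roles[f"REFSP{k}"] = "reference"

    return SyntheticCohort(
        config=cfg,
        expression=expression,
        samples=samples,
        catalog=catalog,
        gene_trees=gene_trees,
        cds=cds,
        regions=regions,
        cytosines=cytosines,
        ages=ages,
        truth=truth,
        truncation_truth=truncation_truth,
        taxon_map=taxon_map,
        taxon_roles=taxon_roles,
        recipient_taxa=set(accessions),
    )


# ---------------------------------------------------------------------------
# fixture bundle round trip
# ---------------------------------------------------------------------------

def write_fixture_bundle(cohort: SyntheticCohort, directory: str | Path) -> pd.DataFrame:
    """Write every cohort artifact as plain text; returns the manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(d / "expression.tsv", sep="\t", index=False)
    cohort.samples.to_csv(d / "samples.tsv", sep="\t", index=False)
    write_catalog(cohort.catalog, d / "catalog.tsv")
    with open(d / "trees.nwk", "w") as fh:
        for fam in sorted(cohort.gene_trees):
            fh.write(f"{fam}\t{cohort.gene_trees[fam]}\n")
    write_fasta(cohort.cds, d / "cds.fasta")
    write_regions_gff3(cohort.regions, d / "regions.gff3")
    write_cytosine_report(cohort.cytosines, d / "cytosines.tsv")
    cohort.ages.to_csv(d / "ages.tsv", sep="\t", index=False)
    cohort.truth.to_csv(d / "truth.tsv", sep="\t", index=False)
    cohort.truncation_truth.to_csv(d / "truncation_truth.tsv", sep="\t", index=False)
    taxa = pd.DataFrame(
        sorted(cohort.taxon_map.items()), columns=["leaf_id", "taxon"]
    )
    taxa["role"] = taxa["taxon"].map(cohort.taxon_roles)
    taxa.to_csv(d / "taxa.tsv", sep="\t", index=False)

    counts = {
        "expression.tsv": len(cohort.expression),
        "samples.tsv": len(cohort.samples),
        "catalog.tsv": len(cohort.catalog),
        "trees.nwk": len(cohort.gene_trees),
        "cds.fasta": len(cohort.cds),
        "regions.gff3": len(cohort.regions),
        "cytosines.tsv": len(cohort.cytosines),
        "ages.tsv": len(cohort.ages),
        "truth.tsv": len(cohort.truth),
        "truncation_truth.tsv": len(cohort.truncation_truth),
        "taxa.tsv": len(taxa),
    }
    manifest = pd.DataFrame(sorted(counts.items()), columns=["file", "n_records"])
    manifest.to_csv(d / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_fixture_bundle(directory: str | Path) -> dict:
    """Load a written bundle back into the pipeline's in-memory containers."""
    from . import catalog_io

    d = Path(directory)
    expression, samples = catalog_io.read_expression_table(
        d / "expression.tsv", d / "samples.tsv"
    )
    taxa = pd.read_csv(
        d / "taxa.tsv", sep="\t", dtype={"leaf_id": str, "taxon": str, "role": str}
    )
    taxon_roles = dict(
        taxa.drop_duplicates("taxon")[["taxon", "role"]].itertuples(index=False)
    )
    bundle = {
        "expression": expression,
        "samples": samples,
        "catalog": catalog_io.read_catalog(d / "catalog.tsv"),
        "gene_trees": catalog_io.read_gene_trees(d / "trees.nwk"),
        "cds": catalog_io.read_fasta(d / "cds.fasta"),
        "regions": catalog_io.read_regions(d / "regions.gff3"),
        "cytosines": catalog_io.read_cytosine_report(d / "cytosines.tsv"),
        "ages": pd.read_csv(d / "ages.tsv", sep="\t"),
        "taxon_map": dict(zip(taxa["leaf_id"], taxa["taxon"])),
        "taxon_roles": taxon_roles,
        "recipient_taxa": {t for t, r in taxon_roles.items() if r == "recipient"},
    }
    truth_path = d / "truth.tsv"
    if truth_path.exists():
        bundle["truth"] = pd.read_csv(truth_path, sep="\t")
    trunc_path = d / "truncation_truth.tsv"
    if trunc_path.exists():
        bundle["truncation_truth"] = pd.read_csv(
            trunc_path, sep="\t", keep_default_na=False
        )
    return bundle


# ---------------------------------------------------------------------------
# lightweight planted datasets for individual model contracts
# ---------------------------------------------------------------------------

def simulate_difference_table(
    seed: int,
    n_families: int = 50,
    n_accessions: int = 3,
    n_samples: int = 6,
    mean: float = -1.5,
    family_sd: float = 0.3,
    accession_sd: float = 0.2,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Long table of per-sample log-expression differences with random
    family and accession-within-family effects around a planted mean."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_families):
        fam_eff = rng.normal(0.0, family_sd)
        for a in range(n_accessions):
            acc_eff = rng.normal(0.0, accession_sd)
            diffs = mean + fam_eff + acc_eff + rng.normal(0.0, noise_sd, n_samples)
            rows += [
                (f"fam{f:03d}", f"ACC{a + 1}", float(x)) for x in diffs
            ]
    return pd.DataFrame(rows, columns=["family", "accession", "log_difference"])


def simulate_type_table(
    seed: int,
    n_genes: int = 100,
    n_samples: int = 6,
    effect: float = -1.0,
    family_sd: float = 1.0,
    noise_sd: float = 0.5,
    n_accessions: int = 3,
) -> pd.DataFrame:
    """Long log-expression table with a planted fixed effect of gene type."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        base = 4.0 + rng.normal(0.0, family_sd)
        acc = f"ACC{g % n_accessions + 1}"
        for gene_type, shift in (("lgt", effect), ("donor", 0.0)):
            vals = base + shift + rng.normal(0.0, noise_sd, n_samples)
            rows += [
                (f"fam{g:03d}", acc, gene_type, float(v)) for v in vals
            ]
    return pd.DataFrame(rows, columns=["family", "accession", "gene_type", "log_expression"])


def simulate_interaction_table(
    seed: int,
    n_genes: int = 100,
    n_samples: int = 6,
    divergence_stable: float = 2.0,
    divergence_degenerating: float = 0.0,
    frac_degenerating: float = 0.5,
    family_sd: float = 1.0,
    noise_sd: float = 0.5,
    n_accessions: int = 3,
) -> pd.DataFrame:
    """Vertical/donor log-expression with a status-dependent divergence:
    the planted vertical-minus-donor gap differs between fate classes."""
    rng = np.random.default_rng(seed)
    rows = []
    n_degen = int(round(frac_degenerating * n_genes))
    for g in range(n_genes):
        status = "degenerating" if g < n_degen else "putatively_stable"
        gap = divergence_degenerating if status == "degenerating" else divergence_stable
        base = 4.0 + rng.normal(0.0, family_sd)
        acc = f"ACC{g % n_accessions + 1}"
        for gene_type, shift in (("vertical", gap), ("donor", 0.0)):
            vals = base + shift + rng.normal(0.0, noise_sd, n_samples)
            rows += [
                (f"fam{g:03d}", acc, status, gene_type, float(v)) for v in vals
            ]
    return pd.DataFrame(
        rows, columns=["family", "accession", "status", "gene_type", "log_expression"]
    )


def simulate_truncation_table(
    seed: int,
    n_per_type: int = 300,
    p_lgt: float = 0.33,
    p_vertical: float = 0.16,
) -> pd.DataFrame:
    """Binary truncation calls for paired LGT / vertical gene families."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_per_type):
        rows.append((f"fam{f:03d}", "lgt", bool(rng.random() < p_lgt)))
        rows.append((f"fam{f:03d}", "vertical", bool(rng.random() < p_vertical)))
    return pd.DataFrame(rows, columns=["family", "gene_type", "truncated"])


def simulate_methylation_table(
    seed: int,
    n_genes: int = 200,
    n_accessions: int = 4,
    delta: float = 0.027,
    baseline: float = 0.10,
    n_sites: int = 50,
    family_sd: float = 0.03,
    accession_sd: float = 0.01,
) -> pd.DataFrame:
    """Per-gene region methylation proportions for LGT vs vertical copies,
    binomial site counts around family/accession-shifted probabilities."""
    rng = np.random.default_rng(seed)
    acc_eff = rng.normal(0.0, accession_sd, n_accessions)
    rows = []
    for f in range(n_genes):
        fam_eff = rng.normal(0.0, family_sd)
        a = f % n_accessions
        for gene_type, shift in (("lgt", delta), ("vertical", 0.0)):
            p = np.clip(baseline + shift + fam_eff + acc_eff[a], 0.001, 0.999)
            k = rng.binomial(n_sites, p)
            rows.append(
                (f"fam{f:03d}", f"ACC{a + 1}", gene_type, n_sites, int(k), k / n_sites)
            )
    return pd.DataFrame(
        rows,
        columns=["family", "accession", "group", "n_covered", "n_methylated", "proportion"],
    )


def simulate_age_records(
    seed: int,
    n_families: int = 40,
    n_accessions: int = 5,
    slope: float = 0.0,
    family_sd: float = 1.5,
    noise_sd: float = 0.3,
    age_range_ma: tuple[float, float] = (0.0, 8.0),
) -> pd.DataFrame:
    """Per-gene mean log-expression vs transfer age, with ages shared within
    a family and family-correlated expression (the nonindependence the mixed
    model is meant to absorb)."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_families):
        age = float(rng.uniform(*age_range_ma))
        fam_eff = rng.normal(0.0, family_sd)
        for a in range(n_accessions):
            expr = 4.0 + fam_eff + slope * age + rng.normal(0.0, noise_sd)
            fate = "degenerating" if f % 2 == 0 else "putatively_stable"
            rows.append((f"ACC{a + 1}_L_fam{f:03d}", f"ACC{a + 1}", f"fam{f:03d}", age, float(expr), fate))
    return pd.DataFrame(
        rows, columns=["lgt_id", "accession", "family_id", "age_ma", "mean_log_expression", "fate"]
    )
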