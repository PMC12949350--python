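"""Readers/writers for pipeline inputs, gene-tree paralog grouping, and
paralog-aware TPM aggregation.

Tables are held as pandas DataFrames with fixed column sets; coordinates are
0-based half-open internally and converted at the GFF3 boundary (1-based
inclusive).  Bismark coverage positions are 1-based with start == end per
cytosine.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SAMPLE_COLUMNS",
    "read_sample_sheet",
    "read_expression_table",
    "read_catalog",
    "write_catalog",
    "read_gene_trees",
    "identify_recent_paralogs",
    "aggregate_paralog_tpm",
    "GeneRegions",
    "RegionSet",
    "read_regions",
    "write_regions_gff3",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_fasta",
    "write_fasta",
]


class ValidationError(ValueError):
    """Input failed a referential-integrity or domain check."""


SAMPLE_COLUMNS = ["sample_id", "species_role", "accession", "tissue", "replicate"]
EXPRESSION_COLUMNS = ["gene_id", "sample_id", "tpm"]
CATALOG_COLUMNS = ["lgt_id", "accession", "vertical_ids", "donor_ids", "family_id"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": int})
    missing = set(SAMPLE_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dupes}")
    bad_role = set(sheet["species_role"]) - {"recipient", "donor"}
    if bad_role:
        raise ValidationError(f"unknown species_role values: {sorted(bad_role)}")
    if (sheet["replicate"] < 1).any():
        raise ValidationError("replicate numbers must be >= 1")
    return sheet[SAMPLE_COLUMNS]


def read_expression_table(
    path: str | Path, sample_sheet_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format TPM table plus sample metadata, cross-validated.

    Every expression record's sample_id must resolve to the sheet; TPM must
    be finite and non-negative; (gene_id, sample_id) must be unique.
    """
    samples = read_sample_sheet(sample_sheet_path)
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    missing = set(EXPRESSION_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"expression table missing columns: {sorted(missing)}")
    table = table[EXPRESSION_COLUMNS]
    unknown = sorted(set(table["sample_id"]) - set(samples["sample_id"]))
    if unknown:
        raise ValidationError(f"expression records reference unknown samples: {unknown}")
    tpm = table["tpm"].to_numpy()
    if not np.all(np.isfinite(tpm)) or (tpm < 0).any():
        raise ValidationError("tpm values must be finite and >= 0")
    if table.duplicated(["gene_id", "sample_id"]).any():
        raise ValidationError("duplicate (gene_id, sample_id) records")
    return table, samples


def _split_ids(cell) -> list[str]:
    if isinstance(cell, float) and np.isnan(cell):
        return []
    cell = str(cell).strip()
    return [t for t in cell.split(";") if t] if cell else []


def read_catalog(path: str | Path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CATALOG_COLUMNS) - set(cat.columns)
    if missing:
        raise ValidationError(f"catalog missing columns: {sorted(missing)}")
    cat = cat[CATALOG_COLUMNS].copy()
    cat["vertical_ids"] = cat["vertical_ids"].map(_split_ids)
    cat["donor_ids"] = cat["donor_ids"].map(_split_ids)
    if cat.duplicated(["lgt_id", "accession"]).any():
        raise ValidationError("lgt_id must be unique per accession")
    return cat


def write_catalog(cat: pd.DataFrame, path: str | Path) -> None:
    out = cat.copy()
    out["vertical_ids"] = out["vertical_ids"].map(";".join)
    out["donor_ids"] = out["donor_ids"].map(";".join)
    out[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene trees and paralog grouping
# ---------------------------------------------------------------------------

def read_gene_trees(path: str | Path) -> dict[str, str]:
    """One newick per line, prefixed 'family_id<TAB>newick'."""
    trees: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        family_id, newick = line.split("\t", 1)
        trees[family_id] = newick
    return trees


def _parse_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(
        data=tree,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def identify_recent_paralogs(
    tree: str | dendropy.Tree,
    recipient_taxa: set[str],
    taxon_map: dict[str, str],
    assume_rooted: bool = True,
) -> list[frozenset[str]]:
    """Partition recipient leaves into recent-paralog groups.

    A group of size >= 2 is the leaf set of a maximal clade whose members all
    map (via ``taxon_map``: gene id -> taxon) to recipient taxa — the gene
    copies that arose by duplication within the recipient lineage rather than
    by transfer.  Recipient leaves outside any such clade form singletons.
    Unrooted trees are midpoint-rooted first.
    """
    t = _parse_tree(tree)
    leaves = t.leaf_nodes()
    if not leaves:
        raise ValidationError("empty gene tree")
    names = [lf.taxon.label.replace(" ", "_") for lf in leaves]
    if len(set(names)) != len(names):
        raise ValidationError("gene tree leaf labels are not unique")
    unknown = [n for n in names if n not in taxon_map]
    if unknown:
        raise ValidationError(f"leaves missing from taxon map: {sorted(unknown)}")
    if not any(taxon_map[n] in recipient_taxa for n in names):
        raise ValidationError("tree has no recipient leaves")
    if not assume_rooted:
        t.reroot_at_midpoint(update_bipartitions=False)

    def is_recipient(node) -> bool:
        label = node.taxon.label.replace(" ", "_")
        return taxon_map[label] in recipient_taxa

    # postorder: does every leaf under this node belong to a recipient taxon?
    all_recipient: dict[int, bool] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            all_recipient[id(node)] = is_recipient(node)
        else:
            all_recipient[id(node)] = all(
                all_recipient[id(c)] for c in node.child_nodes()
            )

    groups: list[frozenset[str]] = []
    for node in t.preorder_node_iter():
        if not all_recipient[id(node)]:
            continue
        parent = node.parent_node
        if parent is not None and all_recipient[id(parent)]:
            continue  # not maximal
        members = frozenset(
            lf.taxon.label.replace(" ", "_") for lf in node.leaf_iter()
        )
        groups.append(members)
    return groups


def aggregate_paralog_tpm(
    table: pd.DataFrame,
    groups: list[frozenset[str]] | list[set[str]],
    mode: str = "sum",
) -> pd.DataFrame:
    """Collapse recent paralogs to one expression record per (group, sample).

    mode='sum' adds TPM across group members per sample (the primary
    analysis); mode='max' keeps, for the whole group, the per-sample values of
    the single member with the highest mean TPM across samples (sensitivity
    analysis; ties broken toward the lexicographically smallest gene id).
    The aggregated record carries the lexicographically smallest member id.
    Genes not covered by any group pass through unchanged.
    """
    if mode not in {"sum", "max"}:
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    grouped_genes = set().union(*groups) if groups else set()
    seen = [g for grp in groups for g in grp]
    if len(seen) != len(grouped_genes):
        raise ValidationError("paralog groups are not disjoint")
    present = set(table["gene_id"])
    missing = sorted(grouped_genes - present)
    if missing:
        raise ValidationError(f"group members absent from expression table: {missing}")

    passthrough = table[~table["gene_id"].isin(grouped_genes)]
    pieces = [passthrough]
    for group in groups:
        members = sorted(group)
        rep = members[0]
        sub = table[table["gene_id"].isin(group)]
        if mode == "sum":
            agg = sub.groupby("sample_id", as_index=False)["tpm"].sum()
        else:
            means = sub.groupby("gene_id")["tpm"].mean()
            best = means.reindex(members).idxmax()  # first max -> smallest id
            agg = sub.loc[sub["gene_id"] == best, ["sample_id", "tpm"]]
        agg = agg.assign(gene_id=rep)[EXPRESSION_COLUMNS]
        pieces.append(agg)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["gene_id", "sample_id"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# gene-model regions
# ---------------------------------------------------------------------------

@dataclass
class GeneRegions:
    """Per-gene genomic intervals, 0-based half-open, strand-aware flanks."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    flank: int = 1000
    clipped: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValidationError(f"{self.gene_id}: invalid gene span")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"{self.gene_id}: exon [{s},{e}) outside gene span"
                )
        if self.strand == "+":
            up = (max(0, self.start - self.flank), self.start)
            down = (self.end, self.end + self.flank)
        else:
            up = (self.end, self.end + self.flank)
            down = (max(0, self.start - self.flank), self.start)
        self.upstream = up
        self.downstream = down
        self.clipped = (up[1] - up[0] < self.flank) or (down[1] - down[0] < self.flank)

    def region_intervals(self, region: str) -> list[tuple[int, int]]:
        if region == "gene_body":
            return [(self.start, self.end)]
        if region == "exons":
            return list(self.exons)
        if region == "upstream_1kb":
            return [self.upstream]
        if region == "downstream_1kb":
            return [self.downstream]
        raise ValueError(f"unknown region: {region!r}")


class RegionSet(dict):
    """Mapping gene_id -> GeneRegions."""

    def add(self, regions: GeneRegions) -> None:
        self[regions.gene_id] = regions


def read_regions(gff_path: str | Path, flank: int = 1000) -> RegionSet:
    """Parse gene + exon features from GFF3 into a RegionSet.

    GFF3 1-based inclusive coordinates become 0-based half-open.  Exons are
    attached to their parent gene via the Parent/ID attributes (transcript
    level features, if present, are traversed transparently).
    """
    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    exon_rows: list[tuple[str, int, int]] = []
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValidationError(f"malformed GFF3 line: {line[:80]}")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields
        attr = dict(
            kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
        )
        if ftype == "gene":
            gid = attr.get("ID")
            if gid is None:
                raise ValidationError("gene feature without ID attribute")
            genes[gid] = {
                "chrom": chrom,
                "strand": strand,
                "start": int(start) - 1,
                "end": int(end),
                "exons": [],
            }
        elif ftype in {"mRNA", "transcript"}:
            parent_of[attr["ID"]] = attr.get("Parent", attr["ID"])
        elif ftype == "exon":
            exon_rows.append((attr.get("Parent", ""), int(start) - 1, int(end)))
    regions = RegionSet()
    for parent, s, e in exon_rows:
        gid = parent_of.get(parent, parent)
        if gid not in genes:
            raise ValidationError(f"exon with unknown parent: {parent}")
        genes[gid]["exons"].append((s, e))
    for gid, rec in genes.items():
        regions.add(
            GeneRegions(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=rec["start"],
                end=rec["end"],
                exons=sorted(rec["exons"]),
                flank=flank,
            )
        )
    return regions


def write_regions_gff3(regions: RegionSet, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write("##gff-version 3\n")
    for gid in sorted(regions):
        r = regions[gid]
        buf.write(
            f"{r.chrom}\tlgtfate\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\tID={gid}\n"
        )
        for k, (s, e) in enumerate(r.exons, 1):
            buf.write(
                f"{r.chrom}\tlgtfate\texon\t{s + 1}\t{e}\t.\t{r.strand}\t.\t"
                f"ID={gid}.exon{k};Parent={gid}\n"
            )
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Bismark-coverage dialect and FASTA
# ---------------------------------------------------------------------------

CYTOSINE_COLUMNS = ["chrom", "pos", "count_methylated", "count_unmethylated"]


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Bismark coverage TSV: chrom, start, end, percent, n_meth, n_unmeth.

    Positions are 1-based with start == end; the percentage column is ignored
    and recomputed downstream from the counts.
    """
    raw = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "percent", "count_methylated", "count_unmethylated"],
        dtype={"chrom": str},
    )
    if (raw["start"] != raw["end"]).any():
        raise ValidationError("cytosine records must have start == end")
    if (raw[["count_methylated", "count_unmethylated"]] < 0).to_numpy().any():
        raise ValidationError("negative read counts")
    out = raw.rename(columns={"start": "pos"})[CYTOSINE_COLUMNS].copy()
    return out


def write_cytosine_report(records: pd.DataFrame, path: str | Path) -> None:
    cov = records["count_methylated"] + records["count_unmethylated"]
    pct = np.where(cov > 0, 100.0 * records["count_methylated"] / cov.replace(0, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["pos"],
            "end": records["pos"],
            "percent": np.round(pct, 6),
            "count_methylated": records["count_methylated"],
            "count_unmethylated": records["count_unmethylated"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
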