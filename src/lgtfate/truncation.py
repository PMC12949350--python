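"""Structural truncation calls on coding sequences and the fate
reclassification they trigger.

A recipient CDS is compared against reference orthologs from model grass
genomes and called truncated when any of three rules fires: (i) its ungapped
length is below 70% of every reference's length; (ii) it does not begin with
ATG while every reference does; (iii) it does not end in a stop codon while
every reference does.  A putatively stable gene whose paralog copies are all
truncated is reclassified as degenerating — structural decay implies
functional loss even when expression persists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog_io import ValidationError
from .lmm import ModelReport, fit_binary_glmm

__all__ = [
    "STOP_CODONS",
    "OrthologAlignment",
    "TruncationCall",
    "classify_truncation",
    "reclassify_by_truncation",
    "compare_truncation_rates",
    "test_truncation_vs_category",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


def _ungap(seq: str) -> str:
    return seq.replace("-", "").upper()


@dataclass
class OrthologAlignment:
    """A focal CDS with >= 1 reference orthologs (gaps stripped)."""

    focal_id: str
    focal_seq: str
    references: list[tuple[str, str]]  # (id, seq)

    def __post_init__(self) -> None:
        self.focal_seq = _ungap(self.focal_seq)
        self.references = [(rid, _ungap(rseq)) for rid, rseq in self.references]
        if not self.references:
            raise ValidationError(f"{self.focal_id}: empty reference list")
        if len(self.focal_seq) == 0 or any(len(s) == 0 for _, s in self.references):
            raise ValidationError(f"{self.focal_id}: zero-length sequence")


@dataclass
class TruncationCall:
    focal_id: str
    truncated: bool
    reasons: frozenset[str]
    length_ratio_min: float
    flags: list[str] = field(default_factory=list)


def _has_start(seq: str) -> bool:
    return seq[:3] == START_CODON


def _has_stop(seq: str) -> bool:
    return seq[-3:] in STOP_CODONS


def classify_truncation(
    aln: OrthologAlignment,
    length_threshold: float = 0.70,
    reference_gate: str = "all",
) -> TruncationCall:
    """Apply the three truncation rules.

    ``reference_gate`` controls how strongly the references must show the
    feature required of the focal gene: 'all' (every reference, the strict
    reading) or 'majority'.  The length rule always requires the focal CDS to
    be shorter than ``length_threshold`` times each reference.
    """
    if reference_gate not in {"all", "majority"}:
        raise ValueError(f"reference_gate must be 'all' or 'majority', got {reference_gate!r}")
    ref_lens = np.array([len(s) for _, s in aln.references], dtype=float)
    focal_len = float(len(aln.focal_seq))

    def _gate(flags: list[bool]) -> bool:
        return all(flags) if reference_gate == "all" else (
            sum(flags) > len(flags) / 2
        )

    reasons = set()
    if focal_len < length_threshold * ref_lens.min():
        reasons.add("short_length")
    if not _has_start(aln.focal_seq) and _gate([_has_start(s) for _, s in aln.references]):
        reasons.add("no_start")
    if not _has_stop(aln.focal_seq) and _gate([_has_stop(s) for _, s in aln.references]):
        reasons.add("no_stop")
    return TruncationCall(
        focal_id=aln.focal_id,
        truncated=bool(reasons),
        reasons=frozenset(reasons),
        length_ratio_min=focal_len / ref_lens.max(),
    )


def reclassify_by_truncation(
    fates: pd.DataFrame,
    calls: dict[str, TruncationCall] | pd.DataFrame,
    paralog_groups: list[frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Flip fully truncated putatively stable genes to degenerating.

    ``calls`` maps gene ids to truncation calls (a DataFrame with gene_id /
    truncated columns is also accepted).  When a gene has recent paralogs
    (located via ``paralog_groups``), *all* copies must be truncated for the
    override to fire.  Genes already degenerating are untouched.
    """
    if isinstance(calls, pd.DataFrame):
        call_map = dict(zip(calls["gene_id"], calls["truncated"].astype(bool)))
    else:
        call_map = {gid: c.truncated for gid, c in calls.items()}
    group_of: dict[str, frozenset[str]] = {}
    for group in paralog_groups or []:
        for gid in group:
            group_of[gid] = group

    out = fates.copy()
    missing: list[str] = []
    overrides = []
    for row in out.itertuples():
        if not row.classifiable or row.fate != "putatively_stable":
            overrides.append(False)
            continue
        copies = sorted(group_of.get(row.lgt_id, frozenset({row.lgt_id})))
        absent = [g for g in copies if g not in call_map]
        if absent:
            missing.extend(absent)
            overrides.append(False)
            continue
        overrides.append(all(call_map[g] for g in copies))
    if missing:
        raise ValidationError(
            f"missing truncation calls for genes: {sorted(set(missing))}"
        )
    overrides = np.array(overrides)
    out.loc[overrides, "fate"] = "degenerating"
    out["truncation_override"] = overrides
    return out


def compare_truncation_rates(calls: pd.DataFrame) -> ModelReport:
    """Mixed logistic regression of truncation on gene type.

    ``calls`` columns: family, gene_type in {lgt, vertical}, truncated.
    Random intercepts for family and for type within family (the latter is
    dropped automatically when unidentifiable).  Reports the vertical-vs-LGT
    log-odds (odds ratio < 1 means vertical copies are truncated less often)
    plus raw per-type proportions.  Zero truncations overall -> skipped with
    a flag; complete separation -> Fisher's exact fallback."""
    required = {"family", "gene_type", "truncated"}
    if not required <= set(calls.columns):
        raise ValidationError(f"calls table needs columns {sorted(required)}")
    if set(calls["gene_type"]) != {"lgt", "vertical"}:
        raise ValidationError("gene_type must contain both 'lgt' and 'vertical'")
    return fit_binary_glmm(
        calls,
        response="truncated",
        fixed_col="gene_type",
        vc_cols=["family", "family:gene_type"],
        reference="lgt",
        model_name="truncation_rate_glmm",
    )


def test_truncation_vs_category(fates_with_calls: pd.DataFrame) -> ModelReport:
    """Mixed logistic regression of fate class on truncation status:
    degenerating ~ truncated + (1 | family).

    ``fates_with_calls`` columns: family, fate, truncated.  A single fate
    class present -> skipped with a flag (via the degenerate-response path).
    """
    data = fates_with_calls.copy()
    data["is_degenerating"] = (data["fate"] == "degenerating").astype(int)
    data["trunc_status"] = np.where(data["truncated"].astype(bool), "truncated", "intact")
    return fit_binary_glmm(
        data,
        response="is_degenerating",
        fixed_col="trunc_status",
        vc_cols=["family"],
        reference="intact",
        model_name="fate_vs_truncation_glmm",
    )

test_truncation_vs_category.__test__ = False  # name is domain API, not a pytest test
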