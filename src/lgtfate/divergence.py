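"""Pairwise coding-sequence divergence by the Nei-Gojobori (1986) counting
method with Jukes-Cantor correction.

For each codon, synonymous site content is the fraction of the three
possible single-nucleotide changes at each position that preserve the amino
acid (changes creating a stop codon count as nonsynonymous, so S + N = 3 x
codons).  Site totals are averaged over the two sequences.  Observed
differences within a codon are resolved over all shortest mutational
pathways with equal weighting; pathways passing through a stop codon are
excluded (if every pathway is blocked, all are used).  The proportions
pS = Sd/S and pN = Nd/N are corrected with d = -(3/4) ln(1 - (4/3) p);
p >= 3/4 is flagged as saturated.  omega = dN/dS, undefined when dS = 0.

The ratio contrast between fate classes asks whether successful transfers
are associated with greater coding divergence between the donor lineage and
the recipient's own homolog.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from Bio.Data.CodonTable import standard_dna_table

from .catalog_io import ValidationError
from .stats import rank_sum_test

__all__ = [
    "PairwiseRates",
    "strip_gap_columns",
    "compute_pairwise_rates",
    "compare_rates_by_fate",
    "pick_representative",
]

_CODON_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
BASES = "ACGT"


@dataclass
class PairwiseRates:
    id_a: str
    id_b: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    dS: float
    dN: float
    omega: float
    flags: list[str] = field(default_factory=list)


def _syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous / nonsynonymous site content of one codon."""
    aa = _CODON_AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and _CODON_AA[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _step_is_synonymous(a: str, b: str) -> bool:
    return _CODON_AA[a] == _CODON_AA[b]


def _codon_pair_differences(a: str, b: str) -> tuple[float, float]:
    """Average synonymous / nonsynonymous difference counts between two
    codons over all unblocked shortest mutational pathways."""
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_positions):
        current = a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                steps.append(None)
                break
            steps.append(_step_is_synonymous(current, nxt))
            current = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:  # all pathways pass through a stop: fall back to all
        usable = []
        for order in permutations(diff_positions):
            current = a
            steps = []
            for pos in order:
                nxt = current[:pos] + b[pos] + current[pos + 1 :]
                if nxt in STOP_CODONS:
                    steps.append(False)  # treat the stop step as nonsynonymous
                else:
                    steps.append(_step_is_synonymous(current, nxt))
                current = nxt
            usable.append(steps)
    sd = float(np.mean([sum(s) for s in usable]))
    nd = float(np.mean([len(s) - sum(s) for s in usable]))
    return sd, nd


def strip_gap_columns(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Remove alignment columns where either sequence has a gap, keeping the
    reading frame by dropping whole codon columns that contain a gap."""
    if len(seq_a) != len(seq_b):
        raise ValidationError("aligned sequences must have equal length")
    a_out, b_out = [], []
    for i in range(0, len(seq_a) - len(seq_a) % 3, 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        a_out.append(ca)
        b_out.append(cb)
    return "".join(a_out), "".join(b_out)


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def compute_pairwise_rates(
    seq_a: str,
    seq_b: str,
    id_a: str = "a",
    id_b: str = "b",
    trim_terminal_stop: bool = True,
) -> PairwiseRates:
    """Nei-Gojobori pairwise dN, dS and omega for one aligned codon pair.

    Sequences must be gap-free (use :func:`strip_gap_columns` first), of
    equal length divisible by 3, and free of internal stop codons.  The
    final codon column is trimmed when either sequence ends in a stop.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValidationError("sequences must have equal length")
    if len(a) % 3 != 0:
        raise ValidationError(f"length not divisible by 3: {len(a)}")
    if "-" in a or "-" in b:
        raise ValidationError("gaps present: strip gap columns first")
    codons_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    if trim_terminal_stop and codons_a and (
        codons_a[-1] in STOP_CODONS or codons_b[-1] in STOP_CODONS
    ):
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]
    for k, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValidationError(f"internal stop codon at codon {k}")
    if not codons_a:
        raise ValidationError("no codons left to compare")

    s_total = n_total = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = _syn_nonsyn_sites(ca)
        sb, nb = _syn_nonsyn_sites(cb)
        s_total += (sa + sb) / 2.0
        n_total += (na + nb) / 2.0
        d_s, d_n = _codon_pair_differences(ca, cb)
        sd += d_s
        nd += d_n

    flags: list[str] = []
    p_s = sd / s_total if s_total > 0 else 0.0
    p_n = nd / n_total if n_total > 0 else 0.0
    ds, sat_s = _jc_correct(p_s)
    dn, sat_n = _jc_correct(p_n)
    if sat_s:
        flags.append("dS_saturated")
    if sat_n:
        flags.append("dN_saturated")
    if not math.isnan(ds) and ds > 0 and not math.isnan(dn):
        omega = dn / ds
    else:
        omega = float("nan")
        if ds == 0:
            flags.append("omega_undefined_dS_zero")
    return PairwiseRates(
        id_a=id_a,
        id_b=id_b,
        n_codons=len(codons_a),
        S=s_total,
        N=n_total,
        Sd=sd,
        Nd=nd,
        dS=ds,
        dN=dn,
        omega=omega,
        flags=flags,
    )


def pick_representative(sequences: dict[str, str]) -> str:
    """Choose the representative gene copy: longest ungapped CDS, ties broken
    toward the lexicographically smallest id."""
    if not sequences:
        raise ValidationError("no sequences to choose from")
    return min(sequences, key=lambda gid: (-len(sequences[gid].replace("-", "")), gid))


def compare_rates_by_fate(rates: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Rank-sum contrasts of dS, dN and omega between fate classes.

    ``rates`` columns: fate plus dS / dN / omega.  Returns per-metric group
    means, SDs and two-sided p-values; an empty class omits the contrast."""
    report: dict = {"flags": []}
    for metric in ("dS", "dN", "omega"):
        sub = rates.dropna(subset=[metric])
        stable = sub.loc[sub["fate"] == "putatively_stable", metric].to_numpy()
        degen = sub.loc[sub["fate"] == "degenerating", metric].to_numpy()
        entry = {
            "mean_putatively_stable": float(np.mean(stable)) if len(stable) else float("nan"),
            "sd_putatively_stable": float(np.std(stable, ddof=1)) if len(stable) > 1 else float("nan"),
            "mean_degenerating": float(np.mean(degen)) if len(degen) else float("nan"),
            "sd_degenerating": float(np.std(degen, ddof=1)) if len(degen) > 1 else float("nan"),
            "n_putatively_stable": int(len(stable)),
            "n_degenerating": int(len(degen)),
        }
        if len(stable) == 0 or len(degen) == 0:
            entry["pvalue"] = float("nan")
            report["flags"].append(f"{metric}_contrast_omitted_empty_class")
        else:
            _, entry["pvalue"] = rank_sum_test(stable, degen)
        report[metric] = entry
    return report
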