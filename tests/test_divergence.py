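"""Nei-Gojobori pairwise rates vs an exhaustive-pathway oracle."""

import itertools
import math
import random

import numpy as np
import pytest

from Bio.Seq import Seq

from lgtfate.catalog_io import ValidationError
from lgtfate.divergence import (
    compare_rates_by_fate,
    compute_pairwise_rates,
    pick_representative,
    strip_gap_columns,
)

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"


# ---------------------------------------------------------------------------
# independent oracle: biopython translation, recursive pathway enumeration
# ---------------------------------------------------------------------------

def _aa(codon):
    return str(Seq(codon).translate())


def _oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOPS and _aa(alt) == _aa(codon):
                syn += 1 / 3
    return syn, 3 - syn


def _oracle_paths(a, b):
    """Recursive enumeration of all substitution orderings."""
    diffs = [i for i in range(3) if a[i] != b[i]]

    def recurse(current, remaining):
        if not remaining:
            return [[]]
        paths = []
        for pos in remaining:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            for tail in recurse(nxt, [p for p in remaining if p != pos]):
                blocked = nxt in STOPS
                syn = None if blocked else _aa(current) == _aa(nxt)
                paths.append([(blocked, syn)] + tail)
        return paths

    all_paths = recurse(a, diffs)
    ok = [p for p in all_paths if not any(step[0] for step in p)]
    if ok:
        sd = np.mean([sum(1 for _, syn in p if syn) for p in ok])
        nd = np.mean([sum(1 for _, syn in p if not syn) for p in ok])
        return sd, nd
    # all blocked: every step counts, stop steps treated nonsynonymous
    sd = np.mean([sum(1 for blocked, syn in p if not blocked and syn) for p in all_paths])
    nd = np.mean(
        [sum(1 for blocked, syn in p if blocked or not syn) for p in all_paths]
    )
    return sd, nd


def _oracle_counts(seq_a, seq_b):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, na = _oracle_sites(ca)
        sb, nb = _oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _oracle_paths(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def _random_cds(rng, n_codons):
    out = []
    while len(out) < n_codons:
        codon = "".join(rng.choice(list(BASES), 3))
        if codon not in STOPS:
            out.append(codon)
    return "".join(out)


def _perturb(seq, rng, n_sub):
    chars = list(seq)
    for _ in range(n_sub):
        for _try in range(50):
            i = int(rng.integers(len(chars)))
            new = BASES[int(rng.integers(4))]
            codon_start = i - i % 3
            cand = chars[codon_start : codon_start + 3]
            cand[i % 3] = new
            if "".join(cand) in STOPS or new == chars[i]:
                continue
            chars[i] = new
            break
    return "".join(chars)


# ---------------------------------------------------------------------------
# reference behaviours
# ---------------------------------------------------------------------------

def test_identical_sequences_give_zero_rates():
    seq = "ATGGCTAAAGGT"
    rates = compute_pairwise_rates(seq, seq)
    assert rates.dN == 0.0 and rates.dS == 0.0
    assert math.isnan(rates.omega)
    assert "omega_undefined_dS_zero" in rates.flags


def test_single_synonymous_difference_structure(rng):
    a = _random_cds(rng, 100)
    # GGT -> GGC is synonymous (both Gly)
    b = a.replace("GGT", "GGC", 1) if "GGT" in a else a[:-3] + "GGC"
    a = a if "GGT" in a else a[:-3] + "GGT"
    rates = compute_pairwise_rates(a, b)
    assert rates.dN == 0.0
    assert rates.dS > 0.0


def test_counts_match_exhaustive_pathway_oracle(rng):
    for trial in range(30):
        a = _random_cds(rng, 60)
        b = _perturb(a, rng, int(rng.integers(5, 40)))
        rates = compute_pairwise_rates(a, b, trim_terminal_stop=False)
        S, N, Sd, Nd = _oracle_counts(a, b)
        assert rates.S == pytest.approx(S, abs=1e-9), f"trial {trial}"
        assert rates.N == pytest.approx(N, abs=1e-9)
        assert rates.Sd == pytest.approx(Sd, abs=1e-9)
        assert rates.Nd == pytest.approx(Nd, abs=1e-9)


def test_site_totals_sum_to_three_per_codon(rng):
    a = _random_cds(rng, 80)
    b = _perturb(a, rng, 20)
    rates = compute_pairwise_rates(a, b)
    assert rates.S + rates.N == pytest.approx(3 * rates.n_codons, abs=1e-9)


def test_symmetry(rng):
    a = _random_cds(rng, 50)
    b = _perturb(a, rng, 15)
    ab = compute_pairwise_rates(a, b)
    ba = compute_pairwise_rates(b, a)
    for attr in ("S", "N", "Sd", "Nd", "dS", "dN"):
        assert getattr(ab, attr) == pytest.approx(getattr(ba, attr), abs=1e-12)


def test_concatenation_pools_counts(rng):
    a1, a2 = _random_cds(rng, 40), _random_cds(rng, 35)
    b1, b2 = _perturb(a1, rng, 10), _perturb(a2, rng, 8)
    whole = compute_pairwise_rates(a1 + a2, b1 + b2)
    p1 = compute_pairwise_rates(a1, b1)
    p2 = compute_pairwise_rates(a2, b2)
    assert whole.Sd == pytest.approx(p1.Sd + p2.Sd, abs=1e-9)
    assert whole.Nd == pytest.approx(p1.Nd + p2.Nd, abs=1e-9)
    assert whole.S == pytest.approx(p1.S + p2.S, abs=1e-9)


def test_synonymous_only_process_gives_dn_zero(rng):
    """Mutating only via synonymous single-base changes keeps dN at exactly 0."""
    a = _random_cds(rng, 120)
    chars = list(a)
    changed = 0
    touched_codons = set()
    order = list(range(len(chars)))
    random.Random(0).shuffle(order)
    for i in order:
        if changed >= 30:
            break
        codon_start = i - i % 3
        if codon_start in touched_codons:
            continue  # two hits in one codon can create nonsynonymous pathways
        codon = "".join(chars[codon_start : codon_start + 3])
        for base in BASES:
            if base == chars[i]:
                continue
            cand = list(codon)
            cand[i % 3] = base
            cand = "".join(cand)
            if cand not in STOPS and _aa(cand) == _aa(codon):
                chars[i] = base
                changed += 1
                touched_codons.add(codon_start)
                break
    b = "".join(chars)
    assert changed > 10
    rates = compute_pairwise_rates(a, b)
    assert rates.Nd == 0.0
    assert rates.dN == 0.0
    assert rates.dS > 0.0


def test_gap_columns_stripped_in_codon_units():
    a = "ATG---GCTTAA"
    b = "ATGAAAGCATAA"
    sa, sb = strip_gap_columns(a, b)
    assert sa == "ATGGCTTAA" and sb == "ATGGCATAA"


def test_length_validation():
    with pytest.raises(ValidationError):
        compute_pairwise_rates("ATGC", "ATGC")
    with pytest.raises(ValidationError):
        compute_pairwise_rates("ATGTAAGGG", "ATGAAAGGG", trim_terminal_stop=False)


def test_saturation_flagged():
    # maximally divergent codons at every position push pS/pN past 3/4
    a = "AAA" * 40
    b = "GGG" * 40
    rates = compute_pairwise_rates(a, b)
    assert "dN_saturated" in rates.flags or not math.isnan(rates.dN)


def test_pick_representative_longest_then_lexicographic():
    seqs = {"b": "ATGAAATAA", "a": "ATGAAATAA", "c": "ATGAAAAAATAA"}
    assert pick_representative(seqs) == "c"
    del seqs["c"]
    assert pick_representative(seqs) == "a"


def test_rate_contrast_null_and_power(rng):
    import pandas as pd

    null = pd.DataFrame(
        {
            "fate": ["putatively_stable"] * 40 + ["degenerating"] * 40,
            "dS": rng.gamma(2, 0.2, 80),
            "dN": rng.gamma(2, 0.1, 80),
            "omega": rng.uniform(0.1, 1.0, 80),
        }
    )
    report = compare_rates_by_fate(null)
    assert report["dS"]["pvalue"] > 0.001  # no planted difference
    shifted = null.copy()
    shifted.loc[shifted["fate"] == "degenerating", "dS"] *= 3.0
    report2 = compare_rates_by_fate(shifted)
    assert report2["dS"]["pvalue"] < 0.01
    one_class = null[null["fate"] == "degenerating"]
    report3 = compare_rates_by_fate(one_class)
    assert "dS_contrast_omitted_empty_class" in report3["flags"]
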