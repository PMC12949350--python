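"""Fate calls, expression categories, enrichment, and divergence."""

import numpy as np
import pandas as pd
import pytest

from lgtfate.catalog_io import ValidationError
from lgtfate.expression import (
    TripletExpression,
    classify_expression_categories,
    classify_fate,
    detect_expression,
    expression_divergence,
    log_transform,
    paired_log_difference,
    test_category_enrichment,
)


def _triplet(lgt, vert, donor, name="g1", acc="ACC1", fam="fam000"):
    def prep(v):
        return None if v is None else np.asarray(v, dtype=float)

    lgt = prep(lgt)
    vert = prep(vert)
    donor = prep(donor)
    return TripletExpression(
        lgt_id=name,
        accession=acc,
        family_id=fam,
        sample_ids=[f"s{i}" for i in range(len(lgt))],
        tissues=["leaf"] * len(lgt),
        lgt_tpm=lgt,
        lgt_log=log_transform(lgt),
        vertical_tpm=vert,
        vertical_log=None if vert is None else log_transform(vert),
        donor_tpm=donor,
        donor_log=None if donor is None else log_transform(donor),
        donor_sample_ids=[] if donor is None else [f"d{i}" for i in range(len(donor))],
    )


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tpm,expected", [(0, 0.0), (1, 1.0), (3, 2.0)])
def test_log_transform_reference_points(tpm, expected):
    assert log_transform(tpm) == pytest.approx(expected)


def test_log_transform_rejects_negative():
    with pytest.raises(ValidationError):
        log_transform(-0.5)


@pytest.mark.parametrize(
    "vec,expected",
    [([0, 0, 0.5], True), ([0.49, 0.49], False), ([0, 0, 0], False)],
)
def test_detection_threshold_inclusive(vec, expected):
    assert detect_expression(vec) is expected


def test_detection_empty_vector_errors():
    with pytest.raises(ValidationError):
        detect_expression([])


def test_paired_log_difference_examples(rng):
    t = _triplet([1, 3], [1, 1], [1, 1])
    np.testing.assert_allclose(paired_log_difference(t), [0.0, 1.0])
    # random vectors equal a brute-force loop
    lgt = rng.uniform(0, 50, 9)
    vert = rng.uniform(0, 50, 9)
    t = _triplet(lgt, vert, [1, 1])
    want = [log_transform(a) - log_transform(b) for a, b in zip(lgt, vert)]
    np.testing.assert_allclose(paired_log_difference(t), want)


def test_paired_log_difference_requires_vertical():
    with pytest.raises(ValidationError):
        paired_log_difference(_triplet([1, 2], None, [1, 2]))


# ---------------------------------------------------------------------------
# fate calls
# ---------------------------------------------------------------------------

def test_identical_vectors_are_putatively_stable():
    v = [5.0] * 8
    calls = classify_fate([_triplet(v, v, v)])
    assert calls.loc[0, "fate"] == "putatively_stable"
    assert calls.loc[0, "p_vertical_adj"] == pytest.approx(1.0)


def test_direction_gate_blocks_higher_expression(rng):
    lgt = rng.uniform(400, 500, 12)
    low = rng.uniform(1, 2, 12)
    calls = classify_fate([_triplet(lgt, low, low)])
    # hugely significant but in the wrong direction: stays stable
    assert calls.loc[0, "p_vertical_adj"] < 0.01
    assert calls.loc[0, "fate"] == "putatively_stable"


def test_degenerating_call_when_below_both(rng):
    lgt = rng.uniform(0.5, 1.0, 12)
    vert = rng.uniform(200, 300, 12)
    donor = rng.uniform(200, 300, 12)
    calls = classify_fate([_triplet(lgt, vert, donor)])
    assert calls.loc[0, "fate"] == "degenerating"


def test_missing_or_silent_comparators_flagged_unclassifiable():
    silent = [0.0] * 6
    expressed = [5.0] * 6
    t1 = _triplet(expressed, silent, expressed, name="no_vert")
    t2 = _triplet(expressed, expressed, None, name="no_donor")
    calls = classify_fate([t1, t2])
    assert not calls["classifiable"].any()
    assert calls.loc[0, "unclassifiable_reason"] == "no_expressed_vertical_homolog"
    assert calls.loc[1, "unclassifiable_reason"] == "no_expressed_donor_ortholog"


def test_fate_calls_invariant_to_gene_order(rng):
    triplets = []
    for i in range(12):
        lgt = rng.uniform(0.5, 3.0, 10)
        vert = rng.uniform(1, 100, 10)
        donor = rng.uniform(1, 100, 10)
        triplets.append(_triplet(lgt, vert, donor, name=f"g{i}"))
    fwd = classify_fate(triplets).set_index("lgt_id")
    rev = classify_fate(triplets[::-1]).set_index("lgt_id")
    pd.testing.assert_frame_equal(fwd.sort_index(), rev.sort_index())


def test_alpha_extremes(rng):
    triplets = []
    for i in range(10):
        lgt = rng.uniform(0.5, 1.5, 10)
        vert = rng.uniform(50, 100, 10)
        donor = rng.uniform(50, 100, 10)
        triplets.append(_triplet(lgt, vert, donor, name=f"g{i}"))
    none_called = classify_fate(triplets, alpha=0.0)
    assert (none_called["fate"] == "putatively_stable").all()
    all_called = classify_fate(triplets, alpha=1.0)
    # alpha = 1: every gene with strictly lower medians is degenerating
    assert (all_called["fate"] == "degenerating").all()


def test_null_cohort_false_positive_rate(rng):
    """With no planted effect the degenerating-call rate stays near the
    nominal level (well below alpha after BH)."""
    n = 150
    triplets = []
    for i in range(n):
        base = rng.uniform(5, 50)
        triplets.append(
            _triplet(
                base * rng.lognormal(0, 0.3, 10),
                base * rng.lognormal(0, 0.3, 10),
                base * rng.lognormal(0, 0.3, 10),
                name=f"g{i}",
            )
        )
    calls = classify_fate(triplets)
    rate = (calls["fate"] == "degenerating").mean()
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


# ---------------------------------------------------------------------------
# categories
# ---------------------------------------------------------------------------

def test_identical_groups_no_difference():
    v = list(np.linspace(4, 6, 12))
    cats = classify_expression_categories([_triplet(v, v, v)])
    assert cats.loc[0, "category"] == "no_difference"


def test_donor_like_and_higher_recovered(rng):
    vert = rng.uniform(1, 2, 12)
    donor = rng.uniform(40, 60, 12)
    lgt_donorlike = rng.uniform(40, 60, 12)
    lgt_higher = rng.uniform(900, 1100, 12)
    cats = classify_expression_categories(
        [
            _triplet(lgt_donorlike, vert, donor, name="dl"),
            _triplet(lgt_higher, vert, donor, name="hi"),
        ]
    )
    cats = cats.set_index("lgt_id")
    assert cats.loc["dl", "category"] == "donor_like"
    assert cats.loc["hi", "category"] == "higher"


def test_recipient_like_and_intermediate(rng):
    vert = rng.uniform(40, 60, 12)
    donor = rng.uniform(1, 2, 12)
    lgt_rec = rng.uniform(40, 60, 12)
    lgt_mid = rng.uniform(8, 12, 12)
    cats = classify_expression_categories(
        [
            _triplet(lgt_rec, vert, donor, name="rl"),
            _triplet(lgt_mid, vert, donor, name="mid"),
        ]
    ).set_index("lgt_id")
    assert cats.loc["rl", "category"] == "recipient_like"
    assert cats.loc["mid", "category"] == "intermediate"


def test_small_groups_flagged_unclassifiable():
    cats = classify_expression_categories([_triplet([1.0], [1.0], [1.0])])
    assert cats.loc[0, "category"] == ""
    assert "unclassifiable" in cats.loc[0, "flags"]


def test_category_decision_table_is_exhaustive(rng):
    """Random triplets always land in exactly one category."""
    allowed = {"no_difference", "higher", "intermediate", "recipient_like", "donor_like"}
    triplets = []
    for i in range(60):
        scale = rng.uniform(1, 100, size=3)
        triplets.append(
            _triplet(
                scale[0] * rng.lognormal(0, 0.5, 8),
                scale[1] * rng.lognormal(0, 0.5, 8),
                scale[2] * rng.lognormal(0, 0.5, 8),
                name=f"g{i}",
            )
        )
    cats = classify_expression_categories(triplets)
    assert set(cats["category"]) <= allowed


# ---------------------------------------------------------------------------
# enrichment and divergence
# ---------------------------------------------------------------------------

def test_enrichment_all_no_difference():
    cats = pd.DataFrame({"category": ["no_difference"] * 10})
    report = test_category_enrichment(cats)
    assert report["p_no_difference_majority"] == pytest.approx(2 * 0.5**10, rel=1e-6)
    assert "no_genes_outside_no_difference" in report["flags"]


def test_enrichment_donor_like_only():
    cats = pd.DataFrame({"category": ["donor_like"] * 4})
    report = test_category_enrichment(cats)
    from lgtfate.stats import exact_binomial_test

    assert report["p_donor_like_enrichment"] == pytest.approx(
        exact_binomial_test(4, 4, 0.25)
    )


def test_enrichment_empty_input_errors():
    with pytest.raises(ValidationError):
        test_category_enrichment(pd.DataFrame({"category": []}))


def test_divergence_statistic_values():
    t = _triplet([1] * 4, [7] * 4, [1] * 4)  # log2(8)=3 vs log2(2)=1
    fates = pd.DataFrame(
        {"lgt_id": ["g1"], "accession": ["ACC1"], "fate": ["putatively_stable"]}
    )
    records, contrast = expression_divergence([t], fates)
    assert records.loc[0, "abs_divergence"] == pytest.approx(2.0)
    assert "fate_class_empty_contrast_omitted" in contrast["flags"]


def test_divergence_contrast_detects_planted_difference(rng):
    """Stable genes planted with twice the vertical-donor divergence show a
    significantly larger divergence statistic."""
    triplets, rows = [], []
    for i in range(100):
        stable = i < 50
        gap = rng.normal(0, 2.0 if stable else 0.7)
        base = 30.0
        vert = base * 2.0 ** rng.normal(0, 0.2, 8)
        donor = base * 2.0 ** (gap + rng.normal(0, 0.2, 8))
        triplets.append(_triplet(vert, vert, donor, name=f"g{i}"))
        rows.append(
            {"lgt_id": f"g{i}", "accession": "ACC1",
             "fate": "putatively_stable" if stable else "degenerating"}
        )
    records, contrast = expression_divergence(triplets, pd.DataFrame(rows))
    assert contrast["mean_putatively_stable"] > contrast["mean_degenerating"]
    assert contrast["pvalue"] < 0.05
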