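"""Association between time since transfer and the fate of acquired genes.

Transfer ages (Ma, from molecular dating of the transfer events) are tested
against mean log-expression twice: a naive simple linear regression, and a
linear mixed model with random intercepts for gene family and accession
within family.  The side-by-side report exposes how ignoring the shared
ancestry of the same transfer observed in several accessions inflates the
naive test.  Age differences between fate classes use a rank-sum test, and
ages are binned into 2-Ma intervals for the cohort profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .catalog_io import ValidationError
from .lmm import fit_gaussian_lmm
from .stats import rank_sum_test

__all__ = ["test_age_expression", "compare_age_by_fate", "bin_ages", "AGE_BINS"]

AGE_BINS = ((0.0, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, np.inf))


def test_age_expression(records: pd.DataFrame) -> dict:
    """Linear and mixed-model regressions of log-expression on transfer age.

    ``records`` columns: family_id, accession, age_ma, mean_log_expression.
    Returns {'lm': {slope, se, pvalue, r2}, 'lmm': {slope, se, pvalue, flags}}.
    """
    if len(records) < 10:
        raise ValidationError("need >= 10 records for the age regression")
    if records["family_id"].nunique() < 2:
        raise ValidationError("need >= 2 gene families")
    ages = records["age_ma"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ages)) or np.any(ages < 0):
        raise ValidationError("ages must be finite and >= 0")
    if np.allclose(ages, ages[0]):
        raise ValidationError("constant age: regression undefined")

    y = records["mean_log_expression"].to_numpy(dtype=float)
    X = sm.add_constant(ages)
    ols = sm.OLS(y, X).fit()
    lm = {
        "slope": float(ols.params[1]),
        "se": float(ols.bse[1]),
        "pvalue": float(ols.pvalues[1]),
        "r2": float(ols.rsquared),
    }
    data = records.rename(columns={"family_id": "family"})
    report = fit_gaussian_lmm(
        data,
        formula="mean_log_expression ~ age_ma",
        term="age_ma",
        model_name="age_lmm",
    )
    lmm = {
        "slope": report.estimate,
        "se": report.se,
        "pvalue": report.pvalue,
        "flags": list(report.flags),
    }
    return {"lm": lm, "lmm": lmm, "n": int(len(records))}


def compare_age_by_fate(records: pd.DataFrame) -> dict:
    """Two-sided rank-sum comparison of transfer ages between fate classes."""
    stable = records.loc[records["fate"] == "putatively_stable", "age_ma"].to_numpy()
    degen = records.loc[records["fate"] == "degenerating", "age_ma"].to_numpy()
    out: dict = {
        "n_putatively_stable": int(len(stable)),
        "n_degenerating": int(len(degen)),
        "median_putatively_stable": float(np.median(stable)) if len(stable) else np.nan,
        "median_degenerating": float(np.median(degen)) if len(degen) else np.nan,
        "flags": [],
    }
    if len(stable) == 0 or len(degen) == 0:
        out["pvalue"] = np.nan
        out["flags"].append("fate_class_empty")
        return out
    _, p = rank_sum_test(stable, degen)
    out["pvalue"] = float(p)
    if len(stable) == 1 and len(degen) == 1:
        out["flags"].append("degenerate_single_observation_classes")
    return out


def bin_ages(ages_ma) -> pd.DataFrame:
    """Counts and percentages in half-open 2-Ma bins: [0,2), [2,4), [4,6), >=6."""
    arr = np.asarray(ages_ma, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(~np.isfinite(arr))):
        raise ValidationError("ages must be finite and >= 0")
    rows = []
    for lo, hi in AGE_BINS:
        label = f"[{lo:g},{hi:g})" if np.isfinite(hi) else f">={lo:g}"
        n = int(np.sum((arr >= lo) & (arr < hi)))
        rows.append({"bin": label, "n": n})
    out = pd.DataFrame(rows)
    total = out["n"].sum()
    out["percent"] = 100.0 * out["n"] / total if total else 0.0
    return out

test_age_expression.__test__ = False  # name is domain API, not a pytest test
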