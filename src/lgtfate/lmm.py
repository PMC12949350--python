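"""Mixed-model wrappers shared by the expression, methylation, truncation and
age analyses.

Gaussian responses use statsmodels MixedLM fitted by REML, with a random
intercept per LGT gene family and, where requested, a nested random intercept
for accession within family (variance-component formulation).  Fixed-effect
p-values are Wald z tests on the REML estimates.

Binary responses (truncation, fate class) use the variational Bayes fit of
statsmodels' BinomialBayesMixedGLM; the reported z and p derive from the
approximate posterior mean and SD of the fixed effect.  Complete separation
or a degenerate response falls back to Fisher's exact test on the 2x2 table,
flagged in the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact, norm

__all__ = [
    "ModelReport",
    "fit_gaussian_lmm",
    "fit_difference_lmm",
    "fit_type_lmm",
    "fit_interaction_lmm",
    "fit_binary_glmm",
]


@dataclass
class ModelReport:
    """Summary of one fitted contrast."""

    model: str
    term: str
    estimate: float
    se: float
    pvalue: float
    flags: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "term": self.term,
            "estimate": self.estimate,
            "se": self.se,
            "pvalue": self.pvalue,
            "flags": ";".join(self.flags),
        }


def _wald_p(estimate: float, se: float) -> float:
    if se <= 0 or not np.isfinite(se):
        return float("nan")
    return float(2.0 * norm.sf(abs(estimate / se)))


def fit_gaussian_lmm(
    data: pd.DataFrame,
    formula: str,
    term: str,
    family_col: str = "family",
    accession_col: str | None = "accession",
    model_name: str = "lmm",
) -> ModelReport:
    """REML LMM with random intercepts for family (and accession within
    family when ``accession_col`` is given); reports the named fixed term.

    A singular or non-converging nested fit falls back to the family-only
    random intercept, flagged."""
    flags: list[str] = []
    data = data.reset_index(drop=True)
    if data[family_col].nunique() < 2:
        raise ValueError("need >= 2 families for a family random intercept")

    nested_usable = (
        accession_col is not None
        and accession_col in data.columns
        and data[accession_col].nunique() > 1
        # accession constant within every family is collinear with the
        # family intercept and identifies no extra variance
        and data.groupby(family_col)[accession_col].nunique().max() > 1
        # singleton accession-within-family cells are confounded with the
        # residual: require replication for the nested component
        and data.groupby([family_col, accession_col]).size().max() > 1
    )

    def _fit(with_nested: bool):
        vc = {"accession": f"0 + C({accession_col})"} if with_nested else None
        model = sm.MixedLM.from_formula(
            formula, groups=data[family_col], re_formula="1", vc_formula=vc, data=data
        )
        last_err: Exception | None = None
        for method in ("lbfgs", "bfgs", "cg"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_err = exc
        raise last_err

    result = None
    if nested_usable:
        try:
            result = _fit(True)
            if not np.all(np.isfinite(result.bse_fe.to_numpy())):
                raise ValueError("non-finite fixed-effect SE")
        except Exception:
            flags.append("nested_fit_failed_family_only_fallback")
            result = None
    else:
        flags.append("no_nested_accession_variation_family_only")
    if result is None:
        result = _fit(False)

    names = list(result.fe_params.index)
    if term not in names:
        matches = [n for n in names if term in n]
        if len(matches) != 1:
            raise ValueError(f"term {term!r} not found among {names}")
        term = matches[0]
    est = float(result.fe_params[term])
    se = float(result.bse_fe[term])
    return ModelReport(
        model=model_name,
        term=term,
        estimate=est,
        se=se,
        pvalue=_wald_p(est, se),
        flags=flags,
        extras={"n_obs": int(len(data)), "fe_params": dict(result.fe_params)},
    )


def fit_difference_lmm(data: pd.DataFrame, response: str = "log_difference") -> ModelReport:
    """Intercept-only LMM for paired log-expression differences:
    response ~ 1 + (1 | family / accession).

    The intercept estimates the cohort-wide mean log-fold difference between
    laterally acquired genes and their vertically inherited homologs."""
    return fit_gaussian_lmm(
        data,
        formula=f"{response} ~ 1",
        term="Intercept",
        model_name="difference_lmm",
    )


def fit_type_lmm(
    data: pd.DataFrame,
    response: str = "log_expression",
    type_col: str = "gene_type",
    reference: str | None = None,
) -> ModelReport:
    """LMM with a two-level gene-type fixed effect:
    response ~ Type + (1 | family / accession).

    The coefficient is the log-expression shift of the 'lgt' level relative
    to the comparator (donor or vertical); by default the non-lgt level is
    the reference so a planted reduction yields a negative coefficient."""
    levels = sorted(data[type_col].unique())
    if len(levels) != 2:
        raise ValueError(f"{type_col} must have exactly 2 levels, got {levels}")
    if reference is None:
        others = [lv for lv in levels if lv != "lgt"]
        reference = others[0] if others else levels[0]
    formula = f"{response} ~ C({type_col}, Treatment(reference='{reference}'))"
    report = fit_gaussian_lmm(
        data, formula=formula, term=f"C({type_col}", model_name="type_lmm"
    )
    report.extras["reference"] = reference
    means = data.groupby(type_col)[response].mean()
    report.extras["group_means"] = dict(means)
    return report


def fit_interaction_lmm(
    data: pd.DataFrame,
    response: str = "log_expression",
    status_col: str = "status",
    type_col: str = "gene_type",
) -> ModelReport:
    """LMM testing whether the vertical-donor expression gap depends on fate:
    response ~ Status * Type + (1 | family / accession); reports the
    interaction term."""
    cells = data.groupby([status_col, type_col]).size()
    statuses = sorted(data[status_col].unique())
    types = sorted(data[type_col].unique())
    for s in statuses:
        for t in types:
            if (s, t) not in cells.index:
                raise ValueError(f"empty design cell: ({status_col}={s}, {type_col}={t})")
    formula = f"{response} ~ C({status_col}) * C({type_col})"
    report = fit_gaussian_lmm(data, formula=formula, term=":", model_name="interaction_lmm")
    return report


def fit_binary_glmm(
    data: pd.DataFrame,
    response: str,
    fixed_col: str,
    vc_cols: list[str],
    reference: str | None = None,
    model_name: str = "binary_glmm",
    fisher_fallback: bool = True,
) -> ModelReport:
    """Mixed logistic regression of a binary response on a two-level factor.

    Random intercepts are one variance component per column in ``vc_cols``
    (a single column gives (1|col); a pair [a, b] given as "a:b" strings is
    also accepted for nested terms).  Degenerate responses (all one class, or
    a perfectly separating factor level) are reported through Fisher's exact
    test instead, flagged."""
    flags: list[str] = []
    y = data[response].astype(int)
    levels = sorted(data[fixed_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"{fixed_col} must have exactly 2 levels, got {levels}")
    if reference is None:
        reference = levels[0]
    other = [lv for lv in levels if lv != reference][0]

    table = pd.crosstab(data[fixed_col].astype(str), y).reindex(
        index=levels, columns=[0, 1], fill_value=0
    )
    props = {lv: table.loc[lv, 1] / table.loc[lv].sum() for lv in levels}
    degenerate = y.nunique() < 2
    separated = (table.to_numpy() == 0).any()
    if degenerate or (separated and fisher_fallback):
        flag = "degenerate_response_skipped" if degenerate else "separation_fisher_fallback"
        flags.append(flag)
        if degenerate:
            est, p = float("nan"), float("nan")
        else:
            odds, p = fisher_exact(table.to_numpy())
            est = float(np.log(odds)) if odds > 0 else float("-inf")
        return ModelReport(
            model=model_name,
            term=f"{fixed_col}[{other}]",
            estimate=est,
            se=float("nan"),
            pvalue=float(p),
            flags=flags,
            extras={"proportions": props, "table": table.to_numpy().tolist()},
        )

    from scipy import sparse
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    n = len(data)
    x = (data[fixed_col].astype(str) == other).astype(float).to_numpy()
    exog = np.column_stack([np.ones(n), x])

    # one-hot variance components; components whose groups are all singletons
    # carry no estimable variance (one Bernoulli draw per group) and are
    # dropped with a flag
    blocks, ident_parts = [], []
    vc_id = 0
    for col in vc_cols:
        if ":" in col:
            a, b = col.split(":")
            labels = data[a].astype(str) + ":" + data[b].astype(str)
        else:
            labels = data[col].astype(str)
        codes, idx = np.unique(labels, return_inverse=True)
        counts = np.bincount(idx)
        if counts.max() < 2:
            flags.append(f"vc_dropped_all_singleton:{col}")
            continue
        blocks.append(
            sparse.csr_matrix((np.ones(n), (np.arange(n), idx)), shape=(n, len(codes)))
        )
        ident_parts.append(np.full(len(codes), vc_id, dtype=int))
        vc_id += 1
    if not blocks:
        # no group carries replication: the mixed model degenerates to a GLM
        flags.append("no_usable_random_effects_glm_fallback")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y.to_numpy(), exog, family=sm.families.Binomial()).fit()
        est, se = float(glm.params[1]), float(glm.bse[1])
    else:
        exog_vc = sparse.hstack(blocks).tocsr() if len(blocks) > 1 else blocks[0]
        ident = np.concatenate(ident_parts)
        # fit_vb draws Monte Carlo samples from the legacy global RNG; pin it
        # so identical inputs give identical reports
        state = np.random.get_state()
        np.random.seed(20260101)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = BinomialBayesMixedGLM(y.to_numpy(), exog, exog_vc, ident)
                result = model.fit_vb()
        finally:
            np.random.set_state(state)
        est = float(result.fe_mean[1])
        se = float(result.fe_sd[1])
    return ModelReport(
        model=model_name,
        term=f"{fixed_col}[{other}]",
        estimate=est,
        se=se,
        pvalue=_wald_p(est, se),
        flags=flags,
        extras={
            "proportions": props,
            "odds_ratio": float(np.exp(est)),
            "reference": reference,
        },
    )
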