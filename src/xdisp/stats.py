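"""Propensity-weighted sex-disparity inference.

Per-gene tests ask whether the expression status of X-linked mutations (NEM =
non-expressed vs EM = expressed) is associated with patient sex. Each gene's
2x2 table is filled with sums of matching weights rather than raw counts, and
a Pearson chi-squared statistic (1 df, no continuity correction — weighted
cells are non-integer) is computed on it. Genes are adjusted together with
Benjamini–Hochberg. The *chi-score* is the signed square root of the
statistic: positive when the weighted NEM proportion is larger in females
than males. Under the null the chi-scores are asymptotically standard normal,
so a designated gene set (e.g. a p53-associated set) can be compared with the
remaining X genes by a rank test on its chi-scores.

Also here: the Poisson log-linear mutation-burden model (female/male rate
ratio with Wald CI), the logit-scale RMAF sex comparison adjusted for cancer
type, and the gene-size vs NEM-count correlation check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import logit as _logit
from statsmodels.stats.multitest import multipletests

from .rmaf import STATUS_EM, STATUS_NEM

__all__ = [
    "GeneTestResult",
    "BurdenModelResult",
    "weighted_chi2",
    "gene_tests",
    "bh_adjust",
    "chi_score",
    "set_vs_rest",
    "burden_model",
    "rmaf_sex_compare",
    "size_nem_correlation",
]


@dataclass
class GeneTestResult:
    """Weighted 2x2 sex-by-expression-status test for one gene."""

    gene: str
    table: np.ndarray  # rows (female, male) x cols (NEM, EM), weighted
    chi2_stat: float
    p_value: float
    n_nem_f: int  # unweighted counts
    n_nem_m: int
    prop_nem_f: float  # weighted NEM proportions
    prop_nem_m: float
    testable: bool
    adj_p: float | None = None

    @property
    def chi_score(self) -> float:
        return chi_score(self)


@dataclass
class BurdenModelResult:
    """Weighted Poisson regression of per-patient mutation counts on sex."""

    rate_ratio: float  # female vs male
    ci_low: float
    ci_high: float
    p_value: float
    scope: str
    n_female: int
    n_male: int


def _pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def weighted_chi2(
    gene: str,
    records: pd.DataFrame,
    clinical: pd.DataFrame,
    weights: pd.Series,
) -> GeneTestResult:
    """Test one gene's NEM/EM split against sex on the weighted 2x2 table.

    ``records`` are gene-resolved RMAF records for this gene (one per
    patient); only NEM and EM rows enter the table. ``weights`` maps
    patient_id to its matching weight (missing patients weight 1). A zero row
    or column marginal makes the gene untestable.
    """
    sex = clinical.set_index("patient_id")["sex"]
    sub = records[records["status"].isin([STATUS_NEM, STATUS_EM])].copy()
    sub["sex"] = sub["patient_id"].map(sex)
    sub["w"] = sub["patient_id"].map(weights).fillna(1.0)

    table = np.zeros((2, 2))
    for i, s in enumerate(("female", "male")):
        for j, status in enumerate((STATUS_NEM, STATUS_EM)):
            table[i, j] = sub.loc[
                (sub["sex"] == s) & (sub["status"] == status), "w"
            ].sum()

    n_nem_f = int(((sub["sex"] == "female") & (sub["status"] == STATUS_NEM)).sum())
    n_nem_m = int(((sub["sex"] == "male") & (sub["status"] == STATUS_NEM)).sum())
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    testable = bool(row.min() > 0 and col.min() > 0)
    if testable:
        stat, p = _pearson_chi2(table)
        prop_f = table[0, 0] / row[0]
        prop_m = table[1, 0] / row[1]
    else:
        stat, p = np.nan, np.nan
        prop_f = table[0, 0] / row[0] if row[0] > 0 else np.nan
        prop_m = table[1, 0] / row[1] if row[1] > 0 else np.nan
    return GeneTestResult(
        gene=gene,
        table=table,
        chi2_stat=stat,
        p_value=p,
        n_nem_f=n_nem_f,
        n_nem_m=n_nem_m,
        prop_nem_f=prop_f,
        prop_nem_m=prop_m,
        testable=testable,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_score(result: GeneTestResult) -> float:
    """Signed square root of the chi-squared statistic.

    Plus when the weighted female NEM proportion exceeds the male one, minus
    for the converse (zero if exactly equal, where the statistic is 0 anyway).
    """
    if not result.testable:
        return np.nan
    sign = np.sign(result.prop_nem_f - result.prop_nem_m)
    return float(sign * np.sqrt(result.chi2_stat))


def gene_tests(
    records: pd.DataFrame,
    clinical: pd.DataFrame,
    weights: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the weighted test for every gene with classified mutations.

    The BH family is the set of testable genes (a gene needs classified
    mutations in both sexes and both statuses present somewhere). Output has
    volcano-ready columns ``log2_ratio_fm`` (weighted female/male NEM
    proportion) and ``neg_log10_p``.
    """
    results = [
        weighted_chi2(gene, sub, clinical, weights)
        for gene, sub in records.groupby("gene")
    ]
    rows = []
    for r in results:
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_fm = float(np.log2(r.prop_nem_f / r.prop_nem_m))
        rows.append(
            {
                "gene": r.gene,
                "w_f_nem": r.table[0, 0],
                "w_f_em": r.table[0, 1],
                "w_m_nem": r.table[1, 0],
                "w_m_em": r.table[1, 1],
                "chi2_stat": r.chi2_stat,
                "p_value": r.p_value,
                "n_nem_f": r.n_nem_f,
                "n_nem_m": r.n_nem_m,
                "chi_score": r.chi_score,
                "testable": r.testable,
                "log2_ratio_fm": log2_fm,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["adj_p"] = np.nan
    testable = out["testable"]
    if testable.any():
        out.loc[testable, "adj_p"] = bh_adjust(out.loc[testable, "p_value"])
    out["significant"] = out["adj_p"] <= alpha
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out.sort_values("p_value").reset_index(drop=True)


def set_vs_rest(chi_scores, in_set) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test: designated gene set vs the rest."""
    chi_scores = np.asarray(chi_scores, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    a, b = chi_scores[in_set], chi_scores[~in_set]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = sps.ranksums(a, b)
    return float(stat), float(p)


def burden_model(
    counts, sex, weights=None, scope: str = "X_only"
) -> BurdenModelResult:
    """Weighted Poisson log-linear model of mutation counts on sex.

    ``rate_ratio`` is the female/male per-patient mutation-rate ratio
    exp(beta_female) with its Wald 95% CI.
    """
    counts = np.asarray(counts, dtype=float)
    sex = np.asarray(sex)
    if counts.sum() == 0:
        raise ValueError("all mutation counts are zero")
    female = (sex == "female").astype(float)
    n_f, n_m = int(female.sum()), int(len(sex) - female.sum())
    if n_f == 0 or n_m == 0:
        raise ValueError("both sexes required for the burden model")
    X = sm.add_constant(female)
    w = np.ones_like(counts) if weights is None else np.asarray(weights, float)
    fit = sm.GLM(counts, X, family=sm.families.Poisson(), freq_weights=w).fit()
    beta, se = fit.params[1], fit.bse[1]
    return BurdenModelResult(
        rate_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(fit.pvalues[1]),
        scope=scope,
        n_female=n_f,
        n_male=n_m,
    )


def rmaf_sex_compare(
    records: pd.DataFrame,
    clinical: pd.DataFrame,
    eps: float = 0.01,
    weights: pd.Series | None = None,
) -> tuple[float, float]:
    """Sex effect on logit-RMAF at the mutation level, adjusted for cancer.

    RMAF values are clipped to [eps, 1-eps] before the logit (the scale is
    undefined at 0 and 1). Returns ``(female_coefficient, p_value)`` — a
    negative coefficient means female mutations are expressed at lower RMAF.
    With a single cancer type the cancer adjustment drops out.
    """
    meta = clinical.set_index("patient_id")[["sex", "cancer_type"]]
    df = records.join(meta, on="patient_id")
    df = df[df["rmaf"].notna()].copy()
    if df.empty:
        raise ValueError("no records with RMAF values")
    y = _logit(np.clip(df["rmaf"].to_numpy(float), eps, 1 - eps))
    female = (df["sex"] == "female").astype(float).to_numpy()
    parts = [female]
    if df["cancer_type"].nunique() > 1:
        dummies = pd.get_dummies(df["cancer_type"], drop_first=True).astype(float)
        parts.append(dummies.to_numpy())
    X = sm.add_constant(np.column_stack(parts))
    w = (
        np.ones(len(df))
        if weights is None
        else df["patient_id"].map(weights).fillna(1.0).to_numpy(float)
    )
    fit = sm.WLS(y, X, weights=w).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def size_nem_correlation(gene_lengths, nem_counts) -> tuple[float | None, float | None]:
    """Pearson correlation between gene length and NEM count.

    Returns ``(None, None)`` when either vector has zero variance.
    """
    x = np.asarray(gene_lengths, dtype=float)
    y = np.asarray(nem_counts, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired genes")
    if x.std() == 0 or y.std() == 0:
        return None, None
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
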