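"""Association of predicted response probability with mutation status.

In an external cohort the signature assigns each sample a continuous
response probability; this module relates it to dichotomous gene-mutation
status.  Rare genes are removed by a minimum-recurrence filter (mutated at
least ``min_count`` times, default 3), candidate genes are picked by two
complementary selectors - elastic-net linear regression (grouped, sparse)
and gradient-boosted tree regression (captures interactions such as
epistasis) - and the union is summarized by one joint ordinary-least-squares
fit.  A chi-square group test relates binary predicted response to a gene
group flag (e.g. any spliceosome mutation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb
from scipy.stats import chi2_contingency
from sklearn.linear_model import ElasticNet, ElasticNetCV

from .knee import knee_index

__all__ = [
    "filter_by_frequency",
    "select_by_elastic_net",
    "select_by_boosting",
    "summarize_ols",
    "group_test",
    "GroupTestResult",
]

logger = logging.getLogger(__name__)


def _validate_mutations(mut: pd.DataFrame) -> None:
    vals = mut.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mutation matrix must be binary (0/1)")
    if mut.columns.duplicated().any() or mut.index.duplicated().any():
        raise ValueError("duplicate sample or gene labels")


def filter_by_frequency(mut: pd.DataFrame, min_count: int = 3) -> pd.DataFrame:
    """Keep genes mutated at least ``min_count`` times across samples."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    _validate_mutations(mut)
    keep = mut.sum(axis=0) >= min_count
    if not keep.any():
        warnings.warn(f"no gene mutated at least {min_count} times; empty matrix returned")
    return mut.loc[:, keep]


def select_by_elastic_net(
    probabilities: pd.Series,
    mut: pd.DataFrame,
    mixing: float = 0.5,
    seed: int | None = None,
    cv_folds: int = 5,
) -> pd.Series:
    """Genes with nonzero elastic-net coefficients (signed).

    The penalty strength is chosen on the cross-validated error path by the
    one-standard-error rule: the strongest penalty whose mean CV error is
    within one SE of the minimum.  If that penalty zeroes every coefficient
    the minimum-error penalty is used instead (logged).
    """
    if not 0 <= mixing <= 1:
        raise ValueError("mixing must lie in [0, 1]")
    _validate_mutations(mut)
    y = probabilities.loc[mut.index].to_numpy(dtype=float)
    x = mut.to_numpy(dtype=float)

    # sklearn's l1_ratio=0 pure-ridge path is unsupported; floor it
    l1 = max(mixing, 1e-3)
    cv = ElasticNetCV(
        l1_ratio=l1, alphas=100, cv=cv_folds, random_state=seed, max_iter=5000
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv.fit(x, y)

    mse_mean = cv.mse_path_.mean(axis=1)
    mse_se = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
    i_min = int(np.argmin(mse_mean))
    threshold = mse_mean[i_min] + mse_se[i_min]
    # alphas_ are descending: the first index within threshold is the
    # strongest penalty satisfying the 1-SE rule
    i_1se = int(np.nonzero(mse_mean <= threshold)[0][0])
    alpha = float(cv.alphas_[i_1se])

    def _fit(a: float) -> np.ndarray:
        model = ElasticNet(alpha=a, l1_ratio=l1, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, y)
        return model.coef_

    coefs = _fit(alpha)
    if not np.any(coefs != 0):
        logger.info("1-SE penalty zeroed all coefficients; falling back to CV-minimum penalty")
        coefs = _fit(float(cv.alphas_[i_min]))
    sel = pd.Series(coefs, index=mut.columns, name="coefficient")
    return sel[sel != 0]


def select_by_boosting(
    probabilities: pd.Series,
    mut: pd.DataFrame,
    seed: int | None = None,
    num_rounds: int = 100,
    top_k: int | None = None,
) -> pd.Series:
    """Genes above the knee of the boosted-tree gain decay curve.

    A gradient-boosted regression of probability on mutation indicators is
    fit; genes are ranked by total split gain and the retained set is cut at
    the knee of the gain curve (``top_k`` overrides the knee rule).
    """
    _validate_mutations(mut)
    y = probabilities.loc[mut.index].to_numpy(dtype=float)
    dtrain = xgb.DMatrix(
        mut.to_numpy(dtype=float), label=y, feature_names=list(mut.columns)
    )
    params = {
        "objective": "reg:squarederror",
        "max_depth": 4,
        "eta": 0.1,
        "nthread": 1,
        "verbosity": 0,
        "seed": int(seed or 0) % (2**31),
    }
    model = xgb.train(params, dtrain, num_boost_round=num_rounds)
    gains = pd.Series(model.get_score(importance_type="total_gain"), dtype=float)
    if gains.empty:
        return pd.Series(dtype=float, name="gain")
    gains = gains.sort_values(ascending=False, kind="stable").rename("gain")
    if top_k is not None:
        return gains.iloc[:top_k]
    if len(gains) <= 2:
        return gains
    idx, dist = knee_index(gains.to_numpy())
    return gains if dist <= 0 else gains.iloc[: idx + 1]


@dataclass(frozen=True)
class AssociationSummary:
    table: pd.DataFrame  # gene, coefficient, p_value, source
    n_selected: int
    dropped_collinear: list[str]


def summarize_ols(
    probabilities: pd.Series,
    mut: pd.DataFrame,
    genes_elastic: list[str],
    genes_boosted: list[str],
) -> AssociationSummary:
    """Joint OLS of predicted probability on the union of selected genes."""
    _validate_mutations(mut)
    union = list(dict.fromkeys([*genes_elastic, *genes_boosted]))
    missing = [g for g in union if g not in mut.columns]
    if missing:
        raise KeyError(f"selected genes absent from mutation matrix: {missing}")
    if len(mut) <= len(union) + 1:
        raise ValueError(
            f"need n_samples > n_genes + 1 ({len(mut)} samples, {len(union)} genes)"
        )

    x = mut[union].astype(float)
    dropped: list[str] = []
    seen: dict[tuple, str] = {}
    for g in union:
        key = tuple(x[g])
        if key in seen:
            dropped.append(g)
            warnings.warn(f"gene {g} collinear with {seen[key]}; dropped from OLS")
        else:
            seen[key] = g
    kept = [g for g in union if g not in dropped]

    design = sm.add_constant(x[kept])
    fit = sm.OLS(probabilities.loc[mut.index].astype(float), design).fit()

    def source(g: str) -> str:
        in_e, in_b = g in genes_elastic, g in genes_boosted
        return "both" if in_e and in_b else ("elastic_net" if in_e else "boosted")

    table = pd.DataFrame(
        {
            "gene": kept,
            "coefficient": [fit.params[g] for g in kept],
            "p_value": [fit.pvalues[g] for g in kept],
            "source": [source(g) for g in kept],
        }
    ).sort_values("coefficient", ascending=False, kind="stable").reset_index(drop=True)
    return AssociationSummary(table=table, n_selected=len(kept), dropped_collinear=dropped)


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    statistic_corrected: float
    p_value: float
    p_value_corrected: float
    df: int
    table: np.ndarray


def group_test(calls: pd.Series | np.ndarray, group_flags: pd.Series | np.ndarray) -> GroupTestResult:
    """Pearson chi-square (df=1) of binary predicted response vs a group flag.

    Both the uncorrected statistic and the Yates continuity-corrected one are
    reported.  A zero margin makes the test undefined.
    """
    c = np.asarray(calls).astype(int)
    g = np.asarray(group_flags).astype(int)
    if c.shape != g.shape:
        raise ValueError("calls and group_flags must align")
    tab = np.array(
        [
            [int(((g == 1) & (c == 1)).sum()), int(((g == 1) & (c == 0)).sum())],
            [int(((g == 0) & (c == 1)).sum()), int(((g == 0) & (c == 0)).sum())],
        ]
    )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError(f"zero margin in 2x2 table {tab.tolist()}")
    res_plain = chi2_contingency(tab, correction=False)
    res_yates = chi2_contingency(tab, correction=True)
    return GroupTestResult(
        statistic=float(res_plain.statistic),
        statistic_corrected=float(res_yates.statistic),
        p_value=float(res_plain.pvalue),
        p_value_corrected=float(res_yates.pvalue),
        df=1,
        table=tab,
    )
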