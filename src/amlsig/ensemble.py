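"""Nested gradient-boosted gene-signature ensemble.

The scheme guards a small cohort (n ~ 32) against selection bias with a
frozen nested split plan: the samples are partitioned into inner-train /
outer-hold-out pairs up front (stratified, repeated ``n_outer`` times) and
every later stage reuses exactly those pairs.  Feature selection runs in
two rounds of gradient-boosted fits on random sub-splits of each inner set,
ordering genes by mean total split gain; hyperparameters are tuned by
repeated stratified cross-validation; the final signature is the ensemble
of one boosted model per CV fold per outer pair
(cv_folds x cv_repeats x n_outer models; 5 x 4 x 100 = 2000 by default).
A sample's predicted response is the mode of the kernel density of its
per-model probabilities; it is called a responder iff the mode exceeds 0.5.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import gaussian_kde
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    ParameterGrid,
    RepeatedStratifiedKFold,
    StratifiedShuffleSplit,
    train_test_split,
)

from .preprocess import ExpressionMatrix

__all__ = [
    "NestedSplitPlan",
    "SignatureEnsemble",
    "EnsemblePrediction",
    "make_split_plan",
    "feature_selection_round",
    "tune_hyperparameters",
    "fit_final_ensemble",
    "predict",
    "density_mode",
    "DEFAULT_PARAMS",
    "DEFAULT_NUM_ROUNDS",
    "DEFAULT_GRID",
]

logger = logging.getLogger(__name__)

# round-1 "default" booster settings, pinned for reproducibility
DEFAULT_PARAMS: dict = {
    "objective": "binary:logistic",
    "max_depth": 6,
    "eta": 0.3,
    "min_child_weight": 1,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "lambda": 1.0,
    "nthread": 1,
    "verbosity": 0,
}
DEFAULT_NUM_ROUNDS = 50

# feature-selection rounds use a randomized-subspace stump configuration:
# shallow additive trees with per-tree column subsampling spread split gain
# across every marginally informative gene instead of letting one strong
# gene mask its peers, which is what gain-ranking needs at n ~ 32
SELECTION_PARAMS: dict = {
    "max_depth": 1,
    "eta": 0.1,
    "colsample_bytree": 0.15,
}
SELECTION_NUM_ROUNDS = 300

DEFAULT_GRID: dict = {
    "max_depth": [2, 4, 6],
    "eta": [0.05, 0.1, 0.3],
    "subsample": [0.8, 1.0],
    "num_boost_round": [25, 50],
}

_MAX_FAILURE_FRACTION = 0.10


class MissingFeatureError(KeyError):
    """Prediction input lacks genes the ensemble was trained on."""


@dataclass(frozen=True)
class NestedSplitPlan:
    """Counts and fractions of the frozen nested validation scheme."""

    n_outer: int = 100
    outer_test_fraction: float = 0.2
    round1_reps: int = 20
    round1_val_fraction: float = 0.2
    cv_folds: int = 5
    cv_repeats: int = 4
    top_k_round1: int = 50
    top_k_round2: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_outer", "round1_reps", "cv_folds", "cv_repeats",
                     "top_k_round1", "top_k_round2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("outer_test_fraction", "round1_val_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.top_k_round2 > self.top_k_round1:
            raise ValueError("top_k_round2 cannot exceed top_k_round1")

    @property
    def model_count(self) -> int:
        return self.cv_folds * self.cv_repeats * self.n_outer

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NestedSplitPlan":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class SplitPlanMaterialized:
    """Frozen outer train/hold-out partitions, by sample identifier."""

    pairs: list[tuple[list[str], list[str]]]

    def __len__(self) -> int:
        return len(self.pairs)

    def to_json(self) -> str:
        return json.dumps([{"train": tr, "test": te} for tr, te in self.pairs])

    @classmethod
    def from_json(cls, text: str) -> "SplitPlanMaterialized":
        return cls([(p["train"], p["test"]) for p in json.loads(text)])


def make_split_plan(labels: pd.Series, plan: NestedSplitPlan) -> SplitPlanMaterialized:
    """Materialize ``n_outer`` stratified train/hold-out pairs.

    ``labels`` is the per-sample binary class indexed by sample id.  Each
    pair partitions the full sample set; stratification keeps both classes
    represented in every hold-out despite the small n.
    """
    y = labels.to_numpy()
    if len(labels) < 10:
        raise ValueError("need at least 10 samples for a nested plan")
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 samples for stratification, got {dict(counts)}")
    sss = StratifiedShuffleSplit(
        n_splits=plan.n_outer,
        test_size=plan.outer_test_fraction,
        random_state=plan.seed,
    )
    ids = labels.index.to_numpy()
    pairs = [
        (sorted(ids[tr].tolist()), sorted(ids[te].tolist()))
        for tr, te in sss.split(np.zeros_like(y), y)
    ]
    return SplitPlanMaterialized(pairs)


def _fit_booster(
    x: pd.DataFrame,
    y: np.ndarray,
    params: dict,
    num_rounds: int,
    seed: int,
    eval_set: tuple[pd.DataFrame, np.ndarray] | None = None,
    early_stopping_rounds: int | None = None,
) -> xgb.Booster:
    full = {**DEFAULT_PARAMS, **params, "seed": int(seed) % (2**31)}
    full.pop("num_boost_round", None)
    dtrain = xgb.DMatrix(x.to_numpy(), label=y, feature_names=list(x.columns))
    kwargs: dict = {}
    if eval_set is not None and early_stopping_rounds is not None:
        dval = xgb.DMatrix(
            eval_set[0].to_numpy(), label=eval_set[1], feature_names=list(x.columns)
        )
        kwargs = {
            "evals": [(dval, "validation")],
            "early_stopping_rounds": early_stopping_rounds,
            "verbose_eval": False,
        }
    return xgb.train(full, dtrain, num_boost_round=num_rounds, **kwargs)


def _booster_probs(model: xgb.Booster, x: pd.DataFrame) -> np.ndarray:
    dm = xgb.DMatrix(x.to_numpy(), feature_names=list(x.columns))
    return model.predict(dm)


def feature_selection_round(
    x: pd.DataFrame,
    labels: pd.Series,
    splits: SplitPlanMaterialized,
    reps: int = 20,
    val_fraction: float = 0.2,
    params: dict | None = None,
    num_rounds: int | None = None,
    early_stopping_rounds: int | None = 20,
    seed: int = 0,
) -> pd.Series:
    """Order candidate genes by mean total gain over sub-split boosted fits.

    For every outer pair's inner train set and each of ``reps`` random
    stratified 80/20 sub-splits, a booster is fit on the sub-train portion
    (early-stopped against the held-out validation portion) and per-feature
    total split gain recorded; features absent from a fit's trees contribute
    gain 0 to the mean.  ``x`` is samples x candidate genes
    (Blom-transformed upstream).
    """
    params = {**SELECTION_PARAMS, **(params or {})}
    if num_rounds is None:
        num_rounds = int(params.get("num_boost_round", SELECTION_NUM_ROUNDS))
    rng = np.random.default_rng(seed)
    gains = pd.Series(0.0, index=x.columns)
    n_fits = n_fail = 0
    for tr_ids, _ in splits.pairs:
        x_in, y_in = x.loc[tr_ids], labels.loc[tr_ids].to_numpy()
        for _ in range(reps):
            sub_seed = int(rng.integers(2**31))
            try:
                x_tr, x_val, y_tr, y_val = train_test_split(
                    x_in, y_in, test_size=val_fraction,
                    stratify=y_in, random_state=sub_seed,
                )
                model = _fit_booster(
                    x_tr, y_tr, params, num_rounds, sub_seed,
                    eval_set=(x_val, y_val),
                    early_stopping_rounds=early_stopping_rounds,
                )
                fit_gain = model.get_score(importance_type="total_gain")
            except Exception as exc:  # noqa: BLE001 - fits may fail on tiny folds
                n_fail += 1
                logger.warning("feature-selection fit failed: %s", exc)
                continue
            n_fits += 1
            for feat, g in fit_gain.items():
                gains[feat] += g
    total = n_fits + n_fail
    if total and n_fail / total > _MAX_FAILURE_FRACTION:
        raise RuntimeError(f"{n_fail}/{total} feature-selection fits failed")
    if n_fits == 0:
        raise RuntimeError("no successful feature-selection fit")
    return (gains / n_fits).sort_values(ascending=False, kind="stable")


def tune_hyperparameters(
    x: pd.DataFrame,
    labels: pd.Series,
    grid: dict | None = None,
    cv_folds: int = 5,
    cv_repeats: int = 4,
    seed: int = 0,
) -> dict:
    """Pick the grid point maximizing mean CV area under the ROC curve.

    Ties break toward smaller tree depth, then lower learning rate (the
    less flexible model).
    """
    grid = grid or DEFAULT_GRID
    candidates = list(ParameterGrid(grid))
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    y = labels.to_numpy()
    rkf = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    folds = list(rkf.split(np.zeros_like(y), y))

    scored = []
    for cand in candidates:
        num_rounds = int(cand.get("num_boost_round", DEFAULT_NUM_ROUNDS))
        aucs = []
        for tr, te in folds:
            model = _fit_booster(x.iloc[tr], y[tr], cand, num_rounds, seed)
            prob = _booster_probs(model, x.iloc[te])
            if len(np.unique(y[te])) == 2:
                aucs.append(roc_auc_score(y[te], prob))
        mean_auc = float(np.mean(aucs)) if aucs else 0.0
        scored.append((mean_auc, cand))
    scored.sort(
        key=lambda t: (
            -t[0],
            t[1].get("max_depth", DEFAULT_PARAMS["max_depth"]),
            t[1].get("eta", DEFAULT_PARAMS["eta"]),
        )
    )
    best = dict(scored[0][1])
    best["_mean_cv_auc"] = scored[0][0]
    return best


@dataclass
class SignatureEnsemble:
    """Ordered signature genes plus the full set of fitted boosted models."""

    selected_genes: list[str]
    models: list[xgb.Booster] = field(repr=False)
    tuned_hyperparameters: dict
    split_plan: NestedSplitPlan
    training_metrics: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        expected = self.split_plan.model_count
        if len(self.models) != expected:
            raise ValueError(
                f"model count {len(self.models)} != cv_folds x cv_repeats x n_outer = {expected}"
            )

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        (d / "models").mkdir(parents=True, exist_ok=True)
        (d / "plan.json").write_text(self.split_plan.to_json())
        (d / "hyperparameters.json").write_text(json.dumps(self.tuned_hyperparameters, indent=1))
        (d / "selected_genes.txt").write_text("\n".join(self.selected_genes) + "\n")
        self.training_metrics.to_csv(d / "metrics.tsv", sep="\t", index=False)
        for i, m in enumerate(self.models):
            m.save_model(d / "models" / f"model_{i:04d}.json")

    @classmethod
    def load(cls, directory: str | Path) -> "SignatureEnsemble":
        d = Path(directory)
        plan = NestedSplitPlan.from_json((d / "plan.json").read_text())
        genes = (d / "selected_genes.txt").read_text().split()
        tuned = json.loads((d / "hyperparameters.json").read_text())
        metrics = pd.read_csv(d / "metrics.tsv", sep="\t")
        models = []
        for path in sorted((d / "models").glob("model_*.json")):
            m = xgb.Booster()
            m.load_model(path)
            models.append(m)
        return cls(genes, models, tuned, plan, metrics)


def fit_final_ensemble(
    x: pd.DataFrame,
    labels: pd.Series,
    splits: SplitPlanMaterialized,
    tuned: dict,
    plan: NestedSplitPlan,
) -> SignatureEnsemble:
    """Fit cv_folds x cv_repeats models per outer pair and assemble them.

    ``x`` is samples x selected genes.  Per model, metrics are recorded on
    its CV test fold and on the outer hold-out set, which no earlier stage
    has touched.
    """
    if len(splits) != plan.n_outer:
        raise ValueError(f"split plan has {len(splits)} pairs, expected {plan.n_outer}")
    tuned = {k: v for k, v in tuned.items() if not k.startswith("_")}
    num_rounds = int(tuned.get("num_boost_round", DEFAULT_NUM_ROUNDS))
    y_all = labels
    models: list[xgb.Booster] = []
    rows = []
    n_fail = 0
    for i, (tr_ids, te_ids) in enumerate(splits.pairs):
        x_in, y_in = x.loc[tr_ids], y_all.loc[tr_ids].to_numpy()
        x_out, y_out = x.loc[te_ids], y_all.loc[te_ids].to_numpy()
        rkf = RepeatedStratifiedKFold(
            n_splits=plan.cv_folds, n_repeats=plan.cv_repeats, random_state=plan.seed + i
        )
        for j, (cv_tr, cv_te) in enumerate(rkf.split(np.zeros_like(y_in), y_in)):
            try:
                model = _fit_booster(
                    x_in.iloc[cv_tr], y_in[cv_tr], tuned, num_rounds, plan.seed + i * 1000 + j
                )
            except Exception as exc:  # noqa: BLE001
                n_fail += 1
                logger.warning("final-ensemble fit failed (outer %d, fold %d): %s", i, j, exc)
                continue
            models.append(model)
            cv_prob = _booster_probs(model, x_in.iloc[cv_te])
            out_prob = _booster_probs(model, x_out)
            rows.append(
                {
                    "outer": i,
                    "fold": j,
                    "cv_accuracy": float(((cv_prob > 0.5) == y_in[cv_te]).mean()),
                    "cv_auc": (
                        roc_auc_score(y_in[cv_te], cv_prob)
                        if len(np.unique(y_in[cv_te])) == 2
                        else np.nan
                    ),
                    "holdout_accuracy": float(((out_prob > 0.5) == y_out).mean()),
                    "holdout_auc": (
                        roc_auc_score(y_out, out_prob)
                        if len(np.unique(y_out)) == 2
                        else np.nan
                    ),
                }
            )
    total = len(models) + n_fail
    if n_fail and n_fail / total > _MAX_FAILURE_FRACTION:
        raise RuntimeError(f"{n_fail}/{total} final-ensemble fits failed")
    if n_fail:
        raise RuntimeError(
            f"{n_fail} fits failed: model-count invariant {plan.model_count} cannot be met"
        )
    return SignatureEnsemble(
        selected_genes=list(x.columns),
        models=models,
        tuned_hyperparameters=tuned,
        split_plan=plan,
        training_metrics=pd.DataFrame(rows),
    )


def density_mode(probabilities: np.ndarray, grid_size: int = 1001) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on the unit interval."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("no probabilities")
    if np.ptp(p) < 1e-12:  # point mass: KDE degenerate, mode is the value
        return float(p[0])
    kde = gaussian_kde(p, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, grid_size)
    return float(grid[np.argmax(kde(grid))])


@dataclass(frozen=True)
class EnsemblePrediction:
    """Per-sample model probabilities, density modes, and binary calls."""

    probabilities: pd.DataFrame  # models x samples
    modes: pd.Series
    calls: pd.Series  # "responder" / "non-responder"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": self.modes,
                "call": self.calls,
                "n_models": self.probabilities.shape[0],
            }
        )


def predict(
    ensemble: SignatureEnsemble,
    expr: ExpressionMatrix | pd.DataFrame,
) -> EnsemblePrediction:
    """Predict response for each sample of a Blom-transformed matrix.

    A sample is called a responder iff the mode of its per-model probability
    density exceeds 0.5 (strict: a boundary mode of exactly 0.5 is a
    non-responder call).
    """
    if isinstance(expr, ExpressionMatrix):
        mat = expr.values.T  # samples x genes
    else:
        mat = expr
    missing = [g for g in ensemble.selected_genes if g not in mat.columns]
    if missing:
        raise MissingFeatureError(f"matrix lacks signature genes: {missing}")
    x = mat[ensemble.selected_genes]
    probs = np.vstack([_booster_probs(m, x) for m in ensemble.models])
    prob_df = pd.DataFrame(probs, columns=x.index)
    modes = pd.Series(
        [density_mode(probs[:, j]) for j in range(probs.shape[1])],
        index=x.index,
        name="mode",
    )
    calls = pd.Series(
        np.where(modes > 0.5, "responder", "non-responder"), index=x.index, name="call"
    )
    return EnsemblePrediction(prob_df, modes, calls)
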