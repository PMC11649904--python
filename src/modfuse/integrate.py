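"""Class-weighted elastic-net learning, calibration, and modality integration.

The learner is penalised logistic regression minimising

    mean weighted log-loss + lambda * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2)

with balanced class weights w_c = n / (2 * n_c).  Hyperparameters are tuned
on a grid of ``grid_size`` alphas and lambdas evenly spaced in [0, 1]
(default 20 x 20 = 400 parameter sets), choosing the pair with the best
mean weighted log-loss across stratified folds; ties break toward the
larger lambda, then the larger alpha.  Probabilities are calibrated by
Platt scaling fitted on inner-CV held-out predictions — a strictly monotone
map, so AUROC is unchanged.

Integration strategies over per-modality feature panels:

* forward feature selection (FFS): starting from a baseline modality (or
  the best single modality), greedily add the modality with the best mean
  inner-CV AUROC, recording the held-out test AUROC at every complexity;
* concatenation: one model on all panels' columns;
* ensemble stacking: per-modality out-of-fold predictions feed an
  elastic-net meta model.

The number of modalities to keep is chosen where the test-AUROC
distribution stops improving (one-sided Wilcoxon rank-sum, p < 0.05), and
the final model aggregates per-resample feature importances by robust rank
aggregation before an unpenalised refit supplies signed t-statistics.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .core_io import Config, UsageLog, ValidationError, derive_seed
from .rra import aggregate_ranks

logger = logging.getLogger("modfuse.integrate")

PROB_CLIP = 1e-15
UNPENALISED_MAX_ITER = 10_000
_clip_warned = False


class ConvergenceError(ValidationError):
    pass


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def class_weight_vector(y: np.ndarray) -> np.ndarray:
    """Balanced observation weights w_i = n / (2 * n_class(i))."""
    y = np.asarray(y)
    n = y.size
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValidationError("both classes required for class weights")
    return np.where(y == 1, n / (2.0 * n1), n / (2.0 * n0))


def weighted_log_loss(
    labels: np.ndarray, probabilities: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """-sum w_i [y_i log p_i + (1-y_i) log(1-p_i)] / sum w_i.

    Probabilities at exactly 0 or 1 are clipped to [1e-15, 1 - 1e-15] with
    a warning.
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if weights is None:
        weights = np.ones_like(y)
    w = np.asarray(weights, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        global _clip_warned
        if not _clip_warned:
            logger.warning("probabilities at 0/1 clipped to %.0e "
                           "(warned once)", PROB_CLIP)
            _clip_warned = True
        p = np.clip(p, PROB_CLIP, 1 - PROB_CLIP)
    ll = y * np.log(p) + (1 - y) * np.log1p(-p)
    return float(-(w * ll).sum() / w.sum())


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(score_case > score_control) + 0.5 P(equal)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes required for AUROC")
    ranks = stats.rankdata(s)
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------


@dataclass
class ElasticNetModel:
    alpha: float
    lam: float
    coefficients: pd.Series
    intercept: float
    class_weights: dict[int, float]

    def decision(self, X: pd.DataFrame) -> np.ndarray:
        Xa = X[self.coefficients.index].to_numpy(dtype=float)
        return Xa @ self.coefficients.to_numpy() + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(X)))


def _sklearn_fit(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float, sw: np.ndarray,
    warm: LogisticRegression | None = None, max_iter: int = 5000,
) -> LogisticRegression:
    if lam <= 0:
        est = LogisticRegression(C=np.inf, solver="lbfgs",
                                 max_iter=UNPENALISED_MAX_ITER)
    else:
        C = 1.0 / (lam * sw.sum())
        if warm is not None and warm.get_params()["l1_ratio"] == alpha:
            est = warm
            est.C = C
        else:
            est = LogisticRegression(
                solver="saga", l1_ratio=float(alpha), C=C,
                max_iter=max_iter, tol=1e-5, warm_start=True,
            )
    est.fit(X, y, sample_weight=sw)
    return est


def fit_weighted_elastic_net(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    alpha: float,
    lam: float,
    class_weights: dict[int, float] | None = None,
    usage_log: UsageLog | None = None,
    stage: str = "fit",
) -> ElasticNetModel:
    """Fit a class-weighted elastic-net logistic model.

    ``lam = 0`` gives the unpenalised weighted logistic fit.  Raises
    :class:`ConvergenceError` if the solver exhausts its iterations.
    """
    yv = np.asarray(y)
    if not 0 <= alpha <= 1 or lam < 0:
        raise ValidationError("alpha in [0,1] and lambda >= 0 required")
    if class_weights is None:
        w = class_weight_vector(yv)
    else:
        w = np.where(yv == 1, class_weights[1], class_weights[0])
    if usage_log is not None:
        usage_log.record(stage, "fit", list(X.index))
    est = _sklearn_fit(X.to_numpy(dtype=float), yv, alpha, lam, w,
                       max_iter=20_000)
    if int(np.max(est.n_iter_)) >= est.max_iter:
        raise ConvergenceError(
            f"elastic net did not converge (alpha={alpha}, lambda={lam}, "
            f"n={len(X)}, p={X.shape[1]}, iterations={int(np.max(est.n_iter_))})"
        )
    n1 = int(yv.sum())
    n0 = yv.size - n1
    coefs = pd.Series(est.coef_[0], index=X.columns)
    intercept = float(est.intercept_[0])
    if (coefs == 0.0).all():
        # fully shrunk model: the optimal intercept is the weighted log-odds
        pbar = float((w * yv).sum() / w.sum())
        intercept = float(np.log(pbar / (1 - pbar)))
    return ElasticNetModel(
        alpha=float(alpha),
        lam=float(lam),
        coefficients=coefs,
        intercept=intercept,
        class_weights={0: float(yv.size / (2 * n0)), 1: float(yv.size / (2 * n1))}
        if class_weights is None else dict(class_weights),
    )


@dataclass
class TuneResult:
    alpha: float
    lam: float
    cv_table: pd.DataFrame  # alpha, lam, mean_wll, mean_auroc
    oof_pred: np.ndarray  # held-out predictions at the chosen combination
    cv_auroc: float  # mean fold AUROC at the chosen combination
    n_combinations: int


def tune_elastic_net(
    X: pd.DataFrame,
    y: pd.Series,
    folds: list[tuple[np.ndarray, np.ndarray]],
    grid_size: int = 20,
    usage_log: UsageLog | None = None,
    stage: str = "tune",
) -> TuneResult:
    """Grid-search (alpha, lambda) on [0,1] x [0,1] by mean weighted
    log-loss across folds.

    ``grid_size`` values per axis are evenly spaced, so the default 20
    enumerates 400 combinations.  Lambdas are swept descending with warm
    starts.  Ties break toward larger lambda, then larger alpha.  Each fold
    must contain both classes in training and validation.
    """
    yv = y.to_numpy() if isinstance(y, pd.Series) else np.asarray(y)
    Xv = X.to_numpy(dtype=float)
    if grid_size == 1:
        alphas = lambdas = np.array([0.0])
    else:
        alphas = np.linspace(0.0, 1.0, grid_size)
        lambdas = np.linspace(0.0, 1.0, grid_size)
    lam_desc = lambdas[::-1]
    if usage_log is not None:
        usage_log.record(stage, "tune", list(X.index))

    import warnings

    from sklearn.exceptions import ConvergenceWarning

    n_combo = alphas.size * lambdas.size
    wll = np.zeros((alphas.size, lambdas.size))
    aur = np.zeros((alphas.size, lambdas.size))
    oof = np.zeros((alphas.size, lambdas.size, len(X)))
    with warnings.catch_warnings():
        # grid evaluation tolerates approximate fits; the chosen
        # combination is refit with enforced convergence
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr_idx, va_idx in folds:
            ytr, yva = yv[tr_idx], yv[va_idx]
            if len(np.unique(ytr)) < 2 or len(np.unique(yva)) < 2:
                raise ValidationError("a fold is missing a class")
            sw = class_weight_vector(ytr)
            wva = class_weight_vector(yv)[va_idx]  # full-data prevalence
            Xtr, Xva = Xv[tr_idx], Xv[va_idx]
            for a_i, alpha in enumerate(alphas):
                warm = None
                for l_pos, lam in enumerate(lam_desc):
                    est = _sklearn_fit(Xtr, ytr, alpha, lam, sw, warm=warm)
                    if lam > 0:
                        warm = est
                    p = est.predict_proba(Xva)[:, 1]
                    l_i = lambdas.size - 1 - l_pos
                    wll[a_i, l_i] += weighted_log_loss(yva, p, wva) / len(folds)
                    aur[a_i, l_i] += auroc(yva, p) / len(folds)
                    oof[a_i, l_i, va_idx] = p

    # ties toward larger lambda, then larger alpha
    best = min(
        ((wll[a_i, l_i], -lambdas[l_i], -alphas[a_i], a_i, l_i)
         for a_i in range(alphas.size) for l_i in range(lambdas.size)),
    )
    _, _, _, a_i, l_i = best
    table = pd.DataFrame(
        {
            "alpha": np.repeat(alphas, lambdas.size),
            "lam": np.tile(lambdas, alphas.size),
            "mean_wll": wll.ravel(),
            "mean_auroc": aur.ravel(),
        }
    )
    return TuneResult(
        alpha=float(alphas[a_i]),
        lam=float(lambdas[l_i]),
        cv_table=table,
        oof_pred=oof[a_i, l_i],
        cv_auroc=float(aur[a_i, l_i]),
        n_combinations=n_combo,
    )


# ---------------------------------------------------------------------------
# Platt calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationModel:
    slope: float
    intercept: float


def platt_fit(raw_scores: np.ndarray, labels: np.ndarray) -> CalibrationModel:
    """One-dimensional logistic fit of label on raw score."""
    s = np.asarray(raw_scores, dtype=float)
    y = np.asarray(labels)
    if np.ptp(s) == 0:
        raise ValidationError("constant scores: Platt slope unidentifiable")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes required for Platt scaling")
    est = LogisticRegression(C=np.inf, solver="lbfgs",
                             max_iter=UNPENALISED_MAX_ITER)
    est.fit(s.reshape(-1, 1), y)
    return CalibrationModel(float(est.coef_[0, 0]), float(est.intercept_[0]))


def platt_apply(model: CalibrationModel, raw_scores: np.ndarray) -> np.ndarray:
    s = np.asarray(raw_scores, dtype=float)
    return 1.0 / (1.0 + np.exp(-(model.slope * s + model.intercept)))


# ---------------------------------------------------------------------------
# Forward feature selection over modalities
# ---------------------------------------------------------------------------


@dataclass
class FFSTrace:
    records: pd.DataFrame  # resample, k, modality_added, cv_auroc, test_auroc
    models: dict = field(default_factory=dict)  # (resample, k) -> model info

    def aurocs_at(self, k: int) -> np.ndarray:
        r = self.records
        return r.loc[r["k"] == k, "test_auroc"].to_numpy()

    def complexities(self) -> list[int]:
        return sorted(self.records["k"].unique())

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in self.complexities():
            a = self.aurocs_at(k)
            q1, med, q3 = np.percentile(a, [25, 50, 75])
            rows.append((k, med, q1, q3, a.mean(), len(a)))
        return pd.DataFrame(
            rows, columns=["k", "median_auroc", "q1", "q3", "mean_auroc", "n"]
        )


def _concat_panels(
    panels: dict[str, pd.DataFrame], modalities: list[str], ids
) -> pd.DataFrame:
    pieces = []
    seen: set[str] = set()
    for m in modalities:
        p = panels[m].loc[list(ids)]
        dup = [c for c in p.columns if c in seen]
        if dup:
            logger.info("suffixing %d duplicated feature ids from %s", len(dup), m)
            p = p.rename(columns={c: f"{c}__{m}" for c in dup})
        seen.update(p.columns)
        pieces.append(p)
    return pd.concat(pieces, axis=1)


def ffs_integrate(
    panels: dict[str, pd.DataFrame],
    labels: pd.Series,
    plan,
    baseline: str | None,
    config: Config,
    usage_log: UsageLog | None = None,
) -> FFSTrace:
    """Greedy forward selection of modalities under nested cross-validation.

    Per resample: start from ``baseline`` (or the best single modality when
    None); at each step evaluate each remaining modality by tuning an
    elastic net on the current + candidate features with the resample's
    inner folds, scoring by mean inner-CV AUROC; add the best (ties to the
    alphabetically earlier modality).  Each step's model is refit on the
    full training split, Platt-calibrated on its inner-CV held-out
    predictions, and scored on the held-out 20% test split.
    """
    available = sorted(m for m in panels if panels[m].shape[1] > 0)
    skipped = sorted(set(panels) - set(available))
    for m in skipped:
        logger.warning("modality %s has an empty panel; skipped", m)
    if baseline is not None and baseline not in available:
        raise ValidationError(f"baseline modality {baseline!r} not available")
    records = []
    models = {}
    for r_i, (train_ids, test_ids) in enumerate(plan.splits):
        ytr = labels.loc[train_ids]
        yte = labels.loc[test_ids]
        folds = plan.folds[r_i]
        stage = f"ffs:resample{r_i}"
        current: list[str] = []
        remaining = list(available)
        k = 0
        while remaining:
            k += 1
            if k == 1 and baseline is not None:
                choice, choice_tune = baseline, None
            else:
                choice, choice_tune, best_cv = None, None, -np.inf
                for cand in remaining:
                    Xtr = _concat_panels(panels, current + [cand], train_ids)
                    res = tune_elastic_net(
                        Xtr, ytr, folds,
                        grid_size=config.grid_size,
                        usage_log=usage_log, stage=f"{stage}:k{k}:{cand}",
                    )
                    if res.cv_auroc > best_cv:
                        choice, choice_tune, best_cv = cand, res, res.cv_auroc
            current.append(choice)
            remaining.remove(choice)
            Xtr = _concat_panels(panels, current, train_ids)
            if choice_tune is None:
                choice_tune = tune_elastic_net(
                    Xtr, ytr, folds, grid_size=config.grid_size,
                    usage_log=usage_log, stage=f"{stage}:k{k}:baseline",
                )
            model = fit_weighted_elastic_net(
                Xtr, ytr, choice_tune.alpha, choice_tune.lam,
                usage_log=usage_log, stage=f"{stage}:k{k}",
            )
            cal = platt_fit(choice_tune.oof_pred, ytr.to_numpy())
            Xte = _concat_panels(panels, current, test_ids)
            p_test = platt_apply(cal, model.predict_proba(Xte))
            if usage_log is not None:
                usage_log.record(f"{stage}:k{k}", "evaluate", list(test_ids))
            records.append(
                (r_i, k, choice, choice_tune.cv_auroc, auroc(yte.to_numpy(), p_test))
            )
            models[(r_i, k)] = {
                "modalities": tuple(current),
                "alpha": choice_tune.alpha,
                "lam": choice_tune.lam,
                "coefficients": model.coefficients,
                "calibration": cal,
            }
    trace = FFSTrace(
        records=pd.DataFrame(
            records, columns=["resample", "k", "modality_added", "cv_auroc",
                              "test_auroc"]
        ),
        models=models,
    )
    return trace


def concat_integrate(
    panels: dict[str, pd.DataFrame],
    labels: pd.Series,
    plan,
    config: Config,
    usage_log: UsageLog | None = None,
) -> pd.DataFrame:
    """All panels concatenated into a single model per resample."""
    available = sorted(m for m in panels if panels[m].shape[1] > 0)
    rows = []
    for r_i, (train_ids, test_ids) in enumerate(plan.splits):
        stage = f"concat:resample{r_i}"
        ytr = labels.loc[train_ids]
        Xtr = _concat_panels(panels, available, train_ids)
        res = tune_elastic_net(Xtr, ytr, plan.folds[r_i],
                               grid_size=config.grid_size,
                               usage_log=usage_log, stage=stage)
        model = fit_weighted_elastic_net(Xtr, ytr, res.alpha, res.lam,
                                         usage_log=usage_log, stage=stage)
        cal = platt_fit(res.oof_pred, ytr.to_numpy())
        Xte = _concat_panels(panels, available, test_ids)
        p = platt_apply(cal, model.predict_proba(Xte))
        if usage_log is not None:
            usage_log.record(stage, "evaluate", list(test_ids))
        rows.append((r_i, auroc(labels.loc[test_ids].to_numpy(), p)))
    return pd.DataFrame(rows, columns=["resample", "test_auroc"])


def stacking_integrate(
    panels: dict[str, pd.DataFrame],
    labels: pd.Series,
    plan,
    config: Config,
    usage_log: UsageLog | None = None,
) -> pd.DataFrame:
    """Ensemble stacking: per-modality out-of-fold predictions on the
    training split feed an elastic-net meta model; base models refit on the
    full training split feed the meta model at test time."""
    available = sorted(m for m in panels if panels[m].shape[1] > 0)
    rows = []
    for r_i, (train_ids, test_ids) in enumerate(plan.splits):
        stage = f"stacking:resample{r_i}"
        ytr = labels.loc[train_ids]
        folds = plan.folds[r_i]
        oof_cols, test_cols, used = [], [], []
        for m in available:
            Xtr = panels[m].loc[list(train_ids)]
            res = tune_elastic_net(Xtr, ytr, folds, grid_size=config.grid_size,
                                   usage_log=usage_log, stage=f"{stage}:{m}")
            if np.ptp(res.oof_pred) == 0:
                logger.warning("modality %s produced constant predictions; "
                               "excluded from meta design", m)
                continue
            model = fit_weighted_elastic_net(Xtr, ytr, res.alpha, res.lam,
                                             usage_log=usage_log,
                                             stage=f"{stage}:{m}")
            oof_cols.append(res.oof_pred)
            test_cols.append(model.predict_proba(panels[m].loc[list(test_ids)]))
            used.append(m)
        if not used:
            raise ValidationError("no modality produced usable predictions")
        Z = pd.DataFrame(np.column_stack(oof_cols), index=list(train_ids),
                         columns=used)
        # standardise the meta design so coefficient magnitudes compare
        mu, sd = Z.mean(), Z.std(ddof=1)
        Z = (Z - mu) / sd
        res_meta = tune_elastic_net(Z, ytr, folds, grid_size=config.grid_size,
                                    usage_log=usage_log, stage=f"{stage}:meta")
        meta = fit_weighted_elastic_net(Z, ytr, res_meta.alpha, res_meta.lam,
                                        usage_log=usage_log, stage=f"{stage}:meta")
        Zte = pd.DataFrame(np.column_stack(test_cols), index=list(test_ids),
                           columns=used)
        Zte = (Zte - mu) / sd
        p = meta.predict_proba(Zte)
        if usage_log is not None:
            usage_log.record(stage, "evaluate", list(test_ids))
        rows.append((r_i, auroc(labels.loc[test_ids].to_numpy(), p),
                     meta.coefficients.abs().idxmax()))
    return pd.DataFrame(rows, columns=["resample", "test_auroc",
                                       "top_meta_modality"])


def threshold_select(matrix, labels, p_cut: float = 0.05) -> list[str]:
    """Benchmark selector: features with unadjusted moderated-t p < p_cut."""
    from .rank import moderated_t_association

    assoc = moderated_t_association(matrix, labels)
    return assoc.loc[assoc["p_value"] < p_cut, "feature_id"].tolist()


# ---------------------------------------------------------------------------
# Complexity choice and the final model
# ---------------------------------------------------------------------------


def choose_complexity(trace: FFSTrace, alpha: float = 0.05) -> int:
    """Largest k whose test-AUROC distribution significantly improves on
    k-1 (one-sided Wilcoxon rank-sum, p < alpha) with no significant
    improvement at any later complexity; 1 if no step improves."""
    ks = trace.complexities()
    if len(ks) < 2:
        logger.warning("fewer than 2 complexities; returning k*=1")
        return 1
    k_star = 1
    for k_prev, k in zip(ks[:-1], ks[1:]):
        a_prev = trace.aurocs_at(k_prev)
        a_k = trace.aurocs_at(k)
        p = stats.mannwhitneyu(a_k, a_prev, alternative="greater").pvalue
        if p < alpha:
            k_star = k
    return int(k_star)


@dataclass
class FinalModelReport:
    k_star: int
    combination_counts: Counter
    consensus_features: pd.DataFrame  # feature_id, importance, sign
    model: ElasticNetModel


def _importance_t_statistics(
    X: pd.DataFrame, y: pd.Series, fallback: pd.Series
) -> pd.Series:
    """Wald t/z statistics from an unpenalised logistic refit; falls back to
    penalised coefficients (with a warning) when the refit is degenerate."""
    import warnings

    import statsmodels.api as sm

    try:
        design = sm.add_constant(X.to_numpy(dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is handled below
            fit = sm.Logit(y.to_numpy(), design).fit(disp=0, maxiter=200)
        t = pd.Series(fit.tvalues[1:], index=X.columns)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite t-statistics")
        return t
    except Exception as exc:  # separation / singular design
        logger.warning("unpenalised refit failed (%s); using penalised "
                       "coefficients as importance", exc)
        return fallback.reindex(X.columns).fillna(0.0)


def build_final_model(
    trace: FFSTrace,
    panels: dict[str, pd.DataFrame],
    labels: pd.Series,
    k_star: int,
    config: Config,
    usage_log: UsageLog | None = None,
) -> FinalModelReport:
    """Aggregate per-resample importances at complexity k* by RRA, then
    train the final class-weighted elastic net on the whole training pool
    restricted to consensus features."""
    rankings = []
    combos = Counter()
    n_models = 0
    for (r_i, k), info in sorted(trace.models.items()):
        if k != k_star:
            continue
        n_models += 1
        combos[info["modalities"]] += 1
        coefs = info["coefficients"]
        nonzero = coefs[coefs != 0.0]
        if nonzero.empty:
            continue  # all-zero model contributes no ranks
        order = sorted(nonzero.index, key=lambda f: (-abs(nonzero[f]), str(f)))
        rankings.append(order)
    if not rankings:
        raise ValidationError(
            "no non-zero models at the chosen complexity; lower the FDR or "
            "increase resamples"
        )
    universe = len({c for p in panels.values() for c in p.columns})
    agg = aggregate_ranks(rankings, universe_size=universe, n_lists=n_models)
    consensus = agg.significant(config.rra_fdr)
    if not consensus:
        raise ValidationError(
            "empty consensus at FDR "
            f"{config.rra_fdr}; lower the FDR or increase resamples"
        )
    all_feats = _concat_panels(panels, sorted(panels), labels.index)
    consensus = [f for f in consensus if f in all_feats.columns]
    X = all_feats[sorted(consensus)]

    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True,
        random_state=derive_seed(config.master_seed, "final_model"),
    )
    folds = list(skf.split(np.zeros(len(X)), labels.loc[X.index].to_numpy()))
    res = tune_elastic_net(X, labels, folds, grid_size=config.grid_size,
                           usage_log=usage_log, stage="final:tune")
    model = fit_weighted_elastic_net(X, labels, res.alpha, res.lam,
                                     usage_log=usage_log, stage="final:fit")
    importance = _importance_t_statistics(X, labels, model.coefficients)
    table = pd.DataFrame(
        {
            "feature_id": X.columns,
            "importance": importance.to_numpy(),
            "sign": np.sign(importance.to_numpy()),
        }
    ).sort_values("importance", key=np.abs, ascending=False, kind="mergesort")
    return FinalModelReport(
        k_star=k_star,
        combination_counts=combos,
        consensus_features=table.reset_index(drop=True),
        model=model,
    )
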