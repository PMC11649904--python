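"""Per-modality feature selection and cohort partitioning.

The cohort splits into two disjoint pools: samples measured in every
modality form the final-training pool, and samples lacking at least one
modality form the per-modality selection pools.  Within a selection pool,
the consensus protocol runs per modality:

1. over stratified 80/20 resamples - rank features on the training split,
   run preranked set enrichment (FDR < 20%), pool the significant sets'
   leading edges, fit a class-weighted elastic net on those features, and
   screen the resample by its held-out AUROC (> 0.5 keeps it);
2. aggregate the kept resamples' set rankings (by adjusted enrichment p)
   with robust rank aggregation at FDR 5%;
3. run one final enrichment on the whole selection pool restricted to the
   surviving sets; their leading-edge features are the modality's panel.

Clinical features skip enrichment: per resample an elastic net is tuned
and refit without penalty, features are ranked by the magnitude of their
Wald t-statistics (zero-coefficient features contribute no rank), and the
ranks are aggregated with the same FDR-5% rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .core_io import (
    Config,
    FeatureMatrix,
    GeneSetCollection,
    PhenotypeTable,
    UsageLog,
    ValidationError,
    derive_seed,
)
from .enrich import RankedList, gsea_preranked
from .integrate import (
    _importance_t_statistics,
    auroc,
    fit_weighted_elastic_net,
    tune_elastic_net,
)
from .rank import (
    GeneAnnotationMap,
    cpg_gene_scores,
    moderated_t_association,
    snp_gene_zscores,
)
from .rra import aggregate_ranks

logger = logging.getLogger("modfuse.select")


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def partition_cohort(
    matrices: dict[str, FeatureMatrix], labels: PhenotypeTable
) -> tuple[dict[str, list[str]], list[str]]:
    """Split samples into per-modality selection pools and the training pool.

    Training pool: samples present in every modality.  Selection pool of a
    modality: its samples that are absent from at least one other modality.
    The pools are disjoint by construction.
    """
    labelled = set(labels.sample_ids)
    per_mod = {m: set(fm.sample_ids) & labelled for m, fm in matrices.items()}
    training = set.intersection(*per_mod.values()) if per_mod else set()
    if not training:
        raise ValidationError("no fully characterised samples for training")
    selection = {m: sorted(ids - training) for m, ids in per_mod.items()}
    return selection, sorted(training)


@dataclass
class ResamplePlan:
    """Stratified 80/20 splits with stratified inner folds per resample.

    ``splits[r]`` is (train_ids, test_ids); ``folds[r]`` holds positional
    (train, validation) index pairs into ``splits[r][0]``.
    """

    splits: list[tuple[list[str], list[str]]]
    folds: list[list[tuple[np.ndarray, np.ndarray]]]
    seed: int


def make_resample_plan(
    labels: pd.Series | PhenotypeTable,
    n_resamples: int,
    train_fraction: float = 0.8,
    n_folds: int = 5,
    seed: int = 0,
) -> ResamplePlan:
    if isinstance(labels, PhenotypeTable):
        labels = labels.labels()
    y = labels.to_numpy()
    ids = np.asarray(labels.index.astype(str))
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    if min(n_case, n_ctrl) < n_folds:
        raise ValidationError(
            f"minority class has {min(n_case, n_ctrl)} samples; "
            f"at least {n_folds} required for {n_folds}-fold stratification"
        )
    splits, folds = [], []
    for r in range(n_resamples):
        sss = StratifiedShuffleSplit(
            n_splits=1, train_size=train_fraction,
            random_state=derive_seed(seed, "split", r),
        )
        (tr_idx, te_idx), = sss.split(np.zeros(len(y)), y)
        tr_idx, te_idx = np.sort(tr_idx), np.sort(te_idx)
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=derive_seed(seed, "folds", r),
        )
        fold_pairs = [
            (tr, va) for tr, va in skf.split(np.zeros(len(tr_idx)), y[tr_idx])
        ]
        splits.append((ids[tr_idx].tolist(), ids[te_idx].tolist()))
        folds.append(fold_pairs)
    return ResamplePlan(splits=splits, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# Rankers
# ---------------------------------------------------------------------------


def make_moderated_t_ranker(moderated: bool = True):
    """Feature-level ranker: moderated t; genes are the features themselves."""

    def ranker(matrix: FeatureMatrix, labels: PhenotypeTable):
        assoc = moderated_t_association(matrix, labels, moderated=moderated)
        stats_series = pd.Series(
            assoc["t_statistic"].to_numpy(), index=assoc["feature_id"]
        )
        return RankedList.from_series(stats_series), None

    return ranker


def make_snp_ranker(annotation: GeneAnnotationMap,
                    pc_variance_fraction: float = 0.999):
    """Gene-level ranker for genotype dosages (PC-regression z-scores)."""

    def ranker(matrix: FeatureMatrix, labels: PhenotypeTable):
        table = snp_gene_zscores(
            matrix, annotation, labels,
            pc_variance_fraction=pc_variance_fraction,
        )
        stats_series = pd.Series(
            table["z_value"].to_numpy(), index=table["gene_id"]
        )
        return RankedList.from_series(stats_series), annotation.by_gene()

    return ranker


def make_cpg_ranker(annotation: GeneAnnotationMap, moderated: bool = True):
    """Gene-level ranker for methylation (rank-aggregated CpG p-values)."""

    def ranker(matrix: FeatureMatrix, labels: PhenotypeTable):
        assoc = moderated_t_association(matrix, labels, moderated=moderated)
        table = cpg_gene_scores(assoc, annotation)
        stats_series = pd.Series(
            table["z_value"].to_numpy(), index=table["gene_id"]
        )
        return RankedList.from_series(stats_series), annotation.by_gene()

    return ranker


def default_ranker_for(
    modality: str,
    annotation: GeneAnnotationMap | None = None,
    config: Config | None = None,
):
    config = config or Config()
    if modality == "genomic":
        if annotation is None:
            raise ValidationError("genomic ranking requires a SNP->gene map")
        return make_snp_ranker(annotation, config.pc_variance_fraction)
    if modality == "methylomic":
        if annotation is None:
            raise ValidationError("methylomic ranking requires a CpG->gene map")
        return make_cpg_ranker(annotation, config.moderated_t)
    return make_moderated_t_ranker(config.moderated_t)


# ---------------------------------------------------------------------------
# Molecular consensus selection
# ---------------------------------------------------------------------------


@dataclass
class ConsensusSelection:
    modality: str
    consensus_sets: pd.DataFrame  # set_id, bh_adjusted_p
    selected_features: list[str]
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)


def _features_of_genes(genes, gene_map, matrix: FeatureMatrix) -> list[str]:
    present = set(matrix.feature_ids)
    if gene_map is None:
        return sorted(g for g in genes if g in present)
    out = set()
    for g in genes:
        out.update(f for f in gene_map.get(g, ()) if f in present)
    return sorted(out)


def _ranking_key(result) -> tuple:
    # permutation p-values are discrete, so ties are common with few sets;
    # break them by enrichment strength before the id so rank lists carry
    # evidence, not lexicographic bias
    return (result.adjusted_p, result.p_value, -abs(result.es),
            result.set_id)


def select_molecular_features(
    matrix: FeatureMatrix,
    labels: PhenotypeTable,
    sets: GeneSetCollection,
    plan: ResamplePlan,
    config: Config,
    ranker=None,
    annotation: GeneAnnotationMap | None = None,
    usage_log: UsageLog | None = None,
    single_pass: bool = False,
) -> ConsensusSelection:
    """Resampled enrichment + elastic-net screen + rank-aggregation
    consensus for one molecular modality (see module docstring).

    With ``single_pass=True`` (small cohorts, e.g. the proteomic layer) a
    single enrichment on the whole pool replaces the resampling consensus.
    """
    if ranker is None:
        ranker = default_ranker_for(matrix.modality, annotation, config)
    mod = matrix.modality
    gene_map = None

    def final_selection(surviving_ids: list[str]) -> tuple[pd.DataFrame, list[str]]:
        """Enrichment on the full pool restricted to the surviving sets."""
        ranked_full, gmap = ranker(matrix, labels)
        results = gsea_preranked(
            ranked_full, sets.subset(surviving_ids),
            n_permutations=config.n_permutations,
            min_size=config.gsea_min_size, max_size=config.gsea_max_size,
            weight_exponent=config.gsea_weight_exponent,
            seed=derive_seed(config.master_seed, "consensus_gsea", mod),
        )
        genes = set()
        for res in results:
            genes.update(res.leading_edge)
        feats = _features_of_genes(genes, gmap, matrix)
        table = pd.DataFrame(
            {"set_id": [r.set_id for r in results],
             "adjusted_p": [r.adjusted_p for r in results]}
        )
        return table, feats

    if single_pass:
        ranked, gene_map = ranker(matrix, labels)
        results = gsea_preranked(
            ranked, sets, n_permutations=config.n_permutations,
            min_size=config.gsea_min_size, max_size=config.gsea_max_size,
            weight_exponent=config.gsea_weight_exponent,
            seed=derive_seed(config.master_seed, "single_pass", mod),
        )
        sig = sorted(
            (r for r in results if r.adjusted_p < config.gsea_fdr),
            key=_ranking_key,
        )
        if not sig:
            logger.warning("%s: no enriched sets in single-pass mode", mod)
            return ConsensusSelection(mod, pd.DataFrame(
                columns=["set_id", "bh_adjusted_p"]), [], pd.DataFrame())
        genes = set()
        for r in sig:
            genes.update(r.leading_edge)
        feats = _features_of_genes(genes, gene_map, matrix)
        table = pd.DataFrame(
            {"set_id": [r.set_id for r in sig],
             "bh_adjusted_p": [r.adjusted_p for r in sig]}
        )
        return ConsensusSelection(mod, table, feats, pd.DataFrame())

    rankings: list[list[str]] = []
    audit_rows = []
    for r_i, (train_ids, test_ids) in enumerate(plan.splits):
        stage = f"select:{mod}:resample{r_i}"
        mtrain = matrix.subset_samples(train_ids)
        if usage_log is not None:
            usage_log.record(stage, "fit", train_ids)
        ranked, gene_map = ranker(mtrain, labels)
        results = gsea_preranked(
            ranked, sets, n_permutations=config.n_permutations,
            min_size=config.gsea_min_size, max_size=config.gsea_max_size,
            weight_exponent=config.gsea_weight_exponent,
            seed=derive_seed(config.master_seed, "gsea", mod, r_i),
        )
        sig = sorted(
            (r for r in results if r.adjusted_p < config.gsea_fdr),
            key=_ranking_key,
        )
        if not sig:
            audit_rows.append((r_i, 0, np.nan, False))
            continue
        genes = set()
        for res in sig:
            genes.update(res.leading_edge)
        feats = _features_of_genes(genes, gene_map, mtrain)
        if not feats:
            audit_rows.append((r_i, len(sig), np.nan, False))
            continue
        Xtr = mtrain.data[feats].fillna(0.0)
        ytr = labels.labels(train_ids)
        tune = tune_elastic_net(
            Xtr, ytr, plan.folds[r_i], grid_size=config.screen_grid_size,
            usage_log=usage_log, stage=stage,
        )
        model = fit_weighted_elastic_net(
            Xtr, ytr, tune.alpha, tune.lam, usage_log=usage_log, stage=stage,
        )
        Xte = matrix.subset_samples(test_ids).data[feats].fillna(0.0)
        score = auroc(
            labels.labels(test_ids).to_numpy(), model.predict_proba(Xte)
        )
        if usage_log is not None:
            usage_log.record(stage, "evaluate", test_ids)
        kept = score > config.auroc_screen
        audit_rows.append((r_i, len(sig), score, kept))
        if kept:
            rankings.append([r.set_id for r in sig])

    audit = pd.DataFrame(
        audit_rows, columns=["resample", "n_significant_sets",
                             "screen_auroc", "kept"]
    )
    if not rankings:
        logger.warning("%s: no predictive resamples; empty selection", mod)
        return ConsensusSelection(mod, pd.DataFrame(
            columns=["set_id", "bh_adjusted_p"]), [], audit)
    agg = aggregate_ranks(rankings, universe_size=len(sets),
                          n_lists=len(plan.splits))
    surviving = agg.significant(config.rra_fdr)
    if not surviving:
        logger.warning("%s: rank aggregation kept no sets", mod)
        return ConsensusSelection(mod, pd.DataFrame(
            columns=["set_id", "bh_adjusted_p"]), [], audit)
    _, feats = final_selection(surviving)
    table = agg.table.loc[
        agg.table["item_id"].isin(surviving), ["item_id", "bh_adjusted_p"]
    ].rename(columns={"item_id": "set_id"})
    return ConsensusSelection(mod, table.reset_index(drop=True), feats, audit)


# ---------------------------------------------------------------------------
# Clinical selection
# ---------------------------------------------------------------------------


def select_clinical_features(
    clinical: FeatureMatrix,
    labels: PhenotypeTable,
    plan: ResamplePlan,
    config: Config,
    usage_log: UsageLog | None = None,
    importance: str = "wald",
) -> tuple[list[str], pd.DataFrame]:
    """Consensus clinical features across resampled elastic nets.

    Per resample the tuned model's non-zero-coefficient features are ranked
    by importance magnitude (Wald t from an unpenalised refit by default,
    ``importance='coef'`` for |coefficient|); zero-coefficient features
    contribute no rank.  Rankings are aggregated at FDR ``rra_fdr``.
    """
    rankings = []
    audit_rows = []
    for r_i, (train_ids, test_ids) in enumerate(plan.splits):
        stage = f"select:clinical:resample{r_i}"
        Xtr = clinical.data.loc[train_ids].fillna(0.0)
        ytr = labels.labels(train_ids)
        tune = tune_elastic_net(
            Xtr, ytr, plan.folds[r_i], grid_size=config.screen_grid_size,
            usage_log=usage_log, stage=stage,
        )
        model = fit_weighted_elastic_net(
            Xtr, ytr, tune.alpha, tune.lam, usage_log=usage_log, stage=stage,
        )
        nonzero = model.coefficients[model.coefficients != 0.0]
        if nonzero.empty:
            audit_rows.append((r_i, 0))
            continue
        if importance == "wald":
            scores = _importance_t_statistics(
                Xtr[list(nonzero.index)], ytr, nonzero
            )
        else:
            scores = nonzero
        scores = scores[scores != 0.0]
        if scores.empty:
            audit_rows.append((r_i, 0))
            continue
        order = sorted(scores.index, key=lambda f: (-abs(scores[f]), str(f)))
        rankings.append(order)
        audit_rows.append((r_i, len(order)))
    audit = pd.DataFrame(audit_rows, columns=["resample", "n_ranked"])
    if not rankings:
        logger.warning("clinical: all models empty; no features selected")
        return [], audit
    agg = aggregate_ranks(rankings, universe_size=clinical.shape[1],
                          n_lists=len(plan.splits))
    return sorted(agg.significant(config.rra_fdr)), audit
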