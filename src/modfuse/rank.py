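"""Univariate association and gene-level aggregation of SNPs and CpGs.

Three rankers feed the enrichment stage:

* continuous modalities - per-feature two-group linear model with an
  empirical-Bayes moderated t statistic (feature variances shrunk toward a
  pooled prior fitted by method of moments on log variances, as in limma);
* genotypes - per gene, principal components of the gene's SNP dosages are
  regressed on the label and the overall F-test p is probit-transformed to
  a one-sided z (MAGMA-style);
* methylation - CpG-level p-values are aggregated per gene by robust rank
  aggregation of the CpGs' positions in the global ranking, and the gene
  p-value is probit-transformed to a z signed by the mean CpG t
  (methylRRA-style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_io import FeatureMatrix, PhenotypeTable, ValidationError
from .rra import adjust_bh, beta_score, rho_null_cdf

logger = logging.getLogger("modfuse.rank")

T_CAP = 1e8  # cap for infinite t on perfectly separated features
P_FLOOR = 1e-300


@dataclass
class GeneAnnotationMap:
    """feature_id (SNP/CpG) -> gene id(s); unmapped features are absent."""

    mapping: dict[str, tuple[str, ...]]

    def genes(self) -> list[str]:
        return sorted({g for gs in self.mapping.values() for g in gs})

    def features_of(self, gene: str) -> list[str]:
        return sorted(f for f, gs in self.mapping.items() if gene in gs)

    def by_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for f, gs in self.mapping.items():
            for g in gs:
                out.setdefault(g, []).append(f)
        return {g: sorted(fs) for g, fs in out.items()}


def _fit_f_dist_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) to residual
    variances, following the classic limma approach on log variances."""
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, d / 2))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    # solve trigamma(d0/2) = evar
    try:
        d0 = 2 * optimize.brentq(
            lambda x: special.polygamma(1, x) - evar, 1e-6, 1e6
        )
    except ValueError:
        return np.inf, float(np.exp(emean))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return float(d0), s0_sq


def moderated_t_association(
    matrix: FeatureMatrix,
    labels: PhenotypeTable,
    moderated: bool = True,
) -> pd.DataFrame:
    """Per-feature two-group association: moderated t, p and direction.

    Missing entries are ignored per feature.  With ``moderated=False`` (or a
    degenerate prior) the statistic reduces to the ordinary pooled-variance
    two-sample t.  Returns a table with columns feature_id, t_statistic,
    p_value, direction.
    """
    y = labels.labels(matrix.sample_ids).to_numpy()
    X = matrix.data.to_numpy(dtype=float)
    case = y == 1
    ctrl = y == 0
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValidationError("need at least 2 samples per class")
    obs = ~np.isnan(X)
    n1 = (obs & case[:, None]).sum(axis=0).astype(float)
    n0 = (obs & ctrl[:, None]).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        m1 = np.nansum(np.where(case[:, None], X, np.nan), axis=0) / n1
        m0 = np.nansum(np.where(ctrl[:, None], X, np.nan), axis=0) / n0
        centered = np.where(
            case[:, None], X - m1[None, :], X - m0[None, :]
        )
        rss = np.nansum(centered**2, axis=0)
    df = n1 + n0 - 2
    bad = (n1 < 2) | (n0 < 2) | (df <= 0)
    s2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)

    if moderated:
        d0, s0_sq = _fit_f_dist_prior(s2[~bad], df[~bad])
    else:
        d0, s0_sq = 0.0, 1.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / np.maximum(d0 + df, 1e-12)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    delta = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    t = np.where(np.isfinite(t), t, np.sign(delta) * T_CAP)
    t = np.clip(t, -T_CAP, T_CAP)
    finite_df = np.where(np.isfinite(df_total), df_total, 1e9)
    p = 2 * stats.t.sf(np.abs(t), finite_df)
    p = np.clip(p, P_FLOOR, 1.0)

    table = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "t_statistic": t,
            "p_value": p,
            "direction": np.sign(t),
        }
    )
    table = table[~bad].reset_index(drop=True)
    if table["feature_id"].duplicated().any():
        raise ValidationError("duplicate feature ids in association table")
    return table


def snp_gene_zscores(
    genotypes: FeatureMatrix,
    annotation: GeneAnnotationMap,
    labels: PhenotypeTable,
    pc_variance_fraction: float = 0.999,
    max_pc_divisor: int = 10,
) -> pd.DataFrame:
    """Gene-level association z from PC regression of the label on each
    gene's SNP dosages.

    Per gene: centre the (mean-imputed) SNP submatrix, take principal
    components up to ``pc_variance_fraction`` cumulative variance (capped at
    min(n_snps, n_samples/max_pc_divisor, n_samples - 2), at least one),
    regress the label on them, and convert the overall F-test p one-sided:
    z = Phi^{-1}(1 - p).  Genes whose SNPs are all constant are omitted.
    """
    y = labels.labels(genotypes.sample_ids).to_numpy(dtype=float)
    n = y.size
    rows = []
    data = genotypes.data
    for gene, snps in sorted(annotation.by_gene().items()):
        snps = [s for s in snps if s in data.columns]
        if not snps:
            continue
        X = data[snps].to_numpy(dtype=float)
        # mean-impute residual missingness (QC caps it at <1%)
        col_mean = np.nanmean(X, axis=0)
        nan_mask = np.isnan(X)
        X = np.where(nan_mask, col_mean[None, :], X)
        X = X - X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.any():
            logger.warning("gene %s: all SNPs constant; omitted", gene)
            continue
        X = X[:, keep]
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        var = s**2
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, pc_variance_fraction) + 1)
        cap = max(1, min(X.shape[1], n // max_pc_divisor, n - 2))
        k = min(k, cap, int(np.sum(s > 1e-10 * s[0])))
        pcs = u[:, :k] * s[None, :k]
        # OLS of label on PCs with intercept; overall F-test
        yc = y - y.mean()
        beta, _, _, _ = np.linalg.lstsq(pcs, yc, rcond=None)
        fitted = pcs @ beta
        rss = float(np.sum((yc - fitted) ** 2))
        tss = float(np.sum(yc**2))
        df2 = n - k - 1
        if df2 <= 0 or tss <= 0:
            continue
        r2 = max(0.0, 1 - rss / tss)
        if rss <= 0:
            p = P_FLOOR
        else:
            f = (r2 / k) / ((1 - r2) / df2)
            p = float(stats.f.sf(f, k, df2))
        p = min(max(p, P_FLOOR), 1 - 1e-16)
        z = float(stats.norm.isf(p))
        rows.append((gene, z, p, len(snps)))
    return pd.DataFrame(rows, columns=["gene_id", "z_value", "p_value", "n_units"])


def magma_geneset_test(
    genes: pd.DataFrame,
    sets,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Competitive gene-set test: regress gene z on a set-membership
    indicator plus covariates (default: log unit count); one-sided p for a
    positive membership coefficient, BH-adjusted across sets."""
    g = genes.set_index("gene_id")
    z = g["z_value"].to_numpy(dtype=float)
    n = z.size
    if covariates is None:
        covariates = pd.DataFrame(
            {"log_n_units": np.log(g["n_units"].to_numpy(dtype=float))},
            index=g.index,
        )
    C = covariates.loc[g.index].to_numpy(dtype=float)
    rows = []
    for set_id in sorted(sets):
        member = np.fromiter(
            (gid in sets.members(set_id) for gid in g.index), bool, n
        ).astype(float)
        if member.sum() < 2:
            logger.warning("set %s: fewer than 2 members scored; skipped", set_id)
            continue
        X = np.column_stack([np.ones(n), member, C])
        beta, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ beta
        df = n - X.shape[1]
        if df <= 0:
            continue
        sigma2 = float(resid @ resid) / df
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(max(sigma2 * xtx_inv[1, 1], 1e-300))
        tstat = beta[1] / se
        p = float(stats.t.sf(tstat, df))
        rows.append((set_id, float(beta[1]), p))
    out = pd.DataFrame(rows, columns=["set_id", "beta", "p_value"])
    out["adjusted_p"] = adjust_bh(out["p_value"].to_numpy()) if len(out) else []
    return out


def cpg_gene_scores(
    cpg_assoc: pd.DataFrame, annotation: GeneAnnotationMap
) -> pd.DataFrame:
    """Gene scores from CpG-level association by rank aggregation.

    CpGs are ranked globally by p ascending (ties by |t| descending then
    id); per gene, the minimum beta order-statistic score of its CpGs'
    normalised ranks is converted to a calibrated gene p through the exact
    null distribution of that minimum, and to z = Phi^{-1}(1 - p/2) signed
    by the mean member t.  Genes with no annotated CpG are absent.
    """
    ids = cpg_assoc["feature_id"].astype(str).to_numpy()
    pvals = cpg_assoc["p_value"].to_numpy(dtype=float)
    tstats = cpg_assoc["t_statistic"].to_numpy(dtype=float)
    order = np.lexsort((ids, -np.abs(tstats), pvals))
    n_total = len(ids)
    norm_rank = {ids[j]: (i + 1) / n_total for i, j in enumerate(order)}
    t_of = dict(zip(ids, tstats))
    rows = []
    for gene, cpgs in sorted(annotation.by_gene().items()):
        cpgs = [c for c in cpgs if c in norm_rank]
        if not cpgs:
            continue
        r = np.sort([norm_rank[c] for c in cpgs])
        rho = beta_score(r)
        # exact null CDF of rho gives a calibrated gene p-value
        p = max(rho_null_cdf(rho, len(r)), P_FLOOR)
        sign = np.sign(np.mean([t_of[c] for c in cpgs])) or 1.0
        z = float(stats.norm.isf(min(p / 2, 1 - 1e-16))) * float(sign)
        rows.append((gene, z, p, len(cpgs)))
    return pd.DataFrame(rows, columns=["gene_id", "z_value", "p_value", "n_units"])
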