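"""Modality-specific quality control, imputation, encoding and labelling.

Mirrors the cohort protocol: phenotype labels from the MNSI examination
score (case at >= 3 points, incident case when a baseline control crosses 3
at follow-up); SNP filters on missingness (>= 1%), minor allele frequency
(< 1%) and Hardy-Weinberg equilibrium (chi-square p < 1e-10), followed by a
sample filter on heterozygosity (|z| > 3); strand-aware SNP->gene window
annotation; metabolite missingness filter, k-nearest-neighbour imputation
and a standardised Mahalanobis outlier filter at distance 4; clinical
one-hot encoding and a > 10% missingness drop; covariate residualisation;
and z-score standardisation of every molecular layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FeatureMatrix, ValidationError
from .rank import GeneAnnotationMap

logger = logging.getLogger("modfuse.preprocess")


# ---------------------------------------------------------------------------
# Phenotype labelling
# ---------------------------------------------------------------------------

EXCLUDED = "excluded"


def assign_labels(
    mnsi_baseline: float | None,
    mnsi_followup: float | None,
    threshold: float = 3.0,
):
    """(prevalent, incident) labels from MNSI scores at two timepoints.

    Prevalent case iff baseline >= threshold.  The incident task is defined
    only for baseline controls: incident case iff follow-up >= threshold,
    ``excluded`` when the follow-up score is missing.  A missing baseline
    excludes the sample from both tasks.
    """

    def _missing(x):
        return x is None or (isinstance(x, float) and np.isnan(x))

    for name, score in (("baseline", mnsi_baseline), ("followup", mnsi_followup)):
        if not _missing(score) and not 0 <= score <= 10:
            raise ValidationError(f"mnsi_{name} score {score} outside [0, 10]")
    if _missing(mnsi_baseline):
        return EXCLUDED, EXCLUDED
    prevalent = int(mnsi_baseline >= threshold)
    if prevalent:
        return 1, EXCLUDED
    if _missing(mnsi_followup):
        return 0, EXCLUDED
    return 0, int(mnsi_followup >= threshold)


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------


@dataclass
class SnpQCReport:
    snp_stats: pd.DataFrame  # snp_id, missing_rate, maf, hwe_p
    sample_stats: pd.DataFrame  # sample_id, het_rate, het_z
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["item", "kind", "reason"])
    )


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p against Hardy-Weinberg proportions
    at the observed allele frequency; monomorphic SNPs return 1."""
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValidationError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValidationError("total genotype count must be positive")
    p = (2 * n_aa + n_Aa) / (2 * n)  # alt allele frequency
    if p <= 0 or p >= 1:
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc(
    genotypes: FeatureMatrix,
    missing_max: float = 0.01,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-10,
    het_z_max: float = 3.0,
) -> tuple[FeatureMatrix, SnpQCReport]:
    """Drop SNPs with missing rate >= missing_max, MAF < maf_min or HWE
    p < hwe_p_min; then drop samples whose heterozygosity rate (fraction of
    dosage-1 calls among non-missing calls) deviates more than het_z_max
    standard deviations from the mean.  Every removal is reported once."""
    X = genotypes.data.to_numpy(dtype=float)
    valid = np.isnan(X) | np.isin(X, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ValidationError(
            f"non-dosage value {X[i, j]} at SNP "
            f"{genotypes.feature_ids[j]!r}, sample {genotypes.sample_ids[i]!r}"
        )
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=0).astype(float)
    missing_rate = 1.0 - n_obs / X.shape[0]
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(X, axis=0) / (2 * n_obs)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    hwe_p = np.array(
        [
            hwe_test(
                int(np.nansum(X[:, j] == 0)),
                int(np.nansum(X[:, j] == 1)),
                int(np.nansum(X[:, j] == 2)),
            )
            if n_obs[j] > 0
            else 1.0
            for j in range(X.shape[1])
        ]
    )
    snp_stats = pd.DataFrame(
        {
            "snp_id": genotypes.feature_ids,
            "missing_rate": missing_rate,
            "maf": maf,
            "hwe_p": hwe_p,
        }
    )
    removed_rows = []
    keep_snp = np.ones(X.shape[1], dtype=bool)
    for j, snp in enumerate(genotypes.feature_ids):
        if missing_rate[j] >= missing_max:
            reason = "missing_rate"
        elif maf[j] < maf_min:
            reason = "maf"
        elif hwe_p[j] < hwe_p_min:
            reason = "hwe"
        else:
            continue
        keep_snp[j] = False
        removed_rows.append((snp, "snp", reason))

    Xk = X[:, keep_snp]
    obs_k = ~np.isnan(Xk)
    with np.errstate(invalid="ignore"):
        het_rate = np.nansum(Xk == 1, axis=1) / np.maximum(obs_k.sum(axis=1), 1)
    mu, sd = het_rate.mean(), het_rate.std(ddof=1)
    het_z = (het_rate - mu) / sd if sd > 0 else np.zeros_like(het_rate)
    keep_sample = np.abs(het_z) <= het_z_max
    for i, sample in enumerate(genotypes.sample_ids):
        if not keep_sample[i]:
            removed_rows.append((sample, "sample", "heterozygosity"))
    sample_stats = pd.DataFrame(
        {"sample_id": genotypes.sample_ids, "het_rate": het_rate, "het_z": het_z}
    )
    report = SnpQCReport(
        snp_stats=snp_stats,
        sample_stats=sample_stats,
        removed=pd.DataFrame(removed_rows, columns=["item", "kind", "reason"]),
    )
    out = FeatureMatrix(
        genotypes.modality,
        genotypes.data.loc[keep_sample, genotypes.data.columns[keep_snp]],
    )
    return out, report


def annotate_snps_to_genes(
    snp_positions: pd.DataFrame,
    genes: pd.DataFrame,
    window_upstream: int = 2000,
    window_downstream: int = 500,
) -> GeneAnnotationMap:
    """Map each SNP to every gene whose strand-aware window contains it.

    Coordinates are 1-based inclusive.  For a + strand gene the window is
    [start - upstream, end + downstream]; for - strand it is mirrored
    ([start - downstream, end + upstream]).  SNPs on chromosomes absent
    from the gene table stay unmapped with a warning; unmapped SNPs are
    simply absent from the map.
    """
    if window_upstream < 0 or window_downstream < 0:
        raise ValidationError("windows must be non-negative")
    if (genes["start"] > genes["end"]).any():
        raise ValidationError("gene start must be <= end")
    mapping: dict[str, tuple[str, ...]] = {}
    gene_chroms = set(genes["chrom"].astype(str))
    by_chrom = {c: g for c, g in genes.groupby(genes["chrom"].astype(str))}
    for _, snp in snp_positions.iterrows():
        chrom = str(snp["chrom"])
        if chrom not in gene_chroms:
            logger.warning("SNP %s: unknown chromosome %s", snp["id"], chrom)
            continue
        g = by_chrom[chrom]
        plus = g["strand"] == "+"
        lo = np.where(plus, g["start"] - window_upstream, g["start"] - window_downstream)
        hi = np.where(plus, g["end"] + window_downstream, g["end"] + window_upstream)
        hit = (snp["pos"] >= lo) & (snp["pos"] <= hi)
        if hit.any():
            mapping[str(snp["id"])] = tuple(sorted(g.loc[hit, "id"].astype(str)))
    return GeneAnnotationMap(mapping)


# ---------------------------------------------------------------------------
# Metabolomics-style cleaning
# ---------------------------------------------------------------------------


def drop_high_missingness(
    matrix: FeatureMatrix, max_fraction: float
) -> FeatureMatrix:
    """Drop features whose missing fraction STRICTLY exceeds max_fraction."""
    if not 0 <= max_fraction <= 1:
        raise ValidationError("max_fraction must lie in [0, 1]")
    frac = matrix.data.isna().mean(axis=0)
    keep = frac <= max_fraction
    dropped = (~keep).sum()
    if dropped:
        logger.info("%s: dropped %d features above %.0f%% missingness",
                    matrix.modality, dropped, 100 * max_fraction)
    return FeatureMatrix(matrix.modality, matrix.data.loc[:, keep])


def knn_impute(matrix: FeatureMatrix, k: int = 10) -> FeatureMatrix:
    """k-nearest-neighbour imputation.

    The distance between two samples is the root mean squared difference
    over features observed in both (so sparsely shared pairs are not
    penalised for length); each missing cell is the mean of that feature
    over the k nearest samples in which it is observed.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = matrix.data.to_numpy(dtype=float).copy()
    obs = ~np.isnan(X)
    if (obs.sum(axis=1) == 0).any():
        raise ValidationError("a sample has no observed value")
    if (obs.sum(axis=0) == 0).any():
        missing_cols = [
            f for f, o in zip(matrix.feature_ids, obs.sum(axis=0)) if o == 0
        ]
        raise ValidationError(f"features missing in all samples: {missing_cols}")
    n = X.shape[0]
    X0 = np.where(obs, X, 0.0)
    # pairwise mean squared difference over shared observed features
    shared = obs.astype(float) @ obs.astype(float).T
    sq = (
        (X0**2) @ obs.T.astype(float)
        + obs.astype(float) @ (X0**2).T
        - 2 * X0 @ X0.T
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared > 0, sq / shared, np.inf)
    np.fill_diagonal(d2, np.inf)
    out = X.copy()
    miss_rows, miss_cols = np.where(~obs)
    for i, j in zip(miss_rows, miss_cols):
        donors = np.where(obs[:, j])[0]
        order = donors[np.argsort(d2[i, donors], kind="stable")][:k]
        out[i, j] = X[order, j].mean()
    return FeatureMatrix(matrix.modality, pd.DataFrame(
        out, index=matrix.data.index, columns=matrix.data.columns))


def mahalanobis_filter(
    matrix: FeatureMatrix, cutoff: float = 4.0
) -> tuple[FeatureMatrix, list[str]]:
    """Remove samples with standardised Mahalanobis distance above cutoff.

    The distance is standardised by dividing by sqrt(p) where p is the
    dimension used.  When p >= n/2 the computation runs on the leading
    principal components capturing 95% of variance; a singular covariance
    is shrunk toward its diagonal and logged.
    """
    X = matrix.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("mahalanobis_filter requires a complete matrix")
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    if p >= n / 2:
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2
        k = int(np.searchsorted(np.cumsum(var) / var.sum(), 0.95) + 1)
        Xc = u[:, :k] * s[None, :k]
        p_used = k
    else:
        p_used = p
    cov = np.cov(Xc, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        logger.warning("singular covariance; applying shrinkage")
        cov = 0.9 * cov + 0.1 * np.diag(np.diag(cov))
        inv = np.linalg.pinv(cov)
    d = np.sqrt(np.einsum("ij,jk,ik->i", Xc, inv, Xc))
    standardised = d / np.sqrt(p_used)
    keep = standardised <= cutoff
    removed = [s for s, kflag in zip(matrix.sample_ids, keep) if not kflag]
    return FeatureMatrix(matrix.modality, matrix.data.loc[keep]), removed


# ---------------------------------------------------------------------------
# Generic transforms
# ---------------------------------------------------------------------------


def zscore_standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Standardise each feature to mean 0, sample SD 1 over observed
    entries; missing entries are preserved; constant features are dropped
    with a warning."""
    df = matrix.data
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    constant = (sd == 0) | sd.isna()
    if constant.any():
        logger.warning(
            "%s: dropping %d constant features", matrix.modality, constant.sum()
        )
    df = df.loc[:, ~constant]
    out = (df - mean[~constant]) / sd[~constant]
    return FeatureMatrix(matrix.modality, out)


def one_hot_encode(clinical: pd.DataFrame, modality: str = "clinical") -> FeatureMatrix:
    """One-hot encode categorical columns; numeric columns pass through.

    A categorical column with L observed levels becomes L indicator
    columns named ``col=level``; single-level columns are dropped."""
    pieces = []
    for col in clinical.columns:
        s = clinical[col]
        if pd.api.types.is_numeric_dtype(s):
            pieces.append(s.astype(float).rename(str(col)))
            continue
        levels = sorted(s.dropna().astype(str).unique())
        if len(levels) < 2:
            logger.warning("clinical column %r has one level; dropped", col)
            continue
        for lev in levels:
            ind = (s.astype(str) == lev).astype(float)
            ind[s.isna()] = np.nan
            pieces.append(ind.rename(f"{col}={lev}"))
    out = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=clinical.index)
    return FeatureMatrix(modality, out)


def regress_out_covariates(
    matrix: FeatureMatrix, covariates: pd.DataFrame
) -> FeatureMatrix:
    """Replace each feature by the residuals of a least-squares fit on the
    covariates (intercept included).  Covariates must be complete and of
    full column rank."""
    cov = covariates.loc[matrix.data.index]
    if cov.isna().any().any():
        raise ValidationError("covariates must be complete for all samples")
    C = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify collinear columns by incremental rank
        bad = []
        base = np.ones((len(cov), 1))
        for name in cov.columns:
            cand = np.column_stack([base, cov[name].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(name)
            else:
                base = cand
        raise ValidationError(f"rank-deficient covariates; collinear columns: {bad}")
    X = matrix.data.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    out = np.full_like(X, np.nan)
    if obs.all():
        beta, _, _, _ = np.linalg.lstsq(C, X, rcond=None)
        out = X - C @ beta
    else:
        for j in range(X.shape[1]):
            rows = obs[:, j]
            beta, _, _, _ = np.linalg.lstsq(C[rows], X[rows, j], rcond=None)
            out[rows, j] = X[rows, j] - C[rows] @ beta
    return FeatureMatrix(
        matrix.modality,
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
    )
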