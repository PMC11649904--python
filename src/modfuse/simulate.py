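"""Synthetic multimodal cohort generator with planted pathway signal.

The generator emulates the statistical structure the pipeline assumes in a
population cohort: several molecular layers plus a clinical table, class
imbalance around 1:4, sparse per-sample modality coverage, and pathway-level
planted effects.

Signal model.  Continuous layers (transcripts, proteins, metabolites,
inflammatory proteins, methylation M-values) use equicorrelated within-set
noise: x_ij = sqrt(c) f_i + sqrt(1-c) e_ij with unit variance, and members
of planted sets gain a class-mean shift of ``effect_size`` standard
deviations.  Genotypes are drawn per SNP at Hardy-Weinberg equilibrium with
MAF uniform in ``maf_range``; planted SNPs act through a latent liability
(weighted standardised dosages plus Gaussian noise) thresholded at the
case-fraction quantile, which also defines the cohort's labels.  SNPs and
CpGs group into genes so the gene-level rankers are exercised; gene sets
are non-overlapping draws over each layer's gene universe.

Everything is deterministic given the parameter seed; sub-stage seeds are
derived from it by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    FeatureMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeTable,
    ValidationError,
    derive_seed,
)
from .rank import GeneAnnotationMap

CONTINUOUS_MODALITIES = (
    "transcriptomic",
    "proteomic",
    "metabolomic",
    "inflammatory",
)


def _default_feature_counts() -> dict[str, int]:
    return {
        "genomic": 500,
        "transcriptomic": 300,
        "proteomic": 150,
        "metabolomic": 150,
        "methylomic": 480,
        "inflammatory": 60,
        "clinical": 10,
    }


def _default_missing() -> dict[str, float]:
    # genotype missingness must sit below the 1% QC threshold
    return {
        "genomic": 0.002,
        "transcriptomic": 0.01,
        "proteomic": 0.01,
        "metabolomic": 0.05,
        "methylomic": 0.01,
        "inflammatory": 0.01,
        "clinical": 0.0,
    }


def _default_coverage() -> dict[str, float]:
    return {
        "genomic": 0.7,
        "transcriptomic": 0.7,
        "proteomic": 0.5,
        "metabolomic": 0.7,
        "methylomic": 0.7,
        "inflammatory": 0.8,
        "clinical": 1.0,
    }


@dataclass
class SimulationParams:
    n_samples: int = 400
    case_fraction: float = 0.2
    feature_counts: dict[str, int] = field(default_factory=_default_feature_counts)
    n_gene_sets: int = 10
    set_size_range: tuple[int, int] = (10, 20)
    planted_sets_per_modality: int = 1
    effect_size: float = 1.0
    within_set_correlation: float = 0.3
    missing_fraction: dict[str, float] = field(default_factory=_default_missing)
    modality_coverage: dict[str, float] = field(default_factory=_default_coverage)
    maf_range: tuple[float, float] = (0.05, 0.5)
    snps_per_gene: int = 2
    cpgs_per_gene: int = 2
    planted_clinical: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.case_fraction < 1:
            raise ValidationError("case_fraction must be in (0,1)")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0 <= self.within_set_correlation < 1:
            raise ValidationError("within_set_correlation must be in [0,1)")
        for m, c in self.modality_coverage.items():
            if not 0 < c <= 1:
                raise ValidationError(f"coverage for {m} must be in (0,1]")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.feature_counts)


@dataclass
class CohortTruth:
    planted_sets: dict[str, list[str]]
    effects: dict[str, pd.Series]  # per-feature true effect sizes
    latent_risk: pd.Series


@dataclass
class SimulatedCohort:
    matrices: dict[str, FeatureMatrix]
    phenotype: PhenotypeTable
    gene_sets: dict[str, GeneSetCollection]
    annotations: dict[str, GeneAnnotationMap]
    truth: CohortTruth


def simulate_genesets(
    universe: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    seed: int,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Draw non-overlapping sets with sizes uniform in ``set_size_range``
    from a feature universe; deterministic under seed."""
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValidationError(
            f"requested set size up to {hi} from a universe of {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    pool = list(universe)
    rng.shuffle(pool)
    sets = []
    cursor = 0
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if cursor + size > len(pool):
            raise ValidationError(
                f"universe of {len(universe)} too small for {n_sets} "
                f"non-overlapping sets of size up to {hi}"
            )
        members = frozenset(pool[cursor: cursor + size])
        cursor += size
        sets.append(GeneSet(f"{prefix}{i + 1:03d}", f"simulated set {i + 1}", members))
    return GeneSetCollection(sets)


def _gene_universe(modality: str, params: SimulationParams) -> list[str]:
    n = params.feature_counts[modality]
    if modality == "genomic":
        n_genes = max(1, n // params.snps_per_gene)
        return [f"gg{i:04d}" for i in range(1, n_genes + 1)]
    if modality == "methylomic":
        n_genes = max(1, n // params.cpgs_per_gene)
        return [f"mg{i:04d}" for i in range(1, n_genes + 1)]
    prefix = {"transcriptomic": "tx", "proteomic": "pr",
              "metabolomic": "mb", "inflammatory": "if"}[modality]
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _equicorrelated(
    rng: np.random.Generator, n: int, features: list[str],
    sets: GeneSetCollection, corr: float, correlated_sets: list[str],
) -> pd.DataFrame:
    """Unit-variance noise; members of ``correlated_sets`` (the planted
    pathways) share an equicorrelated factor, all other features are
    independent."""
    X = rng.standard_normal((n, len(features)))
    if corr > 0:
        col = {f: j for j, f in enumerate(features)}
        for set_id in correlated_sets:
            idx = [col[m] for m in sorted(sets.members(set_id)) if m in col]
            f = rng.standard_normal(n)
            X[:, idx] = np.sqrt(corr) * f[:, None] + np.sqrt(1 - corr) * X[:, idx]
    return pd.DataFrame(X, columns=features)


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Generate per-modality matrices, phenotype, gene sets, SNP/CpG->gene
    annotations and ground truth.  See the module docstring for the signal
    model."""
    n = params.n_samples
    if int(n * params.case_fraction) < 1 or int(n * params.case_fraction) >= n:
        raise ValidationError("degenerate class sizes at this n_samples")
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    gene_sets: dict[str, GeneSetCollection] = {}
    planted: dict[str, list[str]] = {}
    # the planted-pathway module (class shift + shared factor) exists only
    # when the effect is active; at effect 0 every feature is pure noise
    active = params.effect_size > 0
    for m in params.modalities:
        if m == "clinical":
            continue
        universe = _gene_universe(m, params)
        # small panels carry fewer annotated sets, capped by feasibility
        n_sets = min(params.n_gene_sets,
                     len(universe) // params.set_size_range[1])
        if n_sets < 1:
            raise ValidationError(
                f"{m}: universe of {len(universe)} too small for sets of "
                f"size up to {params.set_size_range[1]}"
            )
        prefix = {"genomic": "GEN", "transcriptomic": "TRX", "proteomic": "PRO",
                  "metabolomic": "MET", "methylomic": "MTH",
                  "inflammatory": "INF"}[m]
        gene_sets[m] = simulate_genesets(
            universe, n_sets, params.set_size_range,
            derive_seed(params.seed, "genesets", m), prefix=f"{prefix}_SET",
        )
        ids = sorted(gene_sets[m])
        planted[m] = ids[: params.planted_sets_per_modality]

    # --- genotypes and liability-derived labels -------------------------
    annotations: dict[str, GeneAnnotationMap] = {}
    effects: dict[str, pd.Series] = {}
    matrices: dict[str, FeatureMatrix] = {}

    rng_g = np.random.default_rng(derive_seed(params.seed, "genomic"))
    geno = None
    if "genomic" in params.modalities:
        genes = _gene_universe("genomic", params)
        snp_ids, snp_gene = [], {}
        for g in genes:
            for s in range(params.snps_per_gene):
                sid = f"snp_{g}_{s + 1}"
                snp_ids.append(sid)
                snp_gene[sid] = (g,)
        annotations["genomic"] = GeneAnnotationMap(snp_gene)
        maf = rng_g.uniform(*params.maf_range, size=len(snp_ids))
        G = rng_g.binomial(2, maf, size=(n, len(snp_ids))).astype(float)
        planted_genes = {
            g for sid in planted["genomic"]
            for g in gene_sets["genomic"].members(sid)
        }
        planted_snps = [j for j, s in enumerate(snp_ids)
                        if snp_gene[s][0] in planted_genes]
        eff = pd.Series(0.0, index=snp_ids)
        if planted_snps and params.effect_size > 0:
            beta = params.effect_size / np.sqrt(len(planted_snps))
            sd = np.sqrt(2 * maf * (1 - maf))
            Gs = (G - 2 * maf[None, :]) / sd[None, :]
            genetic = Gs[:, planted_snps].sum(axis=1) * beta
            eff.iloc[planted_snps] = beta
        else:
            genetic = np.zeros(n)
        effects["genomic"] = eff
        geno = pd.DataFrame(G, index=sample_ids, columns=snp_ids)
    else:
        genetic = np.zeros(n)

    rng_lab = np.random.default_rng(derive_seed(params.seed, "labels"))
    liability = genetic + rng_lab.standard_normal(n)
    threshold = np.quantile(liability, 1 - params.case_fraction)
    labels = (liability >= threshold).astype(int)
    if labels.sum() in (0, n):
        raise ValidationError("degenerate class: all cases or all controls")

    if geno is not None:
        matrices["genomic"] = FeatureMatrix("genomic", geno)

    # --- continuous molecular layers ------------------------------------
    for m in params.modalities:
        if m in ("genomic", "clinical"):
            continue
        rng_m = np.random.default_rng(derive_seed(params.seed, "matrix", m))
        if m == "methylomic":
            genes = _gene_universe("methylomic", params)
            feats, feat_gene = [], {}
            for g in genes:
                for c in range(params.cpgs_per_gene):
                    cid = f"cpg_{g}_{c + 1}"
                    feats.append(cid)
                    feat_gene[cid] = (g,)
            annotations["methylomic"] = GeneAnnotationMap(feat_gene)
            # sets are over genes; expand to CpG level for the noise model
            cpg_sets = GeneSetCollection(
                GeneSet(sid, "", frozenset(
                    f for f in feats
                    if feat_gene[f][0] in gene_sets[m].members(sid)))
                for sid in sorted(gene_sets[m])
            )
            X = _equicorrelated(rng_m, n, feats, cpg_sets,
                                params.within_set_correlation,
                                planted[m] if active else [])
            planted_feats = sorted(
                set().union(*(cpg_sets.members(s) for s in planted[m]))
            )
            # M-value-like bimodal feature offsets
            offsets = rng_m.choice([-3.0, 3.0], size=len(feats))
            offsets = offsets + rng_m.normal(0, 0.5, size=len(feats))
            X = X + offsets[None, :]
        else:
            feats = _gene_universe(m, params)
            X = _equicorrelated(rng_m, n, feats, gene_sets[m],
                                params.within_set_correlation,
                                planted[m] if active else [])
            planted_feats = sorted(
                set().union(*(gene_sets[m].members(s) for s in planted[m]))
            )
        eff = pd.Series(0.0, index=feats)
        eff.loc[planted_feats] = params.effect_size
        effects[m] = eff
        X = X + np.outer(labels, eff.to_numpy())
        X.index = sample_ids
        matrices[m] = FeatureMatrix(m, X)

    # --- clinical layer --------------------------------------------------
    if "clinical" in params.modalities:
        rng_c = np.random.default_rng(derive_seed(params.seed, "clinical"))
        n_feat = params.feature_counts["clinical"]
        names, cols = [], []
        eff = {}
        n_cont = max(1, n_feat // 2)
        for j in range(n_feat):
            planted_here = j < params.planted_clinical
            e = params.effect_size if planted_here else 0.0
            if j < n_cont:
                x = rng_c.standard_normal(n) + e * labels
                names.append(f"cl_cont{j + 1:02d}")
            else:
                latent = rng_c.standard_normal(n) + e * labels
                x = (latent > np.quantile(latent, 0.7)).astype(float)
                names.append(f"cl_bin{j + 1:02d}")
            eff[names[-1]] = e
            cols.append(x)
        clin = pd.DataFrame(np.column_stack(cols), index=sample_ids, columns=names)
        matrices["clinical"] = FeatureMatrix("clinical", clin)
        effects["clinical"] = pd.Series(eff)

    # --- missingness ------------------------------------------------------
    for m, fm in matrices.items():
        frac = params.missing_fraction.get(m, 0.0)
        if frac > 0:
            rng_na = np.random.default_rng(derive_seed(params.seed, "missing", m))
            mask = rng_na.random(fm.data.shape) < frac
            data = fm.data.mask(mask)
            # keep every sample partially observed
            empty = data.isna().all(axis=1)
            if empty.any():
                data.loc[empty, data.columns[0]] = fm.data.loc[empty, data.columns[0]]
            matrices[m] = FeatureMatrix(m, data)

    matrices = apply_block_missingness(
        matrices, params.modality_coverage, derive_seed(params.seed, "coverage")
    )

    # --- phenotype table with MNSI-style scores --------------------------
    rng_p = np.random.default_rng(derive_seed(params.seed, "phenotype"))
    mnsi_base = np.where(
        labels == 1, rng_p.integers(3, 11, size=n), rng_p.integers(0, 3, size=n)
    ).astype(float)
    mnsi_follow = np.where(
        rng_p.random(n) < 0.8,
        np.clip(mnsi_base + rng_p.integers(-1, 3, size=n), 0, 10),
        np.nan,
    )
    phenotype = PhenotypeTable(
        pd.DataFrame(
            {
                "label": labels,
                "mnsi_baseline": mnsi_base,
                "mnsi_followup": mnsi_follow,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    truth = CohortTruth(
        planted_sets=planted,
        effects=effects,
        latent_risk=pd.Series(liability, index=sample_ids),
    )
    return SimulatedCohort(matrices, phenotype, gene_sets, annotations, truth)


def apply_block_missingness(
    matrices: dict[str, FeatureMatrix],
    coverage: dict[str, float] | float,
    seed: int,
) -> dict[str, FeatureMatrix]:
    """Retain each sample in each modality independently with the stated
    probability, guaranteeing at least one retained modality per sample.
    Retention patterns are deterministic under seed."""
    if not isinstance(coverage, dict):
        coverage = {m: float(coverage) for m in matrices}
    for m in matrices:
        c = coverage.get(m, 1.0)
        if c <= 0:
            raise ValidationError(f"coverage for {m} must be positive")
    all_samples = sorted(set().union(*(set(fm.sample_ids) for fm in matrices.values())))
    rng = np.random.default_rng(seed)
    modality_names = sorted(matrices)
    keep = {
        m: rng.random(len(all_samples)) < coverage.get(m, 1.0)
        for m in modality_names
    }
    # a sample must keep at least one modality
    for i in range(len(all_samples)):
        if not any(keep[m][i] for m in modality_names):
            forced = modality_names[int(rng.integers(len(modality_names)))]
            keep[forced][i] = True
    out = {}
    sample_pos = {s: i for i, s in enumerate(all_samples)}
    for m in modality_names:
        fm = matrices[m]
        mask = [keep[m][sample_pos[s]] for s in fm.sample_ids]
        out[m] = FeatureMatrix(m, fm.data.loc[mask])
    return out
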