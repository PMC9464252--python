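"""Genome-wide orchestration of the functionally informed tests.

Per phenotype: inverse-normal transform, covariate null model, then per
gene and variant category the score/RLRT two-stage tests with the
category-appropriate kernel design, pooled parametric null finalization
per (phenotype x category x test-type) group, Cauchy combination of
category-only and category+pLOF designs into a single gbvc and a single
kernel test per gene, Bonferroni flags and genomic inflation factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, kernels
from .annotate import QualifyingSets, VariantAnnotation
from .assoc import GeneTestRecord, NullMixture, derive_seed

__all__ = [
    "StudyConfig",
    "GeneData",
    "inverse_normal_transform",
    "test_gene_category",
    "pool_and_finalize",
    "bonferroni_cutoff",
    "conditional_test",
    "choose_conditioning_variant",
    "run_study",
]


@dataclass
class StudyConfig:
    maf_max: float = 0.001
    hwe_min: float = 1e-5
    call_rate_min: float = 0.9
    missense_weight_min: float = 0.8
    splice_delta_min: float = 0.1
    rbp_effect_min: float = 0.25
    slrt_t: float = 0.1
    alpha: float = 0.05
    n_null_per_gene: int = 100
    n_null_conditional: int = 250_000
    master_seed: int = 0
    #: minimum pooled statistics required to fit a group null
    min_group_statistics: int = 100
    #: column of the covariate table used to stratify the phenotype
    #: transform (e.g. sex); None transforms the whole sample at once
    int_stratify_by: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.slrt_t < 1.0):
            raise ValueError("slrt_t must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def inverse_normal_transform(
    values: np.ndarray, groups: np.ndarray | None = None
) -> np.ndarray:
    """Rank-based inverse-normal transform, optionally within groups.

    Maps ranks to standard-normal quantiles via (rank - 0.5) / n; missing
    values stay missing; requires >= 10 non-missing values per group and
    a non-constant input.
    """
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    if groups is None:
        groups = np.zeros(v.shape[0])
    groups = np.asarray(groups)
    for grp in pd.unique(groups[~pd.isna(groups)]):
        mask = (groups == grp) & ~np.isnan(v)
        n = int(mask.sum())
        if n < 10:
            raise ValueError(f"group {grp!r}: need >= 10 non-missing values, got {n}")
        if np.nanstd(v[mask]) == 0:
            raise ValueError(f"group {grp!r}: constant phenotype cannot be transformed")
        ranks = stats.rankdata(v[mask], method="average")
        out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


# ---------------------------------------------------------------------------
# per-gene data container


@dataclass
class GeneData:
    """One gene's qualifying variants for one category, plus the gene's
    pLOF set for the joint (category + pLOF) designs."""

    gene_id: str
    category: str
    strand: str
    G: np.ndarray  # n x m raw dosages (NaN missing)
    weights: np.ndarray
    variant_ids: list[str]
    positions: np.ndarray
    aa_positions: np.ndarray | None = None
    effect_vectors: np.ndarray | None = None  # m x R
    is_also_plof: np.ndarray | None = None
    plof_G: np.ndarray | None = None  # n x m_plof
    plof_weights: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.G.shape[1]

    def n_carriers(self) -> int:
        return int((np.nan_to_num(self.G, nan=0.0) >= 1).any(axis=1).sum())

    @classmethod
    def from_annotations(
        cls,
        gene_id: str,
        category: str,
        anns: list[VariantAnnotation],
        genotypes,  # io.GenotypeMatrix
        plof_anns: list[VariantAnnotation] | None = None,
    ) -> "GeneData | None":
        ids = [a.variant_id for a in anns if a.variant_id in set(genotypes.variant_ids)]
        anns = [a for a in anns if a.variant_id in set(genotypes.variant_ids)]
        if not ids:
            return None
        sub = genotypes.subset_variants(ids)
        aa = (
            np.array([a.aa_position for a in anns])
            if category == "missense"
            else None
        )
        ev = (
            np.array([a.effect_vector for a in anns], dtype=float)
            if category == "rbp"
            else None
        )
        plof_G = plof_w = None
        if plof_anns:
            pids = [a.variant_id for a in plof_anns if a.variant_id in set(genotypes.variant_ids)]
            if pids:
                plof_G = genotypes.subset_variants(pids).dosages
                plof_w = np.ones(len(pids))
        return cls(
            gene_id,
            category,
            anns[0].strand,
            sub.dosages,
            np.array([a.weight for a in anns]),
            ids,
            sub.pos.astype(float),
            aa_positions=aa,
            effect_vectors=ev,
            is_also_plof=np.array([a.is_also_plof for a in anns]),
            plof_G=plof_G,
            plof_weights=plof_w,
        )


def _burden_factor(G: np.ndarray, w: np.ndarray, design: str = "collapse_max") -> kernels.KernelFactor:
    """Centered max-weight burden as a one-column kernel factor."""
    Gi = np.nan_to_num(np.asarray(G, dtype=float), nan=0.0)
    b = kernels.collapse_max(Gi, w)
    return kernels.KernelFactor((b - b.mean())[:, None], ["burden"], design)


def _plof_burden(gene: GeneData) -> np.ndarray | None:
    if gene.plof_G is None or gene.plof_G.shape[1] == 0:
        return None
    Gi = np.nan_to_num(gene.plof_G, nan=0.0)
    return kernels.collapse_max(Gi, gene.plof_weights)


# ---------------------------------------------------------------------------
# per-gene testing


def _run_design(
    gene: GeneData,
    phi: kernels.KernelFactor,
    null: assoc.NullModel,
    config: StudyConfig,
    phenotype: str,
    test_type: str,
    combined: bool,
    triggered: bool,
    score_pair: tuple[float, float] | None = None,
) -> GeneTestRecord:
    """Score test plus, when the gene triggered, RLRT and null draws."""
    if score_pair is None:
        q_score, p_score = assoc.score_test(null, phi)
    else:
        q_score, p_score = score_pair
    rec = GeneTestRecord(
        gene.gene_id, gene.category, test_type, phi.design,
        score_stat=q_score, score_p=p_score,
        n_variants=gene.m, n_carriers=gene.n_carriers(),
    )
    rec.combined_with_plof = combined
    if triggered:
        rec.lrt_triggered = True
        rec.rlrt = assoc.rlrt_stat(null.y, null.X, phi)
        seed = derive_seed(
            config.master_seed, phenotype, gene.gene_id, gene.category,
            test_type, "plof" if combined else "solo",
        )
        rec.null_stats = assoc.sample_rlrt_null(
            phi, null.X, config.n_null_per_gene, seed
        )
    else:
        rec.final_p = p_score
    return rec


def test_gene_category(
    gene: GeneData,
    null: assoc.NullModel,
    config: StudyConfig,
    phenotype: str = "trait",
) -> list[GeneTestRecord]:
    """All test records for one gene in its variant category.

    pLOF: max-weight collapsing, score test only.  Missense: gbvc burden
    and locally collapsing kernel; if either score p < t, RLRTs plus the
    two pLOF-combined designs.  Splice: as missense with the weighted
    linear kernel, dual splice/pLOF variants moved to the pLOF side of
    joint designs.  RBP: kernel-only sLRT; if pLOF variants slipped into
    the set they are removed and the test repeated.
    """
    if gene.m == 0:
        return []
    t = config.slrt_t
    cat = gene.category

    if cat == "pLOF":
        phi = _burden_factor(gene.G, gene.weights)
        q, p = assoc.score_test(null, phi)
        rec = GeneTestRecord(
            gene.gene_id, cat, "gbvc", "collapse_max",
            score_stat=q, score_p=p, final_p=p,
            n_variants=gene.m, n_carriers=gene.n_carriers(),
        )
        return [rec]

    if cat == "rbp":
        keep = (
            ~gene.is_also_plof
            if gene.is_also_plof is not None and gene.is_also_plof.any()
            else None
        )
        removed_plof = keep is not None
        if removed_plof and keep.sum() == 0:
            return []
        idx = np.where(keep)[0] if removed_plof else slice(None)
        phi = kernels.phi_rbp(
            gene.G[:, idx],
            gene.weights[idx],
            gene.effect_vectors[idx],
            gene.positions[idx],
            variant_ids=[gene.variant_ids[i] for i in np.atleast_1d(np.arange(gene.m)[idx])],
            gene_id=gene.gene_id,
        )
        q, p = assoc.score_test(null, phi)
        rec = _run_design(
            gene, phi, null, config, phenotype, "kernel", False,
            triggered=p < t, score_pair=(q, p),
        )
        if removed_plof:
            rec.flags.add("plof_removed")
        return [rec]

    # missense / splice
    if cat == "missense":
        phi_kernel = kernels.phi_local_collapse(gene.G, gene.weights, gene.aa_positions)
    elif cat == "splice":
        phi_kernel = kernels.phi_linear(gene.G, gene.weights, gene.variant_ids)
    else:
        raise ValueError(f"unknown category {cat!r}")
    phi_burden = _burden_factor(gene.G, gene.weights)

    qb, pb = assoc.score_test(null, phi_burden)
    qk, pk = assoc.score_test(null, phi_kernel)
    triggered = (pb < t) or (pk < t)

    records = [
        _run_design(gene, phi_burden, null, config, phenotype, "gbvc",
                    False, triggered, (qb, pb)),
        _run_design(gene, phi_kernel, null, config, phenotype, "kernel",
                    False, triggered, (qk, pk)),
    ]
    # joint designs need actual pLOF material: without it they would
    # duplicate the category-only test and only add pooled-group noise
    dual = gene.is_also_plof if gene.is_also_plof is not None else np.zeros(gene.m, bool)
    has_plof = (gene.plof_G is not None and gene.plof_G.shape[1] > 0) or dual.any()
    if triggered and has_plof:
        # dual-annotated variants count on the pLOF side only
        cat_keep = ~dual
        plof_parts_G = [gene.plof_G] if gene.plof_G is not None else []
        plof_parts_w = [gene.plof_weights] if gene.plof_weights is not None else []
        if dual.any():
            plof_parts_G.append(gene.G[:, dual])
            plof_parts_w.append(np.ones(int(dual.sum())))
        plof_G = np.concatenate(plof_parts_G, axis=1)
        plof_w = np.concatenate(plof_parts_w)

        # gbvc joint: max weight over category and pLOF variants together
        joint_G = np.concatenate([gene.G[:, cat_keep], plof_G], axis=1)
        joint_w = np.concatenate([gene.weights[cat_keep], plof_w])
        phi_joint_burden = _burden_factor(joint_G, joint_w)

        # kernel joint: concatenate the collapsed pLOF column
        if dual.any():
            if cat == "missense":
                phi_base = kernels.phi_local_collapse(
                    gene.G[:, cat_keep], gene.weights[cat_keep],
                    gene.aa_positions[cat_keep],
                ) if cat_keep.any() else None
            else:
                phi_base = kernels.phi_linear(
                    gene.G[:, cat_keep], gene.weights[cat_keep]
                ) if cat_keep.any() else None
        else:
            phi_base = phi_kernel
        burden = kernels.collapse_max(np.nan_to_num(plof_G, nan=0.0), plof_w)
        if phi_base is None:
            phi_joint_kernel = kernels.KernelFactor(
                (burden - burden.mean())[:, None], ["pLOF"], "local_collapse"
            )
        else:
            phi_joint_kernel = kernels.concat_plof(phi_base, burden)

        records.append(
            _run_design(gene, phi_joint_burden, null, config, phenotype,
                        "gbvc", True, True)
        )
        records.append(
            _run_design(gene, phi_joint_kernel, null, config, phenotype,
                        "kernel", True, True)
        )
    return records


# ---------------------------------------------------------------------------
# pooled finalization


def _group_key(phenotype: str, rec: GeneTestRecord) -> tuple:
    return (phenotype, rec.category, rec.test_type, rec.combined_with_plof)


def pool_and_finalize(
    records_by_pheno: dict[str, list[GeneTestRecord]],
    config: StudyConfig,
) -> tuple[pd.DataFrame, dict[tuple, NullMixture]]:
    """Fit pooled nulls per (phenotype x category x test-type x joint)
    group, assign mixture p-values to triggered records, then Cauchy-
    combine the (category-only, category+pLOF) pair per gene and track.

    Returns the tidy per-(gene, track) results table and the fitted
    mixtures.
    """
    mixtures: dict[tuple, NullMixture] = {}
    groups: dict[tuple, list[GeneTestRecord]] = {}
    for pheno, recs in records_by_pheno.items():
        for rec in recs:
            groups.setdefault(_group_key(pheno, rec), []).append(rec)

    for key, recs in groups.items():
        pooled = [r.null_stats for r in recs if r.null_stats is not None]
        if not pooled:
            continue
        stats_pool = np.concatenate(pooled)
        if stats_pool.size < config.min_group_statistics:
            raise ValueError(
                f"group {key}: only {stats_pool.size} pooled null statistics; "
                "lower slrt_t or raise n_null_per_gene"
            )
        if len(pooled) == 1:
            warnings.warn(
                f"group {key}: single triggered gene, pooled null equals its "
                "gene-specific null", stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mix = assoc.fit_null_mixture(stats_pool, group=str(key))
        mixtures[key] = mix
        for rec in recs:
            if rec.lrt_triggered:
                rec.final_p = assoc.mixture_pvalue(rec.rlrt, mix)

    rows = []
    for pheno, recs in records_by_pheno.items():
        per_gene: dict[tuple, dict[bool, GeneTestRecord]] = {}
        for rec in recs:
            per_gene.setdefault(
                (rec.gene_id, rec.category, rec.test_type), {}
            )[rec.combined_with_plof] = rec
        for (gene_id, cat, ttype), pair in sorted(per_gene.items()):
            base = pair.get(False)
            joint = pair.get(True)
            if base is None:
                continue
            if joint is not None and joint.final_p is not None and base.final_p is not None:
                final = assoc.cauchy_combine([base.final_p, joint.final_p])
                combined = final
            else:
                final = base.final_p
                combined = np.nan
            rows.append(
                {
                    "phenotype": pheno,
                    "gene_id": gene_id,
                    "category": cat,
                    "test_type": ttype,
                    "n_variants": base.n_variants,
                    "n_carriers": base.n_carriers,
                    "score_stat": base.score_stat,
                    "score_p": base.score_p,
                    "rlrt_stat": base.rlrt if base.rlrt is not None else np.nan,
                    "rlrt_p": base.final_p if base.lrt_triggered else np.nan,
                    "combined_p": combined,
                    "final_p": final,
                    "lrt_triggered": base.lrt_triggered,
                }
            )
    return pd.DataFrame(rows), mixtures


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# conditional tests


def choose_conditioning_variant(
    candidates: list[tuple[str, int, float]], gene_start: int
) -> str | None:
    """Most significant nearby single variant; ties go to the variant
    closest to the gene start.  ``candidates`` are (id, pos, p)."""
    if not candidates:
        return None
    best = min(candidates, key=lambda c: (c[2], abs(c[1] - gene_start)))
    return best[0]


def conditional_test(
    gene: GeneData,
    phis: list[kernels.KernelFactor],
    y: np.ndarray,
    X: np.ndarray,
    conditioning_dosage: np.ndarray,
    config: StudyConfig,
    phenotype: str = "trait",
) -> tuple[float, list[GeneTestRecord]]:
    """RLRT conditioned on a single variant added as a covariate.

    The conditioning dosage augments X; for every kernel design the RLRT
    statistic is recomputed, ``n_null_conditional`` gene-specific null
    statistics are sampled, a gene-specific mixture is fitted on their
    top decile, and the resulting p-values are Cauchy-combined across
    designs.
    """
    g = np.asarray(conditioning_dosage, dtype=float)
    g = np.nan_to_num(g, nan=np.nanmean(g))
    Xa = np.column_stack([X, g - g.mean()])
    try:
        null = assoc.fit_null_ols(y, Xa)
        conditioned = True
    except ValueError:
        warnings.warn(
            f"{gene.gene_id}: conditioning variant collinear with covariates; "
            "returning unconditional test", stacklevel=2,
        )
        null = assoc.fit_null_ols(y, X)
        Xa = X
        conditioned = False

    records = []
    p_values = []
    for k, phi in enumerate(phis):
        stat = assoc.rlrt_stat(y, Xa, phi)
        seed = derive_seed(
            config.master_seed, phenotype, gene.gene_id, "conditional", k
        )
        null_stats = assoc.sample_rlrt_null(phi, Xa, config.n_null_conditional, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mix = assoc.fit_null_mixture(null_stats, group=f"{gene.gene_id}:cond:{k}")
        p = assoc.mixture_pvalue(stat, mix)
        rec = GeneTestRecord(
            gene.gene_id, gene.category, "kernel", phi.design,
            rlrt=stat, final_p=p, lrt_triggered=True,
            n_variants=gene.m,
        )
        rec.conditioned = conditioned
        if not conditioned:
            rec.flags.add("conditioning_dropped_collinear")
        records.append(rec)
        p_values.append(p)
    combined = assoc.cauchy_combine(p_values) if len(p_values) > 1 else p_values[0]
    return combined, records


# ---------------------------------------------------------------------------
# full study


def run_study(
    genotypes,
    pheno_df: pd.DataFrame,
    covar_df: pd.DataFrame,
    qualifying: dict[str, QualifyingSets],
    config: StudyConfig,
    phenotypes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full pass over phenotypes, genes and categories.

    ``genotypes`` is an :class:`fikat.io.GenotypeMatrix` whose variants
    already passed QC; ``qualifying`` maps gene -> per-category sets.
    Covariate-missing samples are dropped globally, phenotype-missing
    samples per phenotype.  Returns the results table (with Bonferroni
    flags and per-group genomic inflation) and run metadata.
    """
    pheno_df = pheno_df.set_index("sample_id").reindex(genotypes.sample_ids)
    covar_df = covar_df.set_index("sample_id").reindex(genotypes.sample_ids)
    covar_cols = [c for c in covar_df.columns]
    covar_ok = ~covar_df[covar_cols].isna().any(axis=1).to_numpy()

    if phenotypes is None:
        phenotypes = [c for c in pheno_df.columns]

    gene_data: dict[tuple[str, str], GeneData] = {}
    for gene_id, sets in qualifying.items():
        for cat in ("pLOF", "missense", "splice", "rbp"):
            anns = sets.by_category(cat)
            if not anns:
                continue
            gd = GeneData.from_annotations(
                gene_id, cat, anns, genotypes,
                plof_anns=sets.plof if cat in ("missense", "splice") else sets.plof,
            )
            if gd is not None:
                gene_data[(gene_id, cat)] = gd

    records_by_pheno: dict[str, list[GeneTestRecord]] = {}
    skipped: list[str] = []
    for pheno in phenotypes:
        y_raw = pheno_df[pheno].to_numpy(dtype=float)
        mask = covar_ok & ~np.isnan(y_raw)
        strat = None
        if config.int_stratify_by is not None:
            strat = covar_df[config.int_stratify_by].to_numpy()[mask]
        y = inverse_normal_transform(y_raw[mask], strat)
        X = np.column_stack(
            [np.ones(mask.sum())] + [covar_df[c].to_numpy(dtype=float)[mask] for c in covar_cols]
        )
        null = assoc.fit_null_ols(y, X)
        recs: list[GeneTestRecord] = []
        for (gene_id, cat), gd in sorted(gene_data.items()):
            gd_sub = GeneData(
                gd.gene_id, gd.category, gd.strand,
                gd.G[mask], gd.weights, gd.variant_ids, gd.positions,
                gd.aa_positions, gd.effect_vectors, gd.is_also_plof,
                gd.plof_G[mask] if gd.plof_G is not None else None,
                gd.plof_weights,
            )
            if not np.any(np.nan_to_num(gd_sub.G, nan=0.0) > 0):
                skipped.append(f"{pheno}:{gene_id}:{cat}:no_carriers")
                continue
            try:
                recs.extend(test_gene_category(gd_sub, null, config, pheno))
            except (kernels.EmptyGeneError, ValueError) as exc:
                skipped.append(f"{pheno}:{gene_id}:{cat}:{exc}")
        records_by_pheno[pheno] = recs

    results, mixtures = pool_and_finalize(records_by_pheno, config)
    meta = {"mixtures": mixtures, "skipped": skipped}
    if results.empty:
        return results, meta

    n_tests = len(results)
    cutoff = bonferroni_cutoff(config.alpha, n_tests)
    results["significant"] = results["final_p"] < cutoff
    # inflation diagnostics use the genome-wide score tests (the RLRT is
    # only computed for triggered genes, so its p-values are not a
    # genome-wide series)
    lam = (
        results.groupby(["phenotype", "category", "test_type"])["score_p"]
        .transform(lambda p: assoc.lambda_gc(np.clip(p.to_numpy(dtype=float), 1e-300, 1.0)))
    )
    results["lambda_group"] = lam
    meta["n_tests"] = n_tests
    meta["bonferroni_cutoff"] = cutoff
    return results, meta
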