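"""Synthetic rare-variant study generator.

Generates genotypes, annotations, covariates and phenotypes with the
statistical structure the association tests assume: a singleton-heavy
rare-allele frequency spectrum (log-uniform MAF between 1/(2n) and the
rarity cutoff), the four functional variant categories with weights in
the ranges their predictors produce, amino-acid position sharing among
missense variants, signed per-RBP effect vectors, and phenotypes from
the linear mixed model y = X alpha + G beta + eps with a configurable
causal fraction, effect-sign mixture and gene-level variance explained.

The generator writes the same PLINK + TSV layout the pipeline consumes,
so simulated and real data flow through identical code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import VariantAnnotation
from .io import GenotypeMatrix, write_plink

__all__ = ["SimulationSpec", "sim_genotypes", "sim_annotations", "sim_phenotype", "sim_gene", "sim_study"]


@dataclass
class SimulationSpec:
    n_samples: int = 500
    n_genes: int = 50
    variants_per_gene: int = 10
    maf_max: float = 0.001
    missing_rate: float = 0.0
    #: fraction of missense variants sharing an amino-acid position with
    #: another variant of the same gene
    aa_sharing_fraction: float = 0.2
    #: proportions of genes assigned to each category
    category_mix: dict = field(
        default_factory=lambda: {"pLOF": 0.25, "missense": 0.35, "splice": 0.2, "rbp": 0.2}
    )
    causal_fraction: float = 0.0
    #: probability that a causal effect is positive
    positive_sign_prob: float = 1.0
    #: gene-level fraction of phenotypic variance explained by G beta
    variance_explained: float = 0.0
    #: True couples effect sizes to variant weights
    weights_track_effects: bool = False
    n_covariates: int = 2
    n_rbp: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_max <= 0.5):
            raise ValueError("maf_max must lie in (0, 0.5]")
        if not (0.0 <= self.variance_explained < 1.0):
            raise ValueError("variance_explained must lie in [0, 1)")
        for name in ("aa_sharing_fraction", "causal_fraction", "positive_sign_prob", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def sim_genotypes(
    spec: SimulationSpec, m: int | None = None, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an n x m dosage matrix and its target MAFs.

    MAF per variant is log-uniform on [1/(2n), maf_max] (heavy singleton
    tail); dosages are Binomial(2, MAF); missing calls optional.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    m = m if m is not None else spec.variants_per_gene
    n = spec.n_samples
    lo = 1.0 / (2.0 * n)
    if spec.maf_max <= lo:
        maf = np.full(m, lo)
    else:
        maf = np.exp(rng.uniform(np.log(lo), np.log(spec.maf_max), size=m))
    G = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    if spec.missing_rate > 0:
        mask = rng.random(size=G.shape) < spec.missing_rate
        G[mask] = np.nan
    return G, maf


def _weights(rng: np.random.Generator, category: str, m: int) -> np.ndarray:
    if category == "pLOF":
        return np.ones(m)
    if category == "missense":
        # qualifying missense weights concentrate near the 0.8 cutoff and above
        return rng.uniform(0.8, 1.0, size=m)
    if category == "splice":
        return rng.uniform(0.1, 1.0, size=m)
    if category == "rbp":
        return rng.uniform(0.25, 1.0, size=m)
    raise ValueError(category)


def sim_annotations(
    spec: SimulationSpec,
    gene_id: str,
    category: str,
    variant_ids: list[str],
    positions: np.ndarray,
    strand: str,
    rng: np.random.Generator,
) -> list[VariantAnnotation]:
    """Annotation records for one gene's variants in one category."""
    m = len(variant_ids)
    w = _weights(rng, category, m)
    anns: list[VariantAnnotation] = []
    if category == "missense":
        aa = _aa_positions(spec, m, rng)
    for i, vid in enumerate(variant_ids):
        if category == "pLOF":
            anns.append(VariantAnnotation(vid, gene_id, "pLOF", 1.0, strand))
        elif category == "missense":
            anns.append(
                VariantAnnotation(
                    vid, gene_id, "missense", float(w[i]), strand, aa_position=int(aa[i])
                )
            )
        elif category == "splice":
            anns.append(VariantAnnotation(vid, gene_id, "splice", float(w[i]), strand))
        elif category == "rbp":
            v = rng.uniform(-1.0, 1.0, size=spec.n_rbp)
            peak = np.abs(v).argmax()
            v = v / np.abs(v[peak]) * w[i] * np.sign(v[peak])  # max |v_j| == weight
            anns.append(
                VariantAnnotation(
                    vid, gene_id, "rbp", float(w[i]), strand, effect_vector=tuple(v)
                )
            )
    return anns


def _aa_positions(spec: SimulationSpec, m: int, rng: np.random.Generator) -> np.ndarray:
    """Amino-acid positions with the configured sharing fraction.

    A fraction of variants is assigned to reuse the position of another
    variant; the rest get distinct positions.
    """
    base = rng.choice(np.arange(1, 10 * m + 1), size=m, replace=False)
    aa = base.copy()
    n_shared = int(round(spec.aa_sharing_fraction * m))
    if n_shared >= 2:
        members = rng.choice(m, size=n_shared, replace=False)
        aa[members] = aa[members[0]]
    return aa


def sim_phenotype(
    G: np.ndarray,
    X: np.ndarray,
    spec: SimulationSpec,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotype from the mixed model y = X alpha + G beta + eps.

    beta is nonzero on a random causal subset with the configured sign
    mixture and is scaled so var(G beta) / var(G beta + eps) equals the
    spec's variance explained (eps is standard normal).  Returns (y, beta).
    """
    n, m = G.shape
    Gi = np.nan_to_num(G, nan=0.0)
    alpha = rng.normal(0.0, 0.5, size=X.shape[1])
    beta = np.zeros(m)
    h2 = spec.variance_explained
    if h2 > 0 and spec.causal_fraction > 0:
        n_causal = max(int(round(spec.causal_fraction * m)), 1)
        causal = rng.choice(m, size=n_causal, replace=False)
        mag = np.abs(rng.normal(1.0, 0.25, size=n_causal))
        if weights is not None and spec.weights_track_effects:
            mag = mag * np.asarray(weights, dtype=float)[causal]
        signs = np.where(rng.random(n_causal) < spec.positive_sign_prob, 1.0, -1.0)
        beta[causal] = mag * signs
        gb = Gi @ beta
        vg = gb.var()
        if vg > 0:
            beta *= np.sqrt(h2 / (1.0 - h2) / vg)
    eps = rng.normal(size=n)
    y = X @ alpha + Gi @ beta + eps
    return y, beta


def sim_covariates(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Intercept plus standard-normal covariates."""
    X = np.column_stack(
        [np.ones(spec.n_samples)]
        + [rng.normal(size=spec.n_samples) for _ in range(spec.n_covariates)]
    )
    return X


@dataclass
class SimulatedGene:
    gene_id: str
    category: str
    strand: str
    G: np.ndarray
    maf: np.ndarray
    variant_ids: list[str]
    positions: np.ndarray
    annotations: list[VariantAnnotation]
    beta: np.ndarray | None = None


def sim_gene(
    spec: SimulationSpec,
    gene_id: str,
    category: str,
    chrom: str,
    start: int,
    rng: np.random.Generator,
) -> SimulatedGene:
    """One gene: genotypes, positions spanning ~5 kb, annotations."""
    m = spec.variants_per_gene
    G, maf = sim_genotypes(spec, m, rng)
    positions = np.sort(rng.choice(np.arange(start, start + 5000), size=m, replace=False))
    variant_ids = [f"{chrom}:{p}:A:C" for p in positions]
    strand = "+" if rng.random() < 0.5 else "-"
    anns = sim_annotations(spec, gene_id, category, variant_ids, positions, strand, rng)
    return SimulatedGene(gene_id, category, strand, G, maf, variant_ids, positions, anns)


def sim_study(spec: SimulationSpec, out_prefix: str | None = None):
    """A full synthetic study: genes across categories, covariates, one
    phenotype; optionally written as PLINK bed/bim/fam + TSV tables.

    Returns (genes, X, y, pheno_df, covar_df, annotation_df).
    """
    rng = np.random.default_rng(spec.seed)
    X = sim_covariates(spec, rng)
    cats, probs = zip(*spec.category_mix.items())
    assignments = rng.choice(cats, size=spec.n_genes, p=np.array(probs) / sum(probs))

    genes: list[SimulatedGene] = []
    start = 1_000_000
    for i in range(spec.n_genes):
        gene = sim_gene(spec, f"G{i:04d}", str(assignments[i]), "1", start, rng)
        genes.append(gene)
        start += 20_000

    G_all = np.concatenate([g.G for g in genes], axis=1)
    w_all = np.concatenate([[a.weight for a in g.annotations] for g in genes])
    y, beta = sim_phenotype(G_all, X, spec, rng, weights=w_all)
    ofs = 0
    for g in genes:
        g.beta = beta[ofs : ofs + g.G.shape[1]]
        ofs += g.G.shape[1]

    sample_ids = [f"S{i:05d}" for i in range(spec.n_samples)]
    pheno_df = pd.DataFrame({"sample_id": sample_ids, "trait": y})
    covar_df = pd.DataFrame(
        {"sample_id": sample_ids}
        | {f"cov{j}": X[:, j + 1] for j in range(spec.n_covariates)}
    )
    ann_rows = []
    for g in genes:
        for a in g.annotations:
            row = {
                "variant_id": a.variant_id,
                "gene_id": a.gene_id,
                "category": a.category,
                "weight": a.weight,
                "aa_position": a.aa_position if a.aa_position is not None else "NA",
                "strand": a.strand,
                "is_plof": int(a.is_also_plof),
            }
            for j in range(spec.n_rbp):
                row[f"effect_{j + 1}"] = (
                    a.effect_vector[j] if a.effect_vector is not None else "NA"
                )
            ann_rows.append(row)
    ann_df = pd.DataFrame(ann_rows)

    if out_prefix is not None:
        gm = GenotypeMatrix(
            G_all,
            sample_ids,
            [v for g in genes for v in g.variant_ids],
            np.array([c for g in genes for c in ["1"] * len(g.variant_ids)]),
            np.concatenate([g.positions for g in genes]),
            ["C"] * G_all.shape[1],
            ["A"] * G_all.shape[1],
        )
        write_plink(gm, out_prefix)
        pheno_df.to_csv(out_prefix + ".pheno.tsv", sep="\t", index=False, na_rep="NA")
        covar_df.to_csv(out_prefix + ".covar.tsv", sep="\t", index=False, na_rep="NA")
        ann_df.to_csv(out_prefix + ".annot.tsv", sep="\t", index=False, na_rep="NA")
        genes_df = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "chrom": "1",
                "start": [int(g.positions.min()) for g in genes],
                "end": [int(g.positions.max()) for g in genes],
                "strand": [g.strand for g in genes],
            }
        )
        genes_df.to_csv(out_prefix + ".genes.tsv", sep="\t", index=False)

    return genes, X, y, pheno_df, covar_df, ann_df
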