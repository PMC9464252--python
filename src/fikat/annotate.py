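"""Variant weights and qualifying-variant sets from effect-prediction tables.

Precomputed predictions (SIFT/PolyPhen for missense, SpliceAI delta scores
for splice variants, RNA-binding-protein binding probabilities for the
reference and alternative allele) are turned into per-variant weights in
[0, 1] and, per gene, into the four category-specific sets of qualifying
variants used by the association tests: pLOF, missense, splice and rbp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAnnotation",
    "InvalidAnnotationError",
    "QUALIFYING_THRESHOLDS",
    "impact_score",
    "splice_weight",
    "rbp_effect",
    "assign_qualifying",
]

#: Default inclusion thresholds per category (minimum weight to qualify).
QUALIFYING_THRESHOLDS: dict[str, float] = {
    "missense": 0.8,
    "splice": 0.1,
    "rbp": 0.25,
}

CATEGORIES = ("pLOF", "missense", "splice", "rbp")


class InvalidAnnotationError(ValueError):
    """Raised when an annotation row violates the input contract."""


@dataclass(frozen=True)
class VariantAnnotation:
    """A single (variant, gene, category) annotation record.

    ``weight`` is the category-specific variant weight in [0, 1]
    (1 for pLOF, mean deleteriousness probability for missense, max
    SpliceAI delta for splice, max |binding-probability change| for rbp).
    ``effect_vector`` holds the signed per-RBP binding changes and is
    present only for rbp variants; ``aa_position`` only for missense.
    """

    variant_id: str
    gene_id: str
    category: str
    weight: float
    strand: str = "+"
    aa_position: int | None = None
    effect_vector: tuple[float, ...] | None = None
    is_also_plof: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidAnnotationError(
                f"{self.variant_id}: unknown category {self.category!r}"
            )
        if not (0.0 <= self.weight <= 1.0) or not np.isfinite(self.weight):
            raise InvalidAnnotationError(
                f"{self.variant_id}: weight {self.weight} outside [0, 1]"
            )
        if (self.category == "rbp") != (self.effect_vector is not None):
            raise InvalidAnnotationError(
                f"{self.variant_id}: effect_vector present iff category is rbp"
            )
        if (self.category == "missense") != (self.aa_position is not None):
            raise InvalidAnnotationError(
                f"{self.variant_id}: aa_position present iff category is missense"
            )
        if self.strand not in ("+", "-"):
            raise InvalidAnnotationError(
                f"{self.variant_id}: strand must be '+' or '-'"
            )


def impact_score(sift: float, polyphen: float, variant_id: str = "?") -> float:
    """Missense impact score: mean predicted deleteriousness probability.

    SIFT scores benign as 1 and deleterious as 0, PolyPhen the reverse,
    so the combined score is ((1 - sift) + polyphen) / 2.
    """
    for name, s in (("sift", sift), ("polyphen", polyphen)):
        if not np.isfinite(s) or not (0.0 <= s <= 1.0):
            raise InvalidAnnotationError(
                f"{variant_id}: {name} score {s} outside [0, 1]"
            )
    return ((1.0 - sift) + polyphen) / 2.0


def splice_weight(deltas: Sequence[float], variant_id: str = "?") -> float:
    """Splice-variant weight: max of the four SpliceAI delta scores
    (acceptor gain/loss, donor gain/loss)."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.shape != (4,):
        raise InvalidAnnotationError(
            f"{variant_id}: expected 4 delta scores, got shape {deltas.shape}"
        )
    if not np.all((deltas >= 0) & (deltas <= 1)):
        raise InvalidAnnotationError(f"{variant_id}: delta scores outside [0, 1]")
    return float(deltas.max())


def rbp_effect(
    p_alt: Sequence[float], p_ref: Sequence[float], variant_id: str = "?"
) -> tuple[np.ndarray, float]:
    """Per-RBP binding change (alt minus ref probability) and its weight.

    Returns the signed effect vector v = p_alt - p_ref (gain of binding
    positive, loss negative) and the weight max_j |v_j|.
    """
    p_alt = np.asarray(p_alt, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    if p_alt.shape != p_ref.shape or p_alt.ndim != 1:
        raise InvalidAnnotationError(
            f"{variant_id}: prediction vectors must be 1-D of equal length"
        )
    for name, p in (("alt", p_alt), ("ref", p_ref)):
        if not np.all((p >= 0) & (p <= 1)):
            raise InvalidAnnotationError(
                f"{variant_id}: {name} binding probabilities outside [0, 1]"
            )
    v = p_alt - p_ref
    return v, float(np.abs(v).max())


@dataclass
class QualifyingSets:
    """Per-gene qualifying variants, one list per category."""

    gene_id: str
    plof: list[VariantAnnotation] = field(default_factory=list)
    missense: list[VariantAnnotation] = field(default_factory=list)
    splice: list[VariantAnnotation] = field(default_factory=list)
    rbp: list[VariantAnnotation] = field(default_factory=list)

    def by_category(self, category: str) -> list[VariantAnnotation]:
        return {
            "pLOF": self.plof,
            "missense": self.missense,
            "splice": self.splice,
            "rbp": self.rbp,
        }[category]


def assign_qualifying(
    annotations: Iterable[VariantAnnotation],
    thresholds: Mapping[str, float] | None = None,
    known_genes: set[str] | None = None,
) -> tuple[dict[str, QualifyingSets], dict[str, int]]:
    """Partition annotations into per-gene qualifying sets.

    pLOF variants always qualify (weight 1).  Missense variants qualify
    if their impact score reaches the threshold, or — the rescue rule —
    if another variant at the same amino-acid position of the same gene
    reaches it.  Splice and rbp variants qualify by weight threshold
    alone.  Variants pointing at genes absent from ``known_genes`` are
    skipped and counted in the returned log dict.

    Output is invariant to input row order: variants are sorted by id
    within each set.
    """
    thr = dict(QUALIFYING_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    skipped = 0
    genes: dict[str, QualifyingSets] = {}
    missense_pool: dict[str, list[VariantAnnotation]] = {}

    for ann in annotations:
        if known_genes is not None and ann.gene_id not in known_genes:
            skipped += 1
            continue
        sets = genes.setdefault(ann.gene_id, QualifyingSets(ann.gene_id))
        if ann.category == "pLOF":
            if ann.weight != 1.0:
                ann = VariantAnnotation(
                    ann.variant_id, ann.gene_id, "pLOF", 1.0, ann.strand
                )
            sets.plof.append(ann)
        elif ann.category == "missense":
            missense_pool.setdefault(ann.gene_id, []).append(ann)
        elif ann.category == "splice":
            if ann.weight >= thr["splice"]:
                sets.splice.append(ann)
        elif ann.category == "rbp":
            if ann.weight >= thr["rbp"]:
                sets.rbp.append(ann)

    # Missense rescue: positions anchored by a variant at/above threshold
    # admit every variant at that position.
    for gene_id, pool in missense_pool.items():
        anchored = {
            a.aa_position for a in pool if a.weight >= thr["missense"]
        }
        sets = genes[gene_id]
        sets.missense.extend(a for a in pool if a.aa_position in anchored)

    for sets in genes.values():
        for cat_list in (sets.plof, sets.missense, sets.splice, sets.rbp):
            cat_list.sort(key=lambda a: a.variant_id)

    return genes, {"skipped_unknown_gene": skipped}


def annotations_from_table(df: pd.DataFrame, n_rbp: int = 8) -> list[VariantAnnotation]:
    """Build annotation records from the external TSV layout.

    Expected columns: variant_id, gene_id, category, sift, polyphen,
    delta_ag, delta_al, delta_dg, delta_dl, rbp_ref_1..R, rbp_alt_1..R,
    aa_position, strand, is_plof; missing values are "NA" (read as NaN).
    Missense rows lacking either SIFT or PolyPhen are excluded (both
    scores are required for the impact score).
    """
    out: list[VariantAnnotation] = []
    ref_cols = [f"rbp_ref_{j}" for j in range(1, n_rbp + 1)]
    alt_cols = [f"rbp_alt_{j}" for j in range(1, n_rbp + 1)]
    for row in df.itertuples(index=False):
        cat = row.category
        vid = row.variant_id
        strand = row.strand if isinstance(row.strand, str) else "+"
        is_plof = bool(row.is_plof) if not pd.isna(row.is_plof) else False
        if cat == "pLOF":
            out.append(VariantAnnotation(vid, row.gene_id, "pLOF", 1.0, strand))
        elif cat == "missense":
            if pd.isna(row.sift) or pd.isna(row.polyphen) or pd.isna(row.aa_position):
                continue
            w = impact_score(float(row.sift), float(row.polyphen), vid)
            out.append(
                VariantAnnotation(
                    vid, row.gene_id, "missense", w, strand,
                    aa_position=int(row.aa_position),
                )
            )
        elif cat == "splice":
            deltas = [row.delta_ag, row.delta_al, row.delta_dg, row.delta_dl]
            if any(pd.isna(d) for d in deltas):
                continue
            w = splice_weight([float(d) for d in deltas], vid)
            out.append(
                VariantAnnotation(
                    vid, row.gene_id, "splice", w, strand, is_also_plof=is_plof
                )
            )
        elif cat == "rbp":
            p_ref = [getattr(row, c) for c in ref_cols]
            p_alt = [getattr(row, c) for c in alt_cols]
            if any(pd.isna(p) for p in p_ref + p_alt):
                continue
            v, w = rbp_effect(
                [float(p) for p in p_alt], [float(p) for p in p_ref], vid
            )
            out.append(
                VariantAnnotation(
                    vid, row.gene_id, "rbp", w, strand,
                    effect_vector=tuple(v), is_also_plof=is_plof,
                )
            )
        else:
            raise InvalidAnnotationError(f"{vid}: unknown category {cat!r}")
    return out
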