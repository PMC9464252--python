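"""Variant-level quality control and ancestry-based pruning.

QC keeps rare (MAF <= 0.1%), well-genotyped (call rate >= 90%),
HWE-consistent (exact-test p >= 1e-5) variants.  Ancestry pruning drops
variants whose allele frequency in any non-reference superpopulation
deviates strongly from the reference population (two-sided Fisher exact
p < 1e-5) or that are selectively missing in a population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "VariantQCReport",
    "QCThresholds",
    "minor_allele_frequency",
    "call_rate",
    "hwe_exact",
    "qc_filter",
    "ancestry_prune",
]


@dataclass(frozen=True)
class QCThresholds:
    maf_max: float = 0.001
    hwe_min: float = 1e-5
    call_rate_min: float = 0.9
    ancestry_min: float = 1e-5


@dataclass
class VariantQCReport:
    variant_id: str
    maf: float
    call_rate: float
    hwe_p: float
    ancestry_p_min: float = 1.0
    fail_reasons: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """Folded minor-allele frequency of one dosage column.

    Dosages are counts of one allele in {0, 1, 2}; NaN marks missing.
    MAF = allele count / (2 * non-missing n), folded to <= 0.5.
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("MAF undefined: all dosages missing")
    af = float(d[ok].sum()) / (2.0 * n)
    return min(af, 1.0 - af)


def call_rate(dosages: np.ndarray) -> float:
    d = np.asarray(dosages, dtype=float)
    return float((~np.isnan(d)).mean())


def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Full enumeration over heterozygote counts conditional on the allele
    counts; the p-value sums the probabilities of all configurations no
    more likely than the observed one (standard exact-test convention).
    Monomorphic sites return 1.
    """
    for c in (n_hom_major, n_het, n_hom_minor):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("empty genotype table")
    # work with the rarer allele
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if rare == 0:
        return 1.0

    # P(het = h | allele counts) over all h with the right parity
    hets = np.arange(rare % 2, rare + 1, 2)
    # log-probabilities via the standard conditional distribution
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    from scipy.special import gammaln

    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    # tolerance guards against ties lost to rounding
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def qc_filter(
    dosages: np.ndarray,
    variant_ids: list[str],
    thresholds: QCThresholds | None = None,
) -> list[VariantQCReport]:
    """Per-variant QC reports for an n x m dosage matrix (NaN missing).

    Every violated threshold is recorded, not just the first.
    """
    thr = thresholds or QCThresholds()
    d = np.asarray(dosages, dtype=float)
    reports = []
    for j, vid in enumerate(variant_ids):
        col = d[:, j]
        ok = ~np.isnan(col)
        cr = float(ok.mean())
        if ok.sum() == 0:
            rep = VariantQCReport(vid, np.nan, 0.0, 1.0)
            rep.fail_reasons.add("low_call_rate")
            reports.append(rep)
            continue
        maf = minor_allele_frequency(col)
        obs = col[ok].astype(int)
        n_het = int((obs == 1).sum())
        n_hom_alt = int((obs == 2).sum())
        n_hom_ref = int((obs == 0).sum())
        hwe_p = hwe_exact(n_hom_ref, n_het, n_hom_alt)
        rep = VariantQCReport(vid, maf, cr, hwe_p)
        if maf > thr.maf_max:
            rep.fail_reasons.add("common")
        if cr < thr.call_rate_min:
            rep.fail_reasons.add("low_call_rate")
        if hwe_p < thr.hwe_min:
            rep.fail_reasons.add("hwe")
        reports.append(rep)
    return reports


def ancestry_prune(
    counts: Mapping[str, tuple[int, int]],
    reference_pop: str,
    p_min: float = 1e-5,
) -> tuple[bool, float, set[str]]:
    """Decide whether one variant survives ancestry-based pruning.

    ``counts`` maps population -> (alt allele count, total genotyped
    alleles).  Each non-reference population is compared with the
    reference by a two-sided Fisher exact test on the 2x2 allele-count
    table; the variant is excluded if any p < ``p_min`` or if any
    population has zero genotyped alleles (selectively missing).

    Returns (keep, min p across comparisons, fail reasons).
    """
    if reference_pop not in counts:
        raise ValueError(f"reference population {reference_pop!r} absent from counts")
    ref_alt, ref_tot = counts[reference_pop]
    if ref_tot <= 0:
        raise ValueError("reference population has no genotyped alleles")
    reasons: set[str] = set()
    p_min_obs = 1.0
    for pop, (alt, tot) in counts.items():
        if tot <= 0:
            reasons.add("selectively_missing")
            continue
        if pop == reference_pop:
            continue
        table = [[alt, tot - alt], [ref_alt, ref_tot - ref_alt]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        p_min_obs = min(p_min_obs, p)
        if p < p_min:
            reasons.add("ancestry")
    return (not reasons, p_min_obs, reasons)
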