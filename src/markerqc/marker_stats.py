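"""Per-marker descriptive statistics and the quality-filter cascade.

Statistics are computed from allele counts under codominant coding: a
heterozygote (dosage 1) contributes one copy of each allele.  All values
are invariant to which allele is labelled "alt" (d -> 2 - d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested for an all-missing locus."""


def allele_frequencies(g: GenotypeMatrix, locus_id: str) -> np.ndarray:
    """Allele frequencies (p_ref, p_alt) at one locus, missing excluded.

    p_alt = sum(dosage) / (2 * n_called).
    """
    j = g.locus_index(locus_id)
    col = g.dosage[:, j]
    called = col != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise UndefinedStatisticError(
            f"locus {locus_id!r} has no non-missing calls"
        )
    p_alt = float(col[called].sum()) / (2 * n_called)
    return np.array([1.0 - p_alt, p_alt])


def gene_diversity(p: np.ndarray) -> float:
    """Gene diversity (expected heterozygosity): 1 - sum(p_i^2)."""
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - np.sum(p**2))


def pic(p: np.ndarray) -> float:
    """Polymorphism information content.

    pic = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    sq = p**2
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * sq[i] * sq[j]
    return float(1.0 - sq.sum() - cross)


def summarize_markers(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus summary table.

    Columns: ``n_called``, ``missing_rate``, ``het_rate``, ``p_alt``,
    ``maf``, ``he``, ``pic``; indexed by locus id.  All-missing loci get
    NaN statistics (they are flagged, not errors).
    """
    d = g.dosage
    n = g.n_samples
    called = d != MISSING
    n_called = called.sum(axis=0)
    missing_rate = 1.0 - n_called / n if n else np.full(g.n_loci, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = (d == 1).sum(axis=0) / n_called
        alt_count = np.where(called, d, 0).sum(axis=0)
        p_alt = alt_count / (2.0 * n_called)
    p_alt = np.where(n_called > 0, p_alt, np.nan)
    het_rate = np.where(n_called > 0, het_rate, np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    he = 1.0 - (p_alt**2 + (1.0 - p_alt) ** 2)
    pic_v = he - 2.0 * (p_alt**2) * ((1.0 - p_alt) ** 2)
    return pd.DataFrame(
        {
            "n_called": n_called.astype(int),
            "missing_rate": missing_rate,
            "het_rate": het_rate,
            "p_alt": p_alt,
            "maf": maf,
            "he": he,
            "pic": pic_v,
        },
        index=pd.Index(g.locus_ids, name="locus_id"),
    )


@dataclass(frozen=True)
class FilterThresholds:
    """Quality-filter cutoffs; defaults follow the published cascade.

    A locus is removed when maf < ``min_maf`` OR pic < ``min_pic`` OR
    het_rate > ``max_het`` OR missing_rate > ``max_missing``.  All
    inequalities are strict, so boundary values are kept.
    """

    min_maf: float = 0.05
    min_pic: float = 0.18
    max_het: float = 0.09
    max_missing: float = 0.24


#: Rejection reasons in fixed evaluation order (first failing rule wins).
FILTER_RULES = ("MAF", "PIC", "het", "missing")


@dataclass
class FilterResult:
    kept: list[str]
    rejected: dict[str, str]  # locus id -> first failing rule
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def filter_markers(
    summaries: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> FilterResult:
    """Apply the quality-filter cascade to a marker summary table.

    Membership is conjunctive; the per-locus rejection reason is the
    first failing rule in MAF, PIC, het, missing order.  Loci with
    undefined statistics (all-missing) fail the MAF rule.
    """
    thr = thresholds or FilterThresholds()
    kept: list[str] = []
    rejected: dict[str, str] = {}
    for lid, row in summaries.iterrows():
        maf, pic_v = row["maf"], row["pic"]
        het, miss = row["het_rate"], row["missing_rate"]
        if not np.isfinite(maf) or maf < thr.min_maf:
            rejected[lid] = "MAF"
        elif pic_v < thr.min_pic:
            rejected[lid] = "PIC"
        elif het > thr.max_het:
            rejected[lid] = "het"
        elif miss > thr.max_missing:
            rejected[lid] = "missing"
        else:
            kept.append(lid)
    return FilterResult(kept=kept, rejected=rejected, thresholds=thr)
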