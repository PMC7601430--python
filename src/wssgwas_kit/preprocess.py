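"""Phenotype derivation and genotype quality control with per-filter accounting.

Yearling weight is a linear extrapolation of the last test-period growth
segment to day 365.  SNP filters (unknown position, sex chromosome, call
rate, minor allele frequency, Hardy-Weinberg heterozygote deviation) and
animal filters (missing rate, parent-progeny opposing homozygotes,
pedigree-genomic deviation, absent phenotypes) are per-unit predicates:
the surviving set is order-independent, but each removed unit is
attributed to the FIRST filter it fails, in the order listed above, so
removal counts sum exactly to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel, SEX_CHROMOSOMES, UNKNOWN_CHROMOSOME
from .pedigree import Pedigree


class InvalidRecordError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class WeightRecord:
    """Two test weighings: w_t at day t (test termination, ~365 d) and the
    previous weighing w_prev at day t_prev."""

    w_t: float
    w_prev: float
    t: float
    t_prev: float


def adjust_yearling_weight(rec: WeightRecord) -> float:
    """YW = (w_t - w_prev)/(t - t_prev) * (365 - t_prev) + w_prev.

    Extrapolates the daily gain of the last growth segment from the
    previous weighing date to day 365.
    """
    if rec.t <= rec.t_prev:
        raise InvalidRecordError(
            f"test day {rec.t} must be after previous weighing day {rec.t_prev}"
        )
    gain = (rec.w_t - rec.w_prev) / (rec.t - rec.t_prev)
    return gain * (365.0 - rec.t_prev) + rec.w_prev


#: Trait-specific record-retention rules: rows must satisfy every
#: (column, operator, value) condition to be kept.  Marbling scores before
#: 2005 are dropped (scored on an incompatible pre-2005 scale).
DEFAULT_TRAIT_RULES: dict[str, list[tuple[str, str, object]]] = {
    "MS": [("year", ">=", 2005)],
}

_OPS = {
    ">=": lambda s, v: s >= v,
    ">": lambda s, v: s > v,
    "<=": lambda s, v: s <= v,
    "<": lambda s, v: s < v,
    "==": lambda s, v: s == v,
    "!=": lambda s, v: s != v,
}


def filter_phenotypes(
    table: pd.DataFrame,
    trait: str,
    rules: list[tuple[str, str, object]] | None = None,
) -> pd.DataFrame:
    """Drop rows violating the trait's retention rules.

    ``rules`` defaults to :data:`DEFAULT_TRAIT_RULES` for the trait (empty
    if none registered).  Rows with a missing trait value are untouched by
    rules (they carry no record to filter).
    """
    if trait not in table.columns:
        raise ConfigurationError(f"trait column {trait!r} not in phenotype table")
    if rules is None:
        rules = DEFAULT_TRAIT_RULES.get(trait, [])
    keep = pd.Series(True, index=table.index)
    for column, op, value in rules:
        if column not in table.columns:
            raise ConfigurationError(f"rule column {column!r} not in table")
        if op not in _OPS:
            raise ConfigurationError(f"unknown rule operator {op!r}")
        keep &= _OPS[op](table[column], value) | table[trait].isna()
    return table.loc[keep].reset_index(drop=True)


@dataclass
class QcThresholds:
    """Quality-control cutoffs (defaults: the BovineSNP50 study settings)."""

    min_call_rate: float = 0.98
    min_maf: float = 0.01
    max_hwe_het_deviation: float = 0.15
    max_animal_missing_rate: float = 0.10
    parent_conflict_rate: float = 0.01
    a22_g_diag_deviation: float = 0.25
    a22_g_offdiag_deviation: float = 0.50


@dataclass
class QcReport:
    removed_by_filter: dict[str, int] = field(default_factory=dict)
    survivors_snps: int | None = None
    survivors_animals: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.removed_by_filter.items()), columns=["filter", "count"]
        )


SNP_FILTER_ORDER = [
    "unknown_position", "sex_chromosome", "call_rate", "maf", "hwe",
]


def filter_snps(
    panel: GenotypePanel, thresholds: QcThresholds | None = None
) -> tuple[GenotypePanel, QcReport]:
    """Apply the SNP filters; attribution follows :data:`SNP_FILTER_ORDER`.

    The HWE check is the literal heterozygote-frequency deviation
    |het_obs - 2p(1-p)| > threshold, not a chi-square test.
    """
    if panel.n_snps == 0:
        raise ValueError("empty genotype panel")
    thr = thresholds or QcThresholds()
    chrom = panel.snp_map["chrom"].astype(str).to_numpy()
    fails = {
        "unknown_position": chrom == UNKNOWN_CHROMOSOME,
        "sex_chromosome": np.isin(chrom, sorted(SEX_CHROMOSOMES)),
        "call_rate": panel.call_rate() < thr.min_call_rate,
    }
    p = panel.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    fails["maf"] = maf < thr.min_maf
    het_obs = np.nanmean(panel.dosages == 1.0, axis=0)
    het_exp = 2.0 * p * (1.0 - p)
    fails["hwe"] = np.abs(het_obs - het_exp) > thr.max_hwe_het_deviation

    report = QcReport()
    attributed = np.zeros(panel.n_snps, dtype=bool)
    for name in SNP_FILTER_ORDER:
        hit = fails[name] & ~attributed
        report.removed_by_filter[name] = int(hit.sum())
        attributed |= fails[name]
    survivors = ~attributed
    report.survivors_snps = int(survivors.sum())
    return panel.subset_snps(survivors), report


ANIMAL_FILTER_ORDER = [
    "missing_rate", "parent_conflict", "pedigree_genomic_deviation",
    "no_phenotype",
]


def filter_animals(
    panel: GenotypePanel,
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    analyzed_traits: list[str] | None = None,
    max_snps_for_deviation: int = 5000,
    deviation_seed: int = 0,
) -> tuple[GenotypePanel, QcReport]:
    """Apply the animal exclusion rules sequentially.

    Rules run in :data:`ANIMAL_FILTER_ORDER`; each later rule sees the
    panel with earlier exclusions already removed (a conflicting progeny,
    for example, no longer contributes to the genomic-deviation check).
    For the deviation rule, G and A22 are compared on a deterministic
    subsample of at most ``max_snps_for_deviation`` SNPs: an animal is
    flagged when |G_ii - A22_ii| exceeds the diagonal threshold or any
    pairwise |G_ij - A22_ij| exceeds the off-diagonal threshold (only the
    progeny is removed in a parent-progeny conflict).
    An animal counts as phenotyped when any analyzed trait is non-missing.
    """
    thr = thresholds or QcThresholds()
    ped_ids = set(pedigree.ids)
    unknown = [a for a in panel.animal_ids if a not in ped_ids]
    if unknown:
        raise ValueError(
            f"{len(unknown)} genotyped animals missing from pedigree "
            f"(first: {unknown[0]!r})"
        )
    report = QcReport()
    current = panel

    # 1. per-animal missing rate
    miss = current.animal_missing_rate() > thr.max_animal_missing_rate
    report.removed_by_filter["missing_rate"] = int(miss.sum())
    current = current.subset_animals(
        [a for a, f in zip(current.animal_ids, miss) if not f]
    )

    # 2. parent-progeny opposing homozygotes: remove the progeny
    genotyped = set(current.animal_ids)
    row = {a: i for i, a in enumerate(current.animal_ids)}
    conflicted: set[str] = set()
    dos = current.dosages
    for child, sire, dam in pedigree.records:
        if child not in genotyped:
            continue
        for parent in (sire, dam):
            if parent is None or parent not in genotyped:
                continue
            c, q = dos[row[child]], dos[row[parent]]
            both = ~np.isnan(c) & ~np.isnan(q)
            if not both.any():
                continue
            opposing = ((c == 0) & (q == 2)) | ((c == 2) & (q == 0))
            if opposing[both].mean() > thr.parent_conflict_rate:
                conflicted.add(child)
    report.removed_by_filter["parent_conflict"] = len(conflicted)
    current = current.subset_animals(
        [a for a in current.animal_ids if a not in conflicted]
    )

    # 3. pedigree vs genomic relationship deviation.  G is computed on
    # informative autosomal SNPs (observed MAF >= 0.05, known position)
    # so that uninformative columns do not deflate the VanRaden scale.
    # Diagonal outliers are flagged first; the pairwise check then runs
    # among the remaining animals only, because a grossly aberrant sample
    # distorts every pairwise entry it touches.
    from .relationships import compute_A, compute_G

    chrom = current.snp_map["chrom"].astype(str).to_numpy()
    p = current.allele_frequencies()
    informative = (
        (np.minimum(p, 1 - p) >= 0.05)
        & (chrom != UNKNOWN_CHROMOSOME)
        & ~np.isin(chrom, sorted(SEX_CHROMOSOMES))
    )
    sub = current.subset_snps(informative)
    if sub.n_snps > max_snps_for_deviation:
        rng = np.random.default_rng(deviation_seed)
        pick = np.zeros(sub.n_snps, dtype=bool)
        pick[rng.choice(sub.n_snps, max_snps_for_deviation, replace=False)] = True
        sub = sub.subset_snps(pick)
    G, _ = compute_G(sub)
    A22 = compute_A(pedigree, subset=current.animal_ids)
    dev = np.abs(G.values - A22.values)
    flag = np.diag(dev) > thr.a22_g_diag_deviation
    ok = np.where(~flag)[0]
    off = dev[np.ix_(ok, ok)]
    np.fill_diagonal(off, 0.0)
    flag[ok[(off > thr.a22_g_offdiag_deviation).any(axis=1)]] = True
    report.removed_by_filter["pedigree_genomic_deviation"] = int(flag.sum())
    current = current.subset_animals(
        [a for a, f in zip(current.animal_ids, flag) if not f]
    )

    # 4. no phenotype for any analyzed trait
    if analyzed_traits is None:
        analyzed_traits = [
            c for c in phenotypes.columns
            if c != "animal" and pd.api.types.is_numeric_dtype(phenotypes[c])
        ]
    recorded = set(
        phenotypes.loc[
            phenotypes[analyzed_traits].notna().any(axis=1), "animal"
        ].astype(str)
    ) if analyzed_traits else set(phenotypes["animal"].astype(str))
    nopheno = [a for a in current.animal_ids if a not in recorded]
    report.removed_by_filter["no_phenotype"] = len(nopheno)
    current = current.subset_animals(
        [a for a in current.animal_ids if a in recorded]
    )

    report.survivors_animals = current.n_animals
    return current, report


def run_qc(
    panel: GenotypePanel,
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    **animal_kwargs,
) -> tuple[GenotypePanel, QcReport, QcReport]:
    """Animal filters first, then SNP filters on the remaining animals."""
    panel, animal_report = filter_animals(
        panel, pedigree, phenotypes, thresholds, **animal_kwargs
    )
    panel, snp_report = filter_snps(panel, thresholds)
    return panel, animal_report, snp_report
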