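"""Synthetic pedigrees, genotypes and phenotypes for the ssGBLUP pipeline.

The generators emulate the statistical structure the single-trait animal
model assumes: a multi-generation pedigree, gene-dropped SNP genotypes
(independent loci by default, optional founder LD blocks), and phenotypes
composed of fixed effects, QTL dosage effects, a pedigree-transmitted
polygenic term and i.i.d. residual noise.  True simulated values are kept
alongside observations so recovery can be tested.

Two packaged fixtures mirror printed material from the Hanwoo BovineSNP50
study this toolkit re-implements: a quality-control fixture with exact
per-filter failure counts, and the table of selected 20-SNP windows with
their annotated genes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .panel import GenotypePanel, SEX_CHROMOSOMES, UNKNOWN_CHROMOSOME
from .pedigree import Pedigree


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs for the pedigree / genotype / phenotype simulators.

    ``sigma_a2`` is the polygenic additive variance; QTL listed in
    ``qtl_spec`` (as ``(snp_index, allele-substitution effect)``) add
    genetic variance on top of it.  ``maf_range`` bounds the founder
    allele frequencies.  ``ld_block_size`` > 1 copies founder alleles in
    blocks of that many SNPs, inducing strong within-block LD.
    """

    n_founders: int = 50
    n_generations: int = 3
    matings_per_generation: int = 25
    offspring_per_mating: int = 2
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000_000
    qtl_spec: list[tuple[int, float]] = field(default_factory=list)
    sigma_a2: float = 1.0
    sigma_e2: float = 1.0
    fixed_effects_spec: list[tuple[str, int, float]] = field(default_factory=list)
    prop_genotyped: float = 1.0
    ld_block_size: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("need at least two founders")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if self.sigma_a2 <= 0 or self.sigma_e2 <= 0:
            raise ConfigurationError("variance components must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        for k, _ in self.qtl_spec:
            if not (0 <= k < self.n_snps):
                raise ConfigurationError(f"QTL index {k} out of range")
        if not (0 < self.prop_genotyped <= 1):
            raise ConfigurationError("prop_genotyped must be in (0, 1]")


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Discrete-generation random-mating pedigree.

    Founders (generation 0) have unknown parents; each later generation
    consists of ``matings_per_generation`` sire/dam pairs drawn from the
    previous generation (sexes alternate at birth), each producing
    ``offspring_per_mating`` offspring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str | None, str | None]] = []
    males: list[str] = []
    females: list[str] = []
    for i in range(config.n_founders):
        aid = f"G0_{i:05d}"
        records.append((aid, None, None))
        (males if i % 2 == 0 else females).append(aid)
    for g in range(1, config.n_generations + 1):
        new_m: list[str] = []
        new_f: list[str] = []
        k = 0
        for _ in range(config.matings_per_generation):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            for _ in range(config.offspring_per_mating):
                aid = f"G{g}_{k:05d}"
                records.append((aid, sire, dam))
                (new_m if k % 2 == 0 else new_f).append(aid)
                k += 1
        males, females = new_m, new_f
    return Pedigree(records)


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> GenotypePanel:
    """Gene-dropping: founder alleles ~ Bernoulli(p_i), descendants inherit
    one allele per parent per locus.  Loci segregate independently unless
    ``ld_block_size`` > 1, in which case founder haplotypes are drawn from
    a shared block-level uniform variate AND transmission picks the
    parental haplotype per block (complete linkage inside a block, free
    recombination between blocks) — a crude but effective LD surrogate."""
    config.validate()
    rng = np.random.default_rng(_subseed(config.seed, "genotypes"))
    n, m = len(pedigree), config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    b = config.ld_block_size
    n_blocks = -(-m // b)
    hap1 = np.zeros((n, m), dtype=np.int8)
    hap2 = np.zeros((n, m), dtype=np.int8)
    s, d = pedigree.parent_indices()
    for i in pedigree.topological_order():
        for hap, parent in ((hap1, s[i]), (hap2, d[i])):
            if parent < 0:
                if b > 1:
                    u = np.repeat(rng.random(n_blocks), b)[:m]
                else:
                    u = rng.random(m)
                hap[i] = u < p
            else:
                if b > 1:
                    pick = np.repeat(rng.random(n_blocks) < 0.5, b)[:m]
                else:
                    pick = rng.random(m) < 0.5
                hap[i] = np.where(pick, hap1[parent], hap2[parent])
    dosages = (hap1 + hap2).astype(np.float32)
    return GenotypePanel(pedigree.ids, dosages, _even_map(config))


def _even_map(config: SimulationConfig) -> pd.DataFrame:
    """Markers evenly spaced across equal-length autosomes."""
    m, k = config.n_snps, config.n_chromosomes
    per = -(-m // k)
    chroms, pos = [], []
    for j in range(m):
        c, r = divmod(j, per)
        chroms.append(str(c + 1))
        pos.append(int((r + 1) * config.chromosome_length_bp / (per + 1)))
    return pd.DataFrame(
        {"snp": [f"snp{j:06d}" for j in range(m)], "chrom": chroms, "pos_bp": pos}
    )


def simulate_phenotypes(
    pedigree: Pedigree,
    panel: GenotypePanel | None,
    config: SimulationConfig,
    trait: str = "y",
) -> pd.DataFrame:
    """Phenotypes y = fixed effects + a + e down the pedigree.

    The true breeding value a is a QTL part (centered dosage times effect,
    requiring ``panel``) plus a polygenic part generated recursively:
    founders ~ N(0, sigma_a2), offspring = parent average + Mendelian
    sampling with variance sigma_a2/2 * (1 - (F_s + F_d)/2) (parental
    inbreeding F from the pedigree A recursion).  Returns one record per
    animal with the observed phenotype, fixed-effect level columns and
    the true components (``true_bv``, ``true_poly``, ``true_qtl``).
    """
    config.validate()
    if config.qtl_spec and panel is None:
        raise ConfigurationError("QTL effects require a genotype panel")
    rng = np.random.default_rng(_subseed(config.seed, "phenotypes"))
    n = len(pedigree)
    s, d = pedigree.parent_indices()
    from .relationships import inbreeding_coefficients

    F = inbreeding_coefficients(pedigree)
    sa2 = config.sigma_a2
    poly = np.zeros(n)
    for i in pedigree.topological_order():
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            ms_var = 0.5 * sa2 * (1.0 - 0.5 * (F[si] + F[di]))
            poly[i] = 0.5 * (poly[si] + poly[di]) + rng.normal(0, np.sqrt(ms_var))
        elif si >= 0 or di >= 0:
            pidx = si if si >= 0 else di
            ms_var = sa2 * (0.75 - 0.25 * F[pidx])
            poly[i] = 0.5 * poly[pidx] + rng.normal(0, np.sqrt(ms_var))
        else:
            poly[i] = rng.normal(0, np.sqrt(sa2))
    qtl = np.zeros(n)
    if config.qtl_spec:
        assert panel is not None
        order = [panel.animal_ids.index(a) for a in pedigree.ids]
        dos = panel.imputed_dosages()[order]
        p = panel.allele_frequencies()
        for k, beta in config.qtl_spec:
            qtl += (dos[:, k] - 2.0 * p[k]) * beta
    a = poly + qtl
    e = rng.normal(0, np.sqrt(config.sigma_e2), size=n)
    table = pd.DataFrame({"animal": pedigree.ids})
    fixed_total = np.zeros(n)
    for name, n_levels, sd in config.fixed_effects_spec:
        levels = rng.integers(n_levels, size=n)
        effects = rng.normal(0, sd, size=n_levels)
        table[name] = [f"{name}_{v}" for v in levels]
        fixed_total += effects[levels]
    table[trait] = fixed_total + a + e
    table["true_bv"] = a
    table["true_poly"] = poly
    table["true_qtl"] = qtl
    return table


def simulate_study(
    config: SimulationConfig, trait: str = "y"
) -> tuple[Pedigree, GenotypePanel, list[str], pd.DataFrame]:
    """Pedigree + genotypes + phenotypes + the genotyped subset.

    The genotyped subset (a fraction ``prop_genotyped``, sampled uniformly
    without replacement) stands in for the genotyped animals nested in a
    larger phenotyped population.
    """
    pedigree = simulate_pedigree(config)
    panel = simulate_genotypes(pedigree, config)
    phenotypes = simulate_phenotypes(pedigree, panel, config, trait=trait)
    rng = np.random.default_rng(_subseed(config.seed, "genotyped_subset"))
    n_geno = max(1, int(round(config.prop_genotyped * len(pedigree))))
    pick = sorted(rng.choice(len(pedigree), size=n_geno, replace=False))
    genotyped = [pedigree.ids[i] for i in pick]
    return pedigree, panel, genotyped, phenotypes


def one_qtl_recovery_study(
    seed: int,
    n_snps: int = 2000,
    qtl_index: int = 1000,
    qtl_fraction: float = 0.25,
    sigma_poly2: float = 0.75,
    heritability: float = 0.4,
):
    """A 500-animal, one-QTL study used for detection-power checks.

    A 5-generation pedigree (100 founders, 100 offspring per generation)
    is genotyped at ``n_snps`` SNPs carrying 20-SNP LD blocks.  The QTL
    effect is set from the realized allele frequency so the QTL explains
    ``qtl_fraction`` of the total additive variance
    sigma_poly2 / (1 - qtl_fraction); the residual variance completes the
    requested heritability.  Returns
    ``(pedigree, panel, phenotypes, qtl_index, sigma_a2, sigma_e2)``.
    """
    sigma_a2 = sigma_poly2 / (1.0 - qtl_fraction)
    v_qtl = qtl_fraction * sigma_a2
    sigma_e2 = sigma_a2 * (1.0 - heritability) / heritability
    base = SimulationConfig(
        n_founders=100, n_generations=4, matings_per_generation=50,
        offspring_per_mating=2, n_snps=n_snps, n_chromosomes=5,
        maf_range=(0.1, 0.5), sigma_a2=sigma_poly2, sigma_e2=sigma_e2,
        ld_block_size=20, seed=seed,
    )
    pedigree = simulate_pedigree(base)
    panel = simulate_genotypes(pedigree, base)
    p = float(panel.allele_frequencies()[qtl_index])
    beta = float(np.sqrt(v_qtl / (2.0 * p * (1.0 - p))))
    base.qtl_spec = [(qtl_index, beta)]
    phenotypes = simulate_phenotypes(pedigree, panel, base)
    return pedigree, panel, phenotypes, qtl_index, sigma_a2, sigma_e2


def null_genome_study(seed: int, n_snps: int = 1700):
    """Like :func:`one_qtl_recovery_study` but with no QTL at all and the
    default independent-locus genome; used to check that no window claims
    a large share of variance under the null."""
    sigma_a2, h2 = 1.0, 0.4
    sigma_e2 = sigma_a2 * (1.0 - h2) / h2
    base = SimulationConfig(
        n_founders=100, n_generations=4, matings_per_generation=50,
        offspring_per_mating=2, n_snps=n_snps, n_chromosomes=5,
        maf_range=(0.1, 0.5), sigma_a2=sigma_a2, sigma_e2=sigma_e2,
        seed=seed,
    )
    pedigree = simulate_pedigree(base)
    panel = simulate_genotypes(pedigree, base)
    phenotypes = simulate_phenotypes(pedigree, panel, base)
    return pedigree, panel, phenotypes, sigma_a2, sigma_e2


def _subseed(seed: int, label: str) -> np.random.SeedSequence:
    tag = zlib.crc32(label.encode()) % 2**31
    return np.random.SeedSequence([seed % 2**31, tag])


# ---------------------------------------------------------------------------
# Quality-control fixture


@dataclass
class QcFixtureSpec:
    """Exact per-filter failure counts for a constructed QC fixture.

    Failure classes are disjoint by construction: every SNP (animal)
    trips at most one filter, and survivors pass all filters with margin.
    """

    n_total_snps: int
    n_unknown_position: int
    n_sex_chromosome: int
    n_low_call_rate: int
    n_low_maf: int
    n_hwe_fail: int
    n_total_animals: int
    n_high_missing: int
    n_parent_conflict: int
    n_pedigree_genomic_deviation: int
    n_no_phenotype: int

    @property
    def n_surviving_snps(self) -> int:
        return self.n_total_snps - (
            self.n_unknown_position + self.n_sex_chromosome
            + self.n_low_call_rate + self.n_low_maf + self.n_hwe_fail
        )

    @property
    def n_surviving_animals(self) -> int:
        return self.n_total_animals - (
            self.n_high_missing + self.n_parent_conflict
            + self.n_pedigree_genomic_deviation + self.n_no_phenotype
        )

    def validate(self) -> None:
        counts = [
            self.n_total_snps, self.n_unknown_position, self.n_sex_chromosome,
            self.n_low_call_rate, self.n_low_maf, self.n_hwe_fail,
            self.n_total_animals, self.n_high_missing, self.n_parent_conflict,
            self.n_pedigree_genomic_deviation, self.n_no_phenotype,
        ]
        if any(c < 0 for c in counts):
            raise ConfigurationError("fixture counts must be non-negative")
        if self.n_surviving_snps < 1:
            raise ConfigurationError("SNP failure counts exceed the panel size")
        if self.n_surviving_animals < max(2, self.n_parent_conflict):
            raise ConfigurationError(
                "animal exclusion counts leave too few survivors "
                "(conflict progeny need surviving genotyped parents)"
            )


def hanwoo_qc_spec() -> QcFixtureSpec:
    """Per-filter counts of the Hanwoo BovineSNP50 study: 45,304 SNPs and
    1,679 genotyped animals in, 34,460 SNPs and 1,540 animals out."""
    return QcFixtureSpec(
        n_total_snps=45_304,
        n_unknown_position=302,
        n_sex_chromosome=1_150,
        n_low_call_rate=2_677,
        n_low_maf=6_684,
        n_hwe_fail=31,
        n_total_animals=1_679,
        n_high_missing=73,
        n_parent_conflict=11,
        n_pedigree_genomic_deviation=39,
        n_no_phenotype=16,
    )


def make_qc_fixture(
    spec: QcFixtureSpec, seed: int = 0
) -> tuple[GenotypePanel, Pedigree, pd.DataFrame]:
    """Panel/pedigree/phenotypes in which exactly the specified numbers of
    SNPs and animals trip each quality filter, and nothing else does.

    Construction (filter margins in parentheses):

    * unknown-position SNPs: chromosome ``"0"``; sex-chromosome SNPs: ``"X"``;
    * low-call-rate SNPs: 4% missing entries (threshold 2%);
    * low-MAF SNPs: founder frequency 0.002 (threshold 0.01);
    * HWE-failing SNPs: every animal heterozygous (deviation 0.5 vs 0.15);
    * surviving SNPs: HWE draws at frequencies in [0.10, 0.45];
    * high-missing animals: 12% missing (threshold 10%);
    * parent-conflict animals: progeny of a surviving genotyped parent with
      6% of surviving hom-parent loci flipped to the opposing homozygote;
    * pedigree-genomic-deviation animals: homozygous alt everywhere, so
      diag(G) far exceeds diag(A22) = 1;
    * no-phenotype animals: absent from the phenotype table.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    m, n = spec.n_total_snps, spec.n_total_animals
    n_surv = spec.n_surviving_animals

    # SNP class layout (permuted)
    classes = (
        ["unknown"] * spec.n_unknown_position
        + ["sex"] * spec.n_sex_chromosome
        + ["call"] * spec.n_low_call_rate
        + ["maf"] * spec.n_low_maf
        + ["hwe"] * spec.n_hwe_fail
        + ["pass"] * spec.n_surviving_snps
    )
    cls = np.array(classes)[rng.permutation(m)]  # class of column j

    p = rng.uniform(0.10, 0.45, size=m)
    p[cls == "maf"] = 0.002

    # animal class layout: surviving block first, then excluded classes
    ids: list[str] = []
    a_cls: list[str] = []
    for label, count in (
        ("surv", n_surv),
        ("miss", spec.n_high_missing),
        ("conf", spec.n_parent_conflict),
        ("dev", spec.n_pedigree_genomic_deviation),
        ("noph", spec.n_no_phenotype),
    ):
        for k in range(count):
            ids.append(f"{label.upper()}{k:05d}")
            a_cls.append(label)
    a_cls_arr = np.array(a_cls)

    # surviving-animal block: exact genotype counts per column so observed
    # MAF and heterozygote frequencies sit at their targets regardless of
    # panel size (per-column random row permutation via argsort)
    n1 = np.round(2.0 * p * (1.0 - p) * n_surv).astype(np.int64)
    n2 = np.round(p * p * n_surv).astype(np.int64)
    ranks = np.argsort(
        rng.random((n_surv, m), dtype=np.float32), axis=0
    ).astype(np.int32)
    dos = np.empty((n, m), dtype=np.float32)
    dos[:n_surv] = (ranks < n2) * 2.0 + ((ranks >= n2) & (ranks < n2 + n1))

    # excluded classes: plain HWE draws (their column stats never enter QC)
    n_other = n - n_surv
    if n_other:
        u = rng.random((n_other, m), dtype=np.float32)
        t1 = ((1.0 - p) ** 2).astype(np.float32)
        t2 = (t1 + 2.0 * p * (1.0 - p)).astype(np.float32)
        dos[n_surv:] = (u > t1).astype(np.float32) + (u > t2)
        del u

    # low-call-rate columns: exactly ceil(2% shortfall + margin) missing
    # entries among surviving animals (threshold: call rate < 0.98)
    k_call = max(1, int(np.ceil(0.04 * n_surv)))
    call_cols = np.where(cls == "call")[0]
    col_mask = np.zeros(m, dtype=bool)
    col_mask[call_cols] = True
    dos[:n_surv][(ranks < k_call) & col_mask] = np.nan
    del ranks

    dos[:, cls == "hwe"] = 1.0

    miss_rows = np.where(a_cls_arr == "miss")[0]
    k_miss = max(1, int(np.round(0.12 * m)))
    for i in miss_rows:
        dos[i, rng.choice(m, size=k_miss, replace=False)] = np.nan

    dev_rows = np.where(a_cls_arr == "dev")[0]
    dos[dev_rows, :] = 2.0

    # conflict progeny: inherit one allele from a surviving parent, then
    # flip opposing homozygotes at 6% of surviving hom-parent loci
    conf_rows = np.where(a_cls_arr == "conf")[0]
    surv_rows = np.where(a_cls_arr == "surv")[0]
    records: list[tuple[str, str | None, str | None]] = []
    pass_cols = cls == "pass"
    for k, i in enumerate(conf_rows):
        parent_row = surv_rows[k]
        par = np.nan_to_num(dos[parent_row], nan=1.0)
        from_parent = np.where(par == 1.0, (rng.random(m) < 0.5), par / 2.0)
        other = rng.random(m) < p
        child = np.asarray(from_parent, dtype=np.float32) + other
        hom_parent = pass_cols & ((par == 0.0) | (par == 2.0))
        flip = hom_parent & (rng.random(m) < 0.06)
        child[flip] = 2.0 - par[flip]
        dos[i] = child
        records.append((ids[i], ids[parent_row], None))
    conflict_children = {ids[i] for i in conf_rows}
    for aid in ids:
        if aid not in conflict_children:
            records.append((aid, None, None))
    pedigree = Pedigree(records)

    # marker map: survivors and failing autosomal classes on autosomes 1..29
    chroms = np.empty(m, dtype=object)
    pos = np.zeros(m, dtype=np.int64)
    auto = ~np.isin(cls, ["unknown", "sex"])
    n_auto = int(auto.sum())
    chroms[auto] = [str(1 + (j % 29)) for j in range(n_auto)]
    pos[auto] = [1000 + 100 * (j // 29) for j in range(n_auto)]
    chroms[cls == "unknown"] = UNKNOWN_CHROMOSOME
    pos[cls == "unknown"] = 0
    chroms[cls == "sex"] = sorted(SEX_CHROMOSOMES)[0]
    pos[cls == "sex"] = np.arange(1, (cls == "sex").sum() + 1) * 1000
    snp_map = pd.DataFrame(
        {"snp": [f"qc_snp{j:06d}" for j in range(m)], "chrom": chroms,
         "pos_bp": pos}
    )
    panel = GenotypePanel(ids, dos, snp_map)

    with_pheno = [a for a, c in zip(ids, a_cls) if c != "noph"]
    phenotypes = pd.DataFrame(
        {"animal": with_pheno,
         "YW": rng.normal(342.0, 45.0, size=len(with_pheno))}
    )
    return panel, pedigree, phenotypes


# ---------------------------------------------------------------------------
# Printed-table fixtures


def load_table2_fixture():
    """Selected 20-SNP windows of the Hanwoo study: 42 (trait, window) rows
    with GV% and the annotated gene list; the single lowercase
    ``bta-mir-2379`` member is typed miRNA, all other symbols gene.
    Returns an :class:`~wssgwas_kit.annotation_network.TraitWindowTable`."""
    from .annotation_network import TraitWindowRow, TraitWindowTable

    with resources.files("wssgwas_kit.data").joinpath(
        "table2_windows.tsv"
    ).open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype={"chrom": str},
                            keep_default_na=False)
    rows = []
    for r in frame.itertuples():
        members = []
        if r.members:
            for sym, typ in zip(r.members.split(";"), r.member_types.split(";")):
                members.append((sym, typ))
        rows.append(
            TraitWindowRow(
                trait=r.trait, chrom=r.chrom,
                start_mb=float(r.start_mb), end_mb=float(r.end_mb),
                gv_percent=float(r.gv_percent), members=members,
            )
        )
    return TraitWindowTable(rows)


def load_mirna_suppressed_fixture() -> pd.DataFrame:
    """The 42 candidate genes reported as suppressed by the three detected
    miRNAs (bta-miR-124a, bta-miR-3064, bta-mir-2379), with a provenance
    flag marking the two symbols that appear in no selected window."""
    with resources.files("wssgwas_kit.data").joinpath(
        "mirna_suppressed_genes.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


DETECTED_MIRNAS = ("bta-miR-124a", "bta-miR-3064", "bta-mir-2379")


def suppressed_gene_edges() -> pd.DataFrame:
    """miRNA-to-gene target edges from the suppressed-gene fixture.

    The source material reports the 42 suppressed genes collectively for
    the three miRNAs without a per-miRNA assignment, so this helper emits
    the coarsest consistent edge set: every detected miRNA paired with
    every suppressed gene.
    """
    genes = load_mirna_suppressed_fixture()["gene"]
    return pd.DataFrame(
        [(mir, g) for mir in DETECTED_MIRNAS for g in genes],
        columns=["mirna", "gene"],
    )
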