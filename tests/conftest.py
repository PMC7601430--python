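import numpy as np
import pandas as pd
import pytest

from wssgwas_kit.panel import GenotypePanel
from wssgwas_kit.pedigree import Pedigree
from wssgwas_kit.synthetic_data import QcFixtureSpec, SimulationConfig


@pytest.fixture
def trio() -> Pedigree:
    """Unrelated sire and dam with one offspring."""
    return Pedigree([("S", None, None), ("D", None, None), ("O", "S", "D")])


@pytest.fixture
def full_sib_mating() -> Pedigree:
    """Offspring of a full-sib mating (inbreeding F = 0.25)."""
    return Pedigree(
        [
            ("A", None, None),
            ("B", None, None),
            ("C", "A", "B"),
            ("D", "A", "B"),
            ("E", "C", "D"),
        ]
    )


def random_pedigree(n_founders: int, n_generations: int, seed: int) -> Pedigree:
    cfg = SimulationConfig(
        n_founders=n_founders,
        n_generations=n_generations,
        matings_per_generation=max(2, n_founders // 2),
        offspring_per_mating=1,
        seed=seed,
    )
    from wssgwas_kit.synthetic_data import simulate_pedigree

    return simulate_pedigree(cfg)


@pytest.fixture
def two_by_two_panel() -> GenotypePanel:
    """Two animals, two SNPs, dosages [[0,2],[2,0]] (the hand-worked G)."""
    snp_map = pd.DataFrame(
        {"snp": ["s1", "s2"], "chrom": ["1", "1"], "pos_bp": [100, 200]}
    )
    return GenotypePanel(["a1", "a2"], np.array([[0.0, 2.0], [2.0, 0.0]]), snp_map)


@pytest.fixture
def small_qc_spec() -> QcFixtureSpec:
    return QcFixtureSpec(
        n_total_snps=2000,
        n_unknown_position=15,
        n_sex_chromosome=40,
        n_low_call_rate=60,
        n_low_maf=80,
        n_hwe_fail=10,
        n_total_animals=60,
        n_high_missing=4,
        n_parent_conflict=3,
        n_pedigree_genomic_deviation=2,
        n_no_phenotype=5,
    )
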