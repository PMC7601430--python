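"""Genotype panel: animals x SNPs dosage matrix plus a marker map."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SEX_CHROMOSOMES = {"X", "Y"}
UNKNOWN_CHROMOSOME = "0"


@dataclass
class GenotypePanel:
    """SNP dosages (0/1/2, ``NaN`` = missing) with a marker map.

    ``snp_map`` has one row per SNP, columns ``snp``, ``chrom`` (string
    label; ``"0"`` = unknown position, ``"X"``/``"Y"`` = sex chromosomes)
    and ``pos_bp`` (1-based).
    """

    animal_ids: list[str]
    dosages: np.ndarray  # (n_animals, n_snps) float
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_map)} SNPs"
            )
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.nan_to_num(p, nan=0.0)

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotypes."""
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def animal_missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries filled by the column mean (2p)."""
        x = self.dosages.astype(np.float64, copy=True)
        p2 = 2.0 * self.allele_frequencies()
        miss = np.isnan(x)
        if miss.any():
            x[miss] = np.broadcast_to(p2, x.shape)[miss]
        return x

    def subset_animals(self, ids: list[str]) -> "GenotypePanel":
        idx = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [idx[str(a)] for a in ids]
        return GenotypePanel(list(ids), self.dosages[rows], self.snp_map)

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            self.animal_ids, self.dosages[:, mask], self.snp_map.loc[mask]
        )

    # -- I/O: genotype TSV (animal, one column per SNP) + map TSV --------
    def to_tsv(self, genotypes_path: str | Path, map_path: str | Path) -> None:
        frame = pd.DataFrame(
            self.dosages, columns=self.snp_map["snp"], index=self.animal_ids
        )
        frame.index.name = "animal"
        frame.to_csv(genotypes_path, sep="\t", na_rep="NA", float_format="%.0f")
        self.snp_map.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, genotypes_path: str | Path, map_path: str | Path
    ) -> "GenotypePanel":
        frame = pd.read_csv(genotypes_path, sep="\t", index_col="animal",
                            na_values=["NA"])
        snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
        frame = frame[snp_map["snp"]]
        return cls(
            [str(a) for a in frame.index],
            frame.to_numpy(dtype=np.float32),
            snp_map,
        )
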