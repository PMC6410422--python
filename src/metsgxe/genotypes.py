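"""In-memory genotype container: additive dosages plus SNP metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """n_subjects x n_snps additive ALT-allele dosages.

    ``dosages`` is a float array with values in {0, 1, 2} and NaN for
    missing calls. Metadata arrays are per-SNP and positions are 1-based.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x SNPs)")
        n, m = self.dosages.shape
        for name in ("snp_ids", "chromosomes", "positions", "ref", "alt"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (m,):
                raise ValueError(f"{name} length {arr.shape} != n_snps {m}")
            setattr(self, name, arr)
        if self.subject_ids is None:
            self.subject_ids = np.array([f"S{i:06d}" for i in range(n)])
        else:
            self.subject_ids = np.asarray(self.subject_ids)
            if self.subject_ids.shape != (n,):
                raise ValueError("subject_ids length mismatch")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing (NaN)")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP from non-missing calls."""
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def snp_table(self) -> pd.DataFrame:
        """SNP metadata as a DataFrame (snp_id, chrom, pos, ref, alt, maf)."""
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chromosomes,
                "pos": self.positions.astype(int),
                "ref": self.ref,
                "alt": self.alt,
                "maf": self.maf(),
            }
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            snp_ids=self.snp_ids[mask],
            chromosomes=self.chromosomes[mask],
            positions=self.positions[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            subject_ids=self.subject_ids,
        )
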