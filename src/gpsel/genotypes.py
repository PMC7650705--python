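"""Genotype container shared by every pipeline stage.

Genotypes are stored as counted-allele dosages in {0, 1, 2} with -1 marking a
missing call, one row per animal and one column per SNP, alongside a marker
map (chromosome, identifier, genetic and physical position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

MAP_COLUMNS = ("chrom", "snp", "cm", "bp")


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with its marker map.

    Parameters
    ----------
    codes
        ``(n_animals, n_snps)`` int8 array of counted-allele dosages; ``-1``
        encodes a missing call.
    animal_ids
        One identifier per row.
    markers
        Marker map with columns ``chrom`` (int), ``snp`` (str), ``cm``
        (float), ``bp`` (int); physical positions are 1-based and strictly
        increasing within a chromosome.
    """

    codes: np.ndarray
    animal_ids: list[str]
    markers: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D animals x SNPs array")
        if len(self.animal_ids) != self.codes.shape[0]:
            raise ValueError("animal_ids length does not match codes rows")
        if len(self.markers) != self.codes.shape[1]:
            raise ValueError("marker map length does not match codes columns")
        missing_cols = set(MAP_COLUMNS) - set(self.markers.columns)
        if missing_cols:
            raise ValueError(f"marker map lacks columns {sorted(missing_cols)}")

    # -- basic shape -------------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    # -- per-marker summaries ---------------------------------------------
    def observed_mask(self) -> np.ndarray:
        return self.codes != MISSING

    def snp_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return self.observed_mask().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per animal."""
        return self.observed_mask().mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per marker, over observed calls.

        Markers with no observed calls get ``nan``.
        """
        obs = self.observed_mask()
        n_obs = obs.sum(axis=0)
        counts = np.where(obs, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = counts / (2.0 * n_obs)
        return np.where(n_obs > 0, freq, np.nan)

    def genotype_counts(self) -> np.ndarray:
        """Per-marker (n_hom_ref, n_het, n_hom_alt) counts over observed calls."""
        out = np.empty((self.n_snps, 3), dtype=np.int64)
        for k in range(3):
            out[:, k] = (self.codes == k).sum(axis=0)
        return out

    def mean_imputed(self) -> np.ndarray:
        """Float copy with missing calls replaced by the marker mean (2p)."""
        codes = self.codes.astype(np.float64)
        obs = self.observed_mask()
        fill = 2.0 * self.allele_freq()
        rows, cols = np.nonzero(~obs)
        codes[rows, cols] = fill[cols]
        return codes

    # -- subsetting --------------------------------------------------------
    def take_animals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.codes[index],
            [self.animal_ids[i] for i in index],
            self.markers.reset_index(drop=True),
        )

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.codes[:, index],
            list(self.animal_ids),
            self.markers.iloc[index].reset_index(drop=True),
        )
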