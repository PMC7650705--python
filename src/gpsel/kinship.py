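"""Genomic relationship matrix (VanRaden method 1).

G = M Mᵀ / (2 Σ p_j (1 - p_j)) with M the dosage matrix centered by twice
the allele frequency.  With frequencies estimated from the sample the
diagonal averages ~1 for a panel in Hardy-Weinberg proportions, and G has a
zero row-sum null space, so a small identity blend is applied before any
inverse-based computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["GRM", "vanraden_grm", "blend_grm"]


@dataclass
class GRM:
    values: np.ndarray
    animal_ids: list[str]
    freqs: np.ndarray = field(repr=False)
    blend_weight: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GRM must be square")
        if len(self.animal_ids) != self.values.shape[0]:
            raise ValueError("animal_ids length does not match GRM order")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, index: np.ndarray) -> "GRM":
        index = np.asarray(index)
        return GRM(
            self.values[np.ix_(index, index)],
            [self.animal_ids[i] for i in index],
            self.freqs,
            self.blend_weight,
        )


def vanraden_grm(genotypes: GenotypeMatrix, freqs="observed") -> GRM:
    """Build G from a genotype panel.

    Missing calls are mean-imputed per marker (2p) before centering.
    ``freqs`` is either ``"observed"`` (estimate from the sample, the
    default and the only frequencies available to a single-herd study) or an
    explicit per-marker array of counted-allele frequencies.
    """
    codes = genotypes.mean_imputed()
    if isinstance(freqs, str):
        if freqs != "observed":
            raise ValueError("freqs must be 'observed' or an array")
        p = genotypes.allele_freq()
    else:
        p = np.asarray(freqs, dtype=np.float64)
        if p.shape != (genotypes.n_snps,):
            raise ValueError("frequency vector length does not match marker count")
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ZeroDivisionError("all markers monomorphic: VanRaden denominator is zero")
    m = codes - 2.0 * p
    g = (m @ m.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry against rounding
    return GRM(g, list(genotypes.animal_ids), p)


def blend_grm(grm: GRM, weight: float = 0.05) -> GRM:
    """Shrink G toward the identity: G* = (1 - w) G + w I.

    Shifts every eigenvalue to (1 - w) λ + w, so any input that is positive
    semi-definite up to rounding becomes safely positive definite.  Weights
    above 0.25 are rejected: that much shrinkage is no longer a numerical
    fix but a change of model.
    """
    if not (0 <= weight <= 0.25):
        raise ValueError("blend weight must lie in [0, 0.25]")
    if weight == 0:
        return grm
    g = (1.0 - weight) * grm.values + weight * np.eye(grm.n)
    return GRM(g, list(grm.animal_ids), grm.freqs, blend_weight=weight)
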