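"""Variant- and sample-level quality control for SNP-chip panels.

Filters and conventions mirror standard chip QC practice: markers are
dropped when call rate <= 0.90, when a one-degree-of-freedom Hardy-Weinberg
goodness-of-fit test falls below 1e-6, or when minor allele frequency is
below 0.01 (strict inequalities as stated); animals are then retained when
their call rate exceeds 0.90.  Missing calls are excluded from MAF and HWE
counts rather than imputed at this stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QCReport",
    "maf",
    "hwe_test",
    "hwe_exact_test",
    "filter_variants",
    "snp_density",
]


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate_snp: float = 0.90
    min_call_rate_sample: float = 0.90
    hwe_alpha: float = 1e-6
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_call_rate_snp", "min_call_rate_sample", "hwe_alpha", "min_maf"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Bookkeeping for one filtering pass; removals itemized in applied order."""

    n_snps_in: int
    n_samples_in: int
    removed_call_rate: int = 0
    removed_hwe: int = 0
    removed_maf: int = 0
    removed_samples: int = 0
    filter_order: tuple[str, ...] = ("snp_call_rate", "hwe", "maf", "sample_call_rate")
    removed_snp_ids: dict = field(default_factory=dict, repr=False)

    @property
    def n_snps_retained(self) -> int:
        return self.n_snps_in - self.removed_call_rate - self.removed_hwe - self.removed_maf

    @property
    def n_samples_retained(self) -> int:
        return self.n_samples_in - self.removed_samples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": [*self.filter_order, "retained_snps", "retained_samples"],
                "count": [
                    self.removed_call_rate,
                    self.removed_hwe,
                    self.removed_maf,
                    self.removed_samples,
                    self.n_snps_retained,
                    self.n_samples_retained,
                ],
            }
        )


def maf(column: np.ndarray) -> float:
    """Minor allele frequency of one genotype column, over non-missing calls."""
    col = np.asarray(column)
    obs = col[col >= 0]
    if obs.size == 0:
        raise ValueError("MAF undefined: column has no observed calls")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def hwe_test(counts: tuple[int, int, int]) -> float:
    """Hardy-Weinberg goodness-of-fit p-value from genotype counts.

    Pearson chi-square with one degree of freedom against expected counts at
    the sample allele frequency.  Monomorphic markers return p = 1 by
    convention (no polymorphism to test).
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("HWE test requires at least one genotyped animal")
    p = (2 * n_aa + n_ab) / (2.0 * n)
    if p in (0.0, 1.0):
        logger.debug("monomorphic marker: HWE p set to 1")
        return 1.0
    expected = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    statistic = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(statistic, df=1))


def hwe_exact_test(counts: tuple[int, int, int]) -> float:
    """Exact Hardy-Weinberg test (sum of heterozygote-count probabilities
    no larger than the observed one, conditional on allele counts)."""
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("HWE test requires at least one genotyped animal")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    log_probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_common + 1)
            + het * math.log(2)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )
        log_probs[het] = lp
    if not log_probs:
        return 1.0
    mx = max(log_probs.values())
    probs = {h: math.exp(lp - mx) for h, lp in log_probs.items()}
    total = sum(probs.values())
    p_obs = probs.get(n_ab, 0.0)
    p_val = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return float(min(1.0, p_val))


def filter_variants(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    exact_hwe: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker filters (call rate, HWE, MAF, in that order) then the
    sample call-rate filter, and itemize removals.

    The fixed order matters because a marker can violate several filters;
    each marker is charged to the first filter that removes it.
    """
    if genotypes.n_snps == 0 or genotypes.n_animals == 0:
        raise ValueError("filter_variants requires a non-empty genotype matrix")
    report = QCReport(n_snps_in=genotypes.n_snps, n_samples_in=genotypes.n_animals)
    hwe = hwe_exact_test if exact_hwe else hwe_test

    current = genotypes

    # 1. marker call rate (remove when call rate <= threshold)
    keep = current.snp_call_rate() > thresholds.min_call_rate_snp
    report.removed_call_rate = int((~keep).sum())
    report.removed_snp_ids["snp_call_rate"] = list(current.markers["snp"][~keep])
    current = current.take_snps(np.flatnonzero(keep))

    # 2. Hardy-Weinberg (remove when p < alpha)
    counts = current.genotype_counts()
    pvals = np.array([hwe(tuple(c)) for c in counts])
    keep = pvals >= thresholds.hwe_alpha
    report.removed_hwe = int((~keep).sum())
    report.removed_snp_ids["hwe"] = list(current.markers["snp"][~keep])
    current = current.take_snps(np.flatnonzero(keep))

    # 3. minor allele frequency (remove when MAF < threshold; monomorphic
    #    markers are always dropped here — they carry no information and
    #    break downstream relationship-matrix scaling)
    p = current.allele_freq()
    maf_all = np.minimum(p, 1 - p)
    keep = (maf_all >= thresholds.min_maf) & (maf_all > 0)
    report.removed_maf = int((~keep).sum())
    report.removed_snp_ids["maf"] = list(current.markers["snp"][~keep])
    current = current.take_snps(np.flatnonzero(keep))

    if current.n_snps == 0:
        raise ValueError("all markers removed by QC; empty panel")

    # 4. sample call rate on the retained panel (retain when rate > threshold)
    keep_samples = current.sample_call_rate() > thresholds.min_call_rate_sample
    report.removed_samples = int((~keep_samples).sum())
    current = current.take_animals(np.flatnonzero(keep_samples))

    logger.info(
        "QC: removed %d (call rate) + %d (HWE) + %d (MAF) markers, %d samples; kept %d x %d",
        report.removed_call_rate,
        report.removed_hwe,
        report.removed_maf,
        report.removed_samples,
        current.n_animals,
        current.n_snps,
    )
    return current, report


def snp_density(markers: pd.DataFrame, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Per-chromosome marker counts in half-open windows [k*w, (k+1)*w).

    Returns a frame (chrom, window, start_bp, count); counts sum to the
    number of markers.  Positions must be sorted within each chromosome.
    """
    for _, grp in markers.groupby("chrom"):
        bp = grp["bp"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise ValueError("marker positions must be strictly increasing within chromosome")
    window = markers["bp"].to_numpy() // window_bp
    out = (
        pd.DataFrame({"chrom": markers["chrom"].to_numpy(), "window": window})
        .groupby(["chrom", "window"])
        .size()
        .rename("count")
        .reset_index()
    )
    out["start_bp"] = out["window"] * window_bp
    return out[["chrom", "window", "start_bp", "count"]]
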