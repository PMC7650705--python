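"""Text-format readers and writers: PLINK ped/map, phenotype CSV, GRM CSV.

The text PLINK dialect is the interchange default for transparency at desk
scale.  Alleles are written as ``A`` (the counted allele) and ``B``; a
missing call is ``0 0``.  On reading, each marker's dosage counts its minor
allele as observed in the file, with ties at 0.5 broken toward the
lexicographically smaller allele label — together with the writer's
minor-allele orientation this makes write-then-read an exact round trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .kinship import GRM

__all__ = [
    "write_plink_text",
    "read_plink_text",
    "write_phenotypes",
    "read_phenotypes",
    "write_grm",
    "read_grm",
]


def write_plink_text(genotypes: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map`` (1-based bp, alleles A/B)."""
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    m = genotypes.markers
    with open(map_path, "w") as fh:
        for row in m.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t{row.cm:g}\t{row.bp}\n")
    allele_pairs = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(genotypes.animal_ids):
            calls = " ".join(allele_pairs[int(c)] for c in genotypes.codes[i])
            fh.write(f"FAM1 {animal} 0 0 0 -9 {calls}\n")
    return ped_path, map_path


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a 6-column ped plus 4-column map into a dosage matrix.

    Dosages count the observed minor allele per marker (ties broken toward
    the lexicographically smaller label); ``0 0`` becomes a missing call.
    """
    markers = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp"],
        dtype={"chrom": int, "snp": str, "cm": float, "bp": int},
    )
    n_snps = len(markers)
    animal_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_snps} fields "
                    f"({n_snps} markers), found {len(parts)}"
                )
            animal_ids.append(parts[1])
            allele_rows.append(parts[6:])
    if not animal_ids:
        raise ValueError(f"{ped_path}: no genotype lines")

    alleles = np.array(allele_rows).reshape(len(animal_ids), n_snps, 2)
    codes = np.full((len(animal_ids), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        if observed.size == 0:
            continue
        labels, counts = np.unique(observed, return_counts=True)
        if labels.size > 2:
            raise ValueError(f"marker {markers['snp'][j]} has more than two alleles")
        is_missing = (col == "0").any(axis=1)
        if labels.size == 1:
            # monomorphic: the minor allele is the unseen one, dosage 0
            codes[:, j] = np.where(is_missing, MISSING, 0)
            continue
        # counted allele = minor allele; ties toward the smaller label
        order = np.lexsort((labels, counts))
        counted = labels[order[0]]
        is_counted = col == counted
        codes[:, j] = np.where(is_missing, MISSING, is_counted.sum(axis=1))
    return GenotypeMatrix(codes, animal_ids, markers)


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> Path:
    """Write the tidy phenotype table (animal_id, trait, stage, value)."""
    path = Path(path)
    phenotypes.to_csv(path, index=False)
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal_id", "trait", "stage", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file must have columns {sorted(required)}")
    return df


def write_grm(grm: GRM, path: str | Path) -> Path:
    """Dense square CSV with animal ids as header and index."""
    path = Path(path)
    pd.DataFrame(grm.values, index=grm.animal_ids, columns=grm.animal_ids).to_csv(path)
    return path


def read_grm(path: str | Path) -> GRM:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("GRM file must be square with matching row/column ids")
    return GRM(df.to_numpy(dtype=float), list(df.columns), freqs=np.array([]))
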