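"""Readers and writers for the CSV dialects the tool touches.

Genotypes come either as SNP dosage matrices (header of marker names,
integer 0/1/2 cells) or as explicit allele-frequency tables whose columns
are named ``locus.allele``. Phenotypes are plain trait tables with a
per-trait kind declaration. Distance matrices are square CSVs with ids in
the first row and column. Cores are written as a plain-text file: a
``#``-prefixed header block with evaluated measures (6 decimal digits)
followed by one selected accession id per line.

Missing cells are empty or ``NA``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    FREQ_SUM_TOL,
    CoreSubset,
    DataError,
    Dataset,
    DistanceMatrix,
    GenotypeMatrix,
    Locus,
    PhenotypeTable,
)

_NA_VALUES = ["", "NA"]


def read_genotypes(path: str | Path, dialect: str = "dosage") -> GenotypeMatrix:
    """Read a genotype CSV in the ``dosage`` or ``frequency`` dialect."""
    df = pd.read_csv(path, index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    ids = [str(i) for i in df.index]
    if dialect == "dosage":
        dosages = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        raw_na = df.isna().to_numpy()
        if (np.isnan(dosages) & ~raw_na).any():
            raise DataError("non-numeric dosage cell")
        return GenotypeMatrix.from_dosages(ids, [str(c) for c in df.columns], dosages)
    if dialect == "frequency":
        return _frequencies_from_frame(ids, df)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _frequencies_from_frame(ids: Sequence[str], df: pd.DataFrame) -> GenotypeMatrix:
    loci: list[Locus] = []
    order: list[str] = []
    groups: dict[str, list[str]] = {}
    for col in df.columns:
        name = str(col)
        if "." not in name:
            raise DataError(f"frequency column {name!r} is not of the form locus.allele")
        locus, allele = name.rsplit(".", 1)
        if locus not in groups:
            groups[locus] = []
            order.append(locus)
        groups[locus].append(allele)
    blocks = []
    for locus in order:
        alleles = groups[locus]
        cols = [f"{locus}.{a}" for a in alleles]
        block = df[cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        obs = ~np.isnan(block).any(axis=1)
        sums = block[obs].sum(axis=1)
        if sums.size and np.max(np.abs(sums - 1.0)) > FREQ_SUM_TOL:
            raise DataError(f"locus {locus!r}: frequencies do not sum to 1 within {FREQ_SUM_TOL}")
        loci.append(Locus(locus, tuple(alleles)))
        blocks.append(block)
    return GenotypeMatrix(ids, loci, np.hstack(blocks))


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix in the frequency dialect (round-trippable)."""
    cols = [f"{l.name}.{a}" for l in geno.loci for a in l.alleles]
    df = pd.DataFrame(geno.frequencies, index=geno.accession_ids, columns=cols)
    df.to_csv(path, index_label="id", na_rep="NA")


def read_phenotypes(path: str | Path, trait_spec: Mapping[str, str]) -> PhenotypeTable:
    """Read a phenotype CSV; ``trait_spec`` maps every column to its kind."""
    df = pd.read_csv(path, index_col=0, na_values=_NA_VALUES, keep_default_na=False, dtype=object)
    ids = [str(i) for i in df.index]
    df.columns = [str(c) for c in df.columns]
    missing = [c for c in df.columns if c not in trait_spec]
    if missing:
        raise DataError(f"trait spec misses columns: {missing}")
    return PhenotypeTable.from_values(ids, dict(trait_spec), df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.values.to_csv(path, index_label="id", na_rep="NA")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square distance CSV with ids in the first row and column."""
    df = pd.read_csv(path, index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise DataError("distance matrix row and column ids differ (non-square?)")
    return DistanceMatrix(ids, df.to_numpy(dtype=float))


def write_distance_matrix(dist: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dist.d, index=dist.accession_ids, columns=dist.accession_ids)
    df.to_csv(path, index_label="id")


def write_core(
    core: CoreSubset,
    dataset: Dataset,
    path: str | Path,
    report: Mapping[str, float] | None = None,
) -> None:
    """Write the selected accession ids, preceded by an evaluation header."""
    lines = []
    if report:
        for measure, value in report.items():
            lines.append(f"# {measure}: {value:.6f}")
    lines.extend(core.ids(dataset.accession_ids))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_core(path: str | Path, dataset: Dataset) -> CoreSubset:
    """Read a core file back into a subset of the given dataset."""
    index = {a: i for i, a in enumerate(dataset.accession_ids)}
    selected = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            selected.append(index[line])
        except KeyError:
            raise DataError(f"core lists unknown accession {line!r}") from None
    core = CoreSubset(selected)
    core.validate_for(dataset.n)
    return core
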