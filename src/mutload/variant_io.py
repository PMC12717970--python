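"""VCF ingestion, accession/site filtering and outgroup polarization.

Coordinates are 1-based inclusive as in VCF.  Genotypes are unphased
ALT-allele dosages in ``{0, 1, 2}`` with ``-1`` for missing; phase is
never used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ConfigError, VariantIOError

logger = logging.getLogger(__name__)

MISSING = -1

POLARIZATION_OK = "ok"
POLARIZATION_OUTGROUP_MISSING = "outgroup_missing"
POLARIZATION_OUTGROUP_HET = "outgroup_het"
POLARIZATION_THIRD_ALLELE = "outgroup_third_allele"


@dataclass
class GenotypeMatrix:
    """Site-by-accession ALT-dosage matrix with per-site flags."""

    accessions: list[str]
    #: per-site frame: chrom, pos, ref, alt, is_indel, is_multiallelic
    sites: pd.DataFrame
    #: (n_sites, n_accessions) int8, -1 = missing
    dosage: np.ndarray
    #: optional boolean mask of imputed cells, same shape as dosage
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.sites), len(self.accessions)):
            raise VariantIOError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.accessions)} accessions"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def missing_fraction_per_accession(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)


@dataclass
class PopulationAssignment:
    """Accession-to-population map with a single flagged outgroup."""

    mapping: dict[str, str]
    outgroup: str

    def __post_init__(self) -> None:
        if self.outgroup not in self.mapping:
            raise ConfigError(f"outgroup {self.outgroup!r} missing from assignment")

    def populations(self) -> list[str]:
        pops = []
        for acc, pop in self.mapping.items():
            if acc != self.outgroup and pop not in pops:
                pops.append(pop)
        return pops

    def members(self, population: str) -> list[str]:
        return [
            a
            for a, p in self.mapping.items()
            if p == population and a != self.outgroup
        ]


@dataclass
class PolarizedSiteTable:
    """Biallelic sites with ancestral/derived assignment vs the outgroup.

    ``derived_dosage`` counts copies of the derived allele for the
    non-outgroup accessions only; sites whose polarization failed keep a
    non-``ok`` status and are excluded from all downstream counts.
    """

    accessions: list[str]
    #: chrom, pos, ref, alt, ancestral, derived, status
    sites: pd.DataFrame
    derived_dosage: np.ndarray

    @property
    def ok_mask(self) -> np.ndarray:
        return (self.sites["status"] == POLARIZATION_OK).to_numpy()

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Records are preserved in file order.  Multiallelic and indel records
    are retained but flagged for :func:`filter_sites`.  Malformed or
    half-called genotypes become missing.
    """
    path = Path(path)
    if not path.exists():
        raise VariantIOError(f"cannot read VCF: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VariantIOError(f"VCF has no samples: {path}")
    if len(set(samples)) != len(samples):
        raise VariantIOError(f"duplicate sample names in {path}")
    rows = []
    dosages = []
    n_malformed = 0
    for v in vcf:
        alts = v.ALT or []
        multi = len(alts) != 1
        alt = alts[0] if alts else "."
        indel = len(v.REF) != 1 or any(len(a) != 1 for a in alts)
        row_dos = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2 or any(a is None or a < 0 for a in alleles):
                row_dos[i] = MISSING
                n_malformed += sum(1 for a in alleles if a is None)
            else:
                row_dos[i] = sum(1 for a in alleles if a >= 1)
        rows.append((v.CHROM, v.POS, v.REF, alt, indel, multi))
        dosages.append(row_dos)
    if n_malformed:
        logger.warning("%d malformed genotype calls set to missing", n_malformed)
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "is_indel", "is_multiallelic"]
    )
    dosage = (
        np.vstack(dosages) if dosages else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(accessions=samples, sites=sites, dosage=dosage)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write GT-only VCF v4.2; round-trips dosages exactly."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.accessions)
            + "\n"
        )
        for i, row in enumerate(matrix.sites.itertuples(index=False)):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in matrix.dosage[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_population_assignment(path: str | Path) -> PopulationAssignment:
    """Two-column TSV (accession, population) with a ``#outgroup=`` header."""
    outgroup = None
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#outgroup="):
                outgroup = line.split("=", 1)[1].strip()
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise VariantIOError(f"{path}: line {ln}: expected 2 columns")
            acc, pop = fields
            if acc in mapping:
                raise VariantIOError(f"{path}: accession {acc!r} assigned twice")
            mapping[acc] = pop
    if outgroup is None:
        raise ConfigError(f"{path}: missing '#outgroup=' header line")
    return PopulationAssignment(mapping=mapping, outgroup=outgroup)


def write_population_assignment(
    assignment: PopulationAssignment, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(f"#outgroup={assignment.outgroup}\n")
        for acc, pop in assignment.mapping.items():
            fh.write(f"{acc}\t{pop}\n")


def filter_accessions(
    matrix: GenotypeMatrix, max_missing: float = 0.25
) -> GenotypeMatrix:
    """Drop accessions whose missing fraction is strictly above the cutoff."""
    if not 0.0 <= max_missing <= 1.0:
        raise ConfigError(f"max_missing={max_missing} outside [0, 1]")
    frac = matrix.missing_fraction_per_accession()
    keep = frac <= max_missing
    removed = [a for a, k in zip(matrix.accessions, keep) if not k]
    if removed:
        logger.info("removed %d accessions with missingness > %s: %s",
                    len(removed), max_missing, removed)
    if not keep.any():
        raise VariantIOError("all accessions removed by missingness filter")
    return GenotypeMatrix(
        accessions=[a for a, k in zip(matrix.accessions, keep) if k],
        sites=matrix.sites.copy(),
        dosage=matrix.dosage[:, keep].copy(),
    )


def filter_sites(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Keep biallelic SNPs only; drop duplicate (chrom, pos) keeping the first."""
    keep = (~matrix.sites["is_indel"] & ~matrix.sites["is_multiallelic"]).to_numpy()
    dup = matrix.sites.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
    if dup.any():
        logger.info("dropping %d duplicate (chrom, pos) records", int(dup.sum()))
    keep &= ~dup
    if not keep.any():
        raise VariantIOError("no sites left after site filter")
    return GenotypeMatrix(
        accessions=list(matrix.accessions),
        sites=matrix.sites.loc[keep].reset_index(drop=True),
        dosage=matrix.dosage[keep].copy(),
    )


def impute_missing(
    matrix: GenotypeMatrix, method: str = "mode", seed: int | None = None
) -> GenotypeMatrix:
    """Replace missing dosages by the per-site modal dosage (ties -> lower).

    A deterministic documented stand-in for LD-based imputation; the
    ``seed`` argument exists for interface stability and is unused by the
    ``mode`` method.
    """
    if method != "mode":
        raise ConfigError(f"unknown imputation method {method!r}")
    dosage = matrix.dosage.copy()
    counts = np.stack([(dosage == k).sum(axis=1) for k in (0, 1, 2)], axis=1)
    observed = counts.sum(axis=1)
    if (observed == 0).any():
        i = int(np.flatnonzero(observed == 0)[0])
        site = matrix.sites.iloc[i]
        raise VariantIOError(
            f"site {site['chrom']}:{site['pos']} has no observed genotypes; "
            "cannot impute"
        )
    modal = counts.argmax(axis=1).astype(np.int8)  # argmax ties -> lowest dosage
    miss = dosage == MISSING
    dosage[miss] = np.broadcast_to(modal[:, None], dosage.shape)[miss]
    return GenotypeMatrix(
        accessions=list(matrix.accessions),
        sites=matrix.sites.copy(),
        dosage=dosage,
        imputed=miss,
    )


def polarize(
    matrix: GenotypeMatrix, assignment: PopulationAssignment
) -> PolarizedSiteTable:
    """Assign ancestral/derived states using the outgroup sample.

    Status is ``ok`` only where the outgroup is homozygous ref or alt;
    where it carries the alt allele homozygously the derived dosage is
    flipped ``d -> 2 - d``.  Het/missing outgroup calls and flagged
    multiallelic records keep a diagnostic status and are excluded from
    downstream counts.
    """
    if assignment.outgroup not in matrix.accessions:
        raise VariantIOError(
            f"outgroup {assignment.outgroup!r} not among VCF samples"
        )
    og_idx = matrix.accessions.index(assignment.outgroup)
    keep_cols = [i for i in range(matrix.n_accessions) if i != og_idx]
    accessions = [matrix.accessions[i] for i in keep_cols]
    og = matrix.dosage[:, og_idx]
    dosage = matrix.dosage[:, keep_cols].astype(np.int8)

    status = np.full(matrix.n_sites, POLARIZATION_OK, dtype=object)
    status[og == 1] = POLARIZATION_OUTGROUP_HET
    status[og == MISSING] = POLARIZATION_OUTGROUP_MISSING
    multi = matrix.sites["is_multiallelic"].to_numpy()
    status[multi] = POLARIZATION_THIRD_ALLELE

    flip = (og == 2) & (status == POLARIZATION_OK)
    derived = np.where(flip, matrix.sites["ref"], matrix.sites["alt"])
    ancestral = np.where(flip, matrix.sites["alt"], matrix.sites["ref"])
    derived_dosage = dosage.copy()
    miss = derived_dosage == MISSING
    derived_dosage[flip] = 2 - derived_dosage[flip]
    derived_dosage[miss] = MISSING

    sites = matrix.sites[["chrom", "pos", "ref", "alt"]].copy()
    sites["ancestral"] = ancestral
    sites["derived"] = derived
    sites["status"] = status
    return PolarizedSiteTable(
        accessions=accessions,
        sites=sites.reset_index(drop=True),
        derived_dosage=derived_dosage,
    )


def maf_filter(table: PolarizedSiteTable, min_maf: float) -> PolarizedSiteTable:
    """Drop sites with minor-allele frequency strictly below ``min_maf``.

    MAF is computed over non-missing dosages of the (non-outgroup)
    accessions; monomorphic sites have MAF 0 and are removed by any
    positive threshold.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ConfigError(f"min_maf={min_maf} outside [0, 0.5]")
    dos = table.derived_dosage.astype(float)
    dos[dos == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=1) / 2.0
    freq = np.nan_to_num(freq, nan=0.0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= min_maf
    return PolarizedSiteTable(
        accessions=list(table.accessions),
        sites=table.sites.loc[keep].reset_index(drop=True),
        derived_dosage=table.derived_dosage[keep].copy(),
    )


def subset_sites(table: PolarizedSiteTable, mask: np.ndarray) -> PolarizedSiteTable:
    """Return a new table restricted to sites where ``mask`` is True."""
    return PolarizedSiteTable(
        accessions=list(table.accessions),
        sites=table.sites.loc[mask].reset_index(drop=True),
        derived_dosage=table.derived_dosage[mask].copy(),
    )


def derived_allele_frequencies(
    table: PolarizedSiteTable, accessions: Sequence[str]
) -> np.ndarray:
    """Per-site derived-allele frequency over the given accession subset."""
    idx = [table.accessions.index(a) for a in accessions]
    dos = table.derived_dosage[:, idx].astype(float)
    dos[dos == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=1) / 2.0
    return freq


def matrix_from_simulation(result) -> tuple[GenotypeMatrix, PopulationAssignment]:
    """Build a :class:`GenotypeMatrix` and assignment from a SimResult."""
    names: list[str] = []
    cols: list[np.ndarray] = []
    mapping: dict[str, str] = {}
    for pop, mat in result.populations.items():
        for i in range(mat.shape[0]):
            name = f"{pop}_{i:03d}"
            names.append(name)
            mapping[name] = pop
            cols.append(mat[i])
    og = result.config.outgroup_name
    names.append(og)
    mapping[og] = "outgroup"
    cols.append(result.outgroup)
    dosage = np.stack(cols, axis=1).astype(np.int8)
    sites = result.truth[["chrom", "pos", "ref", "alt"]].copy()
    sites["is_indel"] = False
    sites["is_multiallelic"] = False
    matrix = GenotypeMatrix(accessions=names, sites=sites, dosage=dosage)
    return matrix, PopulationAssignment(mapping=mapping, outgroup=og)
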