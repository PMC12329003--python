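"""Genotype matrix container, VCF round-trip and SNP filtering.

The pipeline starts from a diploid biallelic SNP matrix in VCF form, as produced
by an upstream mapping/genotyping workflow. Genotypes are stored as alt-allele
dosage (0, 1, 2) with -1 for missing. Sites carry a locus identifier (for
target-enrichment data, the assembled locus/contig the SNP lies on), used by the
one-SNP-per-locus thinning step that removes within-locus linkage.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1


class VCFParseError(ValueError):
    """Raised when a VCF cannot be parsed (malformed header or records)."""


class EmptyInputError(ValueError):
    """Raised when no usable biallelic SNP records remain after reading."""


@dataclass(frozen=True)
class SiteMeta:
    """Per-SNP metadata.

    ``locus_id`` groups SNPs into physical loci; for capture data this is the
    assembled target contig, and equals ``chrom`` unless overridden.
    """

    locus_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    mean_depth: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for individuals x SNP sites.

    ``calls[i, j]`` is the alt-allele dosage of individual ``i`` at site ``j``,
    in {0, 1, 2, MISSING}. ``depths`` optionally carries per-call read depth.
    """

    individuals: list[str]
    sites: list[SiteMeta]
    calls: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual identifiers must be unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site indices."""
        index = np.asarray(index)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            sites=[self.sites[i] for i in index],
            calls=self.calls[:, index],
            depths=None if self.depths is None else self.depths[:, index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in index],
            sites=list(self.sites),
            calls=self.calls[index, :],
            depths=None if self.depths is None else self.depths[index, :],
        )

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing calls (NaN if none)."""
        called = self.calls != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)


@dataclass
class PopulationMap:
    """Individual -> locality -> region assignment."""

    frame: pd.DataFrame  # columns: individual, locality, region

    def __post_init__(self) -> None:
        required = {"individual", "locality", "region"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"popmap requires columns {sorted(required)}")
        dup = self.frame["individual"].duplicated()
        if dup.any():
            name = self.frame.loc[dup, "individual"].iloc[0]
            raise ValueError(f"duplicate individual in popmap: {name!r}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def individuals(self) -> list[str]:
        return list(self.frame["individual"])

    @property
    def localities(self) -> list[str]:
        return list(pd.unique(self.frame["locality"]))

    @property
    def regions(self) -> list[str]:
        return list(pd.unique(self.frame["region"]))

    def group_of(self, group_by: str = "locality") -> pd.Series:
        if group_by not in ("locality", "region"):
            raise ValueError("group_by must be 'locality' or 'region'")
        return self.frame.set_index("individual")[group_by]

    def group_indices(
        self, matrix: GenotypeMatrix, group_by: str = "locality"
    ) -> dict[str, np.ndarray]:
        """Map each group to the row indices of its individuals in ``matrix``.

        Raises if any matrix individual is absent from the map.
        """
        assignment = self.group_of(group_by)
        missing = [s for s in matrix.individuals if s not in assignment.index]
        if missing:
            raise KeyError(f"individuals absent from popmap: {missing[:5]}")
        groups: dict[str, list[int]] = {}
        for i, name in enumerate(matrix.individuals):
            groups.setdefault(assignment[name], []).append(i)
        return {g: np.asarray(ix, dtype=int) for g, ix in groups.items()}


@dataclass(frozen=True)
class FilterConfig:
    """SNP filter settings.

    Defaults follow the VCFtools-style filtering used for target-enrichment SNP
    panels: minor allele frequency strictly above ``maf_min``, a site genotyped
    in at least ``1 - max_missing_fraction`` of individuals, mean read depth of
    at least ``min_mean_depth`` across genotyped individuals, and one SNP kept
    per locus to avoid within-locus linkage disequilibrium.
    """

    maf_min: float = 0.05
    max_missing_fraction: float = 0.20
    min_mean_depth: float = 3.0
    one_snp_per_locus: bool = True
    rng_seed: int = 0
    #: If True, keep the first SNP of each locus instead of a seeded-random one.
    first_snp: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0.0 <= self.max_missing_fraction <= 1.0):
            raise ValueError("max_missing_fraction must be in [0, 1]")


@dataclass
class FilterReport:
    """Counts removed per criterion, in application order."""

    n_input: int
    removed_maf: int
    removed_missing: int
    removed_depth: int
    removed_thinning: int
    n_retained: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNV records are retained; multiallelic records and indels
    are skipped with a logged count. ``./.`` and ``.|.`` genotypes map to
    MISSING. Per-call FORMAT/DP is read when present.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises assorted types on bad headers
        raise VCFParseError(f"cannot parse VCF header of {path}: {exc}") from exc

    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    sites: list[SiteMeta] = []
    n_skipped = 0
    have_depth = False
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosage_rows.append(dosage.astype(np.int8))
        try:
            dp = var.format("DP")
        except KeyError:  # DP not declared in this VCF's header
            dp = None
        if dp is not None:
            dp = dp.reshape(-1).astype(float)
            dp[dp < 0] = np.nan
            have_depth = True
            mean_depth = float(np.nanmean(dp)) if np.isfinite(dp).any() else float("nan")
        else:
            dp = np.full(len(samples), np.nan)
            mean_depth = float("nan")
        depth_rows.append(dp)
        sites.append(
            SiteMeta(
                locus_id=var.CHROM,
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                mean_depth=mean_depth,
            )
        )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/indel records", n_skipped)
    if not sites:
        raise EmptyInputError(f"no biallelic SNP records retained from {path}")
    calls = np.stack(dosage_rows, axis=1)
    depths = np.stack(depth_rows, axis=1) if have_depth else None
    matrix = GenotypeMatrix(samples, sites, calls, depths)
    matrix.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return matrix


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a VCFv4.2 file with GT and DP fields (inverse of :func:`read_vcf`)."""
    if matrix.n_sites == 0 or matrix.n_individuals == 0:
        raise EmptyInputError("refusing to write an empty genotype matrix")
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = list(dict.fromkeys(s.chrom for s in matrix.sites))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popsplit\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        for j, site in enumerate(matrix.sites):
            fields = [
                site.chrom,
                str(site.pos),
                f"{site.locus_id}:{site.pos}",
                site.ref_allele,
                site.alt_allele,
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for i in range(matrix.n_individuals):
                if matrix.depths is not None and np.isfinite(matrix.depths[i, j]):
                    dp = str(int(round(matrix.depths[i, j])))
                elif np.isfinite(site.mean_depth):
                    dp = str(int(round(site.mean_depth)))
                else:
                    dp = "."
                fields.append(f"{gt_codes[int(matrix.calls[i, j])]}:{dp}")
            fh.write("\t".join(fields) + "\n")


def filter_sites(
    matrix: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP filters in the order MAF -> missingness -> depth -> thinning.

    MAF uses a strict inequality (a site at exactly ``maf_min`` is removed).
    Depth filtering is skipped for sites with unknown mean depth. Per-locus
    thinning keeps one seeded-uniform-random SNP per locus (or the first SNP in
    ``first_snp`` mode). Removing every site is reported, not raised.
    """
    config = config or FilterConfig()
    keep = np.ones(matrix.n_sites, dtype=bool)

    maf = matrix.minor_allele_frequencies()
    fail_maf = ~(maf > config.maf_min)  # NaN (all-missing site) also fails
    removed_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    miss = matrix.missing_fraction()
    fail_miss = keep & (miss > config.max_missing_fraction)
    removed_missing = int(fail_miss.sum())
    keep &= ~fail_miss

    depth = np.array([s.mean_depth for s in matrix.sites])
    fail_depth = keep & np.isfinite(depth) & (depth < config.min_mean_depth)
    removed_depth = int(fail_depth.sum())
    keep &= ~fail_depth

    removed_thinning = 0
    if config.one_snp_per_locus:
        rng = np.random.default_rng(config.rng_seed)
        by_locus: dict[str, list[int]] = {}
        for j in np.nonzero(keep)[0]:
            by_locus.setdefault(matrix.sites[j].locus_id, []).append(int(j))
        for locus, idx in by_locus.items():
            if len(idx) > 1:
                chosen = idx[0] if config.first_snp else int(rng.choice(idx))
                for j in idx:
                    if j != chosen:
                        keep[j] = False
                        removed_thinning += 1

    retained = np.nonzero(keep)[0]
    report = FilterReport(
        n_input=matrix.n_sites,
        removed_maf=removed_maf,
        removed_missing=removed_missing,
        removed_depth=removed_depth,
        removed_thinning=removed_thinning,
        n_retained=len(retained),
    )
    logger.info("filter_sites: %s", report.as_dict())
    if len(retained) == 0:
        logger.warning("filter_sites removed every site")
    return matrix.take_sites(retained), report


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a tab-separated individual / locality / region map."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["individual", "locality", "region"],
        dtype=str,
        comment="#",
    )
    if frame.isna().any().any():
        raise ValueError(f"popmap {path} must have three tab-separated columns")
    return PopulationMap(frame)


def write_popmap(popmap: PopulationMap, path: str | os.PathLike) -> None:
    popmap.frame[["individual", "locality", "region"]].to_csv(
        path, sep="\t", header=False, index=False
    )
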