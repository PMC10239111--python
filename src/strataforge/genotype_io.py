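"""Genotype containers, readers/writers and quality-control filters.

The central container is :class:`GenotypeMatrix`: a samples x variants matrix
of alt-allele dosages in {0, 1, 2} with ``nan`` marking missing calls, plus a
variant table (id, chrom, pos, ref, alt) and sample identifiers. Two on-disk
representations are supported: VCF 4.2 (GT field only) and a tab-delimited
dosage table with variants as rows and samples as columns.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    EmptyResultError,
    ParameterError,
    ParseError,
)

logger = logging.getLogger("strataforge")

#: columns of the variant table, in file order
VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix with variant and sample annotations.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` float array with values in {0, 1, 2}
        and ``nan`` for missing genotypes.
    sample_ids
        Unique sample identifiers, length ``n_samples``.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt``; positions are
        1-based and non-decreasing within each chromosome.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ParameterError("dosages must be a 2-D samples x variants array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ParameterError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.variants) != m:
            raise ParameterError(
                f"{len(self.variants)} variant records for {m} dosage columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ParameterError("duplicate sample IDs")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (np.any(vals < 0) or np.any(vals > 2) or np.any(vals % 1 != 0)):
            raise ParameterError("dosages must be in {0, 1, 2} or missing")
        self.variants = self.variants.reset_index(drop=True)
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ParameterError(f"positions decrease within chromosome {chrom}")

    # -- basic properties ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def allele_freqs(self) -> np.ndarray:
        """Alt-allele frequency per variant, over non-missing calls only."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freqs()
        return np.minimum(f, 1.0 - f)

    def variant_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean."""
        x = self.dosages.copy()
        if np.isnan(x).any():
            means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
            means = np.where(np.isnan(means), 0.0, means)  # all-missing column
            idx = np.where(np.isnan(x))
            x[idx] = means[idx[1]]
        return x

    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample / variant indices."""
        sidx = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        vidx = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        return GenotypeMatrix(
            self.dosages[np.ix_(sidx, vidx)],
            self.sample_ids[sidx],
            self.variants.iloc[vidx].reset_index(drop=True),
        )


# -- readers / writers ------------------------------------------------------

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 with a GT FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=strataforge\n")
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.sample_ids))
            + "\n"
        )
        for j, rec in enumerate(g.variants.itertuples(index=False)):
            gts = "\t".join(
                _GT_STRINGS.get(d, "./.") for d in g.dosages[:, j]
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = np.asarray(vcf.samples, dtype=object)
    rows: list[np.ndarray] = []
    recs: list[tuple] = []
    n_multi = 0
    try:
        for v in vcf:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(v.gt_types, dtype=float)
            dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
            rows.append(dos)
            vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
            recs.append((vid, str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
    except Exception as exc:
        raise ParseError(f"malformed VCF record near record {len(recs) + 1}: {exc}") from exc
    if n_multi:
        logger.info("skipped %d multiallelic records in %s", n_multi, path)
    if not recs:
        raise EmptyInputError(f"no biallelic records in {path}")
    variants = pd.DataFrame(recs, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(np.column_stack(rows), samples, variants)


def write_dosage_table(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write variants x samples dosages as TSV (first five columns annotate)."""
    df = g.variants.copy()
    body = pd.DataFrame(g.dosages.T, columns=g.sample_ids.astype(str))
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def _read_dosage_table(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty dosage table {path}") from exc
    except Exception as exc:
        raise ParseError(f"cannot parse dosage table {path}: {exc}") from exc
    missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"dosage table {path} lacks columns {missing_cols}")
    if df.empty:
        raise EmptyInputError(f"no variants in dosage table {path}")
    variants = df[VARIANT_COLUMNS].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    body = df.drop(columns=VARIANT_COLUMNS)
    dosages = body.to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, np.asarray(body.columns, dtype=object), variants)


def read_genotypes(path: str | os.PathLike, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from ``vcf`` or ``dosage-table`` files.

    Multiallelic VCF records are skipped with a logged count; only biallelic
    records enter the matrix.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise EmptyInputError(f"{path} is empty")
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-table":
        return _read_dosage_table(path)
    raise ParameterError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | os.PathLike, format: str = "vcf") -> None:
    if format == "vcf":
        write_vcf(g, path)
    elif format == "dosage-table":
        write_dosage_table(g, path)
    else:
        raise ParameterError(f"unknown genotype format {format!r}")


# -- quality control --------------------------------------------------------

def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    snp_missing_max: float = 0.05,
    sample_missing_max: float = 0.03,
) -> GenotypeMatrix:
    """Remove low-MAF / high-missingness variants, then high-missingness samples.

    Variants are filtered first (MAF < ``maf_min`` or missing rate >
    ``snp_missing_max``), then samples with missing rate >
    ``sample_missing_max`` over the retained variants. MAF is computed on
    non-missing alleles only. The fixed variant-first order is logged.
    """
    for name, t in [("maf_min", maf_min), ("snp_missing_max", snp_missing_max),
                    ("sample_missing_max", sample_missing_max)]:
        if not 0.0 <= t <= 1.0:
            raise ParameterError(f"{name}={t} outside [0, 1]")
    keep_v = np.where(
        (g.maf() >= maf_min) & (g.variant_missing_rate() <= snp_missing_max)
    )[0]
    if keep_v.size == 0:
        raise EmptyResultError(
            f"QC removed all {g.n_variants} variants "
            f"(maf_min={maf_min}, snp_missing_max={snp_missing_max})"
        )
    out = g.subset(variants=keep_v)
    keep_s = np.where(out.sample_missing_rate() <= sample_missing_max)[0]
    out = out.subset(samples=keep_s)
    logger.info(
        "qc_filter (variants first, then samples): %d/%d variants, %d/%d samples kept",
        keep_v.size, g.n_variants, keep_s.size, g.n_samples,
    )
    return out


def heterozygosity_filter(g: GenotypeMatrix, n_sd: float = 3.0) -> GenotypeMatrix:
    """Drop samples whose heterozygous-call fraction lies beyond ``n_sd`` SDs."""
    het = np.nanmean(g.dosages == 1.0, axis=1)
    sd = het.std()
    if sd == 0:
        return g
    keep = np.where(np.abs(het - het.mean()) <= n_sd * sd)[0]
    if keep.size < g.n_samples:
        logger.info("heterozygosity filter removed %d samples", g.n_samples - keep.size)
    return g.subset(samples=keep)
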