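"""Containers and file formats shared by every pipeline stage.

The common currency is :class:`SparseCountMatrix` — a cells × features
sparse integer matrix carried together with its barcode and feature name
lists, serialized as a Matrix Market triplet file plus two TSVs (the
10x-style "MTX bundle").  Donor genotypes travel as VCF; everything else
is TSV with a header row.

Conventions
-----------
* VCF positions are 1-based; MTX indices are 1-based on disk, 0-based in
  memory.
* Barcode order is the universe: per-cell outputs are reported in input
  barcode order.
* Orientation of an MTX bundle on disk is auto-detected from the barcode
  and feature list lengths; a square matrix is ambiguous and requires an
  explicit ``orientation`` argument.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an input file violates the expected format contract."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SparseCountMatrix:
    """Cells × features non-negative integer counts with axis labels.

    Parameters
    ----------
    counts : scipy.sparse matrix
        Shape ``(n_cells, n_features)``; stored as CSR.
    barcodes : list of str
        Unique cell barcodes, one per row.
    features : list of str
        Feature (gene / hashtag) identifiers, one per column.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    features: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = list(self.barcodes)
        self.features = list(self.features)
        if self.counts.shape != (len(self.barcodes), len(self.features)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes are not unique")
        if self.counts.nnz:
            data = self.counts.data
            if (data < 0).any():
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer counts")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_cells(self, barcodes: list[str]) -> "SparseCountMatrix":
        """Row subset in the given barcode order."""
        index = {b: i for i, b in enumerate(self.barcodes)}
        rows = [index[b] for b in barcodes]
        return SparseCountMatrix(self.counts[rows], barcodes, self.features)


@dataclass
class SiteTable:
    """Biallelic SNV sites: (chrom, pos, ref, alt) with 1-based positions."""

    chrom: list[str]
    pos: list[int]
    ref: list[str]
    alt: list[str]

    def __post_init__(self) -> None:
        n = len(self.chrom)
        if not (len(self.pos) == len(self.ref) == len(self.alt) == n):
            raise FormatError("site table columns differ in length")
        keys = list(zip(self.chrom, self.pos, self.ref, self.alt))
        if len(set(keys)) != n:
            raise FormatError("duplicate sites")
        for c, p, r, a in keys:
            if p < 1:
                raise FormatError(f"position {p} is not 1-based")
            if r == a:
                raise FormatError(f"ref == alt at {c}:{p}")

    def __len__(self) -> int:
        return len(self.chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteTable":
        return cls(
            list(df["chrom"].astype(str)),
            list(df["pos"].astype(int)),
            list(df["ref"].astype(str)),
            list(df["alt"].astype(str)),
        )


@dataclass
class DonorGenotypeMatrix:
    """Donors × sites diploid genotypes coded 0/1/2 (ALT allele dosage)."""

    donors: list[str]
    genotypes: np.ndarray  # (n_donors, n_sites) int

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.genotypes.ndim != 2 or self.genotypes.shape[0] != len(self.donors):
            raise FormatError("genotype matrix shape does not match donor list")
        if self.genotypes.size and not np.isin(self.genotypes, (0, 1, 2)).all():
            raise FormatError("genotypes must be 0, 1 or 2")

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class CellMetadataTable:
    """Per-cell sample / tumor-type / cell-type labels."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("barcode", "sample_id", "tumor_type", "cell_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if self.frame["barcode"].duplicated().any():
            raise FormatError("duplicate barcodes in metadata")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def barcodes(self) -> list[str]:
        return list(self.frame["barcode"])


# ---------------------------------------------------------------------------
# MTX bundle
# ---------------------------------------------------------------------------

def _read_tsv_column(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx_bundle(
    matrix_path: str,
    barcodes_path: str,
    features_path: str,
    orientation: str | None = None,
) -> SparseCountMatrix:
    """Read a Matrix Market triplet file with its barcode/feature TSVs.

    Orientation on disk (cells-by-features vs the 10x-conventional
    features-by-cells) is auto-detected from the axis lengths.  When the
    matrix is square the orientation is ambiguous and ``orientation``
    must be given as ``"cells_by_features"`` or ``"features_by_cells"``.
    """
    mat = scipy.io.mmread(matrix_path)
    if not np.issubdtype(mat.dtype, np.integer):
        dense_ok = np.allclose(mat.data, np.round(mat.data)) if sp.issparse(mat) else False
        if not dense_ok:
            raise FormatError(f"{matrix_path}: non-integer entries")
        mat = mat.astype(int)
    mat = sp.csr_matrix(mat)
    barcodes = _read_tsv_column(barcodes_path)
    features = _read_tsv_column(features_path)
    nb, nf = len(barcodes), len(features)
    if mat.shape == (nb, nf) and mat.shape == (nf, nb):
        if orientation is None:
            raise FormatError(
                "square matrix: pass orientation='cells_by_features' or "
                "'features_by_cells' explicitly"
            )
        if orientation == "features_by_cells":
            mat = sp.csr_matrix(mat.T)
    elif mat.shape == (nb, nf):
        pass
    elif mat.shape == (nf, nb):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {nb} barcodes x {nf} "
            f"features nor its transpose"
        )
    return SparseCountMatrix(mat, barcodes, features)


def write_mtx_bundle(
    scm: SparseCountMatrix,
    matrix_path: str,
    barcodes_path: str,
    features_path: str,
) -> None:
    """Write an MTX bundle in cells-by-features orientation."""
    scipy.io.mmwrite(matrix_path, sp.coo_matrix(scm.counts), field="integer")
    with open(barcodes_path, "w") as fh:
        fh.writelines(b + "\n" for b in scm.barcodes)
    with open(features_path, "w") as fh:
        fh.writelines(f + "\n" for f in scm.features)


def write_bundle_dir(scm: SparseCountMatrix, outdir: str, prefix: str) -> dict:
    """Write ``<prefix>.mtx / <prefix>.barcodes.tsv / <prefix>.features.tsv``."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, f"{prefix}.mtx"),
        "barcodes": os.path.join(outdir, f"{prefix}.barcodes.tsv"),
        "features": os.path.join(outdir, f"{prefix}.features.tsv"),
    }
    write_mtx_bundle(scm, paths["matrix"], paths["barcodes"], paths["features"])
    return paths


def read_bundle_dir(outdir: str, prefix: str, orientation: str | None = None) -> SparseCountMatrix:
    return read_mtx_bundle(
        os.path.join(outdir, f"{prefix}.mtx"),
        os.path.join(outdir, f"{prefix}.barcodes.tsv"),
        os.path.join(outdir, f"{prefix}.features.tsv"),
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes_vcf(
    vcf_path: str, donor_ids: list[str]
) -> tuple[DonorGenotypeMatrix, SiteTable, dict]:
    """Read donor genotypes at biallelic SNV sites from a VCF.

    GT "0/0" → 0, "0/1"/"1/0" → 1, "1/1" → 2 (phased "|" separators are
    treated identically).  Sites with any missing genotype among the
    requested donors are dropped; multi-allelic records are skipped.
    Both events are counted in the returned report dict.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    absent = [d for d in donor_ids if d not in samples]
    if absent:
        raise FormatError(f"donors absent from VCF header: {absent}")
    cols = [samples.index(d) for d in donor_ids]

    report = {"n_kept": 0, "n_dropped_missing": 0, "n_skipped_multiallelic": 0}
    chrom, pos, ref, alt, rows = [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            report["n_skipped_multiallelic"] += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types[cols]
        if (gt == 2).any():
            report["n_dropped_missing"] += 1
            continue
        dosage = np.where(gt == 3, 2, gt)
        rows.append(dosage)
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        report["n_kept"] += 1

    geno = np.array(rows, dtype=int).reshape(len(rows), len(donor_ids)).T
    return (
        DonorGenotypeMatrix(list(donor_ids), geno),
        SiteTable(chrom, pos, ref, alt),
        report,
    )


def write_genotypes_vcf(
    geno: DonorGenotypeMatrix, sites: SiteTable, vcf_path: str
) -> None:
    """Write a minimal VCFv4.2 with GT fields for each donor."""
    if geno.n_sites != len(sites):
        raise FormatError("genotype matrix and site table disagree in length")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    # VCF requires records sorted by contig then position
    order = sorted(range(len(sites)), key=lambda i: (sites.chrom[i], sites.pos[i]))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(sites.chrom[i] for i in order):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.donors)
            + "\n"
        )
        for i in order:
            gts = "\t".join(gt_str[g] for g in geno.genotypes[:, i])
            fh.write(
                f"{sites.chrom[i]}\t{sites.pos[i]}\t.\t{sites.ref[i]}\t"
                f"{sites.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_metadata_tsv(path: str) -> CellMetadataTable:
    return CellMetadataTable(read_tsv(path))
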