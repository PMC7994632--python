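"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular formats are UTF-8 TSV with ``.`` as the missing sentinel and
full-precision (repr round-trip) floats on write.  Genomic coordinates are
1-based inclusive everywhere, matching VCF and GFF3 native conventions; no
half-open conversion is ever exposed.

Genotype dosages count copies of the ALT allele (0, 1, 2) with ``NaN`` as
the in-memory missing sentinel.  Minor allele frequency is always
``min(f, 1 - f)`` of the ALT-allele frequency computed over non-missing
calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "TRAITS",
    "SnpRecord",
    "GenotypeMatrix",
    "PhenotypeTable",
    "GeneModel",
    "AssocStat",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_summary_stats",
    "write_summary_stats",
    "read_gff3",
]

#: Trait codes: grains per panicle, kilo-grain weight, tillers per plant,
#: yield per plant.
TRAITS = ("GPP", "KGW", "TP", "YD")

MISSING = "."

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P", "N"]


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Well-formed input whose values violate a field contract."""


_SNP_ID_RE = re.compile(r"^chr(\d{2})_(\d+)$")


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP named ``chr{chrom:02d}_{pos}`` when auto-generated."""

    snp_id: str
    chrom: int
    pos: int
    allele_ref: str = "A"
    allele_alt: str = "G"

    @staticmethod
    def auto_id(chrom: int, pos: int) -> str:
        return f"chr{chrom:02d}_{pos}"

    @classmethod
    def from_id(cls, snp_id: str, allele_ref: str = "A", allele_alt: str = "G") -> "SnpRecord":
        m = _SNP_ID_RE.match(snp_id)
        if not m:
            raise ValidationError(f"snp_id {snp_id!r} is not of the form chrCC_POS")
        return cls(snp_id, int(m.group(1)), int(m.group(2)), allele_ref, allele_alt)


@dataclass
class GenotypeMatrix:
    """Lines x biallelic SNPs as ALT-allele dosages with SNP metadata.

    ``dosage`` is float with values in {0, 1, 2, NaN}; rows are lines in
    ``line_ids`` order, columns are SNPs in ``snps`` order.
    """

    line_ids: list[str]
    snps: list[SnpRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.snps)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.line_ids)}, {len(self.snps)})"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise ValidationError(f"dosage values outside {{0,1,2,missing}}: {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_index(snp_id)]

    def alt_freq(self) -> np.ndarray:
        """Per-SNP ALT-allele frequency over non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def subset_snps(self, keep: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            snps=[self.snps[i] for i in keep],
            dosage=self.dosage[:, keep],
        )

    def subset_lines(self, keep_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.line_ids.index(l) for l in keep_ids]
        return GenotypeMatrix(list(keep_ids), list(self.snps), self.dosage[idx, :])


def concat_lines(panels: Iterable[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack panels line-wise over the union of their SNPs (e.g. to pool
    populations for LD estimation); a SNP absent from a panel is missing
    for that panel's lines."""
    panels = list(panels)
    union: list[SnpRecord] = []
    seen: dict[str, int] = {}
    for p in panels:
        for s in p.snps:
            if s.snp_id not in seen:
                seen[s.snp_id] = len(union)
                union.append(s)
    n_lines = sum(p.n_lines for p in panels)
    dosage = np.full((n_lines, len(union)), np.nan)
    row = 0
    for p in panels:
        cols = [seen[s.snp_id] for s in p.snps]
        dosage[row : row + p.n_lines, cols] = p.dosage
        row += p.n_lines
    return GenotypeMatrix(
        line_ids=[l for p in panels for l in p.line_ids],
        snps=union,
        dosage=dosage,
    )


@dataclass
class PhenotypeTable:
    """Long-format phenotype records keyed by (line_id, dataset_id, trait)."""

    frame: pd.DataFrame  # columns: line_id, dataset_id, trait, value

    COLUMNS = ["line_id", "dataset_id", "trait", "value"]

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in self.COLUMNS if c not in f.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks columns {missing}")
        self.frame = f = f[self.COLUMNS].reset_index(drop=True)
        bad = f["trait"][~f["trait"].isin(TRAITS)]
        if len(bad):
            raise ValidationError(f"unknown trait codes: {sorted(set(bad))}")
        if f.duplicated(["line_id", "dataset_id", "trait"]).any():
            raise ValidationError("duplicate (line_id, dataset_id, trait) rows")
        vals = f["value"].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValidationError("non-finite phenotype values")

    def values_for(self, dataset_id: str, trait: str, line_ids: Sequence[str]) -> np.ndarray:
        """Trait values aligned to ``line_ids`` (NaN where unphenotyped)."""
        sub = self.frame[
            (self.frame["dataset_id"] == dataset_id) & (self.frame["trait"] == trait)
        ]
        lut = dict(zip(sub["line_id"], sub["value"]))
        return np.array([lut.get(l, np.nan) for l in line_ids], dtype=float)

    def datasets(self) -> list[str]:
        return sorted(self.frame["dataset_id"].unique())


@dataclass(frozen=True)
class GeneModel:
    """A gene with 1-based inclusive coordinates."""

    gene_id: str
    chrom: int
    start: int
    end: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class AssocStat:
    """Per-SNP single-dataset association summary (GCTA .mlma-like)."""

    snp: SnpRecord
    trait: str
    dataset_id: str
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"{self.snp.snp_id}: SE must be > 0, got {self.se}")
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.snp.snp_id}: P must be in (0, 1], got {self.p}")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read a genotype panel from VCF (biallelic SNPs only) or dosage TSV.

    Dosage is the ALT-allele count; ``./.`` (VCF) or ``.`` (TSV) map to the
    missing sentinel.  Multiallelic VCF records are rejected.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        if len(v.ALT) != 1 or v.ALT[0] == ".":
            raise FormatError(
                f"non-biallelic record at {v.CHROM}:{v.POS} (ALT={v.ALT}); "
                "only biallelic SNPs are supported"
            )
        chrom = int(str(v.CHROM).lower().removeprefix("chr"))
        snps.append(
            SnpRecord(SnpRecord.auto_id(chrom, v.POS), chrom, v.POS, v.REF, v.ALT[0])
        )
        rows.append(gt_map[v.gt_types])
    dosage = np.column_stack(rows) if rows else np.empty((len(line_ids), 0))
    return GenotypeMatrix(line_ids, snps, dosage)


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    alleles: list[tuple[str, str]] | None = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#ref_alt"):
            alleles = [tuple(a.split(":")) for a in first.rstrip("\n").split("\t")[1:]]
            header_line = fh.readline()
        else:
            header_line = first
        header = header_line.rstrip("\n").split("\t")
        if not header or header[0] != "line_id":
            raise FormatError("dosage TSV line 1: first column must be 'line_id'")
        snp_ids = header[1:]
        if alleles is not None and len(alleles) != len(snp_ids):
            raise FormatError("dosage TSV: #ref_alt arity does not match header")
        line_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=3 if alleles is not None else 2):
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(snp_ids) + 1:
                raise FormatError(
                    f"dosage TSV line {lineno}: expected {len(snp_ids) + 1} fields, "
                    f"got {len(fields)}"
                )
            line_ids.append(fields[0])
            rows.append(
                [np.nan if v == MISSING else float(v) for v in fields[1:]]
            )
    if alleles is None:
        snps = [SnpRecord.from_id(s) for s in snp_ids]
    else:
        snps = [SnpRecord.from_id(s, r, a) for s, (r, a) in zip(snp_ids, alleles)]
    dosage = np.array(rows, dtype=float).reshape(len(line_ids), len(snp_ids))
    return GenotypeMatrix(line_ids, snps, dosage)


def write_genotypes(g: GenotypeMatrix, path: str) -> None:
    """Write a dosage TSV (header of snp_ids, first column line_id).

    A ``#ref_alt`` comment line carries the REF:ALT alleles so the file
    round-trips through :func:`read_genotypes` on all fields.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#ref_alt\t" + "\t".join(f"{s.allele_ref}:{s.allele_alt}" for s in g.snps) + "\n")
        fh.write("line_id\t" + "\t".join(g.snp_ids) + "\n")
        for i, lid in enumerate(g.line_ids):
            vals = [
                MISSING if np.isnan(d) else str(int(d)) for d in g.dosage[i]
            ]
            fh.write(lid + "\t" + "\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t", dtype={"line_id": str, "dataset_id": str,
                                               "trait": str}, na_values=[MISSING],
                        float_precision="round_trip")
    return PhenotypeTable(frame)


def write_phenotypes(t: PhenotypeTable, path: str) -> None:
    out = t.frame.copy()
    out["value"] = [MISSING if pd.isna(v) else repr(float(v)) for v in out["value"]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(path: str, trait: str = "", dataset_id: str = "") -> list[AssocStat]:
    """Read a GCTA-.mlma-like TSV (SNP/CHR/POS/A1/A2/BETA/SE/P/N).

    ``trait``/``dataset_id`` label the returned records; the file itself is
    one dataset x one trait.
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"summary-stat file lacks columns {missing}")
    out: list[AssocStat] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        se, p = float(row.SE), float(row.P)
        if not se > 0:
            raise ValidationError(f"row {i}: SE must be > 0, got {se}")
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"row {i}: P must be in (0, 1], got {p}")
        # A1 is the effect allele (= ALT dosage allele), A2 the other
        snp = SnpRecord(str(row.SNP), int(row.CHR), int(row.POS), str(row.A2), str(row.A1))
        out.append(AssocStat(snp, trait, dataset_id, float(row.BETA), se, p, int(row.N)))
    return out


def write_summary_stats(stats: Sequence[AssocStat], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in stats:
            fh.write(
                "\t".join(
                    [
                        s.snp.snp_id,
                        str(s.snp.chrom),
                        str(s.snp.pos),
                        s.snp.allele_alt,  # A1 = effect allele = ALT dosage allele
                        s.snp.allele_ref,
                        repr(float(s.beta)),
                        repr(float(s.se)),
                        repr(float(s.p)),
                        str(s.n),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene records from a GFF3 file (feature type ``gene`` only).

    Coordinates are kept 1-based inclusive; ``gene_id`` comes from the ID
    attribute and a missing ID raises :class:`ValidationError`.
    """
    from gffutils.iterators import DataIterator

    genes: list[GeneModel] = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        ids = feat.attributes.get("ID")
        if not ids:
            raise ValidationError(
                f"gene record at {feat.seqid}:{feat.start}-{feat.end} has no ID attribute"
            )
        desc = feat.attributes.get("description", [""])[0]
        chrom = int(str(feat.seqid).lower().removeprefix("chr"))
        genes.append(GeneModel(ids[0], chrom, feat.start, feat.end, desc))
    return genes
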