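"""Domain types and I/O for two-bulk variant tables.

A bulked-segregant experiment sequences two DNA pools (a wild-type-phenotype
bulk and a mutant bulk) and records, at every variant site, how many reads
carry the mutant (ALT) allele in each pool.  This module holds the in-memory
representation of such a table — :class:`VariantCall` with per-bulk
:class:`AlleleDepth` — and the readers/writers for the two supported
dialects:

* a small VCF 4.2 subset with two bulk samples and a ``FORMAT=AD`` field
  (read with :mod:`cyvcf2`);
* an 8-column tab-separated table ``chrom pos ref alt wt_alt wt_total
  mut_alt mut_total`` with a ``#``-prefixed header.

Coordinates are 1-based point positions in both dialects.  The "mutant
allele" is always the ALT allele: the pipeline assumes variants were called
against the wild-type reference genome.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "AlleleDepth",
    "BulkDesign",
    "VariantCall",
    "VariantClass",
    "classify_alleles",
    "read_variants",
    "write_variants",
]

_DNA = set("ACGTN")

TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "wt_alt",
    "wt_total",
    "mut_alt",
    "mut_total",
)


class VariantClass(enum.Enum):
    """SNP if both alleles are single bases, INDEL otherwise."""

    SNP = "SNP"
    INDEL = "INDEL"


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """Classify a ref/alt pair purely by allele lengths."""
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNP
    return VariantClass.INDEL


@dataclass(frozen=True)
class AlleleDepth:
    """Read support for one bulk at one site.

    ``alt_depth`` reads carry the mutant allele out of ``total_depth`` reads
    covering the site.  ``total_depth`` is the site coverage, i.e. the sum
    over all alleles' AD entries.
    """

    alt_depth: int
    total_depth: int

    def __post_init__(self) -> None:
        if self.alt_depth < 0 or self.total_depth < 0:
            raise ValidationError(
                f"negative depth: alt={self.alt_depth} total={self.total_depth}"
            )
        if self.alt_depth > self.total_depth:
            raise ValidationError(
                f"alt_depth {self.alt_depth} exceeds total_depth {self.total_depth}"
            )


@dataclass(frozen=True)
class BulkDesign:
    """The two-bulk experimental design.

    Defaults mirror a typical MutMap+ setup: 30 plants per phenotype bulk,
    mean sequencing depths of ~18x (wild-type bulk) and ~21x (mutant bulk).
    """

    wt_bulk_id: str = "wt_bulk"
    mut_bulk_id: str = "mut_bulk"
    n_wt: int = 30
    n_mut: int = 30
    mean_depth_wt: float = 18.06
    mean_depth_mut: float = 20.90

    def __post_init__(self) -> None:
        if self.n_wt < 1 or self.n_mut < 1:
            raise ValidationError("bulk sizes must be >= 1")
        if self.mean_depth_wt <= 0 or self.mean_depth_mut <= 0:
            raise ValidationError("mean depths must be positive")
        if self.wt_bulk_id == self.mut_bulk_id:
            raise ConfigurationError("the two bulks must have distinct ids")


@dataclass(frozen=True)
class VariantCall:
    """One variant site with per-bulk allele depths.

    ``depths`` maps each bulk id of the associated :class:`BulkDesign` to an
    :class:`AlleleDepth`.  ``vclass`` is derived from the allele lengths and
    never set independently.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depths: dict[str, AlleleDepth] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _DNA:
                raise ValidationError(
                    f"{name} allele {allele!r} is not a non-empty uppercase DNA string"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical ({self.ref!r})")

    @property
    def vclass(self) -> VariantClass:
        return classify_alleles(self.ref, self.alt)

    def depth(self, bulk_id: str) -> AlleleDepth:
        return self.depths[bulk_id]


def _check_bulks(variant: VariantCall, design: BulkDesign, where: str) -> None:
    expected = {design.wt_bulk_id, design.mut_bulk_id}
    if set(variant.depths) != expected:
        raise ConfigurationError(
            f"{where}: depths carry bulks {sorted(variant.depths)}, expected {sorted(expected)}"
        )


def read_variants(
    path: str | Path, format: str, design: BulkDesign
) -> list[VariantCall]:
    """Read a two-bulk variant table.

    ``format`` is ``"vcf"`` or ``"tsv"`` (case-insensitive).  Input order is
    preserved; multi-allelic VCF records are split into one
    :class:`VariantCall` per ALT allele, each inheriting the record's site
    coverage (sum of all AD entries) as ``total_depth``.
    """
    fmt = format.lower()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        return _read_tsv(path, design)
    if fmt == "vcf":
        return _read_vcf(path, design)
    raise ConfigurationError(f"unknown format {format!r}; expected 'vcf' or 'tsv'")


def _read_tsv(path: Path, design: BulkDesign) -> list[VariantCall]:
    with open(path) as fh:
        header = fh.readline()
    if not header:
        return []
    names = header.lstrip("#").split()
    if tuple(names) != TSV_COLUMNS:
        raise FormatError(
            f"{path}: TSV header {names} does not match expected columns {list(TSV_COLUMNS)}"
        )
    table = pd.read_csv(path, sep="\t", skiprows=1, names=TSV_COLUMNS,
                        dtype={"chrom": str, "ref": str, "alt": str})
    out: list[VariantCall] = []
    for i, row in enumerate(table.itertuples(index=False), start=2):
        try:
            out.append(
                VariantCall(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    depths={
                        design.wt_bulk_id: AlleleDepth(int(row.wt_alt), int(row.wt_total)),
                        design.mut_bulk_id: AlleleDepth(int(row.mut_alt), int(row.mut_total)),
                    },
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return out


def _read_vcf(path: Path, design: BulkDesign) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for bulk_id in (design.wt_bulk_id, design.mut_bulk_id):
        if bulk_id not in samples:
            raise ConfigurationError(
                f"{path}: sample {bulk_id!r} not present (samples: {samples})"
            )
    idx = {b: samples.index(b) for b in (design.wt_bulk_id, design.mut_bulk_id)}
    out: list[VariantCall] = []
    for record in vcf:
        ad = record.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: record {record.CHROM}:{record.POS} has no AD field"
            )
        # site coverage = sum of AD over ref + every alt, per sample
        totals = {b: int(ad[i][ad[i] >= 0].sum()) for b, i in idx.items()}
        for alt_i, alt in enumerate(record.ALT):
            depths = {}
            for bulk_id, i in idx.items():
                alt_depth = int(ad[i][alt_i + 1])
                if alt_depth < 0:
                    raise FormatError(
                        f"{path}: missing AD entry at {record.CHROM}:{record.POS} "
                        f"sample {bulk_id}"
                    )
                try:
                    depths[bulk_id] = AlleleDepth(alt_depth, totals[bulk_id])
                except ValidationError as exc:
                    raise ValidationError(
                        f"{path}: record {record.CHROM}:{record.POS}: {exc}"
                    ) from exc
            out.append(
                VariantCall(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    depths=depths,
                )
            )
    return out


def write_variants(
    variants: Iterable[VariantCall],
    path: str | Path,
    format: str,
    design: BulkDesign,
) -> Path:
    """Write a variant table; ``read_variants`` round-trips every field."""
    fmt = format.lower()
    path = Path(path)
    variants = list(variants)
    for v in variants:
        _check_bulks(v, design, f"{v.chrom}:{v.pos}")
    if fmt == "tsv":
        _write_tsv(variants, path, design)
    elif fmt == "vcf":
        _write_vcf(variants, path, design)
    else:
        raise ConfigurationError(f"unknown format {format!r}; expected 'vcf' or 'tsv'")
    return path


def _write_tsv(variants: Sequence[VariantCall], path: Path, design: BulkDesign) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TSV_COLUMNS) + "\n")
        for v in variants:
            wt = v.depth(design.wt_bulk_id)
            mut = v.depth(design.mut_bulk_id)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{wt.alt_depth}\t{wt.total_depth}\t{mut.alt_depth}\t{mut.total_depth}\n"
            )


def _write_vcf(variants: Sequence[VariantCall], path: Path, design: BulkDesign) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsa-mutfind\n")
        for chrom in dict.fromkeys(v.chrom for v in variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{design.wt_bulk_id}\t{design.mut_bulk_id}\n"
        )
        for v in variants:
            wt = v.depth(design.wt_bulk_id)
            mut = v.depth(design.mut_bulk_id)
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tAD\t"
                f"{wt.total_depth - wt.alt_depth},{wt.alt_depth}\t"
                f"{mut.total_depth - mut.alt_depth},{mut.alt_depth}\n"
            )
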