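"""SNP/Indel-index computation and the three-stage candidate filter.

The SNP/Indel-index of a site in one bulk is the fraction of reads covering
the site that carry the mutant allele: 1 means the mutant allele is fixed in
the pool, 0 means absent, ~0.5 a heterozygous pool.  For a recessive
mutation mapped by two phenotype bulks, the causal site is expected at
index 1 in the mutant bulk (every plant homozygous mutant) and below 0.5 in
the wild-type-phenotype bulk (a mix of homozygous wild type, index 0, and
heterozygotes, expected index 0.5).

The filter is an ordered cascade of per-site predicates:

1. *low-index removal* — drop sites with index < ``low_index_cutoff`` in
   **both** bulks (noise and caller artefacts uncorrelated with either pool);
2. *mutant-index requirement* — keep sites with mutant-bulk index >=
   ``mut_index_required`` (default 1.0, i.e. every covering read mutant);
3. *wild-type-index bound* — keep sites with wild-type-bulk index strictly
   below ``wt_index_max`` (default 0.5).

Sites with too little coverage to evaluate an index (total depth below
``min_depth``) are disqualified at stage 1: an uncovered mutant bulk cannot
certify index = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .variants import BulkDesign, VariantCall, VariantClass

__all__ = [
    "FilterCriteria",
    "FilterReport",
    "IndexedVariant",
    "StageCount",
    "annotate",
    "compute_index",
    "run_cascade",
    "stage_low_index",
    "stage_mut_fixed",
    "stage_wt_bounded",
]

STAGE_NAMES = ("input", "low_index", "mut_fixed", "wt_bound")

_STAGE_LABELS = {
    "input": "input",
    "low_index": f"index >= cutoff in a bulk",
    "mut_fixed": "mutant-bulk index = 1",
    "wt_bound": "wt-bulk index < 0.5",
}


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the cascade and their comparison semantics.

    ``low_index_cutoff`` — stage-1 removal threshold (remove when *both*
    bulk indices fall strictly below it).  ``mut_index_required`` — minimum
    mutant-bulk index at stage 2 (>=; at the default 1.0 this demands
    alt_depth == total_depth exactly, no tolerance).  ``wt_index_max`` —
    strict upper bound on the wild-type-bulk index at stage 3.
    ``min_depth`` — minimum total depth per bulk for an index to be defined.
    """

    low_index_cutoff: float = 0.3
    mut_index_required: float = 1.0
    wt_index_max: float = 0.5
    min_depth: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_index_cutoff <= 1.0:
            raise ValidationError("low_index_cutoff must lie in [0, 1]")
        if not 0.0 < self.mut_index_required <= 1.0:
            raise ValidationError("mut_index_required must lie in (0, 1]")
        if not 0.0 < self.wt_index_max <= 1.0:
            raise ValidationError("wt_index_max must lie in (0, 1]")
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")


def compute_index(
    alt_depth: int, total_depth: int, min_depth: int = 1
) -> float | None:
    """Mutant-read fraction at one site in one bulk.

    Returns ``alt_depth / total_depth`` at full floating precision, or
    ``None`` (undefined) when ``total_depth < min_depth``.  Rounding to two
    decimals happens only at presentation.
    """
    if alt_depth < 0 or total_depth < 0:
        raise ValidationError("depths must be non-negative")
    if alt_depth > total_depth:
        raise ValidationError(
            f"alt_depth {alt_depth} exceeds total_depth {total_depth}"
        )
    if total_depth < min_depth:
        return None
    return alt_depth / total_depth


@dataclass(frozen=True)
class IndexedVariant:
    """A variant with its per-bulk indices; ``None`` marks an undefined index."""

    variant: VariantCall
    wt_index: float | None
    mut_index: float | None


def annotate(
    variants: Iterable[VariantCall],
    design: BulkDesign,
    criteria: FilterCriteria = FilterCriteria(),
) -> list[IndexedVariant]:
    """Compute both bulk indices for every variant, preserving order."""
    out = []
    for v in variants:
        wt = v.depth(design.wt_bulk_id)
        mut = v.depth(design.mut_bulk_id)
        out.append(
            IndexedVariant(
                variant=v,
                wt_index=compute_index(wt.alt_depth, wt.total_depth, criteria.min_depth),
                mut_index=compute_index(mut.alt_depth, mut.total_depth, criteria.min_depth),
            )
        )
    return out


def stage_low_index(
    indexed: Iterable[IndexedVariant], criteria: FilterCriteria = FilterCriteria()
) -> list[IndexedVariant]:
    """Remove sites below the cutoff in both bulks, and uncovered sites."""
    kept = []
    for iv in indexed:
        if iv.wt_index is None or iv.mut_index is None:
            continue
        if iv.wt_index < criteria.low_index_cutoff and iv.mut_index < criteria.low_index_cutoff:
            continue
        kept.append(iv)
    return kept


def stage_mut_fixed(
    indexed: Iterable[IndexedVariant], criteria: FilterCriteria = FilterCriteria()
) -> list[IndexedVariant]:
    """Keep sites whose mutant-bulk index reaches the required level."""
    return [
        iv
        for iv in indexed
        if iv.mut_index is not None and iv.mut_index >= criteria.mut_index_required
    ]


def stage_wt_bounded(
    indexed: Iterable[IndexedVariant], criteria: FilterCriteria = FilterCriteria()
) -> list[IndexedVariant]:
    """Keep sites whose wild-type-bulk index is strictly below the bound."""
    return [
        iv
        for iv in indexed
        if iv.wt_index is not None and iv.wt_index < criteria.wt_index_max
    ]


@dataclass(frozen=True)
class StageCount:
    name: str
    n_total: int
    n_snps: int
    n_indels: int


def _count(name: str, indexed: Sequence[IndexedVariant]) -> StageCount:
    n_snps = sum(1 for iv in indexed if iv.variant.vclass is VariantClass.SNP)
    return StageCount(name, len(indexed), n_snps, len(indexed) - n_snps)


@dataclass(frozen=True)
class FilterReport:
    """Survivor counts after each cascade stage plus the surviving set.

    ``stage_counts`` is ordered input -> low-index removal -> mutant-index
    requirement -> wild-type-index bound; counts are non-increasing along
    the cascade, and SNPs/indels are tallied separately at every stage.
    """

    stage_counts: tuple[StageCount, ...]
    survivors: tuple[IndexedVariant, ...]

    @property
    def n_input_snps(self) -> int:
        return self.stage_counts[0].n_snps

    @property
    def n_input_indels(self) -> int:
        return self.stage_counts[0].n_indels

    def funnel(self) -> list[int]:
        return [sc.n_total for sc in self.stage_counts]

    def funnel_text(self) -> str:
        """Human-readable funnel block (survivor counts after each filter)."""
        lines = ["funnel: " + " -> ".join(str(n) for n in self.funnel())]
        width = max(len(_STAGE_LABELS[sc.name]) for sc in self.stage_counts)
        for sc in self.stage_counts:
            lines.append(
                f"  {_STAGE_LABELS[sc.name]:<{width}}  {sc.n_total:>7} "
                f"({sc.n_snps} SNPs, {sc.n_indels} indels)"
            )
        for iv in self.survivors:
            v = iv.variant
            wt = "NA" if iv.wt_index is None else f"{iv.wt_index:.2f}"
            mut = "NA" if iv.mut_index is None else f"{iv.mut_index:.2f}"
            lines.append(
                f"  survivor: {v.chrom}:{v.pos} {v.ref}>{v.alt} "
                f"wt-index={wt} mut-index={mut}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": sc.name,
                    "n": sc.n_total,
                    "n_snps": sc.n_snps,
                    "n_indels": sc.n_indels,
                }
                for sc in self.stage_counts
            ],
            "survivors": [
                {
                    "chrom": iv.variant.chrom,
                    "pos": iv.variant.pos,
                    "ref": iv.variant.ref,
                    "alt": iv.variant.alt,
                    "vclass": iv.variant.vclass.value,
                    "wt_index": iv.wt_index,
                    "mut_index": iv.mut_index,
                }
                for iv in self.survivors
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def run_cascade(
    variants: Iterable[VariantCall],
    design: BulkDesign,
    criteria: FilterCriteria = FilterCriteria(),
) -> FilterReport:
    """Annotate then apply the three filter stages in order; deterministic."""
    indexed = annotate(variants, design, criteria)
    counts = [_count("input", indexed)]
    indexed = stage_low_index(indexed, criteria)
    counts.append(_count("low_index", indexed))
    indexed = stage_mut_fixed(indexed, criteria)
    counts.append(_count("mut_fixed", indexed))
    indexed = stage_wt_bounded(indexed, criteria)
    counts.append(_count("wt_bound", indexed))
    return FilterReport(stage_counts=tuple(counts), survivors=tuple(indexed))
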