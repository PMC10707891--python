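import pytest

from bsa_mutfind import AlleleDepth, BulkDesign, VariantCall


@pytest.fixture
def design():
    return BulkDesign()


def _call(design, chrom, pos, wt, mut, ref="C", alt="T"):
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depths={
            design.wt_bulk_id: AlleleDepth(*wt),
            design.mut_bulk_id: AlleleDepth(*mut),
        },
    )


@pytest.fixture
def make_call(design):
    """Factory for a VariantCall with (alt, total) depth pairs per bulk."""

    def _make(chrom="chr1", pos=1, wt=(0, 10), mut=(0, 10), ref="C", alt="T"):
        return _call(design, chrom, pos, wt, mut, ref, alt)

    return _make


@pytest.fixture
def toy_variants(design):
    """Five hand-evaluated variants exercising every cascade stage.

    A survives all stages; B fails the fixed-mutant requirement (19/20);
    C fails the wild-type bound (10/15 = 0.667); D is low-index in both
    bulks; E is heterozygous-like in the mutant bulk (10/20).
    """
    return [
        _call(design, "chr1", 100, wt=(3, 15), mut=(20, 20)),  # A
        _call(design, "chr1", 200, wt=(3, 15), mut=(19, 20)),  # B
        _call(design, "chr1", 300, wt=(10, 15), mut=(20, 20)),  # C
        _call(design, "chr1", 400, wt=(2, 15), mut=(2, 20)),  # D
        _call(design, "chr1", 500, wt=(8, 15), mut=(10, 20)),  # E
    ]


@pytest.fixture
def candidate_variant(design):
    """The archetypal surviving candidate: fixed in the mutant bulk (29/29),
    rare in the wild-type bulk (2/16)."""
    return _call(design, "chr1", 2_771_134, wt=(2, 16), mut=(29, 29))
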