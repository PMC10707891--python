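"""Index a small two-bulk variant table and run the filtering cascade.

Builds five variants by hand, computes the per-bulk SNP-index for each and
applies the three filter stages.  The printed funnel shows how many sites
survive each stage; the single survivor is the only site that is fixed in
the mutant bulk (index 1) while staying below 0.5 in the wild-type bulk —
the signature of a recessive causal mutation.
"""

from bsa_mutfind import AlleleDepth, BulkDesign, VariantCall, run_cascade

design = BulkDesign()


def call(pos, wt, mut):
    return VariantCall(
        chrom="chr1", pos=pos, ref="C", alt="T",
        depths={design.wt_bulk_id: AlleleDepth(*wt),
                design.mut_bulk_id: AlleleDepth(*mut)},
    )


variants = [
    call(100, wt=(3, 15), mut=(20, 20)),   # causal-like: fixed in mutant bulk
    call(200, wt=(3, 15), mut=(19, 20)),   # one wild-type read in mutant bulk
    call(300, wt=(10, 15), mut=(20, 20)),  # too frequent in wild-type bulk
    call(400, wt=(2, 15), mut=(2, 20)),    # low-index noise in both bulks
    call(500, wt=(8, 15), mut=(10, 20)),   # heterozygous-like everywhere
]

report = run_cascade(variants, design)
print(report.funnel_text())
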