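# bsa-mutfind

Bulked-segregant SNP/Indel-index filtering for isolating recessive causal
mutations in EMS-mutagenized lines, together with a forward simulator of the
experimental design and a Monte-Carlo power analysis of the filter.

## The problem and who this is for

Forward genetic screens in selfing crops (rice, wheat, tomato, ...) produce
recessive mutants whose causal lesion must be found among thousands of
background EMS mutations. In a MutMap+-style design, a heterozygous parent
is selfed, its progeny are sorted by phenotype into a mutant bulk and a
wild-type-phenotype bulk, and both pooled DNA samples are sequenced. At
every variant site the **SNP/Indel-index** of a bulk is

```
index = (reads carrying the mutant allele) / (total reads covering the site)
```

For a recessive causal mutation the mutant bulk is composed entirely of
homozygotes, so its index is 1; the wild-type bulk mixes homozygous wild
type (index 0) and heterozygotes (expected index 0.5), so its index stays
below 0.5. Candidate isolation is an ordered three-stage filter over all
sites:

1. remove sites with index < 0.3 in **both** bulks (noise uncorrelated with
   either pool);
2. keep sites with mutant-bulk index = 1 (exactly: every covering read
   mutant);
3. keep sites with wild-type-bulk index strictly < 0.5.

The package implements this cascade over VCF (two samples with `AD`) or TSV
tables, a simulator that emulates the whole design (Mendelian selfing with
Haldane recombination, phenotype bulking, Poisson depth / binomial read
sampling), the Mendelian segregation chi-square test, pigment-content
formulas, and Monte-Carlo evaluation of the filter's sensitivity and false
positives. It is aimed at people running or planning such screens and at
anyone who wants to know *how often* this filter isolates a single
candidate before committing to a sequencing design.

## Worked example

```python
from bsa_mutfind import SimulationConfig, run_cascade, simulate_experiment

config = SimulationConfig(seed=7)   # 30+30 bulks, ~18x/~21x, 2000 het + 100 fixed background
variants, truth = simulate_experiment(config)
report = run_cascade(variants, config.design)
print(report.funnel_text())
```

prints

```
funnel: 2101 -> 2092 -> 107 -> 6
  input                         2101 (2101 SNPs, 0 indels)
  index >= cutoff in a bulk     2092 (2092 SNPs, 0 indels)
  mutant-bulk index = 1          107 (107 SNPs, 0 indels)
  wt-bulk index < 0.5              6 (6 SNPs, 0 indels)
  survivor: chr1:2053654 G>A wt-index=0.23 mut-index=1.00
  ...
  survivor: chr1:2771134 C>T wt-index=0.26 mut-index=1.00
```

2,101 simulated sites funnel down to 6 survivors: the true causal site
(chr1:2771134) plus five background mutations tightly linked to it — the
survivor set delineates a candidate region around the causal mutation, as
in real bulked-segregant data. With `linkage=False` (free assortment) the
causal site is typically the sole survivor.

The same pipeline runs from the shell:

```
bsa-mutfind simulate --seed 7 --out-variants sim.tsv --out-truth truth.json
bsa-mutfind filter sim.tsv --out-report report.json
bsa-mutfind segtest --wt 102 --mut 30 --ratio 3:1
# -> chi2(1) = 0.36, p = 0.5465 (consistent with 3:1 at alpha = 0.05)
bsa-mutfind power --seed 1 --n-replicates 100
```

`examples/` contains one short narrative script per capability.

## Layout

- `src/bsa_mutfind/variants.py` — domain types, VCF/TSV readers and writers
- `src/bsa_mutfind/index.py` — index computation and the filtering cascade
- `src/bsa_mutfind/simulate.py` — the forward simulator
- `src/bsa_mutfind/phenotype.py` — segregation test, pigment quantification
- `src/bsa_mutfind/power.py` — Monte-Carlo sensitivity / false-positive analysis
- `src/bsa_mutfind/cli.py` — the `bsa-mutfind` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
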