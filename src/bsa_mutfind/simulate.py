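"""Forward simulator of an EMS bulked-segregant sequencing experiment.

The model follows the genetics of a MutMap+-style design.  A selfed M4
plant is heterozygous for one recessive causal mutation and for a load of
background EMS mutations (predominantly C->T / G->A transitions); further
EMS mutations are already fixed homozygous.  Selfing produces M5 progeny:
each plant receives two independent gametes, and within a gamete alleles at
heterozygous sites on one chromosome follow a linear Markov walk along the
genetic map, recombining between adjacent sites with the Haldane
probability r = (1 - exp(-2d/100)) / 2.  Progeny with two mutant copies at
the causal site show the mutant phenotype (recessive); all others look wild
type.  Phenotype-sorted bulks of equal-proportion pooled DNA are then
"sequenced": per site and bulk, total depth is Poisson with the bulk's mean
coverage and mutant-read counts are binomial at the bulk allele frequency,
optionally corrupted by a per-read miscall rate.

All heterozygous mutations are modelled in coupling phase (mutant alleles
on one homolog), and the genetic map is linear in physical position within
each chromosome.  Setting ``linkage=False`` makes every site segregate
independently (free recombination), the textbook idealization of an
unlinked background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, SimulationError, ValidationError
from .variants import AlleleDepth, BulkDesign, VariantCall

__all__ = [
    "ChromosomeSpec",
    "ProgenyPopulation",
    "SimulationConfig",
    "SimTruth",
    "Site",
    "build_bulks",
    "default_chromosomes",
    "generate_variants",
    "haldane_r",
    "load_config",
    "sample_depths",
    "self_progeny",
    "simulate_experiment",
]

_TRANSITIONS = (("C", "T"), ("G", "A"))
_TRANSVERSIONS = (
    ("A", "C"), ("A", "T"), ("C", "A"), ("C", "G"),
    ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G"),
)


def haldane_r(d):
    """Haldane map function: map distance d (cM) -> recombination fraction.

    r = (1 - exp(-2 d / 100)) / 2, assuming no crossover interference.
    Accepts scalars or arrays; raises on negative distances.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: physical length in bp and genetic length in cM."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp < 1 or self.length_cm <= 0:
            raise ValidationError(f"chromosome {self.name}: lengths must be positive")


def default_chromosomes() -> tuple[ChromosomeSpec, ...]:
    """A rice-like genome: 12 chromosomes, 30 Mb / 125 cM each."""
    return tuple(
        ChromosomeSpec(f"chr{i}", 30_000_000, 125.0) for i in range(1, 13)
    )


@dataclass(frozen=True)
class Site:
    """A segregating site definition (pre-sequencing ground truth)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    cm: float  # genetic position within its chromosome
    zygosity: str  # "het" (heterozygous in the parent) or "hom" (fixed)
    is_causal: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs.

    Defaults emulate the study design this simulator is matched to: bulks
    of 30 + 30 selfed M5 plants at mean depths 18.06x / 20.90x, one
    recessive causal C->T site, a 90% transition-biased EMS spectrum, an
    order-of-magnitude background load of 2,000 heterozygous plus 100 fixed
    mutations, and no sequencing error.
    """

    chromosomes: tuple[ChromosomeSpec, ...] = field(default_factory=default_chromosomes)
    n_background: int = 2000
    n_fixed: int = 100
    transition_fraction: float = 0.9
    causal_chrom: str = "chr1"
    causal_pos: int = 2_771_134
    design: BulkDesign = field(default_factory=BulkDesign)
    error_rate: float = 0.0
    misphenotyping_rate: float = 0.0
    n_progeny: int = 240
    linkage: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.n_fixed < 0:
            raise ConfigurationError("mutation counts must be >= 0")
        for name, rate in (
            ("transition_fraction", self.transition_fraction),
            ("error_rate", self.error_rate),
            ("misphenotyping_rate", self.misphenotyping_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        chrom = self._chrom_map().get(self.causal_chrom)
        if chrom is None:
            raise ConfigurationError(
                f"causal chromosome {self.causal_chrom!r} is not declared"
            )
        if not 1 <= self.causal_pos <= chrom.length_bp:
            raise ConfigurationError("causal position lies outside its chromosome")
        if self.n_progeny < self.design.n_wt + self.design.n_mut:
            raise ConfigurationError(
                "n_progeny must be at least the summed bulk sizes"
            )

    def _chrom_map(self) -> dict[str, ChromosomeSpec]:
        return {c.name: c for c in self.chromosomes}

    def genetic_position(self, chrom: str, pos: int) -> float:
        """cM position, linear in physical position within the chromosome."""
        spec = self._chrom_map()[chrom]
        return pos / spec.length_bp * spec.length_cm


def load_config(path: str | Path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "chromosomes" in kwargs:
        kwargs["chromosomes"] = tuple(
            ChromosomeSpec(c["name"], int(c["length_bp"]), float(c["length_cm"]))
            for c in kwargs["chromosomes"]
        )
    if "design" in kwargs:
        kwargs["design"] = BulkDesign(**kwargs["design"])
    try:
        return SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def generate_variants(
    config: SimulationConfig, rng: np.random.Generator
) -> list[Site]:
    """Place the causal site plus background mutations on the genome.

    Background sites are uniform over the genome without collisions; each
    ref/alt pair is a transition (C->T or G->A) with probability
    ``transition_fraction``, otherwise a random transversion.  The causal
    site is always C->T.  Sites are returned sorted by genome coordinate.
    """
    chroms = config.chromosomes
    genome_bp = sum(c.length_bp for c in chroms)
    n_sites = config.n_background + config.n_fixed
    if n_sites >= genome_bp:
        raise ConfigurationError(
            f"cannot place {n_sites} mutations on a {genome_bp} bp genome"
        )

    taken = {(config.causal_chrom, config.causal_pos)}
    weights = np.array([c.length_bp for c in chroms], dtype=float)
    weights /= weights.sum()

    placed: list[tuple[str, int]] = []
    while len(placed) < n_sites:
        need = n_sites - len(placed)
        chrom_idx = rng.choice(len(chroms), size=need, p=weights)
        for ci in chrom_idx:
            spec = chroms[ci]
            pos = int(rng.integers(1, spec.length_bp + 1))
            if (spec.name, pos) in taken:
                continue
            taken.add((spec.name, pos))
            placed.append((spec.name, pos))

    zygosities = ["het"] * config.n_background + ["hom"] * config.n_fixed
    sites = [
        Site(
            chrom=config.causal_chrom,
            pos=config.causal_pos,
            ref="C",
            alt="T",
            cm=config.genetic_position(config.causal_chrom, config.causal_pos),
            zygosity="het",
            is_causal=True,
        )
    ]
    for (chrom, pos), zyg in zip(placed, zygosities):
        if rng.random() < config.transition_fraction:
            ref, alt = _TRANSITIONS[rng.integers(2)]
        else:
            ref, alt = _TRANSVERSIONS[rng.integers(len(_TRANSVERSIONS))]
        sites.append(
            Site(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                cm=config.genetic_position(chrom, pos),
                zygosity=zyg,
                is_causal=False,
            )
        )
    order = {c.name: i for i, c in enumerate(chroms)}
    sites.sort(key=lambda s: (order[s.chrom], s.pos))
    return sites


@dataclass(frozen=True)
class ProgenyPopulation:
    """Genotypes and phenotypes of a selfed progeny cohort.

    ``genotypes`` has shape (n_progeny, n_sites): copies of the mutant
    allele per plant and site, column order matching ``sites``.
    ``is_mutant`` marks the recorded phenotype (True = mutant), including
    any misphenotyping flips.
    """

    sites: tuple[Site, ...]
    genotypes: np.ndarray
    is_mutant: np.ndarray


def _gamete_states(cm: np.ndarray, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Markov crossover walk: True where the gamete carries the mutant homolog."""
    k = cm.size
    r = haldane_r(np.diff(cm))
    flips = np.empty((n_gametes, k), dtype=bool)
    flips[:, 0] = rng.random(n_gametes) < 0.5
    if k > 1:
        flips[:, 1:] = rng.random((n_gametes, k - 1)) < r
    return np.logical_xor.accumulate(flips, axis=1)


def self_progeny(
    sites: Sequence[Site],
    n_progeny: int,
    rng: np.random.Generator,
    *,
    misphenotyping_rate: float = 0.0,
    linkage: bool = True,
) -> ProgenyPopulation:
    """Self the heterozygous parent and genotype/phenotype the progeny.

    Each plant gets two independent gametes.  Fixed ("hom") sites always
    transmit the mutant allele; heterozygous sites segregate with Haldane
    recombination along each chromosome (or independently if
    ``linkage=False``).  Phenotype is recessive on the causal genotype and
    then flipped with ``misphenotyping_rate``.
    """
    sites = tuple(sites)
    causal_cols = [i for i, s in enumerate(sites) if s.is_causal]
    if len(causal_cols) != 1:
        raise SimulationError(f"expected exactly one causal site, got {len(causal_cols)}")
    m = len(sites)
    genotypes = np.zeros((n_progeny, m), dtype=np.int8)

    hom_cols = [i for i, s in enumerate(sites) if s.zygosity == "hom"]
    genotypes[:, hom_cols] = 2

    het_cols = np.array([i for i, s in enumerate(sites) if s.zygosity == "het"], dtype=int)
    if het_cols.size:
        if linkage:
            # per chromosome, in declared site order (already genome-sorted)
            chrom_of = np.array([sites[i].chrom for i in het_cols])
            for chrom in dict.fromkeys(chrom_of):
                cols = het_cols[chrom_of == chrom]
                cm = np.array([sites[i].cm for i in cols], dtype=float)
                states = _gamete_states(cm, 2 * n_progeny, rng)
                genotypes[:, cols] = (
                    states[:n_progeny].astype(np.int8) + states[n_progeny:].astype(np.int8)
                )
        else:
            genotypes[:, het_cols] = rng.binomial(2, 0.5, size=(n_progeny, het_cols.size))

    is_mutant = genotypes[:, causal_cols[0]] == 2
    if misphenotyping_rate > 0.0:
        flips = rng.random(n_progeny) < misphenotyping_rate
        is_mutant = np.logical_xor(is_mutant, flips)
    return ProgenyPopulation(sites=sites, genotypes=genotypes, is_mutant=is_mutant)


def build_bulks(
    progeny: ProgenyPopulation,
    design: BulkDesign,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the two phenotype bulks and pool their alleles.

    Selects ``n_wt`` wild-type-phenotype and ``n_mut`` mutant plants
    uniformly without replacement; the bulk allele frequency at a site is
    the summed genotype over selected plants divided by twice the bulk
    size (equal-proportion DNA pooling).  Returns (wt_freqs, mut_freqs).
    """
    wt_pool = np.flatnonzero(~progeny.is_mutant)
    mut_pool = np.flatnonzero(progeny.is_mutant)
    if wt_pool.size < design.n_wt or mut_pool.size < design.n_mut:
        raise SimulationError(
            f"need {design.n_wt} wild-type-phenotype and {design.n_mut} mutant "
            f"plants but have {wt_pool.size} and {mut_pool.size}; "
            "increase n_progeny"
        )
    wt_sel = rng.choice(wt_pool, size=design.n_wt, replace=False)
    mut_sel = rng.choice(mut_pool, size=design.n_mut, replace=False)
    wt_freqs = progeny.genotypes[wt_sel].sum(axis=0) / (2 * design.n_wt)
    mut_freqs = progeny.genotypes[mut_sel].sum(axis=0) / (2 * design.n_mut)
    return wt_freqs, mut_freqs


def sample_depths(
    sites: Sequence[Site],
    wt_freqs: np.ndarray,
    mut_freqs: np.ndarray,
    design: BulkDesign,
    error_rate: float,
    rng: np.random.Generator,
) -> list[VariantCall]:
    """Simulate pooled sequencing of both bulks at every site.

    Per site and bulk, total depth is Poisson at the bulk's mean coverage;
    mutant-read depth is binomial at probability f(1-e) + (1-f)e, where f
    is the bulk allele frequency and e the per-read miscall rate.
    Zero-depth outcomes are kept (they exercise the undefined-index path).
    """
    sites = tuple(sites)
    out: list[VariantCall] = []
    for bulk_freqs in (wt_freqs, mut_freqs):
        if np.any((np.asarray(bulk_freqs) < 0) | (np.asarray(bulk_freqs) > 1)):
            raise ValidationError("bulk allele frequencies must lie in [0, 1]")
    wt_tot = rng.poisson(design.mean_depth_wt, len(sites))
    wt_alt = rng.binomial(wt_tot, wt_freqs * (1 - error_rate) + (1 - wt_freqs) * error_rate)
    mut_tot = rng.poisson(design.mean_depth_mut, len(sites))
    mut_alt = rng.binomial(mut_tot, mut_freqs * (1 - error_rate) + (1 - mut_freqs) * error_rate)
    for i, s in enumerate(sites):
        out.append(
            VariantCall(
                chrom=s.chrom,
                pos=s.pos,
                ref=s.ref,
                alt=s.alt,
                depths={
                    design.wt_bulk_id: AlleleDepth(int(wt_alt[i]), int(wt_tot[i])),
                    design.mut_bulk_id: AlleleDepth(int(mut_alt[i]), int(mut_tot[i])),
                },
            )
        )
    return out


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated experiment, for downstream evaluation."""

    causal_chrom: str
    causal_pos: int
    sites: tuple[Site, ...]
    wt_freqs: np.ndarray
    mut_freqs: np.ndarray

    def site_class(self, chrom: str, pos: int, linked_window_cm: float = 10.0) -> str:
        """Classify a site: causal / fixed / linked / unlinked.

        "linked" means a heterozygous background site on the causal
        chromosome within ``linked_window_cm`` of the causal site.
        """
        site = next(s for s in self.sites if s.chrom == chrom and s.pos == pos)
        if site.is_causal:
            return "causal"
        if site.zygosity == "hom":
            return "fixed"
        causal = next(s for s in self.sites if s.is_causal)
        if site.chrom == causal.chrom and abs(site.cm - causal.cm) <= linked_window_cm:
            return "linked"
        return "unlinked"

    def to_dict(self, include_freqs: bool = False) -> dict:
        d = {
            "causal": {"chrom": self.causal_chrom, "pos": self.causal_pos},
            "sites": [
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref,
                    "alt": s.alt,
                    "cm": s.cm,
                    "zygosity": s.zygosity,
                    "is_causal": s.is_causal,
                }
                for s in self.sites
            ],
        }
        if include_freqs:
            d["wt_freqs"] = self.wt_freqs.tolist()
            d["mut_freqs"] = self.mut_freqs.tolist()
        return d

    def to_json(self, include_freqs: bool = False, **kwargs) -> str:
        return json.dumps(self.to_dict(include_freqs), **kwargs)


def simulate_experiment(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantCall], SimTruth]:
    """Run the full generator: sites -> progeny -> bulks -> read depths.

    Deterministic given ``config.seed`` (or the supplied ``rng``).  Returns
    the simulated variant table and the ground truth naming the causal site.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites = generate_variants(config, rng)
    progeny = self_progeny(
        sites,
        config.n_progeny,
        rng,
        misphenotyping_rate=config.misphenotyping_rate,
        linkage=config.linkage,
    )
    wt_freqs, mut_freqs = build_bulks(progeny, config.design, rng)
    variants = sample_depths(
        sites, wt_freqs, mut_freqs, config.design, config.error_rate, rng
    )
    truth = SimTruth(
        causal_chrom=config.causal_chrom,
        causal_pos=config.causal_pos,
        sites=tuple(sites),
        wt_freqs=wt_freqs,
        mut_freqs=mut_freqs,
    )
    return variants, truth
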