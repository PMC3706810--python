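"""Mutant genomes, crossing schemes, pools and foreground-genome accounting.

A mutagenized founder carries a configurable number of randomly placed
homozygous mutations, one of which is causal.  Mapping populations are bred
from it under two schemes:

* **outcross** — founder x diverged accession, then selfing of the F1 to give
  an F2 in which natural polymorphisms (the marker map) segregate;
* **backcross** — one to three successive crosses of a causal-allele carrier
  to the isogenic, non-mutagenized parent, then one selfing to give a
  BC_nF2 in which only the induced mutations segregate.

Because the founder is homozygous for every mutation and the partner carries
none, an individual's genotype at any mutation is exactly the number of its
homologs with founder origin at that position — genotypes are derived from
segment origins rather than tracked separately, so the two can never drift
apart.

Phenotyping is deterministic: an individual is mutant iff it is homozygous
for the causal mutation.  Pools may deliberately include mis-scored plants,
drawn from the phenotypically wild-type fraction of the same population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .landscape import GenomeSpec
from .meiosis import FOUNDER, PARTNER, Haplotype, MeiosisModel, sample_gamete

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSet:
    """Homozygous induced mutations of the founder; exactly one is causal."""

    chroms: tuple[str, ...]
    positions: tuple[int, ...]
    causal_index: int

    def __post_init__(self):
        if len(self.chroms) != len(self.positions) or not self.positions:
            raise ValidationError("mutation chroms/positions misaligned or empty")
        if len(set(zip(self.chroms, self.positions))) != len(self.positions):
            raise ValidationError("mutation positions must be unique")
        if not 0 <= self.causal_index < len(self.positions):
            raise ValidationError("causal_index out of range")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def causal(self) -> tuple[str, int]:
        return self.chroms[self.causal_index], self.positions[self.causal_index]

    def on_chrom(self, chrom: str) -> np.ndarray:
        return np.asarray(
            [p for c, p in zip(self.chroms, self.positions) if c == chrom],
            np.int64)


@dataclass
class RecombinantGenome:
    """A diploid individual: two haplotypes over a shared genome."""

    genome: GenomeSpec
    haplotypes: tuple[Haplotype, Haplotype]

    @classmethod
    def founder_mutant(cls, genome: GenomeSpec) -> "RecombinantGenome":
        return cls(genome, (Haplotype.uniform(genome, FOUNDER),
                            Haplotype.uniform(genome, FOUNDER)))

    @classmethod
    def nonmutant_parent(cls, genome: GenomeSpec) -> "RecombinantGenome":
        """The crossing partner (diverged accession or isogenic progenitor)."""
        return cls(genome, (Haplotype.uniform(genome, PARTNER),
                            Haplotype.uniform(genome, PARTNER)))

    def genotype(self, chrom: str, pos) -> np.ndarray | int:
        """Copies of the mutant-parent (founder) allele at position(s)."""
        h1, h2 = self.haplotypes
        a1 = h1.origin_at(chrom, pos)
        a2 = h2.origin_at(chrom, pos)
        return (np.asarray(a1) == FOUNDER).astype(np.int64) + \
               (np.asarray(a2) == FOUNDER).astype(np.int64)

    def foreground_fraction(self) -> float:
        """Base-pair fraction of the diploid genome with founder origin."""
        total = fg = 0
        for chrom, length in self.genome.chromosomes:
            for hap in self.haplotypes:
                a, _ = hap.origin_lengths(chrom, length)
                fg += a
                total += length
        return fg / total


@dataclass
class Pool:
    """A phenotypically selected (possibly contaminated) mutant pool."""

    individuals: list[RecombinantGenome]
    mutations: MutationSet
    scheme: str
    generation: str
    misscored_count: int = 0

    def __post_init__(self):
        if not self.individuals:
            raise ValidationError("pool must contain at least one individual")

    @property
    def size(self) -> int:
        return len(self.individuals)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def mutagenize(spec: GenomeSpec, n_mutations: int,
               rng: np.random.Generator) -> MutationSet:
    """Place ``n_mutations`` unique positions uniformly over the genome.

    Chromosomes are chosen length-weighted, positions uniformly within; one
    mutation is selected uniformly at random as causal.
    """
    if n_mutations < 1:
        raise ValidationError("n_mutations must be >= 1")
    if n_mutations > spec.total_length:
        raise ValidationError("more mutations than base pairs in the genome")
    names = spec.names
    lengths = np.array([spec.length_of(c) for c in names], float)
    probs = lengths / lengths.sum()
    seen: set[tuple[str, int]] = set()
    chroms: list[str] = []
    positions: list[int] = []
    while len(seen) < n_mutations:
        k = n_mutations - len(seen)
        idx = rng.choice(len(names), size=k, p=probs)
        pos = (rng.random(k) * lengths[idx]).astype(np.int64) + 1
        for i, p in zip(idx, pos):
            key = (names[i], int(p))
            if key not in seen:
                seen.add(key)
                chroms.append(key[0])
                positions.append(key[1])
    causal = int(rng.integers(n_mutations))
    return MutationSet(tuple(chroms), tuple(positions), causal)


def phenotype(ind: RecombinantGenome, mutations: MutationSet) -> str:
    """``"mutant"`` iff the individual is homozygous for the causal mutation."""
    chrom, pos = mutations.causal
    return "mutant" if int(ind.genotype(chrom, pos)) == 2 else "wildtype"


def _self(parent: RecombinantGenome, model: MeiosisModel,
          rng: np.random.Generator) -> RecombinantGenome:
    return RecombinantGenome(parent.genome, (sample_gamete(parent, model, rng),
                                             sample_gamete(parent, model, rng)))


def _cross(mother: RecombinantGenome, father: RecombinantGenome,
           model: MeiosisModel, rng: np.random.Generator) -> RecombinantGenome:
    return RecombinantGenome(mother.genome, (sample_gamete(mother, model, rng),
                                             sample_gamete(father, model, rng)))


def _backcross_lineage_parent(model: MeiosisModel, mutations: MutationSet,
                              backcross_rounds: int, rng: np.random.Generator,
                              carrier_parent: bool = True,
                              max_tries: int = 200) -> RecombinantGenome:
    """Breed one BC_n individual to be selfed into an F2 population.

    With ``carrier_parent`` (default) the individual carried into each
    backcross round must be heterozygous for the causal mutation, so that the
    final F2 segregates mutants.  With ``carrier_parent=False`` a random
    individual is carried forward regardless of its causal genotype
    (the unconditioned lineage whose expected foreground fraction follows the
    1/2^(n+1) backcross theory exactly).
    """
    genome = model.genome
    recurrent = RecombinantGenome.nonmutant_parent(genome)
    current = _cross(RecombinantGenome.founder_mutant(genome), recurrent,
                     model, rng)  # F1, always a carrier
    chrom, pos = mutations.causal
    for _ in range(backcross_rounds):
        for _ in range(max_tries):
            cand = _cross(current, recurrent, model, rng)
            if not carrier_parent or int(cand.genotype(chrom, pos)) >= 1:
                break
        else:
            raise ValidationError(
                "could not obtain a causal-allele carrier; is the landscape sane?")
        current = cand
    return current


def breed_population(scheme: str,
                     pop_size: int,
                     model: MeiosisModel,
                     mutations: MutationSet,
                     rng: np.random.Generator,
                     backcross_rounds: int = 1,
                     n_parent_siblings: int = 1,
                     carrier_parent: bool = True) -> list[RecombinantGenome]:
    """Breed an F2 mapping population under the given crossing scheme.

    outcross
        founder x diverged accession, self the F1; causal genotypes segregate
        1:2:1.
    backcross
        ``backcross_rounds`` successive crosses of a carrier to the isogenic
        parent, then selfing of the final BC individual.  With
        ``n_parent_siblings > 1`` that many independent lineages each
        contribute an equal share of the population (remainder round-robin).
    """
    if pop_size < 1:
        raise ValidationError("pop_size must be >= 1")
    if scheme == "outcross":
        f1 = _cross(RecombinantGenome.founder_mutant(model.genome),
                    RecombinantGenome.nonmutant_parent(model.genome),
                    model, rng)
        return [_self(f1, model, rng) for _ in range(pop_size)]
    if scheme != "backcross":
        raise ValidationError(f"unknown scheme {scheme!r}")
    if backcross_rounds < 1:
        raise ValidationError("backcross_rounds must be >= 1 for the backcross scheme")
    if n_parent_siblings < 1:
        raise ValidationError("n_parent_siblings must be >= 1")
    shares = [pop_size // n_parent_siblings] * n_parent_siblings
    for i in range(pop_size % n_parent_siblings):
        shares[i] += 1
    population: list[RecombinantGenome] = []
    for share in shares:
        if share == 0:
            continue
        bc = _backcross_lineage_parent(model, mutations, backcross_rounds, rng,
                                       carrier_parent=carrier_parent)
        population.extend(_self(bc, model, rng) for _ in range(share))
    return population


def select_pool(population: list[RecombinantGenome],
                mutations: MutationSet,
                n_mutants: int,
                misscore_rate: float,
                rng: np.random.Generator,
                scheme: str = "outcross",
                generation: str = "F2") -> Pool:
    """Assemble a pool of ``n_mutants`` plants scored as mutant.

    ``round(misscore_rate * n_mutants)`` of them are mis-scored: phenotypically
    wild-type siblings (a natural mixture of heterozygotes and homozygous
    wild-type) substituted into the pool.
    """
    if not 0 <= misscore_rate < 1:
        raise ValidationError("misscore_rate must be in [0, 1)")
    n_mis = int(round(misscore_rate * n_mutants))
    n_true = n_mutants - n_mis
    mutants, wildtypes = [], []
    for ind in population:
        (mutants if phenotype(ind, mutations) == "mutant" else wildtypes).append(ind)
    if len(mutants) < n_true or len(wildtypes) < n_mis:
        raise ValidationError(
            f"population has {len(mutants)} mutants / {len(wildtypes)} wild-types; "
            f"need {n_true} + {n_mis} — increase pop_size")
    chosen = [mutants[i] for i in rng.choice(len(mutants), n_true, replace=False)]
    chosen += [wildtypes[i] for i in rng.choice(len(wildtypes), n_mis, replace=False)]
    return Pool(individuals=chosen, mutations=mutations, scheme=scheme,
                generation=generation, misscored_count=n_mis)


def breed_pool(scheme: str,
               n_mutants: int,
               model: MeiosisModel,
               mutations: MutationSet,
               rng: np.random.Generator,
               misscore_rate: float = 0.0,
               backcross_rounds: int = 1,
               n_parent_siblings: int = 1,
               mutant_fraction: float = 0.25,
               safety: float = 1.4) -> Pool:
    """Breed a population just large enough and select a pool from it.

    Sizes the F2 population for the expected 1/4 mutant fraction with a
    safety margin, growing it on the rare occasions selection still falls
    short.
    """
    pop_size = max(int(np.ceil(n_mutants / mutant_fraction * safety)), n_mutants + 8)
    population = breed_population(scheme, pop_size, model, mutations, rng,
                                  backcross_rounds=backcross_rounds,
                                  n_parent_siblings=n_parent_siblings)
    for _ in range(6):
        try:
            generation = "F2" if scheme == "outcross" else f"BC{backcross_rounds}F2"
            return select_pool(population, mutations, n_mutants, misscore_rate,
                               rng, scheme=scheme, generation=generation)
        except ValidationError:
            extra = breed_population(scheme, pop_size // 2 + 8, model, mutations,
                                     rng, backcross_rounds=backcross_rounds,
                                     n_parent_siblings=n_parent_siblings)
            population = population + extra
    raise ValidationError("could not assemble pool after repeated breeding")


def foreground_fraction(ind: RecombinantGenome) -> float:
    """Base-pair fraction of an individual's genome of founder origin."""
    return ind.foreground_fraction()


def write_genome_dump(ind: RecombinantGenome, mutations: MutationSet, path) -> None:
    """Dump per-homolog segments and mutation genotypes as a TSV (debugging
    aid and input for the direct-sequencing mode)."""
    with open(path, "w") as fh:
        fh.write("record\tchrom\tstart\tend\torigin\n")
        for h, hap in enumerate(ind.haplotypes, start=1):
            for chrom, length in ind.genome.chromosomes:
                for start, end, origin in hap.segments(chrom, length):
                    label = "A" if origin == FOUNDER else "B"
                    fh.write(f"hap{h}\t{chrom}\t{start}\t{end}\t{label}\n")
        for chrom, pos in zip(mutations.chroms, mutations.positions):
            g = int(ind.genotype(chrom, pos))
            fh.write(f"genotype\t{chrom}\t{pos}\t{pos}\t{g}\n")
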