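"""Pooled sequencing at marker and mutation loci.

Sequencing a pool is simulated in two stages.  Coverage: the total number of
reads ``m`` is distributed over the ``k`` sequenced loci by one multinomial
draw with the normalized per-locus coverage weights ``n_i`` as probabilities
(so GC and mapping biases enter through the weight landscape, and coverages
sum to ``m`` exactly).  Alleles: each locus's ``c_i`` reads are split between
mutant-parent allele, other-parent allele and sequencing error by a trinomial
with probabilities ``(a1*(1-s), a2*(1-s), s)``, where ``a1``/``a2`` are the
true allele frequencies in the pool and ``s`` the per-read error rate
(default 0.3%).  Error reads are then re-assigned to one of the two parental
alleles, by default with probability 1/2 each (``error_mode="split"``); the
alternative ``"flip"`` assigns every error read to the opposite allele.

Whole-genome mode sequences every locus; target-enrichment mode restricts
reads to loci flagged as enriched and leaves the rest at zero coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .landscape import MarkerMap
from .pedigree import MutationSet, Pool

logger = logging.getLogger(__name__)

DEFAULT_ERROR_RATE = 0.003


@dataclass
class SeqParams:
    """Sequencing-run parameters.

    Exactly one of ``coverage`` (target mean reads per sequenced locus) or
    ``total_reads`` must be given; ``coverage`` is converted as
    ``m = round(coverage * number of sequenced loci)``.
    """

    error_rate: float = DEFAULT_ERROR_RATE
    coverage: float | None = None
    total_reads: int | None = None
    mode: str = "wgs"                # "wgs" | "enrichment"
    error_mode: str = "split"        # "split" | "flip"

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValidationError("error_rate must be in [0, 1)")
        if (self.coverage is None) == (self.total_reads is None):
            raise ValidationError("give exactly one of coverage or total_reads")
        if self.mode not in ("wgs", "enrichment"):
            raise ValidationError(f"unknown sequencing mode {self.mode!r}")
        if self.error_mode not in ("split", "flip"):
            raise ValidationError(f"unknown error_mode {self.error_mode!r}")

    def reads_for(self, n_loci: int) -> int:
        if self.total_reads is not None:
            return int(self.total_reads)
        return int(round(self.coverage * n_loci))


@dataclass
class PoolCounts:
    """Per-locus read counts from one sequencing simulation.

    ``df`` columns: ``chrom``, ``pos``, ``cov``, ``count_mut``, ``count_wt``,
    ``is_mutation`` (True at induced-mutation loci, False at natural
    markers).  ``count_mut + count_wt == cov`` per locus and coverages sum to
    the realized total read count ``m`` over sequenced loci.
    """

    df: pd.DataFrame
    m: int
    mode: str = "wgs"

    def __post_init__(self):
        counts = self.df["count_mut"] + self.df["count_wt"]
        if not (counts == self.df["cov"]).all():
            raise ValidationError("allele counts do not sum to coverage")
        if int(self.df["cov"].sum()) != self.m:
            raise ValidationError("coverages do not sum to total reads")

    def at_mutations(self) -> pd.DataFrame:
        return self.df[self.df["is_mutation"]]

    def at_markers(self) -> pd.DataFrame:
        return self.df[~self.df["is_mutation"]]


def assign_coverage(weights: np.ndarray, m: int,
                    rng: np.random.Generator) -> np.ndarray:
    """One multinomial draw of per-locus coverages summing exactly to ``m``."""
    w = np.asarray(weights, float)
    if m < 0:
        raise ValidationError("total reads must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValidationError("all coverage weights are zero")
    return rng.multinomial(m, w / total)


def true_allele_frequencies(pool: Pool, loci: pd.DataFrame) -> np.ndarray:
    """Mutant-parent allele frequency ``a1`` at each locus.

    ``a1`` is the count of founder-origin homologs at the locus over the
    ``2 * pool size`` chromosomes in the pool; ``a2 = 1 - a1``.
    """
    n = pool.size
    total = np.zeros(len(loci), np.int64)
    for chrom, sub in loci.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        idx = sub.index.to_numpy()
        acc = np.zeros(len(pos), np.int64)
        for ind in pool.individuals:
            acc += ind.genotype(chrom, pos)
        total[loci.index.get_indexer(idx)] = acc
    return total / (2.0 * n)


def sample_allele_counts(cov: np.ndarray, a1: np.ndarray, error_rate: float,
                         rng: np.random.Generator,
                         error_mode: str = "split"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Split per-locus coverages into (mutant, other) allele read counts.

    Equivalent to a trinomial draw with probabilities
    ``(a1*(1-s), (1-a1)*(1-s), s)`` followed by re-assignment of the error
    category: half/half under ``"split"``, all-to-the-other-allele under
    ``"flip"``.
    """
    cov = np.asarray(cov)
    a1 = np.broadcast_to(np.asarray(a1, float), cov.shape)
    err = rng.binomial(cov, error_rate)
    good = cov - err
    mut = rng.binomial(good, a1)
    if error_mode == "split":
        err_mut = rng.binomial(err, 0.5)
    elif error_mode == "flip":
        # an error read reports the allele the sampled chromosome does not carry
        err_mut = rng.binomial(err, 1.0 - a1)
    else:
        raise ValidationError(f"unknown error_mode {error_mode!r}")
    count_mut = mut + err_mut
    return count_mut, cov - count_mut


def sequence_pool(pool: Pool, markers: MarkerMap | None,
                  params: SeqParams, rng: np.random.Generator) -> PoolCounts:
    """Simulate sequencing of a pool at marker and mutation loci.

    Mutation loci not present in the marker map receive the genome-average
    coverage weight 1.  In enrichment mode only loci flagged ``enriched``
    (markers) are sequenced; everything else gets zero coverage.
    """
    mutations = pool.mutations
    mut_df = pd.DataFrame({
        "chrom": list(mutations.chroms),
        "pos": list(mutations.positions),
        "norm_weight": 1.0,
        "enriched": False,
        "is_mutation": True,
    })
    if markers is not None:
        loci = markers.df[["chrom", "pos", "norm_weight", "enriched"]].copy()
        loci["is_mutation"] = False
        key = set(zip(loci["chrom"], loci["pos"]))
        dup = [(c, p) in key for c, p in zip(mut_df["chrom"], mut_df["pos"])]
        mut_df = mut_df[~np.asarray(dup)]
        loci = pd.concat([loci, mut_df], ignore_index=True)
    else:
        loci = mut_df

    if params.mode == "enrichment":
        sequenced = loci["enriched"].to_numpy()
        if not sequenced.any():
            raise ValidationError("enrichment mode but no loci flagged enriched")
    else:
        sequenced = np.ones(len(loci), bool)

    m = params.reads_for(int(sequenced.sum()))
    cov = np.zeros(len(loci), np.int64)
    cov[sequenced] = assign_coverage(
        loci.loc[sequenced, "norm_weight"].to_numpy(), m, rng)
    a1 = true_allele_frequencies(pool, loci)
    count_mut, count_wt = sample_allele_counts(cov, a1, params.error_rate, rng,
                                               params.error_mode)
    df = pd.DataFrame({
        "chrom": loci["chrom"], "pos": loci["pos"], "cov": cov,
        "count_mut": count_mut, "count_wt": count_wt,
        "is_mutation": loci["is_mutation"],
    })
    return PoolCounts(df=df, m=int(cov.sum()), mode=params.mode)


# ---------------------------------------------------------------------------
# Interchange formats
# ---------------------------------------------------------------------------

def write_pool_counts(counts: PoolCounts, path) -> None:
    df = counts.df.copy()
    df["is_mutation"] = df["is_mutation"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_pool_counts(path) -> PoolCounts:
    df = pd.read_csv(path, sep="\t")
    df["is_mutation"] = df["is_mutation"].astype(bool)
    return PoolCounts(df=df, m=int(df["cov"].sum()))


def write_vcf_like(counts: PoolCounts, path) -> None:
    """Minimal VCF-style export (allele depths in the AD field)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool\n")
        for row in counts.df.itertuples():
            fh.write(f"{row.chrom}\t{row.pos}\t.\tN\tN\t.\tPASS\t.\tAD\t"
                     f"{row.count_wt},{row.count_mut}\n")
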