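# popseqsim

Forward simulation of **mapping-by-sequencing** experiments — bulk segregant
analysis by whole-genome (or target-enriched) sequencing of pooled mutant
recombinants — for planning forward-genetic screens in plants.

Mapping-by-sequencing crosses a mutagenized mutant either to a diverged
accession (**outcross**, F2) or back to its isogenic progenitor
(**backcross**, BC<sub>n</sub>F2), pools phenotypically mutant F2 plants, and
sequences the pool. Phenotypic selection fixes the causal mutation and its
linked neighborhood, so local skews in parental allele frequencies reveal the
causal locus. How many recombinants to pool, how deep to sequence, how many
backcross rounds to do, and whether to sequence single- or paired-end are
design questions that are expensive to answer experimentally — and cheap to
answer by simulation. `popseqsim` answers them for configurable genomes and
recombination landscapes.

## Model

* **Meiosis.** Crossovers per chromosome per meiosis follow a trinomial
  none/one/two-or-more count model, X ~ Trinomial(n, [p₁, p₂, p₃]); the
  "two or more" category resolves to 2 + Geometric extras. A crossover lands
  between adjacent markers with probability p_mᵢ and uniformly within the
  interval, i.e. with per-bp density p_mᵢ/lᵢ. Additional crossovers are
  spaced by a gamma(shape, scale) distribution in genetic-distance
  coordinates, modelling crossover interference.
* **Mutagenesis and breeding.** The founder carries 700 or 1,400 uniformly
  placed homozygous mutations, one causal; plants are mutant iff homozygous
  for it. Outcross, 1–3-round backcross (optionally from multiple sibling
  lineages), mis-scored (phenotypically wild-type) plants, and
  direct sequencing of single genomes are supported.
* **Sequencing.** Per-locus coverage is one multinomial draw,
  cᵢ ~ Multinomial(m, [n₁ … n_k]), over coverage-normalization weights;
  reads split between parental alleles by a trinomial with a 0.3% per-read
  error category, rᵢ ~ Trinomial(cᵢ, [a₁(1−s), a₂(1−s), s]).
* **Analysis.** Backcross pools: a mutation is a homozygous candidate
  mutation (CAM) iff its mutant read frequency exceeds both
  g_f = 1 − (2m+1)/(2n) (pool-composition threshold; m mis-scored of n
  plants) and r_f = 1 − e − 1/c_p (read-sampling threshold at coverage c_p).
  Outcross pools: a sliding-window binomial likelihood-ratio statistic
  against the 0.5 null yields a confidence mapping interval at P = 0.99;
  CAMs are the induced mutations inside it.
* **Read pairing.** The informative fraction of single-end reads vs
  paired-end pairs (insert = 3× read length; a pair counts once) is estimated
  from 100,000 random alignments against a marker set.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
import popseqsim as pq

land, markers = pq.synthesize_landscape(pq.arabidopsis_like(),
                                        markers_per_chrom=1000, seed=7)
model = pq.MeiosisModel(land, markers)
rng = np.random.default_rng(7)

muts = pq.mutagenize(model.genome, 1400, rng)          # founder mutant
pool = pq.breed_pool("outcross", 100, model, muts, rng)  # 100 mutant F2s
counts = pq.sequence_pool(pool, markers, pq.SeqParams(coverage=25), rng)
res = pq.analyze_outcross(counts, muts, pool_size=pool.size)
print(res.chrom, res.start, res.end, res.length, res.cam_count)
```

Output (seed 7):

```
interval  : Chr2:4,571,507-8,083,388  (3.51 Mb)
peak      : Chr2:6,497,481
CAMs      : 50
causal    : Chr2:6,547,841  inside: True
```

The 99% mapping interval on Chr2 spans 3.5 Mb, contains 50 of the 1,400
induced mutations (the candidate set to inspect), and does contain the causal
mutation. The same pool analysed as a backcross (30 plants, 25x, thresholds
g_f/r_f) yields 15 homozygous CAMs including the causal one.

From the shell, the `popseq` tool exposes the same machinery:

```sh
popseq synth-landscape --preset arabidopsis --out-dir land/
popseq sweep --config sweep.yaml --seed 7 --out-dir results/
popseq readsim --preset arabidopsis --read-lengths 100,250
```

`sweep` grids pool size × coverage with hundreds of replicates per cell and
writes summary/replicate TSVs (mean ± SD interval length or CAM count, and
the fraction of replicates whose interval contains the causal mutation).

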