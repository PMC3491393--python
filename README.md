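# tfbsload

Quantifying how population-level DNA sequence variation impinges on
transcription factor binding sites (TFBSs), and how much of that
variation is functionally "buffered".

Regulatory mutations are common — isogenic fly panels segregate SNPs at
roughly 3% of bases, human cohorts at ~0.25% — yet most bound motifs
keep working. This package implements an analysis toolkit for asking,
from reference sequences, ChIP-defined bound regions, position weight
matrices (PWMs) and per-sample genotypes:

* which motif positions are constrained within a population
  (position-wise diversity vs scrambled-motif nulls),
* how deleterious the observed variation is per binding site
  (the **mutational load** statistic),
* how individual variation relates to cross-species conservation
  (**branch length scores** over multiple alignments and a phylogeny),
* and whether binding signal is maintained despite score-reducing
  mutations (per-individual ChIP **buffering** analysis and
  conservation × mutation interaction models).

It is aimed at regulatory-genomics researchers working with
population variation panels (DGRP-style isogenic lines or diploid
cohorts) intersected with TF ChIP data.

## The core statistic

For a motif instance with major-allele PWM score `w0` and observed
alleles with scores `w_i` at frequencies `p_i`, the mutational load is

```
L = (w0 − Σ_i w_i · p_i) / w0
```

floored at zero. A monomorphic site has `L = 0`; a site where half the
population carries an allele that destroys the PWM match approaches
`L = 0.5`; score-gaining minor alleles are assigned zero load (only
bound instances enter the analysis, which biases against detecting
sites whose major allele is the weak one). Load is expressed relative
to the **major** allele, not the best-scoring one, for the same reason.

Conservation of an instance is its branch length score (BLS): the
fraction of total phylogenetic branch length spanned by species whose
aligned sequence retains a motif match within 50 bp of movement and
within 1 point of score drop. A CTCF-style binding site is "buffered"
when individuals homozygous for the minor variant retain at least
two-thirds of the major variant's (quantile-normalized) ChIP signal.

Because load distributions are strongly zero-inflated, significance
testing uses permutation tests with values shuffled within each TF, and
a trend statistic — the dot product of the mean-centered, unit-L2
normalized data vector with the index vector (1, …, N).

## Worked example

Everything is exercisable on synthetic data with a ground-truth
manifest — no downloads. The `fly` preset plants 80 bound motif
instances in a 100 kb genome and simulates 162 isogenic lines at ~3%
per-base diversity with information-content-proportional constraint at
bound motifs:

```python
import numpy as np
from tfbsload import io_formats as io, synthetic as syn
from tfbsload import variation as var, load_metric as lm
from tfbsload.pwm import scan

syn.simulate("fly", "flydemo", seed=1)
pwm = io.read_pwm("flydemo/motif.pwm")
genome = io.read_fasta("flydemo/genome.fa")
regions = io.read_regions("flydemo/regions.bed")
sites = io.read_variants("flydemo/variants.dgrp.tsv", dialect="dgrp_table")
kept, removed = var.filter_dgrp(sites)

instances = [i for i in scan(pwm, genome, regions=regions) if i.bound]
records = [lm.make_load_record(i, var.alleles_for_instance(i, kept, pwm))
           for i in instances]
loads = np.array([r.load for r in records])
print(len(instances), len(kept), int((loads > 0).sum()),
      lm.trimmed_mean_load(loads))
```

prints `86` bound instances, `2933` variant sites surviving the six
confidence filters, `2` instances with score-reducing variation and a
trimmed-mean load of `2.5e-05`. The same population generated *without*
selection yields 18 of 82 varying instances and a trimmed-mean load of
`9.7e-03` — constraint at bound motifs suppresses both the frequency
and the severity of motif mutations, which is exactly what the load
statistic is built to detect.

On the per-individual ChIP side, the `ctcf` preset generates 500
polymorphic binding sites across 12 individuals with a planted
conservation-dependent buffering term:

```python
from tfbsload import buffering as buf
chip = syn.make_chip_individuals(n_sites=500, seed=1)
table = buf.site_buffering_table(chip.table)
counts, odds, p = buf.buffering_by_conservation(table)
fit = buf.mutation_effect_model(buf.delta_records(chip.table))
```

classifies 372 homozygous polymorphic sites, of which 71% are buffered
overall — 54% at weakly conserved sites (BLS < 0.5) versus 86% at
conserved sites (Fisher p = 7.0e-12) — and the interaction model
recovers the planted negative conservation × mutation coefficient
(−0.87, p = 5.2e-70): conservation dampens the effect of motif
mutations on binding.

A `tfbsload` console script exposes the same steps as subcommands
(`simulate`, `scan`, `filter-variants`, `load`, `bls`, `posdiv`,
`permtest`, `buffering`); every stochastic subcommand takes `--seed`.

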