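# ppiseq

Analysis toolkit for pooled double-barcode protein–protein interaction
(PPI) sequencing screens in *S. cerevisiae*, built around the
split-mDHFR protein-fragment complementation assay: strains carrying a
bait–prey construct pair are tagged with a chromosomal double barcode,
grown in competition under methotrexate selection, and sequenced at
several time points. A reconstituted reporter confers a growth advantage,
so the strength of an interaction is read out as a **relative fitness**
inferred from the barcode's frequency trajectory. Because fitness is a
quantitative, environment-comparable score, the same pool re-grown under
perturbations (FK506, H₂O₂, NaCl, CuSO₄, …) reveals **dynamic PPIs** —
interactions that appear, strengthen or collapse across environments.

The package covers the full computational path, plus a generative
simulator used for validation and as the test-fixture source:

| module | role |
| --- | --- |
| `ppiseq.barcode_io` | FASTQ → validated double-barcode counts (quality + structural regex filters, unique-best Hamming matching, per-sample demultiplexing) |
| `ppiseq.chimera` | PCR-chimera rate estimation and expected-count subtraction |
| `ppiseq.fitness` | global Poisson maximum-likelihood lineage fitness, zeroed on reporter-negative controls |
| `ppiseq.ppi_call` | genotype-pair scoring vs controls, dynamic-PPI tests, OD-AUC and luciferase validation scores |
| `ppiseq.simulate` | generative model of the pooled assay (selection, 1:8 bottlenecks, chimeric PCR, read sampling, synthetic FASTQ) |
| `ppiseq.scale` | pooled-mating complexity and detection-vs-depth calculators |

## Model

Lineage *l* with relative fitness *s<sub>l</sub>* (per generation) has
expected pool frequency

φ<sub>l</sub>(t) = f<sub>l</sub> · exp(s<sub>l</sub>·t − x̄(t)),

where f<sub>l</sub> is its initial frequency and x̄(t) is the cumulative
mean fitness of the pool — the term that makes trajectories of fit
lineages "bend" as their competition stiffens. Reads are modelled as
R<sub>l,t</sub> ~ Poisson(D<sub>t</sub>·φ<sub>l</sub>(t)) at sample depth
D<sub>t</sub>; each lineage's (f<sub>l</sub>, s<sub>l</sub>) maximizes the
Poisson likelihood, and x̄ is solved self-consistently so that
Σ<sub>l</sub> φ<sub>l</sub>(t) = 1 at every time point. Fitness is
reported relative to mDHFR(−) control lineages (mean control fitness ≡ 0),
with a saturated-model-normalized log-likelihood as a per-trajectory
quality flag. Interaction calls are one-sided Welch t-tests of a pair's
~75 fitness estimates (25 barcode pairs × 3 replicates) against the pooled
controls, Bonferroni-corrected ×500; dynamic calls are two-sided tests
against the permissive (DMSO) environment, corrected ×400.

## Worked example

Simulate the experiment-scale pool (2,500 lineages = 100 genotype pairs ×
25 barcode pairs, generations 0/3/6/9/12, ~67 reads/barcode, 0.2%
chimeras), then run the pipeline:

```
$ ppiseq simulate --seed 1 -o demo/
$ ppiseq correct --counts demo/counts.tsv --rate 0.002 -o demo/corrected.tsv
$ ppiseq fit --counts demo/corrected.tsv -o demo/fitness.tsv
$ ppiseq call --fitness demo/fitness.tsv -o demo/ppi
```

`demo/fitness.tsv` adds `Fitness`, `Likelihood` and `Trajectory_used`
columns per lineage; `demo/ppi_scores.tsv` aggregates them per genotype
pair. For this seed the three fittest pairs come back as

```
      Bait    Prey  mean_fitness     sem  p_bonferroni
96  Bait09  Prey07        0.3760  0.0022           0.0
97  Bait09  Prey08        0.3793  0.0023           0.0
98  Bait09  Prey09        0.3849  0.0015           0.0
```

i.e. their per-generation growth advantages (true values 0.375, 0.380 and
0.385 in the generator) are recovered to ~0.005 with s.e.m. ≈ 0.002, and
the control lineages' mean fitness is exactly 0 by construction. The
mating-scale calculator reproduces the pooled-mating bound:

```
$ ppiseq scale complexity
2.187e+07
```

(10¹⁰ cells/plate × 8.1% mating × 2.7% recombination ≥ 2×10⁷ unique
double-barcoded diploids per plate.)

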