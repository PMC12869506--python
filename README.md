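# comodmap

Cross-species refinement of disease gene co-expression networks with
single-cell expression data, plus seizure-assay time-to-event fitting.

## The problem

Human gene co-expression networks implicated in disease — such as the
320-gene epilepsy-associated M30 network derived from post-mortem brain
expression — are too large to validate gene by gene. One way to focus them
is to ask which parts of the network are conserved as a co-expressed unit in
a genetically tractable model organism. `comodmap` implements that workflow
for *Drosophila*:

1. **Ortholog expansion** — map the human gene list to fly genes using
   integer orthology-support scores (DIOPT-style), keeping pairs with score
   ≥ 3 and classifying the mapping as one-to-one, many-to-one, or
   one-to-many (tied partners within a configurable score window).
2. **Expression filtering** — from a whole-brain single-cell count matrix,
   keep catalog genes with ≥ 5000 total counts across all cells, then
   restrict to a coherent set of neuronal cell types (the 45-label default
   list ships with the package).
3. **Co-expression module detection** — pairwise Spearman correlation r_s
   across cells on the log2-transformed matrix, agglomerative clustering on
   the distance d = 1 − r_s (complete linkage by default), and extraction of
   flat clusters that pass explicit size and mean intra-correlation
   criteria.
4. **Enrichment statistics** — hypergeometric upper-tail tests throughout:
   disease-category enrichment of a module against its source network,
   generic over-representation analysis (ORA) of a gene set against GMT
   collections with Benjamini–Hochberg FDR, and the overlap test for two
   enriched-term lists in a term universe.
5. **Seizure-assay quantification** — fit the variable-slope sigmoid
   `f(t) = bottom + (top − bottom) / (1 + 10^((log10 T50 − log10 t)·h))`
   to cumulative fraction-seized time courses, report T50/logEC50, and
   normalize against same-day background controls; summarize mechanical
   (bang-sensitivity) assays as per-vial seized fractions.

A fully seeded synthetic-data generator (`comodmap.simulate`) produces
every input with known ground truth — negative-binomial counts with planted
latent-factor modules, ortholog tables with exact mapping compositions, GMT
collections with planted enriched terms, and binomial seizure time courses —
so the entire pipeline is testable without any external download.

## The statistics at the core

For a module of n genes drawn from a background of N genes of which K carry
a disease annotation, observing k annotated genes in the module has
upper-tail probability

    P(X ≥ k),  X ~ Hypergeometric(N, K, n)

and fold enrichment (k/n)/(K/N). For example, 13 epilepsy-associated genes
among a 26-gene module from a 320-gene network holding 53 gives
P = 3.45×10⁻⁵ and roughly threefold enrichment.

## Worked example

```sh
python examples/01_simulate_and_recover_module.py
```

prints

```
simulated 200 genes x 2000 cells, 26-gene planted module
top module: 26 genes, r_s 0.34..0.56 (mean 0.47)
Jaccard vs planted truth: 1.00
```

The generator planted a 26-gene module (a shared lognormal per-cell factor)
among 200 genes; Spearman correlation plus complete-linkage clustering at a
cut height of 1.0 recovered exactly the planted members (Jaccard 1.0), with
an intra-module correlation band (r_s 0.34–0.56) of the same order as the
0.36–0.84 band reported for real fly-brain modules. The other examples
cover ortholog catalogs (`02`), enrichment statistics (`03`), T50 fitting
(`04`) and the config-driven end-to-end pipeline (`05`).

The same functionality is available from the shell:

```sh
comodmap run --config config.yaml      # full pipeline
comodmap map-orthologs --table orthologs.tsv --out catalog.tsv
comodmap fit-t50 --csv timecourse.csv --genotype knockdown
comodmap overlap-test --n-a 449 --n-b 367 --overlap 155 --universe 27047
```

## Layout

```
src/comodmap/      library: simulate, orthologs, expression, coexpress,
                   enrichment, seizure, pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    models, parameters, numerical choices, limitations
```
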