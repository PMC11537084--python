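# markerbench

**Which rRNA marker region can actually resolve bacterial species?**
`markerbench` quantifies, on fully synthetic data, how the choice of
amplicon marker — whole rRNA operon (16S–ITS–23S–ITS–5S, ~5.1 kb), the
16S, 23S or 5S gene alone, or the 16S V3–V4 amplicon — affects
species-level classification accuracy *within a genus*, and how those
per-species error rates propagate into microbial-community composition
estimates and two-group differential-abundance results.

It is aimed at microbiome researchers choosing a sequencing strategy
(long-read operon vs short-read 16S/V3-V4) and at method developers who
need a controlled, download-free testbed for marker-based classifiers.

## What it does

1. **Synthetic references** (`synthgen`): multi-genus, multi-species
   genome collections whose operon copies have controlled
   within/between-species divergence and conserved V3–V4 primer
   footprints (341F `CCTACGGGNGGCWGCAG` / 805R `GACTACHVGGGTATCTAATCC`);
   plus Dirichlet community profiles with Geometric(*p* = 0.01)
   concentrations and two-group study tables with planted effects.
2. **Extraction** (`extract`): operon / 16S / 23S / 5S sub-regions from
   annotations; V3–V4 by degenerate-primer in-silico PCR with a
   ⌊0.10 × primer length⌋ mismatch budget; length filters 4,000–6,000 bp
   (operon) and 430–550 bp (amplicon).
3. **Error injection** (`errors`): per-position mismatch/insertion/
   deletion draws at platform rates — nanopore-class
   (0.0116 / 0.0081 / 0.0144) for operon-borne markers, Illumina-class
   (0.0089 / 0.00045 / 0.00045) for 16S and V3–V4.
4. **Classification** (`classify`): Kraken-style exact 31-mer match
   counting and BLAST-style best local alignment (Smith–Waterman, match
   +2 / mismatch −3 / gap −5, −2), with random tie-breaking and
   best-copy-per-genome reduction.
5. **Evaluation** (`evaluate`): per-genus accuracy / macro precision /
   sensitivity, species confusion matrices P(predicted | true), paired
   Wilcoxon signed-rank marker comparisons.
6. **Community simulation** (`commsim`): largest-remainder read
   allocation and multinomial confusion-row reassignment over library
   sizes 5,000–1,000,000.
7. **Compositional analysis** (`compost`): Pearson r, CLR / Aitchison
   distance, PCoA, ANOSIM.
8. **Differential abundance** (`diffab`): TSS → arcsin√ → per-species
   OLS on a case/control indicator, significance at raw p < 0.05, and
   Venn-style FNR/FDR agreement against a reference significant set.

The `pipeline` module chains everything under one master seed;
`markerbench` is the matching CLI.

## Worked example

```python
from markerbench import pipeline

cfg = pipeline.RunConfig(master_seed=1, methods=("kmer",))
bench, comm = pipeline.run_full(cfg, anosim_permutations=199)
print(bench.metrics.groupby("region").accuracy.mean())
```

prints the mean within-genus species classification accuracy per marker
on the default desk-scale collection (3 genera × 3 species × 2 genomes):

```
region
16S       1.000000
23S       1.000000
5S        0.666667
V3V4      1.000000
operon    1.000000
```

All long markers classify perfectly at the default 2% between-species
divergence; the 108 bp 5S gene cannot separate species once
nanopore-class errors are injected — one third of genomes are called by
a random tie-break among equally scoring species. The community stage
then shows what that means downstream:
`comm.correlation_table` holds the Pearson r between true and predicted
species proportions per library size (1.000 for identity-like confusion
matrices, degrading with off-diagonal mass), and
`comm.study_agreements` the differential-abundance FNR/FDR per marker —
in the run above the 5S-based study calls 39 species significant where
the reference calls 30 (false-discovery rate 0.36, false-negative rate
0.17), while every longer marker reproduces the reference significant
set exactly.

## Layout

```
src/markerbench/   library (synthgen, extract, errors, classify,
                   evaluate, commsim, compost, diffab, pipeline, cli)
tests/             pytest suite, including oracle-equivalence and
                   calibration property tests
scripts/           acceptance script
docs/methods.md    model and design notes
```
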