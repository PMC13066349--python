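# phylodi

Evolutionary characterization of human gene sets: phylostratigraphic
age assignment, divergence-index estimation with selection-mode
classification, and observed-vs-expected enrichment analysis — with a
synthetic-data generator so the whole pipeline runs and is validated
without any external downloads.

The package is aimed at molecular evolution analyses of curated gene
sets (the motivating case: cell-surface receptor genes regulating
appetite, compared against all protein-coding genes and against the
GPCR superfamily).

## The indices

**PAI (phylostratigraphic age index)** dates a gene's origin on an
ordered 16-stage taxon ladder from the root of the tree of life (rank 1,
cellular organisms) to *Homo sapiens* (rank 16). Given a best-hit
ortholog table (gene, subject species, identity fraction), the gene's
PAI is the minimum divergence rank among species whose hit identity is
≥ 0.5 (closed bound, configurable); with no qualifying hit the gene maps
to rank 16. Lower PAI = older gene.

**DI (divergence index)** is the mean pairwise dN/dS between the focal
CDS and its orthologs in four hominids (chimpanzee, bonobo, gorilla,
Sumatran orangutan):

    DI = (1/n) Σᵢ (dN/dS)ᵢ

estimated per pair by Nei–Gojobori (1986) counting with Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3). DI ≪ 1 → stabilizing selection,
DI ≈ 1 → neutral, DI > 1 → diversifying. Pairs with dS = 0 have an
undefined ratio and are excluded from the mean.

**Enrichment** compares a study set's observed count in a category
(e.g. PAI = 6, or DI ≤ 0.25) against the count expected from a
background distribution, n·m/M, using a two-cell 1-df chi-square
goodness of fit without continuity correction; a 2×2 variant tests
independence of two binary partitions (e.g. low-DI × development-
associated).

## Worked example

The numbered scripts under `analysis/` run the full study on a
deterministic synthetic universe of 19,504 genes containing an 80-gene
receptor study set, its 67-gene GPCR subset, a 420-gene GPCR background
and a 23-gene development-associated subset:

```bash
python analysis/01_simulate_universe.py   # build inputs (scratch/, results/tables/)
python analysis/02_assign_ages.py         # PAI from ortholog hits
python analysis/03_estimate_divergence.py # omega recovery for the dN/dS estimator
python analysis/04_enrichment.py          # enrichment report (results/report/)
```

`analysis/04_enrichment.py` prints:

```
            set  background     category  observed  expected   n            p      tier
   Receptors_80      allCDS        PAI=6        37     13.14  80 5.969665e-13 p < 0.001
    allGPCR_420      allCDS        PAI=6       152     68.97 420 7.816337e-28 p < 0.001
     appGPCR_67 allGPCR_420        PAI=6        35     24.25  67 6.265523e-03  p < 0.01
app_not_GPCR_13      allCDS PAI in {7,8}         6      2.29  13 7.033260e-03  p < 0.01
   Receptors_80      allCDS     DI<=0.25        45     35.76  80 3.778679e-02  p < 0.05
     appGPCR_67 allGPCR_420     DI<=0.25        38     27.76  67 1.107466e-02  p < 0.05

2x2 development split (rows ['DI<=0.25', 'DI>0.25'], cols ['development', 'other']):
  observed [[18, 27], [5, 30]]  expected [[12.94, 32.06], [10.06, 24.94]]
  chi2 = 6.355, p = 0.0117
```

Reading the first row: of the 80 receptor genes, 37 date to ladder rank 6
(the vertebrate stage), where the genome-wide background of 19,504 genes
(3,203 at rank 6) predicts only 13.14 — a strong enrichment (p < 0.001)
indicating coordinated origin of the set at that stage. The last block
shows that development-associated genes concentrate in the low-DI
(strong stabilizing selection) half of the set: 18 observed vs 12.94
expected.

`analysis/03_estimate_divergence.py` validates the dN/dS machinery by
simulating codon pairs at known selection strength ω and recovering it:

```
 omega  mean_ratio  sd_ratio  mean_dS  n_replicates
   0.1      0.1040    0.0141   0.0758            25
   0.5      0.5068    0.0483   0.0756            25
   1.0      1.0170    0.0935   0.0759            25
   2.0      1.9661    0.1535   0.0792            25
```

## Library and CLI

All computation lives in `src/phylodi/` (`strata`, `divergence`,
`genesets`, `enrichment`, `simulate`, `io`, `pipeline`); the analysis
scripts are thin drivers over it. A `phylodi` console command exposes
the stages (`simulate`, `pai`, `dnds`, `di`, `enrich`, `run`) over the
TSV/FASTA formats documented in `phylodi.io`:

```bash
phylodi simulate --paperlike --out-dir work/
phylodi run --universe work/universe.tsv --hits work/hits.tsv \
    --species-map work/species_map.tsv --study-set work/Receptors_80.txt \
    --gpcr-set work/allGPCR_420.txt --out-dir work/report
```

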