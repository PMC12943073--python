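# ribotally

Genomic inventory and statistical models of the bacterial translation
machinery.

Bacteria differ by three orders of magnitude in doubling time, and fast
growers pay for speed with genomic investment in translation: many ribosomal
RNA (*rrn*) operons for parallel ribosome biogenesis, and a large, uneven
pool of tRNA genes. `ribotally` is a toolkit for quantifying that
investment from annotated genomes and fitting the models that describe it.
It is aimed at comparative genomicists and molecular evolution researchers
working from RefSeq GenBank annotations.

## What it computes

**Inventory.** From GenBank flat files (.gbff), `ribotally` counts *rrn*
operons (as the number of 16S rRNA genes — each operon carries exactly one
16S, one 23S and one 5S) and tRNA genes classified per amino acid from
their `product`/`anticodon` annotations, with initiator (fMet) and
selenocysteine tRNAs tracked as their own classes. Multi-replicon genomes
(two-chromosome *Vibrio*, multi-contig drafts) are merged before counting.

**Growth models.** Machinery counts decline with generation time *T*
(minutes) toward hard floors:

$$N_{rrn} = 1 + \alpha e^{-\beta T} \qquad N_{tRNA} = \gamma + \alpha e^{-\beta T}$$

Fitted by Gaussian maximum likelihood with the error variance profiled out,
and tested against a constant null via the likelihood-ratio chi-square
$G^2 = 2(\ln L_{model} - \ln L_{null})$.

**tRNA allocation.** Within a genome, the number of tRNA genes serving
amino acid *i* follows its usage and decoding difficulty:

$$M_{tRNA} = \beta_0 + \beta_1 N_{AA} + \beta_2\,\mathrm{CFS}$$

where $N_{AA}$ is the total codon count for that amino acid over all CDSs
and CFS its synonymous codon family size. Fitted by OLS over the 19
standard amino acids excluding Met (whose initiator role inflates its tRNA
count), with a full ANOVA table and per-coefficient *t*-tests.

**Synthetic data.** Deterministic generators for annotated GenBank genomes
with prescribed feature counts (plus a ground-truth manifest), growth
datasets, and allocation tables — every pipeline stage is testable offline.

## Worked example

Fit the allocation model to the packaged *Vibrio natriegens* table
(19 amino acids, genome-wide codon counts, 129 tRNA genes overall):

```
$ ribotally fit-allocation --fixture vibrio_natriegens
term    df      SS        MS        F         p
Model   2       144.85534 72.42767  13.99081  0.00031
Residual 16     82.82887  5.17680
Total   18      227.68421

coefficient  estimate    SE          t         p
Intercept    -0.277900   1.347807    -0.20619  0.83925
N_AA         4.2965e-05  1.9757e-05  2.17467   0.04500
CFS          1.042735    0.439046    2.37500   0.03039

R-squared    0.6362
```

Both predictors are significant: each additional synonymous codon in the
family adds about one tRNA gene (CFS coefficient 1.04, p = 0.030), and
every ~23,000 extra codons of usage adds another (N_AA coefficient
4.3e-05, p = 0.045); together they explain 63.6% of the variance in
per-amino-acid tRNA gene counts.

Generate a synthetic genome and recover its inventory:

```
$ ribotally simulate-genome --n-rrn 7 --trna "L:17,S:7,W:2" --seed 1 \
      --out syn.gbff --manifest syn.json
$ ribotally inventory syn.gbff
species             n_rrn  rrna_16S  rrna_23S  rrna_5S  n_trna  ... trna_L ... trna_S ... trna_W ...
Synthetica exempli  7      7         7         7        26      ... 17     ... 7      ... 2      ...
```

The counts match the generator's manifest exactly — the parser/inventory
path is validated by this round trip over randomised genomes.

Other subcommands: `usage` (codon/amino-acid usage and RSCU from a
genome's CDSs), `fit-growth` (per-kingdom floor-model fits + LRTs from a
species table), `simulate-growth`, and `report` (end-to-end over a
directory of `<accession>.gbff` files; `scripts/fetch_genomes.py` can
download the packaged 20-species study set from NCBI).

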