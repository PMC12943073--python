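# Methods

## Feature inventory

The inventory is computed from GenBank FEATURES annotations only; no
sequence-based gene finding is attempted. Three feature kinds are
extracted (CDS, rRNA, tRNA); coordinates are kept 1-based inclusive with
`join(...)` locations stored as ordered segment lists, and minus-strand
sequences are reverse-complemented only when a caller asks for extracted
sequence.

**rrn operon count.** Defined as the number of rRNA features whose
`product` contains "16S". Every rrn operon contains exactly one 16S gene,
so this definition is exact on complete annotations and — unlike clustering
rRNA genes by genomic proximity — remains well defined on fragmented,
multi-contig assemblies where the three genes of one operon may fall on
different contigs. Counts for all three classes (16S/23S/5S) are reported,
and unequal class counts raise a warning rather than being reconciled:
a 16S/23S mismatch is information about annotation quality that the user
should see.

**tRNA classification.** The `product` qualifier (`tRNA-Leu`,
`tRNA-fMet`, `tRNA-Sec`) takes precedence; when absent, the amino acid is
decoded from the `anticodon` qualifier by reverse-complementing the
anticodon and reading the resulting codon off the genetic code. Features
with neither qualifier are tallied as unclassified, never dropped
silently, so the identity `n_trna = Σ m_trna + n_sec + n_unclassified`
holds for every assembly. Initiator (fMet) tRNAs are counted inside Met
(they are Met isoacceptors) and also tracked separately; selenocysteine
tRNAs are counted in the genome total but excluded from the per-amino-acid
map, since Sec has no codon family of its own in the standard code.
tRNA pseudogenes (`/pseudo`) are excluded by default — RefSeq flags them
as non-functional — with a flag to include them, since conventions differ
between annotation pipelines.

## Codon and amino-acid usage

Genetic codes come from the NCBI translation-table registry (table 11 for
bacteria; tables differ only in codon assignments and start-codon sets).
Usage counts every clean in-frame codon of every CDS, initiator codons
included: N_AA is a raw codon tally, so GTG/TTG starts count as Val/Leu,
not Met — start-context correction is deliberately not applied, keeping
N_AA interpretable as total decoding demand per amino acid. Codons with
ambiguous bases are skipped and counted, not imputed. Stop codons never
enter N_AA; internal stops additionally warn, as they usually indicate
mis-annotation. RSCU is each codon's count over its synonymous-family
mean, 0 for unused families.

## Growth models

Counts are modelled as Gaussian around the floor-decay means with a common
unknown variance. The likelihood's error family is a modelling choice:
for responses of this magnitude (1–11 operons, 32–129 tRNA genes) a
Gaussian with profiled variance is the minimal assumption that yields a
log-likelihood suitable for a G² test, and it is the same family the
simulators draw from, so recovery tests are well posed. Profiling gives
σ̂² = RSS/n and lnL = −(n/2)[ln(2πσ̂²) + 1]; a perfect fit (RSS = 0) is
reported as a +inf sentinel with a degeneracy flag rather than an error.

**Optimisation.** For fixed β both mean functions are linear in the
remaining parameters, so the fit profiles β: an exact inner solve
(closed-form for the rrn model with α ≥ 0; non-negative least squares for
(γ, α) in the tRNA model) at each of 200 log-spaced β values spanning
10⁻⁶–10⁰·⁵ min⁻¹, then bounded Brent refinement of ln β inside the best
bracket (tolerance 1e-14 on ln β). This replaces generic multi-start
search in (ln α, ln β) space: the inner solve removes the parameters that
cause ridge-shaped likelihoods, the scan cannot miss an optimum interior
to the grid, and zero-noise parameters are recovered to ~1e-8 relative
error. A β at the grid edge flags the fit as not converged. The constant
null's MLE is the sample mean, computed directly.

**LRT degrees of freedom** equal the difference in mean-function parameter
counts: 1 for the rrn model vs null, 2 for the tRNA model vs null. This
convention is verified in the tests: applied to the packaged model/null
log-likelihood pairs it reproduces the published p-values (0.000384,
0.000152) to two significant figures, which chi-square(2) would not.

**Generation times** are parsed from printed ranges ("~7–15 min", "~2 h",
"~7 days") as the arithmetic mid-range converted to minutes. Ranks are
carried through for plot-data output only; fits always use minutes.

## Allocation regression

OLS via the normal equations on the design (1, N_AA, CFS), 19 rows (20
standard amino acids minus Met, excluded for its initiator function).
The ANOVA partitions Σ(y−ȳ)² into model and residual sums of squares —
the overall-regression F on (2, n−3) df, not a sequential decomposition;
the Total SS of the packaged tables pins this convention down.
Coefficient standard errors are σ̂²(XᵀX)⁻¹ with σ̂² = SS_res/(n−3);
coefficient p-values are two-sided under t(n−3); no multiple-testing
correction is applied (three coefficients, a priori model). A
rank-deficient design (N_AA proportional to CFS) is rejected with an error
naming the collinearity. An independent statsmodels fit and a brute-force
RSS minimiser serve as cross-checks in the test suite, never as the
implementation.

## Synthetic data

The genome generator emits syntactically valid GenBank records with a
ground-truth manifest, making parse→inventory an exact round trip. It
emulates what the inventory reads — feature tables with rRNA products,
tRNA products/anticodons, CDSs of prescribed codon composition, multiple
replicons, alternating strands, optional pseudogenes — and nothing the
pipeline does not read: intergenic filler is random sequence, rRNA gene
bodies are placeholder runs, and there is no promoter/operon architecture.
Passing round-trip tests therefore validates parsing and counting logic,
not robustness to the annotation idiosyncrasies of real RefSeq files
(those are exercised via the optional genome-download path).

Growth simulations add Gaussian noise to the floor-decay means, mirroring
the fitting assumption. Default conditions are the study's: 20 species
with generation times log-spaced over the observed 10–10080 min span
(generation times span three orders of magnitude, so log spacing is the
natural design), σ = 1, and the published tRNA-model parameters
(α = 157.32, β = 0.0564 min⁻¹, γ = 40.95) as the reference point for
recovery checks — under these conditions 200 replicates give a median
relative error on β of about 1.6%. Optional integer rounding clips rrn
counts at 1 (a genome has at least one operon) but does not re-impose the
γ floor on noisy tRNA draws. Allocation tables draw N_AA log-uniform over
[6×10³, 2×10⁵] — the span observed in fast-growing genomes — and CFS from
{1, 2, 3, 4, 6}.

All generators are pure functions of their spec including the seed;
identical specs give byte-identical GenBank output.

## Known limitations

- The inventory trusts annotations; unannotated or mis-annotated tRNAs
  (and rRNA fragments in draft genomes) propagate into the counts.
- The Gaussian error model treats counts as continuous; for responses
  near the floor (N_rrn = 1) a count model (Poisson/negative binomial)
  would be more principled — left as an extension hook.
- Published per-amino-acid tables are packaged for the two fastest
  growers only; reproducing the per-kingdom growth-model parameter
  estimates themselves requires downloading the 20 RefSeq genomes
  (`scripts/fetch_genomes.py`), and re-annotation drift may shift counts
  slightly from the published ones.
- Phylogenetic non-independence of the 20 species is not modelled; no
  phylogenetically independent contrasts are implemented.
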