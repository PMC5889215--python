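# Methods

## Scope and data flow

The package computes, from sequencing data of a surface-display sort-seq
kinase specificity screen: per-peptide read counts, enrichment scores and
the high-efficiency classification; position- and charge-resolved
specificity statistics; and independent linear motifs. A simulator
generates complete synthetic screens from a ground-truth kinase model so
that every stage is testable without experimental data.

Stages and their containers:

1. `library_builder` — phosphosite definitions -> `PeptideLibrary`
   (15-mers, Tyr->Ala variants, controls, flanked DNA encodings);
2. `read_processing` — FASTQ -> `CountTable` per sample
   (merge -> trim -> translate -> substring count);
3. `enrichment` — count tables -> `EnrichmentTable`
   (frequencies, scores, replicate averages, >= 1.5 labels);
4. `specificity_stats` — matrices (`f_i,j`, `E_i,j`, log-ratio heatmaps,
   logo heights), substrate sets, net-charge statistics;
5. `motif_extraction` — greedy binomial motif search;
6. `screen_simulator` — ground truth -> counts/FASTQ -> recovery harness.

## Library construction

A peptide is the 15-residue window centred on an annotated phosphotyrosine,
glycine-padded where the window crosses a protein terminus. Windows with
two or more tyrosines additionally yield a variant with every non-central
tyrosine replaced by alanine, so phosphorylation of the central site can be
read out without interference; both versions take part in all quantitative
analyses. Identical 15-mers arising from distinct proteins are collapsed to
the first occurrence (logged): counting is by 15-mer, so duplicates would
make read assignment ambiguous.

Control sequences come in triplets sharing 14 random flanking residues and
differing only at the centre (Y/F/A). Flanking residues are drawn uniformly
from the 19 non-tyrosine residues, which keeps each control a single-site
sequence; controls are excluded from every quantitative statistic.

DNA encoding uses one fixed codon per residue — the most prevalent codon per
amino acid in E. coli K-12, shipped in `constants.ECOLI_PREFERRED_CODONS`
and user-overridable — with the scaffold-fusion flanks
`GCTGGCCAGTCTGGCCAG` / `GGAGGGCAGTCTGGGCAGTCTG` appended. No GC-content or
melting-temperature optimisation is applied. Encoding and translation are
exact inverses, property-tested over random 15-mers.

## Read processing

Paired reads are merged by reverse-complementing the reverse read and
scanning for the longest 3' overlap of length >= `min_overlap` (default 15)
with at most `max_mismatch` (default 2) mismatches, keeping the forward base
at disagreements. These defaults are configuration, not fidelity claims —
pre-merged single-end input bypasses merging entirely. The coding region is
the substring strictly between exact matches of the two flanks; reads
missing either flank are dropped and counted in the run report. Translation
is frame 1 of the standard genetic code; trailing bases are dropped, stops
render as `*`, and codons containing non-ACGT characters as `X`. Base
qualities are ignored throughout.

A read counts for a peptide when its translation contains the peptide's
15-mer as a contiguous substring (per-peptide grep semantics). Reads with
indels frameshift and match nothing; a read matching several peptides — a
corner case excluded by the library's 15-mer uniqueness check — would
increment each matched peptide but contribute once to `n_total`, and is
logged. Counting is implemented by hashing every 15-residue window of each
read against the library map, which is exactly equivalent to (and tested
against) the naive per-(read, peptide) substring loop.

## Enrichment scores

`f_peptide = n_peptide / n_total` per sample;
`score = f_sorted / f_unsorted` per same-day sorted/unsorted pair;
replicates are averaged arithmetically (unweighted by depth) after
scoring, skipping replicates where a score is undefined. A peptide with
zero unsorted frequency gets an undefined score rather than infinity: at
500-1000 unsorted reads per peptide a zero indicates library dropout, not
enrichment. An optional pseudocount (default 0) added to both frequencies
is available for sparse data. "High-efficiency" means averaged score
>= 1.5, threshold inclusive. No correction is applied for variable
surface-display levels; the statistic is designed for comparisons between
kinases screened on the same library, where display variation is common to
both.

## Specificity statistics: two frequency semantics

`f_i,j` (and hence `E_i,j = f_i,j,sorted / f_i,j,unsorted`, averaged across
replicates after division, and the `log10(E_a/E_b)` heatmaps) is
**read-weighted**: the fraction of mapped reads whose peptide carries
residue *i* at position *j*. Probability-logo heights and normalized
abundances are computed on **unweighted sequence sets** (a substrate set
against the full library). Both semantics are deliberate and kept separate
in the API.

Logo heights use exact binomial tails summed in log space
(`gammaln` + `logsumexp`) rather than a normal approximation: with
foregrounds of at most a few thousand sequences exactness is cheap and
directly testable (the suite checks agreement with an exact rational-sum
oracle to 1e-9). A residue absent from the background but present in the
foreground yields an infinite height and indicates a foreground that is not
drawn from the background's composition. Positions are labelled -7..+7 with
0 at the central tyrosine; matrices are 20 x 15 with residues in fixed
alphabetical one-letter order, frequency columns summing to 1.

Net charge is `#(K) + #(R) - #(D) - #(E)`; histidine and the central
(phospho)tyrosine are ignored. Selective-substrate sets partition the
universe of peptides with defined scores for both kinases into a-only /
b-only / both-high / both-low at the shared threshold.

## Motif extraction

Greedy recursion: among all (residue, position != 0) cells, compute
`P(X >= k)` with `n` the current foreground size and `p` the residue's
frequency in the current background; fix the most significant cell if
`P <= alpha` (default 1e-6) and `k >= min_occurrence` (default 20); filter
both foreground and background to matching sequences (background
re-filtering is the canonical behaviour); repeat until no cell qualifies,
emit the motif, remove its matching sequences from the original foreground,
restart. Ties on the tail probability break to the lower |position|,
negative before positive, then alphabetical residue, making extraction
fully deterministic. Tyrosine is never fixed at a non-central position —
multi-tyrosine motifs cannot be unambiguously interpreted in a library
defined around a central tyrosine, so they are excluded at the search stage
rather than filtered afterwards. Only over-representation is searched;
conditional negative selection is outside this procedure's expressive
range.

## Screen simulator

The generator's defaults are the emulated study conditions: a library of
unique 15-mers with central tyrosine and flanking residues i.i.d. from an
acidic-skewed, hydrophobic-depleted composition (D+E = 19%, S/G/P near 8%,
I/V/F/M/C/W at 1-4%, Y at 3% so a realistic minority of windows carry extra
tyrosines); top-25% sort gate; 25% target mean phosphorylation extent
(within the screen's 20-30% operating band); 750 reads per peptide unsorted
by default, 1000 where a test emulates the deep-sequencing condition;
fluorescence background 0.05 and lognormal noise CV 0.3 (exploratory knobs,
not estimates — no quantitative noise model of sorting/labeling exists to
fit them to); 500 cells per peptide, enough that sorting noise is dominated
by sequencing sampling at the depths used.

The model is log-linear: `log rate = base + sum_j w[res_j, j] +
c * net_charge`, with the central column fixed at zero. Phosphorylation is
single-hit, `p = 1 - exp(-rate * t)` — the simplest monotone map from rate
to extent, standing in for unmodelled enzyme kinetics. The reaction time
solves `mean_p(1 - exp(-rate_p * t)) = target` by bracketed root finding to
1e-6 in the achieved extent. Under this convention a positive charge
coefficient rewards positively charged substrates, so high scorers shift
positive in net charge — the direction a charge-tolerant kinase displays —
and a negative coefficient produces the mirrored shift; the recovery tests
exercise both signs.

Cells are assigned peptides at uniform abundance (a Dirichlet abundance
option would emulate uncorrected display variability; uniform is the
default because the analysis itself makes no display correction).
Fluorescence is `(phospho_indicator + background) * LogNormal(CV)`; the
brightest 25% of all cells are collected; reads are multinomial over cell
populations at the configured depth (the sorted sample is sequenced at the
same total depth as the unsorted one). FASTQ emission reconstructs each
peptide's flanked construct, optionally injects one single-nucleotide
insertion or deletion into the coding region per affected read, and emits
either merged single-end reads or an overlapping R1/R2 pair (default read
length 60 over the 85-nt construct, a 35-nt overlap), exercising the full
merge path. Everything is driven by one seed.

`recover_model` estimates position effects as `log10` of the
replicate-averaged `E_i,j` matrix and the charge preference as the
least-squares slope of `log(avg score)` on net charge. Recovery is
validated by rank (planted cell in the top 3 of its column) and by slope
sign, over 20 independent seeded screens of 500 peptides at 1000 reads per
peptide — sizes at which one run takes a fraction of a second and the whole
recovery experiment stays lightweight while estimator noise is still
visible.

## What the simulator does and does not establish

Passing recovery tests shows the pipeline's statistics are consistent and
sensitive under the generative model: positional and electrostatic
preferences planted in the rate law are recovered from counts alone. The
simulator does not model PCR amplification bias, display-level variation
(by default), antibody-binding chemistry, sorter optics, position-dependent
synthesis error rates, or correlated residue preferences; agreement on
synthetic screens therefore validates the computation, not the biology of
any particular kinase.

## Degenerate inputs and numerical conventions

Empty samples (zero mapped reads) raise rather than return NaN tables.
Undefined values propagate as NaN through matrices and are excluded from
averages; `enrichment_ratio` is undefined where either operand is undefined
or zero and is exactly antisymmetric elsewhere. Binomial tails are clamped
at log10 <= 0 to absorb rounding in the log-sum. Frequency columns are
checked to 1e-9. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`.
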