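# phosphoscreen

Analysis pipeline for high-throughput tyrosine kinase substrate specificity
screens based on bacterial surface-display of peptide libraries, fluorescence
sorting and deep sequencing (sort-seq / FACS-seq), together with a seeded
screen simulator so that every stage can be validated against planted ground
truth.

## The problem

Tyrosine kinases recognise the sequence context of the tyrosines they
phosphorylate. In the screen this package analyses, each bacterial cell
displays one 15-residue peptide (a window around a known human
phosphotyrosine site, with the tyrosine central), a purified kinase domain
phosphorylates the displayed library for a limited time, cells are stained
with a pan-phosphotyrosine antibody, the brightest 25% are collected by cell
sorting, and the peptide-coding DNA of sorted and unsorted samples is deep
sequenced. For every peptide the **enrichment score**

```
f_peptide = n_peptide / n_total          (per sample)
score     = f_peptide,sorted / f_peptide,unsorted
```

is a quantitative proxy for how efficiently that peptide is phosphorylated;
scores from replicate screens are averaged, and peptides with an averaged
score >= 1.5 are classified as high-efficiency substrates. Downstream
statistics resolve the specificity by position and by charge:

* residue-specific enrichment `E_i,j = f_i,j,sorted / f_i,j,unsorted` for
  residue *i* at position *j* (read-weighted), and `log10(E_a/E_b)` heatmaps
  contrasting two kinases;
* probability-logo heights for a substrate set against the full-library
  background: signed log10 binomial tail probabilities
  `-log10 P(X >= k)` (over-represented) / `+log10 P(X <= k)`
  (under-represented) with `X ~ Binomial(n, p)`;
* normalized abundance of a residue at a position (subset fraction over
  library fraction) and net charge `#(K,R) - #(D,E)` distributions;
* iterative greedy motif extraction (motif-x style): repeatedly fix the most
  significant (residue, position) cell subject to a minimum occurrence of 20
  and a binomial significance threshold of 1e-6, filtering foreground and
  background, until no cell qualifies.

The simulator generates the whole experiment from a ground-truth kinase
model (per-position log-rate weights plus a net-charge coefficient):
single-hit phosphorylation `p = 1 - exp(-rate*t)` with the reaction time
calibrated to a 20-30% library-mean extent, noisy fluorescence, a top-25%
sort gate, multinomial sequencing at 500-1000 reads per peptide, and
optional paired FASTQ emission with single-nucleotide indels.

## Worked example

```python
import phosphoscreen as ps
from scipy import stats

library = ps.sample_synthetic_library(500, seed=11)
model = ps.KinaseModel.with_preferences({("I", -1): 1.5, ("P", 3): 1.0},
                                        charge_coeff=0.25)
config = ps.SimConfig(library=library, reads_per_peptide_unsorted=1000, seed=202)
table, results = ps.simulate_replicates(model, config, n_replicates=3)

high = table.high_efficiency_ids()
rho = stats.spearmanr(table.avg_scores, results[0].truth.p_phospho).statistic
est = ps.recover_model(results, library, table)
```

printing, for this seed:

```
high-efficiency substrates (score >= 1.5): 73 / 500
Spearman(score, true phosphorylation probability) = 0.990
top residues at -1 by recovered log10 enrichment: I (+0.39), W (+0.12), C (+0.09)
recovered net-charge slope: +0.210 (planted +0.25)
logo height at (I, -1): 5.5
```

The simulated kinase preferred isoleucine at -1 and positively charged
substrates; both preferences are recovered from sequencing counts alone: the
planted cell tops its column of the recovered position-effect matrix, the
least-squares slope of log score against net charge carries the planted
sign, and the enrichment score tracks the true phosphorylation probability
almost monotonically.

A command-line interface mirrors the library: `phosphoscreen build-library`,
`count`, `score`, `compare`, `motifs`, `simulate` (see `--help` on each).

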