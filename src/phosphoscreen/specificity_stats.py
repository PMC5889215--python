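"""Position- and charge-resolved specificity statistics.

Two distinct readings of "frequency" coexist and are kept separate:

* read-weighted: f_i,j is the fraction of mapped *reads* whose peptide has
  residue i at position j; ratios of sorted over unsorted read-weighted
  matrices give the residue-specific enrichment E_i,j, and log10 ratios of
  two kinases' E matrices give differential-preference heatmaps;
* sequence-counting: probability-logo heights and normalized abundances are
  computed on unweighted *sets* of sequences (a foreground substrate set
  against the full-library background) via exact binomial tail
  probabilities.

All matrices are 20 residues x 15 positions, positions labelled -7..+7 with
0 at the central tyrosine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .constants import AA_ALPHABET, PEPTIDE_LENGTH, POSITIONS, pos_to_index
from .library_builder import PeptideLibrary
from .read_processing import CountTable

_LN10 = np.log(10.0)

MATRIX_KINDS = ("frequency", "enrichment", "log_ratio", "logo_height",
                "normalized_abundance", "log_enrichment")


@dataclass
class PositionMatrix:
    """A residue x position matrix with a semantics tag.

    `df` has the 20 standard residues (alphabetical one-letter order) as rows
    and integer positions -7..+7 as columns. NaN marks undefined cells.
    """

    df: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind}")
        self.df = self.df.reindex(index=list(AA_ALPHABET), columns=list(POSITIONS))

    def value(self, residue: str, position: int) -> float:
        return float(self.df.at[residue, position])

    def write_tsv(self, path: str | Path) -> None:
        self.df.rename_axis("residue").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str) -> "PositionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="residue")
        df.columns = df.columns.astype(int)
        return cls(df, kind)


def residue_counts(seqs: Iterable[str], weights: Iterable[float] | None = None) -> pd.DataFrame:
    """Residue x position occurrence counts over 15-mers, optionally weighted."""
    mat = pd.DataFrame(0.0, index=list(AA_ALPHABET), columns=list(POSITIONS))
    w_iter = iter(weights) if weights is not None else None
    for seq in seqs:
        if len(seq) != PEPTIDE_LENGTH:
            raise ValueError(f"expected 15-mer, got {seq!r}")
        w = next(w_iter) if w_iter is not None else 1.0
        for pos in POSITIONS:
            mat.at[seq[pos_to_index(pos)], pos] += w
    return mat


def residue_position_frequency(counts: CountTable, library: PeptideLibrary) -> PositionMatrix:
    """Read-weighted residue frequency f_i,j for one sequencing sample.

    Each peptide's 15-mer contributes its read count at every position;
    columns are normalized by total mapped reads, so each column of the
    result sums to 1.
    """
    if counts.total_mapped <= 0:
        raise ValueError("no mapped reads")
    pids = counts.counts.index
    mat = residue_counts(library.sequences(pids), counts.counts.to_numpy(dtype=float))
    return PositionMatrix(mat / counts.total_mapped, "frequency")


def residue_enrichment(f_sorted: PositionMatrix, f_unsorted: PositionMatrix) -> PositionMatrix:
    """Residue-specific enrichment E_i,j = f_sorted / f_unsorted (elementwise).

    Cells unobserved in the unsorted sample are undefined (NaN). For
    replicate screens compute one E matrix per replicate and average with
    :func:`average_matrices`.
    """
    if f_sorted.kind != "frequency" or f_unsorted.kind != "frequency":
        raise ValueError("residue_enrichment expects two frequency matrices")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = f_sorted.df / f_unsorted.df
    return PositionMatrix(e.where(f_unsorted.df > 0), "enrichment")


def average_matrices(matrices: Sequence[PositionMatrix]) -> PositionMatrix:
    """Elementwise mean over replicate matrices, ignoring undefined cells."""
    if not matrices:
        raise ValueError("no matrices to average")
    kind = matrices[0].kind
    if any(m.kind != kind for m in matrices):
        raise ValueError("cannot average matrices of different kinds")
    stacked = np.stack([m.df.to_numpy(dtype=float) for m in matrices])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
        mean = np.nanmean(stacked, axis=0)
    return PositionMatrix(pd.DataFrame(mean, index=list(AA_ALPHABET), columns=list(POSITIONS)), kind)


def enrichment_ratio(e_a: PositionMatrix, e_b: PositionMatrix) -> PositionMatrix:
    """log10(E_a / E_b), the differential-preference heatmap of two kinases.

    Undefined wherever either operand is undefined or zero; antisymmetric
    under swapping the two kinases.
    """
    if e_a.kind != "enrichment" or e_b.kind != "enrichment":
        raise ValueError("enrichment_ratio expects two enrichment matrices")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log10(e_a.df / e_b.df)
    ratio = ratio.where((e_a.df > 0) & (e_b.df > 0))
    return PositionMatrix(ratio, "log_ratio")


def log10_binom_sf(k: int, n: int, p: float) -> float:
    """log10 P(X >= k) for X ~ Binomial(n, p), by exact log-space summation."""
    if not 0 <= p <= 1:
        raise ValueError("p outside [0, 1]")
    if k <= 0:
        return 0.0
    if k > n:
        return -np.inf
    if p == 0.0:
        return -np.inf
    if p == 1.0:
        return 0.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + i * np.log(p) + (n - i) * np.log1p(-p)
    )
    return min(float(logsumexp(log_terms)) / _LN10, 0.0)


def log10_binom_cdf(k: int, n: int, p: float) -> float:
    """log10 P(X <= k) for X ~ Binomial(n, p), by exact log-space summation."""
    if not 0 <= p <= 1:
        raise ValueError("p outside [0, 1]")
    if k >= n:
        return 0.0
    if k < 0:
        return -np.inf
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return -np.inf
    i = np.arange(0, k + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + i * np.log(p) + (n - i) * np.log1p(-p)
    )
    return min(float(logsumexp(log_terms)) / _LN10, 0.0)


def plogo_height(k: int, n: int, p: float) -> float:
    """Probability-logo height for one (residue, position) cell.

    With k foreground occurrences out of n sequences against background
    frequency p: over-represented cells (k/n >= p) get -log10 P(X >= k) (a
    positive height), under-represented ones +log10 P(X <= k) (negative).
    """
    if n <= 0:
        raise ValueError("empty foreground")
    if p == 0.0 and k > 0:
        return np.inf  # residue never seen in the background
    if k / n >= p:
        return -log10_binom_sf(k, n, p)
    return log10_binom_cdf(k, n, p)


def sequence_frequency_matrix(seqs: Sequence[str]) -> PositionMatrix:
    """Unweighted per-sequence residue frequencies (columns sum to 1)."""
    if not seqs:
        raise ValueError("empty sequence set")
    return PositionMatrix(residue_counts(seqs) / len(seqs), "frequency")


def plogo_matrix(foreground: Sequence[str], background: Sequence[str]) -> PositionMatrix:
    """Probability-logo heights of a foreground set against the library background.

    Both sets are unweighted sequence lists; the background is typically the
    full library. Heights are signed log10 binomial tail probabilities (see
    :func:`plogo_height`).
    """
    if not foreground:
        raise ValueError("empty foreground")
    fg_counts = residue_counts(foreground)
    bg_freq = residue_counts(background) / len(background)
    n = len(foreground)
    heights = pd.DataFrame(np.nan, index=list(AA_ALPHABET), columns=list(POSITIONS))
    for aa in AA_ALPHABET:
        for pos in POSITIONS:
            k = int(fg_counts.at[aa, pos])
            p = float(bg_freq.at[aa, pos])
            heights.at[aa, pos] = plogo_height(k, n, p)
    return PositionMatrix(heights, "logo_height")


def normalized_abundance(
    subset: Sequence[str], library: Sequence[str], residue: str, position: int
) -> float:
    """Subset fraction carrying `residue` at `position`, over the library fraction.

    Unweighted sequence counting: e.g. a subset with 16% +5 lysine against a
    library with 8% gives 2.
    """
    if not subset:
        raise ValueError("empty subset")
    idx = pos_to_index(position)
    lib_frac = sum(s[idx] == residue for s in library) / len(library)
    if lib_frac == 0:
        return np.nan
    sub_frac = sum(s[idx] == residue for s in subset) / len(subset)
    return sub_frac / lib_frac


def net_charge(aa_seq: str) -> int:
    """count(Lys, Arg) - count(Asp, Glu); His and the phosphotyrosine ignored."""
    return (
        aa_seq.count("K") + aa_seq.count("R") - aa_seq.count("D") - aa_seq.count("E")
    )


def net_charge_distribution(seqs: Iterable[str]) -> pd.Series:
    """Histogram of net charges over a sequence set."""
    charges = pd.Series([net_charge(s) for s in seqs])
    return charges.value_counts().sort_index()


@dataclass(frozen=True)
class SubstrateSet:
    """A named, rule-defined set of peptide ids."""

    name: str
    peptide_ids: frozenset[str]
    rule: str = ""

    def __len__(self) -> int:
        return len(self.peptide_ids)


def selective_substrates(
    scores_a: pd.Series,
    scores_b: pd.Series,
    threshold: float = 1.5,
    name_a: str = "a",
    name_b: str = "b",
) -> tuple[dict[str, SubstrateSet], dict[str, float]]:
    """Partition the shared score-defined universe by the >= threshold cutoff.

    Returns four sets — a_only (>= for a, < for b), b_only, both_high,
    both_low — plus their fractions of the defined universe (summing to 1).
    Peptides undefined for either kinase are excluded.
    """
    common = scores_a.index.intersection(scores_b.index)
    if len(common) == 0:
        raise ValueError("score tables share no peptides")
    a = scores_a[common]
    b = scores_b[common]
    defined = common[a.notna() & b.notna()]
    a, b = a[defined], b[defined]
    masks = {
        f"{name_a}_only": (a >= threshold) & (b < threshold),
        f"{name_b}_only": (a < threshold) & (b >= threshold),
        "both_high": (a >= threshold) & (b >= threshold),
        "both_low": (a < threshold) & (b < threshold),
    }
    sets = {
        key: SubstrateSet(
            key, frozenset(defined[mask]),
            rule=f"{name_a} vs {name_b} at threshold {threshold}",
        )
        for key, mask in masks.items()
    }
    n = len(defined)
    fractions = {key: len(s) / n for key, s in sets.items()}
    return sets, fractions
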