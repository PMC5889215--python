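"""Per-peptide frequencies, enrichment scores, and substrate classification.

A peptide's enrichment score is the ratio of its read frequency in the
sorted sample to its frequency in the matched unsorted sample; replicate
screens are averaged before any further analysis. Peptides with an averaged
score >= 1.5 are classified as high-efficiency substrates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .read_processing import CountTable

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.5


class EmptySampleError(ValueError):
    """A count table with no mapped reads cannot be converted to frequencies."""


def peptide_frequencies(counts: CountTable) -> pd.Series:
    """Convert raw counts to frequencies f = n_peptide / n_total."""
    if counts.total_mapped <= 0:
        raise EmptySampleError(f"{counts.sample_id}: no mapped reads")
    return counts.counts / counts.total_mapped


def enrichment_score(
    sorted_f: pd.Series, unsorted_f: pd.Series, pseudocount: float = 0.0
) -> pd.Series:
    """Per-peptide sorted/unsorted frequency ratio.

    Peptides absent from the unsorted sample get NaN (undefined), not
    infinity: with unsorted samples sequenced at hundreds of reads per
    peptide, an unsorted zero signals a library dropout rather than
    enrichment. A pseudocount added to both frequencies is available but off
    by default.
    """
    if set(sorted_f.index) != set(unsorted_f.index):
        raise ValueError("sorted and unsorted tables cover different peptides")
    unsorted_f = unsorted_f.reindex(sorted_f.index)
    num = sorted_f + pseudocount
    den = unsorted_f + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / den
    return score.where(den > 0, np.nan)


def average_replicates(scores_by_replicate: Mapping[str, pd.Series] | pd.DataFrame) -> pd.Series:
    """Arithmetic mean over replicates, ignoring undefined (NaN) scores.

    A peptide undefined in every replicate stays undefined; one defined in
    only some replicates is averaged over those, with a logged warning.
    """
    if isinstance(scores_by_replicate, Mapping):
        df = pd.DataFrame(dict(scores_by_replicate))
    else:
        df = scores_by_replicate
    if df.shape[1] == 0:
        raise ValueError("at least one replicate required")
    defined = df.notna().sum(axis=1)
    partial = ((defined > 0) & (defined < df.shape[1])).sum()
    if partial:
        logger.warning("%d peptides undefined in some replicates; averaged over the rest", partial)
    return df.mean(axis=1, skipna=True)


def classify_substrates(
    avg_scores: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    exclude: Iterable[str] = (),
) -> pd.Series:
    """Label peptides high (score >= threshold, inclusive) / low / undefined.

    `exclude` removes peptides (typically the control sequences) from the
    classification entirely.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    scores = avg_scores.drop(index=[p for p in exclude if p in avg_scores.index])
    labels = pd.Series("undefined", index=scores.index, dtype=object)
    labels[scores >= threshold] = "high"
    labels[scores < threshold] = "low"
    return labels


@dataclass
class EnrichmentTable:
    """Replicate and averaged enrichment scores for one kinase."""

    kinase: str
    per_replicate: pd.DataFrame  # peptides x replicates, NaN = undefined
    threshold: float = DEFAULT_THRESHOLD
    avg_scores: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.avg_scores = average_replicates(self.per_replicate)

    @property
    def labels(self) -> pd.Series:
        return classify_substrates(self.avg_scores, self.threshold)

    def high_efficiency_ids(self) -> list[str]:
        labels = self.labels
        return list(labels.index[labels == "high"])


def score_replicates(
    replicate_pairs: Iterable[tuple[CountTable, CountTable]],
    kinase: str = "kinase",
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = 0.0,
) -> EnrichmentTable:
    """Build an EnrichmentTable from (unsorted, sorted) count-table pairs."""
    cols = {}
    for i, (unsorted_ct, sorted_ct) in enumerate(replicate_pairs, start=1):
        cols[f"rep{i}"] = enrichment_score(
            peptide_frequencies(sorted_ct), peptide_frequencies(unsorted_ct), pseudocount
        )
    return EnrichmentTable(kinase, pd.DataFrame(cols), threshold)


def load_score_table(path: str | Path) -> pd.DataFrame:
    """Load a pre-averaged score table: peptide name, sequence, one column per kinase.

    Returns a DataFrame indexed by peptide id with a `sequence` column and one
    float column per kinase. Accepts comma- or tab-delimited text.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]
    name_col, seq_col = df.columns[0], df.columns[1]
    df = df.rename(columns={name_col: "peptide_id", seq_col: "sequence"})
    df = df.set_index("peptide_id")
    for col in df.columns:
        if col != "sequence":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def join_known_pairs(
    avg_scores_by_kinase: Mapping[str, pd.Series],
    pairs: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join screen scores against an external (kinase, phosphosite) pair list.

    `pairs` needs columns `kinase` and `phosphosite_id` using the library's id
    convention. Returns the matched per-pair table (with scores) and a
    per-kinase summary of matched-pair counts and the fraction scoring >=
    threshold. Unmatched pairs are logged, not fatal.
    """
    rows = []
    unmatched = 0
    for r in pairs.itertuples():
        scores = avg_scores_by_kinase.get(r.kinase)
        if scores is None or r.phosphosite_id not in scores.index:
            unmatched += 1
            continue
        score = scores[r.phosphosite_id]
        if pd.isna(score):
            unmatched += 1
            continue
        rows.append((r.kinase, r.phosphosite_id, float(score)))
    if unmatched:
        logger.info("%d pairs not measured in the screens", unmatched)
    joined = pd.DataFrame(rows, columns=["kinase", "phosphosite_id", "score"])
    if len(joined):
        summary = joined.groupby("kinase").agg(
            n_pairs=("score", "size"),
            frac_high=("score", lambda s: float((s >= threshold).mean())),
        )
    else:
        summary = pd.DataFrame(columns=["n_pairs", "frac_high"])
    return joined, summary
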