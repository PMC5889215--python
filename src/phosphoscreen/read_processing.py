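"""Raw reads to per-peptide counts: merge, trim, translate, substring-count.

The counting contract mirrors a per-peptide `grep -c` over translated reads:
a read counts for a peptide when its translation contains the 15-mer as a
contiguous substring. Reads with indels or disrupted codons translate to
strings that match no library member and drop out of the analysis; no
alignment or error correction is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .constants import FLANK_3, FLANK_5, PEPTIDE_LENGTH
from .library_builder import LibraryConfigError, PeptideLibrary

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP: dict[str, str] = dict(_STANDARD.forward_table)
_CODON_MAP.update({codon: "*" for codon in _STANDARD.stop_codons})


@dataclass
class SequencingSample:
    """A sequencing sample: which kinase/replicate and sorted vs unsorted."""

    sample_id: str
    kinase: str
    replicate: int
    condition: str  # "sorted" | "unsorted"

    def __post_init__(self) -> None:
        if self.condition not in ("sorted", "unsorted"):
            raise ValueError(f"condition must be sorted/unsorted, got {self.condition}")


@dataclass
class CountTable:
    """Per-peptide read counts for one sample.

    `counts` covers every library peptide (zeros included); `total_mapped` is
    the number of reads that matched at least one peptide — it equals
    counts.sum() unless some read matched several peptides.
    """

    sample_id: str
    counts: pd.Series
    total_mapped: int

    def write_tsv(self, path: str | Path) -> None:
        df = self.counts.rename("count").rename_axis("peptide_id").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, sample_id: str | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        counts = df.set_index("peptide_id")["count"].astype(int)
        return cls(sample_id or Path(path).stem, counts, int(counts.sum()))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def merge_read_pair(
    fwd: str, rev: str, min_overlap: int = 15, max_mismatch: int = 2
) -> str | None:
    """Assemble a read pair into one contiguous read.

    The reverse read is reverse-complemented and the longest 3' overlap of
    length >= `min_overlap` with <= `max_mismatch` mismatches is taken; the
    forward base wins at mismatching positions. Returns None when no
    acceptable overlap exists.
    """
    if not fwd or not rev:
        raise ValueError("both reads must be non-empty")
    rc = reverse_complement(rev)
    for olap in range(min(len(fwd), len(rc)), min_overlap - 1, -1):
        tail, head = fwd[-olap:], rc[:olap]
        mismatches = sum(a != b for a, b in zip(tail, head))
        if mismatches <= max_mismatch:
            return fwd + rc[olap:]
    return None


def trim_coding_region(merged: str) -> str | None:
    """Cut out the peptide-coding region between the two scaffold flanks.

    Both flanks must be present, in order, as exact matches; otherwise the
    read is unusable and None is returned.
    """
    start = merged.find(FLANK_5)
    if start == -1:
        return None
    coding_start = start + len(FLANK_5)
    end = merged.find(FLANK_3, coding_start)
    if end == -1:
        return None
    return merged[coding_start:end]


def translate_dna(coding: str) -> str:
    """Translate frame 1 under the standard genetic code.

    Trailing 1-2 nt are dropped; stop codons render as '*' and codons with
    characters outside ACGT as 'X'.
    """
    coding = coding.upper()
    out = []
    for i in range(0, len(coding) - len(coding) % 3, 3):
        out.append(_CODON_MAP.get(coding[i : i + 3], "X"))
    return "".join(out)


def count_matches(
    translated_reads: Iterable[str], library: PeptideLibrary, sample_id: str = "sample"
) -> CountTable:
    """Count reads containing each library 15-mer as a contiguous substring.

    Substring containment reproduces per-peptide grep counting: a read
    matching several peptides increments each of them but contributes once to
    `total_mapped`. Library 15-mers must be unique (checked up front).
    """
    if len(library) == 0:
        raise LibraryConfigError("empty library")
    seq_to_id = library.seq_to_id()
    counts = {pid: 0 for pid in library.peptide_ids}
    total_mapped = 0
    for read in translated_reads:
        hits = set()
        for i in range(len(read) - PEPTIDE_LENGTH + 1):
            pid = seq_to_id.get(read[i : i + PEPTIDE_LENGTH])
            if pid is not None:
                hits.add(pid)
        if hits:
            total_mapped += 1
            if len(hits) > 1:
                logger.warning("read matches %d peptides: %s", len(hits), sorted(hits))
            for pid in hits:
                counts[pid] += 1
    return CountTable(
        sample_id, pd.Series(counts, name="count").astype(int), total_mapped
    )


def _read_fastq_seqs(path: str | Path) -> Iterator[str]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq)


def process_reads(
    reads: Iterable[str] | Iterable[tuple[str, str]],
    library: PeptideLibrary,
    paired: bool = False,
    min_overlap: int = 15,
    max_mismatch: int = 2,
    sample_id: str = "sample",
) -> tuple[CountTable, dict[str, int]]:
    """Run merge (optional) -> trim -> translate -> count; return table + report."""
    report = {"reads_in": 0, "merged": 0, "trimmed": 0, "mapped": 0}
    translated: list[str] = []
    for item in reads:
        report["reads_in"] += 1
        if paired:
            fwd, rev = item  # type: ignore[misc]
            merged = merge_read_pair(fwd, rev, min_overlap, max_mismatch)
            if merged is None:
                continue
        else:
            merged = item  # type: ignore[assignment]
        report["merged"] += 1
        coding = trim_coding_region(merged)
        if coding is None:
            continue
        report["trimmed"] += 1
        translated.append(translate_dna(coding))
    table = count_matches(translated, library, sample_id=sample_id)
    report["mapped"] = table.total_mapped
    return table, report


def count_fastq(
    r1: str | Path,
    library: PeptideLibrary,
    r2: str | Path | None = None,
    min_overlap: int = 15,
    max_mismatch: int = 2,
    sample_id: str | None = None,
) -> tuple[CountTable, dict[str, int]]:
    """Count a FASTQ sample (merged single-end, or paired R1/R2)."""
    sid = sample_id or Path(r1).stem
    if r2 is None:
        return process_reads(_read_fastq_seqs(r1), library, sample_id=sid)
    pairs = zip(_read_fastq_seqs(r1), _read_fastq_seqs(r2))
    return process_reads(
        pairs, library, paired=True, min_overlap=min_overlap,
        max_mismatch=max_mismatch, sample_id=sid,
    )
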